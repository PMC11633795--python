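"""Ground-truth deformation construction and warping utilities.

The ground-truth motion is split the way abdominal motion decomposes
clinically:

* **Respiratory motion** — a smooth, SI-dominant field that peaks at the
  diaphragm (the inferior extent of the lung mask), decays toward the
  inferior image boundary, and vanishes toward the posterior spine.  It is a
  separable parametric stand-in for a biomechanical lung model: amplitude ×
  axial (SI) profile × anterior-posterior profile.  Presets low/medium/high
  give 10/20/38 mm peak SI amplitude.
* **Digestive motion** — a hard, uniform translation (default 5 mm in both AP
  and LAT) applied to every voxel of a gastrointestinal organ mask and
  exactly zero outside it.  The field is deliberately discontinuous at the
  mask boundary; the QA correspondence analysis uses the forward field
  directly and never needs to invert it there.

Fields follow the push-forward convention: a material point at planning
position ``p`` lies at ``p + u(p)`` in the deformed anatomy.  Warping an
image therefore requires the inverse displacement, obtained by fixed-point
iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import AP, LR, SI, PULLBACK, PUSHFORWARD, ImageVolume, VectorField, zero_field_like
from .phantom import StructureSet

#: peak SI amplitude (mm) of the named respiratory presets
RESPIRATORY_PRESETS = {"low": 10.0, "medium": 20.0, "high": 38.0}


@dataclass(frozen=True)
class RespiratoryPreset:
    name: str
    amplitude_mm: float

    @staticmethod
    def from_name(name: str) -> "RespiratoryPreset":
        if name not in RESPIRATORY_PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(RESPIRATORY_PRESETS)}")
        return RespiratoryPreset(name, RESPIRATORY_PRESETS[name])


def _resolve_amplitude(preset) -> float:
    if isinstance(preset, RespiratoryPreset):
        return preset.amplitude_mm
    if isinstance(preset, str):
        return RespiratoryPreset.from_name(preset).amplitude_mm
    return float(preset)


def max_gradient(f: VectorField) -> float:
    """Largest |finite-difference gradient| of any component along any axis."""
    g = 0.0
    for c in range(3):
        for ax in range(3):
            d = np.diff(f.u[..., c], axis=ax) / f.spacing[ax]
            if d.size:
                g = max(g, float(np.abs(d).max()))
    return g


def respiratory_field(
    geometry: ImageVolume | VectorField,
    preset: "RespiratoryPreset | str | float",
    structures: StructureSet,
    si_sigma_mm: float = 40.0,
    ap_ramp_mm: float = 80.0,
) -> VectorField:
    """Smooth SI-dominant respiratory field peaking at the diaphragm plane.

    ``u_SI(y, z) = -A · exp(-(z - z_d)² / 2σ_z²) · w(y)`` where ``z_d`` is the
    inferior extent of the lung mask and ``w`` is a raised-cosine ramp from 1
    anteriorly down to 0 at the anterior edge of the spine (so the spine and
    everything posterior to it stay put).  The sign is negative: inhalation
    pushes the diaphragm and abdomen inferiorly.  AP and LR components are
    zero.

    Raises if the analytic gradient bound ``max |∂u/∂x| < 1`` would be
    violated — such a field would fold and could not be inverted.
    """
    amplitude = _resolve_amplitude(preset)
    f = zero_field_like(geometry)
    if amplitude == 0.0:
        return f
    for name in ("lung", "spine"):
        if name not in structures:
            raise ValueError(f"respiratory field needs a {name!r} mask")

    # invertibility: max slope of the Gaussian is A·e^{-1/2}/σ, of the cosine
    # ramp A·π/(2L); both must stay below 1
    g_si = amplitude * np.exp(-0.5) / si_sigma_mm
    g_ap = amplitude * np.pi / (2.0 * ap_ramp_mm)
    if max(g_si, g_ap) >= 1.0:
        raise ValueError(
            f"amplitude {amplitude} mm too large for si_sigma={si_sigma_mm} mm / "
            f"ap_ramp={ap_ramp_mm} mm (gradient bound {max(g_si, g_ap):.2f} >= 1); "
            "increase the decay lengths"
        )

    lung_idx = np.argwhere(structures["lung"])
    z_d = structures.origin[SI] + lung_idx[:, SI].min() * structures.spacing[SI]
    spine_idx = np.argwhere(structures["spine"])
    y_spine = structures.origin[AP] + spine_idx[:, AP].min() * structures.spacing[AP]

    shape = f.shape
    z = geometry.origin[SI] + np.arange(shape[SI]) * geometry.spacing[SI]
    y = geometry.origin[AP] + np.arange(shape[AP]) * geometry.spacing[AP]
    axial = np.exp(-((z - z_d) ** 2) / (2.0 * si_sigma_mm**2))
    ramp = np.clip((y - (y_spine - ap_ramp_mm)) / ap_ramp_mm, 0.0, 1.0)
    w = 0.5 * (1.0 + np.cos(np.pi * ramp))

    f.u[..., SI] = -amplitude * w[None, :, None] * axial[None, None, :]
    if max_gradient(f) >= 1.0:  # belt and braces on the discrete lattice
        raise ValueError("discrete gradient bound violated; increase decay lengths")
    return f


def digestive_shift(
    geometry: ImageVolume | VectorField,
    mask: np.ndarray,
    shift_ap_mm: float = 5.0,
    shift_lr_mm: float = 5.0,
    feather_mm: float = 0.0,
) -> VectorField:
    """Uniform AP/LAT translation applied to every voxel of an organ mask.

    Exactly ``(u_LR, u_AP, u_SI) = (shift_lr, shift_ap, 0)`` inside the mask
    and zero outside.  ``feather_mm > 0`` optionally smooths the indicator at
    the boundary (a deviation from the hard uniform shift; off by default).
    """
    f = zero_field_like(geometry)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(f.shape):
        raise ValueError(f"mask shape {mask.shape} does not match geometry {f.shape}")
    if not mask.any():
        warnings.warn("digestive_shift: empty mask, returning zero field", stacklevel=2)
        return f
    if feather_mm > 0:
        w = gaussian_filter(mask.astype(float), feather_mm / f.spacing)
    else:
        w = mask.astype(float)
    f.u[..., LR] = w * shift_lr_mm
    f.u[..., AP] = w * shift_ap_mm
    return f


def combine(fields: list[VectorField]) -> VectorField:
    """Voxelwise vector sum of displacement fields sharing one geometry."""
    if not fields:
        raise ValueError("no fields to combine")
    first = fields[0]
    out = first.copy()
    for f in fields[1:]:
        if not first.same_geometry(f):
            raise ValueError("cannot combine fields with mismatched geometry")
        if f.convention != first.convention:
            raise ValueError("cannot combine fields with mixed conventions")
        out.u += f.u
    return out


def invert_dvf(f: VectorField, iters: int = 50, tol_mm: float = 0.01) -> VectorField:
    """Invert a displacement field by fixed-point iteration.

    Iterates ``v_{k+1}(p) = -u(p + v_k(p))`` until the max update falls below
    ``tol_mm`` or ``iters`` is reached.  Converges wherever the field is
    smooth (gradient bound < 1); near hard discontinuities such as the
    digestive-shift boundary the residual may stay finite — inspect it with
    :func:`composition_residual`.

    The returned field carries the opposite convention label: the inverse of
    a push-forward field is the resampling (pull-back) field and vice versa.
    """
    points = f.voxel_centers()
    v = -f.u.reshape(-1, 3)
    for _ in range(iters):
        v_new = -f.sample(points + v, mode="nearest")
        delta = np.abs(v_new - v).max()
        v = v_new
        if delta < tol_mm:
            break
    conv = PULLBACK if f.convention == PUSHFORWARD else PUSHFORWARD
    return VectorField(v.reshape(f.u.shape), f.origin.copy(), f.spacing.copy(), convention=conv)


def composition_residual(f: VectorField, inv: VectorField) -> np.ndarray:
    """Per-voxel ‖u(p + v(p)) + v(p)‖ — how far f∘inv is from the identity."""
    points = f.voxel_centers()
    v = inv.u.reshape(-1, 3)
    r = f.sample(points + v, mode="nearest") + v
    return np.linalg.norm(r, axis=1).reshape(f.shape)


_FILL = {"intensity": -1000.0, "mask": 0.0, "dose": 0.0}


def warp_image(
    img: ImageVolume,
    f: VectorField,
    mode: str = "intensity",
    inverse: VectorField | None = None,
    iters: int = 50,
    tol_mm: float = 0.01,
) -> ImageVolume:
    """Warp an image by a displacement field.

    For a push-forward field the warped image is ``deformed(x) = img(x +
    f⁻¹(x))``, with the inverse displacement obtained by fixed-point
    iteration (or supplied precomputed via ``inverse``).  A pull-back field
    is used directly as the resampling displacement.  Interpolation is
    trilinear for ``intensity``/``dose`` (fill −1000 / 0 HU·cGy outside the
    field of view) and nearest-neighbor for ``mask`` (fill 0).
    """
    if mode not in _FILL:
        raise ValueError(f"mode must be one of {sorted(_FILL)}")
    if not img.same_geometry(f):
        raise ValueError("image and field geometry mismatch")
    if f.convention == PUSHFORWARD:
        v = inverse if inverse is not None else invert_dvf(f, iters=iters, tol_mm=tol_mm)
    else:
        v = f
    points = img.voxel_centers() + v.u.reshape(-1, 3)
    order = 0 if mode == "mask" else 1
    vals = img.sample(points, order=order, fill=_FILL[mode])
    return ImageVolume(vals.reshape(img.shape), img.origin.copy(), img.spacing.copy())


def warp_structures(
    structures: StructureSet, f: VectorField, inverse: VectorField | None = None
) -> StructureSet:
    """Warp every mask of a structure set (nearest-neighbor)."""
    if f.convention == PUSHFORWARD and inverse is None:
        inverse = invert_dvf(f)
    out = {}
    for name, m in structures.masks.items():
        img = ImageVolume(m.astype(float), structures.origin, structures.spacing)
        out[name] = warp_image(img, f, mode="mask", inverse=inverse).data > 0.5
    return StructureSet(out, structures.origin.copy(), structures.spacing.copy())


def ground_truth_field(
    geometry: ImageVolume | VectorField,
    structures: StructureSet,
    preset: "RespiratoryPreset | str | float" = "high",
    shift_ap_mm: float = 5.0,
    shift_lr_mm: float = 5.0,
    digestive_rois: tuple[str, ...] = ("stomach_duodenum", "small_bowel"),
    **resp_kwargs,
) -> VectorField:
    """The full ground-truth DVF: respiratory field + per-organ digestive shifts."""
    parts = [respiratory_field(geometry, preset, structures, **resp_kwargs)]
    for roi in digestive_rois:
        parts.append(digestive_shift(geometry, structures[roi], shift_ap_mm, shift_lr_mm))
    return combine(parts)
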