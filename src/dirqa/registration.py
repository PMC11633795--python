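"""The candidate DIR under test: rigid spine pre-alignment + demons.

Commercial registration engines cannot be reimplemented, so the package
ships a classical multi-resolution demons registration (via SimpleITK's
symmetric-forces demons filter) as a reproducible candidate, and treats any
externally produced DVF as a first-class input through :func:`import_dvf` —
which is the actual clinical QA use-case.

Conventions: :func:`demons_register` internally estimates the resampling
(pull-back) field ``d`` on the fixed grid with ``moving(x + d(x)) ≈
fixed(x)`` and returns its fixed-point inverse, i.e. a canonical
push-forward field mapping moving-anatomy positions to fixed-anatomy
positions.  With ``fixed`` = deformed CT and ``moving`` = planning CT this
is directly comparable to the ground-truth DVF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import binary_dilation

from .core import PULLBACK, PUSHFORWARD, ImageVolume, VectorField, read_dvf
from .deform import invert_dvf


@dataclass
class RegistrationParams:
    """Multi-resolution demons settings.

    ``levels`` coarse-to-fine pyramid levels (shrink factors 2^(levels-1)…1);
    ``iterations`` demons iterations per level; ``update_sigma_vox`` /
    ``field_sigma_vox`` Gaussian smoothing (in voxels of the current level)
    of the update step and the accumulated field.
    """

    levels: int = 3
    iterations: tuple[int, ...] = (100, 60, 30)
    update_sigma_vox: float = 1.0
    field_sigma_vox: float = 1.5
    intensity_difference_threshold: float = 0.001

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.update_sigma_vox < 0 or self.field_sigma_vox < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if len(self.iterations) < self.levels:
            self.iterations = tuple(self.iterations) + (self.iterations[-1],) * (
                self.levels - len(self.iterations)
            )


# ---------------------------------------------------------------- rigid stage

def rigid_prealign(
    fixed: ImageVolume,
    moving: ImageVolume,
    spine_mask: np.ndarray,
    search_mm: float = 12.0,
    dilate_vox: int = 2,
) -> np.ndarray:
    """Translation-only alignment of the bony anatomy (spine).

    Exhaustive integer-voxel search maximizing normalized cross-correlation
    over the (dilated) spine mask, refined per axis by a quadratic fit to the
    correlation surface.  Returns the translation ``t`` (mm) such that
    ``moving(x + t) ≈ fixed(x)``.
    """
    if not fixed.same_geometry(moving):
        raise ValueError("fixed and moving must share a lattice for the rigid search")
    spine_mask = np.asarray(spine_mask, dtype=bool)
    if not spine_mask.any():
        raise ValueError("spine mask is empty")
    if dilate_vox > 0:
        spine_mask = binary_dilation(spine_mask, iterations=dilate_vox)

    radius = np.maximum(1, np.ceil(search_mm / fixed.spacing).astype(int))
    shape = np.array(fixed.shape)
    idx = np.argwhere(spine_mask)
    keep = np.all((idx >= radius) & (idx < shape - radius), axis=1)
    idx = idx[keep]
    if idx.shape[0] == 0:
        raise ValueError("spine mask too close to the volume edge for the search radius")

    fvals = fixed.data[tuple(idx.T)]
    fvals = fvals - fvals.mean()
    fnorm = np.sqrt((fvals**2).sum())

    offsets = [np.arange(-r, r + 1) for r in radius]
    ncc = np.empty([len(o) for o in offsets])
    for a, da in enumerate(offsets[0]):
        for b, db in enumerate(offsets[1]):
            for c, dc in enumerate(offsets[2]):
                mv = moving.data[idx[:, 0] + da, idx[:, 1] + db, idx[:, 2] + dc]
                mv = mv - mv.mean()
                denom = fnorm * np.sqrt((mv**2).sum())
                ncc[a, b, c] = (fvals * mv).sum() / denom if denom > 0 else -1.0

    best = np.unravel_index(np.argmax(ncc), ncc.shape)
    shift_vox = np.array([offsets[a][best[a]] for a in range(3)], dtype=float)
    if ncc[best] >= 1.0 - 1e-9:  # exact match; refinement would only add bias
        return shift_vox * fixed.spacing
    # sub-voxel refinement: 1-D parabola through the peak along each axis
    for a in range(3):
        if 0 < best[a] < ncc.shape[a] - 1:
            sl = list(best)
            sl[a] = slice(best[a] - 1, best[a] + 2)
            c0, c1, c2 = ncc[tuple(sl)]
            denom = c0 - 2 * c1 + c2
            if denom < 0:
                shift_vox[a] += 0.5 * (c0 - c2) / denom
    return shift_vox * fixed.spacing


# -------------------------------------------------------------- demons stage

def _to_sitk(img: ImageVolume) -> sitk.Image:
    im = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(img.data, (2, 1, 0)).astype(np.float32))
    )
    im.SetOrigin(tuple(img.origin))
    im.SetSpacing(tuple(img.spacing))
    return im


def _shrink(image: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return image
    smoothed = sitk.SmoothingRecursiveGaussian(image, [0.5 * factor * s for s in image.GetSpacing()])
    return sitk.Shrink(smoothed, [factor] * 3)


def _demons_pullback(
    fixed: ImageVolume, moving: ImageVolume, params: RegistrationParams
) -> VectorField:
    """Raw demons output: pull-back field d with moving(x + d(x)) ≈ fixed(x)."""
    for img in (fixed, moving):
        if not np.all(np.isfinite(img.data)):
            raise ValueError("non-finite intensities")
    if not fixed.same_geometry(moving):
        raise ValueError("fixed and moving must share a lattice (apply rigid stage first)")

    f_full, m_full = _to_sitk(fixed), _to_sitk(moving)
    filt = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    filt.SetIntensityDifferenceThreshold(params.intensity_difference_threshold)
    if params.field_sigma_vox > 0:
        filt.SetSmoothDisplacementField(True)
        filt.SetStandardDeviations(params.field_sigma_vox)
    if params.update_sigma_vox > 0:
        filt.SetSmoothUpdateField(True)
        filt.SetUpdateFieldStandardDeviations(params.update_sigma_vox)

    df = None
    factors = [2 ** (params.levels - 1 - i) for i in range(params.levels)]
    for level, factor in enumerate(factors):
        f_l, m_l = _shrink(f_full, factor), _shrink(m_full, factor)
        if df is None:
            df = sitk.Image(f_l.GetSize(), sitk.sitkVectorFloat64)
            df.CopyInformation(f_l)
        else:
            df = sitk.Resample(df, f_l, sitk.Transform(), sitk.sitkLinear)
        filt.SetNumberOfIterations(int(params.iterations[level]))
        df = filt.Execute(f_l, m_l, df)
    if factors[-1] != 1:
        df = sitk.Resample(df, f_full, sitk.Transform(), sitk.sitkLinear)

    u = np.transpose(sitk.GetArrayFromImage(df), (2, 1, 0, 3)).astype(float)
    return VectorField(u, fixed.origin.copy(), fixed.spacing.copy(), convention=PULLBACK)


def demons_register(
    fixed: ImageVolume, moving: ImageVolume, params: RegistrationParams | None = None
) -> VectorField:
    """Multi-resolution symmetric-forces demons; returns a push-forward DVF.

    Deterministic: the demons update is purely gradient-driven, with no
    random sampling.
    """
    params = params or RegistrationParams()
    return invert_dvf(_demons_pullback(fixed, moving, params))


def register(
    fixed: ImageVolume,
    moving: ImageVolume,
    spine_mask: np.ndarray | None = None,
    params: RegistrationParams | None = None,
) -> tuple[VectorField, np.ndarray]:
    """Rigid spine pre-alignment followed by demons; the clinical pipeline.

    The rigid translation t (moving(x + t) ≈ fixed(x)) is composed exactly
    with the demons pull-back field — moving(x + d(x) + t) ≈ fixed(x) ⇒
    d_total = d + t — before the final inversion to push-forward.  Returns
    the push-forward DVF and the rigid translation (mm).
    """
    params = params or RegistrationParams()
    t = np.zeros(3)
    if spine_mask is not None and np.asarray(spine_mask).any():
        t = rigid_prealign(fixed, moving, spine_mask)
    if np.any(np.abs(t) > 1e-9):
        shifted = ImageVolume(moving.data, moving.origin - t, moving.spacing)
        # resample onto the fixed lattice so demons sees aligned inputs
        pts = fixed.voxel_centers()
        data = shifted.sample(pts, order=1, fill=-1000.0).reshape(fixed.shape)
        moving_aligned = ImageVolume(data, fixed.origin.copy(), fixed.spacing.copy())
    else:
        moving_aligned = moving
    pullback = _demons_pullback(fixed, moving_aligned, params)
    pullback.u += t
    return invert_dvf(pullback), t


# ------------------------------------------------------------------- imports

def import_dvf(path, declared_convention: str | None = None) -> VectorField:
    """Load an externally produced DVF and canonicalize it.

    The sidecar (or ``declared_convention``) must state push-forward or
    pull-back; pull-back fields are converted by fixed-point inversion.
    Component order is restored to (LR, AP, SI) from the sidecar metadata.
    """
    f = read_dvf(path, declared_convention)
    if f.convention == PULLBACK:
        f = invert_dvf(f)
        assert f.convention == PUSHFORWARD
    return f
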