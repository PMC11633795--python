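"""Synthetic abdominal phantom: CT-like anatomy, ROI masks, analytic dose.

The phantom is deliberately stylized — ellipsoids and tubes, not patient
anatomy — because every downstream QA quantity depends only on masks,
intensities and geometry, never on anatomical realism.  It provides the same
inputs a planning CT, an RT-structure set and a recalculated plan would:

* a body of soft tissue (~40 HU) containing lung (~-700 HU), a spine column
  (~700 HU), a GTV seated just anterior to the spine, and two gastrointestinal
  organs (stomach+duodenum, small bowel);
* smooth intra-body intensity texture plus white noise, so that an
  intensity-based registration has something to lock onto;
* an analytic multi-level dose cloud (dose painting: a broad kernel at the
  lower prescription level plus tighter boost kernels) evaluated directly at
  physical coordinates.

All shapes are parameterized as fractions of the physical extent, so any grid
of at least 32 voxels per axis produces a consistent phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ImageVolume, VectorField

REQUIRED_STRUCTURES = ("body", "lung", "spine", "gtv", "stomach_duodenum", "small_bowel")

#: organs that must be pairwise disjoint
_DISJOINT = ("gtv", "stomach_duodenum", "small_bowel")


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # intensities (HU)
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_lung: float = -700.0
    hu_spine: float = 700.0
    hu_gtv: float = 60.0
    hu_stomach: float = 0.0
    hu_bowel: float = 20.0
    noise_sigma_hu: float = 20.0
    # smooth soft-tissue heterogeneity inside the body
    texture_sigma_hu: float = 60.0
    texture_scale_mm: float = 8.0
    # invariant parameters
    max_gtv_spine_distance_mm: float = 30.0
    stomach_volume_range_cm3: tuple[float, float] = (40.0, 90.0)

    def validate(self) -> None:
        if any(n < 32 for n in self.shape):
            raise ValueError(f"grid dims must be >= 32 per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")


@dataclass
class StructureSet:
    """Named binary ROI masks sharing one lattice geometry."""

    masks: dict[str, np.ndarray]
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks do not share a lattice: {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.masks.values())).shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_cm3(self, name: str) -> float:
        return self.masks[name].sum() * self.voxel_volume_mm3 / 1000.0

    def centroid_mm(self, name: str) -> np.ndarray:
        idx = np.argwhere(self.masks[name])
        if idx.size == 0:
            raise ValueError(f"mask {name!r} is empty")
        return self.origin + idx.mean(axis=0) * self.spacing

    def validate(self, max_gtv_spine_distance_mm: float = 30.0) -> None:
        """Check the structure-set invariants; raise on violation."""
        for name in REQUIRED_STRUCTURES:
            if name not in self.masks:
                raise ValueError(f"missing required structure {name!r}")
        body = self.masks["body"]
        for name, m in self.masks.items():
            if name != "body" and np.any(m & ~body):
                raise ValueError(f"structure {name!r} extends outside the body")
        for i, a in enumerate(_DISJOINT):
            for b in _DISJOINT[i + 1 :]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"structures {a!r} and {b!r} overlap")
        c = self.centroid_mm("gtv")
        spine_pts = self.origin + np.argwhere(self.masks["spine"]) * self.spacing
        d = np.min(np.linalg.norm(spine_pts - c, axis=1))
        if d > max_gtv_spine_distance_mm:
            raise ValueError(
                f"GTV centroid is {d:.1f} mm from the spine "
                f"(limit {max_gtv_spine_distance_mm} mm)"
            )


@dataclass
class PlanPrescription:
    """Ordered prescription dose levels in cGy; the highest is the reference."""

    levels: list[float]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("prescription needs at least one dose level")
        if any(lv <= 0 for lv in self.levels):
            raise ValueError("dose levels must be positive")
        self.levels = sorted(float(lv) for lv in self.levels)

    @property
    def highest_level(self) -> float:
        return self.levels[-1]


@dataclass
class DoseModel:
    """Static analytic dose cloud: Gaussian boost kernels plus a low-dose bath.

    The dose is a function of physical coordinates only — it never depends on
    the lattice used to sample it nor on the anatomy.  Sampling it at
    displacement-corresponded points therefore isolates exactly the dose error
    a registration error would introduce into dose accumulation.
    """

    components: list[tuple[np.ndarray, float, float]]  # (center mm, scale mm, peak cGy)
    bath_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bath_scale_mm: float = 120.0
    bath_peak_cgy: float = 0.0

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Dose (cGy) at (N, 3) physical points."""
        pts = np.asarray(points, dtype=float)
        d = self.bath_peak_cgy * np.exp(
            -np.sum((pts - self.bath_center) ** 2, axis=-1) / (2.0 * self.bath_scale_mm**2)
        )
        for center, scale, peak in self.components:
            d = d + peak * np.exp(-np.sum((pts - center) ** 2, axis=-1) / (2.0 * scale**2))
        return d

    def to_dict(self) -> dict:
        return {
            "components": [
                {"center_mm": list(map(float, c)), "scale_mm": float(s), "peak_cgy": float(p)}
                for c, s, p in self.components
            ],
            "bath_center_mm": list(map(float, self.bath_center)),
            "bath_scale_mm": float(self.bath_scale_mm),
            "bath_peak_cgy": float(self.bath_peak_cgy),
        }

    @staticmethod
    def from_dict(d: dict) -> "DoseModel":
        return DoseModel(
            [
                (np.asarray(c["center_mm"], dtype=float), float(c["scale_mm"]), float(c["peak_cgy"]))
                for c in d["components"]
            ],
            bath_center=np.asarray(d["bath_center_mm"], dtype=float),
            bath_scale_mm=float(d["bath_scale_mm"]),
            bath_peak_cgy=float(d["bath_peak_cgy"]),
        )

    def lipschitz_bound_cgy_per_mm(self) -> float:
        """Upper bound on |∇dose|: sum of each kernel's max gradient."""
        g = self.bath_peak_cgy * np.exp(-0.5) / self.bath_scale_mm
        for _, scale, peak in self.components:
            g += abs(peak) * np.exp(-0.5) / scale
        return float(g)


# --------------------------------------------------------------------- phantom

def _ellipsoid(coords, center_frac, radii_frac, span, origin):
    x, y, z = coords
    c = origin + np.asarray(center_frac) * span
    r = np.asarray(radii_frac) * span
    return ((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2 + ((z - c[2]) / r[2]) ** 2 <= 1.0


def generate_phantom(
    config: PhantomConfig | None = None, seed: int = 0
) -> tuple[ImageVolume, StructureSet]:
    """Build the CT-like volume and its structure set, deterministically.

    Identical ``(config, seed)`` give a bit-identical phantom.
    """
    cfg = config or PhantomConfig()
    cfg.validate()
    shape = tuple(cfg.shape)
    spacing = np.asarray(cfg.spacing, dtype=float)
    origin = np.asarray(cfg.origin, dtype=float)
    span = (np.array(shape) - 1) * spacing

    ii = np.indices(shape, dtype=float)
    coords = [origin[a] + ii[a] * spacing[a] for a in range(3)]
    x, y, z = coords

    # body: elliptical cylinder spanning nearly the full SI extent
    cb = origin + np.array([0.5, 0.5, 0.0]) * span
    body = (
        (((x - cb[0]) / (0.41 * span[0])) ** 2 + ((y - cb[1]) / (0.35 * span[1])) ** 2 <= 1.0)
        & (z >= origin[2] + 0.02 * span[2])
        & (z <= origin[2] + 0.98 * span[2])
    )

    # two lung ellipsoids in the superior part; their inferior extent is the
    # diaphragm plane used by the respiratory motion model
    lung = _ellipsoid(coords, (0.32, 0.45, 0.79), (0.16, 0.22, 0.17), span, origin) | _ellipsoid(
        coords, (0.68, 0.45, 0.79), (0.16, 0.22, 0.17), span, origin
    )
    lung &= body

    # posterior spine column
    cs = origin + np.array([0.5, 0.79, 0.0]) * span
    spine = (
        (((x - cs[0]) / (0.075 * span[0])) ** 2 + ((y - cs[1]) / (0.065 * span[1])) ** 2 <= 1.0)
        & body
    )

    gtv = _ellipsoid(coords, (0.5, 0.63, 0.5), (0.063, 0.063, 0.063), span, origin)
    stomach = _ellipsoid(coords, (0.34, 0.395, 0.55), (0.147, 0.116, 0.132), span, origin)
    bowel = _ellipsoid(coords, (0.53, 0.37, 0.29), (0.20, 0.137, 0.147), span, origin)

    # enforce containment and pairwise disjointness by construction
    gtv &= body & ~spine & ~lung
    stomach &= body & ~spine & ~lung & ~gtv
    bowel &= body & ~spine & ~lung & ~gtv & ~stomach

    ct = np.full(shape, cfg.hu_air)
    ct[body] = cfg.hu_soft
    ct[stomach] = cfg.hu_stomach
    ct[bowel] = cfg.hu_bowel
    ct[lung] = cfg.hu_lung
    ct[gtv] = cfg.hu_gtv
    ct[spine] = cfg.hu_spine

    rng = np.random.default_rng(seed)
    if cfg.texture_sigma_hu > 0:
        tex = gaussian_filter(rng.standard_normal(shape), sigma=cfg.texture_scale_mm / spacing)
        tex *= cfg.texture_sigma_hu / tex.std()
        ct[body & ~lung & ~spine] += tex[body & ~lung & ~spine]
    if cfg.noise_sigma_hu > 0:
        ct += rng.normal(0.0, cfg.noise_sigma_hu, shape)

    structures = StructureSet(
        {
            "body": body,
            "lung": lung,
            "spine": spine,
            "gtv": gtv,
            "stomach_duodenum": stomach,
            "small_bowel": bowel,
        },
        origin,
        spacing,
    )
    structures.validate(cfg.max_gtv_spine_distance_mm)
    return ImageVolume(ct, origin, spacing), structures


# ------------------------------------------------------------------ dose model

def build_dose_model(
    structures: StructureSet,
    rx: PlanPrescription,
    outer_scale_mm: float = 30.0,
    scale_shrink: float = 0.45,
    bath_fraction: float = 0.10,
) -> DoseModel:
    """Construct the analytic dose cloud for a (possibly multi-level) plan.

    Level ``i`` contributes a Gaussian kernel of peak ``levels[i] -
    levels[i-1]`` centered on the GTV centroid, with scales shrinking inward —
    a dose-painting pattern: the lowest level covers a broad region, each boost
    a tighter one.  A wide low-dose bath (default 10% of the highest level)
    represents scatter/entrance dose.  By construction the dose at the GTV
    centroid is ``highest_level * (1 + bath_fraction)``, so the maximum over
    the GTV exceeds the highest prescription.
    """
    if "gtv" not in structures:
        raise ValueError("structure set has no 'gtv' mask; cannot center the dose model")
    center = structures.centroid_mm("gtv")
    increments = np.diff([0.0] + list(rx.levels))
    components = [
        (center.copy(), outer_scale_mm * scale_shrink**i, float(inc))
        for i, inc in enumerate(increments)
    ]
    return DoseModel(
        components,
        bath_center=center.copy(),
        bath_peak_cgy=bath_fraction * rx.highest_level,
    )


def evaluate_dose(model: DoseModel, geometry: ImageVolume | VectorField) -> ImageVolume:
    """Sample the dose cloud at every voxel center of ``geometry`` (cGy)."""
    dose = model.evaluate(geometry.voxel_centers()).reshape(geometry.shape)
    return ImageVolume(dose, geometry.origin.copy(), geometry.spacing.copy())
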