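"""Geometric QA: candidate-vs-ground-truth DVF comparison.

All comparisons happen on a common *analysis grid*: 1 mm isotropic, origin
aligned with the reference lattice, covering the intersection of the two
fields' physical extents (snapped outward to whole mm; analysis-grid voxels
that fall outside a source extent are flagged invalid and excluded from
statistics rather than filled).

The per-voxel magnitude error is the Euclidean norm of the componentwise
difference between candidate and ground-truth displacement, components
matched by anatomical label (LR, AP, SI).  ROI statistics (mean, 90th
percentile, max, histogram) are computed over planning-space ROIs moved to
the analysis grid by nearest-neighbor resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .core import ImageVolume, VectorField
from .phantom import StructureSet

ANALYSIS_SPACING_MM = 1.0

#: the ROIs reported by default: entire body plus tumor and GI organs
DEFAULT_ROIS = ("body", "gtv", "stomach_duodenum", "small_bowel")


@dataclass
class ErrorMap:
    """Per-voxel DVF magnitude error (mm) on the 1 mm³ analysis grid."""

    data: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    valid: np.ndarray  # analysis voxels inside both source extents
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.allclose(self.spacing, ANALYSIS_SPACING_MM):
            raise ValueError(f"error maps live on the 1 mm analysis grid, got {self.spacing}")
        if np.any(self.data[self.valid] < 0):
            raise ValueError("magnitude errors must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class ROIStats:
    """Summary of a scalar map over one ROI."""

    roi: str
    mean: float
    p90: float
    max: float
    count: int
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    def as_dict(self) -> dict:
        return {
            "roi": self.roi,
            "mean": self.mean,
            "p90": self.p90,
            "max": self.max,
            "count": self.count,
            "hist_edges": self.hist_edges.tolist(),
            "hist_counts": self.hist_counts.tolist(),
        }


# ------------------------------------------------------------------ resampling

def analysis_geometry(
    f: VectorField | ImageVolume, reference: VectorField | ImageVolume
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Origin and shape of the 1 mm analysis grid for a field/reference pair.

    Grid points sit at ``reference.origin + integer mm``; the bounding box is
    the intersection of the two physical extents snapped outward to whole mm.
    """
    lo_f, hi_f = f.extent()
    lo_r, hi_r = reference.extent()
    lo = np.maximum(lo_f, lo_r)
    hi = np.minimum(hi_f, hi_r)
    if np.any(hi < lo):
        raise ValueError("field and reference physical extents are disjoint")
    start = reference.origin + np.floor(lo - reference.origin)
    stop = reference.origin + np.ceil(hi - reference.origin)
    shape = tuple(int(n) + 1 for n in np.round(stop - start))
    return start, shape


def resample_to_analysis_grid(
    f: VectorField, reference: VectorField | ImageVolume | None = None
) -> VectorField:
    """Trilinearly resample a DVF onto the 1 mm isotropic analysis grid.

    Vector components are interpolated independently and never re-oriented
    (axes are already canonical).  The returned field carries a ``valid``
    boolean array marking voxels inside both source extents.  A field already
    on the target grid is returned as an identical copy (no resampling).
    """
    reference = reference if reference is not None else f
    origin, shape = analysis_geometry(f, reference)
    spacing = np.full(3, ANALYSIS_SPACING_MM)

    if (
        tuple(f.shape) == shape
        and np.array_equal(f.origin, origin)
        and np.allclose(f.spacing, spacing)
    ):
        out = f.copy()
        out.valid = np.ones(shape, dtype=bool)  # type: ignore[attr-defined]
        return out

    idx_grid = np.indices(shape, dtype=float)
    phys = [origin[a] + idx_grid[a] * ANALYSIS_SPACING_MM for a in range(3)]
    src_idx = np.stack([(phys[a] - f.origin[a]) / f.spacing[a] for a in range(3)])
    u = np.empty(shape + (3,))
    for c in range(3):
        u[..., c] = map_coordinates(f.u[..., c], src_idx, order=1, mode="nearest")
    out = VectorField(u, origin, spacing, convention=f.convention)
    lo_f, hi_f = f.extent()
    valid = np.ones(shape, dtype=bool)
    for a in range(3):
        valid &= (phys[a] >= lo_f[a] - 1e-9) & (phys[a] <= hi_f[a] + 1e-9)
    out.valid = valid  # type: ignore[attr-defined]
    return out


def resample_mask_to(
    mask: np.ndarray,
    src_origin: np.ndarray,
    src_spacing: np.ndarray,
    origin: np.ndarray,
    spacing: np.ndarray,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Nearest-neighbor mask transfer between lattices."""
    idx_grid = np.indices(shape, dtype=float)
    src_idx = np.stack(
        [
            (origin[a] + idx_grid[a] * spacing[a] - src_origin[a]) / src_spacing[a]
            for a in range(3)
        ]
    )
    return map_coordinates(mask.astype(np.uint8), src_idx, order=0, mode="constant", cval=0) > 0


# ----------------------------------------------------------------- error maps

def _valid_of(f: VectorField) -> np.ndarray:
    return getattr(f, "valid", np.ones(f.shape, dtype=bool))


def magnitude_error_map(candidate: VectorField, truth: VectorField) -> ErrorMap:
    """Per-voxel Euclidean norm of the candidate-minus-truth DVF difference."""
    if tuple(candidate.shape) != tuple(truth.shape) or not np.allclose(
        candidate.origin, truth.origin
    ):
        raise ValueError("candidate and truth must be on the same analysis grid")
    err = np.linalg.norm(candidate.u - truth.u, axis=-1)
    valid = _valid_of(candidate) & _valid_of(truth)
    return ErrorMap(
        err,
        candidate.origin.copy(),
        candidate.spacing.copy(),
        valid,
        provenance={"kind": "magnitude_error"},
    )


def magnitude_map(f: VectorField) -> ErrorMap:
    """Per-voxel displacement magnitude ‖u‖ as an analysis-grid scalar map."""
    return ErrorMap(
        np.linalg.norm(f.u, axis=-1),
        f.origin.copy(),
        f.spacing.copy(),
        _valid_of(f),
        provenance={"kind": "magnitude"},
    )


def roi_error_stats(
    err: ErrorMap,
    structures: StructureSet,
    rois: tuple[str, ...] = DEFAULT_ROIS,
    hist_bin_width_mm: float = 1.0,
) -> dict[str, ROIStats]:
    """Mean / 90th-percentile / max / histogram of a scalar map per ROI.

    Percentiles use linear interpolation between order statistics.  ROI masks
    are moved from the planning lattice to the analysis grid by
    nearest-neighbor resampling; invalid analysis voxels are excluded.
    """
    out: dict[str, ROIStats] = {}
    for roi in rois:
        m = resample_mask_to(
            structures[roi], structures.origin, structures.spacing, err.origin, err.spacing, err.shape
        )
        m &= err.valid
        vals = err.data[m]
        if vals.size == 0:
            raise ValueError(f"ROI {roi!r} is empty on the analysis grid")
        hi = max(hist_bin_width_mm, float(np.ceil(vals.max() / hist_bin_width_mm)) * hist_bin_width_mm)
        edges = np.arange(0.0, hi + hist_bin_width_mm, hist_bin_width_mm)
        counts, edges = np.histogram(vals, bins=edges)
        out[roi] = ROIStats(
            roi=roi,
            mean=float(vals.mean()),
            p90=float(np.percentile(vals, 90)),
            max=float(vals.max()),
            count=int(vals.size),
            hist_edges=edges,
            hist_counts=counts,
        )
    return out
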