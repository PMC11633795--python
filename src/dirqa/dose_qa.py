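"""Dosimetric QA: the dose error a DIR would introduce into dose accumulation.

The analysis follows a three-step voxel correspondence.  For each planning
voxel A (within the body contour):

1. find its corresponding physical point under the ground-truth DVF
   (A′ = A + u_truth(A)) and under the candidate DVF (A″ = A + u_cand(A));
2. read the recalculated dose at both points — here the "recalculation" is
   the static analytic dose cloud, a function of physical position only, so
   both dose maps are the same function sampled at different correspondence
   points;
3. the signed dose error is dose(A′) − dose(A″) in cGy (ground-truth-side
   minus candidate-side; no absolute values are taken).

The per-ROI panel reports six metrics, all as percentages of the highest
prescription level: Dmax error and Dmin error (differences of the DVH-level
metrics between candidate- and truth-corresponded dose), mean and maximum
(largest-|·| signed value) of the voxel dose errors, their 95th percentile,
and the mean signed error over the worst 1 cm³ of the ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, VectorField
from .phantom import DoseModel, PlanPrescription, StructureSet

SIGN_CONVENTION = "truth_minus_candidate"


@dataclass
class DoseErrorMap:
    """Signed per-voxel dose error (cGy) on the planning grid, voxel-A indexed."""

    error: np.ndarray  # zero outside `region`
    region: np.ndarray  # voxels where the error was evaluated (body contour)
    origin: np.ndarray
    spacing: np.ndarray
    reference_cgy: float  # highest prescription level

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.error)):
            raise ValueError("dose errors must be finite")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DVHMetrics:
    """Dose-volume-histogram summary of one ROI (all doses in cGy)."""

    dmax: float
    dmin: float
    mean: float
    d95: float  # dose received by (at least) 95% of the ROI volume
    v100: float  # % of ROI volume receiving >= 100% of the highest prescription

    def as_dict(self) -> dict:
        return {"dmax": self.dmax, "dmin": self.dmin, "mean": self.mean,
                "d95": self.d95, "v100": self.v100}


@dataclass
class ErrorPanel:
    """The six per-ROI dose-error metrics, % of the highest prescription."""

    roi: str
    dmax_error_pct: float
    dmin_error_pct: float
    mean_error_pct: float
    max_error_pct: float  # signed error with the largest absolute value
    p95_error_pct: float  # 95th percentile of the signed errors
    top_1cc_error_pct: float
    sign_convention: str = SIGN_CONVENTION

    def as_dict(self) -> dict:
        return {
            "roi": self.roi,
            "dmax_error_pct": self.dmax_error_pct,
            "dmin_error_pct": self.dmin_error_pct,
            "mean_error_pct": self.mean_error_pct,
            "max_error_pct": self.max_error_pct,
            "p95_error_pct": self.p95_error_pct,
            "top_1cc_error_pct": self.top_1cc_error_pct,
            "sign_convention": self.sign_convention,
        }


# -------------------------------------------------------------- correspondence

def correspondence_points(
    geometry: ImageVolume | VectorField, f: VectorField
) -> tuple[np.ndarray, np.ndarray]:
    """Physical points p + u(p) for every voxel center p of the planning grid.

    Returns the (N, 3) corresponded points and a boolean flag per point
    marking those that left the field's physical extent.
    """
    if tuple(geometry.shape) != tuple(f.shape):
        raise ValueError("geometry and field shape mismatch")
    pts = geometry.voxel_centers() + f.u.reshape(-1, 3)
    lo, hi = f.extent()
    outside = np.any((pts < lo) | (pts > hi), axis=1)
    return pts, outside


def dose_error_map(
    model: DoseModel,
    f_truth: VectorField,
    f_cand: VectorField,
    region: np.ndarray,
    rx: PlanPrescription,
) -> DoseErrorMap:
    """Signed dose error D(A + u_truth(A)) − D(A + u_cand(A)) over a region."""
    if tuple(f_truth.shape) != tuple(f_cand.shape) or not np.allclose(
        f_truth.origin, f_cand.origin
    ):
        raise ValueError("truth and candidate fields must share the planning lattice")
    region = np.asarray(region, dtype=bool)
    if region.shape != tuple(f_truth.shape):
        raise ValueError("region mask shape mismatch")
    if not region.any():
        raise ValueError("empty evaluation region")

    idx = np.argwhere(region)
    p = f_truth.origin + idx * f_truth.spacing
    d_truth = model.evaluate(p + f_truth.u[region])
    d_cand = model.evaluate(p + f_cand.u[region])
    err = np.zeros(f_truth.shape)
    err[region] = d_truth - d_cand
    return DoseErrorMap(
        err, region, f_truth.origin.copy(), f_truth.spacing.copy(), rx.highest_level
    )


# ----------------------------------------------------------------- DVH metrics

def dvh_metrics(dose, mask: np.ndarray | None, rx: PlanPrescription) -> DVHMetrics:
    """DVH summary of a dose distribution over an ROI.

    ``dose`` may be an :class:`ImageVolume` (with ``mask`` selecting the ROI)
    or a flat array of in-ROI dose samples (``mask=None``).  D95% is the dose
    exceeded by 95% of the ROI volume, i.e. the 5th dose percentile (linear
    interpolation); V100% counts voxels at or above the highest prescription.
    """
    vals = dose.data[np.asarray(mask, dtype=bool)] if mask is not None else np.asarray(dose, dtype=float)
    if vals.size == 0:
        raise ValueError("empty ROI")
    return DVHMetrics(
        dmax=float(vals.max()),
        dmin=float(vals.min()),
        mean=float(vals.mean()),
        d95=float(np.percentile(vals, 5)),
        v100=float(100.0 * np.mean(vals >= rx.highest_level)),
    )


def dose_at_corresponded(
    model: DoseModel, f: VectorField, roi_mask: np.ndarray
) -> np.ndarray:
    """Dose samples D(p + u(p)) for the planning-ROI voxels.

    Equivalent to evaluating the recalculated dose on the warped ROI of the
    deformed CT — the deformed-side ROI analysis — while staying indexed by
    planning voxels.
    """
    idx = np.argwhere(np.asarray(roi_mask, dtype=bool))
    p = f.origin + idx * f.spacing
    return model.evaluate(p + f.u[tuple(idx.T)])


# ---------------------------------------------------------------------- panel

def error_panel(
    e: DoseErrorMap,
    metrics_truth: DVHMetrics,
    metrics_cand: DVHMetrics,
    roi_mask: np.ndarray,
    rx: PlanPrescription,
    roi: str = "",
) -> ErrorPanel:
    """Assemble the six-metric dose-error panel for one ROI.

    Dmax/Dmin errors are DVH-metric-level differences (candidate-side metric
    minus truth-side metric); the remaining four summarize the signed
    voxelwise error distribution.  Everything is normalized to the highest
    prescription level and reported in percent.
    """
    if rx.highest_level <= 0:
        raise ValueError("prescription reference must be positive")
    roi_mask = np.asarray(roi_mask, dtype=bool) & e.region
    vals = e.error[roi_mask]
    if vals.size == 0:
        raise ValueError(f"ROI {roi!r} has no voxels inside the evaluation region")

    n_1cc = int(np.ceil(1000.0 / e.voxel_volume_mm3))
    if vals.size < n_1cc:
        warnings.warn(
            f"ROI {roi!r} smaller than 1 cc; top-1cc uses the whole ROI", stacklevel=2
        )
        top = vals
    else:
        top = vals[np.argsort(np.abs(vals))[-n_1cc:]]

    scale = 100.0 / rx.highest_level
    return ErrorPanel(
        roi=roi,
        dmax_error_pct=(metrics_cand.dmax - metrics_truth.dmax) * scale,
        dmin_error_pct=(metrics_cand.dmin - metrics_truth.dmin) * scale,
        mean_error_pct=float(vals.mean()) * scale,
        max_error_pct=float(vals[np.argmax(np.abs(vals))]) * scale,
        p95_error_pct=float(np.percentile(vals, 95)) * scale,
        top_1cc_error_pct=float(top.mean()) * scale,
    )


def dose_qa_report(
    model: DoseModel,
    f_truth: VectorField,
    f_cand: VectorField,
    structures: StructureSet,
    rx: PlanPrescription,
    rois: tuple[str, ...] = ("gtv", "stomach_duodenum", "small_bowel"),
) -> dict:
    """Run the full dosimetric QA for a set of ROIs.

    Per ROI: DVH metrics of the truth- and candidate-corresponded dose
    (both computed; the ground-truth-corresponded side is the reference) and
    the six-metric error panel.  The voxel error map covers the body contour.
    """
    emap = dose_error_map(model, f_truth, f_cand, structures["body"], rx)
    report: dict = {"sign_convention": SIGN_CONVENTION, "reference_cgy": rx.highest_level}
    panels, dvh = {}, {}
    for roi in rois:
        mask = structures[roi]
        m_truth = dvh_metrics(dose_at_corresponded(model, f_truth, mask), None, rx)
        m_cand = dvh_metrics(dose_at_corresponded(model, f_cand, mask), None, rx)
        panels[roi] = error_panel(emap, m_truth, m_cand, mask, rx, roi=roi)
        dvh[roi] = {"truth": m_truth, "candidate": m_cand}
    body_truth = dvh_metrics(dose_at_corresponded(model, f_truth, structures["body"]), None, rx)
    body_cand = dvh_metrics(dose_at_corresponded(model, f_cand, structures["body"]), None, rx)
    panels["body"] = error_panel(emap, body_truth, body_cand, structures["body"], rx, roi="body")
    dvh["body"] = {"truth": body_truth, "candidate": body_cand}
    report["panels"] = panels
    report["dvh"] = dvh
    report["error_map"] = emap
    return report
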