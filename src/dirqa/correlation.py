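"""Binned correlation analysis: displacement magnitude vs. error statistics.

Voxelwise scatter between displacement magnitude, registration error, and
dose error is extremely noisy, so each relationship is summarized on
equal-width bins of the key quantity (default 75 bins, in the 50-100 range
customary for this analysis).  Per bin: the mean of the tracked statistic
and its *range*, defined as the span between the 25th and 75th percentile of
the in-bin distribution.  The bin's nominal magnitude is the center of its
key interval.  Bins holding fewer voxels than a floor (default 10) are
flagged and excluded from correlation — they carry mostly outlier noise.

Three analyses are run per ROI:

a. ground-truth displacement magnitude → DIR magnitude error,
b. ground-truth displacement magnitude → dose error,
c. DIR magnitude error → dose error,

each correlated (Pearson, on the binned summaries) against both the per-bin
mean and the per-bin range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import VectorField
from .geometry_qa import ErrorMap, resample_mask_to
from .phantom import StructureSet

DEFAULT_N_BINS = 75
DEFAULT_MIN_COUNT = 10

ANALYSES = {
    "magnitude_vs_magnitude_error": ("gt_magnitude", "magnitude_error"),
    "magnitude_vs_dose_error": ("gt_magnitude", "dose_error"),
    "magnitude_error_vs_dose_error": ("magnitude_error", "dose_error"),
}


@dataclass
class BinnedStats:
    """Per-bin summaries of a tracked statistic over equal-width key bins."""

    edges: np.ndarray  # (n_bins + 1,)
    centers: np.ndarray  # nominal magnitude of each bin
    counts: np.ndarray
    mean: np.ndarray
    p25: np.ndarray
    p75: np.ndarray
    retained: np.ndarray  # bins with count >= min_count
    n_total: int
    degenerate: bool = False  # all key values identical -> single bin

    @property
    def range(self) -> np.ndarray:
        return self.p75 - self.p25


@dataclass
class CorrelationResult:
    coefficient: float
    analysis: str  # one of ANALYSES
    against: str  # "mean" | "range"
    roi: str = ""
    n_bins_used: int = 0
    degenerate: bool = False  # zero variance on either axis -> coefficient 0

    def as_dict(self) -> dict:
        return {
            "coefficient": None if self.degenerate else self.coefficient,
            "analysis": self.analysis,
            "against": self.against,
            "roi": self.roi,
            "n_bins_used": self.n_bins_used,
            "degenerate": self.degenerate,
        }


def bin_voxels(
    key: np.ndarray,
    stat: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    bin_width: float | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> BinnedStats:
    """Equal-width binning of ``stat`` by ``key`` with per-bin mean/p25/p75.

    ``bin_width`` (e.g. < 1 mm) overrides ``n_bins``.  If every key value is
    identical the result is a single flagged bin — no correlation can be
    computed from it.
    """
    key = np.asarray(key, dtype=float).ravel()
    stat = np.asarray(stat, dtype=float).ravel()
    if key.shape != stat.shape:
        raise ValueError("key and stat must have equal length")
    if key.size == 0:
        raise ValueError("no voxels to bin")

    lo, hi = float(key.min()), float(key.max())
    if hi == lo:
        return BinnedStats(
            edges=np.array([lo, lo]),
            centers=np.array([lo]),
            counts=np.array([key.size]),
            mean=np.array([stat.mean()]),
            p25=np.array([np.percentile(stat, 25)]),
            p75=np.array([np.percentile(stat, 75)]),
            retained=np.array([True]),
            n_total=key.size,
            degenerate=True,
        )
    if bin_width is not None:
        n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = np.linspace(lo, hi, n_bins + 1)

    which = np.clip(np.searchsorted(edges, key, side="right") - 1, 0, n_bins - 1)
    df = pd.DataFrame({"bin": which, "stat": stat})
    g = df.groupby("bin")["stat"]
    agg = g.agg(
        count="count",
        mean="mean",
        p25=lambda s: s.quantile(0.25),
        p75=lambda s: s.quantile(0.75),
    ).reindex(range(n_bins))

    counts = agg["count"].fillna(0).to_numpy(dtype=int)
    return BinnedStats(
        edges=edges,
        centers=0.5 * (edges[:-1] + edges[1:]),
        counts=counts,
        mean=agg["mean"].to_numpy(dtype=float),
        p25=agg["p25"].to_numpy(dtype=float),
        p75=agg["p75"].to_numpy(dtype=float),
        retained=counts >= min_count,
        n_total=key.size,
    )


def correlate_bins(b: BinnedStats, against: str = "mean") -> CorrelationResult:
    """Pearson correlation between bin nominal magnitudes and a bin statistic.

    Requires at least 3 retained bins.  If either axis has zero variance the
    coefficient is undefined; it is reported as 0 with ``degenerate=True``.
    """
    if against not in ("mean", "range"):
        raise ValueError("against must be 'mean' or 'range'")
    keep = b.retained & (b.counts > 0)
    if keep.sum() < 3:
        raise ValueError(f"only {int(keep.sum())} retained bins; need >= 3 for correlation")
    x = b.centers[keep]
    y = (b.mean if against == "mean" else b.range)[keep]
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(0.0, "", against, n_bins_used=int(keep.sum()), degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r, "", against, n_bins_used=int(keep.sum()))


def run_correlation_suite(
    truth_magnitude: ErrorMap,
    magnitude_error: ErrorMap,
    dose_error: np.ndarray,
    structures: StructureSet,
    rois: tuple[str, ...] = ("body", "gtv", "small_bowel", "stomach_duodenum"),
    n_bins: int = DEFAULT_N_BINS,
    min_count: int = DEFAULT_MIN_COUNT,
) -> dict:
    """The full Table-4-style grid: three analyses × ROIs × {mean, range}.

    All inputs live on the analysis grid: ground-truth magnitude map, DIR
    magnitude-error map, and the signed dose-error array (same lattice).
    Degenerate combinations (e.g. a perfect candidate, where every error is
    zero) are flagged rather than reported as numbers.
    """
    if dose_error.shape != magnitude_error.shape:
        raise ValueError("dose-error array must be on the analysis grid")
    quantities = {
        "gt_magnitude": truth_magnitude.data,
        "magnitude_error": magnitude_error.data,
        "dose_error": dose_error,
    }
    valid = truth_magnitude.valid & magnitude_error.valid
    results: dict[str, dict] = {}
    for roi in rois:
        m = resample_mask_to(
            structures[roi],
            structures.origin,
            structures.spacing,
            magnitude_error.origin,
            magnitude_error.spacing,
            magnitude_error.shape,
        )
        m &= valid
        if not m.any():
            raise ValueError(f"ROI {roi!r} empty on the analysis grid")
        roi_res: dict[str, dict] = {}
        for name, (key_q, stat_q) in ANALYSES.items():
            b = bin_voxels(
                quantities[key_q][m], quantities[stat_q][m], n_bins=n_bins, min_count=min_count
            )
            entry: dict[str, object] = {"bins": b}
            for against in ("mean", "range"):
                if b.degenerate:
                    res = CorrelationResult(0.0, name, against, roi, 1, degenerate=True)
                else:
                    try:
                        res = correlate_bins(b, against)
                    except ValueError:
                        res = CorrelationResult(0.0, name, against, roi, 0, degenerate=True)
                    res.analysis, res.roi = name, roi
                entry[against] = res
            roi_res[name] = entry
        results[roi] = roi_res
    return results
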