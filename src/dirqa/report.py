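"""End-to-end QA workflow orchestration and the machine-readable QA record.

:func:`run_workflow` executes the whole pipeline — phantom, ground-truth
deformation, candidate registration (or an imported/constructed candidate),
geometric QA on the 1 mm analysis grid, dosimetric QA on the planning grid,
and the binned correlation suite — and returns a :class:`QAReport`.  Every
numeric field in the report is the direct output of one upstream operation;
conventions (DVF direction, dose-error sign, percentile method, top-1cc
rule) are embedded so downstream consumers never have to guess.

Given fixed seeds the report is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation as corr
from . import dose_qa, geometry_qa
from .core import PUSHFORWARD, ImageVolume, VectorField, write_image, write_mask
from .deform import ground_truth_field, invert_dvf, warp_image
from .phantom import (
    DoseModel,
    PhantomConfig,
    PlanPrescription,
    StructureSet,
    build_dose_model,
    generate_phantom,
)
from .registration import RegistrationParams, import_dvf, register

log = logging.getLogger("dirqa")

SCHEMA_VERSION = 1

CONVENTIONS = {
    "dvf_direction": PUSHFORWARD,
    "dose_error_sign": dose_qa.SIGN_CONVENTION,
    "percentile_method": "linear interpolation between order statistics",
    "top_1cc_rule": "mean signed error over the 1 cm3 of ROI voxels with largest |error|",
    "body_statistics": "all voxels inside the body mask",
    "units": {"displacement": "mm", "dose": "cGy", "panel": "% of highest prescription"},
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "phantom": {},
    "deformation": {"preset": "high", "shift_ap_mm": 5.0, "shift_lr_mm": 5.0},
    "candidate": {"source": "demons"},
    "registration": {},
    "prescription": {"levels": [4500.0, 7500.0]},
    "bins": corr.DEFAULT_N_BINS,
}


@dataclass
class QAReport:
    metadata: dict
    magnitude_summary: dict[str, geometry_qa.ROIStats]
    error_summary: dict[str, geometry_qa.ROIStats]
    dose_panels: dict[str, dose_qa.ErrorPanel]
    dvh: dict[str, dict[str, dose_qa.DVHMetrics]]
    correlations: dict
    # heavyweight intermediates, not serialized to JSON
    arrays: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return _jsonify(
            {
                "schema_version": SCHEMA_VERSION,
                "metadata": self.metadata,
                "magnitude_summary": {k: v.as_dict() for k, v in self.magnitude_summary.items()},
                "error_summary": {k: v.as_dict() for k, v in self.error_summary.items()},
                "dose_panels": {k: v.as_dict() for k, v in self.dose_panels.items()},
                "dvh": {
                    roi: {side: m.as_dict() for side, m in sides.items()}
                    for roi, sides in self.dvh.items()
                },
                "correlations": _correlations_dict(self.correlations),
            }
        )

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def _correlations_dict(results: dict) -> dict:
    out: dict = {}
    for roi, analyses in results.items():
        out[roi] = {}
        for name, entry in analyses.items():
            b: corr.BinnedStats = entry["bins"]
            out[roi][name] = {
                "mean": entry["mean"].as_dict(),
                "range": entry["range"].as_dict(),
                "bins": {
                    "centers": b.centers,
                    "counts": b.counts,
                    "mean": np.where(np.isnan(b.mean), None, np.round(b.mean, 9)).tolist(),
                    "range": np.where(np.isnan(b.range), None, np.round(b.range, 9)).tolist(),
                    "retained": b.retained,
                    "degenerate": b.degenerate,
                },
            }
    return out


# ------------------------------------------------------------------- workflow

def _merge_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _make_candidate(
    cfg: dict,
    planning_ct: ImageVolume,
    deformed_ct: ImageVolume,
    truth: VectorField,
    structures: StructureSet,
) -> tuple[VectorField, dict]:
    src = cfg.get("source", "demons")
    if src == "demons":
        params = RegistrationParams(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in cfg.get("registration", {}).items()})
        dvf, t = register(deformed_ct, planning_ct, structures["spine"], params)
        return dvf, {"source": "demons", "rigid_translation_mm": t.tolist()}
    if src == "ground_truth":
        return truth.copy(), {"source": "ground_truth"}
    if src == "zero":
        z = truth.copy()
        z.u[:] = 0.0
        return z, {"source": "zero"}
    if src == "import":
        dvf = import_dvf(cfg["path"], cfg.get("convention"))
        return dvf, {"source": "import", "path": str(cfg["path"])}
    raise ValueError(f"unknown candidate source {src!r}")


def run_workflow(config: dict | None = None) -> QAReport:
    """Execute the full QA pipeline per the configuration; see DEFAULT_CONFIG.

    Stages: phantom → ground-truth DVF → deformed CT → candidate DVF →
    geometric QA → dosimetric QA → correlation suite → report.  Any stage
    failure propagates with a stage-tagged message.
    """
    cfg = _merge_config(config)
    seed = int(cfg["seed"])
    stage = "phantom"
    try:
        phantom_cfg = PhantomConfig(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in cfg["phantom"].items()})
        planning_ct, structures = generate_phantom(phantom_cfg, seed=seed)
        rx = PlanPrescription(list(cfg["prescription"]["levels"]))
        model = build_dose_model(structures, rx)
        log.info("phantom: %s @ %s mm", phantom_cfg.shape, phantom_cfg.spacing)

        stage = "deform"
        dcfg = cfg["deformation"]
        truth = ground_truth_field(
            planning_ct,
            structures,
            preset=dcfg.get("preset", "high"),
            shift_ap_mm=dcfg.get("shift_ap_mm", 5.0),
            shift_lr_mm=dcfg.get("shift_lr_mm", 5.0),
        )
        truth_inv = invert_dvf(truth)
        deformed_ct = warp_image(planning_ct, truth, inverse=truth_inv)

        stage = "candidate"
        cand_cfg = dict(cfg["candidate"])
        cand_cfg.setdefault("registration", cfg.get("registration", {}))
        candidate, cand_meta = _make_candidate(cand_cfg, planning_ct, deformed_ct, truth, structures)

        stage = "geometry_qa"
        truth_a = geometry_qa.resample_to_analysis_grid(truth, planning_ct)
        cand_a = geometry_qa.resample_to_analysis_grid(candidate, planning_ct)
        err_map = geometry_qa.magnitude_error_map(cand_a, truth_a)
        mag_map = geometry_qa.magnitude_map(truth_a)
        error_summary = geometry_qa.roi_error_stats(err_map, structures)
        magnitude_summary = geometry_qa.roi_error_stats(mag_map, structures)

        stage = "dose_qa"
        dose_report = dose_qa.dose_qa_report(model, truth, candidate, structures, rx)

        stage = "correlation"
        body_a = geometry_qa.resample_mask_to(
            structures["body"], structures.origin, structures.spacing,
            err_map.origin, err_map.spacing, err_map.shape,
        )
        dose_err_a = dose_qa.dose_error_map(model, truth_a, cand_a, body_a, rx)
        correlations = corr.run_correlation_suite(
            mag_map, err_map, dose_err_a.error, structures, n_bins=int(cfg["bins"])
        )

        stage = "report"
        metadata = {
            "seed": seed,
            "schema_version": SCHEMA_VERSION,
            "conventions": CONVENTIONS,
            "phantom": {"shape": list(phantom_cfg.shape), "spacing": list(phantom_cfg.spacing),
                        "noise_sigma_hu": phantom_cfg.noise_sigma_hu},
            "deformation": dcfg,
            "candidate": cand_meta,
            "prescription_cgy": rx.levels,
            "analysis_grid_spacing_mm": geometry_qa.ANALYSIS_SPACING_MM,
            "bins": int(cfg["bins"]),
        }
        return QAReport(
            metadata=metadata,
            magnitude_summary=magnitude_summary,
            error_summary=error_summary,
            dose_panels=dose_report["panels"],
            dvh=dose_report["dvh"],
            correlations=correlations,
            arrays={
                "planning_ct": planning_ct,
                "deformed_ct": deformed_ct,
                "structures": structures,
                "truth": truth,
                "candidate": candidate,
                "error_map": err_map,
                "magnitude_map": mag_map,
                "dose_error_map": dose_report["error_map"],
                "dose_error_map_analysis": dose_err_a,
                "dose_model": model,
            },
        )
    except Exception as exc:  # re-tag with the failing stage
        raise RuntimeError(f"workflow failed in stage {stage!r}: {exc}") from exc


# ------------------------------------------------------------------ rendering

def render_report(
    report: QAReport, outdir: str | Path, formats: tuple[str, ...] = ("json", "csv"),
    save_volumes: bool = False,
) -> list[Path]:
    """Write the QA record: JSON always, CSV tables, optional plots/volumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = outdir / "report.json"
    p.write_text(report.to_json())
    written.append(p)

    if "csv" in formats:
        for name, summary in (
            ("magnitude_summary", report.magnitude_summary),
            ("error_summary", report.error_summary),
        ):
            rows = [
                {"roi": s.roi, "mean_mm": s.mean, "p90_mm": s.p90, "max_mm": s.max, "voxels": s.count}
                for s in summary.values()
            ]
            f = outdir / f"{name}.csv"
            pd.DataFrame(rows).to_csv(f, index=False)
            written.append(f)
            for s in summary.values():
                f = outdir / f"{name}_hist_{s.roi}.csv"
                pd.DataFrame(
                    {"bin_lo_mm": s.hist_edges[:-1], "bin_hi_mm": s.hist_edges[1:],
                     "count": s.hist_counts}
                ).to_csv(f, index=False)
                written.append(f)
        f = outdir / "dose_panel.csv"
        pd.DataFrame([pnl.as_dict() for pnl in report.dose_panels.values()]).to_csv(f, index=False)
        written.append(f)
        rows = []
        for roi, analyses in report.correlations.items():
            for name, entry in analyses.items():
                for against in ("mean", "range"):
                    r: corr.CorrelationResult = entry[against]
                    rows.append(
                        {"roi": roi, "analysis": name, "against": against,
                         "coefficient": "" if r.degenerate else r.coefficient,
                         "degenerate": r.degenerate, "n_bins_used": r.n_bins_used}
                    )
        f = outdir / "correlations.csv"
        pd.DataFrame(rows).to_csv(f, index=False)
        written.append(f)

    if "plots" in formats:
        written += _render_plots(report, outdir)

    if save_volumes:
        a = report.arrays
        for name in ("planning_ct", "deformed_ct"):
            f = outdir / f"{name}.nii.gz"
            write_image(a[name], f)
            written.append(f)
        for name in ("truth", "candidate"):
            f = outdir / f"{name}_dvf.nii.gz"
            a[name].save(f)
            written.append(f)
        sdir = outdir / "structures"
        sdir.mkdir(exist_ok=True)
        s: StructureSet = a["structures"]
        for mname, m in s.masks.items():
            f = sdir / f"{mname}.nii.gz"
            write_mask(m, s.origin, s.spacing, f)
            written.append(f)
        (outdir / "dose_model.json").write_text(json.dumps(a["dose_model"].to_dict(), indent=2))
        written.append(outdir / "dose_model.json")
    return written


def _render_plots(report: QAReport, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (title, summary) in zip(
        axes,
        [("Ground-truth |u| (mm)", report.magnitude_summary),
         ("DIR magnitude error (mm)", report.error_summary)],
    ):
        for s in summary.values():
            ax.stairs(s.hist_counts, s.hist_edges, label=s.roi)
        ax.set_xlabel(title)
        ax.set_ylabel("voxels")
        ax.set_yscale("log")
        ax.legend(fontsize=7)
    fig.tight_layout()
    f = outdir / "histograms.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    written.append(f)

    fig, ax = plt.subplots(figsize=(8, 4))
    metrics = ["dmax_error_pct", "dmin_error_pct", "mean_error_pct",
               "max_error_pct", "p95_error_pct", "top_1cc_error_pct"]
    rois = list(report.dose_panels)
    width = 0.8 / len(rois)
    xs = np.arange(len(metrics))
    for i, roi in enumerate(rois):
        vals = [getattr(report.dose_panels[roi], m) for m in metrics]
        ax.bar(xs + i * width, vals, width, label=roi)
    ax.set_xticks(xs + 0.4 - width / 2)
    ax.set_xticklabels([m.replace("_error_pct", "").replace("_pct", "") for m in metrics],
                       fontsize=8)
    ax.set_ylabel("% of highest prescription")
    ax.legend(fontsize=7)
    fig.tight_layout()
    f = outdir / "dose_panel.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    written.append(f)
    return written
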