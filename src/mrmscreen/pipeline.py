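"""End-to-end orchestration: simulate/load -> preprocess -> fit -> classify
-> annotate -> non-target screening -> templates.

The stage order is fixed; every stage logs its effective parameters and row
counts, and a run emits a machine-readable manifest (parameters, seed,
timings, output checksums).  Class association labels are defined
geometrically: a fitted peak is associated with the calibration congener on
its channel whose retention time is nearest — the same rule an analyst uses
when reading a peak off against the calibration run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from . import classify as _classify
from .errors import ConfigError
from .io_mrm import (
    CALIBRATION_OWNER,
    CalibrationTable,
    Chromatogram,
    SampleMeta,
    StandardTable,
    read_chromatogram,
    write_chromatogram,
)
from .peakfit import FittedPeak, fit_all_regions
from .preprocess import BaselineConfig, SmoothingConfig, preprocess_trace
from .synthgen import GroundTruth, PlacedPeak, SimBatch, SimConfig, default_sim_config, simulate_batch

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitStageConfig:
    min_height: float = 50.0
    min_gap: float = 0.10  # minutes
    rt_tolerance: float = 0.05  # calibration lookup window for component counts
    gof_target: float = 0.90
    n_max: int = 6


@dataclass(frozen=True)
class ClassifyStageConfig:
    algorithm: str = "random_forest"
    train_fraction: float = 0.8
    cv_folds: int = 7
    holdout_samples: tuple[str, ...] | None = None


@dataclass(frozen=True)
class AnnotateStageConfig:
    epsilon: float | None = None  # None -> one rt grid step
    nontarget_rt_tolerance: float | None = None  # None -> 3 grid steps
    min_occurrence: float = 0.5
    standard_exclusion: float = 0.15  # minutes around a standard rt


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    fit: FitStageConfig = field(default_factory=FitStageConfig)
    classify: ClassifyStageConfig = field(default_factory=ClassifyStageConfig)
    annotate: AnnotateStageConfig = field(default_factory=AnnotateStageConfig)
    sim: SimConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "PipelineConfig":
        from .synthgen import Interferent, TruePeak

        kwargs: dict = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if seed is not None:
            kwargs["seed"] = int(seed)
        for key in ("simulate", "input_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        section_types = {
            "smoothing": SmoothingConfig,
            "baseline": BaselineConfig,
            "fit": FitStageConfig,
            "classify": ClassifyStageConfig,
            "annotate": AnnotateStageConfig,
        }
        for key, typ in section_types.items():
            if key in raw and raw[key] is not None:
                params = dict(raw[key])
                if key == "classify" and params.get("holdout_samples"):
                    params["holdout_samples"] = tuple(params["holdout_samples"])
                kwargs[key] = typ(**params)
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "peaks" in sim_raw:
                sim_raw["peaks"] = tuple(TruePeak(**p) for p in sim_raw["peaks"])
            if "interferents" in sim_raw:
                sim_raw["interferents"] = tuple(
                    Interferent(**p) for p in sim_raw["interferents"]
                )
            for tup_key in ("standard_rts", "drift_range"):
                if tup_key in sim_raw:
                    sim_raw[tup_key] = tuple(sim_raw[tup_key])
            kwargs["sim"] = SimConfig(**sim_raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    batch: SimBatch
    peaks_by_sample: dict[str, list[FittedPeak]]
    calibration_peaks: list[FittedPeak]
    labeled: list[_classify.LabeledPeak]
    model: _classify.ClassifierModel | None
    train_samples: list[str]
    test_samples: list[str]
    classified_by_sample: dict[str, list[tuple[FittedPeak, int]]]
    annotated: list[_annotate.AnnotatedPeak]
    nontargets: list[_annotate.NonTargetPeak]
    templates: list[_annotate.LocationTemplate]
    eval_report: dict
    recovery: dict


# ---------------------------------------------------------------------------
# batch persistence (CSV/JSON layout used by the simulate subcommand)
# ---------------------------------------------------------------------------

def write_batch(batch: SimBatch, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    (out / "calibration").mkdir(parents=True, exist_ok=True)
    for sid, traces in batch.samples.items():
        d = out / "samples" / sid
        d.mkdir(exist_ok=True)
        for tr in traces:
            write_chromatogram(tr, d / f"channel_{tr.channel_id:02d}.csv")
    for tr in batch.calibration:
        write_chromatogram(tr, out / "calibration" / f"channel_{tr.channel_id:02d}.csv")
    batch.standards.write_csv(out / "standards.csv")
    batch.calibration_table.write_csv(out / "calibration_table.csv")
    pd.DataFrame(
        [
            {"sample_id": m.sample_id, "location": m.location, "date": str(m.date)}
            for m in batch.sample_meta.values()
        ]
    ).to_csv(out / "sample_meta.csv", index=False)
    truth = {
        "shifts": batch.truth.shifts,
        "placements": [dataclasses.asdict(p) for p in batch.truth.placements],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def load_batch(in_dir: str | Path) -> SimBatch:
    src = Path(in_dir)
    if not (src / "standards.csv").exists():
        raise ConfigError(f"{src}: not a batch directory (standards.csv missing)")
    meta_df = pd.read_csv(src / "sample_meta.csv")
    import datetime as _dt

    meta = {
        str(r.sample_id): SampleMeta(
            sample_id=str(r.sample_id),
            location=str(r.location),
            date=_dt.date.fromisoformat(str(r.date)),
        )
        for r in meta_df.itertuples()
    }
    samples: dict[str, list[Chromatogram]] = {}
    for sid in sorted(meta):
        d = src / "samples" / sid
        traces = []
        for f in sorted(d.glob("channel_*.csv")):
            ch = int(f.stem.split("_")[1])
            traces.append(read_chromatogram(f, "csv", channel_id=ch, sample=meta[sid]))
        samples[sid] = traces
    calibration = [
        read_chromatogram(f, "csv", channel_id=int(f.stem.split("_")[1]))
        for f in sorted((src / "calibration").glob("channel_*.csv"))
    ]
    truth = GroundTruth(shifts={}, placements=())
    truth_path = src / "truth.json"
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        truth = GroundTruth(
            shifts={k: float(v) for k, v in raw.get("shifts", {}).items()},
            placements=tuple(PlacedPeak(**p) for p in raw.get("placements", [])),
        )
    return SimBatch(
        samples=samples,
        sample_meta=meta,
        calibration=calibration,
        standards=StandardTable.read_csv(src / "standards.csv"),
        calibration_table=CalibrationTable.read_csv(src / "calibration_table.csv"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _designated_standard_rts(standards: StandardTable, channel_id: int) -> list[float]:
    rts = sorted(standards.rts(CALIBRATION_OWNER, channel_id))
    if len(rts) < 3:
        raise ConfigError("need three calibration standards for feature extraction")
    return rts[:3]


def _near_any(rt: float, anchors: Sequence[float], tol: float) -> bool:
    return any(abs(rt - a) <= tol for a in anchors)


def associate_label(peak: FittedPeak, calib: CalibrationTable) -> int | None:
    """Nearest-calibration-rt class association on the peak's channel."""
    entries = calib.entries_for_channel(peak.channel_id)
    if entries.empty:
        return None
    idx = (entries["rt"] - peak.rt).abs().idxmin()
    return int(entries.loc[idx, "class_id"])


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full analysis chain on a simulated or loaded batch."""
    if cfg.simulate:
        sim = cfg.sim if cfg.sim is not None else default_sim_config(seed=cfg.seed)
        if cfg.sim is not None and cfg.sim.seed != cfg.seed:
            sim = dataclasses.replace(sim, seed=cfg.seed)
        log.info("simulating batch: %d samples x %d channels", sim.n_samples, sim.n_channels)
        batch = simulate_batch(sim)
    else:
        if not cfg.input_dir:
            raise ConfigError("simulation disabled and no input_dir configured")
        batch = load_batch(cfg.input_dir)

    calib = batch.calibration_table
    step = batch.calibration[0].grid_step
    epsilon = cfg.annotate.epsilon if cfg.annotate.epsilon is not None else step
    nt_tol = (
        cfg.annotate.nontarget_rt_tolerance
        if cfg.annotate.nontarget_rt_tolerance is not None
        else 3 * step
    )

    # --- preprocess + fit the calibration run (reference frame, no alignment)
    calibration_peaks: list[FittedPeak] = []
    for tr in batch.calibration:
        proc = preprocess_trace(tr, cfg.smoothing, cfg.baseline)
        for res in fit_all_regions(
            proc,
            calib,
            cfg.fit.min_height,
            cfg.fit.min_gap,
            cfg.fit.rt_tolerance,
            cfg.fit.gof_target,
            cfg.fit.n_max,
        ):
            calibration_peaks.extend(res.peaks)
    scaling = _annotate.default_scaling(calibration_peaks)

    # --- preprocess + fit every sample channel
    peaks_by_sample: dict[str, list[FittedPeak]] = {}
    for sid, traces in batch.samples.items():
        peaks: list[FittedPeak] = []
        for tr in traces:
            proc = preprocess_trace(
                tr,
                cfg.smoothing,
                cfg.baseline,
                sample_standards=batch.standards.rts(sid, tr.channel_id),
                calib_standards=batch.standards.rts(CALIBRATION_OWNER, tr.channel_id),
            )
            for res in fit_all_regions(
                proc,
                calib,
                cfg.fit.min_height,
                cfg.fit.min_gap,
                cfg.fit.rt_tolerance,
                cfg.fit.gof_target,
                cfg.fit.n_max,
            ):
                peaks.extend(res.peaks)
        peaks_by_sample[sid] = peaks
        log.info("sample %s: %d fitted peaks", sid, len(peaks))

    # --- features + association labels (standards excluded from classification)
    ref_channel = batch.calibration[0].channel_id
    designated = _designated_standard_rts(batch.standards, ref_channel)
    labeled: list[_classify.LabeledPeak] = []
    for sid, peaks in peaks_by_sample.items():
        std_rts = sorted(batch.standards.rts(CALIBRATION_OWNER, ref_channel))
        for p in peaks:
            if _near_any(p.rt, std_rts, cfg.annotate.standard_exclusion):
                continue
            label = associate_label(p, calib)
            if label is None:
                continue
            labeled.append(
                _classify.LabeledPeak(
                    features=_classify.extract_features(p, designated),
                    label=label,
                    source_peak=p,
                )
            )

    # --- train/test split by sample, train, predict everywhere
    holdout = cfg.classify.holdout_samples
    train, test = _classify.split_train_test(
        labeled,
        train_fraction=cfg.classify.train_fraction,
        holdout_samples=list(holdout) if holdout else None,
        seed=cfg.seed,
    )
    model = _classify.train_classifier(
        train, cfg.classify.algorithm, cv_folds=cfg.classify.cv_folds, seed=cfg.seed
    )
    train_samples = sorted({p.sample_id for p in train})
    test_samples = sorted({p.sample_id for p in test})

    classified_by_sample: dict[str, list[tuple[FittedPeak, int]]] = {
        sid: [] for sid in peaks_by_sample
    }
    by_sample_labeled: dict[str, list[_classify.LabeledPeak]] = {}
    for lp in labeled:
        by_sample_labeled.setdefault(lp.sample_id, []).append(lp)
    for sid, lps in by_sample_labeled.items():
        preds = _classify.predict_classes(model, [lp.features for lp in lps])
        classified_by_sample[sid] = [
            (lp.source_peak, pred) for lp, pred in zip(lps, preds)
        ]

    # --- annotate, screen non-targets, build templates
    annotated: list[_annotate.AnnotatedPeak] = []
    for sid in sorted(classified_by_sample):
        annotated.extend(
            _annotate.select_target_peaks(
                classified_by_sample[sid], calib, scaling, epsilon
            )
        )
    nontargets = _annotate.find_nontarget_peaks(
        classified_by_sample, annotated, nt_tol, cfg.annotate.min_occurrence
    )
    locations = sorted({m.location for m in batch.sample_meta.values()})
    sample_locations = {sid: m.location for sid, m in batch.sample_meta.items()}
    templates = [
        _annotate.build_template(annotated, loc, sample_locations) for loc in locations
    ]

    eval_report = _evaluate(model, train, test, annotated, batch, test_samples, cfg)
    recovery = _score_recovery(annotated, batch, step)

    return PipelineResult(
        batch=batch,
        peaks_by_sample=peaks_by_sample,
        calibration_peaks=calibration_peaks,
        labeled=labeled,
        model=model,
        train_samples=train_samples,
        test_samples=test_samples,
        classified_by_sample=classified_by_sample,
        annotated=annotated,
        nontargets=nontargets,
        templates=templates,
        eval_report=eval_report,
        recovery=recovery,
    )


def _evaluate(model, train, test, annotated, batch: SimBatch, test_samples, cfg) -> dict:
    """Classifier accuracies plus present/absent confusion metrics on the
    test samples (autonomous annotation vs ground-truth placements)."""
    report: dict = {
        "algorithm": model.algorithm,
        "cv_accuracy": model.cv_accuracy,
        "training_accuracy": _classify.training_accuracy(model, train),
        "testing_accuracy": _classify.training_accuracy(model, test),
    }
    if batch.truth.placements:
        universe = {
            (sid, cid)
            for sid in test_samples
            for cid in batch.calibration_table.class_ids
        }
        auto = {
            (a.sample_id, a.class_id) for a in annotated if a.sample_id in test_samples
        }
        manual = {
            (p.sample_id, p.class_id)
            for p in batch.truth.placements
            if p.kind == "target" and p.sample_id in test_samples
        }
        counts = _classify.label_against_manual(auto & universe, manual, universe)
        m = _classify.compute_metrics(counts, zero_division="zero")
        report.update(
            {
                "detection": {
                    "tp": counts.tp,
                    "tn": counts.tn,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
            }
        )
    return report


def _score_recovery(annotated, batch: SimBatch, step: float) -> dict:
    """Fraction of true target placements recovered as correctly-classed
    annotated peaks with rt error <= 2 grid steps (in the aligned frame,
    truth sits at the calibration retention time)."""
    if not batch.truth.placements:
        return {}
    calib = batch.calibration_table
    ann = {(a.sample_id, a.class_id): a for a in annotated}
    n_true = 0
    n_recovered = 0
    for p in batch.truth.placements:
        if p.kind != "target":
            continue
        n_true += 1
        a = ann.get((p.sample_id, p.class_id))
        if a is None:
            continue
        if abs(a.peak.rt - calib.rt_of(p.class_id)) <= 2 * step:
            n_recovered += 1
    return {
        "n_true_targets": n_true,
        "n_recovered": n_recovered,
        "recovery_fraction": (n_recovered / n_true) if n_true else float("nan"),
    }


# ---------------------------------------------------------------------------
# artifact writing
# ---------------------------------------------------------------------------

def write_outputs(result: PipelineResult, out_dir: str | Path, cfg: PipelineConfig,
                  timings: dict[str, float] | None = None) -> dict:
    """Write stage outputs as CSV/JSON plus a manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    peak_rows = []
    for sid, pairs in sorted(result.classified_by_sample.items()):
        for peak, cid in pairs:
            peak_rows.append(
                {
                    "sample_id": sid,
                    "channel_id": peak.channel_id,
                    "rt": peak.rt,
                    "amplitude": peak.amplitude,
                    "width": peak.width,
                    "height": peak.height,
                    "area": peak.area,
                    "predicted_class": cid,
                }
            )
    pd.DataFrame(peak_rows).to_csv(out / "peaks.csv", index=False)

    pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "class_id": a.class_id,
                "rt": a.peak.rt,
                "height": a.peak.height,
                "area": a.peak.area,
                "score": a.score,
            }
            for a in result.annotated
        ]
    ).to_csv(out / "annotated.csv", index=False)

    pd.DataFrame(
        [
            {
                "associated_class_id": nt.associated_class_id,
                "mean_rt": nt.mean_rt,
                "occurrence_fraction": nt.occurrence_fraction,
                "n_members": len(nt.member_peaks),
            }
            for nt in result.nontargets
        ]
    ).to_csv(out / "nontarget.csv", index=False)

    template_rows = []
    for t in result.templates:
        for cid, val in t.intensities.items():
            template_rows.append(
                {
                    "location": t.location,
                    "n_samples": t.n_samples,
                    "class_id": cid,
                    "mean_intensity": val,
                }
            )
    pd.DataFrame(template_rows).to_csv(out / "templates.csv", index=False)

    report = dict(result.eval_report)
    report["recovery"] = result.recovery
    (out / "eval_report.json").write_text(json.dumps(report, indent=1))

    files = ["peaks.csv", "annotated.csv", "nontarget.csv", "templates.csv", "eval_report.json"]
    manifest = {
        "seed": cfg.seed,
        "parameters": cfg.to_dict(),
        "timings_s": timings or {},
        "outputs": {
            f: {
                "sha256": hashlib.sha256((out / f).read_bytes()).hexdigest(),
                "bytes": (out / f).stat().st_size,
            }
            for f in files
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
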