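"""File-based pipeline orchestration: simulate -> preprocess -> qc -> aoi
-> features -> associate, plus the guided-viewing track.

Stages communicate through CSV/JSON artifacts in a working directory and
append entries (parameters, seed, output hashes) to ``manifest.json``, so
any stage can be rerun or audited independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aoi as aoi_mod
from . import features as feat_mod
from . import guided as guided_mod
from . import preprocess as pp
from . import qc as qc_mod
from . import stats as stats_mod
from . import synthetic as syn
from .geometry import GOGGLES_EXP1, MONITOR_EXP2
from .types import AOISet, GazeRecording, blinks_to_frame, fixations_to_frame

log = logging.getLogger("gazemem")

VALENCE_CYCLE = ("negative", "neutral", "positive", "scrambled")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with stated-procedure defaults:
    100 ms minimum fixation, 3301-sample drift window, 0.6 blink
    aspect-ratio threshold / 83 ms minimum, 0.5 signal-loss threshold in
    over 50% of samples, 6-of-24 minimum valid trials, 7000 ms fixated
    exposure and 200 deg/s transitions in guided viewing."""

    experiment: str = "exp1"
    out_dir: str = "gazemem_out"
    rng_seed: int = 0
    n_subjects: int = 24
    n_pictures: int = 48
    window_samples: int = pp.DRIFT_WINDOW_SAMPLES
    lambda_multiplier: float = 6.0
    min_fixation_ms: float = pp.MIN_FIXATION_MS
    blink_ar_threshold: float = pp.BLINK_AR_THRESHOLD
    blink_min_ms: float = pp.BLINK_MIN_MS
    bandwidth_deg: float = aoi_mod.DEFAULT_BANDWIDTH_DEG
    min_cluster_frac: float = aoi_mod.DEFAULT_MIN_CLUSTER_FRAC
    min_valid_frac: float = 0.25
    fdr_alpha: float = 0.05
    recall_effect_beta: float = 0.5
    log_level: str = "INFO"

    def validate(self) -> None:
        problems = []
        if self.experiment not in ("exp1", "exp2"):
            problems.append(f"experiment: {self.experiment!r} not in (exp1, exp2)")
        if self.window_samples % 2 == 0:
            problems.append(
                "window_samples: must be odd (correct_drift moving median)"
            )
        for name in ("n_subjects", "n_pictures"):
            if getattr(self, name) < 1:
                problems.append(f"{name}: must be >= 1")
        for name in ("lambda_multiplier", "bandwidth_deg", "min_fixation_ms"):
            if getattr(self, name) <= 0:
                problems.append(f"{name}: must be > 0")
        if not 0 < self.min_valid_frac <= 1:
            problems.append("min_valid_frac: must be in (0, 1]")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest_add(out: Path, stage: str, params: dict, outputs: list[Path]) -> None:
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else []
    manifest = [e for e in manifest if e["stage"] != stage]
    manifest.append(
        {
            "stage": stage,
            "params": params,
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }
    )
    mpath.write_text(json.dumps(manifest, indent=1))


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise FileNotFoundError(f"missing artifact {name}; run stage {stage!r} first")
    return p


def _sim_config(cfg: PipelineConfig) -> syn.SimConfig:
    return syn.SimConfig(
        n_subjects=cfg.n_subjects,
        n_pictures=cfg.n_pictures,
        recall_effect_beta=cfg.recall_effect_beta,
        rng_seed=cfg.rng_seed,
    )


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    """Synthesise layouts, trial schedule, calibrations and gaze CSVs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = _sim_config(cfg)
    rng = np.random.default_rng([cfg.rng_seed, 0xA01])
    layouts = {}
    for i in range(cfg.n_pictures):
        pid = f"p{i:03d}"
        layouts[pid] = syn.generate_aoi_layout(pid, int(rng.integers(3, 9)), rng)
    (out / "layouts.json").write_text(
        json.dumps({pid: l.to_dict() for pid, l in layouts.items()}, indent=1)
    )
    schedule = pd.DataFrame(
        {
            "trial_id": np.arange(cfg.n_pictures),
            "picture_id": [f"p{i:03d}" for i in range(cfg.n_pictures)],
            "valence": [VALENCE_CYCLE[i % 4] for i in range(cfg.n_pictures)],
            "onset_ms": np.arange(cfg.n_pictures) * scfg.trial_ms,
        }
    )
    schedule.to_csv(out / "schedule.csv", index=False)

    outputs = [out / "layouts.json", out / "schedule.csv"]
    gaze_dir = out / "gaze"
    gaze_dir.mkdir(exist_ok=True)
    cal_rows = []
    truth_fix = []
    ordered = [layouts[p] for p in schedule["picture_id"]]
    for s in range(cfg.n_subjects):
        srng = syn.subject_rng(cfg.rng_seed, s)
        sid = f"s{s:03d}"
        rec, truth = syn.generate_gaze_recording(scfg, ordered, srng, subject_id=sid)
        rec.to_csv(gaze_dir / f"{sid}.csv")
        outputs.append(gaze_dir / f"{sid}.csv")
        tf = truth.fixations.copy()
        tf["subject_id"] = sid
        truth_fix.append(tf)
        cal = syn.generate_calibration_record(scfg, deviation_deg=1.0, rng=srng, subject_id=sid)
        c = cal.gaze.copy()
        c["subject_id"] = sid
        c["target_x_px"] = cal.targets_px[c["target_idx"], 0]
        c["target_y_px"] = cal.targets_px[c["target_idx"], 1]
        cal_rows.append(c)
    pd.concat(truth_fix, ignore_index=True).to_csv(out / "truth_fixations.csv", index=False)
    pd.concat(cal_rows, ignore_index=True).to_csv(out / "calibrations.csv", index=False)
    outputs += [out / "truth_fixations.csv", out / "calibrations.csv"]
    _manifest_add(out, "simulate", {"seed": cfg.rng_seed, **asdict(cfg)}, outputs)
    return outputs


def _load_recordings(cfg: PipelineConfig) -> dict[str, GazeRecording]:
    out = Path(cfg.out_dir)
    gaze_dir = _require(out, "gaze", "simulate")
    scfg = _sim_config(cfg)
    recs = {}
    for f in sorted(gaze_dir.glob("s*.csv")):
        recs[f.stem] = GazeRecording.from_csv(
            f, f.stem, scfg.sampling_rate_hz, scfg.geometry
        )
    return recs


def stage_preprocess(cfg: PipelineConfig) -> list[Path]:
    """Drift-correct and detect fixation/blink events for every subject."""
    out = Path(cfg.out_dir)
    params = pp.VelocityParams(lambda_multiplier=cfg.lambda_multiplier)
    fix_frames, blink_frames = [], []
    for sid, rec in _load_recordings(cfg).items():
        corrected = (
            pp.correct_drift(rec, cfg.window_samples)
            if cfg.experiment == "exp1"
            else rec
        )
        fx = pp.detect_fixations(corrected, params, cfg.min_fixation_ms)
        bl = pp.detect_blinks(corrected, cfg.blink_ar_threshold, cfg.blink_min_ms)
        ff = fixations_to_frame(fx)
        ff["subject_id"] = sid
        bf = blinks_to_frame(bl)
        bf["subject_id"] = sid
        fix_frames.append(ff)
        blink_frames.append(bf)
    pd.concat(fix_frames, ignore_index=True).to_csv(out / "fixations.csv", index=False)
    pd.concat(blink_frames, ignore_index=True).to_csv(out / "blinks.csv", index=False)
    sidecar = out / "preprocess_params.json"
    sidecar.write_text(
        json.dumps(
            {
                "window_samples": cfg.window_samples,
                "lambda_multiplier": cfg.lambda_multiplier,
                "min_fixation_ms": cfg.min_fixation_ms,
                "blink_ar_threshold": cfg.blink_ar_threshold,
                "blink_min_ms": cfg.blink_min_ms,
            },
            indent=1,
        )
    )
    outputs = [out / "fixations.csv", out / "blinks.csv", sidecar]
    _manifest_add(out, "preprocess", {"lambda": cfg.lambda_multiplier}, outputs)
    return outputs


def stage_qc(cfg: PipelineConfig) -> list[Path]:
    """Subject screening (calibration + velocity) and trial screening."""
    out = Path(cfg.out_dir)
    recs = _load_recordings(cfg)
    fixations = pd.read_csv(_require(out, "fixations.csv", "preprocess"))
    cal = pd.read_csv(_require(out, "calibrations.csv", "simulate"))

    calibrations = {}
    for sid, grp in cal.groupby("subject_id"):
        targets = (
            grp.drop_duplicates("target_idx")
            .sort_values("target_idx")[["target_x_px", "target_y_px"]]
            .to_numpy()
        )
        calibrations[sid] = syn.CalibrationRecord(sid, targets, grp)
    vel = {sid: qc_mod.velocity_summary(rec) for sid, rec in recs.items()}
    subjects = qc_mod.screen_subjects(calibrations, vel)

    profile = qc_mod.grand_pupil_profile(list(recs.values()))
    trial_frames = []
    from .types import FixationEvent

    for sid, rec in recs.items():
        fx = [
            FixationEvent(
                int(r.trial_id),
                r.onset_ms,
                r.offset_ms,
                (r.x_px, r.y_px),
                (r.x_deg, r.y_deg),
            )
            for r in fixations[fixations["subject_id"] == sid].itertuples()
        ]
        tv = qc_mod.screen_trials(fx, rec, profile)
        trial_frames.append(qc_mod.validity_frame(tv, sid))
    trials = pd.concat(trial_frames, ignore_index=True)
    # subjects with zero valid trials are dropped
    no_valid = trials.groupby("subject_id")["valid"].sum()
    for sid in no_valid[no_valid == 0].index:
        i = subjects["subject_id"] == sid
        subjects.loc[i, "keep"] = False
        subjects.loc[i, "reasons"] = (
            subjects.loc[i, "reasons"].str.rstrip(",") + ",no_valid_trials"
        ).str.lstrip(",")
    subjects.to_csv(out / "qc_subjects.csv", index=False)
    trials.to_csv(out / "qc_trials.csv", index=False)
    report = {
        "n_subjects": len(subjects),
        "n_subjects_dropped": int((~subjects["keep"]).sum()),
        "drop_reasons": subjects.loc[~subjects["keep"], "reasons"].tolist(),
        "n_trials": len(trials),
        "n_trials_invalid": int((~trials["valid"]).sum()),
        "invalid_by_reason": trials.loc[~trials["valid"], "reasons"]
        .str.split(",")
        .explode()
        .value_counts()
        .to_dict(),
    }
    (out / "qc_report.json").write_text(json.dumps(report, indent=1))
    (out / "qc_report.txt").write_text(
        "\n".join(
            [
                f"subjects: {report['n_subjects']} "
                f"({report['n_subjects_dropped']} dropped)",
                f"trials: {report['n_trials']} "
                f"({report['n_trials_invalid']} invalid)",
            ]
            + [f"  {k}: {v}" for k, v in report["invalid_by_reason"].items()]
        )
        + "\n"
    )
    outputs = [out / "qc_subjects.csv", out / "qc_trials.csv", out / "qc_report.json", out / "qc_report.txt"]
    _manifest_add(out, "qc", {}, outputs)
    return outputs


def stage_aoi(cfg: PipelineConfig) -> list[Path]:
    """Derive per-picture AOIs from pooled post-QC fixations."""
    out = Path(cfg.out_dir)
    fixations = pd.read_csv(_require(out, "fixations.csv", "preprocess"))
    subjects = pd.read_csv(_require(out, "qc_subjects.csv", "qc"))
    schedule = pd.read_csv(_require(out, "schedule.csv", "simulate"))
    keep = set(subjects.loc[subjects["keep"], "subject_id"])
    pool_ids = aoi_mod.sample_pooled_subjects(sorted(keep), seed=cfg.rng_seed)
    fx = fixations[fixations["subject_id"].isin(pool_ids)].merge(
        schedule[["trial_id", "picture_id"]], on="trial_id"
    )
    aoi_dir = out / "aois"
    aoi_dir.mkdir(exist_ok=True)
    outputs = []
    for pid, grp in fx.groupby("picture_id"):
        pts = grp[["x_deg", "y_deg"]].to_numpy()
        try:
            aset = aoi_mod.derive_aois(
                pts, cfg.bandwidth_deg, cfg.min_cluster_frac, picture_id=str(pid)
            )
            aset = aoi_mod.derive_no_interest_centroids(
                pts, aset, cfg.bandwidth_deg, min_required=1
            )
        except ValueError as err:
            log.warning("picture %s: %s", pid, err)
            aset = aoi_mod.derive_aois(
                pts, cfg.bandwidth_deg, cfg.min_cluster_frac, picture_id=str(pid)
            )
        p = aoi_dir / f"{pid}.json"
        aset.to_json(p)
        outputs.append(p)
    _manifest_add(out, "aoi", {"bandwidth_deg": cfg.bandwidth_deg}, outputs)
    return outputs


def stage_features(cfg: PipelineConfig) -> list[Path]:
    """Per-trial features, within-picture z-scores, recall outcomes and
    subject x valence aggregates."""
    out = Path(cfg.out_dir)
    fixations = pd.read_csv(_require(out, "fixations.csv", "preprocess"))
    blinks = pd.read_csv(_require(out, "blinks.csv", "preprocess"))
    schedule = pd.read_csv(_require(out, "schedule.csv", "simulate"))
    trials = pd.read_csv(_require(out, "qc_trials.csv", "qc"))
    subjects = pd.read_csv(_require(out, "qc_subjects.csv", "qc"))
    aoi_dir = _require(out, "aois", "aoi")
    aoi_sets = {p.stem: AOISet.from_json(p) for p in sorted(aoi_dir.glob("*.json"))}
    keep = set(subjects.loc[subjects["keep"], "subject_id"])

    from .types import BlinkEvent, FixationEvent

    tables = []
    for sid in sorted(keep):
        fx = [
            FixationEvent(
                int(r.trial_id), r.onset_ms, r.offset_ms, (r.x_px, r.y_px), (r.x_deg, r.y_deg)
            )
            for r in fixations[fixations["subject_id"] == sid].itertuples()
        ]
        bl = [
            BlinkEvent(int(r.trial_id), r.onset_ms, r.offset_ms)
            for r in blinks[blinks["subject_id"] == sid].itertuples()
        ]
        tables.append(
            feat_mod.extract_features(fx, bl, aoi_sets, schedule, subject_id=sid)
        )
    table = pd.concat(tables, ignore_index=True)
    table = table.merge(trials[["subject_id", "trial_id", "valid"]], on=["subject_id", "trial_id"])
    table = feat_mod.zstandardize_within_picture(table)

    scfg = _sim_config(cfg)
    rng = np.random.default_rng([cfg.rng_seed, 0x5EC])
    recall = syn.generate_recall_outcomes(table, scfg, rng)
    n_per_valence = max(
        int(schedule.groupby("valence")["trial_id"].count().max()), 1
    )
    agg = feat_mod.aggregate_subjects(
        table, recall, cfg.min_valid_frac, trials_per_valence=n_per_valence
    )
    # subject-level covariates (batch factors assigned at random in synthesis)
    crng = np.random.default_rng([cfg.rng_seed, 0xC0])
    subs = sorted(agg["subject_id"].unique())
    meta = pd.DataFrame(
        {
            "subject_id": subs,
            "sex": crng.integers(0, 2, len(subs)),
            "age": np.round(crng.normal(22.3, 3.3, len(subs)), 1),
            "goggles": crng.integers(0, 2, len(subs)),
            "recall_room": crng.integers(0, 3, len(subs)),
        }
    )
    agg = agg.merge(meta, on="subject_id")
    table.to_csv(out / "features.csv", index=False)
    recall.to_csv(out / "recall.csv", index=False)
    agg.to_csv(out / "aggregates.csv", index=False)
    schema = {
        "features.csv": {c: str(table[c].dtype) for c in table.columns},
        "aggregates.csv": {c: str(agg[c].dtype) for c in agg.columns},
    }
    (out / "features_schema.json").write_text(json.dumps(schema, indent=1))
    outputs = [out / "features.csv", out / "recall.csv", out / "aggregates.csv", out / "features_schema.json"]
    _manifest_add(out, "features", {"min_valid_frac": cfg.min_valid_frac}, outputs)
    return outputs


def stage_associate(cfg: PipelineConfig) -> list[Path]:
    """Mixed-model association of each feature with recall counts."""
    out = Path(cfg.out_dir)
    agg = pd.read_csv(_require(out, "aggregates.csv", "features"))
    results = stats_mod.run_association_analysis(agg)
    payload = {f: r.to_dict() for f, r in results.items()}
    (out / "association.json").write_text(json.dumps(payload, indent=1))
    lines = []
    for f, r in results.items():
        lines.append(
            f"{f}: t({r.main_df:.0f}) = {r.main_t:.2f}, P = {r.main_p:.2e}, "
            f"P_fdr = {r.main_p_fdr:.2e}, R2b* = {r.r2:.3f} "
            f"[{r.r2_ci[0]:.3f}, {r.r2_ci[1]:.3f}]; interaction "
            f"F({r.interaction_df[0]:.0f}, {r.interaction_df[1]:.0f}) = "
            f"{r.interaction_f:.2f}, P_fdr = {r.interaction_p_fdr:.2f}"
        )
    (out / "association.txt").write_text("\n".join(lines) + "\n")
    outputs = [out / "association.json", out / "association.txt"]
    _manifest_add(out, "associate", {}, outputs)
    return outputs


EXP1_STAGES = ["simulate", "preprocess", "qc", "aoi", "features", "associate"]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order; returns the manifest."""
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    stage_fns = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "qc": stage_qc,
        "aoi": stage_aoi,
        "features": stage_features,
        "associate": stage_associate,
    }
    for name in EXP1_STAGES:
        log.info("stage %s", name)
        try:
            stage_fns[name](cfg)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
    return json.loads((Path(cfg.out_dir) / "manifest.json").read_text())
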