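"""Visual-exploration features per subject x trial, and their aggregation.

Four features per 2.5 s picture trial:

* ``n_fix`` — fixation count in the picture window (a fixation counts if
  its onset lies inside the window);
* ``n_fix_in_aois`` — the subset landing in an interest AOI;
* ``n_aois`` — number of unique interest AOIs fixated;
* ``blink_duration_ms`` — total eyes-closed time over the full trial;
* ``interfix_distance_deg`` — mean angular distance between temporally
  consecutive fixation centroids (defined only when n_fix >= 2).

Features are z-standardised within picture across subjects (n-1 SD), so
inherent stimulus differences do not masquerade as subject differences,
then averaged per subject x valence over valid trials; a subject x
valence cell based on fewer than 25% of its trials is dropped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .aoi import assign_fixations
from .types import AOISet, BlinkEvent, FixationEvent

FEATURES = ["n_fix", "n_fix_in_aois", "n_aois", "blink_duration_ms", "interfix_distance_deg"]
#: The four features entering the memory analysis (n_aois is redundant
#: with n_fix_in_aois and is reported descriptively only).
ANALYSIS_FEATURES = ["n_fix", "n_fix_in_aois", "blink_duration_ms", "interfix_distance_deg"]


def extract_features(
    fixations: list[FixationEvent],
    blinks: list[BlinkEvent],
    aoi_sets: dict[str, AOISet],
    trial_schedule: pd.DataFrame,
    subject_id: str = "s000",
    picture_ms: float = 2500.0,
) -> pd.DataFrame:
    """One row per trial of ``trial_schedule`` (columns ``trial_id,
    picture_id, valence, onset_ms`` and optionally ``trial_onset_ms,
    trial_offset_ms`` for the blink window)."""
    fix_by_trial: dict[int, list[FixationEvent]] = {}
    for e in fixations:
        fix_by_trial.setdefault(e.trial_id, []).append(e)
    blink_by_trial: dict[int, list[BlinkEvent]] = {}
    for b in blinks:
        blink_by_trial.setdefault(b.trial_id, []).append(b)

    rows = []
    for rec in trial_schedule.itertuples(index=False):
        tid = int(rec.trial_id)
        pic_on = float(rec.onset_ms)
        pic_off = pic_on + picture_ms
        tr_on = float(getattr(rec, "trial_onset_ms", pic_on))
        tr_off = float(getattr(rec, "trial_offset_ms", pic_off))
        fx = sorted(fix_by_trial.get(tid, []), key=lambda e: e.onset_ms)
        in_window = [e for e in fx if pic_on <= e.onset_ms < pic_off]
        n_fix = len(in_window)
        layout = aoi_sets.get(str(rec.picture_id))
        if layout is None:
            raise KeyError(f"no AOI set for picture {rec.picture_id!r}")
        labels = assign_fixations([e.centroid_deg for e in in_window], layout)
        n_in = sum(1 for l in labels if l >= 0)
        n_aois = len({l for l in labels if l >= 0})
        blink_ms = 0.0
        for b in blink_by_trial.get(tid, []):
            blink_ms += max(0.0, min(b.offset_ms, tr_off) - max(b.onset_ms, tr_on))
        if n_fix >= 2:
            c = np.array([e.centroid_deg for e in in_window])
            interfix = float(np.mean(np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1]))))
        else:
            interfix = np.nan
        rows.append(
            {
                "subject_id": subject_id,
                "trial_id": tid,
                "picture_id": str(rec.picture_id),
                "valence": rec.valence,
                "n_fix": n_fix,
                "n_fix_in_aois": n_in,
                "n_aois": n_aois,
                "blink_duration_ms": blink_ms,
                "interfix_distance_deg": interfix,
            }
        )
    return pd.DataFrame(rows)


def zstandardize_within_picture(
    table: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Add ``z_<feature>`` columns standardised within picture over valid
    trials (n-1 SD).  Zero-variance pictures get z = 0 with a warning;
    pictures with fewer than 2 valid trials get missing z values."""
    features = features or FEATURES
    out = table.copy()
    valid = out["valid"] if "valid" in out.columns else pd.Series(True, index=out.index)
    for feat in features:
        zcol = f"z_{feat}"
        out[zcol] = np.nan
        for pic, grp in out.groupby("picture_id"):
            m = valid.loc[grp.index] & grp[feat].notna()
            vals = grp.loc[m, feat].astype(float)
            if len(vals) < 2:
                continue
            sd = vals.std(ddof=1)
            if sd == 0:
                warnings.warn(f"picture {pic}: feature {feat} has zero variance")
                out.loc[vals.index, zcol] = 0.0
            else:
                out.loc[vals.index, zcol] = (vals - vals.mean()) / sd
    return out


def aggregate_subjects(
    table: pd.DataFrame,
    recall_outcomes: pd.DataFrame,
    min_valid_frac: float = 0.25,
    trials_per_valence: int = 24,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Mean z-feature per subject x valence over valid trials, plus the
    per-valence free-recall count.

    Cells resting on fewer than ``min_valid_frac`` of the valence's trials
    (default 6 of 24) are dropped.  ``recall_outcomes`` needs columns
    ``subject_id, picture_id, recalled``.
    """
    features = features or FEATURES
    zcols = [f"z_{f}" for f in features if f"z_{f}" in table.columns]
    valid = table["valid"] if "valid" in table.columns else pd.Series(True, index=table.index)
    t = table[valid].copy()
    t = t[t["valence"] != "scrambled"]
    min_trials = int(np.ceil(min_valid_frac * trials_per_valence))

    recall = recall_outcomes.merge(
        table[["subject_id", "picture_id", "valence"]].drop_duplicates(),
        on=["subject_id", "picture_id"],
        how="left",
    )
    recall_counts = (
        recall[recall["valence"].notna() & (recall["valence"] != "scrambled")]
        .groupby(["subject_id", "valence"], observed=True)["recalled"]
        .sum()
        .rename("recall_count")
    )

    rows = []
    for (subj, val), grp in t.groupby(["subject_id", "valence"], observed=True):
        n_valid = len(grp)
        if n_valid < min_trials:
            continue
        row = {"subject_id": subj, "valence": val, "n_valid_trials": n_valid}
        for zc in zcols:
            row[zc] = float(grp[zc].mean())
        row["recall_count"] = float(recall_counts.get((subj, val), np.nan))
        rows.append(row)
    return pd.DataFrame(rows)
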