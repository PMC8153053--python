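"""Guided-viewing scan paths, compliance scoring and the condition analysis.

A moving circle steers gaze through a picture's AOIs.  Three conditions:

* ``area_of_no_interest`` — one halt on the central AOI, then
  AOIs_pic - 1 halts on areas of no interest;
* ``guided_fixation`` — one halt on every interest AOI;
* ``guided_fixation_x2`` — every interest AOI twice, the second pass
  repeating the first pass's order.

Every path fixates for exactly 7000 ms in total, split equally over its
halts (kept as exact rationals), with transitions at 200 deg/s; total
presentation time therefore varies with the scan-path geometry but the
fixated exposure never does.  Compliance of recorded gaze is scored by
the Pearson correlation between the rendered circle trajectory and the
gaze trace, and by the latency between each halt onset and the first
gaze sample inside the target (searched within 416.67 ms).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import fdr_bh
from .types import AOISet, GazeRecording, PathSegment, ScanPath

TOTAL_FIXATED_MS = Fraction(7000)
TRANSITION_SPEED_DEG_S = 200.0
LAG_WINDOW_MS = 50 / 120 * 1000.0  # 50 samples at 120 Hz = 416.67 ms

CONDITIONS = ("area_of_no_interest", "guided_fixation", "guided_fixation_x2")


def match_picture_sets(pictures: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Partition 54 pictures into 3 sets of 18, matched on valence
    (6 per valence per set), AOI count and memorability.

    Within each valence, pictures are ordered by (AOIs_pic, memorability)
    and dealt round-robin, which balances both quantities across sets.
    Requires columns ``picture_id, valence, aois_pic, memorability``.
    """
    df = pictures.copy()
    valences = sorted(df["valence"].unique())
    if len(df) != 54 or any((df["valence"] == v).sum() != 18 for v in valences):
        raise ValueError("need 54 pictures, 18 per valence")
    if not df["aois_pic"].between(3, 8).all():
        raise ValueError("aois_pic must lie in [3, 8]")
    rng = np.random.default_rng(seed)
    df["set"] = -1
    for v in valences:
        sub = df[df["valence"] == v].copy()
        # seeded jitter breaks ties reproducibly before the deal
        sub["_r"] = rng.random(len(sub))
        sub = sub.sort_values(["aois_pic", "memorability", "_r"])
        df.loc[sub.index, "set"] = np.arange(len(sub)) % 3
    return df.drop(columns=[c for c in ("_r",) if c in df.columns])


def _center_aoi_index(aoi_set: AOISet) -> int:
    """Interest AOI nearest the screen centre (the path's first halt)."""
    d = [np.hypot(*a.centroid_deg) for a in aoi_set.interest]
    return int(np.argmin(d))


def build_scan_path(
    aoi_set: AOISet, condition: str, rng: np.random.Generator
) -> ScanPath:
    """Moving-circle schedule for one trial.

    Halt count n is AOIs_pic (or doubled); each halt lasts exactly
    7000/n ms; the order is a uniform shuffle of the non-centre targets
    with the centre AOI always first.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    k = aoi_set.aois_pic
    interest = aoi_set.interest
    no_interest = aoi_set.no_interest
    center = _center_aoi_index(aoi_set)
    if condition == "area_of_no_interest":
        if len(no_interest) < k - 1:
            raise ValueError(
                f"need >= {k - 1} no-interest centroids, have {len(no_interest)}"
            )
        picked = list(rng.permutation(len(no_interest))[: k - 1])
        targets = [(interest[center].centroid_deg, "interest")] + [
            (no_interest[i].centroid_deg, "no_interest") for i in picked
        ]
    else:
        others = [i for i in range(k) if i != center]
        order = [center] + [others[i] for i in rng.permutation(len(others))]
        targets = [(interest[i].centroid_deg, "interest") for i in order]
        if condition == "guided_fixation_x2":
            targets = targets + targets  # second pass repeats the first order
    n = len(targets)
    if not 3 <= n <= 16:
        raise ValueError(f"halt count {n} outside [3, 16]")
    halt = TOTAL_FIXATED_MS / n
    radius = float(np.mean([a.radius_deg for a in interest]))
    return ScanPath(
        picture_id=aoi_set.picture_id,
        condition=condition,
        segments=[PathSegment(t, halt, kind) for t, kind in targets],
        circle_radius_deg=radius,
        transition_speed_deg_s=TRANSITION_SPEED_DEG_S,
    )


def schedule_trials(
    sets: pd.DataFrame,
    condition_by_set: dict[int, str],
    rng: np.random.Generator,
    max_run: int = 4,
    max_tries: int = 10_000,
) -> pd.DataFrame:
    """Quasi-random trial order: each picture once, with at most
    ``max_run`` consecutive trials of identical valence and of identical
    set, found by rejection sampling."""
    df = sets.copy()
    for _ in range(max_tries):
        perm = rng.permutation(len(df))
        cand = df.iloc[perm].reset_index(drop=True)
        ok = True
        for col in ("valence", "set"):
            run = 1
            vals = cand[col].to_numpy()
            for a, b in zip(vals[:-1], vals[1:]):
                run = run + 1 if a == b else 1
                if run > max_run:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            cand["condition"] = cand["set"].map(condition_by_set)
            cand["trial_id"] = np.arange(len(cand))
            return cand
    raise RuntimeError(
        f"no ordering satisfying runs <= {max_run} for valence and set "
        f"found in {max_tries} tries"
    )


def render_path(path: ScanPath, sampling_rate_hz: float) -> pd.DataFrame:
    """Expected circle position sampled on the recording grid.

    Columns ``t_ms, x_deg, y_deg``; also used to synthesise perfectly
    compliant gaze in tests.
    """
    dt = 1000.0 / sampling_rate_hz
    # absolute segment boundaries
    bounds = []  # (halt_start, halt_end, target); legs in between
    t = 0.0
    for i, seg in enumerate(path.segments):
        halt = float(seg.halt_ms)
        bounds.append((t, t + halt, seg.target_deg))
        t += halt
        if i + 1 < len(path.segments):
            nxt = path.segments[i + 1].target_deg
            leg = float(np.hypot(nxt[0] - seg.target_deg[0], nxt[1] - seg.target_deg[1]))
            t += leg / path.transition_speed_deg_s * 1000.0
    total = t
    ts = np.arange(0.0, total, dt)
    x = np.empty(len(ts))
    y = np.empty(len(ts))
    for i_s, tt in enumerate(ts):
        # find the containing halt or leg
        pos = None
        for i, (h0, h1, tgt) in enumerate(bounds):
            if h0 - 1e-9 <= tt < h1 - 1e-9:
                pos = tgt
                break
            if i + 1 < len(bounds) and h1 - 1e-9 <= tt < bounds[i + 1][0] - 1e-9:
                nxt = bounds[i + 1][2]
                frac = (tt - h1) / (bounds[i + 1][0] - h1)
                pos = (
                    tgt[0] + frac * (nxt[0] - tgt[0]),
                    tgt[1] + frac * (nxt[1] - tgt[1]),
                )
                break
        if pos is None:
            pos = bounds[-1][2]
        x[i_s], y[i_s] = pos
    return pd.DataFrame({"t_ms": ts, "x_deg": x, "y_deg": y})


def halt_onsets(path: ScanPath) -> list[tuple[float, tuple[float, float]]]:
    """Absolute onset time and target of every halt."""
    out = []
    t = 0.0
    for i, seg in enumerate(path.segments):
        out.append((t, seg.target_deg))
        t += float(seg.halt_ms)
        if i + 1 < len(path.segments):
            nxt = path.segments[i + 1].target_deg
            leg = float(np.hypot(nxt[0] - seg.target_deg[0], nxt[1] - seg.target_deg[1]))
            t += leg / path.transition_speed_deg_s * 1000.0
    return out


@dataclass(frozen=True)
class ComplianceScore:
    trial_id: int
    path_correlation: float
    mean_arrival_lag_ms: float | None
    n_halts_found: int
    n_halts: int


def score_compliance(
    recording: GazeRecording,
    path: ScanPath,
    trial_id: int = 0,
    lag_window_ms: float = LAG_WINDOW_MS,
    correlation_mode: str = "concatenated",
) -> ComplianceScore:
    """Gaze-vs-circle agreement for one trial.

    The expected circle position is rendered at the recording rate and
    correlated with gaze (by default on the concatenation of the x and y
    series; ``correlation_mode="per_axis"`` averages the two axis-wise
    correlations instead).  Arrival lag per halt is the delay until the
    first gaze sample within the circle radius of the new target,
    searched within ``lag_window_ms`` of halt onset.
    """
    tr = recording.trial_samples(trial_id)
    if tr.empty:
        raise ValueError(f"recording has no samples for trial {trial_id}")
    geom = recording.geometry
    gx, gy = geom.px_to_deg(tr["x_px"].to_numpy(float), tr["y_px"].to_numpy(float))
    gx = np.asarray(gx, float)
    gy = np.asarray(gy, float)
    t = tr["t_ms"].to_numpy(float) - float(tr["t_ms"].iloc[0])

    expected = render_path(path, recording.sampling_rate_hz)
    n = min(len(expected), len(t))
    if n < 3:
        raise ValueError("no usable overlap between recording and path timeline")
    ex = expected["x_deg"].to_numpy()[:n]
    ey = expected["y_deg"].to_numpy()[:n]
    if correlation_mode == "per_axis":
        rx = sps.pearsonr(gx[:n], ex).statistic
        ry = sps.pearsonr(gy[:n], ey).statistic
        r = float((rx + ry) / 2.0)
    else:
        r = float(
            sps.pearsonr(
                np.concatenate([gx[:n], gy[:n]]), np.concatenate([ex, ey])
            ).statistic
        )

    lags = []
    found = 0
    radius = path.circle_radius_deg
    for onset, tgt in halt_onsets(path):
        # arrival is referenced to the first displayed frame of the halt
        i0 = int(np.searchsorted(t, onset - 1e-9))
        if i0 >= len(t):
            continue
        onset_grid = t[i0]
        m = (t >= onset_grid - 1e-9) & (t <= onset_grid + lag_window_ms + 1e-9)
        idx = np.flatnonzero(m)
        hit = None
        for i in idx:
            if np.hypot(gx[i] - tgt[0], gy[i] - tgt[1]) <= radius:
                hit = t[i] - onset_grid
                break
        if hit is not None:
            lags.append(hit)
            found += 1
    mean_lag = float(np.mean(lags)) if lags else None
    return ComplianceScore(
        trial_id=trial_id,
        path_correlation=r,
        mean_arrival_lag_ms=mean_lag,
        n_halts_found=found,
        n_halts=len(path.segments),
    )


def percent_change(mean_ref: float, mean_new: float) -> float:
    """Percent change of a condition mean relative to a reference mean."""
    return (mean_new - mean_ref) / mean_ref * 100.0


def fit_condition_effect(recall: pd.DataFrame) -> dict:
    """Condition effect on free recall.

    ``recall`` needs one row per subject x condition with columns
    ``subject_id, condition, recall_count`` and optional ``sex, age``.
    Random-intercept mixed model, Wald F for the condition factor, two
    post-hoc paired contrasts (guided_fixation vs area_of_no_interest and
    guided_fixation_x2 vs guided_fixation) FDR-corrected over 2, and
    percent changes between condition means.
    """
    import statsmodels.formula.api as smf

    from .stats import _fit_lmm, _inner_df, _wald_f, r2_beta

    counts = recall.groupby("subject_id")["condition"].nunique()
    complete = counts[counts == len(CONDITIONS)].index
    dropped = sorted(set(recall["subject_id"]) - set(complete))
    data = recall[recall["subject_id"].isin(complete)].copy()
    if data["subject_id"].nunique() < 3:
        raise ValueError("need at least 3 subjects with all conditions")

    formula = "recall_count ~ C(condition)"
    covars = []
    if "sex" in data.columns and data["sex"].nunique() > 1:
        covars.append("C(sex)")
    if "age" in data.columns and data["age"].nunique() > 1:
        covars.append("age")
    if covars:
        formula += " + " + " + ".join(covars)
    res, kind = _fit_lmm(formula, data)
    cond_names = [n for n in res.model.exog_names if "condition" in n]
    f_cond, q = _wald_f(res, cond_names)
    df_den = _inner_df(data, len(cond_names))
    p_cond = float(sps.f.sf(f_cond, q, df_den))

    means = data.groupby("condition")["recall_count"].mean()
    wide = data.pivot_table(
        index="subject_id", columns="condition", values="recall_count"
    )
    contrasts = [
        ("guided_fixation", "area_of_no_interest"),
        ("guided_fixation", "guided_fixation_x2"),
    ]
    rows = []
    for ref, other in contrasts:
        diff = wide[other] - wide[ref]
        tt = sps.ttest_rel(wide[other], wide[ref])
        df_t = len(diff) - 1
        r2, lo, hi = r2_beta(float(tt.statistic) ** 2, 1, df_t)
        rows.append(
            {
                "contrast": f"{other}_vs_{ref}",
                "t": float(tt.statistic),
                "df": df_t,
                "p": float(tt.pvalue),
                "percent_change": percent_change(means[ref], means[other]),
                "R2_beta": r2,
                "R2_beta_ci": [lo, hi],
            }
        )
    posthoc = pd.DataFrame(rows)
    posthoc["p_fdr"] = fdr_bh(posthoc["p"].to_numpy())
    return {
        "model": kind,
        "condition_F": f_cond,
        "condition_df": [q, df_den],
        "condition_p": p_cond,
        "condition_means": means.to_dict(),
        "posthoc": posthoc,
        "dropped_subjects": dropped,
    }
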