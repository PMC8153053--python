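"""Mixed-model association between exploration features and free recall.

Per feature, the per-subject-per-valence recall count is modelled as

    recall_count ~ z_feature * valence + sex + age + goggles + recall_room

with a random intercept per subject.  The interaction with valence is
tested first (Wald F, FDR-corrected over the four features); when it is
not significant the model is refit without it and the feature's main
effect is reported (FDR over four).  A significant interaction keeps the
full model for the main effect and triggers three per-valence post-hoc
tests (FDR over three).  Effect sizes are the generalized semipartial
R-squared for mixed models, with confidence limits from inverting the
noncentral-F distribution for the noncentrality parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .features import ANALYSIS_FEATURES

ALPHA = 0.05


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def r2_beta(
    f_stat: float, q_num_df: float, nu_den_df: float, conf: float = 0.95
) -> tuple[float, float, float]:
    """Generalized semipartial R^2 for a fixed effect in a mixed model.

    R2 = (q/nu) F / (1 + (q/nu) F).  The confidence interval inverts the
    noncentral-F distribution of the observed statistic for its
    noncentrality parameter and maps the bounds through the same formula
    (lower bound floored at zero).
    """
    if not np.isfinite(f_stat):
        raise ValueError("F statistic must be finite")
    if f_stat < 0 or q_num_df <= 0 or nu_den_df <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    ratio = (q_num_df / nu_den_df) * f_stat
    r2 = ratio / (1.0 + ratio)

    lo_q = (1.0 - conf) / 2.0

    def ncp_to_r2(nc: float) -> float:
        return (nc / nu_den_df) / (1.0 + nc / nu_den_df)

    def solve(prob: float) -> float | None:
        # find nc with P(F_{q,nu,nc} <= f_stat) == prob; cdf decreases in nc
        f0 = sps.ncf.cdf(f_stat, q_num_df, nu_den_df, 0.0)
        if f0 <= prob:
            return None  # no positive solution
        hi = max(10.0, 4.0 * q_num_df * max(f_stat, 1.0))
        while sps.ncf.cdf(f_stat, q_num_df, nu_den_df, hi) > prob:
            hi *= 2.0
            if hi > 1e8:
                return None
        return brentq(
            lambda nc: sps.ncf.cdf(f_stat, q_num_df, nu_den_df, nc) - prob, 0.0, hi
        )

    nc_lo = solve(1.0 - lo_q)  # cdf == 0.975 -> lower bound
    nc_hi = solve(lo_q)  # cdf == 0.025 -> upper bound
    ci_low = 0.0 if nc_lo is None else ncp_to_r2(nc_lo)
    ci_high = r2 if nc_hi is None else ncp_to_r2(nc_hi)
    return float(r2), float(ci_low), float(max(ci_high, ci_low))


@dataclass
class AssociationResult:
    """Mixed-model results for one exploration feature."""

    feature: str
    main_t: float
    main_df: float
    main_p: float
    main_p_fdr: float | None
    interaction_f: float
    interaction_df: tuple[float, float]
    interaction_p: float
    interaction_p_fdr: float | None
    interaction_significant: bool
    r2: float
    r2_ci: tuple[float, float]
    posthoc: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "feature": self.feature,
            "main_t": self.main_t,
            "main_df": self.main_df,
            "main_p": self.main_p,
            "main_p_fdr": self.main_p_fdr,
            "interaction_F": self.interaction_f,
            "interaction_df": list(self.interaction_df),
            "interaction_p": self.interaction_p,
            "interaction_p_fdr": self.interaction_p_fdr,
            "R2_beta": self.r2,
            "R2_beta_ci": list(self.r2_ci),
            "notes": self.notes,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def _covariate_terms(data: pd.DataFrame) -> list[str]:
    terms = []
    for c in ("sex", "goggles", "recall_room"):
        if c in data.columns and data[c].nunique() > 1:
            terms.append(f"C({c})")
    if "age" in data.columns and data["age"].nunique() > 1:
        terms.append("age")
    return terms


def _inner_df(data: pd.DataFrame, n_within_params: int) -> float:
    """nlme-style denominator df for within-subject fixed effects."""
    return len(data) - data["subject_id"].nunique() - n_within_params


def _fit_lmm(formula: str, data: pd.DataFrame):
    """Random-intercept LMM; falls back to subject fixed effects on a
    singular or non-converging fit."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "lbfgs", "powell"):
            try:
                model = smf.mixedlm(formula, data, groups=data["subject_id"])
                kwargs = {} if method is None else {"method": method}
                res = model.fit(reml=True, **kwargs)
                if np.isfinite(res.params).all() and np.isfinite(res.bse_fe).all():
                    return res, "lmm"
            except Exception:
                continue
        # downgraded fit: subject as a fixed factor, OLS
        res = smf.ols(formula + " + C(subject_id)", data).fit()
        return res, "ols_subject_fe"


def _wald_f(res, names: list[str]) -> tuple[float, int]:
    """Joint Wald test of the named fixed-effect coefficients; returns
    (F, q) with F = chi2 / q."""
    exog_names = list(res.model.exog_names)
    idx = [exog_names.index(n) for n in names]
    k = len(res.params)
    L = np.zeros((len(idx), k))
    for r, i in enumerate(idx):
        L[r, i] = 1.0
    w = res.wald_test(L, scalar=True)
    chi2 = float(np.squeeze(w.statistic))
    return chi2 / len(idx), len(idx)


def fit_association(
    aggregates: pd.DataFrame,
    feature_name: str,
    interaction_significant: bool | None = None,
) -> AssociationResult:
    """Mixed-model association of one z-feature with recall counts.

    ``interaction_significant`` may be forced by the caller (after the
    FDR step across features); by default the raw interaction p at 0.05
    decides whether the main effect comes from the full or reduced model.
    """
    zcol = f"z_{feature_name}"
    data = aggregates.dropna(subset=[zcol, "recall_count"]).copy()
    n_subj = data["subject_id"].nunique()
    cells = data.groupby("subject_id")["valence"].nunique()
    if n_subj < 20 or (cells >= 2).sum() < 20:
        raise ValueError(
            "need at least 20 subjects with at least 2 valence cells each "
            f"(have {int((cells >= 2).sum())})"
        )
    covars = _covariate_terms(data)
    base = f"recall_count ~ {zcol} * C(valence)"
    if covars:
        base += " + " + " + ".join(covars)
    notes: list[str] = []

    res_full, kind = _fit_lmm(base, data)
    if kind != "lmm":
        notes.append("singular LMM; downgraded to subject fixed effects")
    inter_names = [
        n for n in res_full.model.exog_names if ":" in n and zcol in n
    ]
    f_int, q_int = _wald_f(res_full, inter_names)
    n_within = len(
        [n for n in res_full.model.exog_names if zcol in n or "valence" in n]
    )
    df_int = _inner_df(data, n_within)
    p_int = float(sps.f.sf(f_int, q_int, df_int))

    if interaction_significant is None:
        interaction_significant = p_int < ALPHA

    if interaction_significant:
        # keep the interaction; main effect from the full model
        t_main = float(res_full.params[zcol] / res_full.bse[zcol])
        df_main = df_int
        posthoc = _posthoc_per_valence(data, zcol, covars)
    else:
        reduced = f"recall_count ~ {zcol} + C(valence)"
        if covars:
            reduced += " + " + " + ".join(covars)
        res_red, kind_r = _fit_lmm(reduced, data)
        if kind_r != "lmm":
            notes.append("singular reduced LMM; downgraded")
        t_main = float(res_red.params[zcol] / res_red.bse[zcol])
        n_within_r = len(
            [n for n in res_red.model.exog_names if zcol in n or "valence" in n]
        )
        df_main = _inner_df(data, n_within_r)
        posthoc = None
    p_main = float(2.0 * sps.t.sf(abs(t_main), df_main))
    r2, lo, hi = r2_beta(t_main**2, 1, df_main)
    return AssociationResult(
        feature=feature_name,
        main_t=t_main,
        main_df=df_main,
        main_p=p_main,
        main_p_fdr=None,
        interaction_f=f_int,
        interaction_df=(q_int, df_int),
        interaction_p=p_int,
        interaction_p_fdr=None,
        interaction_significant=bool(interaction_significant),
        r2=r2,
        r2_ci=(lo, hi),
        posthoc=posthoc,
        notes=notes,
    )


def _posthoc_per_valence(
    data: pd.DataFrame, zcol: str, covars: list[str]
) -> pd.DataFrame:
    """Per-valence feature effect (one row per subject per valence -> OLS),
    FDR-corrected over the three valences."""
    rows = []
    for val, grp in data.groupby("valence", observed=True):
        formula = f"recall_count ~ {zcol}"
        cv = [c for c in covars if grp[c.replace("C(", "").rstrip(")")].nunique() > 1] if covars else []
        if cv:
            formula += " + " + " + ".join(cv)
        res = smf.ols(formula, grp).fit()
        rows.append(
            {
                "valence": val,
                "t": float(res.tvalues[zcol]),
                "df": float(res.df_resid),
                "p": float(res.pvalues[zcol]),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    return out


def run_association_analysis(
    aggregates: pd.DataFrame, features: list[str] | None = None
) -> dict[str, AssociationResult]:
    """The full multi-feature scheme: interaction FDR across features,
    conditional refit, then main-effect FDR across features."""
    features = features or ANALYSIS_FEATURES
    first_pass = {f: fit_association(aggregates, f) for f in features}
    p_int = fdr_bh([first_pass[f].interaction_p for f in features])
    results: dict[str, AssociationResult] = {}
    for f, p_adj in zip(features, p_int):
        sig = p_adj < ALPHA
        res = (
            first_pass[f]
            if first_pass[f].interaction_significant == sig
            else fit_association(aggregates, f, interaction_significant=sig)
        )
        res.interaction_p_fdr = float(p_adj)
        results[f] = res
    p_main = fdr_bh([results[f].main_p for f in features])
    for f, p_adj in zip(features, p_main):
        results[f].main_p_fdr = float(p_adj)
    return results
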