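"""Carryover decomposition across visits and score-outcome association.

``carryover_decomposition`` regresses the sibling score at each visit on
all prior visits' scores (entered in temporal order, recording each term's
added explained variance) plus current sibling status (tested adjusted for
all prior scores, i.e. type II), separating the *direct* effect of having
siblings now from the *carryover* of the microbial sibling signature laid
down at earlier visits.

``associate_outcome`` relates a standardized logit-transformed sibling
score to a binary clinical outcome by logistic regression (odds ratio per
1 SD of the score in the analyzed population), unadjusted, adjusted for
sibling status, or stratified by it; ``associate_count_outcome`` does the
same for count outcomes with a quasi-Poisson model (Poisson likelihood,
Pearson-dispersion-scaled standard errors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit

LOGIT_EPS = 1e-6
MODEL_VARIANTS = ("crude", "adjusted", "stratified_siblings",
                  "stratified_no_siblings")


# ---------------------------------------------------------------------
# carryover
# ---------------------------------------------------------------------

@dataclass
class CarryoverDecomposition:
    table: pd.DataFrame
    """Long format: one row per (visit, term) with columns
    ``component`` (fraction of the visit's score variance), ``F``, ``p``,
    ``kind`` in {carryover, direct, residual}, and ``n``."""


def _ols_rss(y, X):
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    return float(fit.ssr), fit


def carryover_decomposition(scores_by_visit: pd.DataFrame,
                            status_by_visit: pd.DataFrame,
                            min_n: int = 10) -> CarryoverDecomposition:
    """Consecutive type-II variance decomposition of per-visit scores.

    Parameters
    ----------
    scores_by_visit : DataFrame, children x visits (temporal column order).
    status_by_visit : DataFrame, children x visits, binary current sibling
        status (older sibling present at that visit).

    For visit t the model ``score_t ~ score_1 + ... + score_{t-1} +
    status_t`` is fitted on children observed at all entering visits;
    each prior score's component is its added explained variance in entry
    order, and the status component is its type-II (adjusted for all prior
    scores) contribution, both with F-test p-values against the full-model
    residual.
    """
    visits = list(scores_by_visit.columns)
    if len(visits) < 2:
        raise ValueError("need >= 2 visits")
    rows = []
    for t in range(1, len(visits)):
        cur = visits[t]
        prior = visits[:t]
        df = pd.concat(
            [scores_by_visit[prior + [cur]],
             status_by_visit[cur].rename("status")], axis=1).dropna()
        n = len(df)
        if n < min_n:
            raise ValueError(
                f"visit {cur!r}: only {n} complete cases (< {min_n})")
        y = df[cur].to_numpy(dtype=float)
        tot = ((y - y.mean()) ** 2).sum()
        X_all = df[prior + ["status"]].to_numpy(dtype=float)
        rss_full, fit_full = _ols_rss(y, X_all)
        df_res = n - X_all.shape[1] - 1
        mse = rss_full / df_res
        # collinearity note rather than hard failure
        rank = np.linalg.matrix_rank(sm.add_constant(X_all))
        note = "" if rank == X_all.shape[1] + 1 else "aliased regressors"
        # prior scores: consecutive added variance
        rss_prev = tot
        for j, term in enumerate(prior):
            rss_j, _ = _ols_rss(y, df[prior[:j + 1]].to_numpy(dtype=float))
            ss_add = max(rss_prev - rss_j, 0.0)
            f = ss_add / mse if mse > 0 else np.inf
            p = float(stats.f.sf(f, 1, df_res)) if np.isfinite(f) else 0.0
            rows.append({"visit": cur, "term": f"score_{term}",
                         "kind": "carryover", "component": ss_add / tot,
                         "F": f, "p": p, "n": n, "note": note})
            rss_prev = rss_j
        # status: type II (drop from full model)
        rss_nostat, _ = _ols_rss(y, df[prior].to_numpy(dtype=float))
        ss_stat = max(rss_nostat - rss_full, 0.0)
        f = ss_stat / mse if mse > 0 else np.inf
        p = float(stats.f.sf(f, 1, df_res)) if np.isfinite(f) else 0.0
        rows.append({"visit": cur, "term": "status", "kind": "direct",
                     "component": ss_stat / tot, "F": f, "p": p, "n": n,
                     "note": note})
        rows.append({"visit": cur, "term": "residual", "kind": "residual",
                     "component": rss_full / tot, "F": np.nan, "p": np.nan,
                     "n": n, "note": note})
    return CarryoverDecomposition(pd.DataFrame(rows))


# ---------------------------------------------------------------------
# outcome association
# ---------------------------------------------------------------------

@dataclass
class AssociationResult:
    outcome: str
    model: str
    estimate: float        # OR (binary) or rate ratio (count) per 1 SD
    ci_low: float
    ci_high: float
    p: float
    n: int
    estimate_per_percentile: float | None = None
    note: str = ""
    compartment: str | None = None
    visit: str | None = None


def standardized_logit(scores: pd.Series, eps: float = LOGIT_EPS) -> pd.Series:
    """z = (logit(score) - mean) / sd with scores clipped to [eps, 1-eps].

    Standardization is over the analyzed sample, so Var(z) = 1 and the
    regression coefficient is per one population SD of the logit score.
    """
    s = pd.Series(scores).astype(float).clip(eps, 1 - eps)
    lz = pd.Series(logit(s), index=s.index)
    sd = lz.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("score is constant: standardized logit undefined")
    return (lz - lz.mean()) / sd


def _variant_subset(df: pd.DataFrame, model: str) -> pd.DataFrame:
    if model == "stratified_siblings":
        return df[df["status"] == 1]
    if model == "stratified_no_siblings":
        return df[df["status"] == 0]
    return df


def associate_outcome(scores, outcome, status, model: str = "crude",
                      outcome_name: str = "outcome",
                      eps: float = LOGIT_EPS, **meta) -> AssociationResult:
    """Logistic regression of a binary outcome on the standardized logit
    sibling score; the OR is per 1 SD.  ``model`` selects crude, adjusted
    (+ sibling status), or status-stratified fits.

    The per-SD estimate is reported alongside an OR per percentile of the
    raw probability score (``estimate_per_percentile``), since per-SD and
    per-percentile scalings are both in circulation for such scores.
    """
    if model not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {model!r}")
    df = pd.concat([pd.Series(scores, name="score"),
                    pd.Series(outcome, name="y"),
                    pd.Series(status, name="status")], axis=1).dropna()
    df["z"] = standardized_logit(df["score"], eps=eps)
    df = _variant_subset(df, model)
    n = len(df)
    y = df["y"].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"{model}: outcome has a single class in stratum")
    cols = ["z", "status"] if model == "adjusted" else ["z"]
    X = sm.add_constant(df[cols].astype(float))
    note = ""
    try:
        fit = sm.Logit(y, X).fit(disp=0)
        if not np.isfinite(fit.bse["z"]):
            raise np.linalg.LinAlgError
    except Exception:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-4, L1_wt=0.0)
        note = "separation: L2-penalized fallback, CI unavailable"
    beta = float(fit.params["z"])
    if note:
        ci_lo = ci_hi = np.nan
        p = np.nan
    else:
        lo, hi = fit.conf_int().loc["z"]
        ci_lo, ci_hi = float(np.exp(lo)), float(np.exp(hi))
        p = float(fit.pvalues["z"])
    # per-percentile scaling on the raw probability score
    Xr = sm.add_constant(df[["score"] + (["status"] if model == "adjusted"
                                         else [])].astype(float))
    try:
        fr = sm.Logit(y, Xr).fit(disp=0)
        per_pct = float(np.exp(fr.params["score"] * 0.01))
    except Exception:
        per_pct = None
    return AssociationResult(
        outcome=outcome_name, model=model, estimate=float(np.exp(beta)),
        ci_low=ci_lo, ci_high=ci_hi, p=p, n=n,
        estimate_per_percentile=per_pct, note=note, **meta)


def associate_count_outcome(scores, counts, status, model: str = "crude",
                            outcome_name: str = "infection_count",
                            eps: float = LOGIT_EPS, **meta) -> AssociationResult:
    """Quasi-Poisson regression of a count outcome on the standardized
    logit sibling score; the rate ratio is per 1 SD, with standard errors
    scaled by the Pearson dispersion."""
    if model not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {model!r}")
    df = pd.concat([pd.Series(scores, name="score"),
                    pd.Series(counts, name="y"),
                    pd.Series(status, name="status")], axis=1).dropna()
    if (df["y"] < 0).any() or not np.allclose(df["y"], np.round(df["y"])):
        raise ValueError("count outcome must be non-negative integers")
    df["z"] = standardized_logit(df["score"], eps=eps)
    df = _variant_subset(df, model)
    n = len(df)
    cols = ["z", "status"] if model == "adjusted" else ["z"]
    X = sm.add_constant(df[cols].astype(float))
    fit = sm.GLM(df["y"].astype(float), X,
                 family=sm.families.Poisson()).fit(scale="X2")
    beta = float(fit.params["z"])
    lo, hi = fit.conf_int().loc["z"]
    return AssociationResult(
        outcome=outcome_name, model=model, estimate=float(np.exp(beta)),
        ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
        p=float(fit.pvalues["z"]), n=n, note="quasi-poisson", **meta)


def association_table(results) -> pd.DataFrame:
    """Long-format table of AssociationResults (one row per fit)."""
    return pd.DataFrame([{
        "outcome": r.outcome, "compartment": r.compartment, "visit": r.visit,
        "model": r.model, "estimate": r.estimate, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "p": r.p, "n": r.n, "note": r.note}
        for r in results])
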