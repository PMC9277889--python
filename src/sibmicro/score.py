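"""The microbiota-derived sibling score.

A sample's sibling score is the cross-validated probability that its child
has one or more older siblings, predicted by linear discriminant analysis
from the leading ordination axes (default: first 10 PCoA components of a
weighted UniFrac matrix) of that compartment and visit.  Because every
score comes from a model that never saw the sample's fold, the score is not
overfitted towards class separation: under null labels its cross-validated
AUC centres on 0.5.

The ordination is computed once on all samples before fold splitting
(matching the usual construction); an optional ``strict`` mode re-embeds
each training fold and projects held-out samples out-of-sample, closing the
small information leak this creates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.manifold import MDS as _SKMDS
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .diversity import OrdinationResult, gower_center, pcoa
from .community import _as_array

DEFAULT_COMPONENTS = 10
DEFAULT_FOLDS = 10


# ---------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------

def mds_components(dm, k: int = DEFAULT_COMPONENTS,
                   method: str = "pcoa", seed=None) -> pd.DataFrame:
    """First ``k`` ordination axes of a distance matrix.

    ``method='pcoa'`` (metric MDS; default) orders axes by eigenvalue and
    returns at most the number of positive axes, warning when fewer than
    ``k`` are available.  ``method='nmds'`` uses non-metric SMACOF.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d, ids = _as_array(dm)
    if k > len(d) - 1:
        raise ValueError("k must be <= n - 1")
    if method == "pcoa":
        res = pcoa(d, k=k, sample_ids=ids)
        return res.samples
    if method == "nmds":
        m = _SKMDS(n_components=k, metric=False, dissimilarity="precomputed",
                   random_state=np.random.default_rng(seed).integers(2**31),
                   normalized_stress="auto", n_init=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = m.fit_transform(d)
        return pd.DataFrame(coords, index=ids,
                            columns=[f"NMDS{i+1}" for i in range(k)])
    raise ValueError(f"unknown embedding method {method!r}")


def pcoa_project(d_train: np.ndarray, d_new_to_train: np.ndarray, k: int):
    """Out-of-sample PCoA projection (for strict per-fold embedding).

    Returns ``(train_coords, new_coords)`` on the training axes, using the
    standard Gower-centering projection of new squared distances onto the
    training eigenbasis.
    """
    g = gower_center(d_train)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    v = eigvecs[:, pos][:, :k]
    lam = eigvals[pos][:k]
    train = v * np.sqrt(lam)
    a_new = -0.5 * d_new_to_train ** 2
    a_tr = -0.5 * d_train ** 2
    centered = (a_new - a_new.mean(axis=1, keepdims=True)
                - a_tr.mean(axis=0, keepdims=True) + a_tr.mean())
    new = centered @ v / np.sqrt(lam)
    return train, new


# ---------------------------------------------------------------------
# linear discriminant analysis
# ---------------------------------------------------------------------

@dataclass
class LDAModel:
    """Two-class Gaussian LDA with pooled covariance and empirical priors.

    Posterior P(class 1 | x) = logistic(w.x + b) with
    w = Sigma_pooled^-1 (mu1 - mu0); a ridge eps = 1e-8 * trace/dim is added
    when the pooled covariance is singular.
    """

    w: np.ndarray
    b: float
    classes: tuple
    ridge_used: bool = False


def lda_fit(X, labels) -> LDAModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) != 2:
        raise ValueError("LDA here is two-class")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("each class needs >= 2 samples")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n = len(X)
    cov = (((X0 - mu0).T @ (X0 - mu0)) + ((X1 - mu1).T @ (X1 - mu1))) / (n - 2)
    ridge_used = False
    try:
        w = np.linalg.solve(cov, mu1 - mu0)
        if not np.all(np.isfinite(w)) or np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.trace(cov) / cov.shape[0]
        cov = cov + np.eye(cov.shape[0]) * max(eps, 1e-12)
        w = np.linalg.solve(cov, mu1 - mu0)
        ridge_used = True
    pi1 = len(X1) / n
    b = float(-0.5 * (mu1 + mu0) @ w + np.log(pi1 / (1 - pi1)))
    return LDAModel(w=w, b=b, classes=classes, ridge_used=ridge_used)


def lda_posterior(model: LDAModel, X) -> np.ndarray:
    """P(class 1 | x) for each row of X."""
    X = np.asarray(X, dtype=float)
    return expit(X @ model.w + model.b)


# ---------------------------------------------------------------------
# cross-validated sibling score
# ---------------------------------------------------------------------

@dataclass
class SiblingScoreSet:
    scores: pd.DataFrame      # sample_id -> score, fold, label
    cv_auc: float
    n_components: int
    folds: int
    seed: object
    compartment: str | None = None
    visit: str | None = None
    method: str = "pcoa"


def auc_mann_whitney(labels, scores) -> float:
    """AUC as the tie-corrected Mann-Whitney probability."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))


def cv_sibling_score(dm, labels, k: int = DEFAULT_COMPONENTS,
                     folds: int = DEFAULT_FOLDS, seed=None,
                     method: str = "pcoa", strict: bool = False,
                     fold_assignment=None,
                     compartment=None, visit=None) -> SiblingScoreSet:
    """Cross-validated LDA class probabilities as a sibling score.

    The embedding is computed once on all samples (unless ``strict``);
    stratified folds keep both classes in every training split; each
    sample's score comes from the model that did not see its fold, and
    ``cv_auc`` pools all out-of-fold scores.  ``fold_assignment`` (array of
    fold indices per sample) overrides the stratified split, e.g. to hold
    folds fixed while perturbing labels.
    """
    d, ids = _as_array(dm)
    y = pd.Series(np.asarray(labels), index=ids).to_numpy()
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) != 2:
        raise ValueError("need exactly 2 classes")
    if counts.min() < folds:
        if counts.min() < 2:
            raise ValueError("minority class too small to stratify")
        folds = int(counts.min())
        warnings.warn(f"reduced folds to {folds} to keep both classes per fold")
    if fold_assignment is not None:
        fa = np.asarray(fold_assignment)
        splits = [(np.flatnonzero(fa != f), np.flatnonzero(fa == f))
                  for f in np.unique(fa)]
        folds = len(splits)
    else:
        rng_state = int(np.random.default_rng(seed).integers(2**31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=rng_state)
        splits = list(skf.split(np.zeros(len(y)), y))
    scores = np.full(len(y), np.nan)
    fold_ids = np.full(len(y), -1)
    if not strict:
        X = mds_components(d, k=min(k, len(d) - 1), method=method,
                           seed=seed).to_numpy()
        for f, (tr, te) in enumerate(splits):
            model = lda_fit(X[tr], y[tr])
            scores[te] = lda_posterior(model, X[te])
            fold_ids[te] = f
    else:
        for f, (tr, te) in enumerate(splits):
            Xtr, Xte = pcoa_project(d[np.ix_(tr, tr)], d[np.ix_(te, tr)],
                                    k=min(k, len(tr) - 1))
            model = lda_fit(Xtr, y[tr])
            scores[te] = lda_posterior(model, Xte)
            fold_ids[te] = f
    pos = max(np.unique(y).tolist())
    auc = auc_mann_whitney(y == pos, scores)
    df = pd.DataFrame({"score": scores, "fold": fold_ids,
                       "label": y}, index=ids)
    return SiblingScoreSet(df, cv_auc=auc, n_components=k, folds=folds,
                           seed=seed, compartment=compartment, visit=visit,
                           method=method)


def auc_vs_components(dms: dict, labels, k_range, folds: int = DEFAULT_FOLDS,
                      seed=None, method: str = "pcoa") -> pd.DataFrame:
    """Cross-validated AUC at each component count for each metric.

    ``dms`` maps metric name -> distance matrix over the same samples; the
    same fold assignment is reused across metrics and k for comparability.
    Component counts beyond n - 1 are truncated with a warning.
    """
    first = next(iter(dms.values()))
    d0, ids = _as_array(first)
    n = len(d0)
    k_range = [k for k in k_range if k >= 1]
    if any(k > n - 1 for k in k_range):
        warnings.warn("k_range truncated to n - 1")
        k_range = [k for k in k_range if k <= n - 1]
    y = pd.Series(np.asarray(labels), index=ids).to_numpy()
    rng_state = int(np.random.default_rng(seed).integers(2**31))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_state)
    splits = list(skf.split(np.zeros(n), y))
    pos = max(np.unique(y).tolist())
    rows = []
    for name, dm in dms.items():
        d, _ = _as_array(dm)
        kmax = min(max(k_range), n - 1)
        X_full = mds_components(d, k=kmax, method=method, seed=seed).to_numpy()
        for k in k_range:
            X = X_full[:, :min(k, X_full.shape[1])]
            scores = np.full(n, np.nan)
            for tr, te in splits:
                model = lda_fit(X[tr], y[tr])
                scores[te] = lda_posterior(model, X[te])
            rows.append({"metric": name, "k": k,
                         "cv_auc": auc_mann_whitney(y == pos, scores)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# loess score-vs-gap curves
# ---------------------------------------------------------------------

def loess(x, y, span: float = 0.75, degree: int = 2, grid=None) -> pd.DataFrame:
    """Local polynomial regression with tricube weights.

    ``span`` is the fraction of points in each local window; the fit is
    evaluated on ``grid`` (default: 100 points over the observed x range —
    never extrapolated beyond it).
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) <= degree + 1:
        raise ValueError("too few points for the local polynomial degree")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)
    q = max(degree + 1, int(np.ceil(span * len(x))))
    fitted = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        dist = np.abs(x - x0)
        dmax = np.partition(dist, q - 1)[q - 1]
        if dmax == 0:
            fitted[i] = y[dist == 0].mean()
            continue
        w = np.clip(1 - (dist / dmax) ** 3, 0, None) ** 3
        use = w > 0
        deg = min(degree, max(0, use.sum() - 1))
        coeffs = np.polyfit(x[use] - x0, y[use], deg, w=np.sqrt(w[use]))
        fitted[i] = coeffs[-1]
    return pd.DataFrame({"x": grid, "fitted": fitted})


@dataclass
class ScoreGapCurve:
    curve: pd.DataFrame            # gap grid + loess fit
    observations: pd.DataFrame     # gap, score per child with older siblings
    reference_mean: float          # mean score of children with no older sibs
    span: float
    degree: int

    def fitted_at(self, gap: float) -> float:
        c = self.curve
        if gap < c["x"].min() or gap > c["x"].max():
            raise ValueError("gap outside the fitted range")
        return float(np.interp(gap, c["x"], c["fitted"]))


def score_gap_curve(scores, exposures, span: float = 0.75, degree: int = 2,
                    gap_truncate: float = 10.0) -> ScoreGapCurve:
    """Loess fit of sibling score against age gap to the closest older
    sibling, with the mean score of children without older siblings as a
    horizontal reference.  The curve is fitted over gaps up to
    ``gap_truncate`` years only; larger gaps are excluded rather than
    clamped to the boundary, which would pile heterogeneous children onto
    one x-value and bias the right edge of the fit."""
    scores = pd.Series(scores)
    rows, ref = [], []
    for e in exposures:
        if e.child_id not in scores.index:
            continue
        s = scores[e.child_id]
        if e.n_older >= 1:
            if e.gap_closest_older > gap_truncate:
                continue
            rows.append({"child_id": e.child_id,
                         "gap": e.gap_closest_older,
                         "n_older": e.n_older, "score": s})
        else:
            ref.append(s)
    obs = pd.DataFrame(rows)
    if len(obs) < 10:
        raise ValueError("need >= 10 children with older siblings")
    fit = loess(obs["gap"], obs["score"], span=span, degree=degree)
    return ScoreGapCurve(curve=fit, observations=obs,
                         reference_mean=float(np.mean(ref)) if ref else np.nan,
                         span=span, degree=degree)
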