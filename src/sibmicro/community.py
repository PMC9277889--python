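"""Distance-based and abundance-based community hypothesis testing.

``permanova`` partitions the variance of a (Gower-centered) distance matrix
across design terms, either sequentially (terms entered in order; r-squared
values plus the residual sum to 1) or marginally (each term adjusted for
all others), with a free-permutation p-value.  ``betadisper`` checks the
homogeneity-of-dispersions assumption; ``welch_distance_ttest`` is a
two-group location test robust to unequal multivariate dispersions.
Abundance-based testing uses rank tests with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable
from .diversity import gower_center

DEFAULT_N_PERM = 9999

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


def _as_array(dm) -> tuple[np.ndarray, list]:
    if isinstance(dm, DistanceMatrix):
        return dm.data, list(dm.ids)
    d = np.asarray(dm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("expected a symmetric square distance matrix")
    return d, list(range(len(d)))


def _encode_term(values: pd.Series) -> np.ndarray:
    """Column(s) for one design term: numeric as-is, categorical dummy-coded."""
    if pd.api.types.is_numeric_dtype(values) and values.nunique() > 2:
        return values.to_numpy(dtype=float)[:, None]
    return pd.get_dummies(values.astype(str), drop_first=True)\
             .to_numpy(dtype=float)


def _basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], 0))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0
    return u[:, s > tol]


# ---------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------

@dataclass
class PermanovaResult:
    terms: pd.DataFrame            # index term; columns df, ss, r_squared, F, p
    residual_ss: float
    total_ss: float
    mode: str
    n_permutations: int
    seed: object = None
    n: int = 0

    @property
    def residual_r_squared(self) -> float:
        return self.residual_ss / self.total_ss


def permanova(dm, design: pd.DataFrame, terms=None, mode: str = "sequential",
              n_perm: int = DEFAULT_N_PERM, seed=None) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    dm : DistanceMatrix or square array
    design : DataFrame aligned with (or indexable by) the matrix's ids;
        each requested column is one term.  Rows with a missing value in
        any term are dropped (complete-case).
    mode : "sequential" (terms in order; r2 + residual r2 = 1) or
        "marginal" (each term adjusted for all others).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("sequential", "marginal"):
        raise ValueError("mode must be 'sequential' or 'marginal'")
    d, ids = _as_array(dm)
    terms = list(terms) if terms is not None else list(design.columns)
    sub = design.loc[ids, terms] if not design.index.equals(pd.Index(ids)) \
        else design[terms]
    complete = ~sub.isna().any(axis=1)
    if not complete.all():
        keep = np.flatnonzero(complete.to_numpy())
        d = d[np.ix_(keep, keep)]
        sub = sub.iloc[keep]
    n = len(d)
    for t in terms:
        vc = sub[t].value_counts()
        if not pd.api.types.is_numeric_dtype(sub[t]) and (vc < 2).any():
            warnings.warn(f"term {t!r} has groups of size < 2")

    g = gower_center(d)
    total_ss = float(np.trace(g))

    ones = np.ones((n, 1))
    blocks = [_encode_term(sub[t]) for t in terms]
    # sequential projections H_0 (intercept) .. H_k (full)
    hats, qs = [], _basis(ones)
    hats.append(qs @ qs.T)
    ranks = [qs.shape[1]]
    X = ones
    for b in blocks:
        X = np.hstack([X, b])
        q = _basis(X)
        hats.append(q @ q.T)
        ranks.append(q.shape[1])
    h_full = hats[-1]
    df_terms = np.diff(ranks)
    if mode == "sequential":
        mats = [hats[j + 1] - hats[j] for j in range(len(terms))]
        dfs = list(df_terms)
    else:
        mats, dfs = [], []
        for j in range(len(terms)):
            X_mj = np.hstack([ones] + [b for i, b in enumerate(blocks) if i != j])
            q = _basis(X_mj)
            mats.append(h_full - q @ q.T)
            dfs.append(ranks[-1] - q.shape[1])
    aliased = [terms[j] for j in range(len(terms)) if dfs[j] == 0]
    if aliased:
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    m_res = np.eye(n) - h_full
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def stats_for(gmat):
        ss_terms = np.array([(m * gmat).sum() for m in mats])
        ss_res = (m_res * gmat).sum()
        f = (ss_terms / dfs) / (ss_res / df_res)
        return ss_terms, ss_res, f

    ss_terms, ss_res, f_obs = stats_for(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, f_p = stats_for(g[np.ix_(perm, perm)])
        exceed += f_p >= f_obs
    pvals = (exceed + 1) / (n_perm + 1)

    out = pd.DataFrame({
        "df": dfs, "ss": ss_terms,
        "r_squared": ss_terms / total_ss if total_ss > 0 else np.nan,
        "F": f_obs, "p": pvals}, index=terms)
    return PermanovaResult(out, float(ss_res), total_ss, mode, n_perm, seed, n)


# ---------------------------------------------------------------------
# betadisper
# ---------------------------------------------------------------------

@dataclass
class DispersionResult:
    group_mean_dist: pd.Series     # mean distance to group centroid
    ratio: float                   # largest / smallest group mean
    F: float
    p: float
    n_permutations: int
    distances: pd.Series = field(repr=False, default=None)


def _centroid_distances(d: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Distance of every sample to its group centroid in PCoA space.

    Negative-eigenvalue axes enter as imaginary coordinates whose squared
    contribution is subtracted (the standard betadisper construction);
    tiny negative squared distances are clipped to 0.
    """
    g = gower_center(d)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    pos, neg = eigvals > 1e-10, eigvals < -1e-10
    xr = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    xi = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    z = np.empty(len(d))
    for lvl in np.unique(groups):
        m = groups == lvl
        dr = ((xr[m] - xr[m].mean(axis=0)) ** 2).sum(axis=1)
        di = ((xi[m] - xi[m].mean(axis=0)) ** 2).sum(axis=1) if xi.size else 0.0
        z[m] = np.sqrt(np.clip(dr - di, 0, None))
    return z


def betadisper(dm, groups, n_perm: int = DEFAULT_N_PERM, seed=None
               ) -> DispersionResult:
    """Homogeneity of multivariate dispersions (distance to group centroid).

    The headline statistic is the ratio of the average distance-to-centroid
    of the most over the least dispersed group; the permutation test
    permutes group labels of the centroid distances under a one-way ANOVA F.
    """
    d, ids = _as_array(dm)
    groups = pd.Series(np.asarray(groups), index=ids)
    sizes = groups.value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"excluding size-1 groups: {singletons}")
        keep = np.flatnonzero(~groups.isin(singletons).to_numpy())
        d = d[np.ix_(keep, keep)]
        groups = groups.iloc[keep]
    if groups.nunique() < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    garr = groups.to_numpy()
    z = _centroid_distances(d, garr)

    def anova_f(zv, gv):
        grand = zv.mean()
        ss_b = sum(len(zv[gv == l]) * (zv[gv == l].mean() - grand) ** 2
                   for l in np.unique(gv))
        ss_w = sum(((zv[gv == l] - zv[gv == l].mean()) ** 2).sum()
                   for l in np.unique(gv))
        df_b, df_w = len(np.unique(gv)) - 1, len(zv) - len(np.unique(gv))
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = anova_f(z, garr)
    rng = np.random.default_rng(seed)
    exceed = sum(anova_f(z, garr[rng.permutation(len(garr))]) >= f_obs
                 for _ in range(n_perm))
    p = (exceed + 1) / (n_perm + 1)
    means = pd.Series({l: z[garr == l].mean() for l in np.unique(garr)})
    ratio = float(means.max() / means.min()) if means.min() > 0 else np.inf
    return DispersionResult(means, ratio, float(f_obs), float(p), n_perm,
                            pd.Series(z, index=groups.index))


# ---------------------------------------------------------------------
# Welch-type two-group distance test
# ---------------------------------------------------------------------

@dataclass
class WelchDistanceResult:
    statistic: float
    p: float
    n_permutations: int
    group_sizes: dict


def _tw2(d2: np.ndarray, mask1: np.ndarray) -> float:
    """Welch-type T^2 from squared distances for a two-group split.

    Per-group variance s_g^2 = (sum of within-group squared distances) /
    (n_g (n_g - 1)); squared distance between centroids recovered from the
    mean cross-group squared distance minus the within-group spreads.
    """
    n1 = int(mask1.sum())
    n2 = len(mask1) - n1
    m2 = ~mask1
    w1 = d2[np.ix_(mask1, mask1)].sum() / 2.0   # sum over pairs within group 1
    w2 = d2[np.ix_(m2, m2)].sum() / 2.0
    cross = d2[np.ix_(mask1, m2)].mean()
    # SS_g = (1/n_g) sum_{j<k in g} d2_jk ; s_g^2 = SS_g / (n_g - 1)
    s1 = (w1 / n1) / (n1 - 1)
    s2 = (w2 / n2) / (n2 - 1)
    # mean cross d2 = ||mu1 - mu2||^2 + SS_1/n1 + SS_2/n2
    between2 = cross - w1 / (n1 * n1) - w2 / (n2 * n2)
    denom = s1 / n1 + s2 / n2
    if denom <= 0:
        return 0.0 if between2 <= 0 else np.inf
    return max(between2, 0.0) / denom


def welch_distance_ttest(dm, groups, n_perm: int = DEFAULT_N_PERM, seed=None
                         ) -> WelchDistanceResult:
    """Two-group multivariate Welch-type t-test on a distance matrix.

    Compares group locations while allowing unequal multivariate
    dispersions (the situation where naive PERMANOVA inflates its type-I
    error); significance by label permutation.
    """
    d, ids = _as_array(dm)
    garr = pd.Series(np.asarray(groups), index=ids).to_numpy()
    levels = np.unique(garr)
    if len(levels) != 2:
        raise ValueError("welch_distance_ttest requires exactly 2 groups")
    sizes = {l: int((garr == l).sum()) for l in levels}
    if min(sizes.values()) < 3:
        warnings.warn("group size < 3: Welch-type test is unstable")
    d2 = d ** 2
    mask1 = garr == levels[0]
    t_obs = _tw2(d2, mask1)
    rng = np.random.default_rng(seed)
    n1 = mask1.sum()
    exceed = 0
    for _ in range(n_perm):
        perm_mask = np.zeros(len(garr), dtype=bool)
        perm_mask[rng.choice(len(garr), size=n1, replace=False)] = True
        exceed += _tw2(d2, perm_mask) >= t_obs
    p = (exceed + 1) / (n_perm + 1)
    return WelchDistanceResult(float(t_obs), float(p), n_perm, sizes)


def enumerate_two_group_stats(stat, d: np.ndarray, n1: int) -> np.ndarray:
    """Statistic under every distinct two-group relabeling (small-n oracle).

    ``stat(d_squared, mask1) -> float`` is evaluated for all C(n, n1)
    assignments of ``n1`` samples to group 1; the caller turns the vector
    into an exact permutation p-value.
    """
    n = len(d)
    d2 = d ** 2
    vals = []
    for comb in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        vals.append(stat(d2, mask))
    return np.asarray(vals)


# ---------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------

def aggregate_rank(table: FeatureTable, rank: str = "genus") -> pd.DataFrame:
    """Relative abundances aggregated to a taxonomic rank.

    ASVs without an assignment at the requested rank are collapsed to their
    highest assigned rank with an ``"<name> unclassified"`` label, so that
    unassigned lineages never pool into one spurious super-taxon.
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy")
    if rank not in TAXONOMIC_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    level = TAXONOMIC_RANKS.index(rank)
    labels = {}
    for asv in table.asv_ids:
        lin = table.taxonomy.get(asv, [])
        if len(lin) > level and lin[level]:
            labels[asv] = lin[level]
        else:
            assigned = [x for x in lin if x]
            labels[asv] = (f"{assigned[-1]} unclassified" if assigned
                           else "unclassified")
    rel = table.relative_abundance()
    return rel.T.groupby(pd.Series(labels)).sum().T


def top_taxa(table: FeatureTable, rank: str = "genus", n: int = 10
             ) -> tuple[list[str], pd.DataFrame]:
    """The ``n`` taxa with highest mean relative abundance at ``rank``.

    Ties in mean abundance break lexicographically for determinism.
    Returns ``(names, aggregated relative-abundance table)``.
    """
    agg = aggregate_rank(table, rank)
    means = agg.mean(axis=0)
    order = sorted(means.index, key=lambda t: (-means[t], t))
    return order[:n], agg


@dataclass
class DiffAbundanceResult:
    table: pd.DataFrame   # index taxon; medians per group, test, p, q, note


def diff_abundance(abundances: pd.DataFrame, groups, taxa=None
                   ) -> DiffAbundanceResult:
    """Rank tests on relative abundances with BH FDR across the tested set.

    Two groups -> Wilcoxon rank-sum (exact when combined n <= 25 without
    ties, tie-corrected normal approximation otherwise); more -> Kruskal-
    Wallis.  Constant taxa get p = 1 with a note.
    """
    groups = pd.Series(np.asarray(groups), index=abundances.index)
    taxa = list(taxa) if taxa is not None else list(abundances.columns)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for taxon in taxa:
        vals = abundances[taxon]
        by = [vals[groups == l].to_numpy() for l in levels]
        medians = {f"median_{l}": float(np.median(v)) for l, v in zip(levels, by)}
        note = ""
        if vals.nunique() == 1:
            p, test = 1.0, "constant"
            note = "constant taxon"
        elif len(levels) == 2:
            test = "wilcoxon"
            pooled = np.concatenate(by)
            exact = len(pooled) <= 25 and len(np.unique(pooled)) == len(pooled)
            res = stats.mannwhitneyu(
                by[0], by[1], alternative="two-sided",
                method="exact" if exact else "asymptotic")
            p = float(res.pvalue)
        else:
            test = "kruskal"
            p = float(stats.kruskal(*by).pvalue)
        rows.append({"taxon": taxon, **medians, "test": test, "p": p,
                     "note": note})
    df = pd.DataFrame(rows).set_index("taxon")
    df["q"] = bh_fdr(df["p"].to_numpy())
    return DiffAbundanceResult(df)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def dunn_posthoc(values, groups) -> pd.DataFrame:
    """Dunn's pairwise z-tests after Kruskal-Wallis, with tie correction
    and BH FDR across the pairs.  Groups with fewer than 2 members are
    excluded."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [l for l in np.unique(groups) if (groups == l).sum() >= 2]
    if len(levels) < 3:
        raise ValueError("Dunn's test needs >= 3 groups of size >= 2")
    keep = np.isin(groups, levels)
    values, groups = values[keep], groups[keep]
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(levels, 2):
        ra = ranks[groups == a].mean()
        rb = ranks[groups == b].mean()
        na, nb = (groups == a).sum(), (groups == b).sum()
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (ra - rb) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p": float(p)})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df
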