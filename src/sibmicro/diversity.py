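"""Alpha diversity, dissimilarity matrices, and ordination.

Shannon diversity is reported in natural-log units (nats) by default.
Weighted UniFrac defaults to the raw (unnormalized) form computed from ASV
counts; pass ``normalized=True`` for the variant divided by its maximum
attainable value.  Samples are expected to pass the read-depth filter
(default 2000 reads, samples with >= 2000 reads kept) before distances are
computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import FeatureTable

MIN_READS_DEFAULT = 2000


def filter_min_depth(table: FeatureTable, min_reads: int = MIN_READS_DEFAULT
                     ) -> FeatureTable:
    """Keep samples with row sum >= ``min_reads``; ASV columns are preserved."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = table.depths[table.depths >= min_reads].index
    if len(keep) == 0:
        warnings.warn("depth filter removed every sample")
    return table.subset(keep)


def shannon(counts_row, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over taxa with p_i > 0 (nats)."""
    x = np.asarray(counts_row, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def richness(counts_row) -> int:
    """Number of ASVs observed (count > 0)."""
    return int((np.asarray(counts_row) > 0).sum())


def alpha_diversity(table: FeatureTable, rarefy_depth: int | None = None,
                    seed=None) -> pd.DataFrame:
    """Per-sample Shannon (nats) and richness; optionally on rarefied counts."""
    rng = np.random.default_rng(seed)
    rows = {}
    for sid, row in table.counts.iterrows():
        x = row.to_numpy()
        if rarefy_depth is not None:
            if x.sum() < rarefy_depth:
                warnings.warn(f"{sid}: depth below rarefaction target, skipped")
                continue
            x = rarefy(x, rarefy_depth, rng)
        rows[sid] = {"shannon": shannon(x) if x.sum() else 0.0,
                     "richness": richness(x)}
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefy(counts_row, depth: int, seed=None) -> np.ndarray:
    """Subsample a count vector to exactly ``depth`` reads without replacement."""
    x = np.asarray(counts_row, dtype=np.int64)
    if x.sum() < depth:
        raise ValueError("rarefaction depth exceeds sample depth")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(x, depth).astype(np.int64)


# ---------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------

_TREE_METRICS = {"weighted_unifrac", "unweighted_unifrac"}
_PA_METRICS = {"jaccard", "unweighted_unifrac"}


def _check_tree_coverage(table: FeatureTable, tree: TreeNode,
                         on_missing: str) -> FeatureTable:
    tips = {t.name for t in tree.tips()}
    missing = [a for a in table.asv_ids if a not in tips]
    if not missing:
        return table
    if on_missing == "error":
        raise ValueError(
            f"{len(missing)} table ASVs absent from the tree "
            f"(e.g. {missing[:3]}); pass on_missing='drop' to drop them")
    warnings.warn(f"dropping {len(missing)} ASVs absent from the tree")
    kept = [a for a in table.asv_ids if a in tips]
    return FeatureTable(table.counts[kept], taxonomy=table.taxonomy,
                        sample_meta=table.sample_meta)


def beta_diversity_matrix(table: FeatureTable, metric: str,
                          tree: TreeNode | None = None,
                          normalized: bool = False,
                          on_missing: str = "error") -> DistanceMatrix:
    """Pairwise dissimilarities under one of the supported metrics.

    ``weighted_unifrac`` / ``unweighted_unifrac`` need a rooted tree whose
    tips cover the table's ASVs.  ``jaccard`` and unweighted UniFrac are
    computed on presence/absence.
    """
    if metric not in {"weighted_unifrac", "unweighted_unifrac",
                      "bray_curtis", "jaccard"}:
        raise ValueError(f"unknown metric {metric!r}")
    counts = table.counts
    kwargs = {}
    if metric in _TREE_METRICS:
        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        table = _check_tree_coverage(table, tree, on_missing)
        counts = table.counts
        kwargs = {"tree": tree, "taxa": table.asv_ids}
        if metric == "weighted_unifrac":
            kwargs["normalized"] = normalized
    data = counts.to_numpy()
    if metric == "jaccard":
        data = data > 0
    skbio_name = {"weighted_unifrac": "weighted_unifrac",
                  "unweighted_unifrac": "unweighted_unifrac",
                  "bray_curtis": "braycurtis", "jaccard": "jaccard"}[metric]
    dm = beta_diversity(skbio_name, data, ids=table.sample_ids, **kwargs)
    return dm


def weighted_unifrac(table: FeatureTable, tree: TreeNode,
                     normalized: bool = False,
                     on_missing: str = "error") -> DistanceMatrix:
    return beta_diversity_matrix(table, "weighted_unifrac", tree=tree,
                                 normalized=normalized, on_missing=on_missing)


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    return beta_diversity_matrix(table, "bray_curtis")


def jaccard(table: FeatureTable) -> DistanceMatrix:
    return beta_diversity_matrix(table, "jaccard")


def unweighted_unifrac(table: FeatureTable, tree: TreeNode,
                       on_missing: str = "error") -> DistanceMatrix:
    return beta_diversity_matrix(table, "unweighted_unifrac", tree=tree,
                                 on_missing=on_missing)


# ---------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues (negatives reported as-is),
    and per-axis proportion of explained variance."""

    samples: pd.DataFrame          # samples x axes, ordered by eigenvalue
    eigvals: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower double-centering of a squared-distance matrix: -0.5 J D^2 J."""
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix | np.ndarray, k: int | None = None,
         sample_ids=None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Coordinates are eigenvector * sqrt(eigenvalue) for positive eigenvalues
    only; negative eigenvalues are reported but not corrected (no Cailliez /
    Lingoes), since downstream analyses use only leading positive axes.
    """
    if isinstance(dm, DistanceMatrix):
        d, ids = dm.data, list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        ids = list(sample_ids) if sample_ids is not None \
            else [f"s{i}" for i in range(len(d))]
    g = gower_center(d)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0])) if len(eigvals) else []
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    n_pos = coords.shape[1]
    if k is not None:
        if k > len(d) - 1:
            raise ValueError("k must be <= n - 1")
        if k > n_pos:
            warnings.warn(f"only {n_pos} positive axes available (asked {k})")
        coords = coords[:, :min(k, n_pos)]
    tot = eigvals[eigvals > 0].sum()
    prop = np.where(eigvals > 0, eigvals, 0.0) / tot if tot > 0 \
        else np.zeros_like(eigvals)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(pd.DataFrame(coords, index=ids, columns=cols),
                            eigvals, prop)


def pcoa_skbio(dm: DistanceMatrix):
    """scikit-bio's PCoA, exposed for cross-checking."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _skbio_pcoa(dm, method="eigh", dimensions=0)
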