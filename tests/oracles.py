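"""Independent brute-force oracles used to validate the fast paths.

These deliberately share no code with the package: UniFrac walks every
branch explicitly, Bray-Curtis/Jaccard use the textbook set/sum formulas,
and the permutation oracles enumerate every distinct relabeling.
"""

import itertools

import numpy as np


def branch_tip_sets(tree):
    """(branch_length, set of tip names below) for every non-root node."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        out.append((node.length or 0.0, frozenset(tips)))
    return out


def weighted_unifrac_pair(tree, counts_a, counts_b, taxa, normalized=False):
    """Per-branch hand sum: sum b * |p_A(subtree) - p_B(subtree)|."""
    ta, tb = counts_a.sum(), counts_b.sum()
    idx = {t: i for i, t in enumerate(taxa)}
    num = den = 0.0
    for length, tips in branch_tip_sets(tree):
        cols = [idx[t] for t in tips if t in idx]
        pa = counts_a[cols].sum() / ta
        pb = counts_b[cols].sum() / tb
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    return num / den if normalized else num


def unweighted_unifrac_pair(tree, counts_a, counts_b, taxa):
    """(unique branch length) / (total branch length observed in either)."""
    idx = {t: i for i, t in enumerate(taxa)}
    uniq = tot = 0.0
    for length, tips in branch_tip_sets(tree):
        cols = [idx[t] for t in tips if t in idx]
        in_a = counts_a[cols].sum() > 0
        in_b = counts_b[cols].sum() > 0
        if in_a or in_b:
            tot += length
            if in_a != in_b:
                uniq += length
    return uniq / tot if tot > 0 else 0.0


def bray_curtis_pair(x, y):
    return np.abs(x - y).sum() / (x + y).sum()


def jaccard_pair(x, y):
    a, b = x > 0, y > 0
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(a, b).sum() / union


def pseudo_f_two_group(d, mask1):
    """One-factor PERMANOVA pseudo-F from raw distances (textbook sums)."""
    n = len(d)
    d2 = d ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for mask in (mask1, ~mask1):
        idx = np.flatnonzero(mask)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / 1.0) / (ss_within / (n - 2))


def exhaustive_p(stat_fn, d, n1, observed=None):
    """Exact permutation p over all C(n, n1) two-group assignments.

    ``stat_fn(d, mask1) -> float``.  ``observed`` defaults to the first
    assignment (samples 0..n1-1 in group 1).
    """
    n = len(d)
    vals = []
    for comb in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        vals.append(stat_fn(d, mask))
    vals = np.asarray(vals)
    if observed is None:
        mask = np.zeros(n, dtype=bool)
        mask[:n1] = True
        observed = stat_fn(d, mask)
    return (vals >= observed - 1e-12).mean(), vals
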