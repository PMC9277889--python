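"""Synthetic longitudinal cohort generator with known ground truth.

Emulates the statistical structure of a birth cohort sampled repeatedly in
two body compartments (airway: 1 week, 1 month, 3 months; gut: 1 week,
1 month, 1 year, 4 years, 6 years): sibship structures with realistic
marginals, sibling-driven shifts in taxon abundances whose magnitude decays
with the age gap to the closest older sibling, AR(1)-style carryover of the
sibling signature between adjacent visits, covariate confounding (delivery
mode, breastfeeding), and binary / count clinical outcomes driven by the
latent sibling exposure.

Counts are logistic-normal + multinomial rather than Dirichlet-multinomial:
an explicit latent log-composition makes the carryover coefficient a
directly tunable ground truth.  A single master seed is split into
independent streams (sibships / tree / counts / outcomes) so each stage can
be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import FeatureTable, DAYS_PER_YEAR
from .sibship import Sibling, SibshipRecord, exposure_at

AIRWAY_VISITS = (("1w", 7 / DAYS_PER_YEAR), ("1m", 30 / DAYS_PER_YEAR),
                 ("3m", 91 / DAYS_PER_YEAR))
GUT_VISITS = (("1w", 7 / DAYS_PER_YEAR), ("1m", 30 / DAYS_PER_YEAR),
              ("1y", 1.0), ("4y", 4.0), ("6y", 6.0))


@dataclass(frozen=True)
class AgeGapKernel:
    """Maps age gap (years, to the closest older sibling) to effect in [0,1].

    ``sigmoid``: logistic drop around ``center`` (airway-like: steep decline
    for gaps beyond 4-6 y).  ``saturating``: flat at 1 up to ``center``, then
    exponential decay (gut-like: effect persists to ~10 y gaps).
    """

    shape: str = "sigmoid"   # "sigmoid" | "saturating"
    center: float = 5.0      # years
    width: float = 1.0       # years

    def __call__(self, gap):
        gap = np.asarray(gap, dtype=float)
        if self.shape == "sigmoid":
            out = 1.0 / (1.0 + np.exp((gap - self.center) / self.width))
        elif self.shape == "saturating":
            out = np.where(gap <= self.center, 1.0,
                           np.exp(-(gap - self.center) / self.width))
        else:
            raise ValueError(f"unknown kernel shape {self.shape!r}")
        return out if out.shape else float(out)


@dataclass(frozen=True)
class SimConfig:
    """All tunable knobs of the cohort generator.

    Sibship marginals default to a cohort in which ~57 percent of children have an
    older sibling at birth and younger siblings arrive mostly between ages
    1 and 4, negatively associated with already having an older sibling, so
    that by age 6 roughly 11% have no siblings, 46% only older, 32% only
    younger, and 11% both.
    """

    n_children: int = 300
    n_taxa: int = 120
    seed: int = 0

    # visit schedule: compartment -> ((label, age in years), ...)
    visit_schedule: dict = field(default_factory=lambda: {
        "airway": AIRWAY_VISITS, "gut": GUT_VISITS})

    # sibship marginals
    p_older: float = 0.5675
    n_older_probs: tuple = (0.70, 0.22, 0.05, 0.02, 0.01)  # P(n_older = 1..5 | >=1)
    gap_log_mean: float = float(np.log(2.6))   # closest-gap lognormal (years)
    gap_log_sd: float = 0.6
    gap_count_slope: float = 0.18    # gap grows with number of older siblings
    gap_min: float = 0.8             # minimum plausible sibling spacing
    p_younger_by6_given_older: float = 0.185
    p_younger_by6_given_no_older: float = 0.742
    younger_arrival: tuple = (1.0, 4.0)   # child age window (years)

    # sequencing depth: lognormal, floored at 1 read
    depth_log_mean: float = float(np.log(15000.0))
    depth_log_sd: float = 1.0

    # community model
    baseline_sd: float = 1.5
    age_drift_scale: float = 1.2      # visit separation along log age
    frac_affected: float = 0.15       # taxa carrying the sibling effect
    delta_scale: float = 0.8          # per-taxon |effect| on the log scale
    effect_size: float = 1.0          # global multiplier on delta
    visit_effect: dict | None = None  # label -> weight on the direct effect
    kernels: dict = field(default_factory=lambda: {
        "airway": AgeGapKernel("sigmoid", center=5.0, width=1.0),
        "gut": AgeGapKernel("saturating", center=10.0, width=2.0)})
    lambda_carryover: float = 0.5     # AR(1) coefficient in [0, 1)
    p_csection: float = 0.22
    covariate_effect: float = 0.25
    sigma_child: float = 0.30         # persistent per-child log-scale noise
    sigma_sample: float = 0.40        # per-sample log-scale noise

    # outcome model
    outcome_alpha: float = float(np.log(0.07 / 0.93))
    beta_outcome: float = -0.3
    count_log_mean: float = float(np.log(2.0))
    beta_count: float = 0.0
    nb_dispersion: float = 3.0        # negative-binomial size for counts

    def validate(self) -> None:
        if not 0 <= self.p_older <= 1:
            raise ValueError("p_older must be in [0, 1]")
        for p in (self.p_younger_by6_given_older,
                  self.p_younger_by6_given_no_older, self.p_csection):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.lambda_carryover < 1:
            raise ValueError("carryover coefficient must be in [0, 1)")
        if self.depth_log_mean <= 0:
            raise ValueError("depth mean must be positive")
        if abs(sum(self.n_older_probs) - 1) > 1e-9:
            raise ValueError("n_older_probs must sum to 1")
        if not all(len(v) >= 1 for v in self.visit_schedule.values()):
            raise ValueError("every compartment needs at least one visit")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort (for recovery tests)."""

    child_ids: list
    exposure: np.ndarray            # e_i = g(gap_i) * 1[n_older > 0], in [0, 1]
    n_older: np.ndarray
    gap_closest_older: np.ndarray   # nan when no older sibling
    covariates: pd.DataFrame        # per child (delivery mode, breastfeeding)
    compositions: dict              # (compartment, visit) -> samples x taxa
    latent_deviation: dict          # (compartment, visit) -> child x taxa
    seeds: dict
    delta: dict = field(default_factory=dict)         # compartment -> taxa effect vector
    exposure_by_compartment: dict = field(default_factory=dict)


@dataclass
class Cohort:
    config: SimConfig
    sibships: list
    tree: TreeNode
    tables: dict                    # compartment -> FeatureTable (all visits)
    truth: SimTruth
    outcomes: pd.DataFrame | None = None


def _split_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(4)
    return dict(zip(("sibships", "tree", "counts", "outcomes"), children))


# ---------------------------------------------------------------------
# sibships
# ---------------------------------------------------------------------

def generate_sibships(config: SimConfig, seed=None) -> list[SibshipRecord]:
    """Draw sibship records whose marginals match the configured targets."""
    config.validate()
    ss = _split_seeds(config.seed)["sibships"] if seed is None else seed
    rng = np.random.default_rng(ss)
    records = []
    base = date(2010, 1, 1)
    for i in range(config.n_children):
        child_birth = base + timedelta(days=int(rng.integers(0, 365)))
        sibs = []
        has_older = rng.random() < config.p_older
        if has_older:
            n_older = 1 + rng.choice(len(config.n_older_probs),
                                     p=config.n_older_probs)
            gap = max(config.gap_min, rng.lognormal(
                config.gap_log_mean + config.gap_count_slope * (n_older - 1),
                config.gap_log_sd))
            gaps = [gap]
            for _ in range(n_older - 1):
                gaps.append(gaps[-1] + max(config.gap_min,
                                           rng.lognormal(np.log(2.0), 0.3)))
            for g in gaps:
                bd = child_birth - timedelta(days=int(round(g * DAYS_PER_YEAR)))
                sibs.append(Sibling(bd, "male" if rng.random() < 0.5 else "female"))
        p_younger = (config.p_younger_by6_given_older if has_older
                     else config.p_younger_by6_given_no_older)
        if rng.random() < p_younger:
            lo, hi = config.younger_arrival
            at_age = rng.uniform(lo, hi)
            bd = child_birth + timedelta(days=int(round(at_age * DAYS_PER_YEAR)))
            sibs.append(Sibling(bd, "male" if rng.random() < 0.5 else "female"))
        records.append(SibshipRecord(f"child_{i:05d}", child_birth, tuple(sibs)))
    return records


# ---------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------

def generate_tree(n_taxa: int, seed=None) -> TreeNode:
    """Random rooted bifurcating tree with exponential branch lengths."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"asv_{i + 1:04d}", length=float(rng.exponential(0.5)))
             for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.5)), children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------

def generate_counts(config: SimConfig, sibships, tree, seed=None):
    """Simulate count tables for every compartment and visit.

    Latent log-composition per sample:
    ``baseline_visit + u_t + child_noise + sample_noise`` where the sibling
    deviation follows ``u_t = effect_size * w_t * e_i * delta + lambda *
    u_{t-1} + covariate terms``.  Counts are multinomial draws at a
    lognormal per-sample depth.
    """
    config.validate()
    ss = _split_seeds(config.seed)["counts"] if seed is None else seed
    rng = np.random.default_rng(ss)
    n, p = config.n_children, config.n_taxa
    child_ids = [r.child_id for r in sibships]

    # per-child sibling exposure from the age-gap kernel (time-constant)
    n_older = np.zeros(n, dtype=int)
    gap = np.full(n, np.nan)
    for i, rec in enumerate(sibships):
        older = [s for s in rec.siblings if s.birth_date < rec.child_birth_date]
        n_older[i] = len(older)
        if older:
            latest = max(s.birth_date for s in older)
            gap[i] = (rec.child_birth_date - latest).days / DAYS_PER_YEAR

    covars = pd.DataFrame({
        "child_id": child_ids,
        "csection": (rng.random(n) < config.p_csection).astype(int),
        "breastfeeding_months": np.round(
            np.clip(rng.normal(6.0, 3.0, n), 0, 18), 1),
    }).set_index("child_id")

    tables, compositions, latents = {}, {}, {}
    exposure_by_comp, delta_by_comp = {}, {}
    for comp, visits in config.visit_schedule.items():
        kern = config.kernels.get(comp, AgeGapKernel())
        e = np.where(n_older > 0, kern(np.nan_to_num(gap, nan=0.0)), 0.0)
        exposure_by_comp[comp] = e

        delta = np.zeros(p)
        n_aff = max(1, int(round(config.frac_affected * p)))
        idx = rng.choice(p, size=n_aff, replace=False)
        delta[idx] = rng.normal(0, 1, n_aff)
        # clip magnitudes so no single taxon dominates the shift
        delta[idx] = np.sign(delta[idx]) * np.clip(
            np.abs(delta[idx]), 0.5, 1.5) * config.delta_scale
        delta_by_comp[comp] = delta

        gamma_cov = np.zeros(p)
        idx_c = rng.choice(p, size=n_aff, replace=False)
        gamma_cov[idx_c] = rng.normal(0, config.covariate_effect, n_aff)

        base = rng.normal(0, config.baseline_sd, p)
        drift = rng.normal(0, 1, p)
        child_noise = rng.normal(0, config.sigma_child, (n, p))

        rows, metas = [], []
        u_prev = np.zeros((n, p))
        for label, age in visits:
            w = 1.0 if config.visit_effect is None else \
                float(config.visit_effect.get(label, 0.0))
            direct = config.effect_size * w * np.outer(e, delta)
            cov_term = np.outer(covars["csection"].to_numpy(), gamma_cov)
            u = direct + config.lambda_carryover * u_prev + cov_term
            baseline_t = base + config.age_drift_scale * np.log1p(age) * drift
            eta = baseline_t[None, :] + u + child_noise \
                + rng.normal(0, config.sigma_sample, (n, p))
            comp_probs = np.exp(eta - eta.max(axis=1, keepdims=True))
            comp_probs /= comp_probs.sum(axis=1, keepdims=True)
            depths = np.maximum(1, np.round(rng.lognormal(
                config.depth_log_mean, config.depth_log_sd, n))).astype(int)
            counts = np.vstack([rng.multinomial(depths[i], comp_probs[i])
                                for i in range(n)])
            compositions[(comp, label)] = comp_probs
            latents[(comp, label)] = u
            u_prev = u
            for i, rec in enumerate(sibships):
                ref = rec.child_birth_date + timedelta(
                    days=int(round(age * DAYS_PER_YEAR)))
                exp_i = exposure_at(rec, ref)
                metas.append({
                    "sample_id": f"{rec.child_id}_{comp}_{label}",
                    "child_id": rec.child_id,
                    "compartment": comp,
                    "visit_age_label": label,
                    "visit_age_years": age,
                    "collection_date": ref,
                    "older_siblings": int(exp_i.n_older > 0),
                    "status": exp_i.status.value,
                    "n_older": exp_i.n_older,
                    "gap_closest_older": exp_i.gap_closest_older,
                    "csection": int(covars.loc[rec.child_id, "csection"]),
                    "breastfeeding_months":
                        float(covars.loc[rec.child_id, "breastfeeding_months"]),
                })
            rows.append(counts)
        counts_all = np.vstack(rows)
        meta = pd.DataFrame(metas).set_index("sample_id")
        asv_ids = [f"asv_{i + 1:04d}" for i in range(p)]
        taxonomy = _toy_taxonomy(asv_ids)
        tables[comp] = FeatureTable(
            pd.DataFrame(counts_all, index=meta.index, columns=asv_ids),
            taxonomy=taxonomy, sample_meta=meta)

    truth = SimTruth(
        child_ids=child_ids,
        exposure=exposure_by_comp[list(config.visit_schedule)[0]],
        n_older=n_older, gap_closest_older=gap, covariates=covars,
        compositions=compositions, latent_deviation=latents,
        seeds={"master": config.seed}, delta=delta_by_comp,
        exposure_by_compartment=exposure_by_comp)
    return tables, truth


def _toy_taxonomy(asv_ids, n_genera=20):
    """Toy ranked lineages: ASVs binned into pseudo-genera within families."""
    tax = {}
    for i, a in enumerate(asv_ids):
        g = i % n_genera
        fam = g // 4
        tax[a] = ["Bacteria", f"phylum_{fam % 5:02d}", f"class_{fam:02d}",
                  f"order_{fam:02d}", f"family_{fam:02d}", f"genus_{g:02d}"]
    return tax


# ---------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------

def generate_outcomes(truth: SimTruth, beta_outcome=None, seed=None,
                      config: SimConfig | None = None) -> pd.DataFrame:
    """Binary and count outcomes driven by the latent sibling exposure.

    ``P(outcome) = logistic(alpha + beta * z(e))`` with z the standardized
    exposure; counts are negative-binomial for quasi-Poisson testing.
    """
    cfg = config or SimConfig()
    beta = cfg.beta_outcome if beta_outcome is None else beta_outcome
    ss = (_split_seeds(cfg.seed)["outcomes"] if seed is None else seed)
    rng = np.random.default_rng(ss)
    e = np.asarray(truth.exposure, dtype=float)
    sd = e.std()
    z = (e - e.mean()) / sd if sd > 0 else np.zeros_like(e)
    p_out = 1.0 / (1.0 + np.exp(-(cfg.outcome_alpha + beta * z)))
    binary = (rng.random(len(e)) < p_out).astype(int)
    mu = np.exp(cfg.count_log_mean + cfg.beta_count * z)
    k = cfg.nb_dispersion
    counts = rng.negative_binomial(k, k / (k + mu))
    return pd.DataFrame({"child_id": truth.child_ids, "outcome": binary,
                         "infection_count": counts}).set_index("child_id")


# ---------------------------------------------------------------------
# one-call cohort
# ---------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> Cohort:
    """Sibships, tree, per-compartment tables, ground truth, and outcomes."""
    config.validate()
    seeds = _split_seeds(config.seed)
    sibships = generate_sibships(config, seeds["sibships"])
    tree = generate_tree(config.n_taxa, seeds["tree"])
    tables, truth = generate_counts(config, sibships, tree, seeds["counts"])
    outcomes = generate_outcomes(truth, seed=seeds["outcomes"], config=config)
    return Cohort(config=config, sibships=sibships, tree=tree,
                  tables=tables, truth=truth, outcomes=outcomes)
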