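# Methods

This note documents the models, the estimators, the defaults and why they
were chosen, what the synthetic cohorts do and do not emulate, and the
numerical details a maintainer needs.

## Sibship exposures

All exposure variables derive from sibling birth dates relative to the
index child at a reference date. *Older* siblings are fixed at birth;
*younger* siblings accrue over time, so status is a longitudinal variable
(none → younger_only, older_only → both) while `n_older` is constant.
Ages are exact day differences divided by 365.25; dates are ISO-8601.
Age-gap strata are `lt2` (gap < 2), `from2to4` (2 ≤ gap ≤ 4, closed on
both ends to match the plain reading of "2 to 4 years"), `gt4` (gap > 4).
Twins (a sibling sharing the child's birth date) are rejected at record
construction. Ties for the closest older sibling are resolved by sex
ordering then record order, with a warning.

The **sibling burden** is Σᵢ exp(−gapᵢ/τ) over older siblings. The
exponential kernel is this package's own concrete choice for a "total
burden from the age gaps to all older siblings": it is 1 for a just-older
sibling, decays smoothly, is monotone in the right directions, and has a
single interpretable scale. Default τ = 4 years, the scale at which
airway sibling effects visibly fade. Treat the functional form as a
modelling convention, not an estimated quantity.

## Diversity

Shannon diversity is −Σ p log p in **nats** (a base argument exists; the
log base is a convention, not a finding). Richness counts ASVs with
count > 0. Rarefaction subsamples without replacement
(`multivariate_hypergeometric`); the unrarefied path is the primary one,
the rarefied path a sensitivity analysis. The depth filter keeps samples
with **≥ 2000 reads**.

Distances come from scikit-bio: weighted UniFrac defaults to the **raw
(unnormalized)** form computed from counts (the normalized variant is a
flag); unweighted UniFrac and Jaccard are presence/absence; Bray–Curtis
uses counts. Distance matrices are computed per compartment pooled across
visits (the ordination convention), with per-visit blocks extracted for
testing and scoring.

PCoA eigendecomposes the Gower-centered matrix; coordinates are
eigenvector·√eigenvalue over **positive** eigenvalues only. Negative
eigenvalues are reported untouched — no Cailliez/Lingoes correction —
because every downstream consumer uses only leading positive axes.
The implementation is a ~20-line `eigh` wrapper (cross-checked against
scikit-bio's PCoA in the tests) because the betadisper construction needs
the negative-axis eigenvectors too.

## Distance-based inference

**PERMANOVA.** For terms entered as design columns (categoricals
dummy-coded, numerics linear), projections are built from rank-revealing
orthonormal bases, so aliased terms are detected and reported by name.
Sequential mode partitions tr(G) exactly: Σ r²(terms) + r²(residual) = 1
to 1e−10 (a test asserts this). Marginal mode tests each term adjusted
for all others (full-model residual SS vs the model dropping that term).
Permutations are free (unrestricted) row permutations; p = (#{F* ≥ F}+1)/
(B+1), default B = 9999, so the smallest attainable p is 1/(B+1). No
permutation strata are used even though visits are repeated measures —
per-visit analyses make this moot within a visit, and the pooled-visit
ordination is never itself tested.

**Betadisper.** Samples are embedded with all PCoA axes, negative-
eigenvalue axes entering as imaginary coordinates whose squared
contribution is subtracted; distance-to-centroid uses the group centroid,
tiny negative squared distances clip to 0. The headline statistic is the
ratio of the largest to smallest group mean distance-to-centroid; the
permutation test permutes group labels over the fixed distances under a
one-way ANOVA F.

**Welch-type distance t-test.** For two groups, per-group spread
s²_g = SS_g/(n_g−1) with SS_g = (1/n_g)Σ_{j<k∈g} d²_jk, squared centroid
separation ‖μ₁−μ₂‖² = mean cross-group d² − SS₁/n₁ − SS₂/n₂, and
T²_w = ‖μ₁−μ₂‖² / (s²₁/n₁ + s²₂/n₂), with a label-permutation p. This is
the robust post hoc companion to PERMANOVA when betadisper rejects: the
tests show it holds its size under a 3:1 variance imbalance with unequal
group sizes, where it is validated by simulation properties (exhaustive
enumeration at small n, type-I calibration, power comparable to
PERMANOVA under equal dispersions) rather than against any external code.

**Differential abundance.** Relative abundances are aggregated to a rank
(ASVs unassigned at that rank collapse to "<highest assigned> unclassified"
so that no spurious pooled 'NA genus' can win the top-10); the top-n taxa
by mean relative abundance (lexicographic tie-break) are tested —
Wilcoxon rank-sum for two groups (exact when combined n ≤ 25 without
ties, tie-corrected normal otherwise), Kruskal–Wallis for more — with BH
FDR across exactly the tested set. Constant taxa get p = 1 with a note.
Dunn's test (tie-corrected z, BH across pairs) covers ≥ 3-group post hocs.

## The sibling score

The embedding is metric MDS (PCoA) of the compartment×visit distance
matrix, computed **once on all samples before fold splitting**, with the
first k = 10 axes as features. This mirrors the usual construction and
creates a small, label-free information leak through the embedding; a
`strict=True` mode re-embeds each training fold and projects held-out
samples out-of-sample via the Gower projection formula for users who want
none. Non-metric MDS (`method="nmds"`) is available since both labels
appear in the literature for this construction; PCoA is the default
because it is deterministic and eigenvalue-ordered.

LDA uses the pooled within-class covariance (denominator n−2), empirical
class priors, and posterior P(1|x) = logistic(wᵀx + b),
w = Σ⁻¹(μ₁−μ₀). A ridge ε = 1e−8·tr(Σ)/d is added only when Σ is
singular or numerically ill-conditioned, and the model records that it
was used. Folds are stratified on the class label (10 by default,
reduced with a warning when the minority class is smaller); the AUC is
the tie-corrected Mann–Whitney statistic on pooled out-of-fold scores.
The anti-overfitting contract — null-label cv AUC centred on 0.5 — and
fold exclusivity (a sample's score cannot depend on its own label) are
asserted by the test suite.

Score-vs-gap curves use loess: local quadratic, tricube weights, span
0.75, evaluated only inside the observed gap range. The fit uses gaps up
to 10 years and **excludes** (rather than clamps) larger gaps: clamping
would pile children with genuinely decayed exposure onto the boundary
x-value and bias the right edge of the curve. The mean score of children
with no older siblings is carried as a horizontal reference.

## Carryover and outcomes

For visit t, `score_t ~ score_1 + … + score_{t−1} + status_t` is fitted
on children complete across all entering visits (≥ 10 required). Prior
scores are entered **in temporal order**, each reporting its added
explained variance (the consecutive part); current status reports its
type-II contribution, i.e. variance beyond *all* prior scores. This
reading makes the two benchmark cases exact: a direct-effect-only world
(per-visit status, no persistence) puts < 2% on prior scores, and a
perfect-persistence world puts all explained variance on the first prior
score and none on status. Both are asserted in tests. F-tests use the
full-model residual mean square.

Binary outcomes: scores are clipped to [1e−6, 1−1e−6], logit-transformed,
standardized to unit variance on the analyzed sample, and entered in a
logistic regression; the OR is per 1 SD, with Wald 95% CIs. Model
variants: crude, adjusted for sibling status, and status-stratified
(standardization happens before stratification, so "1 SD" means the same
thing across strata). Because per-SD and per-percentile scalings of such
scores are both in circulation and are easy to conflate, the result also
carries an OR per percentile of the raw probability score — the two are
deliberately emitted side by side rather than silently reconciled.
Complete cases only; separation falls back to an L2-penalized fit with
the CI marked unavailable. Count outcomes use a quasi-Poisson GLM
(Poisson likelihood, Pearson-dispersion-scaled SEs), which the tests show
keeps ≥ 90% CI coverage under negative-binomial overdispersion where a
plain Poisson interval undercovers.

## The synthetic cohort generator

Per child: an older-sibling indicator (P = 0.5675), a number of older
siblings (0.70/0.22/0.05/0.02/0.01 over 1–5 given any), a closest gap
that is lognormal (median ≈ 2.6 y, log-sd 0.6, floor 0.8 y) with a small
positive shift per additional older sibling (which reproduces the
observed *positive* gap-vs-count rank correlation ≈ 0.2), and a younger
sibling arriving between ages 1 and 4 with probability 0.185 given older
siblings and 0.742 given none. These defaults jointly match a cohort in
which ~58% have an older sibling at the first visit and the age-6
fractions are ~11/45–47/32/10–11% (none/older-only/younger-only/both);
the two published-style anchors are mutually inconsistent by ~2.5
percentage points under any time-constant `n_older`, so the default
splits the difference — each marginal is matched within ±2 points.

The latent sibling exposure is e = g(gap) for children with older
siblings, where g is a **sigmoid** kernel centred at 5 y (airway) or a
**saturating** kernel flat to 10 y then exponentially decaying (gut).
Counts are logistic-normal + multinomial: per-sample log-composition =
visit baseline (+ log-age drift separating visits) + u_t + persistent
child noise (σ = 0.3) + sample noise (σ = 0.4), with the sibling
deviation u_t = effect_size·w_t·e·δ + λ·u_{t−1} + covariate terms.
The logistic-normal choice (over Dirichlet-multinomial) exists precisely
so that the carryover coefficient λ (default 0.5) is an explicit, tunable
AR(1) ground truth. δ is a sparse per-compartment taxon effect vector
(15% of taxa, magnitudes clipped to 0.4–1.2 on the log scale so no single
taxon dominates the shift); delivery mode (P(C-section) = 0.22) perturbs
its own sparse taxon set. Depths are lognormal (median 15k reads, log-sd
1, floor 1 read) so a realistic few percent of samples fall under the
2000-read filter and exercise it. `effect_size = 1` was fixed by
calibrating the simulated airway sibling r² trajectory to the order of
magnitude reported for infant airway cohorts — increasing across the
three visits, typically ~0.02–0.05 at 1 week rising to ~0.05–0.15 by
3 months at n = 300, with the realized values depending on which taxa
the drawn effect vector lands on. This is a calibration of the
simulation's regime, not a reproduced estimate. Outcomes: P(y=1) = logistic(α + β·z(e)) with α = logit(0.07)
(≈ 7% prevalence) and β = −0.3; counts are negative-binomial (size 3)
for the quasi-Poisson tests. One master seed is split into four
independent streams (sibships/tree/counts/outcomes), so any stage can be
regenerated alone and everything is byte-reproducible.

What the generator does **not** emulate: realistic absolute alpha-
diversity levels (a 120-taxon logistic-normal community is far more even
than a real infant airway), taxonomic realism beyond a toy lineage
table, within-visit age jitter, informative missingness, strain dynamics,
or read-level error. Passing tests therefore demonstrate that the
estimators recover the structures they target under a faithful abstract
model of the study design — not that they would return identical numbers
on real sequencing data.

## Problem sizes and numerics

Test and acceptance runs use deliberately scaled-down designs: cohorts of
100–500 children, 40–120 taxa, 199–999 permutations in simulation loops
(9999 where a single p-value is compared to exhaustive enumeration at
n = 7), 50–200 replicates for type-I/coverage checks. Oracle agreement
for distances is asserted at 1e−10, the variance-partition identity at
1e−10, isometry checks at 1e−8. Degenerate inputs are contracts, not
crashes: empty depth-filter results warn, all-zero rows are domain
errors for Shannon, constant scores refuse standardization, aliased
design terms are named, single-class strata are refused.

Known limitations: marginal PERMANOVA recomputes one reduced model per
term per permutation-free pass (fine at cohort scale, not optimized for
thousands of samples); the Welch-type statistic is two-group only;
NMDS inherits SMACOF's local optima (seeded); the loess implementation
is the plain local-quadratic/tricube estimator without statistical
errors bands.
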