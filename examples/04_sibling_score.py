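"""The cross-validated sibling score and its age-gap curve.

The score is LDA's out-of-fold probability that a sample's child has older
siblings, computed from the first 10 PCoA components of the weighted
UniFrac matrix.  Plotted against the age gap to the closest older sibling
it recovers the simulated kernel: a sigmoid drop around 5-year gaps in
the airway.
"""

from datetime import timedelta

import pandas as pd

from sibmicro import (SimConfig, simulate_cohort, filter_min_depth,
                      weighted_unifrac, bray_curtis, cv_sibling_score,
                      auc_vs_components, score_gap_curve, exposure_at)

cohort = simulate_cohort(SimConfig(n_children=300, n_taxa=100, seed=21,
                                   effect_size=3.0))
table = filter_min_depth(cohort.tables["airway"])
meta = table.sample_meta
dm = weighted_unifrac(table, cohort.tree)
vids = meta.index[meta.visit_age_label == "3m"]
sub = dm.filter(vids)
labels = meta.loc[list(sub.ids), "older_siblings"].to_numpy()

sset = cv_sibling_score(sub, labels, k=10, folds=10, seed=1)
print(f"10-fold cross-validated AUC (3-month airway): {sset.cv_auc:.3f}")
print("-> every sample is scored by a model that never saw its fold, so "
      "this AUC\n   is an honest estimate of how much sibling signal the "
      "community carries.")

curves = auc_vs_components(
    {"wuf": sub, "bray": bray_curtis(table.subset(vids))},
    labels, k_range=[1, 2, 5, 10, 15], folds=10, seed=1)
print("\ncv AUC vs number of ordination components:")
print(curves.pivot(index="k", columns="metric", values="cv_auc").round(3))

child = meta.loc[sset.scores.index, "child_id"]
scores = pd.Series(sset.scores["score"].to_numpy(), index=child.to_numpy())
exposures = [exposure_at(r, r.child_birth_date + timedelta(days=91))
             for r in cohort.sibships if r.child_id in scores.index]
curve = score_gap_curve(scores, exposures)
print(f"\nloess score-vs-gap curve (span 0.75, local quadratic):")
for gap in (1, 2, 4, 6, 8):
    print(f"  gap {gap} y: fitted score {curve.fitted_at(gap):.2f}")
print(f"  reference (no older siblings): {curve.reference_mean:.2f}")
print("-> the fitted drop beyond ~5-year gaps mirrors the simulated "
      "sigmoid kernel.")
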