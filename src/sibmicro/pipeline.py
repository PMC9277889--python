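"""End-to-end pipeline: simulate -> filter -> distances -> PERMANOVA ->
sibling score -> carryover -> outcome association, with a reproducible
JSON run report."""

from __future__ import annotations

import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, diversity, outcomes, score as score_mod
from .io import write_run_report
from .simulate import SimConfig, simulate_cohort


def run_pipeline(config: SimConfig, n_perm: int = 999, min_reads: int = 2000,
                 k: int = 10, folds: int = 10, outdir=None) -> dict:
    """Run every stage on one simulated cohort and return the run report.

    Distances are pooled within compartment across visits (the ordination
    convention); PERMANOVA and sibling scores are computed per visit on the
    per-visit block of the pooled matrix.
    """
    t0 = time.time()
    config.validate()
    cohort = simulate_cohort(config)
    report = {
        "seed": config.seed,
        "parameters": {"n_children": config.n_children,
                       "n_taxa": config.n_taxa, "n_perm": n_perm,
                       "min_reads": min_reads, "k_components": k,
                       "folds": folds,
                       "effect_size": config.effect_size,
                       "lambda_carryover": config.lambda_carryover},
        "compartments": {},
    }
    score_frames = {}
    for comp, table in cohort.tables.items():
        filtered = diversity.filter_min_depth(table, min_reads)
        meta = filtered.sample_meta
        dm = diversity.weighted_unifrac(filtered, cohort.tree)
        centry = {"n_samples": len(filtered.sample_ids),
                  "n_filtered_out": len(table.sample_ids) - len(filtered.sample_ids),
                  "visits": {}}
        visit_scores = {}
        for label, _age in config.visit_schedule[comp]:
            vids = meta.index[meta["visit_age_label"] == label]
            if len(vids) < 4 * folds:
                warnings.warn(f"{comp}/{label}: too few samples, skipped")
                continue
            sub = dm.filter(vids)
            design = meta.loc[list(sub.ids),
                              ["older_siblings", "csection"]].astype(float)
            pr = community.permanova(sub, design, mode="marginal",
                                     n_perm=n_perm, seed=config.seed)
            sset = score_mod.cv_sibling_score(
                sub, meta.loc[list(sub.ids), "older_siblings"].to_numpy(),
                k=k, folds=folds, seed=config.seed,
                compartment=comp, visit=label)
            child = meta.loc[sset.scores.index, "child_id"]
            visit_scores[label] = pd.Series(
                sset.scores["score"].to_numpy(), index=child.to_numpy())
            centry["visits"][label] = {
                "permanova_r2_siblings": float(
                    pr.terms.loc["older_siblings", "r_squared"]),
                "permanova_p_siblings": float(
                    pr.terms.loc["older_siblings", "p"]),
                "cv_auc": sset.cv_auc,
                "n": pr.n,
            }
        score_frames[comp] = visit_scores
        if len(visit_scores) >= 2:
            sbv = pd.DataFrame(visit_scores)
            status = cohort.tables[comp].sample_meta.drop_duplicates("child_id")\
                .set_index("child_id")["older_siblings"]
            status_bv = pd.DataFrame(
                {v: status for v in sbv.columns}, index=sbv.index)
            dec = outcomes.carryover_decomposition(sbv, status_bv)
            centry["carryover"] = dec.table.to_dict(orient="records")
        report["compartments"][comp] = centry

    # outcome association with the last-visit score of each compartment
    assoc = []
    for comp, visit_scores in score_frames.items():
        if not visit_scores:
            continue
        last = list(visit_scores)[-1]
        s = visit_scores[last]
        status = cohort.tables[comp].sample_meta.drop_duplicates("child_id")\
            .set_index("child_id")["older_siblings"]
        out = cohort.outcomes
        for variant in ("crude", "adjusted"):
            try:
                r = outcomes.associate_outcome(
                    s, out["outcome"], status, model=variant,
                    compartment=comp, visit=last)
                assoc.append(r)
            except ValueError as exc:
                warnings.warn(f"association skipped: {exc}")
        try:
            assoc.append(outcomes.associate_count_outcome(
                s, out["infection_count"], status, model="crude",
                compartment=comp, visit=last))
        except ValueError as exc:
            warnings.warn(f"count association skipped: {exc}")
    report["associations"] = outcomes.association_table(assoc)\
        .to_dict(orient="records")
    report["runtime_seconds"] = round(time.time() - t0, 2)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_run_report(report, outdir / "run_report.json")
    return report
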