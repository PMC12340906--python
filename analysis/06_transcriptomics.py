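#!/usr/bin/env python
"""Bulk and single-cell transcriptomic signatures of the subtypes.

Bulk: per-cohort TMM/logCPM + moderated-t differential expression for each
subtype against controls, then the three-cohort consistency filter
(p < 0.05 everywhere, FC > 1.5 somewhere, shared sign). Single cell:
per-(sample, microglial state) pseudobulk, state inclusion by cell-count /
read-depth minima, per-state differential expression, and the
subtype-split AND control-contrast gene-selection rule.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from methylsubtypes.rnaseq import (
    cross_cohort_deg_filter,
    de_moderated,
    low_expression_filter,
    pseudobulk,
    state_deg_selection,
    tmm_logcpm,
)
from methylsubtypes.simulate import (
    SimulationConfig,
    generate_expression_data,
    generate_methylation_cohorts,
    generate_sc_counts,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    _, sheets, truth = generate_methylation_cohorts(cfg)
    counts = generate_expression_data(cfg, truth)

    summary = {}
    for grp in ("S1", "S2"):
        tables = {}
        for i, c in enumerate(counts):
            logcpm, _ = tmm_logcpm(c.loc[low_expression_filter(c)])
            meta = sheets[i].copy()
            meta["subtype"] = [truth.subtype_of_sample[s] for s in meta.index]
            tables[f"cohort{i}"] = de_moderated(logcpm, meta, (grp, "HC"))
        tab = cross_cohort_deg_filter(tables)
        tab.query("selected").to_csv(args.results / f"06_bulk_deg_{grp}.tsv", sep="\t")
        selected = set(tab.query("selected").index)
        causal = set(truth.causal_genes[grp]) & set(tab.index)
        summary[f"bulk_{grp}"] = {
            "n_selected": len(selected),
            "planted_recovery": round(len(selected & causal) / len(causal), 3),
        }

    sc_counts, sc_meta = generate_sc_counts(cfg, truth)
    groups = sc_meta.drop_duplicates("sample_id").set_index("sample_id")["group"]
    pb = pseudobulk(
        sc_counts,
        sc_meta,
        groups.to_dict(),
        compared_groups=["S1", "S2", "HC"],
        min_cells=10,
        min_depth=1000,
    )
    per_state = {}
    for state, included in pb.included.items():
        if not included:
            continue
        c = pb.counts[state]
        logcpm, _ = tmm_logcpm(c.loc[low_expression_filter(c, max_frac=0.95)])
        meta = pd.DataFrame({"subtype": groups.reindex(c.columns)})
        per_state[state] = {
            "s1_vs_s2": de_moderated(logcpm, meta, ("S1", "S2")),
            "s1_vs_hc": de_moderated(logcpm, meta, ("S1", "HC")),
            "s2_vs_hc": de_moderated(logcpm, meta, ("S2", "HC")),
        }
    sel, pooled = state_deg_selection(per_state)
    planted = set()
    for key, genes in truth.sc_causal_genes.items():
        planted.update(genes)
    summary["single_cell"] = {
        "states_included": sorted(per_state),
        "states_excluded": sorted(s for s, ok in pb.included.items() if not ok),
        "genes_per_state": {s: len(g) for s, g in sel.items()},
        "n_pooled_genes": len(pooled),
        "planted_recall": round(
            len(set(pooled) & planted) / len(planted), 3
        ) if planted else None,
    }
    with open(args.results / "06_transcriptomic_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
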