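#!/usr/bin/env python
"""Generate the synthetic multi-cohort study and write it to disk.

Produces the reference study conditions (3 cohorts, 150 LOAD + 75 control
samples each, 5,000 probes, two shared subtypes, one cohort-specific
cluster) plus bulk counts, single-cell counts, cell-type CpG panels and
paired summary-statistic tracks. Matrices land under scratch/sim/ (large,
regenerable); a compact truth summary lands under results/.
"""

import argparse
import json
from pathlib import Path

from methylsubtypes.preprocess import write_beta_tsv
from methylsubtypes.simulate import (
    SimulationConfig,
    generate_celltype_panels,
    generate_expression_data,
    generate_methylation_cohorts,
    generate_sc_counts,
    generate_summary_stats,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    args.results.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    betas, sheets, truth = generate_methylation_cohorts(cfg)
    for b, s in zip(betas, sheets):
        write_beta_tsv(b, args.outdir / f"beta_{b.cohort}.tsv")
        s.to_csv(args.outdir / f"samples_{b.cohort}.csv")
    for c in generate_expression_data(cfg, truth):
        c.to_csv(args.outdir / f"counts_{c.columns[0][:2]}.tsv", sep="\t")
    sc_counts, sc_meta = generate_sc_counts(cfg, truth)
    sc_counts.to_csv(args.outdir / "sc_counts.tsv", sep="\t")
    sc_meta.to_csv(args.outdir / "sc_cells.csv")
    for p in generate_celltype_panels(cfg, truth):
        with open(args.outdir / f"panel_{p.cell_type}_L{p.specificity_level}.txt", "w") as fh:
            fh.write("\n".join(p.probe_ids) + "\n")
    for reg, (m, g) in generate_summary_stats(cfg, truth).items():
        m.to_csv(args.outdir / f"sumstats_{reg}_mqtl.tsv", sep="\t", index=False)
        g.to_csv(args.outdir / f"sumstats_{reg}_gwas.tsv", sep="\t", index=False)
    truth.to_json(args.outdir / "truth.json")

    summary = {
        "seed": args.seed,
        "cohorts": [b.cohort for b in betas],
        "platforms": [b.platform for b in betas],
        "n_probes_per_cohort": [b.values.shape[0] for b in betas],
        "n_samples_per_cohort": [b.values.shape[1] for b in betas],
        "causal_cpgs_per_group": {k: len(v) for k, v in truth.causal_cpgs.items()},
        "coloc_regions": len(truth.coloc_scenario_of_region),
    }
    with open(args.results / "01_simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
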