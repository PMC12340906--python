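"""Multi-cohort synthetic data with known ground truth.

Emulates the study design the pipeline targets: three postmortem brain
cohorts with shared latent methylation subtypes of the disease group, one
cohort-specific cluster, covariate and batch structure, a 450K-like probe
subset in one cohort, subtype-differential CpGs and genes, cell-type CpG
panels with a planted enrichment, and paired association-summary tracks with
shared / distinct / null causal variants for colocalization.

Methylation is simulated on the logit (M-value-like) scale with Gaussian
noise and mapped back through the inverse logit, so beta values stay in (0,1)
while covariate and subtype effects are exactly linear on the modelling
scale. Each generator draws from its own named substream of the master seed,
so adding or reordering generators never perturbs another's output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import BetaMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_methylation_cohorts",
    "generate_expression_data",
    "generate_sc_counts",
    "generate_celltype_panels",
    "generate_summary_stats",
]

CELL_TYPES = ["neuron_ex", "neuron_in", "oligodendrocyte", "microglia", "astrocyte"]
PANEL_CELL_TYPES = ["neuron", "oligodendrocyte", "microglia", "astrocyte"]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic multi-cohort experiment.

    Defaults are the conditions of the scaled-down reference experiment:
    3 cohorts of 150 disease + 75 control samples, 5,000 probes, two shared
    subtypes shifting 5% of probes by 0.1 beta, and one extra latent group
    present only in the first cohort (the source of "Unassigned" clusters).
    """

    n_cohorts: int = 3
    n_load_per_cohort: int = 150
    n_hc_per_cohort: int = 75
    n_probes: int = 5000
    n_shared_subtypes: int = 2
    cohort_specific_cluster: bool = True
    specific_cluster_cohort: int = 0
    frac_subtype_cpgs: float = 0.05
    delta_beta: float = 0.10
    noise_sd: float = 0.25  # logit-scale residual sd (~0.06 beta sd at beta=0.5)
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": 0.10,
            "sex": 0.15,
            "microglia": 0.30,
            "batch": 0.15,
        }
    )
    platform_mask_fracs: dict = field(default_factory=lambda: {2: 0.6})
    # bulk RNA
    n_genes: int = 2000
    frac_subtype_genes: float = 0.05
    log2fc: float = 1.0
    nb_dispersion: float = 0.3
    # single cell
    n_states: int = 12
    n_included_states: int = 7
    n_sc_genes: int = 1000
    n_sc_samples: int = 60
    cells_per_state: int = 15
    n_cells_small_state: int = 3
    sc_degs_per_state: int = 10
    # panels
    panel_size: int = 300
    panel_or: float = 8.0
    enriched_cell_type: str = "microglia"
    # summary stats
    n_regions_per_scenario: int = 4
    n_variants_per_region: int = 100
    gwas_n: int = 50000
    mqtl_n: int = 400
    causal_z: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_subtype_cpgs", "frac_subtype_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        for c, f in self.platform_mask_fracs.items():
            if not 0.0 < f <= 1.0:
                raise ConfigurationError(f"platform mask fraction for cohort {c}: {f}")
        if self.n_shared_subtypes < 1:
            raise ConfigurationError("n_shared_subtypes must be >= 1")
        if not 0.0 <= self.delta_beta < 0.5:
            raise ConfigurationError("delta_beta must be in [0, 0.5)")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for downstream oracles."""

    subtype_of_sample: dict = field(default_factory=dict)
    causal_cpgs: dict = field(default_factory=dict)
    causal_genes: dict = field(default_factory=dict)
    sc_causal_genes: dict = field(default_factory=dict)
    enriched_panel: str = ""
    coloc_scenario_of_region: dict = field(default_factory=dict)
    probe_ids: list = field(default_factory=list)
    sample_cohort: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent substream keyed by (seed, stable hash of stream name)."""
    key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng([config.seed & 0x7FFFFFFF, key])


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _subtype_names(config: SimulationConfig) -> list[str]:
    return [f"S{i + 1}" for i in range(config.n_shared_subtypes)]


def generate_methylation_cohorts(
    config: SimulationConfig,
) -> tuple[list[BetaMatrix], list[pd.DataFrame], SyntheticTruth]:
    """Simulate beta matrices + sample sheets for every cohort.

    Disease samples are split evenly among the shared subtypes (plus the
    cohort-specific group in its designated cohort); each subtype shifts its
    own disjoint causal-CpG set by ``delta_beta`` on the beta scale (applied
    as the equivalent logit offset). Covariates act linearly on the logit
    scale with per-probe random weights. The masked cohort only carries its
    450K-like probe subset.
    """
    rng = _rng(config, "methylation")
    p = config.n_probes
    probe_ids = [f"cg{i:07d}" for i in range(p)]

    # baseline methylation; causal probes drawn from the mid-range so the
    # planted beta-scale shift is not distorted by the logistic curvature
    base_beta = rng.uniform(0.08, 0.92, size=p)
    mid = np.where((base_beta >= 0.35) & (base_beta <= 0.65))[0]
    n_causal = int(round(config.frac_subtype_cpgs * p))
    groups = _subtype_names(config)
    if config.cohort_specific_cluster:
        groups_all = groups + ["cohort-specific"]
    else:
        groups_all = list(groups)
    need = n_causal * len(groups_all)
    pool = rng.permutation(mid)[:need]
    causal: dict[str, np.ndarray] = {}
    for gi, g in enumerate(groups_all):
        causal[g] = np.sort(pool[gi * n_causal : (gi + 1) * n_causal])

    base_logit = _logit(base_beta)
    # signed logit offsets chosen so inverse-logit moves beta by +-delta_beta
    offsets = {}
    for g, idx in causal.items():
        sign = rng.choice([-1.0, 1.0], size=len(idx))
        target = np.clip(base_beta[idx] + sign * config.delta_beta, 0.02, 0.98)
        offsets[g] = (idx, _logit(target) - base_logit[idx])

    eff = config.covariate_effects
    cov_names = list(eff)
    w = rng.normal(size=(p, len(cov_names)))  # per-probe covariate weights

    betas: list[BetaMatrix] = []
    sheets: list[pd.DataFrame] = []
    truth = SyntheticTruth(
        causal_cpgs={g: [probe_ids[i] for i in idx] for g, (idx, _) in offsets.items()},
        probe_ids=list(probe_ids),
    )

    for c in range(config.n_cohorts):
        crng = _rng(config, f"methylation/cohort{c}")
        n_load, n_hc = config.n_load_per_cohort, config.n_hc_per_cohort
        n = n_load + n_hc
        sample_ids = [f"C{c}_{i:04d}" for i in range(n)]
        diagnosis = np.array(["LOAD"] * n_load + ["HC"] * n_hc)
        labels = np.array(["HC"] * n, dtype=object)
        cohort_groups = list(groups)
        if config.cohort_specific_cluster and c == config.specific_cluster_cohort:
            cohort_groups = groups + ["cohort-specific"]
        for i in range(n_load):
            labels[i] = cohort_groups[i % len(cohort_groups)]

        age = crng.normal(75.0, 8.0, size=n)
        sex = crng.integers(0, 2, size=n)
        pmi = np.clip(crng.normal(12.0, 4.0, size=n), 1.0, None)
        props = crng.dirichlet([8.0, 6.0, 7.0, 2.0, 3.0], size=n)
        batch = np.array([f"b{(i % 2) + 1}" for i in crng.permutation(n)])

        sheet = pd.DataFrame(
            {
                "diagnosis": diagnosis,
                "age": age,
                "sex": sex,
                "postmortem_interval": pmi,
                "batch": batch,
                "cohort": f"cohort{c}",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        for j, ct in enumerate(CELL_TYPES):
            sheet[ct] = props[:, j]

        # covariate design on standardized columns
        design_cols = {}
        for name in cov_names:
            if name == "sex":
                x = sex.astype(float)
            elif name == "batch":
                x = (batch == "b2").astype(float)
            elif name == "age":
                x = age
            elif name in CELL_TYPES:
                x = props[:, CELL_TYPES.index(name)]
            else:
                raise ConfigurationError(f"unknown covariate effect {name!r}")
            sd = x.std()
            design_cols[name] = (x - x.mean()) / (sd if sd > 0 else 1.0)

        logit = np.tile(base_logit[:, None], (1, n))
        for k, name in enumerate(cov_names):
            logit += eff[name] * np.outer(w[:, k], design_cols[name])
        for g, (idx, off) in offsets.items():
            members = np.where(labels == g)[0]
            if len(members):
                logit[np.ix_(idx, members)] += off[:, None]
        logit += crng.normal(0.0, config.noise_sd, size=(p, n))
        beta = np.clip(_expit(logit), 1e-6, 1 - 1e-6)

        values = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)
        platform = "EPIC-like"
        if c in config.platform_mask_fracs:
            frac = config.platform_mask_fracs[c]
            mask_rng = _rng(config, "platform_mask")
            kept = np.sort(
                mask_rng.choice(p, size=int(round(frac * p)), replace=False)
            )
            values = values.iloc[kept]
            platform = "450K-like"
        betas.append(BetaMatrix(values=values, cohort=f"cohort{c}", platform=platform))
        sheets.append(sheet)
        for s, lab in zip(sample_ids, labels):
            truth.subtype_of_sample[s] = lab
            truth.sample_cohort[s] = f"cohort{c}"

    return betas, sheets, truth


def generate_expression_data(
    config: SimulationConfig, truth: SyntheticTruth
) -> list[pd.DataFrame]:
    """Negative-binomial bulk RNA counts per cohort (genes x samples).

    Causal genes carry the configured log2 fold change in their designated
    subtype relative to everyone else, with the sign fixed per gene so the
    direction is consistent across cohorts.
    """
    rng = _rng(config, "expression")
    g = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(g)]
    base = rng.normal(4.0, 1.0, size=g)  # natural-log mean expression
    n_causal = int(round(config.frac_subtype_genes * g))
    order = rng.permutation(g)
    subtypes = _subtype_names(config)
    truth.causal_genes = {}
    effects = np.zeros((g, len(subtypes)))
    for si, s in enumerate(subtypes):
        idx = np.sort(order[si * n_causal : (si + 1) * n_causal])
        truth.causal_genes[s] = [gene_ids[i] for i in idx]
        sign = rng.choice([-1.0, 1.0], size=len(idx))
        effects[idx, si] = sign * config.log2fc * np.log(2.0)

    samples_by_cohort: dict[str, list[str]] = {}
    for s, c in truth.sample_cohort.items():
        samples_by_cohort.setdefault(c, []).append(s)

    out = []
    disp = config.nb_dispersion
    for c, sample_ids in sorted(samples_by_cohort.items()):
        crng = _rng(config, f"expression/{c}")
        n = len(sample_ids)
        libfac = np.exp(crng.normal(0.0, 0.3, size=n))
        mu = np.exp(base)[:, None] * libfac[None, :]
        for si, s in enumerate(subtypes):
            members = [
                j for j, sid in enumerate(sample_ids)
                if truth.subtype_of_sample[sid] == s
            ]
            if members:
                mu[:, members] *= np.exp(effects[:, si])[:, None]
        counts = crng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mu))
        out.append(
            pd.DataFrame(counts, index=gene_ids, columns=sample_ids, dtype=np.int64)
        )
    return out


def generate_sc_counts(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-level counts with (sample, state) labels for one cohort.

    Returns ``(counts genes x cells, cell_meta)``. States beyond
    ``n_included_states`` get only ``n_cells_small_state`` cells per sample so
    the downstream inclusion rule has something to exclude. Per-state causal
    genes are upregulated in one subtype relative to both the other subtype
    and controls.
    """
    rng = _rng(config, "sc")
    sc_cohort = f"cohort{config.n_cohorts - 1}"
    pool = [s for s, c in truth.sample_cohort.items() if c == sc_cohort]
    labels = {s: truth.subtype_of_sample[s] for s in pool}
    keep_groups = set(_subtype_names(config)) | {"HC"}
    pool = [s for s in pool if labels[s] in keep_groups]
    samples = list(rng.permutation(pool))[: config.n_sc_samples]
    samples.sort()

    g = config.n_sc_genes
    gene_ids = [f"SG{i:05d}" for i in range(g)]
    base = rng.normal(1.0, 0.8, size=g)
    subtypes = _subtype_names(config)
    order = rng.permutation(g)
    truth.sc_causal_genes = {}
    state_effect = {}
    pos = 0
    for st in range(config.n_included_states):
        for s in subtypes:
            idx = np.sort(order[pos : pos + config.sc_degs_per_state])
            pos += config.sc_degs_per_state
            truth.sc_causal_genes[f"MG{st}:{s}"] = [gene_ids[i] for i in idx]
            state_effect[(st, s)] = idx

    cells, meta_rows = [], []
    disp = config.nb_dispersion
    lfc = config.log2fc * np.log(2.0)
    for sid in samples:
        srng = _rng(config, f"sc/{sid}")
        for st in range(config.n_states):
            n_cells = (
                config.cells_per_state
                if st < config.n_included_states
                else config.n_cells_small_state
            )
            mu = np.exp(base + srng.normal(0.0, 0.1, size=g))
            lab = labels[sid]
            if (st, lab) in state_effect:
                mu[state_effect[(st, lab)]] *= np.exp(lfc)
            m = np.tile(mu[:, None], (1, n_cells))
            counts = srng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * m))
            cells.append(counts)
            for ci in range(n_cells):
                meta_rows.append((f"{sid}_MG{st}_{ci}", sid, f"MG{st}", lab))
    meta = pd.DataFrame(
        meta_rows, columns=["cell_id", "sample_id", "state", "group"]
    ).set_index("cell_id")
    counts = pd.DataFrame(
        np.concatenate(cells, axis=1), index=gene_ids, columns=meta.index
    )
    return counts, meta


@dataclass
class CpGPanel:
    cell_type: str
    specificity_level: int
    probe_ids: list


def generate_celltype_panels(
    config: SimulationConfig, truth: SyntheticTruth
) -> list[CpGPanel]:
    """Cell-type CpG panels at three nested specificity levels.

    The ``enriched_cell_type`` panel over-samples the causal CpGs at the
    configured odds ratio; levels 2 and 3 are nested random subsets of level 1
    (sizes 2/3 and 1/3), which preserves the enrichment odds in expectation.
    Other cell types draw probes uniformly, so their enrichment is null.
    """
    rng = _rng(config, "panels")
    if not truth.causal_cpgs:
        raise ConfigurationError("truth lacks causal CpGs; run methylation first")
    universe = list(truth.probe_ids)
    n_univ = len(universe)
    causal = sorted(set().union(*truth.causal_cpgs.values()))
    causal_mask = np.isin(np.array(universe), np.array(causal))
    n_causal = int(causal_mask.sum())

    def inclusion_probs(odds_ratio: float) -> tuple[float, float]:
        # solve q0 so the expected panel size matches panel_size given the OR
        from scipy.optimize import brentq

        def size_at(q0):
            q1 = odds_ratio * q0 / (1.0 - q0 + odds_ratio * q0)
            return q0 * (n_univ - n_causal) + q1 * n_causal - config.panel_size

        q0 = brentq(size_at, 1e-9, 0.999999)
        q1 = odds_ratio * q0 / (1.0 - q0 + odds_ratio * q0)
        return q0, q1

    panels: list[CpGPanel] = []
    truth.enriched_panel = config.enriched_cell_type
    for ct in PANEL_CELL_TYPES:
        or_ = config.panel_or if ct == config.enriched_cell_type else 1.0
        q0, q1 = inclusion_probs(or_)
        probs = np.where(causal_mask, q1, q0)
        level1 = [p for p, keep in zip(universe, rng.random(n_univ) < probs) if keep]
        level2 = sorted(rng.choice(level1, size=max(1, (2 * len(level1)) // 3), replace=False))
        level3 = sorted(rng.choice(level2, size=max(1, len(level2) // 2), replace=False))
        panels.append(CpGPanel(ct, 1, sorted(level1)))
        panels.append(CpGPanel(ct, 2, list(level2)))
        panels.append(CpGPanel(ct, 3, list(level3)))
    return panels


def generate_summary_stats(
    config: SimulationConfig, truth: SyntheticTruth
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Paired (mQTL, GWAS) summary-statistic tracks per genomic region.

    Scenarios cycle shared / distinct / null: shared regions place one common
    causal variant in both tracks, distinct regions place different causal
    variants, null regions none. Standard errors follow se = 1/sqrt(2 maf
    (1-maf) n) for the stated per-track sample sizes, and causal effects are
    sized to a fixed causal z-score.
    """
    rng = _rng(config, "sumstats")
    scenarios = ["shared", "distinct", "null"]
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    region_i = 0
    for scen in scenarios:
        for _ in range(config.n_regions_per_scenario):
            region = f"R{region_i:03d}"
            region_i += 1
            nv = config.n_variants_per_region
            maf = rng.uniform(0.05, 0.5, size=nv)
            variants = [f"{region}_rs{j:04d}" for j in range(nv)]
            tracks = []
            if scen == "shared":
                c1 = c2 = int(rng.integers(nv))
            elif scen == "distinct":
                c1, c2 = rng.choice(nv, size=2, replace=False)
            else:
                c1 = c2 = -1
            for track_n, cidx in ((config.mqtl_n, c1), (config.gwas_n, c2)):
                se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * track_n)
                true_beta = np.zeros(nv)
                if cidx >= 0:
                    true_beta[cidx] = config.causal_z * se[cidx]
                beta = rng.normal(true_beta, se)
                z = beta / se
                from scipy.stats import norm

                p = 2.0 * norm.sf(np.abs(z))
                tracks.append(
                    pd.DataFrame(
                        {
                            "variant_id": variants,
                            "beta": beta,
                            "se": se,
                            "p": p,
                            "maf": maf,
                            "n": track_n,
                            "region": region,
                        }
                    )
                )
            out[region] = (tracks[0], tracks[1])
            truth.coloc_scenario_of_region[region] = scen
    return out
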