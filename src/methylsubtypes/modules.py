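"""Co-methylation modules and cross-platform preservation.

A deliberately simplified module detector stands in for full weighted
correlation-network analysis: probes are clustered by average linkage on the
correlation distance 1 - |r| and the tree is cut at a fixed height; small
clusters fall into the unassigned module. Each module is summarized per
sample by its eigenprobe (first principal component of the standardized
module submatrix, sign-aligned to the module mean profile). Preservation of
a cluster-associated module on a reduced probe set (the 450K-like subset)
requires (i) the subset-recomputed eigenprobe still separates the cluster
labels by ANOVA and (ii) full- and subset-eigenprobes do not differ within
any cluster by a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway, ttest_rel
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ModuleSet",
    "detect_modules",
    "eigenprobe",
    "module_anova",
    "preservation_test",
]

UNASSIGNED_MODULE = "module0"


@dataclass
class ModuleSet:
    members: dict[str, list[str]]  # module id -> probe ids (disjoint)
    eigenprobes: pd.DataFrame | None = None  # samples x modules
    unassigned: str = UNASSIGNED_MODULE


def detect_modules(
    values: pd.DataFrame,
    min_module_size: int = 10,
    cut_height: float = 0.5,
) -> ModuleSet:
    """Cluster probes (rows) by average linkage on 1 - |Pearson r|."""
    arr = values.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 probes")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    members: dict[str, list[str]] = {UNASSIGNED_MODULE: []}
    next_id = 1
    for lab in sorted(
        np.unique(raw), key=lambda v: (-int((raw == v).sum()), int(v))
    ):
        probes = [p for p, r in zip(values.index, raw) if r == lab]
        if len(probes) < min_module_size:
            members[UNASSIGNED_MODULE].extend(probes)
        else:
            members[f"module{next_id}"] = probes
            next_id += 1
    return ModuleSet(members=members)


def eigenprobe(submatrix: pd.DataFrame) -> pd.Series:
    """First PC of the standardized module probes, one score per sample.

    The sign is fixed so the score correlates non-negatively with the module
    mean profile (an arbitrary but reproducible orientation).
    """
    arr = submatrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    zs = (arr - mean) / sd
    u, s, vt = np.linalg.svd(zs, full_matrices=False)
    score = vt[0]
    mean_profile = zs.mean(axis=0)
    if np.corrcoef(score, mean_profile)[0, 1] < 0:
        score = -score
    return pd.Series(score, index=submatrix.columns, name="eigenprobe")


def compute_eigenprobes(values: pd.DataFrame, modules: ModuleSet) -> pd.DataFrame:
    cols = {}
    for mid, probes in modules.members.items():
        if mid == modules.unassigned or len(probes) < 2:
            continue
        cols[mid] = eigenprobe(values.loc[probes])
    return pd.DataFrame(cols)


def module_anova(scores: pd.Series, labels) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA of an eigenprobe across cluster labels + Tukey HSD."""
    labels = np.asarray(labels)
    groups = [scores.to_numpy()[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    f, p = f_oneway(*groups)
    tk = pairwise_tukeyhsd(scores.to_numpy(), labels.astype(str))
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return float(f), float(p), tukey


@dataclass
class PreservationVerdict:
    module: str
    anova_p_full: float
    anova_p_subset: float
    paired_p_by_cluster: dict = field(default_factory=dict)
    preserved: bool = False
    note: str = ""


def preservation_test(
    modules: ModuleSet,
    full_values: pd.DataFrame,
    subset_values: pd.DataFrame,
    labels,
    alpha: float = 0.05,
) -> dict[str, PreservationVerdict]:
    """Cross-platform preservation of cluster-associated modules.

    Only modules whose full-probe eigenprobe separates the labels (ANOVA
    p < alpha) are assessed. "Preserved" requires the subset-recomputed
    eigenprobe to remain significant AND the paired full-vs-subset
    comparison within every cluster to be non-significant.
    """
    labels = np.asarray(labels)
    verdicts: dict[str, PreservationVerdict] = {}
    for mid, probes in modules.members.items():
        if mid == modules.unassigned or len(probes) < 2:
            continue
        full_e = eigenprobe(full_values.loc[probes])
        _, p_full, _ = module_anova(full_e, labels)
        if p_full >= alpha:
            continue  # not cluster-associated; nothing to preserve
        sub_probes = [p for p in probes if p in subset_values.index]
        if len(sub_probes) < 2:
            verdicts[mid] = PreservationVerdict(
                mid, p_full, np.nan, {}, False, "too few probes on subset platform"
            )
            continue
        sub_e = eigenprobe(subset_values.loc[sub_probes])
        sub_e = sub_e.reindex(full_e.index)
        _, p_sub, _ = module_anova(sub_e, labels)
        paired = {}
        all_ns = True
        for g in np.unique(labels):
            a = full_e.to_numpy()[labels == g]
            b = sub_e.to_numpy()[labels == g]
            if len(a) < 2 or np.allclose(a, b):
                paired[str(g)] = 1.0
                continue
            pv = float(ttest_rel(a, b).pvalue)
            paired[str(g)] = pv
            if pv < alpha:
                all_ns = False
        verdicts[mid] = PreservationVerdict(
            mid, p_full, p_sub, paired, bool(p_sub < alpha and all_ns), ""
        )
    return verdicts
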