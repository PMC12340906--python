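"""Fisher-exact overlap statistics and over-representation tests.

The overlap of two feature lists inside a finite universe is summarized by
the 2x2 table (a = overlap, b/c = list-exclusive counts, d = remainder) with
the conditional maximum-likelihood odds ratio under Fisher's noncentral
hypergeometric model — the estimate printed by Fisher's exact test and by
the geneOverlap package — and an upper-tail (enrichment) hypergeometric p.
The same machinery drives cell-type CpG-panel enrichment and a generic
gene-set over-representation analysis against user-supplied GMT sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapResult",
    "fisher_overlap",
    "CpGPanel",
    "celltype_enrichment",
    "ora",
    "read_gmt",
]

from .simulate import CpGPanel  # canonical panel container


@dataclass
class OverlapResult:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    sample_odds_ratio: float
    p: float
    universe: int


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _cmle_odds_ratio(a: int, m1: int, n1: int, total: int, tol: float = 1e-6) -> float:
    """Conditional MLE: the odds psi with E[A | margins, psi] = a.

    The expectation is computed from exact noncentral hypergeometric weights
    in log space; the root is bracketed and solved on log(psi).
    """
    lo = max(0, m1 + n1 - total)
    hi = min(m1, n1)
    if a <= lo:
        return 0.0
    if a >= hi:
        return np.inf
    support = np.arange(lo, hi + 1)
    base = _log_binom(m1, support) + _log_binom(total - m1, n1 - support)

    def expect_minus_a(log_psi: float) -> float:
        lw = base + support * log_psi
        lw -= logsumexp(lw)
        return float(np.exp(lw) @ support) - a

    left, right = -1.0, 1.0
    while expect_minus_a(left) > 0:
        left *= 2
        if left < -500:
            return 0.0
    while expect_minus_a(right) < 0:
        right *= 2
        if right > 500:
            return np.inf
    return float(np.exp(brentq(expect_minus_a, left, right, xtol=tol, rtol=tol)))


def fisher_overlap(
    list_a_size: int, list_b_size: int, overlap: int, universe: int
) -> OverlapResult:
    """Enrichment of the overlap of two lists drawn from a shared universe."""
    a = int(overlap)
    b = int(list_a_size) - a
    c = int(list_b_size) - a
    d = int(universe) - list_a_size - list_b_size + a
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"impossible 2x2 table from sizes ({list_a_size}, {list_b_size}, "
            f"overlap {overlap}, universe {universe})"
        )
    p = float(hypergeom.sf(a - 1, universe, list_a_size, list_b_size))
    cmle = _cmle_odds_ratio(a, list_a_size, list_b_size, universe)
    sample = (a * d) / (b * c) if b > 0 and c > 0 else np.inf if a > 0 else 0.0
    return OverlapResult(a, b, c, d, cmle, sample, p, int(universe))


def celltype_enrichment(
    dmps: list[str], panels: list[CpGPanel], universe: list[str]
) -> pd.DataFrame:
    """Per-(cell type, specificity level) enrichment of a DMP list.

    Panels and the DMP list are restricted to the universe first; p-values
    are BH-adjusted across panels. An empty DMP list yields a flagged table
    with undefined odds ratios.
    """
    uni = set(universe)
    dmp = sorted(set(dmps) & uni)
    rows = []
    for panel in panels:
        probes = sorted(set(panel.probe_ids) & uni)
        if not dmp:
            rows.append(
                {
                    "cell_type": panel.cell_type,
                    "specificity_level": panel.specificity_level,
                    "panel_size": len(probes),
                    "overlap": 0,
                    "odds_ratio": np.nan,
                    "p": np.nan,
                    "flag": "empty DMP list",
                }
            )
            continue
        ov = len(set(probes) & set(dmp))
        res = fisher_overlap(len(dmp), len(probes), ov, len(uni))
        flag = ""
        if len(dmp) == len(uni):
            flag = "DMP list equals universe; odds ratio degenerate"
        rows.append(
            {
                "cell_type": panel.cell_type,
                "specificity_level": panel.specificity_level,
                "panel_size": len(probes),
                "overlap": ov,
                "odds_ratio": res.odds_ratio,
                "p": res.p,
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def read_gmt(path) -> dict[str, set]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def ora(
    genes: list[str],
    gene_sets: dict[str, set],
    universe: list[str],
    alpha: float = 0.05,
    min_size: int = 10,
    max_size: int = 2000,
) -> pd.DataFrame:
    """Generic over-representation analysis of a query gene list.

    Hypergeometric upper-tail p per set (sets restricted to the universe and
    filtered to [min_size, max_size]), BH FDR, fold enrichment, and the
    contributing genes. Query genes outside the universe are dropped with a
    warning.
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    uni = set(universe)
    query = set(genes)
    missing = query - uni
    if missing:
        import warnings

        warnings.warn(
            f"{len(missing)} query genes absent from universe; dropped", stacklevel=2
        )
        query &= uni
    rows = []
    for name, members in sorted(gene_sets.items()):
        members = set(members) & uni
        if not min_size <= len(members) <= max_size:
            continue
        hits = sorted(query & members)
        if not query:
            continue
        p = float(hypergeom.sf(len(hits) - 1, len(uni), len(members), len(query)))
        expected = len(members) * len(query) / len(uni)
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "query_size": len(query),
                "overlap": len(hits),
                "fold_enrichment": len(hits) / expected if expected > 0 else np.nan,
                "p": p,
                "genes": ";".join(hits),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set", "set_size", "query_size", "overlap", "fold_enrichment", "p", "genes"],
    )
    if len(out):
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_bh"] < alpha
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
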