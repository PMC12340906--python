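"""Approximate-Bayes-factor colocalization of paired association signals.

Given per-variant summary statistics (beta, se) for two traits in one
genomic region — here a subtype-DMP mQTL track and an AD GWAS track — each
variant gets a Wakefield approximate Bayes factor, and the five standard
hypotheses are scored: H0 no association, H1/H2 one trait only, H3 two
distinct causal variants, H4 one shared causal variant. A region is called
significant when PP(H3) + PP(H4) > 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["filter_cis_mqtls", "wakefield_abf", "coloc", "ColocResult"]

DEFAULT_PRIOR_W = 0.15**2  # prior effect variance for a quantitative trait


def filter_cis_mqtls(stats: pd.DataFrame, threshold: float = 1e-5) -> pd.DataFrame:
    """Retain variants with p strictly below the suggestive threshold.

    Returns an empty frame when nothing passes; callers drop such regions.
    """
    if "p" not in stats.columns:
        raise KeyError("summary statistics need a 'p' column")
    return stats.loc[stats["p"] < threshold].copy()


def wakefield_abf(beta, se, prior_w: float = DEFAULT_PRIOR_W) -> np.ndarray:
    """Log approximate Bayes factor per variant.

    With V = se^2, Z = beta/se and r = W/(V+W):
    log ABF = 0.5 log(1-r) + 0.5 r Z^2.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    v = se**2
    r = prior_w / (v + prior_w)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * r * z**2


@dataclass
class ColocResult:
    region: str
    pp: np.ndarray  # posterior probabilities H0..H4
    n_variants: int
    priors: tuple[float, float, float]
    significant: bool

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    @property
    def pp_h3(self) -> float:
        return float(self.pp[3])


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc(
    track1: pd.DataFrame,
    track2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_w1: float = DEFAULT_PRIOR_W,
    prior_w2: float = DEFAULT_PRIOR_W,
    region: str = "",
    significance: float = 0.90,
) -> ColocResult:
    """Five-hypothesis colocalization posterior for one region.

    Tracks are joined on ``variant_id``; log Bayes factors are taken from an
    ``lbf`` column when present and computed from beta/se otherwise. All
    sums run in log space. The single-causal-variant-per-trait assumption of
    the ABF framework applies.
    """
    merged = track1.merge(track2, on="variant_id", suffixes=("_1", "_2"))
    if len(merged) == 0:
        raise ValueError("tracks share no variants")
    lbf1 = (
        merged["lbf_1"].to_numpy(dtype=float)
        if "lbf_1" in merged
        else wakefield_abf(merged["beta_1"], merged["se_1"], prior_w1)
    )
    lbf2 = (
        merged["lbf_2"].to_numpy(dtype=float)
        if "lbf_2" in merged
        else wakefield_abf(merged["beta_2"], merged["se_2"], prior_w2)
    )
    l1 = logsumexp(lbf1)
    l2 = logsumexp(lbf2)
    l12 = logsumexp(lbf1 + lbf2)
    lh = np.array(
        [
            0.0,
            np.log(p1) + l1,
            np.log(p2) + l2,
            np.log(p1) + np.log(p2) + _log_diff_exp(l1 + l2, l12),
            np.log(p12) + l12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(
        region=region or str(track1.get("region", pd.Series([""])).iloc[0]),
        pp=pp,
        n_variants=len(merged),
        priors=(p1, p2, p12),
        significant=bool(pp[3] + pp[4] > significance),
    )
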