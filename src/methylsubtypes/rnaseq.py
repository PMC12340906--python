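"""Bulk and pseudobulk transcriptomic signatures of the methylation subtypes.

Bulk route: low-expression filtering, TMM normalization to log2 CPM,
per-cohort moderated-t differential expression (linear model with
empirical-Bayes variance shrinkage), and the three-cohort consistency
filter — nominal p < 0.05 in every cohort, |fold change| > 1.5 in at least
one, and a shared direction of effect.

Single-cell route: cell counts are summed into per-(sample, microglial
state) pseudobulk profiles, states failing minimum cell-count/read-depth
criteria are excluded, per-state differential expression reuses the
moderated-t engine, and a gene is reported for a state when it separates
the two subtypes AND differs from controls in at least one subtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist

from .preprocess import build_design
from .ewas import _ols_per_probe

__all__ = [
    "low_expression_filter",
    "tmm_factors",
    "tmm_logcpm",
    "de_moderated",
    "cross_cohort_deg_filter",
    "PseudobulkSet",
    "pseudobulk",
    "state_deg_selection",
]


def low_expression_filter(
    counts: pd.DataFrame, min_count: int = 10, max_frac: float = 0.80
) -> list[str]:
    """Genes NOT lowly expressed: drop those with count < min_count in
    strictly more than ``max_frac`` of samples (exactly max_frac is kept)."""
    low = (counts < min_count).mean(axis=1)
    return list(counts.index[low <= max_frac])


def _tmm_pair(obs, ref, lib_obs, lib_ref, logratio_trim=0.3, sum_trim=0.05):
    """Trimmed mean of M-values of one library against the reference."""
    with np.errstate(divide="ignore", invalid="ignore"):
        po = obs / lib_obs
        pr = ref / lib_ref
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    ok = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
    m, a, w = m[ok], a[ok], w[ok]
    if len(m) == 0:
        return 1.0
    # double trim by rank, the canonical recipe (30% on M, 5% on A)
    n = len(m)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = (m[keep] / w[keep]).sum() / (1.0 / w[keep]).sum()
    if not np.isfinite(f) or abs(f) < 1e-6:
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """TMM normalization factors (geometric-mean centered to multiply to ~1).

    Reference library = the sample whose 75th-percentile count fraction is
    closest to the mean across samples.
    """
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    f75 = np.array([np.quantile(arr[:, i] / lib[i], 0.75) for i in range(arr.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(arr[:, i], arr[:, ref], lib[i], lib[ref])
            for i in range(arr.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_logcpm(counts: pd.DataFrame, prior_count: float = 0.5):
    """TMM-normalized log2 counts-per-million against effective library sizes."""
    factors = tmm_factors(counts)
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    eff = lib * factors.to_numpy()
    logcpm = np.log2(
        (counts.to_numpy(dtype=float) + prior_count) / (eff + 1.0)[None, :] * 1e6
    )
    return pd.DataFrame(logcpm, index=counts.index, columns=counts.columns), factors


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (limma's approach)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float):
    """Empirical-Bayes variance moderation: method-of-moments fit of a
    scaled inverse-chi-square prior (d0, s0^2) on log variances."""
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(emean)
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
        post[~ok] = s02 * d0 / (d0 + df) if d0 > 0 else s02
    return post, d0, s02


def de_moderated(
    logcpm: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple[str, str],
    label_col: str = "subtype",
    covariates: list[str] | None = None,
    svs: np.ndarray | None = None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated-t differential expression on log2 CPM.

    Ordinary least squares per gene, then residual variances are shrunk
    toward a common prior; the moderated t has df = residual + prior df.
    ``d0_override`` fixes the prior df (0 = ordinary t, inf = fully pooled).
    The group coefficient on log2 CPM is the log2 fold change.
    """
    group, ref = contrast
    keep = samples[label_col].isin([group, ref])
    sub = samples.loc[keep]
    if (sub[label_col] == group).sum() < 3 or (sub[label_col] == ref).sum() < 3:
        raise ValueError("contrast groups need >= 3 samples each")
    y = logcpm[sub.index].to_numpy(dtype=float)
    cols = [np.ones(len(sub)), (sub[label_col] == group).to_numpy(dtype=float)]
    if covariates:
        cols.append(build_design(sub, covariates).to_numpy(dtype=float))
    if svs is not None:
        cols.append(np.asarray(svs, dtype=float)[keep.to_numpy()])
    x = np.column_stack(cols)
    n, pdim = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ (xtx_inv @ x.T).T
    resid = y - beta @ x.T
    df_res = n - pdim
    s2 = (resid**2).sum(axis=1) / df_res
    unsc = xtx_inv[1, 1]
    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0:
            post = s2.copy()
        elif np.isinf(d0):
            post = np.full_like(s2, np.exp(np.log(s2[s2 > 0]).mean()))
        else:
            _, _, s02 = _squeeze_var(s2, df_res)
            post = (d0 * s02 + df_res * s2) / (d0 + df_res)
    else:
        post, d0, _ = _squeeze_var(s2, df_res)
    se = np.sqrt(post * unsc)
    eff = beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, eff / se, 0.0)
    df_total = df_res + (0.0 if d0_override == 0 else d0)
    if np.isinf(df_total):
        pvals = 2.0 * norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    return pd.DataFrame(
        {
            "gene_id": logcpm.index,
            "log2fc": eff,
            "se": se,
            "t": tstat,
            "p": pvals,
            "df": df_total,
        }
    ).set_index("gene_id")


def cross_cohort_deg_filter(
    tables: dict[str, pd.DataFrame],
    p_thresh: float = 0.05,
    fc_thresh: float = 1.5,
) -> pd.DataFrame:
    """Three-flag consistency selection across cohorts.

    selected <=> p < p_thresh in all cohorts AND |log2FC| > log2(fc_thresh)
    in at least one cohort AND the sign of log2FC agrees in all cohorts.
    Gene universes are inner-joined.
    """
    if len(tables) < 2:
        raise ValueError("need at least two cohorts")
    cohorts = sorted(tables)
    genes = tables[cohorts[0]].index
    for c in cohorts[1:]:
        genes = genes.intersection(tables[c].index)
    lfc = pd.DataFrame({c: tables[c].loc[genes, "log2fc"] for c in cohorts})
    pv = pd.DataFrame({c: tables[c].loc[genes, "p"] for c in cohorts})
    out = pd.DataFrame(index=genes)
    for c in cohorts:
        out[f"log2fc_{c}"] = lfc[c]
        out[f"p_{c}"] = pv[c]
    out["pass_p_all"] = (pv < p_thresh).all(axis=1)
    out["pass_fc_any"] = (lfc.abs() > np.log2(fc_thresh)).any(axis=1)
    sign = np.sign(lfc)
    out["consistent_sign"] = (sign.nunique(axis=1) == 1) & (sign != 0).all(axis=1)
    out["selected"] = out["pass_p_all"] & out["pass_fc_any"] & out["consistent_sign"]
    return out


@dataclass
class PseudobulkSet:
    """Per-state pseudobulk matrices with the inclusion verdicts."""

    counts: dict[str, pd.DataFrame]  # state -> genes x samples summed counts
    cells_per_sample: dict[str, pd.Series]
    included: dict[str, bool]
    excluded_log: list = field(default_factory=list)


def pseudobulk(
    counts: pd.DataFrame,
    cell_meta: pd.DataFrame,
    group_of_sample: dict[str, str],
    compared_groups: list[str],
    min_cells: int = 10,
    min_depth: int = 1000,
) -> PseudobulkSet:
    """Sum cell counts into per-(sample, state) profiles with inclusion rules.

    ``cell_meta`` must carry ``sample_id`` and ``state`` per cell (indexed by
    the columns of ``counts``). A state is included only when every compared
    group averages at least ``min_cells`` cells and ``min_depth`` summed
    counts per sample. Sums are exact integer identities.
    """
    meta = cell_meta.loc[counts.columns]
    out_counts: dict[str, pd.DataFrame] = {}
    out_cells: dict[str, pd.Series] = {}
    included: dict[str, bool] = {}
    log: list = []
    for state in sorted(meta["state"].unique()):
        cells = meta.index[meta["state"] == state]
        sub = counts[cells]
        by_sample = sub.T.groupby(meta.loc[cells, "sample_id"]).sum().T
        ncells = meta.loc[cells].groupby("sample_id").size()
        out_counts[state] = by_sample
        out_cells[state] = ncells
        ok = True
        for g in compared_groups:
            gs = [s for s in by_sample.columns if group_of_sample.get(s) == g]
            if not gs:
                ok = False
                log.append((state, g, "no samples"))
                continue
            mean_cells = float(ncells.reindex(gs).fillna(0).mean())
            mean_depth = float(by_sample[gs].sum(axis=0).mean())
            if mean_cells < min_cells:
                ok = False
                log.append((state, g, f"mean cells {mean_cells:.1f} < {min_cells}"))
            if mean_depth < min_depth:
                ok = False
                log.append((state, g, f"mean depth {mean_depth:.0f} < {min_depth}"))
        included[state] = ok
    return PseudobulkSet(out_counts, out_cells, included, log)


def state_deg_selection(
    per_state: dict[str, dict[str, pd.DataFrame]], p: float = 0.05
) -> tuple[dict[str, list[str]], list[str]]:
    """Subtype-specific gene selection per microglial state.

    A gene is selected in a state iff p < ``p`` in the subtype-vs-subtype
    comparison AND p < ``p`` versus controls in at least one subtype. The
    inner dict per state must provide 's1_vs_s2', 's1_vs_hc', 's2_vs_hc'.
    Returns the per-state lists and the pooled deduplicated list.
    """
    per_state_sel: dict[str, list[str]] = {}
    pooled: set[str] = set()
    for state, tabs in sorted(per_state.items()):
        ss = tabs["s1_vs_s2"]
        h1 = tabs["s1_vs_hc"]
        h2 = tabs["s2_vs_hc"]
        genes = ss.index.intersection(h1.index).intersection(h2.index)
        sel = [
            g
            for g in genes
            if ss.loc[g, "p"] < p and (h1.loc[g, "p"] < p or h2.loc[g, "p"] < p)
        ]
        per_state_sel[state] = sel
        pooled.update(sel)
    return per_state_sel, sorted(pooled)
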