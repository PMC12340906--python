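"""Pre-clustering preparation of methylation beta matrices.

Beta values (methylation fractions in [0,1]) are adjusted probe-by-probe for
technical and biological covariates with an ordinary least-squares model, then
non-variant probes are removed with a robust deviation filter, and cohorts
profiled on different array generations (EPIC-like vs 450K-like) are
harmonized onto their shared probe set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "AdjustedMatrix",
    "CollinearDesignError",
    "build_design",
    "residualize",
    "variance_filter",
    "harmonize_platforms",
    "read_beta_tsv",
    "write_beta_tsv",
    "read_sample_table",
]

#: sample-sheet columns that are treated as categorical in designs
CATEGORICAL_COVARIATES = {"sex", "batch", "cohort", "plate", "diagnosis"}


class CollinearDesignError(ValueError):
    """Raised when the covariate design is rank-deficient or near-singular."""


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with cohort/platform metadata."""

    values: pd.DataFrame
    cohort: str = ""
    platform: str = "EPIC-like"

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique:
            raise ValueError("probe ids must be unique")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError(
                "beta matrix contains missing values; impute or drop before loading"
            )
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("beta values must lie in [0,1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AdjustedMatrix:
    """Covariate-adjusted (residualized) methylation values.

    ``residuals`` is probes x samples; every probe's residual vector is
    orthogonal to each design column (including the intercept, so residuals
    are mean-centered per probe).
    """

    residuals: pd.DataFrame
    covariates_used: list[str] = field(default_factory=list)
    design: pd.DataFrame | None = None

    @property
    def probe_ids(self) -> list[str]:
        return list(self.residuals.index)


def build_design(samples: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Expand sample-sheet columns into a numeric design matrix (no intercept).

    Categorical columns (sex, batch, plate, ...) are dummy-coded dropping the
    first level; numeric columns are passed through. Zero-variance columns are
    rejected because they are indistinguishable from the intercept.
    """
    cols: list[pd.Series | pd.DataFrame] = []
    for name in covariates:
        if name not in samples.columns:
            raise KeyError(f"covariate {name!r} not present in sample table")
        col = samples[name]
        if name in CATEGORICAL_COVARIATES or col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            if dummies.shape[1] == 0:
                raise CollinearDesignError(
                    f"covariate {name!r} has a single level (zero variance)"
                )
            cols.append(dummies.astype(float))
        else:
            if float(np.var(col.to_numpy(dtype=float))) == 0.0:
                raise CollinearDesignError(f"covariate {name!r} has zero variance")
            cols.append(col.astype(float))
    design = pd.concat(cols, axis=1)
    design.index = samples.index
    return design


def _check_condition(design: np.ndarray, names: list[str], max_cond: float) -> None:
    s = np.linalg.svd(design - design.mean(axis=0), compute_uv=False)
    if s[-1] == 0 or s[0] / max(s[-1], np.finfo(float).tiny) > max_cond:
        # name the most correlated column pair to make the error actionable
        corr = np.corrcoef(design, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise CollinearDesignError(
            f"design is (near-)collinear; offending columns include "
            f"{names[i]!r} and {names[j]!r} (|r|={abs(corr[i, j]):.4f})"
        )


def residualize(
    beta: BetaMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    covariates: list[str],
    max_condition: float = 1e8,
) -> AdjustedMatrix:
    """Per-probe OLS residuals of methylation on covariates (intercept always included).

    The same linear multiple-regression adjustment is applied to each probe;
    the returned residuals are what clustering and downstream association
    models consume.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    samples = samples.loc[values.columns]
    design = build_design(samples, covariates)
    x = design.to_numpy(dtype=float)
    _check_condition(x, list(design.columns), max_condition)
    # intercept via column of ones; project out the full design with QR
    xi = np.column_stack([np.ones(x.shape[0]), x])
    q, _ = np.linalg.qr(xi)
    y = values.to_numpy(dtype=float)  # probes x samples
    resid = y - (y @ q) @ q.T
    return AdjustedMatrix(
        residuals=pd.DataFrame(resid, index=values.index, columns=values.columns),
        covariates_used=list(covariates),
        design=design,
    )


def variance_filter(
    adjusted: AdjustedMatrix | pd.DataFrame,
    quantile: float = 0.90,
    min_score: float | None = None,
    top_fraction: float | None = None,
) -> list[str]:
    """Select variable probes by the ``quantile``-th percentile absolute deviation.

    Per probe, score = the ``quantile`` percentile of |value - probe median|, a
    robust range statistic. Probes are retained either by an absolute cutoff
    (``score >= min_score``) or by keeping the most variable ``top_fraction``
    of probes; the two modes reflect the two readings of an under-specified
    published filter and exactly one must be given. Probe order is preserved.
    """
    values = adjusted.residuals if isinstance(adjusted, AdjustedMatrix) else adjusted
    if values.shape[1] < 3:
        raise ValueError("variance filter requires at least 3 samples")
    if (min_score is None) == (top_fraction is None):
        raise ValueError("specify exactly one of min_score or top_fraction")
    arr = values.to_numpy(dtype=float)
    dev = np.abs(arr - np.median(arr, axis=1, keepdims=True))
    score = np.quantile(dev, quantile, axis=1)
    if min_score is not None:
        keep = score >= min_score
    else:
        n_keep = int(round(top_fraction * len(score)))
        if n_keep <= 0:
            keep = np.zeros(len(score), dtype=bool)
        else:
            cutoff = np.sort(score)[::-1][n_keep - 1]
            keep = score >= cutoff
            # deterministic tie handling: trim back to n_keep in probe order
            if keep.sum() > n_keep:
                extra = keep.sum() - n_keep
                tied = np.where(keep & (score == cutoff))[0]
                keep[tied[-extra:]] = False
    kept = [p for p, k in zip(values.index, keep) if k]
    if not kept:
        warnings.warn("variance filter retained no probes", stacklevel=2)
    return kept


def harmonize_platforms(matrices: list[BetaMatrix | pd.DataFrame]) -> list[str]:
    """Probe ids shared by every cohort, in canonical lexicographic order."""
    if len(matrices) < 2:
        raise ValueError("harmonization requires at least two cohorts")
    sets = [
        set(m.probe_ids) if isinstance(m, BetaMatrix) else set(m.index)
        for m in matrices
    ]
    shared = set.intersection(*sets)
    if not shared:
        raise ValueError("cohorts share no probes")
    return sorted(shared)


# ---------------------------------------------------------------------------
# plain-text readers/writers


def read_beta_tsv(
    path,
    cohort: str = "",
    platform: str = "EPIC-like",
    impute_missing: bool = False,
) -> BetaMatrix:
    """Read a probes-as-rows TSV (header row = sample ids).

    Missing beta values are rejected by default; with ``impute_missing``
    they are replaced by the probe median (probes missing everywhere are
    dropped with a warning).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if impute_missing and df.isna().to_numpy().any():
        all_missing = df.isna().all(axis=1)
        if all_missing.any():
            warnings.warn(
                f"dropping {int(all_missing.sum())} probes with no observed values",
                stacklevel=2,
            )
            df = df.loc[~all_missing]
        df = df.apply(lambda row: row.fillna(row.median()), axis=1)
    return BetaMatrix(values=df, cohort=cohort, platform=platform)


def write_beta_tsv(beta: BetaMatrix, path) -> None:
    beta.values.to_csv(path, sep="\t", float_format="%.6g")


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if "diagnosis" in df.columns and df["diagnosis"].isna().any():
        raise ValueError("diagnosis missing for some samples")
    return df
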