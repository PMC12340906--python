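"""Sparse partial least squares discriminant analysis (sPLS-DA).

A supervised projection used two ways: to extract the features that
discriminate the discovered clusters, and to build a latent space onto which
replication cohorts are projected for the hull-overlap test. The algorithm
is sparse PLS in the Lê Cao formulation: per component, the dominant singular
pair of the current X'Y cross-covariance is soft-thresholded so exactly
``keepX`` X-weights survive, the data are deflated by regression on the
component score, and a rotation matrix maps standardized data directly to
scores so projection of new cohorts is a single matrix product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SplsdaModel",
    "fit",
    "project",
    "feature_stability",
    "selected_features",
    "save_model",
    "load_model",
]


@dataclass
class SplsdaModel:
    loadings: pd.DataFrame  # features x ncomp sparse X-weights (unit norm)
    rotation: pd.DataFrame  # features x ncomp; scores = X_std @ rotation
    scores: pd.DataFrame  # training samples x ncomp
    keepX: list[int]
    ncomp: int
    center: pd.Series
    scale: pd.Series
    class_levels: list
    y: np.ndarray | None = None

    def selected(self, component: int | None = None) -> list[str]:
        """Features with nonzero loading (union over components by default)."""
        w = self.loadings.to_numpy()
        if component is not None:
            mask = w[:, component] != 0
        else:
            mask = (w != 0).any(axis=1)
        return [f for f, m in zip(self.loadings.index, mask) if m]


def _soft_threshold_keep(u: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so exactly ``keep`` entries stay nonzero, then renormalize."""
    if keep >= u.size:
        lam = 0.0
    else:
        a = np.sort(np.abs(u))[::-1]
        lam = a[keep]  # (keep+1)-th largest magnitude
    out = np.sign(u) * np.clip(np.abs(u) - lam, 0.0, None)
    nrm = np.linalg.norm(out)
    if nrm == 0.0:  # pathological ties; fall back to hard selection
        idx = np.argsort(-np.abs(u), kind="stable")[:keep]
        out = np.zeros_like(u)
        out[idx] = u[idx]
        nrm = np.linalg.norm(out)
    return out / nrm


def fit(
    x,
    y,
    ncomp: int = 6,
    keepX: int | list[int] = 2000,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SplsdaModel:
    """Fit sPLS-DA on samples x features data with class labels ``y``.

    The response is the centered/scaled dummy matrix of the classes. Each
    X-loading column carries exactly keepX nonzeros and unit norm. The
    stored rotation R = W (P'W)^{-1} reproduces the training scores from the
    standardized data and generalizes to new samples.
    """
    xdf = x if isinstance(x, pd.DataFrame) else pd.DataFrame(np.asarray(x, float))
    features = list(xdf.columns)
    xm = xdf.to_numpy(dtype=float)
    n, p = xm.shape
    y = np.asarray(y)
    levels = sorted(pd.unique(y).tolist())
    if len(levels) < 2:
        raise ValueError("sPLS-DA requires at least two classes")
    keep = [int(keepX)] * ncomp if np.isscalar(keepX) else [int(k) for k in keepX]
    if len(keep) != ncomp or any(k < 1 or k > p for k in keep):
        raise ValueError("keepX must give one value in [1, n_features] per component")

    center = xm.mean(axis=0)
    scale = xm.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    xs = (xm - center) / scale
    ym = np.array([[1.0 if yi == lv else 0.0 for lv in levels] for yi in y])
    ym = (ym - ym.mean(axis=0)) / np.where(ym.std(axis=0, ddof=1) == 0, 1, ym.std(axis=0, ddof=1))

    xd, yd = xs.copy(), ym.copy()
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    for h in range(ncomp):
        m = xd.T @ yd  # p x g
        # dominant right singular vector from the small g x g Gram matrix
        gram = m.T @ m
        evals, evecs = np.linalg.eigh(gram)
        v = evecs[:, -1]
        u = np.zeros(p)
        for _ in range(max_iter):
            u_new = _soft_threshold_keep(m @ v, keep[h])
            v_new = m.T @ u_new
            nv = np.linalg.norm(v_new)
            v_new = v_new / nv if nv > 0 else v
            if np.linalg.norm(u_new - u) < tol and np.linalg.norm(v_new - v) < tol:
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        t = xd @ u
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"degenerate component {h + 1}: zero score variance")
        pl = xd.T @ t / tt
        W[:, h], P[:, h], T[:, h] = u, pl, t
        xd = xd - np.outer(t, pl)
        yd = yd - np.outer(t, yd.T @ t / tt)

    rotation = W @ np.linalg.inv(P.T @ W)
    idx = pd.Index(features, name="feature")
    comps = [f"comp{h + 1}" for h in range(ncomp)]
    return SplsdaModel(
        loadings=pd.DataFrame(W, index=idx, columns=comps),
        rotation=pd.DataFrame(rotation, index=idx, columns=comps),
        scores=pd.DataFrame(T, index=xdf.index, columns=comps),
        keepX=keep,
        ncomp=ncomp,
        center=pd.Series(center, index=idx),
        scale=pd.Series(scale, index=idx),
        class_levels=levels,
        y=y,
    )


def project(model: SplsdaModel, x_new, allow_missing: bool = False) -> pd.DataFrame:
    """Project new samples x features data into the model's latent space.

    Missing model features raise by default, listing them. With
    ``allow_missing`` they contribute their training mean (zero after
    centering), which is the convention used for cross-platform projection;
    the caller is expected to warn when too many are absent.
    """
    xdf = (
        x_new
        if isinstance(x_new, pd.DataFrame)
        else pd.DataFrame(np.asarray(x_new, float), columns=model.loadings.index)
    )
    feats = model.loadings.index
    missing = [f for f in feats if f not in xdf.columns]
    if missing and not allow_missing:
        head = ", ".join(map(str, missing[:5]))
        raise KeyError(
            f"{len(missing)} model features absent from new data (e.g. {head})"
        )
    xs = pd.DataFrame(0.0, index=xdf.index, columns=feats)
    present = [f for f in feats if f not in missing]
    sub = xdf[present].to_numpy(dtype=float)
    xs.loc[:, present] = (sub - model.center[present].to_numpy()) / model.scale[
        present
    ].to_numpy()
    scores = xs.to_numpy() @ model.rotation.to_numpy()
    return pd.DataFrame(scores, index=xdf.index, columns=model.rotation.columns)


def selected_features(model: SplsdaModel) -> list[str]:
    return model.selected()


def save_model(model: SplsdaModel, prefix) -> None:
    """Serialize as ``<prefix>.json`` (scalars/vectors) + ``<prefix>_loadings.tsv``."""
    prefix = Path(prefix)
    meta = {
        "keepX": model.keepX,
        "ncomp": model.ncomp,
        "class_levels": [str(c) for c in model.class_levels],
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "features": [str(f) for f in model.loadings.index],
        "rotation": model.rotation.to_numpy().tolist(),
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh)
    model.loadings.to_csv(f"{prefix}_loadings.tsv", sep="\t")


def load_model(prefix) -> SplsdaModel:
    """Load a model written by :func:`save_model` (training scores excluded)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    loadings = pd.read_csv(f"{prefix}_loadings.tsv", sep="\t", index_col=0)
    idx = pd.Index(meta["features"], name="feature")
    loadings.index = idx
    rotation = pd.DataFrame(meta["rotation"], index=idx, columns=loadings.columns)
    return SplsdaModel(
        loadings=loadings,
        rotation=rotation,
        scores=pd.DataFrame(columns=loadings.columns),
        keepX=meta["keepX"],
        ncomp=meta["ncomp"],
        center=pd.Series(meta["center"], index=idx),
        scale=pd.Series(meta["scale"], index=idx),
        class_levels=meta["class_levels"],
    )


def feature_stability(
    x,
    y,
    proportions=(1.0, 0.75, 0.5, 0.25, 0.1, 0.05, 0.01),
    reps: int = 10,
    seed: int = 0,
    ncomp: int = 6,
    keepX: int | list[int] = 2000,
) -> pd.DataFrame:
    """Label-randomization robustness check of the selected-feature set.

    For each proportion p and repetition, the class labels of a random
    ceil(p*n) subset of samples are shuffled among themselves (class
    frequencies preserved), the model is refit, and the overlap between the
    refit selected-feature union and the original union is recorded together
    with the chance-level expectation s^2/m (s features selected of m).
    Proportion 0 means no randomization, so overlap equals the selection size.
    """
    xdf = x if isinstance(x, pd.DataFrame) else pd.DataFrame(np.asarray(x, float))
    y = np.asarray(y)
    n = len(y)
    m = xdf.shape[1]
    base = set(fit(xdf, y, ncomp=ncomp, keepX=keepX).selected())
    rng = np.random.default_rng(seed)
    rows = []
    for p in proportions:
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0,1]")
        for rep in range(reps):
            if p == 0:
                sel = base
            else:
                k = int(np.ceil(p * n))
                idx = rng.choice(n, size=k, replace=False)
                y_rand = y.copy()
                y_rand[idx] = y[rng.permutation(idx)]
                if len(pd.unique(y_rand)) < 2:
                    continue
                sel = set(fit(xdf, y_rand, ncomp=ncomp, keepX=keepX).selected())
            rows.append(
                {
                    "proportion_randomized": p,
                    "rep": rep,
                    "overlap_count": len(base & sel),
                    "n_selected": len(sel),
                    "chance_level": len(base) * len(sel) / m,
                }
            )
    return pd.DataFrame(rows)
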