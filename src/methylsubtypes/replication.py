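"""Cross-cohort replication of methylation clusters.

Two complementary checks decide whether clusters discovered independently in
different cohorts are the same biological subtype:

* probe level — per-cluster median methylation profiles are correlated
  (Pearson) between cohorts and clusters are paired by a mutual-best-match
  rule on the correlation matrix;
* sample level — an sPLS-DA latent space fitted on a discovery cohort is
  used to project the replication cohort; a 2-D convex hull is drawn around
  each discovery cluster and the overlap of each replication cluster with
  each hull is scored by an upper-tail hypergeometric test.

A subtype is confirmed only when a set of clusters, one per cohort, is
mutually matched by correlation AND significant in the hull test in all
directions, under both clustering algorithms. Clusters outside every such
clique are flagged Unassigned.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import hypergeom
import shapely
from shapely import Polygon

from . import splsda as _splsda
from .splsda import SplsdaModel

__all__ = [
    "median_profiles",
    "correlate_and_match",
    "HullTest",
    "hull_projection_test",
    "hull_overlap_test",
    "PairReport",
    "pair_report",
    "ConfirmedSubtypes",
    "confirm_subtypes",
]


def median_profiles(values: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-cluster, per-probe median beta (columns = cluster ids)."""
    labels = np.asarray(labels)
    if len(labels) == 0 or len(labels) != values.shape[1]:
        raise ValueError("labels must be non-empty and match the sample count")
    out = {}
    for lab in np.unique(labels):
        cols = values.columns[labels == lab]
        if len(cols) == 0:
            raise ValueError(f"cluster {lab!r} is empty")
        out[lab] = values[cols].median(axis=1)
    return pd.DataFrame(out)


def correlate_and_match(
    profiles_a: pd.DataFrame, profiles_b: pd.DataFrame, min_r: float = 0.0
):
    """Pearson r between median profiles plus a mutual-best one-to-one matching.

    A pair (i, j) is matched when r[i, j] is both the row and the column
    maximum and r >= min_r. Zero-variance profiles yield missing r.
    """
    shared = profiles_a.index.intersection(profiles_b.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared probes to correlate")
    a = profiles_a.loc[shared]
    b = profiles_b.loc[shared]
    r = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        for cb in b.columns:
            xa, xb = a[ca].to_numpy(), b[cb].to_numpy()
            if xa.std() == 0 or xb.std() == 0:
                r.loc[ca, cb] = np.nan
            else:
                r.loc[ca, cb] = float(np.corrcoef(xa, xb)[0, 1])
    pairs = []
    rv = r.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_max = np.nanmax(rv, axis=1)
        col_max = np.nanmax(rv, axis=0)
    for i, ca in enumerate(r.index):
        for j, cb in enumerate(r.columns):
            v = rv[i, j]
            if np.isnan(v):
                continue
            if v == row_max[i] and v == col_max[j] and v >= min_r:
                pairs.append((ca, cb, float(v)))
    return r, pairs


@dataclass
class HullTest:
    """Hull-overlap contingency of replication clusters vs discovery hulls."""

    contingency: pd.DataFrame  # rows: replication clusters; cols: hulls + outside
    pvalues: pd.DataFrame  # upper-tail hypergeometric per (cluster, hull)
    pvalues_inhull: pd.DataFrame | None = None  # conditioned on in-hull samples
    degenerate: list = field(default_factory=list)
    n_population: int = 0
    n_inhull: int = 0


def _hull_polygon(points: np.ndarray) -> Polygon | None:
    uniq = np.unique(points, axis=0)
    if len(uniq) < 3:
        return None
    try:
        hull = ConvexHull(uniq)
    except QhullError:
        return None  # collinear
    poly = Polygon(uniq[hull.vertices])
    # tolerance buffer so re-projected boundary points (vertices included)
    # are not lost to floating-point noise; boundary counts as inside
    span = max(np.ptp(uniq[:, 0]), np.ptp(uniq[:, 1]), 1.0)
    return poly.buffer(1e-9 * span)


def hull_projection_test(
    model: SplsdaModel,
    discovery_labels,
    replication_values: pd.DataFrame,
    replication_labels,
    min_feature_frac: float = 0.90,
) -> HullTest:
    """Project a replication cohort into a discovery latent space and test overlap.

    Replication samples (rows of the projected matrix) are placed in the
    first two latent components; for each discovery cluster a convex hull is
    drawn around its training scores, and each (replication cluster j,
    discovery hull i) cell is tested with an upper-tail hypergeometric:
    population = all projected replication samples, successes = samples
    inside hull i (boundary counts as inside; a sample may lie in several
    hulls), draws = size of cluster j. Degenerate hulls (<3 distinct points
    or collinear) are flagged and skipped.
    """
    feats = model.loadings.index
    present = feats.intersection(replication_values.columns)
    if len(present) < min_feature_frac * len(feats):
        warnings.warn(
            f"only {len(present)}/{len(feats)} model features present in the "
            "replication cohort; projection uses the intersection",
            stacklevel=2,
        )
    proj = _splsda.project(model, replication_values, allow_missing=True)
    pts = proj.iloc[:, :2].to_numpy()
    disc = model.scores.iloc[:, :2].to_numpy()
    return hull_overlap_test(disc, discovery_labels, pts, replication_labels)


def hull_overlap_test(
    discovery_points: np.ndarray,
    discovery_labels,
    replication_points: np.ndarray,
    replication_labels,
) -> HullTest:
    """Geometry + hypergeometric core of the hull test on given 2-D points.

    Two p-values are reported per (replication cluster, discovery hull)
    cell. ``pvalues`` uses all projected replication samples as the
    population. ``pvalues_inhull`` conditions on the samples that fall
    inside at least one hull: cross-cohort projection shrinks class
    separation (training scores are fit to the discovery labels), so much of
    the replication cloud can land outside every hull for reasons unrelated
    to cluster identity; restricting the population to in-hull samples asks
    only whether a replication cluster concentrates in the matching hull,
    and remains an exact hypergeometric null because labels are independent
    of the geometry under no association.
    """
    discovery_labels = np.asarray(discovery_labels)
    replication_labels = np.asarray(replication_labels)
    pts = np.asarray(replication_points, dtype=float)[:, :2]
    disc = np.asarray(discovery_points, dtype=float)[:, :2]

    hulls, degenerate = {}, []
    for lab in np.unique(discovery_labels):
        poly = _hull_polygon(disc[discovery_labels == lab])
        if poly is None:
            degenerate.append(lab)
        else:
            hulls[lab] = poly

    n = len(pts)
    inside = {}
    point_geoms = shapely.points(pts)
    for lab, poly in hulls.items():
        inside[lab] = shapely.covers(poly, point_geoms)

    rep_clusters = list(np.unique(replication_labels))
    cols = list(hulls) + ["outside"]
    cont = pd.DataFrame(0, index=rep_clusters, columns=cols, dtype=int)
    pvals = pd.DataFrame(np.nan, index=rep_clusters, columns=list(hulls), dtype=float)
    pvals_c = pd.DataFrame(np.nan, index=rep_clusters, columns=list(hulls), dtype=float)
    any_hull = (
        np.column_stack(list(inside.values())).any(axis=1)
        if inside
        else np.zeros(n, bool)
    )
    n_in = int(any_hull.sum())
    for rc in rep_clusters:
        members = replication_labels == rc
        draws = int(members.sum())
        draws_in = int((members & any_hull).sum())
        for lab in hulls:
            k_in = int(inside[lab].sum())
            a = int((inside[lab] & members).sum())
            cont.loc[rc, lab] = a
            pvals.loc[rc, lab] = float(hypergeom.sf(a - 1, n, k_in, draws))
            if n_in > 0:
                pvals_c.loc[rc, lab] = float(
                    hypergeom.sf(a - 1, n_in, k_in, draws_in)
                )
        cont.loc[rc, "outside"] = int((members & ~any_hull).sum())
    return HullTest(
        contingency=cont,
        pvalues=pvals,
        pvalues_inhull=pvals_c,
        degenerate=degenerate,
        n_population=n,
        n_inhull=n_in,
    )


@dataclass
class PairReport:
    """Replication evidence for one ordered cohort pair (a = discovery)."""

    cohort_a: str
    cohort_b: str
    correlation: pd.DataFrame
    matched: list  # (cluster_a, cluster_b, r)
    hull_ab: HullTest  # a as discovery, b projected
    sig_ab: set = field(default_factory=set)  # (cluster_a, cluster_b) significant


def pair_report(
    cohort_a: str,
    cohort_b: str,
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    model_a: SplsdaModel,
    labels_a,
    values_b: pd.DataFrame,
    labels_b,
    alpha: float = 0.05,
    min_r: float = 0.0,
) -> PairReport:
    """Assemble correlation matching + hull test for one ordered cohort pair.

    Significance uses the in-hull-conditioned hypergeometric p, Bonferroni-
    corrected over the tested (cluster, hull) pairs of this direction.
    """
    r, pairs = correlate_and_match(profiles_a, profiles_b, min_r=min_r)
    ht = hull_projection_test(model_a, labels_a, values_b.T, labels_b)
    pv = ht.pvalues_inhull if ht.pvalues_inhull is not None else ht.pvalues
    m = int(pv.notna().to_numpy().sum())
    sig = set()
    for rc in pv.index:
        for dc in pv.columns:
            p = pv.loc[rc, dc]
            if np.isfinite(p) and p * max(m, 1) < alpha:
                sig.add((dc, rc))  # (discovery cluster, replication cluster)
    return PairReport(
        cohort_a=cohort_a,
        cohort_b=cohort_b,
        correlation=r,
        matched=pairs,
        hull_ab=ht,
        sig_ab=sig,
    )


@dataclass
class ConfirmedSubtypes:
    subtypes: list  # list of dict cohort -> cluster id, ordered S1, S2, ...
    unassigned: list  # (cohort, cluster) with no cross-cohort clique

    def name_of(self, cohort: str, cluster) -> str:
        for i, st in enumerate(self.subtypes):
            if st.get(cohort) == cluster:
                return f"S{i + 1}"
        return "Unassigned"


def confirm_subtypes(
    reports_by_method: dict[str, dict[tuple[str, str], PairReport]],
    cohorts: list[str] | None = None,
) -> ConfirmedSubtypes:
    """Intersect per-method cross-cohort cliques into confirmed subtypes.

    For each clustering method, an edge joins cluster i of cohort a to
    cluster j of cohort b when they are mutual-best correlation matches and
    the hull test is significant in both directions. A candidate subtype is a
    clique with one cluster per cohort; only cliques present under every
    method are confirmed. Remaining clusters are Unassigned.
    """
    methods = list(reports_by_method)
    if not methods:
        raise ValueError("no replication reports supplied")
    first = reports_by_method[methods[0]]
    inferred = sorted({c for pair in first for c in pair})
    cohorts = list(cohorts) if cohorts is not None else inferred
    for m in methods:
        got = sorted({c for pair in reports_by_method[m] for c in pair})
        if got != sorted(cohorts):
            raise ValueError(f"method {m!r} covers cohorts {got}, expected {cohorts}")

    clusters_by_cohort: dict[str, set] = {c: set() for c in cohorts}
    for m in methods:
        for (a, b), rep in reports_by_method[m].items():
            clusters_by_cohort[a].update(rep.correlation.index)
            clusters_by_cohort[b].update(rep.correlation.columns)

    def edges(method: str) -> dict[tuple, float]:
        out: dict[tuple, float] = {}
        reps = reports_by_method[method]
        for (a, b), rep in reps.items():
            back = reps.get((b, a))
            for ca, cb, r in rep.matched:
                ok_ab = (ca, cb) in rep.sig_ab
                ok_ba = back is not None and (cb, ca) in back.sig_ab
                if ok_ab and ok_ba:
                    out[((a, ca), (b, cb))] = r
        return out

    def cliques(method: str) -> dict[frozenset, float]:
        e = edges(method)

        def connected(u, v):
            return (u, v) in e or (v, u) in e

        found = {}
        for combo in itertools.product(
            *[[(c, cl) for cl in sorted(clusters_by_cohort[c])] for c in cohorts]
        ):
            if all(connected(u, v) for u, v in itertools.combinations(combo, 2)):
                weight = sum(
                    e.get((u, v), e.get((v, u), 0.0))
                    for u, v in itertools.combinations(combo, 2)
                )
                found[frozenset(combo)] = weight
        return found

    per_method = [cliques(m) for m in methods]
    common = set(per_method[0])
    for c in per_method[1:]:
        common &= set(c)
    # greedy disjoint selection by total correlation weight (deterministic)
    ranked = sorted(
        common,
        key=lambda fs: (-sum(c[fs] for c in per_method), sorted(map(str, fs))),
    )
    used: set = set()
    chosen: list[frozenset] = []
    for fs in ranked:
        if fs & used:
            continue
        chosen.append(fs)
        used |= fs
    chosen.sort(key=lambda fs: sorted(map(str, fs)))
    subtypes = [dict(sorted(fs, key=lambda t: str(t[0]))) for fs in chosen]
    unassigned = [
        (c, cl)
        for c in cohorts
        for cl in sorted(clusters_by_cohort[c])
        if (c, cl) not in used
    ]
    return ConfirmedSubtypes(subtypes=subtypes, unassigned=unassigned)
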