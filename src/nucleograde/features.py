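"""Spatial features of nuclear point patterns in biopsy sections.

Each core-needle-biopsy (CNB) section is reduced to the set of malignant-nucleus
centroids, and 52 features describing the nuclear architecture are computed from
those centroids alone:

* 24 nuclear-graph features — Voronoi-cell geometry (area, perimeter, maximum
  vertex distance), Delaunay-triangulation geometry (edge lengths, triangle
  areas) and minimum-spanning-tree branch lengths, each summarized by four
  population statistics;
* 27 nuclear-density features — neighbor counts within four radii, distances to
  the k-th nearest neighbor for two values of k (each with the four statistics),
  and min/median/max of a k-NN density estimate;
* the nuclear count.

The four population statistics follow the cell-graph convention: mean,
population standard deviation, min/max ratio, and the disorder statistic
sigma / (mu + sigma), a normalized dispersion in [0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, Voronoi
from scipy.spatial.distance import pdist, squareform
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.stats import mannwhitneyu
from shapely.geometry import MultiPoint
from sklearn.neighbors import BallTree, KDTree

logger = logging.getLogger(__name__)

STAT_NAMES = ("mean", "stddev", "min_max_ratio", "disorder")


class DegenerateGeometryError(ValueError):
    """Point configuration does not admit the requested tessellation."""


class SectionExcluded(ValueError):
    """Section has too few nuclei for spatial feature extraction."""


@dataclass(frozen=True)
class PopSummary:
    """Population statistics of a per-object feature distribution."""

    mean: float
    stddev: float
    min_max_ratio: float
    disorder: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mean, self.stddev, self.min_max_ratio, self.disorder)


@dataclass
class CentroidSet:
    """Nuclear centroids of one CNB section.

    Exact-coordinate duplicates are merged on construction so downstream
    tessellations stay well-posed; the merge count is logged.
    """

    patient_id: str
    section_id: str
    points: np.ndarray
    extent: tuple[float, float]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ValueError(f"non-positive extent {self.extent}")
        if pts.size and (
            pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > w or pts[:, 1].max() > h
        ):
            raise ValueError("centroids outside the stated section extent")
        deduped = np.unique(pts, axis=0) if pts.size else pts
        if len(deduped) < len(pts):
            logger.info(
                "section %s: merged %d duplicate centroids",
                self.section_id, len(pts) - len(deduped),
            )
            # keep first-occurrence order for reproducibility of ordering
            _, idx = np.unique(pts, axis=0, return_index=True)
            deduped = pts[np.sort(idx)]
        self.points = deduped

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class DensityConfig:
    """Radii and neighbor counts for the nuclear-density features.

    ``radii`` are the four ball-tree query radii (pixels at nominal 40x),
    ``neighbor_counts`` the two k values for k-NN distances, and ``k_density``
    the k of the k-NN density estimate rho(i) = k / (pi * r_k(i)^2).
    """

    radii: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0)
    neighbor_counts: tuple[int, ...] = (3, 5)
    k_density: int = 5

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, float)
        if r.size == 0 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be positive and strictly increasing")
        k = self.neighbor_counts
        if any(int(x) != x for x in k) or k[0] < 1 or np.any(np.diff(k) <= 0):
            raise ValueError("neighbor_counts must be increasing integers >= 1")
        if self.k_density < 1:
            raise ValueError("k_density must be >= 1")


def feature_names(cfg: DensityConfig | None = None) -> list[str]:
    """Ordered registry of the 52 feature names."""
    cfg = cfg or DensityConfig()
    names: list[str] = []
    for base in ("voronoi.area", "voronoi.perimeter", "voronoi.max_dist",
                 "delaunay.sides", "delaunay.area", "mst.branches"):
        names += [f"{base}.{s}" for s in STAT_NAMES]
    for i in range(1, len(cfg.radii) + 1):
        names += [f"density.neighbors_in_distance.{i}.{s}" for s in STAT_NAMES]
    for i in range(1, len(cfg.neighbor_counts) + 1):
        names += [f"density.dist_for_neighbors.{i}.{s}" for s in STAT_NAMES]
    names += ["density.rho.min", "density.rho.median", "density.rho.max"]
    names += ["count"]
    return names


def popstats(values) -> PopSummary:
    """Mean, population stddev, min/max ratio and disorder of a sample.

    disorder = sigma / (mu + sigma), 0 when sigma = 0; min/max ratio defined
    as 1 when all values are equal (including all-zero).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("popstats requires a non-empty sample")
    if np.any(v < 0):
        raise ValueError("popstats requires non-negative values")
    mu = float(np.mean(v))
    sigma = float(np.std(v))  # population convention (divide by n)
    vmax = float(np.max(v))
    vmin = float(np.min(v))
    mmr = 1.0 if vmax == vmin else vmin / vmax
    disorder = 0.0 if sigma == 0.0 else sigma / (mu + sigma)
    return PopSummary(mu, sigma, mmr, disorder)


# ---------------------------------------------------------------- graph block

def _require_points(cs: CentroidSet, n_min: int, what: str) -> np.ndarray:
    if cs.n < n_min:
        raise DegenerateGeometryError(
            f"{what} requires >= {n_min} points, section {cs.section_id} has {cs.n}"
        )
    return cs.points


def voronoi_features(cs: CentroidSet) -> dict[str, float]:
    """Area, perimeter and max vertex distance of bounded Voronoi cells.

    Unbounded cells (every hull point has one) are excluded rather than
    clipped, so the statistics describe interior nuclear packing only.
    """
    pts = _require_points(cs, 4, "Voronoi tessellation")
    try:
        vor = Voronoi(pts)
    except QhullError as e:  # collinear or otherwise degenerate
        raise DegenerateGeometryError(f"degenerate point set: {e}") from e
    areas, perims, max_dists = [], [], []
    for region_idx in vor.point_region:
        region = vor.regions[region_idx]
        if len(region) < 3 or -1 in region:
            continue
        verts = vor.vertices[region]
        poly = MultiPoint(verts).convex_hull  # Voronoi cells are convex
        if poly.geom_type != "Polygon":
            continue
        areas.append(poly.area)
        perims.append(poly.length)
        max_dists.append(float(pdist(verts).max()))
    if not areas:
        raise DegenerateGeometryError("all Voronoi cells unbounded")
    out: dict[str, float] = {}
    for base, vals in (("voronoi.area", areas), ("voronoi.perimeter", perims),
                       ("voronoi.max_dist", max_dists)):
        for s, v in zip(STAT_NAMES, popstats(vals).as_tuple()):
            out[f"{base}.{s}"] = v
    return out


def _delaunay_edges(pts: np.ndarray) -> tuple[np.ndarray, Delaunay]:
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise DegenerateGeometryError(f"degenerate point set: {e}") from e
    edges = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            i, j = sorted((simplex[a], simplex[b]))
            edges.add((i, j))
    return np.array(sorted(edges), dtype=int), tri


def delaunay_features(cs: CentroidSet) -> dict[str, float]:
    """Edge-length ("sides", unique edges) and triangle-area statistics."""
    pts = _require_points(cs, 3, "Delaunay triangulation")
    edges, tri = _delaunay_edges(pts)
    sides = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    p = pts[tri.simplices]
    u, v = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    areas = 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    out: dict[str, float] = {}
    for base, vals in (("delaunay.sides", sides), ("delaunay.area", areas)):
        for s, v in zip(STAT_NAMES, popstats(vals).as_tuple()):
            out[f"{base}.{s}"] = v
    return out


def mst_branch_lengths(points: np.ndarray) -> np.ndarray:
    """Euclidean MST edge lengths (n - 1 branches).

    Built on the Delaunay edge graph (the Euclidean MST is a subgraph of the
    Delaunay triangulation); falls back to the complete graph for n < 3 or
    collinear inputs.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    if n < 2:
        raise ValueError("MST requires >= 2 points")
    try:
        if n < 3:
            raise DegenerateGeometryError("too few points for triangulation")
        edges, _ = _delaunay_edges(pts)
        w = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
        graph = csr_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n))
    except DegenerateGeometryError:
        graph = csr_matrix(np.triu(squareform(pdist(pts)), k=1))
    mst = minimum_spanning_tree(graph)
    lengths = np.sort(mst.data)
    if len(lengths) != n - 1:
        raise DegenerateGeometryError("point set yields a disconnected graph")
    return lengths


def mst_features(cs: CentroidSet) -> dict[str, float]:
    lengths = mst_branch_lengths(_require_points(cs, 2, "MST"))
    return {
        f"mst.branches.{s}": v
        for s, v in zip(STAT_NAMES, popstats(lengths).as_tuple())
    }


# -------------------------------------------------------------- density block

def neighbors_within(points: np.ndarray, radius: float) -> np.ndarray:
    """Per-point count of other points within ``radius`` (self excluded)."""
    tree = BallTree(points)
    return tree.query_radius(points, r=radius, count_only=True) - 1


def knn_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Per-point distance to the k-th nearest neighbor (self excluded)."""
    if k >= len(points):
        raise ValueError(f"k={k} requires more than {k} points")
    tree = KDTree(points)
    dist, _ = tree.query(points, k=k + 1)
    return dist[:, k]


def density_features(cs: CentroidSet, cfg: DensityConfig | None = None) -> dict[str, float]:
    """Neighbor-count, k-NN-distance and k-NN-density statistics (27 values)."""
    cfg = cfg or DensityConfig()
    k_max = max(max(cfg.neighbor_counts), cfg.k_density)
    if cs.n <= k_max:
        raise ValueError(
            f"density features need n > {k_max} points, section "
            f"{cs.section_id} has {cs.n}"
        )
    pts = cs.points
    out: dict[str, float] = {}
    for i, r in enumerate(cfg.radii, start=1):
        counts = neighbors_within(pts, r)
        for s, v in zip(STAT_NAMES, popstats(counts).as_tuple()):
            out[f"density.neighbors_in_distance.{i}.{s}"] = v
    for i, k in enumerate(cfg.neighbor_counts, start=1):
        dists = knn_distances(pts, k)
        for s, v in zip(STAT_NAMES, popstats(dists).as_tuple()):
            out[f"density.dist_for_neighbors.{i}.{s}"] = v
    r_k = knn_distances(pts, cfg.k_density)
    rho = cfg.k_density / (np.pi * r_k**2)
    out["density.rho.min"] = float(np.min(rho))
    out["density.rho.median"] = float(np.median(rho))
    out["density.rho.max"] = float(np.max(rho))
    return out


# ------------------------------------------------------------------ assembly

@dataclass
class SpatialFeatureVector:
    """The 52 named spatial features of one section."""

    patient_id: str
    section_id: str
    values: dict[str, float] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        s = pd.Series(self.values)
        s["patient_id"] = self.patient_id
        s["section_id"] = self.section_id
        return s


def extract_spatial_features(
    cs: CentroidSet,
    cfg: DensityConfig | None = None,
    min_nuclei: int = 10,
) -> SpatialFeatureVector:
    """All 52 spatial features of a section: 24 graph + 27 density + count."""
    cfg = cfg or DensityConfig()
    if cs.n < min_nuclei:
        raise SectionExcluded(
            f"section {cs.section_id} has {cs.n} nuclei < min_nuclei={min_nuclei}"
        )
    values: dict[str, float] = {}
    values.update(voronoi_features(cs))
    values.update(delaunay_features(cs))
    values.update(mst_features(cs))
    values.update(density_features(cs, cfg))
    values["count"] = float(cs.n)
    ordered = {name: values[name] for name in feature_names(cfg)}
    return SpatialFeatureVector(cs.patient_id, cs.section_id, ordered)


def extract_features_table(
    centroids: pd.DataFrame,
    cfg: DensityConfig | None = None,
    extent: tuple[float, float] = (750.0, 750.0),
    min_nuclei: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-section feature extraction over a centroid table.

    ``centroids`` columns: patient_id, section_id, x, y. Sections below
    ``min_nuclei`` are excluded and returned in the second element, never
    silently dropped.
    """
    rows, excluded = [], []
    for (pid, sid), grp in centroids.groupby(["patient_id", "section_id"], sort=True):
        cs = CentroidSet(str(pid), str(sid), grp[["x", "y"]].to_numpy(), extent)
        try:
            rows.append(extract_spatial_features(cs, cfg, min_nuclei).as_series())
        except (SectionExcluded, DegenerateGeometryError) as e:
            logger.warning("excluding section %s: %s", sid, e)
            excluded.append(str(sid))
    table = pd.DataFrame(rows).reset_index(drop=True)
    return table, excluded


def univariate_compare(X: pd.DataFrame, labels) -> pd.DataFrame:
    """Two-sided Mann-Whitney U comparison of every feature between groups.

    Returns per-feature statistic, p-value, group medians and a tie flag
    (constant features are reported with p = 1 rather than dropped).
    """
    y = np.asarray(labels).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 sections per group")
    rows = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        a, b = v[y == 1], v[y == 0]
        if np.all(v == v[0]):
            rows.append({"feature": col, "statistic": np.nan, "pvalue": 1.0,
                         "median_pos": float(np.median(a)),
                         "median_neg": float(np.median(b)), "constant": True})
            continue
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"feature": col, "statistic": float(stat), "pvalue": float(p),
                     "median_pos": float(np.median(a)),
                     "median_neg": float(np.median(b)), "constant": False})
    return pd.DataFrame(rows).set_index("feature")
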