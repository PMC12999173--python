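"""Per-cluster and per-sample spatial statistics on segmented point clouds.

The neighbourhood scale of a sample is r = 3 x its mean nearest-neighbour
distance (NND).  "AZ density" of a cluster is the number of clusters within
r of it, spherically, counting itself; "local intensity" is the mean
integrated intensity of the clusters within r, including itself (a mean
filter over the point cloud).  All distances are physical (um) with
anisotropic spacing; no edge correction is applied to boundary clusters (a
known, documented bias shared with the measurement convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .core import ClusterTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpatialParams:
    radius_multiplier: float = 3.0
    log_transform_nn: bool = True
    normalization: str = "per_sample_mean"   # {"per_sample_mean", "none"}

    def __post_init__(self):
        if self.radius_multiplier <= 0:
            raise ValueError("radius_multiplier must be > 0")
        if self.normalization not in ("per_sample_mean", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


class SampleTooSmallError(ValueError):
    """Raised when a sample has too few clusters for a statistic."""


class DegenerateCorrelationError(ValueError):
    """Raised when a Pearson correlation margin has zero variance."""


def _positions(table) -> np.ndarray:
    if isinstance(table, ClusterTable):
        return table.positions
    return np.asarray(table, dtype=float)


def nearest_neighbor_distances(table) -> tuple[np.ndarray, float]:
    """Per-cluster NND (um, self excluded) and the sample mean NND."""
    pts = _positions(table)
    if len(pts) < 2:
        raise SampleTooSmallError(
            f"nearest-neighbour distances need >= 2 clusters, got {len(pts)}")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    nnd = d[:, 1]
    return nnd, float(nnd.mean())


def nearest_neighbor_indices(table) -> np.ndarray:
    pts = _positions(table)
    if len(pts) < 2:
        raise SampleTooSmallError("nearest neighbours need >= 2 clusters")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=2)
    return idx[:, 1]


def neighborhood_radius(mean_nnd: float, params: SpatialParams = SpatialParams()) -> float:
    """r = radius_multiplier x mean NND (default multiplier 3)."""
    return params.radius_multiplier * mean_nnd


def az_density(table, r: float) -> np.ndarray:
    """Number of clusters within r of each cluster, spherically, including
    itself; boundary clusters receive no edge correction."""
    if r <= 0:
        raise ValueError("r must be > 0")
    pts = _positions(table)
    tree = cKDTree(pts)
    return np.array([len(tree.query_ball_point(p, r)) for p in pts], dtype=int)


def local_intensity(table, r: float, intensities=None) -> np.ndarray:
    """Mean integrated intensity over the clusters within r of each cluster
    (including itself)."""
    if r <= 0:
        raise ValueError("r must be > 0")
    pts = _positions(table)
    if intensities is None:
        intensities = table.intensities
    intensities = np.asarray(intensities, dtype=float)
    tree = cKDTree(pts)
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        idx = sorted(tree.query_ball_point(p, r))  # stable summation order
        out[i] = intensities[idx].mean()
    return out


def annotate_spatial(table: ClusterTable,
                     params: SpatialParams = SpatialParams()) -> ClusterTable:
    """Fill nnd_um / az_density / local_intensity columns and the sample's
    mean_nnd and radius_r.  Requires >= 2 clusters."""
    out = table.copy()
    nnd, mean_nnd = nearest_neighbor_distances(out)
    r = neighborhood_radius(mean_nnd, params)
    out.df["nnd_um"] = nnd
    out.df["az_density"] = az_density(out, r)
    out.df["local_intensity"] = local_intensity(out, r)
    out.mean_nnd = mean_nnd
    out.radius_r = r
    return out


# ---------------------------------------------------------------------------
# correlations


def _pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise SampleTooSmallError("Pearson correlation needs >= 3 points")
    if np.std(x) < 1e-300 or np.std(y) < 1e-300:
        raise DegenerateCorrelationError("zero variance in a correlation margin")
    return float(pearsonr(x, y).statistic)


def nn_intensity_correlation(table: ClusterTable,
                             params: SpatialParams = SpatialParams()) -> float:
    """Pearson R between each cluster's (log) intensity and the (log)
    intensity of its nearest neighbour; every cluster contributes one
    ordered pair.  The log transform (natural log; Pearson R is base
    invariant) requires positive intensities."""
    idx = nearest_neighbor_indices(table)
    x = table.intensities
    if params.log_transform_nn:
        if np.any(x <= 0):
            raise ValueError("log transform requires positive intensities")
        x = np.log(x)
    return _pearson(x, x[idx])


def intensity_volume_correlation(table: ClusterTable) -> float:
    """Pearson R of (integrated intensity, volume), untransformed."""
    return _pearson(table.df["intensity"], table.df["volume_vox"])


def density_localintensity_correlation(table: ClusterTable, r: float | None = None,
                                       by_compartment: bool = False):
    """Pearson R between AZ density and local intensity, over all clusters.

    Densities and local intensities are computed sample-wide (neighbourhoods
    ignore compartment boundaries); with ``by_compartment`` the clusters are
    then grouped by compartment label and R is computed per group (groups
    with < 3 clusters or a degenerate margin are reported as missing).
    Returns R, or ``(R, {compartment: R or nan})``.
    """
    df = table.df
    if "az_density" in df.columns and "local_intensity" in df.columns and r is None:
        dens = df["az_density"].to_numpy(dtype=float)
        li = df["local_intensity"].to_numpy(dtype=float)
    else:
        if r is None:
            _, mean_nnd = nearest_neighbor_distances(table)
            r = neighborhood_radius(mean_nnd)
        dens = az_density(table, r).astype(float)
        li = local_intensity(table, r)

    overall = _pearson(li, dens)
    if not by_compartment:
        return overall

    per = {}
    comp = df["compartment"].astype(str).to_numpy()
    for name in sorted(set(comp)):
        if not name:
            continue
        sel = comp == name
        if sel.sum() < 3:
            log.info("compartment %s has %d clusters (<3); R reported missing",
                     name, int(sel.sum()))
            per[name] = float("nan")
            continue
        try:
            per[name] = _pearson(li[sel], dens[sel])
        except DegenerateCorrelationError:
            log.info("compartment %s has a degenerate margin; R reported missing", name)
            per[name] = float("nan")
    return overall, per


def compartment_median_ratios(table: ClusterTable,
                              value_column: str = "intensity") -> dict[str, float]:
    """Per-compartment median intensity expressed as a ratio against the
    mean of the per-compartment medians (empty compartments excluded)."""
    df = table.df
    comp = df["compartment"].astype(str)
    groups = {name: g[value_column].to_numpy(dtype=float)
              for name, g in df.groupby(comp) if name and len(g) > 0}
    if len(groups) < 2:
        raise ValueError("compartment ratios need >= 2 non-empty compartments")
    medians = {name: float(np.median(v)) for name, v in groups.items()}
    denom = float(np.mean(list(medians.values())))
    return {name: m / denom for name, m in medians.items()}


def normalize_to_mean(values) -> np.ndarray:
    """Divide by the sample mean (output mean is exactly 1)."""
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if m <= 0:
        raise ValueError("normalization requires a positive mean")
    return values / m


def sample_report(table: ClusterTable,
                  params: SpatialParams = SpatialParams()) -> dict:
    """Per-sample summary used by the pipeline's JSON report."""
    t = annotate_spatial(table, params)
    report = {
        "sample_id": t.sample_id,
        "condition": t.condition,
        "n_clusters": len(t),
        "mean_nnd_um": t.mean_nnd,
        "radius_r_um": t.radius_r,
    }
    try:
        report["pearson_intensity_volume"] = intensity_volume_correlation(t)
    except (SampleTooSmallError, DegenerateCorrelationError):
        report["pearson_intensity_volume"] = None
    try:
        report["pearson_nn_intensity"] = nn_intensity_correlation(t, params)
    except (SampleTooSmallError, DegenerateCorrelationError, ValueError):
        report["pearson_nn_intensity"] = None
    try:
        overall, per = density_localintensity_correlation(t, by_compartment=True)
        report["pearson_density_localintensity"] = overall
        report["pearson_density_localintensity_by_compartment"] = {
            k: (None if np.isnan(v) else v) for k, v in per.items()}
    except (SampleTooSmallError, DegenerateCorrelationError):
        report["pearson_density_localintensity"] = None
        report["pearson_density_localintensity_by_compartment"] = {}
    return report
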