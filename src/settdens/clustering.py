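"""Group sett records into sett clusters and classify their occupancy.

A social group's territory typically contains several setts (one main sett
plus secondary annex/subsidiary/outlier setts), so density is estimated for
*sett clusters* rather than individual setts.  Two setts belong to the same
cluster when their centroids are within a fixed planar distance (500 m by
default); clusters are the connected components of the resulting graph, i.e.
single-linkage chaining.  Each cluster is classified into one of four
occupancy categories with strict precedence:

MSCR  at least one occupied main sett with reproduction
MSC   else, at least one occupied main sett
SSC   else, all setts secondary and at least one occupied
UNOCCUPIED otherwise
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Occupancy categories in increasing precedence order.
CATEGORIES = ("UNOCCUPIED", "SSC", "MSC", "MSCR")

DEFAULT_THRESHOLD_M = 500.0

_REQUIRED_COLS = ("sett_id", "x_m", "y_m", "sett_type", "occupied", "reproduction")


def _validate_setts(setts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLS if c not in setts.columns]
    if missing:
        raise ValueError(f"sett table missing columns: {missing}")
    if setts["sett_id"].duplicated().any():
        dups = setts.loc[setts["sett_id"].duplicated(), "sett_id"].tolist()
        raise ValueError(f"duplicated sett_id values: {dups}")
    xy = setts[["x_m", "y_m"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite sett coordinates")
    bad = setts["reproduction"].astype(bool) & ~(
        setts["occupied"].astype(bool) & (setts["sett_type"] == "main")
    )
    if bad.any():
        raise ValueError(
            "reproduction flagged on setts that are not occupied main setts: "
            f"{setts.loc[bad, 'sett_id'].tolist()}"
        )
    return setts


def cluster_setts(
    setts: pd.DataFrame, threshold_m: float = DEFAULT_THRESHOLD_M
) -> pd.Series:
    """Assign each sett of one site to a cluster by single-linkage chaining.

    Parameters
    ----------
    setts : DataFrame
        Sett records of a single site with columns ``sett_id, x_m, y_m,
        sett_type, occupied, reproduction`` (``site_id`` optional but must be
        constant).
    threshold_m : float
        Between-centroid distance joining two setts into the same cluster.

    Returns
    -------
    Series of integer cluster indices aligned to ``setts``.  Indices are
    canonical: clusters are numbered 0, 1, ... in order of their smallest
    member ``sett_id``, so the labelling is invariant to input order.
    """
    if threshold_m <= 0 or not np.isfinite(threshold_m):
        raise ValueError(f"threshold_m must be positive, got {threshold_m}")
    if len(setts) == 0:
        return pd.Series([], dtype=int, index=setts.index)
    _validate_setts(setts)
    if "site_id" in setts.columns and setts["site_id"].nunique() > 1:
        raise ValueError("cluster_setts operates on one site at a time")

    xy = setts[["x_m", "y_m"]].to_numpy(dtype=float)
    n = len(xy)
    pairs = cKDTree(xy).query_pairs(r=threshold_m, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)

    # canonical relabelling by smallest member sett_id (as string order)
    ids = setts["sett_id"].astype(str).to_numpy()
    order = sorted(set(labels), key=lambda c: min(ids[labels == c]))
    remap = {c: k for k, c in enumerate(order)}
    return pd.Series([remap[c] for c in labels], index=setts.index, dtype=int)


def classify_cluster(members: pd.DataFrame) -> str:
    """Classify a cluster's occupancy category from its member setts."""
    if len(members) == 0:
        raise ValueError("cannot classify an empty cluster")
    occupied = members["occupied"].astype(bool)
    main = members["sett_type"] == "main"
    repro = members["reproduction"].astype(bool)
    if (occupied & main & repro).any():
        return "MSCR"
    if (occupied & main).any():
        return "MSC"
    if (~main).all() and occupied.any():
        return "SSC"
    return "UNOCCUPIED"


def _detection_distance(members: pd.DataFrame) -> float:
    """Perpendicular distance of the cluster's first-detected member sett.

    Uses the ``first_detected`` flag column when present; otherwise falls
    back to the smallest recorded perpendicular distance (with a warning,
    since that is only a proxy for detection order).
    """
    if "perp_distance_m" not in members.columns:
        return float("nan")
    d = pd.to_numeric(members["perp_distance_m"], errors="coerce")
    if "first_detected" in members.columns:
        flagged = members["first_detected"].fillna(False).astype(bool)
        if flagged.any():
            return float(d[flagged].iloc[0])
    if d.notna().any():
        logger.warning(
            "no first_detected flag; using smallest perpendicular distance as "
            "the cluster detection distance"
        )
        return float(d.min())
    return float("nan")


def build_clusters(
    setts: pd.DataFrame, threshold_m: float = DEFAULT_THRESHOLD_M
) -> pd.DataFrame:
    """Cluster and classify the setts of one or several sites.

    Clusters never span sites.  Returns one row per cluster with columns
    ``cluster_id, site_id, n_setts, category, detection_distance_m, members``
    (members is a ';'-joined list of sett ids).
    """
    if len(setts) == 0:
        return pd.DataFrame(
            columns=[
                "cluster_id",
                "site_id",
                "n_setts",
                "category",
                "detection_distance_m",
                "members",
            ]
        )
    if "site_id" not in setts.columns:
        setts = setts.assign(site_id="site")
    rows = []
    for site, sub in setts.groupby("site_id", sort=True):
        labels = cluster_setts(sub, threshold_m)
        for k in sorted(labels.unique()):
            members = sub.loc[labels == k]
            rows.append(
                {
                    "cluster_id": f"{site}-C{k + 1:03d}",
                    "site_id": site,
                    "n_setts": len(members),
                    "category": classify_cluster(members),
                    "detection_distance_m": _detection_distance(members),
                    "members": ";".join(members["sett_id"].astype(str)),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OccupancyProportions:
    """Per-site occupancy proportions among all sett clusters."""

    site_id: str
    n_clusters: int
    n_SSC: int
    n_MSC: int
    n_MSCR: int

    @property
    def n_unoccupied(self) -> int:
        return self.n_clusters - self.n_SSC - self.n_MSC - self.n_MSCR

    @property
    def p_SSC(self) -> float:
        return self.n_SSC / self.n_clusters

    @property
    def p_MSC(self) -> float:
        return self.n_MSC / self.n_clusters

    @property
    def p_MSCR(self) -> float:
        return self.n_MSCR / self.n_clusters

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_SSC, self.p_MSC, self.p_MSCR)


def occupancy_proportions(clusters: pd.DataFrame) -> OccupancyProportions:
    """Exact occupancy proportions for the clusters of one site."""
    if len(clusters) == 0:
        raise ValueError("no clusters: site unusable for occupancy proportions")
    sites = clusters["site_id"].unique() if "site_id" in clusters.columns else ["site"]
    if len(sites) > 1:
        raise ValueError("occupancy_proportions operates on one site at a time")
    counts = clusters["category"].value_counts()
    return OccupancyProportions(
        site_id=str(sites[0]),
        n_clusters=len(clusters),
        n_SSC=int(counts.get("SSC", 0)),
        n_MSC=int(counts.get("MSC", 0)),
        n_MSCR=int(counts.get("MSCR", 0)),
    )


def occupancy_by_site(clusters: pd.DataFrame) -> pd.DataFrame:
    """Occupancy proportions for every site in a cluster table."""
    rows = []
    for _, sub in clusters.groupby("site_id", sort=True):
        p = occupancy_proportions(sub)
        rows.append(
            {
                "site_id": p.site_id,
                "n_clusters": p.n_clusters,
                "n_SSC": p.n_SSC,
                "n_MSC": p.n_MSC,
                "n_MSCR": p.n_MSCR,
                "p_SSC": p.p_SSC,
                "p_MSC": p.p_MSC,
                "p_MSCR": p.p_MSCR,
            }
        )
    return pd.DataFrame(rows)
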