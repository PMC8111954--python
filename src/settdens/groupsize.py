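"""Social-group size per sett cluster from camera and genetic surveys.

Camera traps give, per surveyed cluster, the maximum number of adults (and
the maximum total, adults plus cubs) seen simultaneously over all nights and
all monitored setts of the cluster — a minimum bound on group size.  Hair
trapping gives the number of distinct multilocus genotypes, a second minimum
bound that cannot separate adults from cubs.  Per cluster the total group
size is the maximum of the two bounds, while the adult count is camera-only.
Per-site category means (SSC / MSC / MSCR) form the group-size table; cells
with no surveyed cluster are imputed with the mean of observed values for
the same category among sites of the same habitat type (forested vs
hedgerow), and imputed cells are flagged and excluded from cross-site
summary means.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OCCUPIED_CATEGORIES = ("SSC", "MSC", "MSCR")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up rounding for reported tables (composition keeps full precision)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(str(round(float(x), ndigits + 6)))
    return float(q.quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP))

SIZE_COLUMNS = ("ad_SSC", "badger_SSC", "ad_MSC", "badger_MSC", "ad_MSCR", "badger_MSCR")
DEFAULT_MAX_MISSING_LOCI = 4


def camera_counts(observations: pd.DataFrame) -> tuple[int, int]:
    """Componentwise maxima of simultaneous counts over a cluster's nights.

    ``observations`` holds one row per camera night (possibly across several
    setts of the cluster) with ``adults_simultaneous`` and
    ``total_simultaneous`` columns.
    """
    if len(observations) == 0:
        raise ValueError("no camera observations for this cluster")
    a = observations["adults_simultaneous"].to_numpy(dtype=int)
    t = observations["total_simultaneous"].to_numpy(dtype=int)
    if np.any(t < a):
        raise ValueError("total_simultaneous below adults_simultaneous")
    return int(a.max()), int(t.max())


# -- genotype matching ------------------------------------------------------

def _parse_genotype(s: str) -> tuple:
    """Parse 'a/b;c/d;-' into a tuple of sorted allele pairs (None = missing)."""
    loci = []
    for token in str(s).split(";"):
        token = token.strip()
        if token in ("-", "-/-", "", "NA"):
            loci.append(None)
        else:
            a, b = token.split("/")
            loci.append(tuple(sorted((a.strip(), b.strip()))))
    return tuple(loci)


def _compatible(g1: tuple, g2: tuple) -> bool:
    """Two genotypes match iff they agree wherever both loci are typed."""
    return all(a == b for a, b in zip(g1, g2) if a is not None and b is not None)


def count_genetic_individuals(
    samples: Iterable[str] | pd.Series | pd.DataFrame,
    max_missing_loci: int = DEFAULT_MAX_MISSING_LOCI,
) -> int:
    """Number of distinct individuals among one cluster's genotyped samples.

    Samples match when they agree at every locus where both are typed and
    each has at most ``max_missing_loci`` untyped loci; matching is closed
    transitively (union of compatible pairs).  Samples exceeding the missing
    threshold are excluded with a warning, and a warning is logged when
    transitive chaining merges samples that are not pairwise compatible.
    """
    if isinstance(samples, pd.DataFrame):
        samples = samples["genotype"]
    genos = [_parse_genotype(s) for s in samples]
    if not genos:
        return 0
    lengths = {len(g) for g in genos}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent locus panel lengths: {sorted(lengths)}")

    kept = []
    for g in genos:
        n_missing = sum(1 for locus in g if locus is None)
        if n_missing > max_missing_loci:
            logger.warning(
                "excluding sample with %d missing loci (> %d)", n_missing, max_missing_loci
            )
        else:
            kept.append(g)
    n = len(kept)
    if n == 0:
        return 0

    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _compatible(kept[i], kept[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    for members in groups.values():
        if any(
            not _compatible(kept[i], kept[j])
            for k, i in enumerate(members)
            for j in members[k + 1:]
        ):
            logger.warning(
                "transitive chaining merged samples that are not pairwise compatible"
            )
    return len(groups)


def cluster_group_size(
    camera: tuple[int, int] | None, genetic: int | None
) -> tuple[float, float]:
    """Merge camera maxima and genetic count into (adults, total badgers).

    Adults come from the camera only (genetics cannot age individuals);
    the total is the maximum of the camera total and the genetic count,
    with an absent method contributing 0 to the maximum.
    """
    if camera is None and genetic is None:
        return float("nan"), float("nan")
    adults = float("nan") if camera is None else float(camera[0])
    cam_total = 0 if camera is None else camera[1]
    total = float(max(cam_total, genetic or 0))
    return adults, total


def site_category_means(per_cluster: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic means of cluster group sizes per (site, category).

    ``per_cluster`` has one row per surveyed occupied cluster with columns
    ``site_id, category, adults, total``.  Returns the wide group-size table
    (one row per site, columns ``ad_*`` / ``badger_*`` plus ``*_imputed``
    flags, all False); cells with no surveyed cluster are NaN.
    """
    sites = sorted(per_cluster["site_id"].unique())
    table = pd.DataFrame(index=pd.Index(sites, name="site_id"),
                         columns=list(SIZE_COLUMNS), dtype=float)
    for (site, cat), sub in per_cluster.groupby(["site_id", "category"]):
        if cat not in OCCUPIED_CATEGORIES:
            continue
        ad = sub["adults"].dropna()
        tot = sub["total"].dropna()
        if len(ad):
            table.loc[site, f"ad_{cat}"] = float(ad.mean())
        if len(tot):
            table.loc[site, f"badger_{cat}"] = float(tot.mean())
    for col in SIZE_COLUMNS:
        table[f"{col}_imputed"] = False
    return table


def impute_missing(table: pd.DataFrame, site_habitat) -> pd.DataFrame:
    """Fill missing group-size cells from same-category, same-habitat sites.

    A missing cell for category c in a site of habitat h becomes the mean of
    the observed (non-imputed) values of the same column among sites of
    habitat h.  Observed cells are never altered; the operation is
    idempotent.  An empty pool raises, naming the category/habitat pool.
    """
    out = table.copy()
    habitat = pd.Series(site_habitat)
    for col in SIZE_COLUMNS:
        flag = f"{col}_imputed"
        if flag not in out.columns:
            out[flag] = False
        for site in out.index:
            if not pd.isna(out.loc[site, col]):
                continue
            h = habitat[site]
            pool_sites = [s for s in out.index
                          if habitat[s] == h and s != site
                          and not out.loc[s, flag] and not pd.isna(table.loc[s, col])]
            if not pool_sites:
                raise ValueError(f"no observed values to impute {col} for {h} sites")
            out.loc[site, col] = float(out.loc[pool_sites, col].mean())
            out.loc[site, flag] = True
    return out


def category_means(table: pd.DataFrame, exclude_imputed: bool = True) -> pd.DataFrame:
    """Cross-site mean and sample SD per group-size column.

    By default imputed cells are excluded, so the summary reflects only
    directly estimated group sizes.
    """
    rows = {}
    for col in SIZE_COLUMNS:
        vals = table[col]
        if exclude_imputed and f"{col}_imputed" in table.columns:
            vals = vals[~table[f"{col}_imputed"].fillna(False).astype(bool)]
        vals = vals.dropna()
        rows[col] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                     "n_sites": int(len(vals))}
    return pd.DataFrame(rows).T


def group_size_table(
    camera: pd.DataFrame,
    genetic: pd.DataFrame,
    clusters: pd.DataFrame,
    max_missing_loci: int = DEFAULT_MAX_MISSING_LOCI,
) -> pd.DataFrame:
    """Per-site group-size table from raw camera and genetic tables.

    ``clusters`` maps cluster_id -> (site_id, category); only occupied
    categories are summarized.  Clusters with neither camera nor genetic
    data are left missing (to be imputed later).
    """
    cam_by_cluster = dict(tuple(camera.groupby("cluster_id"))) if len(camera) else {}
    gen_by_cluster = dict(tuple(genetic.groupby("cluster_id"))) if len(genetic) else {}
    rows = []
    for _, cl in clusters.iterrows():
        if cl["category"] not in OCCUPIED_CATEGORIES:
            continue
        cid = cl["cluster_id"]
        cam = camera_counts(cam_by_cluster[cid]) if cid in cam_by_cluster else None
        gen = (count_genetic_individuals(gen_by_cluster[cid], max_missing_loci)
               if cid in gen_by_cluster else None)
        if cam is None and gen is None:
            continue
        adults, total = cluster_group_size(cam, gen)
        rows.append({"site_id": cl["site_id"], "category": cl["category"],
                     "adults": adults, "total": total})
    if not rows:
        return site_category_means(
            pd.DataFrame(columns=["site_id", "category", "adults", "total"]))
    return site_category_means(pd.DataFrame(rows))
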