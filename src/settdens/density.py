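"""Composite site-level densities from cluster density, occupancy and group size.

Adult density combines the three separately estimated components:

    D_Ad  = D_C * (p_SSC*ad_SSC + p_MSC*ad_MSC + p_MSCR*ad_MSCR)
    D_Bad = D_C * (p_SSC*badger_SSC + p_MSC*badger_MSC + p_MSCR*badger_MSCR)

where D_C is the whole-site sett-cluster density (per km^2), p_* the exact
occupancy proportions and ad_* / badger_* the mean adult / total group sizes
per category.  Proportions are carried as integer count fractions whenever
counts are known: the printed two-decimal proportions can shift composite
densities by up to ~0.02 per km^2, while count fractions are exact.
Uncertainty on the composites propagates only the bootstrap CV of D_C;
occupancy proportions and group sizes are treated as fixed.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

CATEGORIES_OCCUPIED = ("SSC", "MSC", "MSCR")


def _as_proportions(proportions) -> dict[str, float]:
    """Accept {'SSC': p, ...} floats or (counts_tuple, n_clusters) pairs."""
    if isinstance(proportions, dict):
        p = {c: float(proportions.get(c, 0.0)) for c in CATEGORIES_OCCUPIED}
    else:
        counts, n = proportions
        if n <= 0:
            raise ValueError("n_clusters must be positive")
        p = {c: float(Fraction(int(k), int(n)))
             for c, k in zip(CATEGORIES_OCCUPIED, counts)}
    for c, v in p.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"proportion p_{c}={v} outside [0, 1]")
    if sum(p.values()) > 1.0 + 1e-9:
        raise ValueError("occupied proportions sum above 1")
    return p


def composite_density(d_c: float, proportions, group_sizes, mode: str | None = None) -> float:
    """Composite density D = D_C * sum_c p_c * size_c, per km^2.

    ``proportions`` is either a dict keyed by category or a
    ``((n_SSC, n_MSC, n_MSCR), n_clusters)`` pair of exact counts.
    ``group_sizes`` maps category to mean size; alternatively pass a row
    with ``ad_*`` / ``badger_*`` fields together with ``mode='adults'`` or
    ``mode='total'``.
    """
    p = _as_proportions(proportions)
    if mode is not None:
        prefix = {"adults": "ad", "total": "badger"}.get(mode)
        if prefix is None:
            raise ValueError(f"mode must be 'adults' or 'total', got '{mode}'")
        group_sizes = {c: group_sizes[f"{prefix}_{c}"] for c in CATEGORIES_OCCUPIED}
    acc = 0.0
    for c in CATEGORIES_OCCUPIED:
        if p[c] == 0.0:
            continue
        size = group_sizes.get(c)
        if size is None or (isinstance(size, float) and np.isnan(size)):
            raise ValueError(f"missing group size for category {c} with p_{c}={p[c]:.3f}")
        if size < 0:
            raise ValueError(f"negative group size for category {c}")
        acc += p[c] * float(size)
    return float(d_c) * acc


def occupied_main_density(d_c: float, p_msc, p_mscr, n_clusters: int | None = None) -> float:
    """Density of occupied main clusters, D_C * (p_MSC + p_MSCR).

    Roughly the density of breeding-capable family groups.  Pass counts with
    ``n_clusters`` to use exact fractions.
    """
    if n_clusters is not None:
        p_msc = Fraction(int(p_msc), int(n_clusters))
        p_mscr = Fraction(int(p_mscr), int(n_clusters))
    tot = float(p_msc) + float(p_mscr)
    if not (0.0 <= tot <= 1.0 + 1e-9):
        raise ValueError("occupied-main proportion outside [0, 1]")
    return float(d_c) * tot


def site_density_table(
    cluster_density: pd.DataFrame,
    occupancy: pd.DataFrame,
    group_sizes: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-site density table from the three component tables.

    ``cluster_density``: site_id, D_C (and optionally D_C_distance, cv,
    ci_low, ci_high); ``occupancy``: site_id, n_clusters, n_SSC, n_MSC,
    n_MSCR; ``group_sizes``: wide table indexed by site_id with ad_* and
    badger_* columns (imputation already applied).  Composite uncertainties
    reuse the bootstrap CV of D_C (components treated as fixed).
    """
    occ = occupancy.set_index("site_id")
    dens = cluster_density.set_index("site_id")
    rows = []
    for site in dens.index:
        o = occ.loc[site]
        gs = group_sizes.loc[site]
        counts = ((int(o["n_SSC"]), int(o["n_MSC"]), int(o["n_MSCR"])),
                  int(o["n_clusters"]))
        d_c = float(dens.loc[site, "D_C"])
        d_ad = composite_density(d_c, counts, gs, mode="adults")
        d_bad = composite_density(d_c, counts, gs, mode="total")
        row = {
            "site_id": site,
            "D_C": d_c,
            "p_SSC": counts[0][0] / counts[1],
            "p_MSC": counts[0][1] / counts[1],
            "p_MSCR": counts[0][2] / counts[1],
            "D_Ad": d_ad,
            "D_Bad": d_bad,
            "D_occupied_main": occupied_main_density(
                d_c, counts[0][1], counts[0][2], n_clusters=counts[1]),
        }
        for col in ("D_C_distance", "cv", "ci_low", "ci_high"):
            if col in dens.columns:
                row[col] = float(dens.loc[site, col])
        for col in gs.index:
            if col.startswith(("ad_", "badger_")):
                row[col] = gs[col]
        if "cv" in dens.columns:
            cv = float(dens.loc[site, "cv"])
            row["D_Ad_sd"] = d_ad * cv
            row["D_Bad_sd"] = d_bad * cv
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_sites(densities: pd.DataFrame, metrics=("D_Ad", "D_Bad", "D_occupied_main")) -> pd.DataFrame:
    """Cross-site mean, sample SD and min/max (with site labels) per metric.

    SD uses the n-1 denominator; ties on min/max resolve to the smallest
    site label.
    """
    if len(densities) < 2:
        raise ValueError("need at least 2 sites to summarize")
    d = densities.set_index("site_id") if "site_id" in densities.columns else densities
    out = {}
    for m in metrics:
        vals = d[m].astype(float)
        vmin, vmax = vals.min(), vals.max()
        out[m] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "min": float(vmin),
            "argmin": sorted(vals.index[vals == vmin])[0],
            "max": float(vmax),
            "argmax": sorted(vals.index[vals == vmax])[0],
        }
    return pd.DataFrame(out).T
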