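"""Published site-level summary tables from the 13-site French badger survey.

These are the printed per-site summaries of the nationwide badger survey the
package's composite estimator was developed for: sett and cluster counts
with occupancy-category counts, distance-sampling cluster densities with
bootstrap uncertainty, and camera/genetic group sizes.  Category counts are
stored as exact integers (recovered from the published proportions and
cluster totals; they reproduce the pooled totals of 57 SSC, 82 MSC and 38
MSCR among 273 clusters).  Group-size cells that the survey could not
estimate directly (no individuals captured in that category at that site)
are stored as missing and are meant to be filled with
:func:`settdens.groupsize.impute_missing`.

Sites A, B, D and H are forest-dominated ("forested"); the rest are
hedgerow-dominated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SITES = tuple("ABCDEFGHIJKLM")

#: habitat type of the whole study site (the SIT covariate)
SITE_HABITAT = {s: ("forested" if s in "ABDH" else "hedgerow") for s in SITES}

# site: (n_setts_detected, n_clusters, n_SSC, n_MSC, n_MSCR)
_CLUSTER_COUNTS = {
    "A": (78, 24, 3, 3, 3),
    "B": (40, 23, 3, 6, 5),
    "C": (35, 21, 2, 3, 7),
    "D": (66, 29, 15, 5, 4),
    "E": (35, 18, 1, 7, 3),
    "F": (36, 22, 7, 5, 1),
    "G": (38, 18, 4, 3, 3),
    "H": (46, 26, 10, 7, 2),
    "I": (29, 15, 1, 7, 4),
    "J": (21, 16, 1, 4, 1),
    "K": (68, 34, 7, 14, 5),
    "L": (11, 11, 1, 9, 0),
    "M": (30, 16, 2, 9, 0),
}

# site: (D_C_distance, D_C, ci_low, ci_high, cv)  [clusters / km^2; CI on D_C]
_CLUSTER_DENSITY = {
    "A": (6.95, 5.39, 3.08, 8.64, 0.2701),
    "B": (6.62, 5.50, 3.11, 9.32, 0.2801),
    "C": (12.80, 3.55, 2.19, 5.24, 0.2171),
    "D": (6.21, 5.17, 2.96, 8.54, 0.2707),
    "E": (10.39, 3.17, 1.84, 4.85, 0.2444),
    "F": (11.30, 4.75, 2.96, 7.09, 0.2385),
    "G": (10.62, 2.29, 1.28, 3.52, 0.2508),
    "H": (7.80, 6.42, 3.75, 10.63, 0.2772),
    "I": (9.42, 2.62, 1.30, 4.36, 0.2944),
    "J": (8.80, 3.59, 2.09, 5.45, 0.2468),
    "K": (18.31, 3.79, 1.95, 6.04, 0.2880),
    "L": (6.70, 1.99, 0.67, 3.78, 0.3954),
    "M": (8.21, 4.11, 2.26, 6.49, 0.2598),
}

# site: (ad_SSC, badger_SSC, ad_MSC, badger_MSC, ad_MSCR, badger_MSCR)
# NaN marks cells with no direct estimate (filled by habitat-type imputation)
_NA = float("nan")
_GROUP_SIZES = {
    "A": (1.00, 1.00, 1.50, 2.25, 3.00, 5.43),
    "B": (1.00, 2.00, 1.75, 3.50, 2.29, 5.71),
    "C": (2.00, 3.50, 1.40, 1.60, 2.00, 4.30),
    "D": (1.60, 2.00, 2.25, 2.50, 2.20, 5.20),
    "E": (_NA, _NA, 1.13, 1.13, 1.75, 4.50),
    "F": (1.33, 1.33, 1.25, 1.25, 2.00, 4.00),
    "G": (1.50, 2.00, 1.00, 1.00, 1.67, 2.67),
    "H": (1.00, 1.00, 1.00, 1.00, 1.50, 4.00),
    "I": (_NA, _NA, 1.50, 1.50, 2.00, 5.17),
    "J": (1.00, 1.00, 1.25, 1.75, 1.40, 3.40),
    "K": (2.00, 2.00, 1.29, 1.29, 1.60, 3.40),
    "L": (_NA, _NA, 1.00, 1.29, 2.00, 5.75),
    "M": (1.00, 1.00, 1.56, 2.11, _NA, _NA),
}


def site_cluster_counts() -> pd.DataFrame:
    """Per-site sett and cluster counts with exact category counts."""
    rows = []
    for s in SITES:
        n_setts, n_cl, ssc, msc, mscr = _CLUSTER_COUNTS[s]
        rows.append({
            "site_id": s, "site_habitat": SITE_HABITAT[s],
            "n_setts_detected": n_setts, "n_clusters": n_cl,
            "n_SSC": ssc, "n_MSC": msc, "n_MSCR": mscr,
            "n_unoccupied": n_cl - ssc - msc - mscr,
            "p_SSC": ssc / n_cl, "p_MSC": msc / n_cl, "p_MSCR": mscr / n_cl,
        })
    return pd.DataFrame(rows)


def sett_cluster_density() -> pd.DataFrame:
    """Per-site distance-sampling cluster densities with bootstrap CI/CV."""
    rows = []
    for s in SITES:
        dcd, dc, lo, hi, cv = _CLUSTER_DENSITY[s]
        rows.append({"site_id": s, "D_C_distance": dcd, "D_C": dc,
                     "ci_low": lo, "ci_high": hi, "cv": cv})
    return pd.DataFrame(rows)


def observed_group_sizes() -> pd.DataFrame:
    """Wide per-site group-size table with NaN where no direct estimate exists.

    Columns match :data:`settdens.groupsize.SIZE_COLUMNS`, plus all-False
    ``*_imputed`` flags, ready for ``impute_missing``.
    """
    cols = ["ad_SSC", "badger_SSC", "ad_MSC", "badger_MSC", "ad_MSCR", "badger_MSCR"]
    table = pd.DataFrame.from_dict(_GROUP_SIZES, orient="index", columns=cols)
    table.index.name = "site_id"
    table = table.astype(float)
    for c in cols:
        table[f"{c}_imputed"] = False
    return table


def site_habitat() -> pd.Series:
    """Whole-site habitat type (forested / hedgerow) per site."""
    return pd.Series(SITE_HABITAT, name="site_habitat")
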