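"""Synthetic study sites with known ground truth.

The generator emulates the statistical structure the composite estimator
assumes: sett clusters placed as a parent-offspring (Thomas-like) point
process restricted to a suitable-habitat mask; occupancy categories drawn
per cluster; a gridded walked-transect survey (theoretical points spaced
1 km apart, 1-2 km transects) with distance-dependent sett detection; and
per-individual camera-night and hair-trap (genetic) capture over each
surveyed cluster's roster.  Every draw flows through one seeded generator
stream, so identical configurations give byte-identical tables.

Geometry is deliberately schematic — a square site with a binary
suitable-habitat mask built from random axis-aligned patches — because only
the suitable-habitat fraction enters the estimator.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from settdens.clustering import DEFAULT_THRESHOLD_M
from settdens.distsamp.keys import key_value

_CELL_M = 100.0  # habitat-mask resolution


class ConfigurationError(ValueError):
    """Invalid synthetic-site configuration; the message names the field."""


def _check(cond: bool, name: str, msg: str):
    if not cond:
        raise ConfigurationError(f"{name}: {msg}")


@dataclass
class SiteConfig:
    """Configuration of one synthetic study site.

    Defaults describe a hedgerow-dominated ~50 km^2 site surveyed on a 1-km
    transect grid, with hazard-rate sett detectability and moderate
    camera/hair capture rates.
    """

    site_id: str = "S1"
    area_km2: float = 50.0
    suitable_fraction: float = 0.35
    site_habitat: str = "hedgerow"  # or "forested"
    cluster_intensity: float = 10.0  # sett clusters per km^2 of suitable habitat
    setts_per_cluster: float = 2.0  # mean; sizes are 1 + Poisson(mean - 1)
    cluster_spread_m: float = 150.0
    # probabilities over (UNOCCUPIED, SSC, MSC, MSCR)
    category_probs: tuple = (0.352, 0.209, 0.300, 0.139)
    # mean adults per occupied category; mean cubs for reproducing clusters
    group_size_params: dict = field(default_factory=lambda: {
        "ad_SSC": 1.34, "ad_MSC": 1.37, "ad_MSCR": 1.95, "cubs_MSCR": 2.51,
    })
    detection: dict = field(default_factory=lambda: {
        "key": "hazard_rate", "sigma": 15.0, "b": 2.5,
    })
    transect_spacing_m: float = 1000.0
    transect_length_km: tuple = (1.0, 2.0)
    camera_detect_prob: float = 0.4
    genetic_detect_prob: float = 0.6
    n_camera_nights: int = 14
    n_loci: int = 24
    genotype_missing_rate: float = 0.03
    seed: int = 0

    def validate(self) -> "SiteConfig":
        f = math.isfinite
        _check(f(self.area_km2) and self.area_km2 > 0, "area_km2", "must be positive")
        _check(f(self.suitable_fraction) and 0 < self.suitable_fraction <= 1,
               "suitable_fraction", "must be in (0, 1]")
        _check(self.site_habitat in ("forested", "hedgerow"), "site_habitat",
               "must be 'forested' or 'hedgerow'")
        _check(f(self.cluster_intensity) and self.cluster_intensity >= 0,
               "cluster_intensity", "must be nonnegative")
        _check(f(self.setts_per_cluster) and self.setts_per_cluster >= 1,
               "setts_per_cluster", "mean must be >= 1")
        _check(f(self.cluster_spread_m) and 0 < self.cluster_spread_m < DEFAULT_THRESHOLD_M / 2,
               "cluster_spread_m",
               f"must be in (0, {DEFAULT_THRESHOLD_M / 2}) so true clusters are recoverable")
        p = np.asarray(self.category_probs, dtype=float)
        _check(p.size == 4 and np.all(p >= 0) and abs(p.sum() - 1.0) <= 1e-9,
               "category_probs", "must be 4 nonnegative probabilities summing to 1")
        _check(self.detection.get("key") in ("uniform", "half_normal", "hazard_rate"),
               "detection", "key must be uniform, half_normal or hazard_rate")
        if self.detection["key"] != "uniform":
            _check(f(self.detection.get("sigma", np.nan)) and self.detection["sigma"] > 0,
                   "detection", "sigma must be positive")
        if self.detection["key"] == "hazard_rate":
            _check(f(self.detection.get("b", np.nan)) and self.detection["b"] > 1,
                   "detection", "hazard-rate b must be > 1")
        _check(f(self.transect_spacing_m) and self.transect_spacing_m > 0,
               "transect_spacing_m", "must be positive")
        lo, hi = self.transect_length_km
        _check(f(lo) and f(hi) and 0 < lo <= hi, "transect_length_km",
               "must be a positive (low, high) range")
        for name in ("camera_detect_prob", "genetic_detect_prob", "genotype_missing_rate"):
            v = getattr(self, name)
            _check(f(v) and 0 <= v <= 1, name, "must be in [0, 1]")
        _check(int(self.n_camera_nights) >= 1, "n_camera_nights", "must be >= 1")
        _check(int(self.n_loci) >= 1, "n_loci", "must be >= 1")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "SiteConfig":
        cfg = cls(**d)
        for name in ("category_probs", "transect_length_km"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "SiteConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated site, for parameter-recovery tests."""

    site_id: str
    n_clusters: int
    suitable_fraction: float  # realized mask fraction
    area_km2: float
    true_cluster_density_per_km2: float  # clusters per km^2 of suitable habitat
    category_counts: dict  # category -> count
    true_category_props: tuple  # (p_SSC, p_MSC, p_MSCR)
    true_group_sizes: dict  # category -> realized mean adults / total
    member_map: dict  # sett_id -> true cluster id
    cluster_parents: dict  # cluster id -> [x_m, y_m] of the parent point
    individual_roster: dict  # cluster id -> list of {id, age}

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["true_category_props"] = tuple(d["true_category_props"])
        return cls(**d)


def _habitat_mask(rng, n_cells: int, fraction: float) -> np.ndarray:
    """Binary mask from random axis-aligned patches, hitting ``fraction`` exactly
    (to cell resolution)."""
    if fraction >= 1.0:
        return np.ones((n_cells, n_cells), dtype=bool)
    target = int(round(fraction * n_cells * n_cells))
    mask = np.zeros((n_cells, n_cells), dtype=bool)
    while mask.sum() < target:
        h = int(rng.integers(3, 13))
        w_ = int(rng.integers(3, 13))
        i = int(rng.integers(0, max(1, n_cells - h + 1)))
        j = int(rng.integers(0, max(1, n_cells - w_ + 1)))
        mask[i:i + h, j:j + w_] = True
    extra = int(mask.sum()) - target
    if extra > 0:
        on = np.flatnonzero(mask.ravel())
        off = rng.choice(on, size=extra, replace=False)
        mask.ravel()[off] = False
    return mask


def _transect_habitat(rng, site_habitat: str) -> str:
    probs = {"forested": ([0.7, 0.2, 0.1]), "hedgerow": ([0.1, 0.2, 0.7])}[site_habitat]
    return str(rng.choice(["forest", "forest_edge", "hedgerow"], p=probs))


def _lay_transects(rng, cfg: SiteConfig, mask: np.ndarray, side_m: float) -> pd.DataFrame:
    """Vertical transects near the theoretical survey grid points.

    Each 1-km grid point is moved to the nearest suitable habitat cell (as
    field transects are placed in close vicinity to their theoretical point
    but inside suitable habitat), then trimmed to the contiguous suitable
    run of cells containing it."""
    from scipy.spatial import cKDTree

    n_cells = mask.shape[0]
    on_cells = np.argwhere(mask)
    if len(on_cells) == 0:
        return pd.DataFrame(columns=["transect_id", "site_id", "x_m", "y0_m", "y1_m",
                                     "length_km", "habitat", "site_habitat"])
    tree = cKDTree((on_cells + 0.5) * _CELL_M)  # cell centres as (y, x)
    spacing = cfg.transect_spacing_m
    coords = np.arange(spacing / 2.0, side_m, spacing)
    rows = []
    k = 0
    for gx in coords:
        for gy in coords:
            ci, cj = min(int(gy // _CELL_M), n_cells - 1), min(int(gx // _CELL_M), n_cells - 1)
            if not mask[ci, cj]:
                _, idx = tree.query([gy, gx])
                ci, cj = on_cells[idx]
                gx = (cj + 0.5) * _CELL_M
                gy = (ci + 0.5) * _CELL_M
            length_m = rng.uniform(*cfg.transect_length_km) * 1000.0
            # planned transects may exceed the grid spacing; clip to the grid
            # cell so survey effort never overlaps between neighbouring points
            half = min(length_m, spacing) / 2.0
            y0, y1 = gy - half, gy + half
            # trim to the contiguous run of suitable cells in this column
            lo = ci
            while lo > 0 and mask[lo - 1, cj]:
                lo -= 1
            hi = ci
            while hi < n_cells - 1 and mask[hi + 1, cj]:
                hi += 1
            y0 = max(y0, lo * _CELL_M, 0.0)
            y1 = min(y1, (hi + 1) * _CELL_M, side_m)
            if y1 <= y0:
                continue
            k += 1
            rows.append({
                "transect_id": f"{cfg.site_id}-W{k:03d}",
                "site_id": cfg.site_id,
                "x_m": float(gx), "y0_m": float(y0), "y1_m": float(y1),
                "length_km": (y1 - y0) / 1000.0,
                "habitat": _transect_habitat(rng, cfg.site_habitat),
                "site_habitat": cfg.site_habitat,
            })
    return pd.DataFrame(rows)


def _perp_distances(xy: np.ndarray, transects: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each point to its nearest transect segment (and which)."""
    if len(transects) == 0 or len(xy) == 0:
        return np.full(len(xy), np.inf), np.full(len(xy), -1)
    tx = transects["x_m"].to_numpy()
    y0 = transects["y0_m"].to_numpy()
    y1 = transects["y1_m"].to_numpy()
    dx = np.abs(xy[:, 0:1] - tx[None, :])
    y = xy[:, 1:2]
    dy = np.where(y < y0[None, :], y0[None, :] - y,
                  np.where(y > y1[None, :], y - y1[None, :], 0.0))
    d = np.hypot(dx, dy)
    idx = d.argmin(axis=1)
    return d[np.arange(len(xy)), idx], idx


_CATEGORIES = ("UNOCCUPIED", "SSC", "MSC", "MSCR")


def generate_site(config: SiteConfig):
    """Generate one synthetic site.

    Returns ``(setts, transects, camera, genetic, truth)``.  The sett table
    contains *all* generated setts with a ``detected`` flag; the distance
    sampling stages use the detected subset.  Camera and genetic tables are
    keyed by the true cluster id (clusters recovered by the clustering stage
    coincide with true clusters whenever the cluster spread is well below
    the clustering threshold).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    side_m = math.sqrt(cfg.area_km2) * 1000.0
    n_cells = max(1, int(round(side_m / _CELL_M)))
    mask = _habitat_mask(rng, n_cells, cfg.suitable_fraction)
    frac = float(mask.sum()) / mask.size
    suitable_km2 = cfg.area_km2 * frac

    # --- cluster parents on suitable habitat ------------------------------
    n_clusters = int(rng.poisson(cfg.cluster_intensity * suitable_km2))
    on_cells = np.argwhere(mask)
    if n_clusters > 0 and len(on_cells):
        pick = on_cells[rng.integers(0, len(on_cells), size=n_clusters)]
        offs = rng.uniform(0.0, _CELL_M, size=(n_clusters, 2))
        parents = np.column_stack([pick[:, 1] * _CELL_M + offs[:, 0],
                                   pick[:, 0] * _CELL_M + offs[:, 1]])
    else:
        n_clusters = 0
        parents = np.empty((0, 2))

    categories = [
        _CATEGORIES[i]
        for i in rng.choice(4, size=n_clusters, p=np.asarray(cfg.category_probs))
    ]
    cluster_ids = [f"{cfg.site_id}-T{i + 1:03d}" for i in range(n_clusters)]

    # --- member setts (uniform within a disc of radius cluster_spread_m) ---
    sett_rows = []
    member_map = {}
    s_idx = 0
    for i in range(n_clusters):
        n_setts = 1 + int(rng.poisson(cfg.setts_per_cluster - 1.0))
        r = cfg.cluster_spread_m * np.sqrt(rng.uniform(size=n_setts))
        th = rng.uniform(0.0, 2.0 * np.pi, size=n_setts)
        pos = parents[i] + np.column_stack([r * np.cos(th), r * np.sin(th)])
        pos = np.clip(pos, 0.0, side_m)  # clipping never increases parent distance
        cat = categories[i]
        for j in range(n_setts):
            s_idx += 1
            sid = f"{cfg.site_id}-S{s_idx:04d}"
            member_map[sid] = cluster_ids[i]
            if cat in ("MSC", "MSCR") and j == 0:
                sett_type, occupied, repro = "main", True, cat == "MSCR"
            elif cat == "SSC":
                sett_type, occupied, repro = "secondary", j == 0 or bool(rng.uniform() < 0.5), False
            elif cat == "UNOCCUPIED":
                sett_type = "main" if rng.uniform() < 0.2 else "secondary"
                occupied, repro = False, False
            else:  # extra setts of main clusters
                sett_type = "secondary"
                occupied, repro = bool(rng.uniform() < 0.5), False
            sett_rows.append({
                "sett_id": sid, "site_id": cfg.site_id,
                "x_m": float(pos[j, 0]), "y_m": float(pos[j, 1]),
                "sett_type": sett_type, "occupied": occupied, "reproduction": repro,
            })
    setts = pd.DataFrame(sett_rows, columns=[
        "sett_id", "site_id", "x_m", "y_m", "sett_type", "occupied", "reproduction"])

    # --- rosters ------------------------------------------------------------
    gp = cfg.group_size_params
    roster = {}
    group_sizes = {}
    for i, cat in enumerate(categories):
        if cat == "UNOCCUPIED":
            continue
        adults = 1 + int(rng.poisson(gp[f"ad_{cat}"] - 1.0))
        cubs = int(rng.poisson(gp["cubs_MSCR"])) if cat == "MSCR" else 0
        roster[cluster_ids[i]] = (
            [{"id": f"{cluster_ids[i]}-A{k + 1}", "age": "adult"} for k in range(adults)]
            + [{"id": f"{cluster_ids[i]}-C{k + 1}", "age": "cub"} for k in range(cubs)]
        )
    for cat in ("SSC", "MSC", "MSCR"):
        idx = [i for i, c in enumerate(categories) if c == cat]
        if idx:
            ads = [sum(1 for m in roster[cluster_ids[i]] if m["age"] == "adult") for i in idx]
            tot = [len(roster[cluster_ids[i]]) for i in idx]
            group_sizes[cat] = {"adults": float(np.mean(ads)), "total": float(np.mean(tot))}

    # --- transect survey and detection --------------------------------------
    transects = _lay_transects(rng, cfg, mask, side_m)
    xy = setts[["x_m", "y_m"]].to_numpy() if len(setts) else np.empty((0, 2))
    dist, nearest = _perp_distances(xy, transects)
    det = cfg.detection
    finite = np.isfinite(dist)
    g = np.zeros(len(setts))
    if finite.any():
        g[finite] = key_value(det["key"], dist[finite],
                              sigma=det.get("sigma"), b=det.get("b"))
    detected = rng.uniform(size=len(setts)) < g
    setts["perp_distance_m"] = np.where(detected, dist, np.nan)
    setts["detected"] = detected
    setts["transect_id"] = [
        transects["transect_id"].iloc[k] if detected[i] and k >= 0 else ""
        for i, k in enumerate(nearest)
    ]
    # first-detected member of each true cluster = its smallest detected distance
    setts["first_detected"] = False
    det_setts = setts.loc[detected]
    if len(det_setts):
        tcl = det_setts["sett_id"].map(member_map)
        first = det_setts.assign(_c=tcl).groupby("_c")["perp_distance_m"].idxmin()
        setts.loc[first.to_numpy(), "first_detected"] = True

    # --- camera survey -------------------------------------------------------
    detected_clusters = {member_map[s] for s in setts.loc[detected, "sett_id"]}
    surveyed = [cid for cid in cluster_ids if cid in roster and cid in detected_clusters]
    cam_rows = []
    if cfg.camera_detect_prob > 0:
        for cid in surveyed:
            n_ad = sum(1 for m in roster[cid] if m["age"] == "adult")
            n_cub = len(roster[cid]) - n_ad
            for night in range(1, int(cfg.n_camera_nights) + 1):
                a = int(rng.binomial(n_ad, cfg.camera_detect_prob))
                c = int(rng.binomial(n_cub, cfg.camera_detect_prob)) if n_cub else 0
                if a + c > 0:
                    cam_rows.append({"cluster_id": cid, "night": night,
                                     "adults_simultaneous": a,
                                     "total_simultaneous": a + c})
    camera = pd.DataFrame(cam_rows, columns=[
        "cluster_id", "night", "adults_simultaneous", "total_simultaneous"])

    # --- hair-trap genetic survey -------------------------------------------
    allele_counts = rng.integers(4, 9, size=int(cfg.n_loci))
    freqs = [rng.dirichlet(np.ones(k)) for k in allele_counts]
    gen_rows = []
    if cfg.genetic_detect_prob > 0:
        for cid in surveyed:
            for member in roster[cid]:
                if rng.uniform() >= cfg.genetic_detect_prob:
                    continue
                geno = [
                    "/".join(str(a) for a in sorted(rng.choice(k, size=2, p=f)))
                    for k, f in zip(allele_counts, freqs)
                ]
                sex = str(rng.choice(["M", "F"]))
                n_samples = 1 + int(rng.poisson(0.4))
                for s in range(1, n_samples + 1):
                    miss = rng.uniform(size=int(cfg.n_loci)) < cfg.genotype_missing_rate
                    tokens = ["-" if m else t for t, m in zip(geno, miss)]
                    gen_rows.append({"cluster_id": cid,
                                     "sample_id": f"{member['id']}-h{s}",
                                     "genotype": ";".join(tokens), "sex": sex})
    genetic = pd.DataFrame(gen_rows, columns=["cluster_id", "sample_id", "genotype", "sex"])

    cat_counts = {c: categories.count(c) for c in _CATEGORIES}
    props = (
        (cat_counts["SSC"] / n_clusters, cat_counts["MSC"] / n_clusters,
         cat_counts["MSCR"] / n_clusters) if n_clusters else (0.0, 0.0, 0.0)
    )
    truth = SyntheticTruth(
        site_id=cfg.site_id,
        n_clusters=n_clusters,
        suitable_fraction=frac,
        area_km2=cfg.area_km2,
        true_cluster_density_per_km2=(n_clusters / suitable_km2 if suitable_km2 else 0.0),
        category_counts=cat_counts,
        true_category_props=props,
        true_group_sizes=group_sizes,
        member_map=member_map,
        cluster_parents={cid: [float(p[0]), float(p[1])]
                         for cid, p in zip(cluster_ids, parents)},
        individual_roster=roster,
    )
    return setts, transects, camera, genetic, truth


def write_site(outdir, setts, transects, camera, genetic, truth: SyntheticTruth):
    """Write the four CSV tables plus the ground-truth JSON sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    setts.to_csv(out / "setts.csv", index=False)
    transects.to_csv(out / "transects.csv", index=False)
    camera.to_csv(out / "camera.csv", index=False)
    genetic.to_csv(out / "genetic.csv", index=False)
    truth.to_json(out / "truth.json")
    return out
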