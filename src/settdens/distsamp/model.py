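"""Maximum-likelihood fitting of line-transect detection functions.

The model follows the statsmodels convention: :class:`DetectionFunction` is
built from data and configuration, and :meth:`DetectionFunction.fit` returns
a :class:`DetectionFunctionResults` carrying estimates, likelihood-based
standard errors, AIC/AICc, effective strip width and goodness of fit.

For perpendicular distances x_1..x_n truncated at w, the conditional
likelihood is  prod_i g(x_i) / integral_0^w g(u) du,  maximized over the key
scale (sigma), hazard-rate shape (b > 1), series-adjustment coefficients and,
for multiple-covariates distance sampling (MCDS), a log-linear model on the
scale, sigma_i = exp(beta0 + beta . z_i) with treatment-coded categorical
covariates.  Conventional distance sampling (CDS) post-stratification fits a
separate detection function per stratum; the combined AIC is the sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.stats import chi2 as chi2_dist
from statsmodels.tools.numdiff import approx_hess1

from settdens.distsamp.keys import (
    KEYS,
    detection_g,
    g_unnormalized,
    integrate_g,
    key_value,
)

DEFAULT_TRUNCATION_M = 55.0
_BIG = 1e10


@dataclass
class DetectionDataset:
    """Truncated perpendicular-distance observations for detection fitting.

    ``observations`` holds one row per detected cluster with a ``distance_m``
    column plus any covariate / transect columns; ``w`` is the truncation
    distance and ``removed_fraction`` the share of raw observations dropped
    by right truncation.
    """

    observations: pd.DataFrame
    w: float
    removed_fraction: float = 0.0

    def __post_init__(self):
        d = self.distances
        if np.any(d < 0):
            raise ValueError("negative perpendicular distances")
        if np.any(d > self.w + 1e-9):
            raise ValueError("retained distances exceed the truncation distance w")

    @property
    def distances(self) -> np.ndarray:
        return self.observations["distance_m"].to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.observations)


def truncate(observations, mode: str = "fixed_w", value: float = DEFAULT_TRUNCATION_M) -> DetectionDataset:
    """Right-truncate distance observations.

    ``mode='fixed_w'`` keeps distances <= value and sets w = value;
    ``mode='percent'`` removes the largest ``value`` fraction of
    observations (rounded to a whole count) and sets w to the largest
    retained distance.
    """
    if isinstance(observations, DetectionDataset):
        observations = observations.observations
    if not isinstance(observations, pd.DataFrame):
        observations = pd.DataFrame({"distance_m": np.asarray(observations, dtype=float)})
    d = observations["distance_m"].to_numpy(dtype=float)
    if np.any(d < 0) or not np.isfinite(d).all():
        raise ValueError("distances must be finite and nonnegative")
    n = len(d)
    if value <= 0:
        raise ValueError(f"truncation value must be positive, got {value}")
    if mode == "fixed_w":
        keep = d <= value
        w = float(value)
    elif mode == "percent":
        if value >= 1:
            raise ValueError(f"percent truncation must be < 1, got {value}")
        n_remove = int(round(value * n))
        cutoff_idx = np.argsort(d, kind="stable")[: n - n_remove]
        keep = np.zeros(n, dtype=bool)
        keep[cutoff_idx] = True
        w = float(d[keep].max()) if keep.any() else 0.0
    else:
        raise ValueError(f"unknown truncation mode '{mode}'")
    kept = observations.loc[keep].reset_index(drop=True)
    return DetectionDataset(observations=kept, w=w, removed_fraction=1.0 - keep.mean() if n else 0.0)


def _as_dataset(data, w=None) -> DetectionDataset:
    if isinstance(data, DetectionDataset):
        return data
    if w is None:
        raise ValueError("w (truncation distance) required when passing raw distances")
    if isinstance(data, pd.DataFrame):
        return DetectionDataset(observations=data.reset_index(drop=True), w=float(w))
    return DetectionDataset(
        observations=pd.DataFrame({"distance_m": np.asarray(data, dtype=float)}), w=float(w)
    )


class DetectionFunction:
    """Line-transect detection-function model.

    Parameters
    ----------
    data : DetectionDataset, DataFrame or array of distances
    w : float, optional
        Truncation distance (required unless ``data`` is a DetectionDataset).
    key : {'uniform', 'half_normal', 'hazard_rate'}
    adjustment : {'none', 'cosine', 'simple_poly', 'hermite'}
    n_adjust : int
        Number of series-adjustment terms.
    scale_covariate : str, optional
        Column of ``data.observations`` used as a categorical MCDS covariate
        on the scale parameter (treatment coding, lexicographically first
        level as reference).  Not available with the uniform key.
    """

    def __init__(self, data, w=None, key="hazard_rate", adjustment="none", n_adjust=0,
                 scale_covariate=None):
        self.data = _as_dataset(data, w)
        if key not in KEYS:
            raise ValueError(f"unknown key '{key}'")
        if key == "uniform" and scale_covariate is not None:
            raise ValueError("scale covariate requires a key with a scale parameter")
        if adjustment == "hermite" and scale_covariate is not None:
            raise ValueError("hermite adjustments are not supported with MCDS scaling")
        self.key = key
        self.adjustment = adjustment if n_adjust else "none"
        self.n_adjust = int(n_adjust)
        self.scale_covariate = scale_covariate
        self.w = self.data.w
        self.x = self.data.distances

        if scale_covariate is not None:
            col = self.data.observations[scale_covariate].astype(str)
            self.levels = sorted(col.unique())
            self._codes = col.map({lv: i for i, lv in enumerate(self.levels)}).to_numpy()
        else:
            self.levels = None
            self._codes = None

    # -- parameter vector layout -------------------------------------------
    @property
    def n_scale_params(self) -> int:
        if self.key == "uniform":
            return 0
        return 1 if self.levels is None else len(self.levels)

    @property
    def n_params(self) -> int:
        return self.n_scale_params + (1 if self.key == "hazard_rate" else 0) + self.n_adjust

    def _unpack(self, params):
        """params -> (sigma per observation or scalar, b, adj coeffs)."""
        k = self.n_scale_params
        sigma = b = None
        pos = k
        if self.key != "uniform":
            beta = np.asarray(params[:k], dtype=float)
            if self.levels is None:
                sigma = np.exp(beta[0])
            else:
                eta = np.concatenate([[beta[0]], beta[0] + beta[1:]])
                sigma = np.exp(eta)  # per level
        if self.key == "hazard_rate":
            b = 1.0 + np.exp(params[pos])
            pos += 1
        coeffs = tuple(params[pos:])
        return sigma, b, coeffs

    def _sigma_per_obs(self, sigma):
        if self.levels is None:
            return sigma
        return sigma[self._codes]

    def loglike(self, params) -> float:
        """Conditional line-transect log-likelihood."""
        sigma, b, coeffs = self._unpack(params)
        if sigma is not None and np.any(~np.isfinite(np.atleast_1d(sigma))):
            return -_BIG
        sig_obs = self._sigma_per_obs(sigma) if sigma is not None else None
        num = g_unnormalized(self.x, self.key, self.w, sigma=sig_obs, b=b,
                             adjustment=self.adjustment, adj_coeffs=coeffs)
        if np.any(num <= 0) or np.any(~np.isfinite(num)):
            return -_BIG
        if self.levels is None:
            mu = integrate_g(self.key, self.w, sigma=sigma, b=b,
                             adjustment=self.adjustment, adj_coeffs=coeffs)
            if not np.isfinite(mu) or mu <= 0:
                return -_BIG
            denom = self.data.n * np.log(mu)
        else:
            mus = np.array([
                integrate_g(self.key, self.w, sigma=s, b=b,
                            adjustment=self.adjustment, adj_coeffs=coeffs)
                for s in sigma
            ])
            if np.any(~np.isfinite(mus)) or np.any(mus <= 0):
                return -_BIG
            denom = float(np.log(mus[self._codes]).sum())
        return float(np.log(num).sum() - denom)

    def _start_params(self) -> np.ndarray:
        x = self.x
        parts = []
        if self.key == "half_normal":
            s0 = max(np.sqrt(np.mean(x**2)), 1e-3)
            parts.append([np.log(s0)] + [0.0] * (self.n_scale_params - 1))
        elif self.key == "hazard_rate":
            s0 = max(0.8 * np.median(x), 1e-3)
            parts.append([np.log(s0)] + [0.0] * (self.n_scale_params - 1))
        start = [v for p in parts for v in p]
        if self.key == "hazard_rate":
            start.append(np.log(1.5))  # b = 2.5
        start.extend([0.0] * self.n_adjust)
        return np.array(start, dtype=float)

    def fit(self, n_restarts: int = 5, seed: int = 0) -> "DetectionFunctionResults":
        """Maximize the likelihood with multi-start quasi-Newton optimization.

        The hazard-rate likelihood can be multimodal, so optimization is
        repeated from perturbed starting points (seeded) and the best
        converged optimum kept.
        """
        if self.data.n == 0:
            raise ValueError("no observations to fit")
        if self.n_params == 0:  # uniform key, no adjustments: g == 1
            llf = -self.data.n * np.log(self.w)
            return DetectionFunctionResults(self, np.empty(0), float(llf), np.empty((0, 0)))

        rng = np.random.default_rng(seed)
        base = self._start_params()
        best = None
        trace = []
        for r in range(max(1, n_restarts)):
            x0 = base if r == 0 else base + rng.normal(0.0, 0.5, size=base.size)
            res = optimize.minimize(lambda p: -self.loglike(p), x0, method="L-BFGS-B")
            trace.append((res.success, float(-res.fun)))
            if res.fun < _BIG / 2 and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError(f"detection fit failed to converge; optimizer trace: {trace}")

        hess = approx_hess1(best.x, lambda p: -self.loglike(p))
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.full((self.n_params, self.n_params), np.nan)
        return DetectionFunctionResults(self, best.x, float(-best.fun), cov)


class DetectionFunctionResults:
    """Fitted detection function: estimates, uncertainty and diagnostics."""

    def __init__(self, model: DetectionFunction, params: np.ndarray, llf: float,
                 cov_params: np.ndarray):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = llf
        self.cov_params = cov_params
        self.nobs = model.data.n
        self.key = model.key
        self.w = model.w
        sigma, b, coeffs = model._unpack(self.params) if model.n_params else (None, None, ())
        self._sigma = sigma
        self._b = b
        self.adj_coeffs = coeffs

    # -- information criteria ---------------------------------------------
    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        k, n = self.n_params, self.nobs
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    # -- parameters --------------------------------------------------------
    def sigma(self, level=None) -> float:
        """Key scale in metres (for MCDS, of the requested covariate level)."""
        if self._sigma is None:
            raise ValueError(f"key '{self.key}' has no scale parameter")
        if self.model.levels is None:
            return float(self._sigma)
        if level is None:
            raise ValueError(f"model has scale levels {self.model.levels}; pass level=")
        return float(self._sigma[self.model.levels.index(str(level))])

    @property
    def b(self) -> float:
        if self._b is None:
            raise ValueError("only the hazard-rate key has a shape parameter b")
        return float(self._b)

    def bse(self) -> dict:
        """Delta-method standard errors for sigma (and b) on their own scale."""
        out = {}
        if self.n_params == 0 or not np.all(np.isfinite(self.cov_params)):
            return out
        se_t = np.sqrt(np.clip(np.diag(self.cov_params), 0, None))
        pos = 0
        if self.model.n_scale_params:
            if self.model.levels is None:
                out["sigma"] = float(self._sigma) * se_t[0]
            else:
                out["sigma_ref"] = float(self._sigma[0]) * se_t[0]
            pos = self.model.n_scale_params
        if self.key == "hazard_rate":
            out["b"] = (self.b - 1.0) * se_t[pos]
        return out

    # -- detection function ------------------------------------------------
    def g(self, x, level=None) -> np.ndarray:
        """Fitted detection probability at distance x (g(0) = 1)."""
        sigma = None
        if self._sigma is not None:
            sigma = self._sigma if self.model.levels is None else self._sigma[
                self.model.levels.index(str(level))
            ]
        return detection_g(x, self.key, self.w, sigma=sigma, b=self._b,
                           adjustment=self.model.adjustment, adj_coeffs=self.adj_coeffs)

    def is_monotone(self, n_grid: int = 1000, tol: float = 1e-6) -> bool:
        """Check weak monotone decrease of g on a grid over [0, w]."""
        grid = np.linspace(0.0, self.w, n_grid)
        levels = self.model.levels or [None]
        for lv in levels:
            gv = self.g(grid, level=lv)
            if np.any(np.diff(gv) > tol):
                return False
        return True

    def esw(self, level=None) -> float:
        """Effective strip width, ESW = ∫_0^w g(x) dx, adaptive quadrature."""
        val, _ = integrate.quad(lambda u: float(self.g(u, level=level)), 0.0, self.w,
                                epsabs=1e-6, limit=200)
        return float(val)

    def pdf(self, x, level=None) -> np.ndarray:
        """Sampling density of detected distances, f(x) = g(x)/ESW."""
        return self.g(x, level=level) / self.esw(level=level)

    # -- goodness of fit ----------------------------------------------------
    def gof_chi2(self, n_bins: int = 6):
        """Chi-squared goodness of fit on equal-width distance bins.

        Expected counts come from the fitted g integrated over each bin;
        adjacent bins with expected count < 1 are merged (with a warning).
        df = (bins used) - (number of parameters) - 1.
        """
        if n_bins < self.n_params + 2:
            raise ValueError("n_bins must be at least n_params + 2")
        edges = np.linspace(0.0, self.w, n_bins + 1)
        x = self.model.x
        obs, _ = np.histogram(x, bins=edges)

        levels = self.model.levels
        exp = np.zeros(n_bins)
        if levels is None:
            esw = self.esw()
            probs = np.array([
                integrate.quad(lambda u: float(self.g(u)), edges[i], edges[i + 1],
                               epsabs=1e-8)[0] / esw
                for i in range(n_bins)
            ])
            exp = self.nobs * probs
        else:
            codes = self.model._codes
            for li, lv in enumerate(levels):
                n_l = int(np.sum(codes == li))
                esw_l = self.esw(level=lv)
                probs = np.array([
                    integrate.quad(lambda u: float(self.g(u, level=lv)), edges[i],
                                   edges[i + 1], epsabs=1e-8)[0] / esw_l
                    for i in range(n_bins)
                ])
                exp += n_l * probs

        while len(exp) > max(2, self.n_params + 2) and np.any(exp < 1.0):
            i = int(np.argmin(exp))
            j = i - 1 if i == len(exp) - 1 else i + 1
            lo, hi = min(i, j), max(i, j)
            warnings.warn("merging adjacent distance bins with expected count < 1")
            exp = np.concatenate([exp[:lo], [exp[lo] + exp[hi]], exp[hi + 1:]])
            obs = np.concatenate([obs[:lo], [obs[lo] + obs[hi]], obs[hi + 1:]])

        chi2 = float(np.sum((obs - exp) ** 2 / exp))
        df = len(exp) - self.n_params - 1
        if df < 1:
            raise ValueError("not enough bins for a chi-squared test after merging")
        p = float(chi2_dist.sf(chi2, df))
        return chi2, df, p

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Detection function (line-transect, conditional likelihood)",
            f"  key: {self.key}   adjustment: {self.model.adjustment} "
            f"({self.model.n_adjust} terms)",
            f"  n obs: {self.nobs}   truncation w: {self.w:g} m",
            f"  log-likelihood: {self.llf:.3f}   AIC: {self.aic:.2f}   "
            f"AICc: {self.aicc:.2f}",
        ]
        se = self.bse()
        if self._sigma is not None:
            if self.model.levels is None:
                s = f"  sigma: {self.sigma():.3f} m"
                if "sigma" in se:
                    s += f" (SE {se['sigma']:.3f})"
                lines.append(s)
                lines.append(f"  ESW: {self.esw():.3f} m")
            else:
                for lv in self.model.levels:
                    lines.append(
                        f"  sigma[{lv}]: {self.sigma(lv):.3f} m   "
                        f"ESW[{lv}]: {self.esw(lv):.3f} m"
                    )
        else:
            lines.append(f"  ESW: {self.esw():.3f} m")
        if self._b is not None:
            s = f"  b: {self.b:.3f}"
            if "b" in se:
                s += f" (SE {se['b']:.3f})"
            lines.append(s)
        if self.adj_coeffs:
            lines.append(f"  adjustment coefficients: {np.round(self.adj_coeffs, 4)}")
        return "\n".join(lines)

    def plot(self, ax=None, bins: int = 12, level=None):
        """Histogram of detection distances with the fitted g(x) overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.x
        if level is not None and self.model.levels is not None:
            x = x[self.model._codes == self.model.levels.index(str(level))]
        ax.hist(x, bins=np.linspace(0, self.w, bins + 1), density=True,
                color="0.8", edgecolor="0.4")
        grid = np.linspace(0, self.w, 200)
        ax.plot(grid, self.g(grid, level=level) / self.esw(level=level), "k-")
        ax.set_xlabel("perpendicular distance (m)")
        ax.set_ylabel("density")
        return ax


@dataclass
class StratifiedDetectionResults:
    """CDS post-stratification: one independent detection fit per stratum."""

    stratify_by: str
    strata: dict = field(default_factory=dict)  # level -> DetectionFunctionResults

    @property
    def levels(self):
        return sorted(self.strata)

    @property
    def llf(self) -> float:
        return sum(r.llf for r in self.strata.values())

    @property
    def n_params(self) -> int:
        return sum(r.n_params for r in self.strata.values())

    @property
    def nobs(self) -> int:
        return sum(r.nobs for r in self.strata.values())

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        return sum(r.aicc for r in self.strata.values())

    @property
    def key(self) -> str:
        return next(iter(self.strata.values())).key

    @property
    def w(self) -> float:
        return next(iter(self.strata.values())).w

    def esw(self, level) -> float:
        return self.strata[str(level)].esw()

    def gof_chi2(self, n_bins: int = 6):
        """Summed chi-squared over strata (df summed as well)."""
        chi2 = df = 0
        for r in self.strata.values():
            c, d, _ = r.gof_chi2(n_bins)
            chi2, df = chi2 + c, df + d
        return chi2, df, float(chi2_dist.sf(chi2, df))

    def summary(self) -> str:
        out = [f"CDS post-stratified by '{self.stratify_by}': "
               f"AIC {self.aic:.2f} ({self.n_params} params, n={self.nobs})"]
        for lv in self.levels:
            out.append(f"--- stratum {lv} ---")
            out.append(self.strata[lv].summary())
        return "\n".join(out)


def fit_detection(
    data,
    w=None,
    key: str = "hazard_rate",
    adjustment: str = "none",
    max_adjust_terms: int = 3,
    stratify_by: str | None = None,
    scale_covariate: str | None = None,
    min_obs: int = 10,
    seed: int = 0,
):
    """Fit a detection function, adding adjustment terms while AIC improves.

    ``stratify_by`` performs CDS post-stratification (independent fit per
    level of the named column); ``scale_covariate`` fits an MCDS log-linear
    scale model instead.  Candidate fits whose detection function is not
    weakly decreasing on [0, w] are rejected.
    """
    dataset = _as_dataset(data, w)
    if stratify_by is not None:
        if scale_covariate is not None:
            raise ValueError("choose either CDS stratification or an MCDS covariate")
        obs = dataset.observations
        strata = {}
        for level, sub in obs.groupby(obs[stratify_by].astype(str), sort=True):
            sub_ds = DetectionDataset(sub.reset_index(drop=True), dataset.w,
                                      dataset.removed_fraction)
            strata[level] = fit_detection(sub_ds, key=key, adjustment=adjustment,
                                          max_adjust_terms=max_adjust_terms,
                                          min_obs=min_obs, seed=seed)
        return StratifiedDetectionResults(stratify_by=stratify_by, strata=strata)

    if dataset.n < min_obs:
        raise ValueError(
            f"{dataset.n} observations < configured floor of {min_obs}"
        )
    best = DetectionFunction(dataset, key=key, adjustment="none", n_adjust=0,
                             scale_covariate=scale_covariate).fit(seed=seed)
    if adjustment != "none":
        for n_terms in range(1, max_adjust_terms + 1):
            try:
                cand = DetectionFunction(dataset, key=key, adjustment=adjustment,
                                         n_adjust=n_terms,
                                         scale_covariate=scale_covariate).fit(seed=seed)
            except (RuntimeError, ValueError):
                break
            if not cand.is_monotone() or cand.aic >= best.aic:
                break
            best = cand
    return best


_KEY_ORDER = {"uniform": 0, "half_normal": 1, "hazard_rate": 2}


def _signature(res) -> tuple:
    if isinstance(res, StratifiedDetectionResults):
        xs = np.concatenate([r.model.x for r in res.strata.values()])
    else:
        xs = res.model.x
    xs = np.sort(xs)
    return (len(xs), round(float(res.w), 9), round(float(xs.sum()), 6),
            round(float((xs**2).sum()), 3))


def select_model(models):
    """AIC model selection over candidates fitted on identical data.

    Ties are broken by fewer parameters, then by key order
    uniform < half_normal < hazard_rate.
    """
    models = list(models)
    if not models:
        raise ValueError("no candidate models")
    sigs = {_signature(m) for m in models}
    if len(sigs) > 1:
        raise ValueError("candidates were fitted on different data or truncation")
    return min(models, key=lambda m: (m.aic, m.n_params, _KEY_ORDER[m.key]))


def esw(results, level=None) -> float:
    """Effective strip width of a fitted detection function, in metres."""
    if level is not None:
        return results.esw(level)
    return results.esw()


def simulate_distances(n: int, key: str, w: float, sigma=None, b=None,
                       rng=None, adjustment: str = "none", adj_coeffs=()) -> np.ndarray:
    """Draw n detection distances from f(x) ∝ g(x) on [0, w] by rejection."""
    rng = np.random.default_rng(rng)
    out = np.empty(0)
    while out.size < n:
        m = max(4 * (n - out.size), 100)
        u = rng.uniform(0.0, w, size=m)
        g = detection_g(u, key, w, sigma=sigma, b=b, adjustment=adjustment,
                        adj_coeffs=adj_coeffs)
        accept = rng.uniform(size=m) < np.clip(g, 0.0, 1.0)
        out = np.concatenate([out, u[accept]])
    return out[:n]
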