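"""Spearman rank-correlation screen with Bonferroni adjustment.

Associations between site-level density and its components are screened
non-parametrically: Spearman's rho computed from midranks, with an exact
permutation p-value for small samples (n <= 9, full enumeration of rank
permutations) and the usual t approximation otherwise.  p-values from a
screen of m tests are Bonferroni-adjusted (min(1, m*p)).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

EXACT_MAX_N = 9


@dataclass(frozen=True)
class CorrelationResult:
    variable_x: str
    variable_y: str
    rho: float
    p_value: float
    p_adjusted: float
    n_sites: int
    significant_at: float


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    return float((rx * ry).sum() / denom)


def spearman(x, y, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value.

    Ties receive midranks.  For n <= ``exact_max_n`` the p-value is exact,
    from full enumeration of the n! permutations of one rank vector;
    otherwise the t approximation ``t = rho*sqrt((n-2)/(1-rho^2))`` with
    n - 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    rx, ry = rankdata(x), rankdata(y)
    rho = _rank_corr(rx, ry)

    if n <= exact_max_n:
        perms = np.array(list(permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        stats = (rx_c[perms] * ry_c).sum(axis=1) / denom
        p = float(np.mean(np.abs(stats) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = float(2.0 * t_dist.sf(np.inf, n - 2))
        else:
            tval = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * t_dist.sf(abs(tval), n - 2))
    return rho, min(p, 1.0)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjust p-values for m tests: elementwise min(1, m*p)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than the number of p-values ({p.size})")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * m)


def correlation_screen(
    data: pd.DataFrame,
    target: str,
    covariates: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen a target column against covariates with Bonferroni control.

    Returns one row per covariate with rho, raw and adjusted p, and the
    per-test cutoff alpha/m implied by the Bonferroni procedure.
    """
    m = len(covariates)
    if m == 0:
        raise ValueError("no covariates to screen")
    cutoff = alpha / m
    rows = []
    for var in covariates:
        rho, p = spearman(data[target], data[var])
        rows.append(
            CorrelationResult(
                variable_x=target,
                variable_y=var,
                rho=rho,
                p_value=p,
                p_adjusted=float(bonferroni([p], m)[0]),
                n_sites=len(data),
                significant_at=cutoff,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
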