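"""Detection-function key forms and series adjustments.

The detection function g(x) gives the probability of detecting an object at
perpendicular distance x from the transect line.  Keys:

* uniform      g(x) = 1
* half_normal  g(x) = exp(-x^2 / (2 sigma^2))
* hazard_rate  g(x) = 1 - exp(-(x/sigma)^(-b)),  b > 1

Series adjustments multiply the key by (1 + sum_j a_j h_j(x_s)) and the
product is renormalized so g(0) = 1.  Cosine and simple-polynomial terms are
scaled by the truncation distance (x_s = x/w); Hermite terms by the key scale
(x_s = x/sigma).  Cosine orders start at 1 for the uniform key and at 2 for
the half-normal and hazard-rate keys, the usual convention.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_hermitenorm

KEYS = ("uniform", "half_normal", "hazard_rate")
ADJUSTMENTS = ("none", "cosine", "simple_poly", "hermite")

#: order of the first adjustment term, per key and series type
FIRST_ORDER = {
    ("uniform", "cosine"): 1,
    ("half_normal", "cosine"): 2,
    ("hazard_rate", "cosine"): 2,
    ("uniform", "simple_poly"): 1,
    ("half_normal", "simple_poly"): 2,
    ("hazard_rate", "simple_poly"): 2,
    ("half_normal", "hermite"): 2,
}


def key_value(key: str, x: np.ndarray, sigma=None, b=None) -> np.ndarray:
    """Evaluate the raw key function (unnormalized; equals 1 at x=0)."""
    x = np.asarray(x, dtype=float)
    if key == "uniform":
        return np.ones_like(x)
    if key == "half_normal":
        return np.exp(-(x**2) / (2.0 * np.asarray(sigma) ** 2))
    if key == "hazard_rate":
        with np.errstate(divide="ignore", over="ignore"):
            z = np.where(x > 0, (x / np.asarray(sigma)) ** (-np.asarray(b)), np.inf)
        return -np.expm1(-z)
    raise ValueError(f"unknown key '{key}'; expected one of {KEYS}")


def adjustment_orders(key: str, adjustment: str, n_terms: int) -> tuple[int, ...]:
    """The term orders used for ``n_terms`` sequential adjustment terms."""
    if adjustment == "none" or n_terms == 0:
        return ()
    if (key, adjustment) not in FIRST_ORDER:
        raise ValueError(f"adjustment '{adjustment}' not supported with key '{key}'")
    start = FIRST_ORDER[(key, adjustment)]
    return tuple(range(start, start + n_terms))


def _series(adjustment: str, xs: np.ndarray, coeffs, orders) -> np.ndarray:
    """1 + sum_j a_j h_j(xs), for scaled distances xs."""
    out = np.ones_like(xs)
    for a, j in zip(coeffs, orders):
        if adjustment == "cosine":
            out = out + a * np.cos(j * np.pi * xs)
        elif adjustment == "simple_poly":
            out = out + a * xs ** (2 * j)
        elif adjustment == "hermite":
            out = out + a * eval_hermitenorm(2 * j, xs)
        else:
            raise ValueError(f"unknown adjustment '{adjustment}'")
    return out


def g_unnormalized(
    x,
    key: str,
    w: float,
    sigma=None,
    b=None,
    adjustment: str = "none",
    adj_coeffs=(),
) -> np.ndarray:
    """key(x) * adjustment series, not yet normalized to g(0)=1."""
    x = np.asarray(x, dtype=float)
    val = key_value(key, x, sigma=sigma, b=b)
    if adjustment != "none" and len(adj_coeffs):
        orders = adjustment_orders(key, adjustment, len(adj_coeffs))
        xs = x / (sigma if adjustment == "hermite" else w)
        val = val * _series(adjustment, xs, adj_coeffs, orders)
    return val


def detection_g(
    x,
    key: str,
    w: float,
    sigma=None,
    b=None,
    adjustment: str = "none",
    adj_coeffs=(),
) -> np.ndarray:
    """Detection probability g(x) on [0, w], normalized so g(0) = 1.

    Raises if any distance exceeds the truncation distance w.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > w):
        raise ValueError(f"distances must lie in [0, {w}]")
    raw = g_unnormalized(x, key, w, sigma=sigma, b=b, adjustment=adjustment, adj_coeffs=adj_coeffs)
    g0 = g_unnormalized(0.0, key, w, sigma=sigma, b=b, adjustment=adjustment, adj_coeffs=adj_coeffs)
    return raw / g0


# 61-point Gauss-Legendre rule, reused for all likelihood integrals
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(61)


def integrate_g(
    key: str,
    w: float,
    sigma=None,
    b=None,
    adjustment: str = "none",
    adj_coeffs=(),
) -> float:
    """∫_0^w of the *unnormalized* g by fixed Gauss-Legendre quadrature."""
    u = 0.5 * w * (_GL_NODES + 1.0)
    vals = g_unnormalized(u, key, w, sigma=sigma, b=b, adjustment=adjustment, adj_coeffs=adj_coeffs)
    return float(0.5 * w * np.sum(_GL_WEIGHTS * vals))
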