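"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's own code paths: the Voronoi oracle
builds each Thiessen cell by exhaustive half-plane intersection (no
scipy.spatial.Voronoi), and the numeric oracles re-derive closed forms
from first principles.
"""

import numpy as np


def shared_edge_length(points: np.ndarray, i: int, j: int, rect: tuple) -> float:
    """Length of the Voronoi edge shared by cells i and j inside ``rect``.

    The edge lies on the perpendicular bisector of (p_i, p_j); points on it
    closer to i and j than to every other site form an interval, found by
    intersecting the linear inequalities |x-p_i|^2 <= |x-p_k|^2 (linear in
    the bisector parameter t) plus the rectangle bounds.
    """
    pi, pj = points[i], points[j]
    mid = 0.5 * (pi + pj)
    d = (pj - pi) / np.linalg.norm(pj - pi)
    perp = np.array([-d[1], d[0]])  # x(t) = mid + t * perp
    t_lo, t_hi = -np.inf, np.inf

    def clip(c1, c0):
        # constraint c0 + c1 * t <= 0
        nonlocal t_lo, t_hi
        if abs(c1) < 1e-300:
            if c0 > 0:
                t_lo, t_hi = 1.0, 0.0
        elif c1 > 0:
            t_hi = min(t_hi, -c0 / c1)
        else:
            t_lo = max(t_lo, -c0 / c1)

    for k in range(len(points)):
        if k in (i, j):
            continue
        pk = points[k]
        c0 = float((mid - pi) @ (mid - pi) - (mid - pk) @ (mid - pk))
        c1 = float(2.0 * perp @ (pk - pi))
        clip(c1, c0)
    xmin, ymin, xmax, ymax = rect
    clip(perp[0], mid[0] - xmax)   # x <= xmax
    clip(-perp[0], xmin - mid[0])  # x >= xmin
    clip(perp[1], mid[1] - ymax)
    clip(-perp[1], ymin - mid[1])
    return max(t_hi - t_lo, 0.0)


def brute_force_adjacency(points: np.ndarray, rect: tuple, tol: float = 1e-9) -> np.ndarray:
    """0/1 adjacency: neighbours iff the shared Voronoi edge clipped to the
    rectangle has positive length."""
    q = len(points)
    w = np.zeros((q, q), dtype=int)
    for i in range(q):
        for j in range(i + 1, q):
            if shared_edge_length(points, i, j, rect) > tol:
                w[i, j] = w[j, i] = 1
    return w


def brute_force_distances(points: np.ndarray) -> np.ndarray:
    q = len(points)
    d = np.zeros((q, q))
    for i in range(q):
        for j in range(q):
            d[i, j] = np.sqrt(
                (points[i, 0] - points[j, 0]) ** 2 + (points[i, 1] - points[j, 1]) ** 2
            )
    return d


def normal_loglik_sum(y, mu, sigma2):
    """Deviance oracle via per-observation scipy log-pdfs."""
    from scipy.stats import norm

    return -2.0 * float(
        np.sum(norm.logpdf(np.ravel(y), loc=np.ravel(mu), scale=np.sqrt(sigma2)))
    )


def ridge_posterior(xmat, resid, sigma2, prior_var):
    """Closed-form Gaussian posterior of coefficients under N(0, prior_var)
    priors: cov = (X'X/s2 + I/v)^-1, mean = cov X'r/s2."""
    p = xmat.shape[1]
    cov = np.linalg.inv(xmat.T @ xmat / sigma2 + np.eye(p) / prior_var)
    return cov @ (xmat.T @ resid) / sigma2, cov
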