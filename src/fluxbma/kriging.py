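"""Posterior prediction, fit diagnostics, and ordinary kriging surfaces.

Site-level posterior predictive summaries come straight from the MCMC
draws (mu_ir plus fresh residual noise per draw). Surfaces are produced
the way the original workflow did: krige the per-site posterior summaries
over a regular grid using an exponential variogram fitted by weighted
least squares to the binned empirical semivariogram. Per-draw kriging is
available separately for uncertainty-propagation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datasets import ChamberDataset
from .geometry import SiteCoordinates
from .mcmc import PosteriorSamples

__all__ = [
    "SitePrediction",
    "Variogram",
    "PredictionSurface",
    "posterior_predict",
    "coverage_check",
    "sum_squared_residuals",
    "fit_variogram",
    "ordinary_kriging_weights",
    "krige",
    "krige_per_draw",
    "make_grid",
]


@dataclass(frozen=True)
class SitePrediction:
    """Posterior predictive summaries for one fitted model."""

    model: str
    site_table: pd.DataFrame  # per-site predictive + spatial-effect summaries
    obs_mean: np.ndarray  # (Q, M) predictive means per observation
    obs_lower: np.ndarray  # (Q, M) 2.5% predictive quantile
    obs_upper: np.ndarray  # (Q, M) 97.5% predictive quantile
    site_draws: np.ndarray  # (n_draws, Q) site-level predictive draws


@dataclass(frozen=True)
class Variogram:
    """Exponential variogram gamma(h) = nugget + sill*(1 - exp(-h/range_)).

    ``sill`` is the partial sill; the practical (95%) correlation range of
    the exponential model is ``3 * range_``.
    """

    nugget: float
    sill: float
    range_: float
    degenerate: bool = False

    @property
    def effective_range(self) -> float:
        return 3.0 * self.range_

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, float)
        gamma = np.where(h > 0, self.nugget + self.sill * (1.0 - np.exp(-h / self.range_)), 0.0)
        return gamma


@dataclass(frozen=True)
class PredictionSurface:
    """Regular-grid kriged field with per-node kriging variance."""

    x: np.ndarray  # (nx,) node centres, metres
    y: np.ndarray  # (ny,)
    values: np.ndarray  # (ny, nx)
    variance: np.ndarray  # (ny, nx), >= 0
    variogram: Variogram

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "value": self.values.ravel(),
                "variance": self.variance.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_ascii_grid(self, path, nodata: float = -9999.0) -> None:
        """ESRI-ASCII-style raster text file of the kriged values."""
        cell = self.x[1] - self.x[0] if len(self.x) > 1 else 1.0
        with open(path, "w") as fh:
            fh.write(f"ncols {len(self.x)}\n")
            fh.write(f"nrows {len(self.y)}\n")
            fh.write(f"xllcorner {self.x[0] - cell / 2:.6f}\n")
            fh.write(f"yllcorner {self.y[0] - cell / 2:.6f}\n")
            fh.write(f"cellsize {cell:.6f}\n")
            fh.write(f"NODATA_value {nodata}\n")
            for row in self.values[::-1]:  # north-up raster order
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


# --------------------------------------------------------------------------
# posterior prediction and diagnostics


def posterior_predict(
    samples: PosteriorSamples, data: ChamberDataset, seed: int = 0
) -> SitePrediction:
    """Predictive draws y* = mu_ir + N(0, sigma^2) per retained draw.

    Site-level summaries aggregate over replicates (the mean of the M
    predictive draws at a site); spatial-effect summaries are the posterior
    mean and SD of s_i / u_i (identically zero for the independent model).
    """
    rng = np.random.default_rng(seed)
    y, xmat, site_idx = data.design_matrix()
    q, m = data.n_sites, data.n_replicates
    n = samples.n_draws

    mu = samples.beta @ xmat.T + samples.effects[:, site_idx]  # (n, QM)
    draws = mu + np.sqrt(samples.sigma2)[:, None] * rng.standard_normal((n, q * m))
    draws3 = draws.reshape(n, q, m)

    obs_mean = draws3.mean(axis=0)
    obs_lower = np.quantile(draws3, 0.025, axis=0)
    obs_upper = np.quantile(draws3, 0.975, axis=0)
    site_draws = draws3.mean(axis=2)  # (n, Q) replicate-aggregated

    qs = np.quantile(site_draws, [0.025, 0.5, 0.975], axis=0)
    table = pd.DataFrame(
        {
            "site_id": data.coords.site_id,
            "x_m": data.coords.x,
            "y_m": data.coords.y,
            "pred_mean": site_draws.mean(axis=0),
            "pred_median": qs[1],
            "pred_q2.5": qs[0],
            "pred_q97.5": qs[2],
            "effect_mean": samples.effects.mean(axis=0),
            "effect_sd": samples.effects.std(axis=0, ddof=1),
        }
    )
    return SitePrediction(
        model=samples.model,
        site_table=table,
        obs_mean=obs_mean,
        obs_lower=obs_lower,
        obs_upper=obs_upper,
        site_draws=site_draws,
    )


def coverage_check(observed, lower, upper) -> float:
    """Fraction of observations strictly outside their [lower, upper]
    posterior predictive interval."""
    observed = np.ravel(observed)
    lower = np.ravel(lower)
    upper = np.ravel(upper)
    if not (len(observed) == len(lower) == len(upper)):
        raise ValueError("observed and interval arrays differ in length")
    outside = (observed < lower) | (observed > upper)
    return float(outside.mean())


def sum_squared_residuals(observed, predicted_mean) -> float:
    """Sum of squared (observed log-flux - posterior predictive mean)."""
    observed = np.ravel(observed)
    predicted_mean = np.ravel(predicted_mean)
    if len(observed) != len(predicted_mean):
        raise ValueError("observed and prediction arrays differ in length")
    return float(np.sum((observed - predicted_mean) ** 2))


# --------------------------------------------------------------------------
# variogram fitting and ordinary kriging


def empirical_variogram(
    values: np.ndarray, coords: SiteCoordinates, n_bins: int = 12, max_dist: float | None = None
) -> pd.DataFrame:
    """Binned method-of-moments semivariogram (lag, gamma, pair count)."""
    xy = coords.xy
    v = np.asarray(values, float)
    q = len(v)
    i, j = np.triu_indices(q, k=1)
    h = np.hypot(*(xy[i] - xy[j]).T)
    g = 0.5 * (v[i] - v[j]) ** 2
    # conventional lag window: half the maximum pair distance, where bins
    # still hold enough pairs for a stable moment estimate
    max_dist = max_dist or float(h.max()) / 2.0
    edges = np.linspace(0, max_dist, n_bins + 1)
    which = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    keep = h <= max_dist
    rows = []
    for b in range(n_bins):
        sel = keep & (which == b)
        if sel.sum() > 0:
            rows.append(
                {"lag": h[sel].mean(), "gamma": g[sel].mean(), "n_pairs": int(sel.sum())}
            )
    return pd.DataFrame(rows)


def fit_variogram(
    values: np.ndarray,
    coords: SiteCoordinates,
    n_bins: int = 12,
    max_dist: float | None = None,
) -> Variogram:
    """Exponential-model variogram fitted by pair-count-weighted least
    squares to the empirical semivariogram.

    A spatially constant field gets the degenerate pure-nugget model.
    """
    v = np.asarray(values, float)
    if len(v) < 5:
        raise ValueError("need at least 5 sites to fit a variogram")
    if np.ptp(v) == 0:
        return Variogram(nugget=0.0, sill=0.0, range_=1.0, degenerate=True)

    emp = empirical_variogram(v, coords, n_bins=n_bins, max_dist=max_dist)
    h = emp["lag"].to_numpy()
    g = emp["gamma"].to_numpy()
    wts = np.sqrt(emp["n_pairs"].to_numpy(float))
    d_max = float(np.hypot(np.ptp(coords.x), np.ptp(coords.y)))
    var = v.var(ddof=1)

    def resid(p):
        nugget, sill, rng_ = p
        return wts * (nugget + sill * (1.0 - np.exp(-h / rng_)) - g)

    p0 = np.array([0.1 * var, max(var, 1e-10), max(d_max / 9.0, 1e-6)])
    sol = least_squares(
        resid,
        p0,
        bounds=([0.0, 1e-12, 1e-9], [np.inf, np.inf, 2.0 * d_max]),
    )
    nugget, sill, rng_ = sol.x
    return Variogram(nugget=float(nugget), sill=float(sill), range_=float(rng_))


def ordinary_kriging_weights(
    site_xy: np.ndarray, node: np.ndarray, variogram: Variogram
) -> tuple[np.ndarray, float]:
    """Solve the ordinary-kriging system at one node.

    Returns the weight vector (summing to 1 by the unbiasedness constraint)
    and the Lagrange multiplier.
    """
    a, _ = _kriging_system(site_xy, variogram)
    g0 = variogram(np.hypot(*(site_xy - node).T))
    rhs = np.append(g0, 1.0)
    try:
        sol = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError:
        a = a + np.diag(np.append(np.full(len(site_xy), 1e-10), 0.0))
        sol = np.linalg.solve(a, rhs)
    return sol[:-1], float(sol[-1])


def _kriging_system(site_xy: np.ndarray, variogram: Variogram):
    from scipy.spatial.distance import cdist

    q = len(site_xy)
    gamma = variogram(cdist(site_xy, site_xy))
    a = np.ones((q + 1, q + 1))
    a[:q, :q] = gamma
    a[q, q] = 0.0
    return a, gamma


def make_grid(boundary: tuple, resolution: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Node centres of a regular grid covering the field rectangle."""
    xmin, ymin, xmax, ymax = boundary
    x = np.arange(xmin + resolution / 2.0, xmax, resolution)
    y = np.arange(ymin + resolution / 2.0, ymax, resolution)
    return x, y


def krige(
    site_values: np.ndarray,
    coords: SiteCoordinates,
    grid: tuple[np.ndarray, np.ndarray],
    variogram: Variogram,
) -> PredictionSurface:
    """Ordinary kriging of per-site values over a regular grid.

    Weights at every node satisfy the unbiasedness constraint (asserted);
    the kriging variance is lambda' gamma_0 + mu, floored at 0 against
    roundoff. With a zero nugget the surface honours the data exactly at
    nodes coinciding with sites.
    """
    v = np.asarray(site_values, float)
    xy = coords.xy
    gx, gy = grid
    a, _ = _kriging_system(xy, variogram)
    try:
        from scipy.linalg import lu_factor, lu_solve

        factor = lu_factor(a)
        solve = lambda rhs: lu_solve(factor, rhs)
    except np.linalg.LinAlgError:
        a = a + np.diag(np.append(np.full(len(xy), 1e-10), 0.0))
        from scipy.linalg import lu_factor, lu_solve

        factor = lu_factor(a)
        solve = lambda rhs: lu_solve(factor, rhs)

    values = np.empty((len(gy), len(gx)))
    variance = np.empty_like(values)
    for iy, ny in enumerate(gy):
        for ix, nx in enumerate(gx):
            node = np.array([nx, ny])
            g0 = variogram(np.hypot(*(xy - node).T))
            sol = solve(np.append(g0, 1.0))
            lam, mu = sol[:-1], sol[-1]
            assert abs(lam.sum() - 1.0) < 1e-8, "kriging weights must sum to 1"
            values[iy, ix] = lam @ v
            variance[iy, ix] = max(float(lam @ g0 + mu), 0.0)
    return PredictionSurface(x=gx, y=gy, values=values, variance=variance, variogram=variogram)


def krige_per_draw(
    draws: np.ndarray,
    coords: SiteCoordinates,
    grid: tuple[np.ndarray, np.ndarray],
    variogram: Variogram,
    max_draws: int = 200,
    seed: int = 0,
) -> tuple[PredictionSurface, np.ndarray]:
    """Krige a subsample of posterior draws and pool them.

    Returns the mean surface (with the mean per-draw kriging variance plus
    the between-draw variance) and the stack of per-draw fields.
    """
    rng = np.random.default_rng(seed)
    n = draws.shape[0]
    idx = rng.choice(n, size=min(max_draws, n), replace=False)
    fields = []
    kvar = None
    for k in idx:
        surf = krige(draws[k], coords, grid, variogram)
        fields.append(surf.values)
        kvar = surf.variance if kvar is None else kvar + surf.variance
    fields = np.stack(fields)
    mean_surface = PredictionSurface(
        x=grid[0],
        y=grid[1],
        values=fields.mean(axis=0),
        variance=kvar / len(idx) + fields.var(axis=0),
        variogram=variogram,
    )
    return mean_surface, fields
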