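"""Synthetic chamber-study generator.

Emulates the sampling design of a year-long pasture N2O campaign: Q
chambers placed at random (with a minimum separation) in a small field,
M monthly replicates, seven soil covariates with published summary
moments, and log-scale fluxes generated from one of the three analysis
models (independent errors, exponential-decay Gaussian process, intrinsic
CAR on Thiessen neighbourhoods). Everything is deterministic given the
seed; all randomness flows from one ``SeedSequence``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .datasets import COVARIATES, ChamberDataset, from_arrays
from .geometry import SiteCoordinates, SpatialWeights, pairwise_distances

logger = logging.getLogger(__name__)

#: per-covariate (mean, sd, min, max); site-static: ph, sand, silt, clay;
#: replicate-varying: moisture, temperature, no3
COVARIATE_MOMENTS = {
    "moisture": (35.57, 9.27, 12.37, 70.0),
    "temperature": (22.16, 3.07, 14.8, 27.3),
    "no3": (18.98, 14.1, 0.0, 90.34),
    "ph": (5.47, 0.29, 5.2, 6.4),
    "sand": (37.25, 7.74, 22.75, 50.89),
    "silt": (44.34, 7.2, 34.44, 60.94),
    "clay": (18.4, 3.07, 9.65, 23.34),
}

SITE_STATIC = ("ph", "sand", "silt", "clay")
REPLICATE_VARYING = ("moisture", "temperature", "no3")

# variance split for replicate-varying covariates: a site offset, a shared
# smooth seasonal wave over the monthly replicates, and i.i.d. noise
_VAR_SITE, _VAR_SEASON, _VAR_NOISE = 0.15, 0.35, 0.50


@dataclass(frozen=True)
class DesignConfig:
    """Study-design parameters of the emulated chamber campaign."""

    n_sites: int = 17
    n_replicates: int = 13
    field_width: float = 16.5  # metres; 16.5 x 16.5 ~= 272 m^2
    field_height: float = 16.5
    min_separation: float = 0.75  # metres
    covariate_moments: dict = field(default_factory=lambda: dict(COVARIATE_MOMENTS))
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 3:
            raise ValueError("need at least 3 sites")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.min_separation <= 0 or self.min_separation**2 * self.n_sites > (
            self.field_width * self.field_height
        ):
            raise ValueError("min_separation not achievable in the field area")
        tex = sum(self.covariate_moments[c][0] for c in ("sand", "silt", "clay"))
        if abs(tex - 100.0) > 1.0:
            raise ValueError(f"texture means must sum to ~100, got {tex:.2f}")

    @property
    def boundary(self) -> tuple:
        return (0.0, 0.0, self.field_width, self.field_height)


@dataclass(frozen=True)
class GenerativeParams:
    """True parameters of the flux-generating model (log scale).

    ``beta`` is length K+1 with the intercept first, covariates in
    :data:`fluxbma.datasets.COVARIATES` order. Defaults are the fitted
    values of the pasture study this design emulates.
    """

    structure: str = "exp"  # independent | exp | icar
    beta: tuple = (-7.5, 0.055, 0.16, -0.018, 0.4, 0.023, 0.033, 0.004)
    sigma2: float = 1.6  # residual variance
    sigma_s2: float = 0.76  # GP partial sill (exp structure)
    theta: float = 1.0  # correlation decay rate per metre
    sigma_u2: float = 1.78  # ICAR conditional variance scale
    delta: float = 1.0  # decay-shape exponent, fixed at 1

    def __post_init__(self):
        if self.structure not in ("independent", "exp", "icar"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if min(self.sigma2, self.sigma_s2, self.sigma_u2) <= 0 or self.theta <= 0:
            raise ValueError("variances and theta must be positive")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_layout(config: DesignConfig, max_attempts: int = 10000) -> SiteCoordinates:
    """Uniform random chamber placement with a hard minimum separation.

    Points are rejection-sampled one at a time; the layout is deterministic
    given ``config.seed``.
    """
    rng = _streams(config.seed, 4)[0]
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < config.n_sites:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_sites} sites with separation "
                f">= {config.min_separation} m after {max_attempts} draws; "
                "enlarge the field or reduce n_sites"
            )
        p = rng.uniform([0, 0], [config.field_width, config.field_height])
        attempts += 1
        if all(np.hypot(*(p - q)) >= config.min_separation for q in pts):
            pts.append(p)
    arr = np.array(pts)
    return SiteCoordinates(site_id=np.arange(1, config.n_sites + 1), x=arr[:, 0], y=arr[:, 1])


def _truncated(rng, mean, sd, lo, hi, size):
    return np.clip(mean + sd * rng.standard_normal(size), lo, hi)


def generate_covariates(coords: SiteCoordinates, config: DesignConfig) -> np.ndarray:
    """Covariate array (Q, M, K) in canonical order.

    Soil pH and texture are static per site; moisture, temperature and
    nitrate vary by replicate with one shared sinusoidal seasonal wave
    (monthly sampling over a year), a site offset, and independent noise.
    Texture triplets are renormalised to sum to 100; all values are clipped
    to the published min-max ranges.
    """
    rng = _streams(config.seed, 4)[1]
    q, m = coords.n_sites, config.n_replicates
    out = np.empty((q, m, len(COVARIATES)))
    season_phase = rng.uniform(0, 2 * np.pi)
    # monthly wave over a 12-month cycle; unit variance over a full period
    months = np.arange(m)
    wave = np.sqrt(2.0) * np.sin(2 * np.pi * months / 12.0 + season_phase)

    for k, name in enumerate(COVARIATES):
        mean, sd, lo, hi = config.covariate_moments[name]
        if name in SITE_STATIC:
            vals = _truncated(rng, mean, sd, lo, hi, q)
            out[:, :, k] = vals[:, None]
        else:
            site = np.sqrt(_VAR_SITE) * rng.standard_normal(q)[:, None]
            noise = np.sqrt(_VAR_NOISE) * rng.standard_normal((q, m))
            z = site + np.sqrt(_VAR_SEASON) * wave[None, :] + noise
            out[:, :, k] = np.clip(mean + sd * z, lo, hi)

    tex = [COVARIATES.index(c) for c in ("sand", "silt", "clay")]
    total = out[:, :, tex].sum(axis=2, keepdims=True)
    out[:, :, tex] *= 100.0 / total
    return out


def exp_correlation_matrix(d: np.ndarray, theta: float, delta: float = 1.0) -> np.ndarray:
    return np.exp(-((theta * d) ** delta))


def draw_gp_effects(rng, d: np.ndarray, sigma_s2: float, theta: float, delta: float = 1.0) -> np.ndarray:
    """Zero-mean GP site effects with covariance sigma_s2 * exp(-(theta d)^delta)."""
    cov = sigma_s2 * exp_correlation_matrix(d, theta, delta)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        logger.warning("GP covariance not PD; adding 1e-8 diagonal jitter")
        chol = np.linalg.cholesky(cov + 1e-8 * np.eye(len(d)))
    return chol @ rng.standard_normal(len(d))


def draw_icar_effects(rng, weights: SpatialWeights, sigma_u2: float) -> np.ndarray:
    """Joint draw from the intrinsic CAR distribution on the sum-to-zero
    subspace, via the eigendecomposition pseudo-inverse of the precision
    (diag(w_i+) - W) / sigma_u2.
    """
    w = weights.w.astype(float)
    lap = np.diag(w.sum(axis=1)) - w
    evals, evecs = np.linalg.eigh(lap / sigma_u2)
    # intrinsic prior: one zero eigenvalue (constant vector) on a connected graph
    keep = evals > 1e-10 * evals.max()
    sd = 1.0 / np.sqrt(evals[keep])
    u = evecs[:, keep] @ (sd * rng.standard_normal(keep.sum()))
    return u - u.mean()


def simulate_fluxes(
    coords: SiteCoordinates,
    covariates: np.ndarray,
    params: GenerativeParams,
    weights: SpatialWeights | None = None,
    n_replicates: int | None = None,
    seed: int = 0,
    back_shift: float = 0.0,
) -> ChamberDataset:
    """Generate a chamber dataset from one of the three analysis models.

    Log-flux = beta0 + X beta + (s_i | u_i | 0) + eps_ir with i.i.d.
    Gaussian residuals. Fluxes are exponentiated back to the natural scale;
    a positive ``back_shift`` is subtracted there (floored at 0) to produce
    occasional exact zeros, as real chamber records contain.
    """
    q, m, k = covariates.shape
    if params.structure == "icar" and weights is None:
        raise ValueError("icar structure requires a SpatialWeights")
    rng = _streams(seed, 4)[2]

    beta = np.asarray(params.beta, float)
    if len(beta) != k + 1:
        raise ValueError(f"beta must have length {k + 1}")
    mu = beta[0] + covariates @ beta[1:]

    if params.structure == "exp":
        d = pairwise_distances(coords).d
        effects = draw_gp_effects(rng, d, params.sigma_s2, params.theta, params.delta)
    elif params.structure == "icar":
        effects = draw_icar_effects(rng, weights, params.sigma_u2)
    else:
        effects = np.zeros(q)

    log_flux = mu + effects[:, None] + np.sqrt(params.sigma2) * rng.standard_normal((q, m))
    flux = np.maximum(np.exp(log_flux) - back_shift, 0.0)
    ds = from_arrays(coords, flux, covariates)
    return ds


def write_truth_sidecar(params: GenerativeParams, path) -> None:
    """True generative parameters, for parameter-recovery tests."""
    with open(path, "w") as fh:
        json.dump(asdict(params), fh, indent=2)


def simulate_dataset(
    config: DesignConfig,
    params: GenerativeParams | None = None,
    back_shift: float = 0.0,
) -> tuple[ChamberDataset, SpatialWeights]:
    """Layout + covariates + fluxes in one call (seed from the config)."""
    from .geometry import thiessen_adjacency

    params = params or GenerativeParams()
    coords = generate_layout(config)
    covs = generate_covariates(coords, config)
    weights = thiessen_adjacency(coords, config.boundary)
    ds = simulate_fluxes(
        coords, covs, params, weights=weights, seed=config.seed, back_shift=back_shift
    )
    return ds, weights
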