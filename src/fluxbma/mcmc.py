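"""Bespoke Gibbs/Metropolis samplers for the three flux-regression models.

All three models share the linear predictor

    y_ir = beta0 + x_ir' beta + (site effect) + eps_ir,  eps ~ N(0, sigma^2)

on log-transformed fluxes, and differ only in the site effect:

* independent - no site effect;
* exp (geostatistical) - s ~ GP(0, sigma_s^2 * exp[-(theta d_ij)^delta]),
  the exponential-decay correlation with delta fixed at 1;
* icar - u follows the intrinsic CAR prior on the Thiessen first-order
  neighbourhood, u_i | u_-i ~ N(mean of neighbours, sigma_u^2 / w_i+),
  identified by a sum-to-zero constraint.

Regression coefficients get diffuse N(0, 1e6) priors; standard deviations
get the uniform priors U(0,5) for sigma and U(0,10) for sigma_u (and
sigma_s), sampled by bounded slice sampling on the SD scale so no Jacobian
is needed. The decay rate theta gets a Uniform prior whose bounds put
correlation rho (default 0.05) at the maximum and minimum inter-site
distances; it is updated by adaptive random-walk Metropolis, with the
adaptation frozen after burn-in.

The deviance trace recorded for DIC conditions on the latent site effects
(the random-effects-focused deviance conventional for these hierarchical
models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

from .datasets import COVARIATES, ChamberDataset
from .geometry import DistanceMatrix, SpatialWeights, pairwise_distances

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# priors and configuration


def theta_prior_bounds(d_min: float, d_max: float, rho: float = 0.05) -> tuple[float, float]:
    """Uniform-prior bounds for the decay rate theta.

    The bounds are the theta values at which the exponential correlation
    exp(-theta d) equals ``rho`` at the maximum and minimum inter-site
    distances: theta_lo = -ln(rho)/d_max, theta_hi = -ln(rho)/d_min.
    """
    if not (0 < d_min < d_max):
        raise ValueError("require 0 < d_min < d_max")
    if not (0 < rho < 1):
        raise ValueError("require 0 < rho < 1")
    c = -np.log(rho)
    return c / d_max, c / d_min


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters shared by the three models."""

    beta_var: float = 1.0e6  # N(0, 1e6) on every coefficient incl. intercept
    sigma_bounds: tuple = (0.0, 5.0)  # sigma ~ U(0, 5)
    sigma_s_bounds: tuple = (0.0, 10.0)  # GP sd, mirroring sigma_u
    sigma_u_bounds: tuple = (0.0, 10.0)  # sigma_u ~ U(0, 10)
    theta_bounds: tuple | None = None  # derived from distances when None
    rho: float = 0.05
    delta: float = 1.0

    def resolve_theta_bounds(self, dist: DistanceMatrix) -> tuple[float, float]:
        if self.theta_bounds is not None:
            lo, hi = self.theta_bounds
            if not (0 < lo < hi):
                raise ValueError("theta bounds must satisfy 0 < lo < hi")
            return lo, hi
        return theta_prior_bounds(dist.d_min, dist.d_max, self.rho)


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 150_000
    burn_in: int = 50_000
    thin: int = 10
    seed: int = 0
    theta_step: float = 0.3  # initial RW-Metropolis sd for theta
    adapt_window: int = 100  # iterations between step-size adaptations

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws for one model fit."""

    model: str  # independent | exp | icar
    beta: np.ndarray  # (n, K+1), intercept first
    sigma2: np.ndarray  # (n,)
    effects: np.ndarray  # (n, Q); zeros for the independent model
    deviance: np.ndarray  # (n,)
    extra: dict = field(default_factory=dict)  # sigma_s2/theta or sigma_u2
    acceptance: dict = field(default_factory=dict)
    config: McmcConfig | None = None

    @property
    def n_draws(self) -> int:
        return len(self.sigma2)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"b_intercept": self.beta[:, 0]}
        for j, name in enumerate(COVARIATES):
            cols[f"b_{name}"] = self.beta[:, j + 1]
        cols["sigma2"] = self.sigma2
        for name, arr in self.extra.items():
            cols[name] = arr
        for i in range(self.effects.shape[1]):
            cols[f"effect_{i + 1}"] = self.effects[:, i]
        cols["deviance"] = self.deviance
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model: str) -> "PosteriorSamples":
        df = pd.read_csv(path)
        beta = df[["b_intercept"] + [f"b_{c}" for c in COVARIATES]].to_numpy()
        eff_cols = sorted(
            (c for c in df.columns if c.startswith("effect_")),
            key=lambda c: int(c.split("_")[1]),
        )
        extra = {
            k: df[k].to_numpy() for k in ("sigma_s2", "theta", "sigma_u2") if k in df
        }
        return cls(
            model=model,
            beta=beta,
            sigma2=df["sigma2"].to_numpy(),
            effects=df[eff_cols].to_numpy(),
            deviance=df["deviance"].to_numpy(),
            extra=extra,
        )


# --------------------------------------------------------------------------
# likelihood pieces and full conditionals (shared by samplers and tests)


def deviance(y: np.ndarray, mu: np.ndarray, sigma2: float) -> float:
    """-2 log N(y | mu, sigma2), summed over observations.

    Conditional on the site effects entering ``mu``.
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    rss = float(np.sum((y - mu) ** 2))
    n = y.size
    return n * (_LOG2PI + np.log(sigma2)) + rss / sigma2


def exp_correlation(d: np.ndarray | DistanceMatrix, theta: float, delta: float = 1.0) -> np.ndarray:
    """Exponential-decay correlation exp[-(theta d)^delta]."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    dm = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    return np.exp(-((theta * dm) ** delta))


def _chol_with_jitter(a: np.ndarray, jitter: float = 1e-8):
    try:
        return cholesky(a, lower=True)
    except np.linalg.LinAlgError:
        logger.warning("Cholesky failed; retrying with %.0e diagonal jitter", jitter)
        return cholesky(a + jitter * np.eye(len(a)), lower=True)


def beta_full_conditional(
    xmat: np.ndarray, resid: np.ndarray, sigma2: float, prior_var: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian full conditional of the coefficients.

    ``resid`` is y minus the site effects. Mean and covariance are the
    ridge/GLS forms (X'X/sigma2 + I/prior_var)^-1 X'resid/sigma2 and
    (X'X/sigma2 + I/prior_var)^-1.
    """
    p = xmat.shape[1]
    prec = xmat.T @ xmat / sigma2 + np.eye(p) / prior_var
    cov = np.linalg.inv(prec)
    mean = cov @ (xmat.T @ resid / sigma2)
    return mean, cov


def gp_effects_full_conditional(
    phi_inv: np.ndarray, sigma_s2: float, resid_site_sums: np.ndarray, n_rep: int, sigma2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian full conditional of the GP site effects s.

    Precision = Phi^-1/sigma_s2 + (M/sigma2) I; mean is the precision-
    weighted combination of the per-site residual sums.
    """
    q = len(resid_site_sums)
    prec = phi_inv / sigma_s2 + (n_rep / sigma2) * np.eye(q)
    cov = np.linalg.inv(prec)
    mean = cov @ (resid_site_sums / sigma2)
    return mean, cov


def icar_conditional(
    u: np.ndarray,
    i: int,
    w: np.ndarray,
    sigma_u2: float,
    resid_site_sum: float | None = None,
    n_rep: int = 0,
    sigma2: float = 1.0,
) -> tuple[float, float]:
    """Single-site conditional of u_i.

    Prior alone (``resid_site_sum=None``): N(weighted neighbour mean,
    sigma_u2 / w_i+) — the arithmetic neighbour average for binary weights.
    With a data term, the normal-normal combination with likelihood
    precision M/sigma2 and data mean the site residual average.
    """
    wi = w[i]
    w_plus = wi.sum()
    if w_plus <= 0:
        raise ValueError(f"site {i} has no neighbours")
    nb_mean = float(wi @ u) / w_plus
    prior_prec = w_plus / sigma_u2
    if resid_site_sum is None:
        return nb_mean, sigma_u2 / w_plus
    prec = prior_prec + n_rep / sigma2
    mean = (prior_prec * nb_mean + resid_site_sum / sigma2) / prec
    return mean, 1.0 / prec


def log_sigma_conditional(sigma: float, rss: float, n_obs: int) -> float:
    """Log full conditional of the residual SD under a flat prior on its
    bounded support (up to an additive constant)."""
    return -n_obs * np.log(sigma) - rss / (2.0 * sigma**2)


def log_sd_scale_conditional(sd: float, quad_form: float, rank: int) -> float:
    """Log conditional of a spatial-effect SD given the effect vector.

    ``quad_form`` is s'Phi^-1 s (GP) or u'(D-W)u (ICAR); ``rank`` is Q for
    the GP and Q-1 for the intrinsic prior.
    """
    return -rank * np.log(sd) - quad_form / (2.0 * sd**2)


def slice_sample_bounded(rng, log_f, x0: float, lo: float, hi: float, max_shrink: int = 200) -> float:
    """Shrinkage slice sampler on a bounded interval."""
    lo = max(lo, 1e-12)
    level = log_f(x0) + np.log(rng.uniform())
    left, right = lo, hi
    for _ in range(max_shrink):
        x1 = rng.uniform(left, right)
        if log_f(x1) >= level:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # numerically stuck slice: keep the current value


def _check_design(xmat: np.ndarray) -> None:
    """Reject only exact singularities (identical or all-zero columns).

    Compositional near-collinearity (sand+silt+clay ~ 100) is deliberately
    allowed through: the diffuse normal prior keeps the posterior proper.
    """
    names = ["intercept"] + list(COVARIATES[: xmat.shape[1] - 1])
    bad = []
    for j in range(xmat.shape[1]):
        if np.all(xmat[:, j] == 0):
            bad.append(f"{names[j]} (all zero)")
        for k in range(j + 1, xmat.shape[1]):
            if np.array_equal(xmat[:, j], xmat[:, k]):
                bad.append(f"{names[j]} == {names[k]}")
    if bad:
        raise ValueError("exactly singular design: " + "; ".join(bad))


def _draw_mvn(rng, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    return mean + _chol_with_jitter(cov) @ rng.standard_normal(len(mean))


# --------------------------------------------------------------------------
# samplers


def _init_state(y, xmat, prior_var):
    p = xmat.shape[1]
    prec = xmat.T @ xmat + np.eye(p) / prior_var
    beta = np.linalg.solve(prec, xmat.T @ y)
    resid = y - xmat @ beta
    sigma = float(np.clip(np.std(resid), 0.05, 4.9))
    return beta, sigma


def fit_independent(
    data: ChamberDataset,
    priors: Priors | None = None,
    config: McmcConfig | None = None,
) -> PosteriorSamples:
    """Gibbs sampler for the independent-errors regression."""
    priors = priors or Priors()
    config = config or McmcConfig()
    y, xmat, _ = data.design_matrix()
    _check_design(xmat)
    rng = np.random.default_rng(config.seed)
    n_obs = len(y)
    q = data.n_sites

    beta, sigma = _init_state(y, xmat, priors.beta_var)
    sig_lo, sig_hi = priors.sigma_bounds

    n_kept = config.n_kept
    out_beta = np.empty((n_kept, xmat.shape[1]))
    out_sigma2 = np.empty(n_kept)
    out_dev = np.empty(n_kept)
    kept = 0
    for it in range(config.n_iter):
        mean, cov = beta_full_conditional(xmat, y, sigma**2, priors.beta_var)
        beta = _draw_mvn(rng, mean, cov)
        rss = float(np.sum((y - xmat @ beta) ** 2))
        sigma = slice_sample_bounded(
            rng, lambda s: log_sigma_conditional(s, rss, n_obs), sigma, sig_lo, sig_hi
        )
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out_beta[kept] = beta
            out_sigma2[kept] = sigma**2
            out_dev[kept] = n_obs * (_LOG2PI + np.log(sigma**2)) + rss / sigma**2
            kept += 1
    return PosteriorSamples(
        model="independent",
        beta=out_beta,
        sigma2=out_sigma2,
        effects=np.zeros((n_kept, q)),
        deviance=out_dev,
        config=config,
    )


def fit_exp_geostat(
    data: ChamberDataset,
    dist: DistanceMatrix | None = None,
    priors: Priors | None = None,
    config: McmcConfig | None = None,
) -> PosteriorSamples:
    """Blocked sampler for the geostatistical (exponential-decay GP) model.

    beta and s have Gaussian full conditionals; sigma and sigma_s are
    slice-sampled on their bounded supports; theta uses adaptive random-walk
    Metropolis on its Uniform support (adaptation only during burn-in).
    """
    priors = priors or Priors()
    config = config or McmcConfig()
    dist = dist or pairwise_distances(data.coords)
    y, xmat, site_idx = data.design_matrix()
    _check_design(xmat)
    rng = np.random.default_rng(config.seed)
    n_obs, q, m = len(y), data.n_sites, data.n_replicates
    th_lo, th_hi = priors.resolve_theta_bounds(dist)
    sig_lo, sig_hi = priors.sigma_bounds
    ss_lo, ss_hi = priors.sigma_s_bounds

    # per-site aggregation operators for the flattened site-major layout
    xsite = np.stack([xmat[site_idx == i].sum(axis=0) for i in range(q)])  # (Q, p)

    beta, sigma = _init_state(y, xmat, priors.beta_var)
    s = np.zeros(q)
    sigma_s = min(1.0, 0.9 * ss_hi)
    theta = 0.5 * (th_lo + th_hi)
    step = config.theta_step
    phi = exp_correlation(dist, theta, priors.delta)
    try:
        phi_cf = cho_factor(phi, lower=True)
    except np.linalg.LinAlgError:
        phi_cf = cho_factor(phi + 1e-8 * np.eye(q), lower=True)
    logdet_phi = 2.0 * np.sum(np.log(np.diag(phi_cf[0])))

    n_kept = config.n_kept
    out = {
        "beta": np.empty((n_kept, xmat.shape[1])),
        "sigma2": np.empty(n_kept),
        "effects": np.empty((n_kept, q)),
        "sigma_s2": np.empty(n_kept),
        "theta": np.empty(n_kept),
        "deviance": np.empty(n_kept),
    }
    kept = acc = tries = 0
    acc_window = 0
    for it in range(config.n_iter):
        # --- theta | s, sigma_s (RW Metropolis on bounded support)
        prop = theta + step * rng.standard_normal()
        tries += 1
        if th_lo < prop < th_hi:
            phi_p = exp_correlation(dist, prop, priors.delta)
            try:
                cf_p = cho_factor(phi_p, lower=True)
            except np.linalg.LinAlgError:
                cf_p = cho_factor(phi_p + 1e-8 * np.eye(q), lower=True)
            logdet_p = 2.0 * np.sum(np.log(np.diag(cf_p[0])))
            quad_cur = float(s @ cho_solve(phi_cf, s))
            quad_p = float(s @ cho_solve(cf_p, s))
            log_ratio = -0.5 * (logdet_p - logdet_phi) - (quad_p - quad_cur) / (
                2.0 * sigma_s**2
            )
            if np.log(rng.uniform()) < log_ratio:
                theta, phi, phi_cf, logdet_phi = prop, phi_p, cf_p, logdet_p
                acc += 1
                acc_window += 1
        if it < config.burn_in and (it + 1) % config.adapt_window == 0:
            rate = acc_window / config.adapt_window
            step *= np.exp(rate - 0.35)  # frozen after burn-in
            acc_window = 0

        # --- s | rest (Gaussian full conditional)
        phi_inv = cho_solve(phi_cf, np.eye(q))
        resid_beta = y - xmat @ beta
        site_sums = np.bincount(site_idx, weights=resid_beta, minlength=q)
        mean_s, cov_s = gp_effects_full_conditional(
            phi_inv, sigma_s**2, site_sums, m, sigma**2
        )
        s = _draw_mvn(rng, mean_s, cov_s)

        # --- sigma_s | s, theta
        quad = float(s @ cho_solve(phi_cf, s))
        sigma_s = slice_sample_bounded(
            rng, lambda v: log_sd_scale_conditional(v, quad, q), sigma_s, ss_lo, ss_hi
        )

        # --- beta | s, sigma
        resid_s = y - s[site_idx]
        mean_b, cov_b = beta_full_conditional(xmat, resid_s, sigma**2, priors.beta_var)
        beta = _draw_mvn(rng, mean_b, cov_b)

        # --- sigma | rest
        rss = float(np.sum((resid_s - xmat @ beta) ** 2))
        sigma = slice_sample_bounded(
            rng, lambda v: log_sigma_conditional(v, rss, n_obs), sigma, sig_lo, sig_hi
        )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out["beta"][kept] = beta
            out["sigma2"][kept] = sigma**2
            out["effects"][kept] = s
            out["sigma_s2"][kept] = sigma_s**2
            out["theta"][kept] = theta
            out["deviance"][kept] = n_obs * (_LOG2PI + np.log(sigma**2)) + rss / sigma**2
            kept += 1

    return PosteriorSamples(
        model="exp",
        beta=out["beta"],
        sigma2=out["sigma2"],
        effects=out["effects"],
        deviance=out["deviance"],
        extra={"sigma_s2": out["sigma_s2"], "theta": out["theta"]},
        acceptance={"theta": acc / max(tries, 1)},
        config=config,
    )


def fit_icar(
    data: ChamberDataset,
    weights: SpatialWeights,
    priors: Priors | None = None,
    config: McmcConfig | None = None,
) -> PosteriorSamples:
    """Single-site Gibbs sampler for the intrinsic CAR model.

    u_i is updated from its normal conditional (ICAR prior blended with the
    site likelihood) in a fixed sweep order, then the whole vector is
    recentred to sum to zero; the intercept carries the level.
    """
    priors = priors or Priors()
    config = config or McmcConfig()
    if not weights.is_connected():
        raise ValueError(
            "adjacency graph is disconnected; the intrinsic CAR prior is "
            "undefined per component without extra constraints"
        )
    y, xmat, site_idx = data.design_matrix()
    _check_design(xmat)
    rng = np.random.default_rng(config.seed)
    n_obs, q, m = len(y), data.n_sites, data.n_replicates
    w = weights.w.astype(float)
    lap = np.diag(w.sum(axis=1)) - w
    sig_lo, sig_hi = priors.sigma_bounds
    su_lo, su_hi = priors.sigma_u_bounds

    beta, sigma = _init_state(y, xmat, priors.beta_var)
    u = np.zeros(q)
    sigma_u = 1.0

    n_kept = config.n_kept
    out = {
        "beta": np.empty((n_kept, xmat.shape[1])),
        "sigma2": np.empty(n_kept),
        "effects": np.empty((n_kept, q)),
        "sigma_u2": np.empty(n_kept),
        "deviance": np.empty(n_kept),
    }
    kept = 0
    for it in range(config.n_iter):
        resid_beta = y - xmat @ beta
        site_sums = np.bincount(site_idx, weights=resid_beta, minlength=q)

        # --- u sweep, then sum-to-zero recentring
        z = rng.standard_normal(q)
        for i in range(q):
            mean_i, var_i = icar_conditional(
                u, i, w, sigma_u**2, site_sums[i], m, sigma**2
            )
            u[i] = mean_i + np.sqrt(var_i) * z[i]
        u -= u.mean()

        # --- sigma_u | u  (pairwise-difference quadratic form, rank Q-1)
        ss_u = float(u @ lap @ u)
        sigma_u = slice_sample_bounded(
            rng, lambda v: log_sd_scale_conditional(v, ss_u, q - 1), sigma_u, su_lo, su_hi
        )

        # --- beta | u, sigma
        resid_u = y - u[site_idx]
        mean_b, cov_b = beta_full_conditional(xmat, resid_u, sigma**2, priors.beta_var)
        beta = _draw_mvn(rng, mean_b, cov_b)

        # --- sigma | rest
        rss = float(np.sum((resid_u - xmat @ beta) ** 2))
        sigma = slice_sample_bounded(
            rng, lambda v: log_sigma_conditional(v, rss, n_obs), sigma, sig_lo, sig_hi
        )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out["beta"][kept] = beta
            out["sigma2"][kept] = sigma**2
            out["effects"][kept] = u.copy()
            out["sigma_u2"][kept] = sigma_u**2
            out["deviance"][kept] = n_obs * (_LOG2PI + np.log(sigma**2)) + rss / sigma**2
            kept += 1

    return PosteriorSamples(
        model="icar",
        beta=out["beta"],
        sigma2=out["sigma2"],
        effects=out["effects"],
        deviance=out["deviance"],
        extra={"sigma_u2": out["sigma_u2"]},
        config=config,
    )


FITTERS = {
    "independent": fit_independent,
    "exp": fit_exp_geostat,
    "icar": fit_icar,
}


# --------------------------------------------------------------------------
# convergence diagnostics


def _autocorr(x: np.ndarray, lag: int) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.nan
    return float(x[:-lag] @ x[lag:]) / denom if lag < len(x) else np.nan


def convergence_report(samples: PosteriorSamples, lags=(1, 5, 10, 50)) -> pd.DataFrame:
    """Per-parameter autocorrelations, effective sample size and a
    split-chain stationarity z-score.

    Constant (degenerate) chains are flagged and get an undefined ESS.
    """
    import arviz as az

    df = samples.to_dataframe()
    if len(df) < 100:
        raise ValueError("need at least 100 retained draws for diagnostics")
    rows = []
    for col in df.columns:
        x = df[col].to_numpy()
        degenerate = bool(np.std(x) == 0)
        half = len(x) // 2
        a, b = x[:half], x[half:]
        denom = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        split_z = np.nan if denom == 0 else float((a.mean() - b.mean()) / denom)
        row = {
            "parameter": col,
            "mean": x.mean(),
            "sd": x.std(ddof=1),
            "ess": np.nan if degenerate else float(az.ess(x)),
            "split_z": split_z,
            "degenerate": degenerate,
        }
        for lag in lags:
            row[f"acf_{lag}"] = np.nan if degenerate else _autocorr(x, lag)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_traces(samples: PosteriorSamples, path, parameters=None) -> None:
    """Trace + autocorrelation panel per parameter, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = samples.to_dataframe()
    parameters = parameters or [c for c in df.columns if not c.startswith("effect_")]
    fig, axes = plt.subplots(len(parameters), 2, figsize=(9, 2.2 * len(parameters)), squeeze=False)
    for ax_row, col in zip(axes, parameters):
        x = df[col].to_numpy()
        ax_row[0].plot(x, lw=0.4)
        ax_row[0].set_ylabel(col, fontsize=8)
        nlags = min(60, len(x) - 1)
        acfs = [_autocorr(x, k) for k in range(1, nlags)]
        ax_row[1].bar(range(1, nlags), acfs, width=1.0)
        ax_row[1].set_ylim(-1, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
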