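"""DIC model comparison and DIC-weighted Bayesian model averaging.

DIC = Dbar + pD where Dbar is the posterior mean of the deviance trace and
pD = Dbar - D(posterior means) is the effective number of parameters.
Posterior model probabilities follow the information-criterion weight form

    p(M_l | D) = p(M_l) exp(-DIC_l / 2) / sum_m p(M_m) exp(-DIC_m / 2)

computed in log space with max-subtraction (DIC values of order 750 would
underflow a naive exponentiation). The averaged posterior predictive is a
mixture distribution: draws are resampled from each model in proportion to
its weight, so the mixture mean is the weight-average of model means while
between-model spread widens the predictive distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ChamberDataset
from .mcmc import PosteriorSamples, deviance


@dataclass(frozen=True)
class DicResult:
    model: str
    dbar: float  # posterior mean deviance
    d_at_mean: float  # deviance at the posterior means
    p_d: float  # effective number of parameters
    dic: float

    def __post_init__(self):
        if not np.isfinite([self.dbar, self.d_at_mean, self.p_d, self.dic]).all():
            raise ValueError("non-finite DIC components")


@dataclass(frozen=True)
class BmaResult:
    models: tuple
    prior_probs: np.ndarray
    posterior_probs: np.ndarray
    mixture_draws: np.ndarray  # (n_out, ...) averaged posterior draws
    component_means: np.ndarray  # (L, ...) per-model means of the input draws

    @property
    def mixture_mean(self) -> np.ndarray:
        return self.mixture_draws.mean(axis=0)


def compute_dic(samples: PosteriorSamples, data: ChamberDataset) -> DicResult:
    """Dbar, pD and DIC from a fit's deviance trace.

    D(posterior mean) plugs the posterior means of the coefficients, site
    effects and residual variance into the conditional deviance.
    """
    dev = samples.deviance
    bad = np.flatnonzero(~np.isfinite(dev))
    if bad.size:
        raise ValueError(f"non-finite deviance at retained iteration {bad[0]}")
    dbar = float(dev.mean())

    y, xmat, site_idx = data.design_matrix()
    beta_bar = samples.beta.mean(axis=0)
    eff_bar = samples.effects.mean(axis=0)
    sigma2_bar = float(samples.sigma2.mean())
    mu = xmat @ beta_bar + eff_bar[site_idx]
    d_at_mean = deviance(y, mu, sigma2_bar)
    p_d = dbar - d_at_mean
    return DicResult(
        model=samples.model, dbar=dbar, d_at_mean=d_at_mean, p_d=p_d, dic=dbar + p_d
    )


def bma_weights(
    dic_values, prior_probs=None
) -> np.ndarray:
    """Posterior model probabilities from information-criterion values.

    Accepts raw DIC numbers or :class:`DicResult` objects. Stable in log
    space: subtracting min(DIC) before exponentiation leaves the
    normalised weights unchanged.
    """
    dic = np.array(
        [d.dic if isinstance(d, DicResult) else float(d) for d in dic_values], float
    )
    if len(dic) < 2:
        raise ValueError("need at least two models to average")
    if prior_probs is None:
        prior_probs = np.full(len(dic), 1.0 / len(dic))
    prior_probs = np.asarray(prior_probs, float)
    if len(prior_probs) != len(dic):
        raise ValueError("one prior probability per model required")
    if abs(prior_probs.sum() - 1.0) > 1e-8 or np.any(prior_probs < 0):
        raise ValueError("prior probabilities must be non-negative and sum to 1")
    log_w = np.log(prior_probs, where=prior_probs > 0, out=np.full_like(prior_probs, -np.inf))
    log_w = log_w - (dic - dic.min()) / 2.0
    w = np.exp(log_w - log_w.max())
    return w / w.sum()


def bma_combine(
    per_model_draws: dict[str, np.ndarray],
    weights,
    prior_probs=None,
    n_out: int | None = None,
    seed: int = 0,
) -> BmaResult:
    """Mixture-average posterior draws across models.

    ``per_model_draws`` maps model tag -> draw array with sites (and any
    further axes) after axis 0; all arrays must share those trailing axes.
    Each output draw picks a model with probability equal to its weight and
    then one of that model's retained draws uniformly.
    """
    models = tuple(per_model_draws)
    weights = np.asarray(weights, float)
    if len(weights) != len(models):
        raise ValueError("one weight per model required")
    shapes = {per_model_draws[m].shape[1:] for m in models}
    if len(shapes) != 1:
        raise ValueError(f"misaligned site grids across models: {sorted(shapes)}")
    if prior_probs is None:
        prior_probs = np.full(len(models), 1.0 / len(models))

    n_out = n_out or max(per_model_draws[m].shape[0] for m in models)
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(models), size=n_out, p=weights / weights.sum())
    draws = np.empty((n_out,) + shapes.pop())
    for li, m in enumerate(models):
        idx = np.flatnonzero(picks == li)
        if idx.size:
            rows = rng.integers(0, per_model_draws[m].shape[0], size=idx.size)
            draws[idx] = per_model_draws[m][rows]
    comp_means = np.stack([per_model_draws[m].mean(axis=0) for m in models])
    return BmaResult(
        models=models,
        prior_probs=np.asarray(prior_probs, float),
        posterior_probs=weights / weights.sum(),
        mixture_draws=draws,
        component_means=comp_means,
    )


def dic_table(dics: list[DicResult], weights=None, prior_probs=None) -> pd.DataFrame:
    """CSV-ready model-comparison table (model, Dbar, pD, DIC, probs)."""
    if weights is None:
        weights = bma_weights(dics, prior_probs)
    if prior_probs is None:
        prior_probs = np.full(len(dics), 1.0 / len(dics))
    return pd.DataFrame(
        {
            "model": [d.model for d in dics],
            "Dbar": [d.dbar for d in dics],
            "pD": [d.p_d for d in dics],
            "DIC": [d.dic for d in dics],
            "prior_prob": prior_probs,
            "posterior_prob": weights,
        }
    )
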