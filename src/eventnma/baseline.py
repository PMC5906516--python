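"""Single-arm Bayesian meta-analysis of reference-treatment arms.

Absolute treatment effects need an absolute anchor: the probability (or rate)
of events on the reference regimen.  This module synthesises the reference
arms of the contributing trials on one of three scales:

* ``logit`` — ``r_i ~ Binomial(n_i, p_i)``, ``logit(p_i) = theta_i``: a
  time-free probability of at least one event over each study's own
  follow-up;
* ``cloglog`` — ``cloglog(p_i) = log(T_i) + theta_i``: ``theta`` is a log
  first-event hazard per year, so the summary converts to a probability over
  any horizon;
* ``log_rate`` — ``y_i ~ Poisson(E_i exp(theta_i))``: ``theta`` is a log
  event rate per person-year (repeat events counted).

Random effects place ``theta_i ~ Normal(m, sd_m^2)``; the reported baseline
uses the posterior of the summary mean ``m`` (not the wider predictive
distribution for a new study — available via ``predictive=True``).

Sampling is Metropolis-within-Gibbs over independent chains: adaptive
random-walk updates for the study effects (and for ``m`` under fixed
effects), an exact Gaussian Gibbs draw for ``m`` under random effects, and
an exact truncated-Gamma Gibbs draw for ``sd_m`` under its uniform prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._mcmc import (
    BlockAdapter,
    McmcSettings,
    convergence_warnings,
    diagnostics,
    sample_sigma_conditional,
)
from .data import EvidenceNetwork, RateArm, RiskArm
from .engine import PriorSpec
from .errors import ConfigurationError, DataError

BaselineScale = Literal["logit", "cloglog", "log_rate"]


@dataclass
class BaselineSamples:
    """Posterior draws from a baseline (single-arm) meta-analysis."""

    scale: BaselineScale
    m: np.ndarray  # summary mean draws (model scale)
    sd: np.ndarray | None  # between-study SD draws (random effects)
    theta: np.ndarray | None  # (ndraw, n_studies) study-level draws
    study_ids: tuple[str, ...]
    diagnostics: pd.DataFrame
    warnings: list[str]

    @property
    def n_draws(self) -> int:
        return self.m.shape[0]

    def probability_draws(self, t: float = 1.0, predictive: bool = False) -> np.ndarray:
        """Per-draw baseline probability of >=1 event by time ``t`` (years).

        On the logit scale ``t`` has no meaning and is ignored: the draw is
        the inverse-logit of ``m``, a probability over the contributing
        studies' own follow-ups.  On the hazard/rate scales the constant-rate
        transform ``p = 1 - exp(-exp(m) * t)`` applies.
        """
        if t < 0:
            raise ValueError(f"time horizon must be >= 0, got {t}")
        m = self.m
        if predictive:
            if self.sd is None:
                raise ConfigurationError("predictive draws need a random-effects fit")
            rng = np.random.default_rng(0)
            m = m + self.sd * rng.standard_normal(m.shape)
        if self.scale == "logit":
            return 1.0 / (1.0 + np.exp(-m))
        return -np.expm1(-np.exp(m) * t)

    def rate_draws(self) -> np.ndarray:
        """Per-draw baseline event rate (events/person-year); log_rate scale."""
        if self.scale != "log_rate":
            raise ConfigurationError(f"rate draws undefined on the {self.scale} scale")
        return np.exp(self.m)


def reference_arms(
    network: EvidenceNetwork, fmt: Literal["risk", "rate"], reference: int = 1
) -> list:
    """Reference-treatment arm records of every study that compares it."""
    arms = []
    for study in network.studies:
        for arm in study.arms_for(fmt):
            if arm.treatment_code == reference:
                arms.append(arm)
    return arms


def fit_baseline(
    arms: Sequence[RiskArm | RateArm],
    scale: BaselineScale,
    effects: Literal["fixed", "random"] = "random",
    priors: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> BaselineSamples:
    """Meta-analyse single arms on the chosen scale.

    Risk arms are required for ``logit``/``cloglog`` and rate arms for
    ``log_rate``; mixing formats is a configuration error.
    """
    if not arms:
        raise DataError("no arms supplied to the baseline meta-analysis")
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcSettings()
    if scale not in ("logit", "cloglog", "log_rate"):
        raise ConfigurationError(f"unknown baseline scale {scale!r}")
    want_risk = scale in ("logit", "cloglog")
    for a in arms:
        if want_risk and not isinstance(a, RiskArm):
            raise ConfigurationError(f"scale {scale!r} needs risk arms, got {type(a).__name__}")
        if not want_risk and not isinstance(a, RateArm):
            raise ConfigurationError(f"scale {scale!r} needs rate arms, got {type(a).__name__}")
    if effects not in ("fixed", "random"):
        raise ConfigurationError(f"unknown effects {effects!r}")

    S = len(arms)
    random_effects = effects == "random"
    study_ids = tuple(a.study_id for a in arms)

    if want_risk:
        r = np.asarray([a.events for a in arms], dtype=float)
        n = np.asarray([a.n for a in arms], dtype=float)
        logT = np.asarray([math.log(a.followup) for a in arms])
    else:
        y = np.asarray([a.events for a in arms], dtype=float)
        E = np.asarray([a.exposure for a in arms], dtype=float)
        logE = np.log(E)

    def loglik(theta: np.ndarray) -> np.ndarray:
        """(C, S) per-study log-likelihood."""
        theta = np.clip(theta, -60.0, 60.0)
        if scale == "logit":
            return r * theta - n * np.logaddexp(0.0, theta)
        if scale == "cloglog":
            h = np.exp(np.clip(logT + theta, -60.0, 30.0))
            return r * np.log(-np.expm1(-h)) - (n - r) * h
        return y * (logE + theta) - E * np.exp(theta)

    if scale == "logit":
        crude = np.log((r + 0.5) / (n - r + 0.5))
    elif scale == "cloglog":
        crude = np.log(-np.log1p(-(r + 0.5) / (n + 1.0))) - logT
    else:
        crude = np.log((y + 0.5) / E)

    C = mcmc.chains
    rng = np.random.default_rng(np.random.SeedSequence([int(mcmc.seed) % (2**31), 13]))
    m = float(crude.mean()) + 0.2 * rng.standard_normal(C)
    theta = crude[None, :] + 0.2 * rng.standard_normal((C, S))
    sd = rng.uniform(0.1, min(0.6, priors.sigma_upper), C)

    adapter = BlockAdapter(S if random_effects else 1, initial=0.3)
    n_iter = mcmc.burn + mcmc.draws * mcmc.thin
    keep_m = np.empty((C, mcmc.draws))
    keep_sd = np.empty((C, mcmc.draws))
    keep_theta = np.empty((C, mcmc.draws, S))
    kept = 0

    ll_cur = loglik(theta if random_effects else m[:, None].repeat(S, axis=1))

    for it in range(n_iter):
        adapting = it < mcmc.burn
        if random_effects:
            # study effects: adaptive random-walk Metropolis
            scales = adapter.scales
            prop = theta + scales[None, :] * rng.standard_normal((C, S))
            ll_prop = loglik(prop)
            log_ratio = (
                ll_prop - ll_cur
                - 0.5 * ((prop - m[:, None]) ** 2 - (theta - m[:, None]) ** 2)
                / sd[:, None] ** 2
            )
            accept = np.log(rng.random((C, S))) < log_ratio
            theta = np.where(accept, prop, theta)
            ll_cur = np.where(accept, ll_prop, ll_cur)
            # m: conditionally Gaussian
            prec = S / sd**2 + 1.0 / priors.mu_sd**2
            mean = theta.sum(axis=1) / sd**2 / prec
            m = mean + rng.standard_normal(C) / np.sqrt(prec)
            # sd: exact truncated-Gamma draw
            q = np.sum((theta - m[:, None]) ** 2, axis=1)
            sd = sample_sigma_conditional(q, S, priors.sigma_upper, rng)
        else:
            scales = adapter.scales
            prop = m + scales[0] * rng.standard_normal(C)
            ll_prop = loglik(prop[:, None].repeat(S, axis=1))
            log_ratio = (ll_prop - ll_cur).sum(axis=1) - 0.5 * (
                prop**2 - m**2
            ) / priors.mu_sd**2
            accept = np.log(rng.random(C)) < log_ratio
            m = np.where(accept, prop, m)
            ll_cur = np.where(accept[:, None], ll_prop, ll_cur)
        if adapting:
            adapter.record(
                accept.mean(axis=0) if random_effects else np.array([accept.mean()])
            )
            adapter.maybe_adapt()
        if it >= mcmc.burn and (it - mcmc.burn) % mcmc.thin == 0:
            keep_m[:, kept] = m
            keep_sd[:, kept] = sd
            keep_theta[:, kept] = theta
            kept += 1

    chains_by_param = {"m": keep_m}
    if random_effects:
        chains_by_param["sd_m"] = keep_sd
    diag = diagnostics(chains_by_param)
    return BaselineSamples(
        scale=scale,
        m=keep_m.reshape(-1),
        sd=keep_sd.reshape(-1) if random_effects else None,
        theta=keep_theta.reshape(-1, S) if random_effects else None,
        study_ids=study_ids,
        diagnostics=diag,
        warnings=convergence_warnings(diag),
    )


def baseline_probability(
    samples: BaselineSamples, t: float = 1.0, predictive: bool = False
) -> dict[str, float]:
    """Posterior mean and 95% CrI of the baseline event probability by ``t``.

    The transform is applied draw-wise before averaging, so for a concave
    transform (``1 - exp(-rt)``) the mean probability sits below the
    transform of the posterior-mean parameter (Jensen).
    """
    if t < 0:
        raise ValueError(f"time horizon must be >= 0, got {t}")
    p = samples.probability_draws(t=t, predictive=predictive)
    lo, hi = np.percentile(p, [2.5, 97.5])
    return {"mean": float(p.mean()), "ci_low": float(lo), "ci_high": float(hi)}
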