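"""MCMC utilities shared by the NMA engine and the baseline meta-analysis.

Both models are sampled with blocked Metropolis-within-Gibbs schemes (the
same structure WinBUGS/JAGS use for arm-based evidence synthesis): random-walk
Metropolis updates for the nonlinear likelihood blocks, exact Gaussian Gibbs
draws for parameters that are conditionally normal, and an exact
truncated-Gamma Gibbs draw for the between-study SD under its uniform prior.
Several independent chains run in parallel (vectorised over a leading chain
axis), which makes split-R-hat and ESS diagnostics meaningful.

The sampler contract the rest of the package relies on is about output
quality only: split-R-hat <= 1.05 and bulk ESS >= 400 for every reported
parameter; fits that miss it carry a warning rather than failing.  Identical
settings and seed reproduce identical draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

RHAT_LIMIT = 1.05
ESS_FLOOR = 400.0

# Robbins-Monro adaptation of proposal scales, burn-in only
ADAPT_INTERVAL = 25
ADAPT_RATE = 0.6
TARGET_ACCEPT = 0.35


@dataclass
class McmcSettings:
    """Sampler budget: independent chains, kept draws per chain, burn-in."""

    chains: int = 4
    draws: int = 3000
    burn: int = 1000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ConfigurationError("need at least 2 chains for diagnostics")
        if self.draws <= 0:
            raise ConfigurationError("draws must be positive")
        if self.burn < 0:
            raise ConfigurationError("burn-in cannot be negative")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")


def sample_sigma_conditional(
    q: np.ndarray, n_effects: int, upper: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact Gibbs draw of the heterogeneity SD given the effect deviations.

    With ``A = n_effects`` deviations whose conditional density contributes
    ``sigma^-A exp(-q / (2 sigma^2))`` and a ``Uniform(0, upper)`` prior, the
    precision ``tau = sigma^-2`` is Gamma((A-1)/2, rate q/2) truncated to
    ``tau >= upper^-2``; drawn by inverse-CDF.  For ``A == 1`` the Gamma shape
    degenerates and a fine grid draw is used instead.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    tau_min = upper**-2
    if n_effects >= 2:
        shape = (n_effects - 1) / 2.0
        scale = 2.0 / np.maximum(q, 1e-300)
        lo = stats.gamma.cdf(tau_min, shape, scale=scale)
        u = lo + rng.random(q.shape) * (1.0 - lo)
        tau = stats.gamma.ppf(np.clip(u, 1e-15, 1 - 1e-16), shape, scale=scale)
        return 1.0 / np.sqrt(np.maximum(tau, tau_min))
    # single-effect fallback: density sigma^-1 exp(-q/(2 sigma^2)) on (0, upper]
    grid = np.exp(np.linspace(np.log(upper) - 12, np.log(upper), 512))
    logd = -np.log(grid)[None, :] - q[:, None] / (2 * grid**2) + np.log(grid)[None, :]
    logd -= logd.max(axis=1, keepdims=True)
    cdf = np.cumsum(np.exp(logd), axis=1)
    cdf /= cdf[:, -1:]
    idx = (cdf < rng.random(q.shape)[:, None]).sum(axis=1)
    return grid[np.minimum(idx, len(grid) - 1)]


class BlockAdapter:
    """Per-block proposal scales tuned toward a target acceptance rate."""

    def __init__(self, n_blocks: int, initial: float = 0.3, target: float = TARGET_ACCEPT):
        self.log_s = np.full(n_blocks, np.log(initial))
        self.target = target
        self.accepted = np.zeros(n_blocks)
        self.tries = 0

    @property
    def scales(self) -> np.ndarray:
        return np.exp(self.log_s)

    def record(self, accepted: np.ndarray) -> None:
        self.accepted += accepted
        self.tries += 1

    def maybe_adapt(self) -> None:
        if self.tries >= ADAPT_INTERVAL:
            rate = self.accepted / self.tries
            self.log_s += ADAPT_RATE * (rate - self.target)
            np.clip(self.log_s, -6.0, 3.0, out=self.log_s)
            self.accepted[:] = 0.0
            self.tries = 0


def diagnostics(
    chains_by_param: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Split-R-hat, bulk ESS and Monte-Carlo SE per parameter.

    Each value is a ``(n_chains, n_draws)`` array of draws from independent
    chains; statistics come from :mod:`arviz`.
    """
    import arviz as az

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, x in chains_by_param.items():
            ess = float(az.ess(x))
            sd = float(x.std())
            rows.append(
                {
                    "parameter": name,
                    "rhat": float(az.rhat(x)),
                    "ess": ess,
                    "mcse_mean": sd / np.sqrt(ess) if ess > 0 else np.inf,
                }
            )
    return pd.DataFrame(rows).set_index("parameter")


def convergence_warnings(diag: pd.DataFrame) -> list[str]:
    out = []
    bad_rhat = diag[diag["rhat"] > RHAT_LIMIT]
    if len(bad_rhat):
        out.append(
            "split-R-hat > 1.05 for: "
            + ", ".join(f"{p} ({v:.3f})" for p, v in bad_rhat["rhat"].items())
        )
    bad_ess = diag[diag["ess"] < ESS_FLOOR]
    if len(bad_ess):
        out.append(
            "bulk ESS < 400 for: "
            + ", ".join(f"{p} ({v:.0f})" for p, v in bad_ess["ess"].items())
        )
    return out
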