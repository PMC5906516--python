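"""Absolute event probabilities, rankings, expected costs and disutilities.

Relative effects only become decision-relevant once they are anchored to an
absolute baseline.  This module combines baseline-meta-analysis draws with
NMA relative-effect draws, draw-wise and on matching scales:

* logit:    ``logit(p_k)   = logit(p_1)   + d_k``  (odds ratios applied)
* cloglog:  ``cloglog(p_k) = cloglog(p_1) + d_k``  i.e. ``p_k = 1-(1-p_1)^HR``
* log-rate: ``r_k = r_1 * exp(d_k)`` then ``p_k = 1 - exp(-r_k t)``

The two posteriors come from separate models, so their draws are paired
independently after resampling to a common length with a fixed seed.

Economic propagation is deliberately simple, mirroring common practice in
health-economic models of adverse events: a per-event cost and a per-
event-experiencer utility decrement are multiplied by the probability of
having at least one event.  Note this understates the cost of repeat events;
an events-based cost (``cost * r * t``, rate scale only) is available but off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .baseline import BaselineSamples
from .engine import PosteriorSamples
from .errors import ConfigurationError


@dataclass
class EconomicInputs:
    """Per-event cost, per-experiencer utility decrement, and time horizon."""

    cost_per_event: float = 333.0  # GBP per severe hypoglycaemic event
    utility_decrement: float = -0.012  # utility per event-experiencer per year
    horizon: float = 1.0  # years

    def __post_init__(self) -> None:
        if not self.horizon > 0:
            raise ConfigurationError("time horizon must be positive")


def rate_to_probability(rate, t):
    """Constant-rate conversion ``p = 1 - exp(-r t)``.

    Vectorised over either argument; negative rates or times are domain
    errors.
    """
    rate = np.asarray(rate, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rates must be non-negative")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    p = -np.expm1(-rate * t)
    return p if p.shape else float(p)


_SCALE_COMPAT = {
    "logit": {"binomial_logit"},
    "cloglog": {"binomial_cloglog", "shared"},
    "log_rate": {"poisson_log", "shared", "binomial_cloglog"},
}


def combine_absolute(
    baseline: BaselineSamples,
    relative: PosteriorSamples,
    inputs: EconomicInputs | None = None,
    n_draws: int = 4000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-treatment absolute event-probability draws by the horizon.

    The baseline scale must match the relative-effect model's scale (logit
    baseline with the logit NMA; cloglog/log-rate baselines with the
    log-hazard NMAs).  Returns a DataFrame of draws, one column per
    treatment code.
    """
    inputs = inputs or EconomicInputs()
    if relative.d is None:
        raise ConfigurationError("absolute outcomes need a consistency fit")
    if relative.spec.likelihood not in _SCALE_COMPAT[baseline.scale]:
        raise ConfigurationError(
            f"baseline scale {baseline.scale!r} does not match the "
            f"{relative.spec.likelihood!r} model's effect scale"
        )
    rng = np.random.default_rng(seed)
    ib = rng.integers(0, baseline.n_draws, size=n_draws)
    ir = rng.integers(0, relative.n_draws, size=n_draws)
    m = baseline.m[ib]
    d = relative.d[ir, :]
    t = inputs.horizon

    if baseline.scale == "logit":
        eta = m[:, None] + d
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -60, 60)))
    else:
        # m is a log hazard (cloglog) or log rate (log_rate): identical algebra
        log_rate_k = np.clip(m[:, None] + d, -60, 60)
        p = -np.expm1(-np.exp(log_rate_k) * t)
    return pd.DataFrame(p, columns=list(relative.treatment_codes))


def rank_treatments(
    effect_draws: pd.DataFrame, lower_is_better: bool = True
) -> pd.DataFrame:
    """Median rank and 95% CrI per treatment from per-draw effect values.

    Rank 1 is the best treatment (fewest events when ``lower_is_better``).
    Ties within a draw are broken deterministically by treatment code.
    """
    if effect_draws.shape[1] < 2:
        raise ConfigurationError("ranking needs at least two treatments")
    codes = np.asarray(effect_draws.columns, dtype=int)
    values = effect_draws.to_numpy()
    if not lower_is_better:
        values = -values
    # lexsort: primary key value, secondary key treatment code
    order = np.lexsort((np.broadcast_to(codes, values.shape), values), axis=1)
    ranks = np.empty_like(order)
    draw_idx = np.arange(values.shape[0])[:, None]
    ranks[draw_idx, order] = np.arange(1, values.shape[1] + 1)
    rows = []
    for j, code in enumerate(codes):
        lo, med, hi = np.percentile(ranks[:, j], [2.5, 50.0, 97.5])
        rows.append(
            {
                "treatment_code": int(code),
                "median_rank": int(round(med)),
                "rank_low": int(np.floor(lo)),
                "rank_high": int(np.ceil(hi)),
            }
        )
    return pd.DataFrame(rows).set_index("treatment_code")


def _summaries(draws: np.ndarray) -> dict[str, float]:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {"mean": float(draws.mean()), "ci_low": float(lo), "ci_high": float(hi)}


def expected_cost(
    probability_draws: pd.DataFrame | np.ndarray, inputs: EconomicInputs | None = None
) -> pd.DataFrame:
    """Expected per-patient event cost: ``cost_per_event * p`` draw-wise."""
    inputs = inputs or EconomicInputs()
    df = pd.DataFrame(probability_draws)
    rows = {
        code: _summaries(inputs.cost_per_event * df[code].to_numpy())
        for code in df.columns
    }
    out = pd.DataFrame(rows).T
    out.index.name = "treatment_code"
    return out


def expected_disutility(
    probability_draws: pd.DataFrame | np.ndarray, inputs: EconomicInputs | None = None
) -> pd.DataFrame:
    """Expected utility decrement: ``utility_decrement * p`` draw-wise."""
    inputs = inputs or EconomicInputs()
    df = pd.DataFrame(probability_draws)
    rows = {
        code: _summaries(inputs.utility_decrement * df[code].to_numpy())
        for code in df.columns
    }
    out = pd.DataFrame(rows).T
    out.index.name = "treatment_code"
    return out


def events_based_cost(
    baseline: BaselineSamples,
    relative: PosteriorSamples,
    inputs: EconomicInputs | None = None,
    n_draws: int = 4000,
    seed: int = 0,
) -> pd.DataFrame:
    """Optional cost per *expected events* (``cost * r * t``), rate scale only.

    Unlike the probability-based cost this accounts for repeat events; it is
    provided for sensitivity analysis and is not used by default.
    """
    inputs = inputs or EconomicInputs()
    if baseline.scale != "log_rate":
        raise ConfigurationError("events-based costs need a log-rate baseline")
    if relative.d is None:
        raise ConfigurationError("events-based costs need a consistency fit")
    rng = np.random.default_rng(seed)
    ib = rng.integers(0, baseline.n_draws, size=n_draws)
    ir = rng.integers(0, relative.n_draws, size=n_draws)
    rates = np.exp(np.clip(baseline.m[ib][:, None] + relative.d[ir, :], -60, 60))
    draws = inputs.cost_per_event * rates * inputs.horizon
    rows = {
        code: _summaries(draws[:, j])
        for j, code in enumerate(relative.treatment_codes)
    }
    out = pd.DataFrame(rows).T
    out.index.name = "treatment_code"
    return out


def outcome_table(
    baseline: BaselineSamples,
    relative: PosteriorSamples,
    inputs: EconomicInputs | None = None,
    labels: Mapping[int, str] | None = None,
    model: str = "",
    n_draws: int = 4000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-treatment probability / rank / cost / disutility summary table."""
    inputs = inputs or EconomicInputs()
    p = combine_absolute(baseline, relative, inputs, n_draws=n_draws, seed=seed)
    ranks = rank_treatments(p, lower_is_better=True)
    cost = expected_cost(p, inputs)
    disu = expected_disutility(p, inputs)
    rows = []
    for code in p.columns:
        prob = _summaries(p[code].to_numpy())
        rows.append(
            {
                "treatment_code": int(code),
                "label": (labels or {}).get(int(code), str(code)),
                "model": model,
                "probability_mean": prob["mean"],
                "probability_low": prob["ci_low"],
                "probability_high": prob["ci_high"],
                "median_rank": ranks.loc[int(code), "median_rank"],
                "rank_low": ranks.loc[int(code), "rank_low"],
                "rank_high": ranks.loc[int(code), "rank_high"],
                "cost_mean": cost.loc[code, "mean"],
                "cost_low": cost.loc[code, "ci_low"],
                "cost_high": cost.loc[code, "ci_high"],
                "disutility_mean": disu.loc[code, "mean"],
                "disutility_low": disu.loc[code, "ci_low"],
                "disutility_high": disu.loc[code, "ci_high"],
            }
        )
    return pd.DataFrame(rows).set_index("treatment_code")
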