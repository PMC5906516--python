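"""Deviance-based model criticism: residual deviance, pD and DIC.

The residual (saturated) deviance compares each data point with its fitted
value; in a well-fitting model its posterior mean is close to the number of
data points.  The effective number of parameters ``pD`` is computed with the
classic plug-in: posterior mean deviance minus the deviance at the posterior
mean of the fitted values (the WinBUGS convention), and ``DIC = Dbar + pD``.

Selection rule: lowest DIC wins, but differences smaller than 3 are not
considered meaningful and the simpler model is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import PosteriorSamples
from .errors import ComparisonError, EventNmaError

DIC_MEANINGFUL_DIFFERENCE = 3.0


def _xlogx_over(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """``a * log(a / b)`` with the ``0 * log 0 = 0`` convention."""
    a, b = np.broadcast_arrays(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    out = np.zeros(a.shape)
    nz = a > 0
    out[nz] = a[nz] * np.log(a[nz] / b[nz])
    return out


def deviance_binomial(r, n, p_hat) -> np.ndarray | float:
    """Per-point saturated binomial deviance.

    ``dev = 2 [ r log(r / (n p)) + (n - r) log((n - r) / (n - n p)) ]`` with
    zero-count terms defined by the ``0 log 0 = 0`` convention.  ``p_hat``
    must lie strictly inside (0, 1).
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("fitted probabilities must lie strictly in (0, 1)")
    if np.any((r < 0) | (r > n)):
        raise ValueError("need 0 <= r <= n")
    dev = 2.0 * (_xlogx_over(r, n * p) + _xlogx_over(n - r, n * (1.0 - p)))
    return dev if dev.shape else float(dev)


def deviance_poisson(y, theta_hat) -> np.ndarray | float:
    """Per-point saturated Poisson deviance.

    ``dev = 2 [ (theta - y) + y log(y / theta) ]`` with ``0 log 0 = 0``;
    ``theta_hat`` is the fitted mean count and must be positive.
    """
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta_hat, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("fitted mean counts must be positive")
    if np.any(y < 0):
        raise ValueError("event counts cannot be negative")
    dev = 2.0 * ((theta - y) + _xlogx_over(y, theta))
    return dev if dev.shape else float(dev)


@dataclass
class FitStatistics:
    """Posterior deviance summaries for one fitted model."""

    dbar: float  # posterior mean residual deviance
    pd: float  # effective number of parameters
    dic: float  # dbar + pd
    n_datapoints: int
    per_point: pd.DataFrame  # study_id, treatment_code, kind, deviance
    model: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "dbar": self.dbar,
            "pD": self.pd,
            "DIC": self.dic,
            "n_datapoints": self.n_datapoints,
            "per_point": self.per_point.to_dict(orient="records"),
        }


def _point_deviances(points: pd.DataFrame, fitted: np.ndarray) -> np.ndarray:
    """(ndraw, n_points) deviance contributions."""
    dev = np.empty_like(fitted)
    kind = points["kind"].to_numpy()
    obs = points["observed"].to_numpy(dtype=float)
    size = points["size"].to_numpy(dtype=float)
    risk = kind == "risk"
    if risk.any():
        dev[:, risk] = deviance_binomial(obs[risk], size[risk], fitted[:, risk])
    rate = ~risk
    if rate.any():
        dev[:, rate] = deviance_poisson(obs[rate], fitted[:, rate])
    return dev


def compute_fit(samples: PosteriorSamples, model: str | None = None) -> FitStatistics:
    """Residual deviance, pD and DIC from a fit's per-draw fitted values."""
    if samples.fitted is None or samples.fitted.size == 0:
        raise EventNmaError("posterior samples carry no fitted values")
    points = samples.points
    dev = _point_deviances(points, samples.fitted)
    per_point_mean = dev.mean(axis=0)
    dbar = float(per_point_mean.sum())

    mean_fitted = samples.fitted.mean(axis=0, keepdims=True)
    d_at_mean = float(_point_deviances(points, mean_fitted).sum())
    p_d = dbar - d_at_mean

    per_point = points[["study_id", "treatment_code", "kind"]].copy()
    per_point["deviance"] = per_point_mean
    label = model if model is not None else (
        f"{samples.spec.likelihood}/{samples.spec.effects}/{samples.spec.structure}"
    )
    return FitStatistics(
        dbar=dbar,
        pd=p_d,
        dic=dbar + p_d,
        n_datapoints=len(points),
        per_point=per_point,
        model=label,
    )


def compare_models(fits: Sequence[FitStatistics]) -> tuple[FitStatistics, pd.DataFrame]:
    """Select a model by DIC with the <3 parsimony rule.

    ``fits`` must be ordered from simplest to most complex and computed on
    the same data points.  The lowest-DIC model wins unless a simpler model
    is within 3 DIC of it, in which case the earliest such model is selected.
    """
    if len(fits) < 2:
        raise ComparisonError("need at least two fits to compare")
    n0 = fits[0].n_datapoints
    if any(f.n_datapoints != n0 for f in fits):
        raise ComparisonError(
            "fits cover different numbers of data points: "
            + ", ".join(f"{f.model}={f.n_datapoints}" for f in fits)
        )
    best = min(f.dic for f in fits)
    selected = next(f for f in fits if f.dic < best + DIC_MEANINGFUL_DIFFERENCE)
    table = pd.DataFrame(
        [
            {
                "model": f.model,
                "Dbar": f.dbar,
                "pD": f.pd,
                "DIC": f.dic,
                "selected": f is selected,
            }
            for f in fits
        ]
    )
    return selected, table


def inconsistency_flag(
    consistency: FitStatistics, inconsistency: FitStatistics
) -> bool:
    """True when the inconsistency model materially improves fit.

    Flags potential inconsistency when the unrelated-effects model has a
    meaningfully smaller posterior mean residual deviance or DIC.
    """
    return (
        inconsistency.dic < consistency.dic - DIC_MEANINGFUL_DIFFERENCE
        or inconsistency.dbar < consistency.dbar - DIC_MEANINGFUL_DIFFERENCE
    )
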