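"""Synthetic trial networks from a homogeneous Poisson event process.

The generator emulates the structure of a basal-insulin severe-hypoglycaemia
evidence base: ~20 mostly two-arm studies of 8 regimens linked through a
common reference treatment (code 1), with some studies reporting the outcome
as a risk (patients with >=1 event), some as a rate (events per person-year)
and some as both.

The central design commitment is that **per-patient Poisson event counts are
the single latent source for both reporting formats**: an arm's risk summary
``r`` counts the patients whose latent count is >= 1, and its rate summary
``y`` sums the same latent counts over exposure ``E = n * T``.  A study that
reports both formats therefore reports two views of the same events, which is
exactly the coherence the shared-parameter model assumes.

By default every patient in an arm shares the arm's rate, making the process
exactly homogeneous.  Real severe-hypoglycaemia data concentrate events in a
small prone subgroup, which depresses the first-event hazard well below the
event rate; the optional ``patient_frailty_shape`` reproduces that with a
mean-one gamma frailty per patient (the arm's event *rate* is unchanged, so
rate-format summaries are unaffected in expectation).

Ground truth (basic log hazard ratios ``d``, heterogeneity ``sigma``, study
baselines ``mu_i``, per-arm rates ``lambda_ik``) is carried alongside the
network for recovery tests.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
import numpy as np

from .data import EvidenceNetwork, RateArm, RiskArm, Study, Treatment, write_network
from .errors import ConfigurationError

# Reference-arm severe-hypoglycaemia rate used throughout: 0.38 events per
# person-year on the reference basal-insulin regimen.
DEFAULT_BASELINE_RATE = 0.38
MIN_FOLLOWUP_YEARS = 4.0 / 52.18  # 4 weeks


@dataclass
class GeneratorConfig:
    """Study-condition knobs for :func:`simulate_network`.

    ``true_log_hr`` has one entry per treatment with ``true_log_hr[0] = 0``
    (the reference).  ``format_mix`` gives the number of studies reporting
    (both, risk only, rate only).  Follow-up is drawn log-uniformly by default
    so that short trials dominate, as they do in real severe-hypoglycaemia
    evidence bases (a few weeks to two years, averaging well under a year).
    """

    n_treatments: int = 8
    n_studies: int = 20
    true_log_hr: tuple[float, ...] = (0.0, -0.30, -0.20, -0.10, 0.05, 0.10, 0.20, 0.30)
    true_sigma: float = 0.3
    baseline_lograte_mean: float = math.log(DEFAULT_BASELINE_RATE)
    baseline_lograte_sd: float = 0.8
    followup_range: tuple[float, float] = (MIN_FOLLOWUP_YEARS, 2.0)
    followup_distribution: str = "log_uniform"  # or "uniform"
    n_range: tuple[int, int] = (50, 500)
    format_mix: tuple[int, int, int] = (12, 4, 4)  # (both, risk_only, rate_only)
    arms_per_study: int = 2
    comparisons: tuple[tuple[int, ...], ...] | None = None  # explicit per-study designs
    patient_frailty_shape: float | None = None  # None: identical patients
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatments < 2:
            raise ConfigurationError("need at least two treatments")
        if len(self.true_log_hr) != self.n_treatments:
            raise ConfigurationError(
                f"true_log_hr has {len(self.true_log_hr)} entries for "
                f"{self.n_treatments} treatments"
            )
        if abs(self.true_log_hr[0]) > 0:
            raise ConfigurationError("true_log_hr[0] is the reference and must be 0")
        if self.true_sigma < 0:
            raise ConfigurationError("true_sigma must be >= 0")
        if sum(self.format_mix) != self.n_studies or any(m < 0 for m in self.format_mix):
            raise ConfigurationError(
                f"format_mix {self.format_mix} must be non-negative and sum to "
                f"n_studies={self.n_studies}"
            )
        if self.n_studies < 1:
            raise ConfigurationError("need at least one study")
        if not self.followup_range[0] > 0:
            raise ConfigurationError("minimum follow-up must be positive")
        if self.followup_range[1] < self.followup_range[0]:
            raise ConfigurationError("followup_range must be (min, max)")
        if self.arms_per_study not in (2, 3):
            raise ConfigurationError("arms_per_study must be 2 or 3")
        if self.patient_frailty_shape is not None and self.patient_frailty_shape <= 0:
            raise ConfigurationError("patient_frailty_shape must be positive")
        if self.comparisons is not None and len(self.comparisons) != self.n_studies:
            raise ConfigurationError("comparisons must list one design per study")


@dataclass
class SimulatedNetwork:
    """A generated evidence network plus the ground truth that produced it."""

    network: EvidenceNetwork
    true_log_hr: tuple[float, ...]
    true_sigma: float
    study_mu: dict[str, float]  # per-study baseline log rate
    arm_rates: dict[str, dict[int, float]]  # study -> treatment -> true rate/PY
    config: GeneratorConfig = field(repr=False)

    def write(self, directory: str | os.PathLike) -> None:
        """Write the CSV tables plus a ``truth.json`` ground-truth sidecar."""
        write_network(self.network, directory)
        truth = {
            "seed": self.config.seed,
            "true_log_hr": list(self.true_log_hr),
            "true_sigma": self.true_sigma,
            "study_mu": self.study_mu,
            "arm_rates": {s: {str(k): v for k, v in d.items()} for s, d in self.arm_rates.items()},
        }
        with open(os.path.join(directory, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1)


def paper_like_config(seed: int = 0) -> GeneratorConfig:
    """The default study conditions: 8 regimens, 20 two-arm studies.

    Twelve studies report both formats, four risk only and four rate only;
    follow-up spans 4 weeks to 2 years (log-uniform, mean ~7 months); the
    reference-arm event rate is centred on 0.38 events/person-year with
    substantial between-study spread; true effects are small
    (|log HR| <= 0.3) with between-study SD 0.3 on the log-hazard scale.
    """
    return GeneratorConfig(seed=seed)


def _study_designs(config: GeneratorConfig, rng: np.random.Generator) -> list[tuple[int, ...]]:
    if config.comparisons is not None:
        return [tuple(c) for c in config.comparisons]
    # Reference-centred network: every study includes treatment 1, and the
    # non-reference treatments cycle so each is compared at least twice.
    others = list(range(2, config.n_treatments + 1))
    designs = []
    for i in range(config.n_studies):
        t = others[i % len(others)]
        if config.arms_per_study == 2:
            designs.append((1, t))
        else:
            extra = others[(i + 1) % len(others)]
            if extra == t:
                extra = others[(i + 2) % len(others)]
            designs.append((1, t, extra))
    return designs


def simulate_network(config: GeneratorConfig) -> SimulatedNetwork:
    """Generate one evidence network under a homogeneous Poisson process.

    Per study ``i`` with baseline treatment ``b`` (the lowest code present):
    ``mu_i ~ Normal(baseline_lograte_mean, baseline_lograte_sd^2)`` and, for
    each non-baseline arm ``k``, a study-specific effect
    ``delta_ik ~ Normal(d_k - d_b, sigma^2)`` (compound-symmetry correlation
    0.5 between arms of a multi-arm study).  Arm rates are
    ``lambda = exp(mu_i + delta)``.  Each of the ``n`` patients contributes a
    latent count ``~ Poisson(lambda * T_i)``; the risk summary binarises the
    counts and the rate summary sums them.  The same seed reproduces the same
    network bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    d = np.asarray(config.true_log_hr, dtype=float)
    designs = _study_designs(config, rng)

    formats = (
        ["both"] * config.format_mix[0]
        + ["risk"] * config.format_mix[1]
        + ["rate"] * config.format_mix[2]
    )
    formats = list(rng.permutation(formats))

    width = max(2, len(str(config.n_studies)))
    lo_t, hi_t = config.followup_range
    studies: list[Study] = []
    study_mu: dict[str, float] = {}
    arm_rates: dict[str, dict[int, float]] = {}

    for i, (design, fmt) in enumerate(zip(designs, formats)):
        sid = f"S{i + 1:0{width}d}"
        if config.followup_distribution == "uniform":
            T = float(rng.uniform(lo_t, hi_t))
        elif config.followup_distribution == "log_uniform":
            T = float(np.exp(rng.uniform(np.log(lo_t), np.log(hi_t))))
        else:
            raise ConfigurationError(
                f"unknown followup_distribution {config.followup_distribution!r}"
            )
        mu_i = float(rng.normal(config.baseline_lograte_mean, config.baseline_lograte_sd))
        baseline = min(design)

        # Study-level effects: sequential conditional construction of the
        # compound-symmetry multivariate normal around the consistency means.
        deltas: dict[int, float] = {baseline: 0.0}
        prev: list[float] = []
        prev_means: list[float] = []
        for t in design:
            if t == baseline:
                continue
            mean_t = d[t - 1] - d[baseline - 1]
            j = len(prev)
            cond_mean = mean_t + sum(p - m for p, m in zip(prev, prev_means)) / (j + 1)
            cond_sd = config.true_sigma * math.sqrt((j + 2) / (2 * (j + 1)))
            delta = float(rng.normal(cond_mean, cond_sd)) if config.true_sigma > 0 else mean_t
            deltas[t] = delta
            prev.append(delta)
            prev_means.append(mean_t)

        risk_arms = []
        rate_arms = []
        arm_rates[sid] = {}
        study_mu[sid] = mu_i
        for t in sorted(design):
            lam = math.exp(mu_i + deltas[t])
            arm_rates[sid][t] = lam
            n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
            if config.patient_frailty_shape is None:
                counts = rng.poisson(lam * T, size=n)
            else:
                # event-prone-patient heterogeneity: each patient's personal
                # rate is lam * G with G ~ Gamma(k, 1/k) (mean 1), so the arm
                # event rate stays lam while the first-event hazard drops to
                # k*log(1 + lam*T/k)/T -- events cluster in few patients
                k = config.patient_frailty_shape
                counts = rng.poisson(lam * T * rng.gamma(k, 1.0 / k, size=n))
            if fmt in ("both", "risk"):
                risk_arms.append(
                    RiskArm(sid, t, events=int((counts >= 1).sum()), n=n, followup=T)
                )
            if fmt in ("both", "rate"):
                rate_arms.append(
                    RateArm(sid, t, events=int(counts.sum()), exposure=n * T)
                )
        studies.append(Study(sid, tuple(risk_arms), tuple(rate_arms)))

    treatments = {
        k: Treatment(k, "glargine (once)" if k == 1 else f"regimen {k}")
        for k in range(1, config.n_treatments + 1)
    }
    network = EvidenceNetwork(treatments=treatments, studies=studies)
    return SimulatedNetwork(
        network=network,
        true_log_hr=tuple(config.true_log_hr),
        true_sigma=config.true_sigma,
        study_mu=study_mu,
        arm_rates=arm_rates,
        config=config,
    )
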