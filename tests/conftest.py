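import warnings

import numpy as np
import pytest

from eventnma import (
    EvidenceNetwork,
    McmcSettings,
    ModelSpec,
    PosteriorSamples,
    RateArm,
    RiskArm,
    Study,
    Treatment,
    paper_like_config,
    simulate_network,
)

warnings.filterwarnings("ignore", category=FutureWarning)


def fast_mcmc(seed: int = 0, draws: int = 1200, burn: int = 600) -> McmcSettings:
    """Sampler settings sized for small unit-test posteriors."""
    return McmcSettings(draws=draws, burn=burn, seed=seed)


@pytest.fixture(scope="session")
def paper_like_sim():
    """One paper-like synthetic network (8 regimens, 20 studies) with truth."""
    return simulate_network(paper_like_config(seed=2018))


@pytest.fixture
def two_treatment_rate_network():
    """Single two-arm rate study with a 2:1 event-rate contrast."""
    study = Study(
        "A",
        rate_arms=(RateArm("A", 1, 100, 100.0), RateArm("A", 2, 50, 100.0)),
    )
    return EvidenceNetwork(
        {1: Treatment(1, "reference"), 2: Treatment(2, "comparator")}, [study]
    )


@pytest.fixture
def two_treatment_risk_network():
    """Single two-arm risk study with log odds ratio log(3.5)."""
    study = Study(
        "A",
        risk_arms=(
            RiskArm("A", 1, 300, 1000, 1.0),
            RiskArm("A", 2, 600, 1000, 1.0),
        ),
    )
    return EvidenceNetwork(
        {1: Treatment(1, "reference"), 2: Treatment(2, "comparator")}, [study]
    )


def degenerate_posterior(
    d_by_treatment: dict[int, np.ndarray], likelihood: str = "binomial_cloglog"
) -> PosteriorSamples:
    """Fabricate a consistency posterior with given basic-parameter draws."""
    import pandas as pd

    codes = sorted(d_by_treatment)
    d = np.column_stack([np.asarray(d_by_treatment[c], dtype=float) for c in codes])
    ndraw = d.shape[0]
    return PosteriorSamples(
        spec=ModelSpec(likelihood=likelihood),
        treatment_codes=tuple(codes),
        reference=codes[0],
        d=d,
        comparisons=None,
        d_comparison=None,
        sigma=None,
        mu=np.zeros((ndraw, 1)),
        study_ids=("S",),
        points=pd.DataFrame(
            {"study_id": [], "treatment_code": [], "kind": [], "link": [],
             "observed": [], "size": []}
        ),
        fitted=np.zeros((ndraw, 0)),
        diagnostics=pd.DataFrame(columns=["rhat", "ess", "mcse_mean"]),
        warnings=[],
        acceptance=1.0,
    )
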