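"""NMA engine: MLE limits, scale agreement, structures, determinism, oracle."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from eventnma import (
    EvidenceNetwork,
    McmcSettings,
    ModelSpec,
    RateArm,
    RiskArm,
    Study,
    Treatment,
    edge_effects,
    fit_inconsistency,
    fit_nma,
    relative_effects,
)
from eventnma.errors import CodingError, ConfigurationError, EstimabilityError
from eventnma.simulate import GeneratorConfig, simulate_network

from conftest import degenerate_posterior, fast_mcmc


def _net(studies, n_treat):
    return EvidenceNetwork(
        {k: Treatment(k, f"t{k}") for k in range(1, n_treat + 1)}, studies
    )


class TestLargeCountLimits:
    def test_fe_poisson_matches_log_count_ratio(self, two_treatment_rate_network):
        spec = ModelSpec(likelihood="poisson_log", effects="fixed", mcmc=fast_mcmc(3))
        samples = fit_nma(two_treatment_rate_network, spec)
        assert samples.d[:, 1].mean() == pytest.approx(math.log(0.5), abs=0.05)

    def test_fe_logit_matches_log_odds_ratio(self, two_treatment_risk_network):
        spec = ModelSpec(likelihood="binomial_logit", effects="fixed", mcmc=fast_mcmc(4))
        samples = fit_nma(two_treatment_risk_network, spec)
        # log OR of 600/1000 vs 300/1000
        assert samples.d[:, 1].mean() == pytest.approx(1.2527629684953680, abs=0.05)

    def test_fe_cloglog_matches_log_hazard_ratio(self):
        # huge-n single study: r/n = 1 - exp(-lambda T), T = 0.5
        lam = (0.4, 0.8)
        T, n = 0.5, 200_000
        arms = tuple(
            RiskArm("A", k + 1, int(round(n * (1 - math.exp(-l * T)))), n, T)
            for k, l in enumerate(lam)
        )
        net = _net([Study("A", risk_arms=arms)], 2)
        spec = ModelSpec(likelihood="binomial_cloglog", effects="fixed", mcmc=fast_mcmc(5))
        samples = fit_nma(net, spec)
        assert samples.d[:, 1].mean() == pytest.approx(math.log(2.0), abs=0.05)


class TestDeterminism:
    def test_same_seed_gives_identical_draws(self, two_treatment_rate_network):
        spec = ModelSpec(likelihood="poisson_log", effects="random", mcmc=fast_mcmc(9))
        a = fit_nma(two_treatment_rate_network, spec)
        b = fit_nma(two_treatment_rate_network, spec)
        assert np.array_equal(a.d, b.d)
        assert np.array_equal(a.sigma, b.sigma)
        pd.testing.assert_frame_equal(a.diagnostics, b.diagnostics)

    def test_shared_model_on_all_rate_network_equals_poisson_model(self, paper_like_sim):
        """Same likelihood, same draws when every study reports rates."""
        cfg = GeneratorConfig(format_mix=(0, 0, 20), seed=21)
        net = simulate_network(cfg).network
        shared = fit_nma(net, ModelSpec(likelihood="shared", mcmc=fast_mcmc(6)))
        poisson = fit_nma(net, ModelSpec(likelihood="poisson_log", mcmc=fast_mcmc(6)))
        assert np.array_equal(shared.d, poisson.d)
        assert np.array_equal(shared.fitted, poisson.fitted)


class TestRelativeEffects:
    def test_degenerate_draws_give_exact_hazard_ratio(self):
        samples = degenerate_posterior(
            {1: np.zeros(100), 2: np.full(100, math.log(2.0))}
        )
        table = relative_effects(samples)
        assert table.loc[2, "median"] == pytest.approx(2.0)
        assert table.loc[2, "ci_low"] == pytest.approx(2.0)
        assert table.loc[2, "ci_high"] == pytest.approx(2.0)

    def test_reference_row_is_exactly_one(self):
        rng = np.random.default_rng(0)
        samples = degenerate_posterior({1: np.zeros(500), 2: rng.normal(0.3, 0.2, 500)})
        table = relative_effects(samples)
        assert table.loc[1, "median"] == 1.0
        assert (table.loc[1, "ci_low"], table.loc[1, "ci_high"]) == (1.0, 1.0)

    def test_rereferencing_matches_per_draw_recomputation(self):
        rng = np.random.default_rng(1)
        draws = {
            1: np.zeros(2000),
            2: rng.normal(-0.2, 0.3, 2000),
            3: rng.normal(0.4, 0.2, 2000),
        }
        samples = degenerate_posterior(draws)
        table = relative_effects(samples, reference=2)
        for code in (1, 2, 3):
            brute = np.exp(draws[code] - draws[2])
            assert table.loc[code, "median"] == pytest.approx(np.median(brute))
            assert table.loc[code, "ci_low"] == pytest.approx(np.percentile(brute, 2.5))

    def test_unknown_reference_is_coding_error(self):
        samples = degenerate_posterior({1: np.zeros(10), 2: np.zeros(10)})
        with pytest.raises(CodingError):
            relative_effects(samples, reference=9)


class TestStructures:
    def _loop_network(self, seed=13):
        cfg = GeneratorConfig(
            n_treatments=3,
            n_studies=6,
            true_log_hr=(0.0, -0.2, 0.1),
            true_sigma=0.0,
            n_range=(2000, 2000),
            format_mix=(0, 0, 6),
            comparisons=((1, 2), (1, 3), (2, 3)) * 2,
            seed=seed,
        )
        return simulate_network(cfg).network

    def test_inconsistency_model_has_one_parameter_per_comparison(self):
        net = self._loop_network()
        spec = ModelSpec(likelihood="poisson_log", effects="fixed", mcmc=fast_mcmc(7))
        cons = fit_nma(net, spec)
        incons = fit_inconsistency(net, spec)
        assert cons.d.shape[1] - 1 == 2  # two basic parameters
        assert incons.d_comparison.shape[1] == 3
        assert incons.comparisons == ((1, 2), (1, 3), (2, 3))

    def test_consistent_data_give_agreeing_edge_estimates(self):
        net = self._loop_network()
        spec = ModelSpec(likelihood="poisson_log", effects="fixed", mcmc=fast_mcmc(8))
        cons = fit_nma(net, spec)
        incons = fit_inconsistency(net, spec)
        edges = edge_effects(incons).set_index(["baseline", "treatment"])
        rel = relative_effects(cons)
        for (b, t), row in edges.iterrows():
            expected = rel.loc[t, "median"] / rel.loc[b, "median"]
            assert math.log(row["median"]) == pytest.approx(
                math.log(expected), abs=0.08
            )

    def test_single_comparison_network_models_coincide(self, two_treatment_rate_network):
        spec = ModelSpec(likelihood="poisson_log", effects="fixed", mcmc=fast_mcmc(2))
        cons = fit_nma(two_treatment_rate_network, spec)
        incons = fit_inconsistency(two_treatment_rate_network, spec)
        assert np.array_equal(cons.d[:, 1], incons.d_comparison[:, 0])


class TestScaleAgreement:
    def test_rare_event_odds_and_hazard_ratios_agree(self):
        """With <2% baseline risk the OR and HR scales are interchangeable."""
        cfg = GeneratorConfig(
            n_treatments=3,
            n_studies=6,
            true_log_hr=(0.0, -0.4, 0.3),
            true_sigma=0.0,
            baseline_lograte_mean=math.log(0.015),
            baseline_lograte_sd=0.2,
            followup_range=(1.0, 1.0),
            followup_distribution="uniform",
            n_range=(20000, 20000),
            format_mix=(6, 0, 0),
            seed=17,
        )
        net = simulate_network(cfg).network
        logit = fit_nma(
            net, ModelSpec(likelihood="binomial_logit", effects="fixed", mcmc=fast_mcmc(1))
        )
        cloglog = fit_nma(
            net, ModelSpec(likelihood="binomial_cloglog", effects="fixed", mcmc=fast_mcmc(1))
        )
        or_med = np.exp(np.median(logit.d[:, 1:], axis=0))
        hr_med = np.exp(np.median(cloglog.d[:, 1:], axis=0))
        assert np.all(np.abs(or_med / hr_med - 1) < 0.05)


class TestValidation:
    def test_disconnected_network_is_estimability_error(self):
        studies = [
            Study("A", rate_arms=(RateArm("A", 1, 5, 10.0), RateArm("A", 2, 5, 10.0))),
            Study("B", rate_arms=(RateArm("B", 3, 5, 10.0), RateArm("B", 4, 5, 10.0))),
        ]
        net = _net(studies, 4)
        with pytest.raises(EstimabilityError):
            fit_nma(net, ModelSpec(likelihood="poisson_log", mcmc=fast_mcmc(0)))

    def test_format_mismatch_is_configuration_error(self, two_treatment_rate_network):
        with pytest.raises(ConfigurationError):
            fit_nma(
                two_treatment_rate_network,
                ModelSpec(likelihood="binomial_logit", mcmc=fast_mcmc(0)),
            )

    def test_multi_arm_random_effects_fit_runs(self):
        cfg = GeneratorConfig(
            n_treatments=4,
            n_studies=6,
            true_log_hr=(0.0, -0.2, 0.0, 0.2),
            true_sigma=0.2,
            arms_per_study=3,
            n_range=(500, 1000),
            format_mix=(0, 0, 6),
            seed=19,
        )
        net = simulate_network(cfg).network
        samples = fit_nma(
            net, ModelSpec(likelihood="poisson_log", effects="random", mcmc=fast_mcmc(12))
        )
        assert samples.d.shape[1] == 4
        assert np.all(samples.sigma > 0)
        assert np.isfinite(samples.diagnostics["rhat"]).all()


class TestExternalOracle:
    def test_shared_re_model_agrees_with_jags(self, tmp_path, paper_like_sim):
        """Full hierarchical cross-check: d and sigma vs an independent Gibbs
        implementation with identical priors on a paper-like network."""
        import json

        net = paper_like_sim.network
        risk = {"r1": [], "n1": [], "r2": [], "n2": [], "lt": [], "t": []}
        rate = {"y1": [], "E1": [], "y2": [], "E2": [], "t": []}
        for s in net.studies:
            if s.rate_arms:
                arms = sorted(s.rate_arms, key=lambda a: a.treatment_code)
                rate["y1"].append(arms[0].events)
                rate["E1"].append(arms[0].exposure)
                rate["y2"].append(arms[1].events)
                rate["E2"].append(arms[1].exposure)
                rate["t"].append(arms[1].treatment_code)
            else:
                arms = sorted(s.risk_arms, key=lambda a: a.treatment_code)
                risk["r1"].append(arms[0].events)
                risk["n1"].append(arms[0].n)
                risk["r2"].append(arms[1].events)
                risk["n2"].append(arms[1].n)
                risk["lt"].append(math.log(arms[0].followup))
                risk["t"].append(arms[1].treatment_code)
        data = {
            "Sr": len(risk["r1"]),
            "Sp": len(rate["y1"]),
            **{f"risk_{k}": v for k, v in risk.items()},
            **{f"rate_{k}": v for k, v in rate.items()},
        }
        (tmp_path / "data.json").write_text(json.dumps(data))
        (tmp_path / "oracle.R").write_text(
            """
suppressMessages({library(rjags); library(jsonlite)})
d <- fromJSON(file.path("%s", "data.json"))
model <- "
model {
  for (j in 1:Sr) {
    rr1[j] ~ dbin(p1[j], nn1[j]);  cloglog(p1[j]) <- lt[j] + mu_r[j]
    rr2[j] ~ dbin(p2[j], nn2[j]);  cloglog(p2[j]) <- lt[j] + mu_r[j] + del_r[j]
    mu_r[j] ~ dnorm(0, 1.0E-4);  del_r[j] ~ dnorm(d[tr[j]], prec)
  }
  for (j in 1:Sp) {
    yy1[j] ~ dpois(EE1[j] * exp(mu_p[j]))
    yy2[j] ~ dpois(EE2[j] * exp(mu_p[j] + del_p[j]))
    mu_p[j] ~ dnorm(0, 1.0E-4);  del_p[j] ~ dnorm(d[tp[j]], prec)
  }
  d[1] <- 0
  for (k in 2:8) { d[k] ~ dnorm(0, 1.0E-4) }
  sd ~ dunif(0, 2);  prec <- 1 / (sd * sd)
}"
data <- list(Sr=d$Sr, Sp=d$Sp, rr1=d$risk_r1, nn1=d$risk_n1, rr2=d$risk_r2,
             nn2=d$risk_n2, lt=d$risk_lt, tr=d$risk_t,
             yy1=d$rate_y1, EE1=d$rate_E1, yy2=d$rate_y2, EE2=d$rate_E2, tp=d$rate_t)
jm <- jags.model(textConnection(model), data=data, n.chains=3,
                 inits=list(.RNG.name="base::Mersenne-Twister", .RNG.seed=42),
                 quiet=TRUE)
update(jm, 4000)
s <- as.matrix(coda.samples(jm, c("d", "sd"), n.iter=16000, thin=2))
out <- c(mean(s[, "sd"]), sapply(2:8, function(k) mean(s[, paste0("d[", k, "]")])))
cat(out, "\\n")
"""
            % tmp_path
        )
        result = subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R")],
            capture_output=True,
            text=True,
            check=True,
        )
        values = [float(v) for v in result.stdout.split()]
        jags_sigma, jags_d = values[0], np.asarray(values[1:])

        samples = fit_nma(
            paper_like_sim.network,
            ModelSpec(
                likelihood="shared",
                effects="random",
                mcmc=McmcSettings(draws=4000, burn=1500, seed=31),
            ),
        )
        assert samples.sigma.mean() == pytest.approx(jags_sigma, abs=0.03)
        np.testing.assert_allclose(samples.d.mean(0)[1:], jags_d, atol=0.05)

    def test_fe_poisson_agrees_with_jags(self, tmp_path, two_treatment_rate_network):
        """Cross-check the sampler against an independent Gibbs implementation."""
        r_script = tmp_path / "oracle.R"
        r_script.write_text(
            """
suppressMessages(library(rjags))
model <- "
model {
  for (i in 1:2) {
    y[i] ~ dpois(E[i] * lambda[i])
    log(lambda[i]) <- mu + d * equals(i, 2)
  }
  mu ~ dnorm(0, 0.0001)
  d ~ dnorm(0, 0.0001)
}"
data <- list(y = c(100, 50), E = c(100, 100))
jm <- jags.model(textConnection(model), data = data, n.chains = 2,
                 inits = list(.RNG.name = "base::Mersenne-Twister", .RNG.seed = 1),
                 quiet = TRUE)
update(jm, 2000)
s <- coda.samples(jm, c("d"), n.iter = 20000)
cat(mean(as.matrix(s)[, "d"]), "\\n")
"""
        )
        result = subprocess.run(
            ["Rscript", str(r_script)], capture_output=True, text=True, check=True
        )
        jags_mean = float(result.stdout.strip().split()[-1])
        spec = ModelSpec(
            likelihood="poisson_log",
            effects="fixed",
            mcmc=McmcSettings(draws=4000, burn=1000, seed=23),
        )
        samples = fit_nma(two_treatment_rate_network, spec)
        assert samples.d[:, 1].mean() == pytest.approx(jags_mean, abs=0.02)
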