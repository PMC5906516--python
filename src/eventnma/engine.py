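"""Bayesian network meta-analysis of event risks and rates.

Four likelihood/link choices are supported, all contrast-based with study
baselines ``mu_i`` and study-specific treatment effects ``delta_ik``
(``delta = 0`` on each study's baseline arm):

* ``binomial_logit`` — ``r ~ Binomial(n, p)``, ``logit(p) = mu + delta``;
  effects are log odds ratios and follow-up time is ignored.
* ``binomial_cloglog`` — ``cloglog(p) = log(T) + mu + delta``; the log
  follow-up offset puts ``mu`` and ``delta`` on the log-hazard (per-year)
  scale, assuming a constant event hazard over follow-up.
* ``poisson_log`` — ``y ~ Poisson(E * lambda)``, ``log(lambda) = mu + delta``;
  also log-hazard scale, and repeat events per patient count.
* ``shared`` — a shared-parameter model: studies contributing rate records
  enter through the Poisson likelihood, risk-only studies through the cloglog
  likelihood, with common basic parameters ``d`` (and common heterogeneity).
  A study reporting both formats contributes only its rate records.

Fixed effects set ``delta_ik = d_k - d_b``; random effects draw ``delta``
around those means with between-study SD ``sigma`` (compound-symmetry
correlation 0.5 within multi-arm studies, equivalent to the usual sequential
conditional construction).  Under consistency all contrasts derive from the
basic parameters ``d_2..d_K`` versus the reference (code 1); the
inconsistency (unrelated-effects) variant gives every observed comparison its
own mean-effect parameter.

Priors are deliberately vague: ``d, mu ~ Normal(0, 100^2)`` on the linear
predictor scale and ``sigma ~ Uniform(0, 2)``, configurable via
:class:`PriorSpec`.

Sampling is blocked Metropolis-within-Gibbs over independent chains: each
study's ``(mu_i, delta_i.)`` block gets an adaptive random-walk Metropolis
update against its local likelihood; under random effects the basic
parameters are conditionally Gaussian given the ``delta`` and are drawn
exactly, as is ``sigma`` from its truncated-Gamma conditional.  This mirrors
the Gibbs structure standard BUGS-family software uses for these models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from ._mcmc import (
    BlockAdapter,
    McmcSettings,
    convergence_warnings,
    diagnostics,
    sample_sigma_conditional,
)
from .data import EvidenceNetwork, Study
from .errors import CodingError, ConfigurationError, EstimabilityError

LIKELIHOODS = ("binomial_logit", "binomial_cloglog", "poisson_log", "shared")

_KIND_LOGIT, _KIND_CLOGLOG, _KIND_RATE = 0, 1, 2


@dataclass
class PriorSpec:
    """Vague prior scales (linear-predictor scale of the chosen model)."""

    d_sd: float = 100.0
    mu_sd: float = 100.0
    sigma_upper: float = 2.0

    def __post_init__(self) -> None:
        if min(self.d_sd, self.mu_sd, self.sigma_upper) <= 0:
            raise ConfigurationError("prior scales must be positive")


@dataclass
class ModelSpec:
    likelihood: Literal[
        "binomial_logit", "binomial_cloglog", "poisson_log", "shared"
    ] = "shared"
    effects: Literal["fixed", "random"] = "random"
    structure: Literal["consistency", "inconsistency"] = "consistency"
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)

    def __post_init__(self) -> None:
        if self.likelihood not in LIKELIHOODS:
            raise ConfigurationError(f"unknown likelihood {self.likelihood!r}")
        if self.effects not in ("fixed", "random"):
            raise ConfigurationError(f"unknown effects {self.effects!r}")
        if self.structure not in ("consistency", "inconsistency"):
            raise ConfigurationError(f"unknown structure {self.structure!r}")

    @property
    def scale_label(self) -> str:
        """Reporting scale of exponentiated effects: OR or HR."""
        return "OR" if self.likelihood == "binomial_logit" else "HR"


@dataclass
class PosteriorSamples:
    """Posterior draws and per-data-point fitted values from one NMA fit."""

    spec: ModelSpec
    treatment_codes: tuple[int, ...]  # treatments with estimable effects
    reference: int
    d: np.ndarray | None  # (ndraw, len(treatment_codes)); reference column is 0
    comparisons: tuple[tuple[int, int], ...] | None  # inconsistency structure
    d_comparison: np.ndarray | None  # (ndraw, n_comparisons)
    sigma: np.ndarray | None  # (ndraw,) for random effects
    mu: np.ndarray  # (ndraw, n_studies)
    study_ids: tuple[str, ...]
    points: pd.DataFrame  # study_id, treatment_code, kind, observed, size
    fitted: np.ndarray  # (ndraw, n_points): p-hat (risk) or theta-hat (rate)
    diagnostics: pd.DataFrame
    warnings: list[str]
    acceptance: float

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]


# ---------------------------------------------------------------------------
# data preparation


def _studies_and_format(network: EvidenceNetwork, spec: ModelSpec) -> list[tuple[Study, str]]:
    """Select the studies a model consumes and the record format each uses."""
    out: list[tuple[Study, str]] = []
    if spec.likelihood in ("binomial_logit", "binomial_cloglog"):
        for s in network.studies:
            if s.risk_arms:
                out.append((s, "risk"))
        if not out:
            raise ConfigurationError(
                f"{spec.likelihood} requires risk records but the network has none"
            )
    elif spec.likelihood == "poisson_log":
        for s in network.studies:
            if s.rate_arms:
                out.append((s, "rate"))
        if not out:
            raise ConfigurationError("poisson_log requires rate records but the network has none")
    else:  # shared: rate records preferred where a study reports both
        for s in network.studies:
            out.append((s, "rate" if s.rate_arms else "risk"))
    return out


class _Prepared:
    """Flattened, study-ordered arrays describing the likelihood's data."""

    def __init__(self, network: EvidenceNetwork, spec: ModelSpec):
        selected = _studies_and_format(network, spec)
        self.study_ids = tuple(s.study_id for s, _ in selected)
        self.n_studies = len(selected)

        rows = []
        s_idx: list[int] = []
        kind: list[int] = []
        obs: list[float] = []
        size: list[float] = []
        logT: list[float] = []
        t_code: list[int] = []
        b_code: list[int] = []
        delta_idx: list[int] = []  # per-point study-arm effect index, -1 for baseline
        self.delta_comp: list[tuple[int, int]] = []  # (baseline, treatment) per effect
        self.delta_study: list[int] = []

        risk_kind = _KIND_LOGIT if spec.likelihood == "binomial_logit" else _KIND_CLOGLOG
        for i, (study, fmt) in enumerate(selected):
            arms = study.arms_for(fmt)
            baseline = study.baseline_code(fmt)
            for arm in sorted(arms, key=lambda a: a.treatment_code):
                s_idx.append(i)
                t_code.append(arm.treatment_code)
                b_code.append(baseline)
                if fmt == "risk":
                    kind.append(risk_kind)
                    obs.append(arm.events)
                    size.append(arm.n)
                    logT.append(math.log(arm.followup))
                else:
                    kind.append(_KIND_RATE)
                    obs.append(arm.events)
                    size.append(arm.exposure)
                    logT.append(0.0)
                if arm.treatment_code == baseline:
                    delta_idx.append(-1)
                else:
                    delta_idx.append(len(self.delta_comp))
                    self.delta_comp.append((baseline, arm.treatment_code))
                    self.delta_study.append(i)
                rows.append(
                    {
                        "study_id": study.study_id,
                        "treatment_code": arm.treatment_code,
                        "kind": "risk" if fmt == "risk" else "rate",
                        "link": {0: "logit", 1: "cloglog", 2: "log"}[kind[-1]],
                        "observed": obs[-1],
                        "size": size[-1],
                    }
                )

        self.points = pd.DataFrame(rows)
        self.s_idx = np.asarray(s_idx)
        self.kind = np.asarray(kind)
        self.obs = np.asarray(obs, dtype=float)
        self.size = np.asarray(size, dtype=float)
        self.logT = np.asarray(logT, dtype=float)
        self.t_code = np.asarray(t_code)
        self.b_code = np.asarray(b_code)
        self.delta_idx = np.asarray(delta_idx)
        self.n_points = len(rows)
        self.n_deltas = len(self.delta_comp)

        present = sorted({int(c) for c in self.t_code})
        self.treatment_codes = tuple(present)
        self.reference = 1
        if self.reference not in present:
            raise EstimabilityError(
                "reference treatment 1 contributes no records to this analysis"
            )
        self._check_connected()

        # distinct observed comparisons, for the inconsistency structure
        comps = sorted(set(self.delta_comp))
        self.comparisons = tuple(comps)
        self.comp_index = {c: j for j, c in enumerate(comps)}

        self.m_logit = self.kind == _KIND_LOGIT
        self.m_clog = self.kind == _KIND_CLOGLOG
        self.m_rate = self.kind == _KIND_RATE
        self.code_col = {c: j for j, c in enumerate(self.treatment_codes)}
        # segment boundaries for per-study likelihood sums (points are
        # study-ordered by construction)
        self.study_starts = np.searchsorted(self.s_idx, np.arange(self.n_studies))

    def _check_connected(self) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.treatment_codes)
        for b, t in self.delta_comp:
            g.add_edge(b, t)
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise EstimabilityError(
                f"comparison graph for this analysis is disconnected: {comps}"
            )

    def crude(self) -> np.ndarray:
        """Per-arm empirical estimates on the model's linear-predictor scale."""
        est = np.empty(self.n_points)
        r, n, y, E = self.obs, self.size, self.obs, self.size
        m = self.m_logit
        est[m] = np.log((r[m] + 0.5) / (n[m] - r[m] + 0.5))
        m = self.m_clog
        if m.any():
            h = -np.log1p(-(r[m] + 0.5) / (n[m] + 1.0))
            est[m] = np.log(h) - self.logT[m]
        m = self.m_rate
        est[m] = np.log((y[m] + 0.5) / E[m])
        return est


# ---------------------------------------------------------------------------
# the Gibbs sampler


class _NmaGibbs:
    def __init__(self, prep: _Prepared, spec: ModelSpec):
        self.prep = prep
        self.spec = spec
        self.priors = spec.priors
        self.random_effects = spec.effects == "random"
        self.consistency = spec.structure == "consistency"

        p = prep
        self.nd = len(p.treatment_codes) - 1 if self.consistency else len(p.comparisons)
        self.S = p.n_studies
        self.A = p.n_deltas

        # design matrix X: delta prior means = X @ basic parameters
        self.X = np.zeros((self.A, self.nd))
        if self.consistency:
            ref_col = p.code_col[p.reference]
            col_of = {}
            j = 0
            for c in p.treatment_codes:
                if p.code_col[c] != ref_col:
                    col_of[c] = j
                    j += 1
            self.basic_labels = [f"d[{c}]" for c in p.treatment_codes if c != p.reference]
            self.col_of = col_of
            for a, (b, t) in enumerate(p.delta_comp):
                if t != p.reference:
                    self.X[a, col_of[t]] = 1.0
                if b != p.reference:
                    self.X[a, col_of[b]] = -1.0
        else:
            self.basic_labels = [f"d[{b},{t}]" for b, t in p.comparisons]
            for a, c in enumerate(p.delta_comp):
                self.X[a, p.comp_index[c]] = 1.0

        # block-diagonal inverse correlation of the random effects:
        # [1] for two-arm studies, 2*(I - J/(1+m)) for m-effect studies
        self.M = np.eye(self.A)
        groups: dict[int, list[int]] = {}
        for a, s in enumerate(p.delta_study):
            groups.setdefault(s, []).append(a)
        self.study_deltas = groups
        for idx in groups.values():
            m = len(idx)
            if m > 1:
                block = 2.0 * (np.eye(m) - np.ones((m, m)) / (1 + m))
                self.M[np.ix_(idx, idx)] = block
        self.XM = self.X.T @ self.M  # (nd, A)
        self.G = self.XM @ self.X  # (nd, nd)
        # fast paths: two-arm studies (single effect) vs multi-arm blocks
        self.single_deltas = np.asarray(
            [idx[0] for idx in groups.values() if len(idx) == 1], dtype=int
        )
        self.single_studies = np.asarray(
            [s for s, idx in groups.items() if len(idx) == 1], dtype=int
        )
        self.multi_groups = [
            (s, np.asarray(idx), self.M[np.ix_(idx, idx)])
            for s, idx in groups.items()
            if len(idx) > 1
        ]

        self.nonbase = p.delta_idx >= 0
        self.nb_idx = p.delta_idx[self.nonbase]
        self.delta_study_arr = np.asarray(p.delta_study, dtype=int)

        # constant pieces of the likelihood
        self.r_lg = p.obs[p.m_logit]
        self.n_lg = p.size[p.m_logit]
        self.r_cl = p.obs[p.m_clog]
        self.n_cl = p.size[p.m_clog]
        self.lt_cl = p.logT[p.m_clog]
        self.y_rt = p.obs[p.m_rate]
        self.e_rt = p.size[p.m_rate]
        self.log_e_rt = np.log(self.e_rt)

    # -- likelihood ---------------------------------------------------------

    def loglik_points(self, mu: np.ndarray, arm_eff: np.ndarray) -> np.ndarray:
        """(C, n_points) log-likelihood given baselines and study-arm effects."""
        p = self.prep
        eta = mu[:, p.s_idx].copy()
        if self.A:
            eta[:, self.nonbase] += arm_eff[:, self.nb_idx]
        eta = np.clip(eta, -60.0, 60.0)
        ll = np.empty_like(eta)
        m = p.m_logit
        if m.any():
            e = eta[:, m]
            ll[:, m] = self.r_lg * e - self.n_lg * np.logaddexp(0.0, e)
        m = p.m_clog
        if m.any():
            h = np.exp(np.clip(self.lt_cl + eta[:, m], -60.0, 30.0))
            ll[:, m] = self.r_cl * np.log(-np.expm1(-h)) - (self.n_cl - self.r_cl) * h
        m = p.m_rate
        if m.any():
            e = eta[:, m]
            ll[:, m] = self.y_rt * (self.log_e_rt + e) - self.e_rt * np.exp(e)
        return ll

    def study_sums(self, ll: np.ndarray) -> np.ndarray:
        return np.add.reduceat(ll, self.prep.study_starts, axis=1)

    def arm_effects(self, d: np.ndarray, delta: np.ndarray | None) -> np.ndarray:
        if self.random_effects:
            return delta
        return d @ self.X.T

    def delta_prior_terms(self, delta: np.ndarray, d: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """(C, S) per-study log prior of the random effects (up to constants)."""
        z = delta - d @ self.X.T
        out = np.zeros((delta.shape[0], self.S))
        inv2s2 = 0.5 / sigma**2
        logsig = np.log(sigma)
        if self.single_deltas.size:
            out[:, self.single_studies] = (
                -z[:, self.single_deltas] ** 2 * inv2s2[:, None] - logsig[:, None]
            )
        for s, idx, M in self.multi_groups:
            zz = z[:, idx]
            quad = np.einsum("ci,ij,cj->c", zz, M, zz)
            out[:, s] = -quad * inv2s2 - len(idx) * logsig
        return out

    def effect_quad(self, delta: np.ndarray, d: np.ndarray) -> np.ndarray:
        """(C,) quadratic form z' M z of the effect deviations."""
        z = delta - d @ self.X.T
        q = (
            np.sum(z[:, self.single_deltas] ** 2, axis=1)
            if self.single_deltas.size
            else np.zeros(delta.shape[0])
        )
        for _, idx, M in self.multi_groups:
            zz = z[:, idx]
            q = q + np.einsum("ci,ij,cj->c", zz, M, zz)
        return q

    # -- the run ------------------------------------------------------------

    def run(self, settings: McmcSettings) -> dict:
        prep, priors = self.prep, self.priors
        C = settings.chains
        rng = np.random.default_rng(
            np.random.SeedSequence([int(settings.seed) % (2**31), 11])
        )

        # crude-based initial state, overdispersed across chains
        crude = prep.crude()
        base_est = np.zeros(self.S)
        for j in range(prep.n_points):
            if prep.delta_idx[j] < 0:
                base_est[prep.s_idx[j]] = crude[j]
        contrasts = np.zeros(self.A)
        for j in range(prep.n_points):
            k = prep.delta_idx[j]
            if k >= 0:
                contrasts[k] = crude[j] - base_est[prep.s_idx[j]]
        d0 = np.linalg.lstsq(self.X, contrasts, rcond=None)[0] if self.A else np.zeros(self.nd)

        d = d0[None, :] + 0.2 * rng.standard_normal((C, self.nd))
        mu = base_est[None, :] + 0.2 * rng.standard_normal((C, self.S))
        delta = contrasts[None, :] + 0.2 * rng.standard_normal((C, self.A))
        sigma = rng.uniform(0.1, min(0.6, priors.sigma_upper), C)

        # two per-study moves spanning the posterior geometry: (A) shift the
        # baseline while keeping every arm's linear predictor fixed, (B) shift
        # the study effects alone
        move_a_adapt = BlockAdapter(self.S, initial=0.3, target=0.44)
        move_b_adapt = BlockAdapter(self.S, initial=0.3, target=0.44)
        d_adapt = BlockAdapter(self.nd, initial=0.2, target=0.4)

        n_iter = settings.burn + settings.draws * settings.thin
        keep_d = np.empty((C, settings.draws, self.nd))
        keep_mu = np.empty((C, settings.draws, self.S))
        keep_delta = np.empty((C, settings.draws, self.A))
        keep_sigma = np.empty((C, settings.draws))
        kept = 0
        accept_total = 0.0

        ll_cur = self.study_sums(self.loglik_points(mu, self.arm_effects(d, delta)))

        for it in range(n_iter):
            adapting = it < settings.burn

            # --- move A: baseline shift with arm predictors held fixed ------
            # mu_j' = mu_j + e, delta_jk' = delta_jk - e: non-baseline arms'
            # linear predictors are unchanged, so only the baseline arm's
            # likelihood, the mu prior and the effects prior enter the ratio
            step = move_a_adapt.scales[None, :] * rng.standard_normal((C, self.S))
            mu_prop = mu + step
            if self.random_effects:
                delta_prop = delta - step[:, self.delta_study_arr]
                prior_cur = self.delta_prior_terms(delta, d, sigma)
                prior_prop = self.delta_prior_terms(delta_prop, d, sigma)
            else:
                delta_prop = delta
                prior_cur = prior_prop = 0.0
            ll_prop = self.study_sums(
                self.loglik_points(mu_prop, self.arm_effects(d, delta_prop))
            )
            log_ratio = (
                ll_prop - ll_cur
                + prior_prop - prior_cur
                - 0.5 * (mu_prop**2 - mu**2) / priors.mu_sd**2
            )
            accept = np.log(rng.random((C, self.S))) < log_ratio
            mu = np.where(accept, mu_prop, mu)
            if self.random_effects and self.A:
                delta = np.where(accept[:, self.delta_study_arr], delta_prop, delta)
            ll_cur = np.where(accept, ll_prop, ll_cur)
            if adapting:
                move_a_adapt.record(accept.mean(axis=0))
                move_a_adapt.maybe_adapt()
            accept_total += accept.mean()

            # --- move B: study-effect shift (random effects only) -----------
            if self.random_effects and self.A:
                b_scales = move_b_adapt.scales[self.delta_study_arr]
                delta_prop = delta + b_scales[None, :] * rng.standard_normal((C, self.A))
                prior_cur = self.delta_prior_terms(delta, d, sigma)
                prior_prop = self.delta_prior_terms(delta_prop, d, sigma)
                ll_prop = self.study_sums(
                    self.loglik_points(mu, self.arm_effects(d, delta_prop))
                )
                log_ratio = ll_prop - ll_cur + prior_prop - prior_cur
                accept = np.log(rng.random((C, self.S))) < log_ratio
                delta = np.where(accept[:, self.delta_study_arr], delta_prop, delta)
                ll_cur = np.where(accept, ll_prop, ll_cur)
                if adapting:
                    move_b_adapt.record(accept.mean(axis=0))
                    move_b_adapt.maybe_adapt()

            # --- basic parameters ------------------------------------------
            if self.nd:
                if self.random_effects:
                    # conditionally Gaussian given delta and sigma; the
                    # likelihood depends on d only through delta, so ll_cur
                    # is unchanged by this exact draw
                    for c in range(C):
                        P = self.G / sigma[c] ** 2 + np.eye(self.nd) / priors.d_sd**2
                        bvec = (self.XM @ delta[c]) / sigma[c] ** 2
                        L = np.linalg.cholesky(P)
                        mean = np.linalg.solve(P, bvec)
                        d[c] = mean + np.linalg.solve(
                            L.T, rng.standard_normal(self.nd)
                        )
                else:
                    d_scales = d_adapt.scales
                    d_accepts = np.zeros(self.nd)
                    for k in range(self.nd):
                        d_prop = d.copy()
                        d_prop[:, k] = d[:, k] + d_scales[k] * rng.standard_normal(C)
                        ll_prop = self.study_sums(
                            self.loglik_points(mu, self.arm_effects(d_prop, delta))
                        )
                        log_ratio = (ll_prop - ll_cur).sum(axis=1) - 0.5 * (
                            d_prop[:, k] ** 2 - d[:, k] ** 2
                        ) / priors.d_sd**2
                        acc = np.log(rng.random(C)) < log_ratio
                        d[acc, k] = d_prop[acc, k]
                        ll_cur = np.where(acc[:, None], ll_prop, ll_cur)
                        d_accepts[k] = acc.mean()
                    if adapting:
                        d_adapt.record(d_accepts)
                        d_adapt.maybe_adapt()

            # --- heterogeneity SD ------------------------------------------
            if self.random_effects and self.A:
                q = self.effect_quad(delta, d)
                sigma = sample_sigma_conditional(q, self.A, priors.sigma_upper, rng)

            if it >= settings.burn and (it - settings.burn) % settings.thin == 0:
                keep_d[:, kept] = d
                keep_mu[:, kept] = mu
                keep_delta[:, kept] = delta
                keep_sigma[:, kept] = sigma
                kept += 1

        return {
            "d": keep_d,
            "mu": keep_mu,
            "delta": keep_delta,
            "sigma": keep_sigma if self.random_effects else None,
            "acceptance": accept_total / n_iter,
        }


def _fitted_values(sampler: _NmaGibbs, d: np.ndarray, mu: np.ndarray,
                   delta: np.ndarray) -> np.ndarray:
    """Per-draw fitted p (risk points) or fitted mean count theta (rate)."""
    p = sampler.prep
    arm_eff = sampler.arm_effects(d, delta)
    eta = mu[:, p.s_idx].copy()
    if sampler.A:
        eta[:, sampler.nonbase] += arm_eff[:, sampler.nb_idx]
    eta = np.clip(eta, -60.0, 60.0)
    fitted = np.empty_like(eta)
    m = p.m_logit
    if m.any():
        fitted[:, m] = 1.0 / (1.0 + np.exp(-eta[:, m]))
    m = p.m_clog
    if m.any():
        h = np.exp(np.clip(p.logT[m] + eta[:, m], -60.0, 30.0))
        fitted[:, m] = -np.expm1(-h)
    m = p.m_rate
    if m.any():
        fitted[:, m] = p.size[m] * np.exp(eta[:, m])
    return fitted


def fit_nma(network: EvidenceNetwork, spec: ModelSpec) -> PosteriorSamples:
    """Fit one NMA model and return posterior draws with diagnostics.

    Raises :class:`EstimabilityError` if the comparison graph of the records
    the model consumes is disconnected, and :class:`ConfigurationError` when
    the likelihood has no records of the format it needs.  Non-convergence
    (split-R-hat > 1.05 or ESS < 400 on reported parameters) attaches a
    warning to the result instead of failing.
    """
    prep = _Prepared(network, spec)
    sampler = _NmaGibbs(prep, spec)
    out = sampler.run(spec.mcmc)

    C, n_keep = out["mu"].shape[:2]
    flat = lambda x: x.reshape(C * n_keep, *x.shape[2:])
    d_chains = out["d"]
    mu = flat(out["mu"])
    delta = flat(out["delta"])
    sigma = flat(out["sigma"]) if out["sigma"] is not None else None

    chains_by_param = {
        name: d_chains[:, :, j] for j, name in enumerate(sampler.basic_labels)
    }
    if sigma is not None:
        chains_by_param["sigma"] = out["sigma"]
    diag = diagnostics(chains_by_param)
    warns = convergence_warnings(diag)

    d_flat = flat(d_chains)
    if sampler.consistency:
        # expand to a full matrix with a zero reference column
        d_full = np.zeros((d_flat.shape[0], len(prep.treatment_codes)))
        for c, j in sampler.col_of.items():
            d_full[:, prep.code_col[c]] = d_flat[:, j]
        d_out, comparisons, d_comp = d_full, None, None
    else:
        d_out, comparisons, d_comp = None, prep.comparisons, d_flat

    fitted = _fitted_values(sampler, d_flat, mu, delta)
    return PosteriorSamples(
        spec=spec,
        treatment_codes=prep.treatment_codes,
        reference=prep.reference,
        d=d_out,
        comparisons=comparisons,
        d_comparison=d_comp,
        sigma=sigma,
        mu=mu,
        study_ids=prep.study_ids,
        points=prep.points,
        fitted=fitted,
        diagnostics=diag,
        warnings=warns,
        acceptance=out["acceptance"],
    )


def fit_inconsistency(network: EvidenceNetwork, spec: ModelSpec) -> PosteriorSamples:
    """Fit the unrelated-mean-effects (inconsistency) variant of ``spec``."""
    return fit_nma(network, replace(spec, structure="inconsistency"))


def _summary_row(draws: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return med, lo, hi


def relative_effects(
    samples: PosteriorSamples, reference: int | None = None
) -> pd.DataFrame:
    """Posterior median effect and 95% CrI per treatment versus a reference.

    Effects are exponentiated to the model's reporting scale (odds ratios for
    the logit model, hazard ratios otherwise).  Re-referencing subtracts the
    reference's basic parameter draw-wise before exponentiating.
    """
    if samples.d is None:
        raise ConfigurationError(
            "relative_effects needs a consistency fit; use edge_effects for "
            "the inconsistency model"
        )
    reference = samples.reference if reference is None else reference
    if reference not in samples.treatment_codes:
        raise CodingError(f"unknown reference treatment {reference}")
    cols = {c: j for j, c in enumerate(samples.treatment_codes)}
    shifted = samples.d - samples.d[:, [cols[reference]]]
    rows = []
    for code in samples.treatment_codes:
        med, lo, hi = _summary_row(np.exp(shifted[:, cols[code]]))
        rows.append(
            {"treatment_code": code, "median": med, "ci_low": lo, "ci_high": hi}
        )
    df = pd.DataFrame(rows).set_index("treatment_code")
    df.attrs["scale"] = samples.spec.scale_label
    df.attrs["reference"] = reference
    return df


def edge_effects(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-comparison posterior medians/CrIs from an inconsistency fit."""
    if samples.d_comparison is None:
        raise ConfigurationError("edge_effects requires an inconsistency fit")
    rows = []
    for j, (b, t) in enumerate(samples.comparisons):
        med, lo, hi = _summary_row(np.exp(samples.d_comparison[:, j]))
        rows.append(
            {"baseline": b, "treatment": t, "median": med, "ci_low": lo, "ci_high": hi}
        )
    df = pd.DataFrame(rows)
    df.attrs["scale"] = samples.spec.scale_label
    return df
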