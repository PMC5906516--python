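"""Run orchestration: configuration, seed splitting, artifacts, reports.

A run executes: obtain data (simulate or read) -> fit the requested NMA
models -> deviance statistics -> baseline meta-analyses -> absolute
outcomes -> rendered comparison report.  Every artifact directory carries a
``meta.json`` with the master seed and a hash of the configuration, and the
report is a pure function of the run directory: every number in it can be
recomputed from the stored draws and summaries.

All randomness flows from one master seed, split per stage with
``numpy.random.SeedSequence`` so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from ._mcmc import McmcSettings
from .baseline import BaselineSamples, baseline_probability, fit_baseline, reference_arms
from .data import EvidenceNetwork, read_network, write_network
from .engine import ModelSpec, PosteriorSamples, PriorSpec, fit_nma, relative_effects
from .errors import ConfigurationError, ReportingError
from .fitstats import compute_fit
from .outcomes import EconomicInputs, outcome_table
from .simulate import GeneratorConfig, paper_like_config, simulate_network

logger = logging.getLogger("eventnma")

_SHORT = {
    "binomial_logit": "logit",
    "binomial_cloglog": "cloglog",
    "poisson_log": "poisson",
    "shared": "shared",
}
_BASELINE_SCALE = {
    "binomial_logit": "logit",
    "binomial_cloglog": "cloglog",
    "poisson_log": "log_rate",
    "shared": "log_rate",
}


def model_key(spec: ModelSpec) -> str:
    eff = "fe" if spec.effects == "fixed" else "re"
    struct = "cons" if spec.structure == "consistency" else "incons"
    return f"{_SHORT[spec.likelihood]}_{eff}_{struct}"


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serialisable to/from YAML or JSON."""

    seed: int = 0
    out_dir: str = "eventnma_run"
    data_path: str | None = None  # directory of CSV tables; None -> simulate
    generator: GeneratorConfig | None = None  # None -> paper-like defaults
    models: tuple[ModelSpec, ...] = ()
    baseline_effects: str = "random"
    economics: EconomicInputs = field(default_factory=EconomicInputs)
    verbose: bool = False

    def __post_init__(self) -> None:
        if not self.models:
            raise ConfigurationError("run configuration lists no models to fit")

    def to_dict(self) -> dict:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj

        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "data_path": self.data_path,
            "generator": enc(self.generator) if self.generator else None,
            "models": [enc(m) for m in self.models],
            "baseline_effects": self.baseline_effects,
            "economics": enc(self.economics),
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed YAML/JSON mapping."""
    seed = int(raw.get("seed", 0))
    mcmc_raw = dict(raw.get("mcmc", {}))
    priors_raw = dict(raw.get("priors", {}))
    models = []
    for m in raw.get("models", []):
        m = dict(m)
        models.append(
            ModelSpec(
                likelihood=m.get("likelihood", "shared"),
                effects=m.get("effects", "random"),
                structure=m.get("structure", "consistency"),
                priors=PriorSpec(**priors_raw),
                mcmc=McmcSettings(**{**mcmc_raw, **m.get("mcmc", {})}),
            )
        )
    gen = None
    if raw.get("generator") is not None:
        g = dict(raw["generator"])
        for key in ("true_log_hr", "followup_range", "n_range", "format_mix"):
            if key in g and isinstance(g[key], list):
                g[key] = tuple(g[key])
        base = dataclasses.asdict(paper_like_config())
        base.update(g)
        base.pop("comparisons", None)
        gen = GeneratorConfig(**base)
    econ = EconomicInputs(**dict(raw.get("economics", {})))
    return RunConfig(
        seed=seed,
        out_dir=str(raw.get("out_dir", "eventnma_run")),
        data_path=raw.get("data_path"),
        generator=gen,
        models=tuple(models),
        baseline_effects=str(raw.get("baseline_effects", "random")),
        economics=econ,
        verbose=bool(raw.get("verbose", False)),
    )


def stage_seed(master: int, stage: int) -> int:
    """Deterministic per-stage child seed below 2**31."""
    return int(np.random.SeedSequence([int(master), int(stage)]).generate_state(1)[0] % (2**31))


def _write_json(path: str, payload: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=float)


def _fit_summary(samples: PosteriorSamples, seed: int, config_hash: str) -> dict:
    eff = relative_effects(samples) if samples.d is not None else None
    out = {
        "seed": seed,
        "config_hash": config_hash,
        "likelihood": samples.spec.likelihood,
        "effects": samples.spec.effects,
        "structure": samples.spec.structure,
        "scale": samples.spec.scale_label,
        "warnings": samples.warnings,
        "diagnostics": samples.diagnostics.reset_index().to_dict(orient="records"),
    }
    if eff is not None:
        out["relative_effects"] = eff.reset_index().to_dict(orient="records")
    if samples.sigma is not None:
        lo, med, hi = np.percentile(samples.sigma, [2.5, 50, 97.5])
        out["sigma"] = {"median": float(med), "ci_low": float(lo), "ci_high": float(hi)}
    return out


def _baseline_for(
    network: EvidenceNetwork, spec: ModelSpec, config: RunConfig, seed: int
) -> BaselineSamples:
    scale = _BASELINE_SCALE[spec.likelihood]
    fmt = "rate" if scale == "log_rate" else "risk"
    arms = reference_arms(network, fmt)
    if not arms and spec.likelihood == "shared":
        scale, fmt = "cloglog", "risk"
        arms = reference_arms(network, fmt)
    return fit_baseline(
        arms,
        scale=scale,
        effects=config.baseline_effects,
        priors=spec.priors,
        mcmc=dataclasses.replace(spec.mcmc, seed=seed),
    )


def run_pipeline(config: RunConfig) -> str:
    """Execute every stage and return the run directory path."""
    t_start = time.time()
    run_dir = config.out_dir
    os.makedirs(run_dir, exist_ok=True)
    chash = config.config_hash
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = f"[{time.time() - t_start:8.2f}s] {msg}"
        log_lines.append(stamp)
        (logger.info if config.verbose else logger.debug)(msg)

    _write_json(
        os.path.join(run_dir, "meta.json"),
        {"seed": config.seed, "config_hash": chash, "config": config.to_dict()},
    )

    # --- stage 0: data -----------------------------------------------------
    data_dir = os.path.join(run_dir, "network")
    if config.data_path is not None:
        network = read_network(config.data_path, format="mixed")
        write_network(network, data_dir)
        log(f"read network from {config.data_path}: {len(network.studies)} studies")
    else:
        gen = config.generator or paper_like_config()
        gen = dataclasses.replace(gen, seed=stage_seed(config.seed, 0))
        sim = simulate_network(gen)
        network = sim.network
        sim.write(data_dir)
        log(f"simulated network: {len(network.studies)} studies, seed {gen.seed}")

    fits_dir = os.path.join(run_dir, "fits")
    base_dir = os.path.join(run_dir, "baseline")
    tables_dir = os.path.join(run_dir, "tables")
    for d in (fits_dir, base_dir, tables_dir):
        os.makedirs(d, exist_ok=True)

    baselines: dict[str, BaselineSamples] = {}
    for i, spec in enumerate(config.models):
        key = model_key(spec)
        t0 = time.time()
        spec = dataclasses.replace(
            spec, mcmc=dataclasses.replace(spec.mcmc, seed=stage_seed(config.seed, 100 + i))
        )
        samples = fit_nma(network, spec)
        mdir = os.path.join(fits_dir, key)
        os.makedirs(mdir, exist_ok=True)

        # draws: basic parameters (+ sigma) to CSV
        if samples.d is not None:
            draws = pd.DataFrame(
                samples.d, columns=[f"d[{c}]" for c in samples.treatment_codes]
            )
        else:
            draws = pd.DataFrame(
                samples.d_comparison,
                columns=[f"d[{b},{t}]" for b, t in samples.comparisons],
            )
        if samples.sigma is not None:
            draws["sigma"] = samples.sigma
        draws.to_csv(os.path.join(mdir, "draws.csv"), index=False)

        _write_json(os.path.join(mdir, "summary.json"), _fit_summary(samples, config.seed, chash))
        fit_stats = compute_fit(samples, model=key)
        _write_json(os.path.join(mdir, "fitstats.json"), fit_stats.to_dict())
        status = "ok" if not samples.warnings else "; ".join(samples.warnings)
        log(f"fit {key}: {time.time() - t0:.1f}s, convergence: {status}")

        # --- baseline + absolute outcomes for consistency fits -------------
        if samples.d is None:
            continue
        scale = _BASELINE_SCALE[spec.likelihood]
        if scale not in baselines:
            t0 = time.time()
            bl = _baseline_for(network, spec, config, stage_seed(config.seed, 200 + len(baselines)))
            baselines[scale] = bl
            bdir = os.path.join(base_dir, bl.scale)
            os.makedirs(bdir, exist_ok=True)
            pd.DataFrame({"m": bl.m, **({"sd_m": bl.sd} if bl.sd is not None else {})}).to_csv(
                os.path.join(bdir, "draws.csv"), index=False
            )
            summary = {
                "seed": config.seed,
                "config_hash": chash,
                "scale": bl.scale,
                "n_studies": len(bl.study_ids),
                "probability_1y": baseline_probability(bl, t=config.economics.horizon),
                "warnings": bl.warnings,
                "diagnostics": bl.diagnostics.reset_index().to_dict(orient="records"),
            }
            if bl.scale == "log_rate":
                rate = bl.rate_draws()
                lo, hi = np.percentile(rate, [2.5, 97.5])
                summary["rate_per_person_year"] = {
                    "mean": float(rate.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            _write_json(os.path.join(bdir, "summary.json"), summary)
            status = "ok" if not bl.warnings else "; ".join(bl.warnings)
            log(f"baseline {bl.scale}: {time.time() - t0:.1f}s, convergence: {status}")

        labels = {c: t.label for c, t in network.treatments.items()}
        table = outcome_table(
            baselines[scale],
            samples,
            config.economics,
            labels=labels,
            model=key,
            seed=stage_seed(config.seed, 300 + i),
        )
        table.to_csv(os.path.join(tables_dir, f"absolute_{key}.csv"))
        rel = relative_effects(samples)
        rel.insert(0, "label", [labels.get(c, str(c)) for c in rel.index])
        rel.to_csv(os.path.join(tables_dir, f"relative_effects_{key}.csv"))

    with open(os.path.join(run_dir, "log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    render_report(run_dir)
    return run_dir


# ---------------------------------------------------------------------------
# reporting


def render_report(run_dir: str) -> str:
    """Build the side-by-side model comparison from a completed run directory.

    Writes ``report/report.md`` plus wide CSVs and returns the report path.
    Raises :class:`ReportingError` if an expected artifact is missing.
    """
    meta_path = os.path.join(run_dir, "meta.json")
    if not os.path.exists(meta_path):
        raise ReportingError(f"{run_dir} has no meta.json; not a run directory")
    with open(meta_path) as fh:
        meta = json.load(fh)

    fits_dir = os.path.join(run_dir, "fits")
    if not os.path.isdir(fits_dir) or not os.listdir(fits_dir):
        raise ReportingError(f"{run_dir} contains no model fits")
    keys = sorted(os.listdir(fits_dir))

    summaries = {}
    fitstats = {}
    for key in keys:
        for name, store in (("summary.json", summaries), ("fitstats.json", fitstats)):
            path = os.path.join(fits_dir, key, name)
            if not os.path.exists(path):
                raise ReportingError(f"missing artifact {path}")
            with open(path) as fh:
                store[key] = json.load(fh)

    report_dir = os.path.join(run_dir, "report")
    os.makedirs(report_dir, exist_ok=True)

    # relative effects side by side
    rel_frames = []
    for key in keys:
        if "relative_effects" not in summaries[key]:
            continue
        df = pd.DataFrame(summaries[key]["relative_effects"]).set_index("treatment_code")
        scale = summaries[key]["scale"]
        rel_frames.append(
            df.rename(
                columns={
                    "median": f"{key} {scale}",
                    "ci_low": f"{key} low",
                    "ci_high": f"{key} high",
                }
            )
        )
    relative = pd.concat(rel_frames, axis=1) if rel_frames else pd.DataFrame()
    relative.to_csv(os.path.join(report_dir, "relative_effects.csv"))

    # fit statistics
    fit_table = pd.DataFrame(
        [
            {
                "model": key,
                "Dbar": fitstats[key]["dbar"],
                "pD": fitstats[key]["pD"],
                "DIC": fitstats[key]["DIC"],
                "n_datapoints": fitstats[key]["n_datapoints"],
            }
            for key in keys
        ]
    ).set_index("model")
    fit_table.to_csv(os.path.join(report_dir, "fit_statistics.csv"))

    # baselines
    base_rows = []
    base_dir = os.path.join(run_dir, "baseline")
    if os.path.isdir(base_dir):
        for scale in sorted(os.listdir(base_dir)):
            with open(os.path.join(base_dir, scale, "summary.json")) as fh:
                s = json.load(fh)
            row = {"scale": scale, **{f"probability_{k}": v for k, v in s["probability_1y"].items()}}
            if "rate_per_person_year" in s:
                row["rate_mean"] = s["rate_per_person_year"]["mean"]
            base_rows.append(row)
    baselines = pd.DataFrame(base_rows)
    baselines.to_csv(os.path.join(report_dir, "baselines.csv"), index=False)

    # absolute outcomes side by side
    tables_dir = os.path.join(run_dir, "tables")
    abs_frames = {}
    if os.path.isdir(tables_dir):
        for fname in sorted(os.listdir(tables_dir)):
            if fname.startswith("absolute_"):
                key = fname[len("absolute_"):-len(".csv")]
                abs_frames[key] = pd.read_csv(os.path.join(tables_dir, fname)).set_index(
                    "treatment_code"
                )
    for quantity in ("probability_mean", "median_rank", "cost_mean", "disutility_mean"):
        wide = pd.DataFrame({key: df[quantity] for key, df in abs_frames.items()})
        wide.to_csv(os.path.join(report_dir, f"{quantity}_by_model.csv"))

    lines = [
        "# Model comparison report",
        "",
        f"seed: {meta['seed']}  config: {meta['config_hash']}",
        "",
        "## Model fit",
        "",
        fit_table.round(2).to_string(),
        "",
        "## Relative effects vs reference (posterior median, 95% CrI)",
        "",
        relative.round(3).to_string() if len(relative) else "(no consistency fits)",
        "",
        "## Baseline on the reference treatment",
        "",
        baselines.round(4).to_string(index=False) if len(baselines) else "(none)",
    ]
    if abs_frames:
        lines += ["", "## Absolute outcomes by model"]
        for key, df in abs_frames.items():
            lines += [
                "",
                f"### {key}",
                "",
                df[
                    [
                        "label",
                        "probability_mean",
                        "median_rank",
                        "cost_mean",
                        "disutility_mean",
                    ]
                ]
                .round(4)
                .to_string(),
            ]
    report_path = os.path.join(report_dir, "report.md")
    with open(report_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return report_path
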