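"""Readers/writers for the tidy data schema, run configuration, pipeline.

One tidy CSV holds a dataset (columns: year, cod, cap, pcod, herring, st,
ice, f_cod, f_cap, f_pcod; empty cells mark missing survey values); the
posterior is a tidy CSV of one row per draw x quantity (structural
parameters, latent states, process errors) plus a JSON diagnostics report.
Every artifact written by the pipeline carries provenance comment lines
(config hash, seed, package version) and reruns with an identical config
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import (
    AbundanceTable,
    ClimateSeries,
    PriorConfig,
    prepare_data,
)
from .inference import (
    PARAM_NAMES,
    PosteriorDraws,
    SamplerConfig,
    bayesian_r2,
    natural_scale,
    posterior_predictive,
    report_table,
    sample_posterior,
)
from .scenario import (
    ScenarioSpec,
    compare_medians,
    hindcast,
    scenario_climate,
)
from . import synthetic

log = logging.getLogger("trigom")

DATA_COLUMNS = ("year", "cod", "cap", "pcod", "herring", "st", "ice",
                "f_cod", "f_cap", "f_pcod")

__all__ = [
    "DATA_COLUMNS", "RunConfig", "read_data", "write_data",
    "write_posterior", "read_posterior", "load_config", "run_pipeline",
]


class ValidationError(ValueError):
    """A schema or invariant breach, naming the offending row/column."""


# --------------------------------------------------------------------------
# dataset CSV
# --------------------------------------------------------------------------

def read_data(path) -> tuple[AbundanceTable, ClimateSeries]:
    """Read and validate a tidy dataset CSV.

    Missing species/herring cells are allowed (flagged in the log); climate
    and fishing columns must be complete, ice strictly positive, years
    unique and consecutive.  Violations raise ValidationError naming the
    row and column.
    """
    df = pd.read_csv(path, comment="#")
    missing_cols = [c for c in DATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing required column(s): {missing_cols}")
    years = df["year"]
    if years.isna().any() or (years != years.astype(int)).any():
        raise ValidationError("column 'year' must be integer and complete")
    dup = years[years.duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate year {int(dup.iloc[0])}")
    df = df.sort_values("year").reset_index(drop=True)
    if (np.diff(df["year"]) != 1).any():
        raise ValidationError("years must be consecutive (step 1)")
    for col in ("cod", "cap", "pcod", "herring"):
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise ValidationError(
                f"non-positive value in column '{col}' at year "
                f"{int(df.loc[bad[0], 'year'])}")
    for col in ("st", "ice", "f_cod", "f_cap", "f_pcod"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValidationError(
                f"missing value in column '{col}' at year "
                f"{int(df.loc[bad[0], 'year'])}")
    bad = df.index[df["ice"] <= 0]
    if len(bad):
        raise ValidationError(
            f"non-positive ice at year {int(df.loc[bad[0], 'year'])}")
    n_missing = int(df[["cod", "cap", "pcod"]].isna().sum().sum())
    if n_missing:
        log.info("dataset has %d missing species observation(s)", n_missing)
    abund = AbundanceTable(
        years=df["year"].to_numpy(), cod=df["cod"].to_numpy(),
        cap=df["cap"].to_numpy(), pcod=df["pcod"].to_numpy(),
        herring=df["herring"].to_numpy(), f_cod=df["f_cod"].to_numpy(),
        f_cap=df["f_cap"].to_numpy(), f_pcod=df["f_pcod"].to_numpy())
    climate = ClimateSeries(years=df["year"].to_numpy(),
                            ice=df["ice"].to_numpy(), st=df["st"].to_numpy())
    return abund, climate


def _provenance_header(meta: dict) -> str:
    lines = [f"# trigom {k}={v}" for k, v in meta.items()]
    return "\n".join(lines) + "\n"


def _write_csv(df: pd.DataFrame, path, meta: dict):
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    Path(path).write_text(_provenance_header(meta) + buf.getvalue())


def write_data(abund: AbundanceTable, climate: ClimateSeries, path,
               meta: dict | None = None):
    """Write a dataset back to the tidy CSV schema (with provenance)."""
    df = pd.DataFrame({
        "year": abund.years, "cod": abund.cod, "cap": abund.cap,
        "pcod": abund.pcod, "herring": abund.herring, "st": climate.st,
        "ice": climate.ice, "f_cod": abund.f_cod, "f_cap": abund.f_cap,
        "f_pcod": abund.f_pcod})
    _write_csv(df, path, meta or {})


# --------------------------------------------------------------------------
# posterior CSV / diagnostics JSON
# --------------------------------------------------------------------------

def write_posterior(draws: PosteriorDraws, path, meta: dict | None = None):
    """Tidy posterior CSV: chain, iteration, name, value; includes latent
    states (x_<species>_<year>) and process errors (eps_<species>_<year>)."""
    frames = [draws.tidy_frame()]
    for si, sp in enumerate(("cod", "cap", "pcod")):
        for yi, yr in enumerate(draws.years):
            frames.append(pd.DataFrame({
                "chain": draws.chain, "iteration": draws.iteration,
                "name": f"x_{sp}_{yr}", "value": draws.states[:, yi, si]}))
    _write_csv(pd.concat(frames, ignore_index=True), path, meta or {})


def write_diagnostics(draws: PosteriorDraws, path):
    Path(path).write_text(json.dumps(draws.diagnostics, indent=2,
                                     sort_keys=True))


def read_posterior(path, years: np.ndarray | None = None) -> PosteriorDraws:
    """Reassemble a PosteriorDraws from a tidy posterior CSV."""
    df = pd.read_csv(path, comment="#")
    wide = df.pivot_table(index=["chain", "iteration"], columns="name",
                          values="value", sort=False)
    wide = wide.sort_index()
    chain = wide.index.get_level_values("chain").to_numpy()
    iteration = wide.index.get_level_values("iteration").to_numpy()
    if years is None:
        yrs = sorted({int(c.rsplit("_", 1)[1]) for c in wide.columns
                      if c.startswith("x_cod_")})
        years = np.arange(yrs[0], yrs[-1] + 1)
    params = wide[list(PARAM_NAMES)].to_numpy()
    n = params.shape[0]
    T = years.size
    states = np.empty((n, T, 3))
    eps = np.empty((n, T - 1, 3))
    for si, sp in enumerate(("cod", "cap", "pcod")):
        for yi, yr in enumerate(years):
            states[:, yi, si] = wide[f"x_{sp}_{yr}"].to_numpy()
        for yi, yr in enumerate(years[1:]):
            eps[:, yi, si] = wide[f"eps_{sp}_{yr}"].to_numpy()
    theta = params.copy()
    theta[:, 21:24] = np.log(theta[:, 21:24])
    theta[:, 30] = np.log(np.maximum(theta[:, 30], 1e-300))
    return PosteriorDraws(
        param_names=PARAM_NAMES, params=params, theta=theta, chain=chain,
        iteration=iteration, states=states, eps=eps, years=years,
        diagnostics={}, config=SamplerConfig())


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

def _from_mapping(cls, mapping: dict | None):
    mapping = dict(mapping or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} option(s): "
                              f"{sorted(unknown)}")
    return cls(**mapping)


@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration: paths, priors, sampler, scenario,
    generator and the master seed."""

    data: str | None = None
    posterior: str | None = None
    outdir: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    priors: PriorConfig = field(default_factory=PriorConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig)
    anomaly_year: int | None = 1995

    def hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name))
                        for f in dataclasses.fields(o)}
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {k: v for k, v in raw.items()
              if k in ("data", "posterior", "outdir", "seed", "log_level",
                       "anomaly_year")}
    seed = int(kwargs.get("seed", 0))
    sampler = dict(raw.get("sampler") or {})
    sampler.setdefault("seed", seed)
    generator = dict(raw.get("generator") or {})
    generator.setdefault("seed", seed)
    scenario = dict(raw.get("scenario") or {})
    scenario.setdefault("seed", seed)
    return RunConfig(
        priors=_from_mapping(PriorConfig, raw.get("priors")),
        sampler=_from_mapping(SamplerConfig, sampler),
        scenario=_from_mapping(ScenarioSpec, scenario),
        generator=_from_mapping(synthetic.GeneratorConfig, generator),
        **kwargs)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig, stages=("simulate", "fit", "diagnose",
                                            "hindcast", "report")) -> dict:
    """Execute the requested stages in dependency order.

    simulate writes data.csv (+ truth.json); fit writes posterior.csv and
    diagnostics.json; diagnose re-reports convergence; hindcast writes
    per-draw scenario trajectories and a median/slope summary; report
    writes the coefficient table.  Returns the in-memory artifacts.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed}
    artifacts: dict = {}

    if "simulate" in stages:
        log.info("simulate: %d years from seed %d",
                 config.generator.n_years, config.generator.seed)
        ds = synthetic.generate(config.generator)
        write_data(ds.abundance, ds.climate, outdir / "data.csv", meta)
        (outdir / "truth.json").write_text(
            json.dumps({**ds.truth_dict(), "provenance": meta},
                       indent=2, sort_keys=True))
        artifacts["dataset"] = ds

    if {"fit", "diagnose", "hindcast", "report"} & set(stages):
        data_path = config.data or outdir / "data.csv"
        abund, climate = read_data(data_path)
        prepared = prepare_data(abund, climate,
                                anomaly_year=config.anomaly_year)
        artifacts["prepared"] = prepared
        artifacts["climate"] = climate

    if "fit" in stages:
        log.info("fit: %d chains x %d iterations", config.sampler.n_chains,
                 config.sampler.n_iter)
        draws = sample_posterior(prepared, config.priors, config.sampler)
        write_posterior(draws, outdir / "posterior.csv", meta)
        draws.diagnostics["provenance"] = meta
        write_diagnostics(draws, outdir / "diagnostics.json")
        artifacts["draws"] = draws
        if not draws.diagnostics.get("converged", True):
            log.warning("fit flagged non-convergent: %s",
                        draws.diagnostics.get("flags"))
    elif {"diagnose", "hindcast", "report"} & set(stages):
        post_path = config.posterior or outdir / "posterior.csv"
        artifacts["draws"] = read_posterior(post_path)

    if "diagnose" in stages:
        from .inference import rhat_table
        draws = artifacts["draws"]
        rh = rhat_table(draws)
        report = {"rhat": {k: float(v) for k, v in rh.items()},
                  "max_rhat": float(rh.max()),
                  "n_retained": int(draws.n_draws),
                  "provenance": meta}
        report.update({k: v for k, v in draws.diagnostics.items()
                       if k in ("acceptance_fraction", "divergences",
                                "flags", "converged")})
        (outdir / "diagnostics.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        artifacts["diagnostics"] = report

    if "hindcast" in stages:
        draws = artifacts["draws"]
        scen = scenario_climate(prepared, climate, config.scenario)
        result = hindcast(draws, prepared, st_z=scen["st_z"],
                          ice_z=scen["ice_z"])
        artifacts["hindcast"] = result
        artifacts["scenario_climate"] = scen
        tidy = []
        for si, sp in enumerate(("cod", "cap", "pcod")):
            for yi, yr in enumerate(result.years):
                tidy.append(pd.DataFrame({
                    "draw": np.arange(draws.n_draws), "year": int(yr),
                    "species": sp,
                    "log_abundance": result.scenario[:, yi, si],
                    "stationary": result.stationary}))
        _write_csv(pd.concat(tidy, ignore_index=True),
                   outdir / "hindcast_trajectories.csv", meta)
        summary = result.median_summary()
        b, s = result.medians()
        split = int(np.clip(config.scenario.split_year,
                            result.years[0], result.years[-2]))
        if split != config.scenario.split_year:
            log.info("split year clamped to %d for this year range", split)
        slopes = compare_medians(b, s, result.years, split_year=split)
        _write_csv(summary, outdir / "hindcast_summary.csv", meta)
        _write_csv(slopes, outdir / "hindcast_slopes.csv", meta)
        artifacts["slopes"] = slopes
        log.info("hindcast: removed %d / %d non-stationary draws",
                 result.n_removed, draws.n_draws)

    if "report" in stages:
        draws = artifacts["draws"]
        table = report_table(draws, data=prepared)
        _write_csv(table, outdir / "coefficients.csv", meta)
        ppc = posterior_predictive(draws, prepared,
                                   np.random.default_rng(config.seed))
        r2 = bayesian_r2(draws, prepared)
        extra = {"ppc_envelope_coverage": ppc["coverage"],
                 "median_bayesian_r2": dict(zip(("cod", "cap", "pcod"),
                                                np.median(r2, axis=0))),
                 "provenance": meta}
        (outdir / "fit_summary.json").write_text(
            json.dumps(extra, indent=2, sort_keys=True))
        artifacts["report"] = table
    return artifacts
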