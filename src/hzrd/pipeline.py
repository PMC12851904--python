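"""Orchestration: run a whole study from one config, emit a results bundle.

A run config names a cohort source (simulate or load), a seed, and a list of
analyses (cohort rule, outcome, estimator, options). The bundle is a
directory with an ``index.json`` plus one JSON per analysis; failures are
isolated per analysis. Floats are serialized at full precision so results
compare exactly across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import pandas as pd
import yaml

from hzrd.config import SyntheticConfig
from hzrd.cohort import OutcomeSpec, build_analysis_cohort
from hzrd.did import build_did_frame, did_2sls
from hzrd.diagnostics import falsification_suite, robustness_grid
from hzrd.exceptions import ConfigError
from hzrd.heterogeneity import rd_gender_interaction, relative_effect
from hzrd.rd import RDConfig, rd_fuzzy, rd_sharp
from hzrd.synthetic import generate_cohort, read_cohort

log = logging.getLogger("hzrd")

SCHEMA_VERSION = 1

ESTIMATORS = ("rd_sharp", "rd_fuzzy", "rd_relative", "did", "gender_interaction",
              "falsification", "robustness_grid")


@dataclass
class AnalysisSpec:
    name: str
    cohort: str = "no_cognitive_impairment"
    outcome: str = "mci"
    estimator: str = "rd_sharp"
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.estimator not in ESTIMATORS:
            raise ConfigError(f"unknown estimator {self.estimator!r}; "
                              f"expected one of {ESTIMATORS}")


@dataclass
class RunConfig:
    cohort_source: dict = field(default_factory=dict)  # {"simulate": {...}} or {"file": path}
    analyses: list = field(default_factory=list)
    output_dir: str = "hzrd_results"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        analyses = [AnalysisSpec(**a) for a in raw.pop("analyses", [])]
        cfg = cls(analyses=analyses, **{k: v for k, v in raw.items()
                                        if k in {"cohort_source", "output_dir", "seed", "log_level"}})
        unknown = set(raw) - {"cohort_source", "output_dir", "seed", "log_level"}
        if unknown:
            raise ConfigError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cfg


def _load_persons(config: RunConfig) -> pd.DataFrame:
    src = config.cohort_source or {"simulate": {}}
    if "simulate" in src:
        syn = SyntheticConfig.from_dict({**src["simulate"], "rng_seed": config.seed})
        return generate_cohort(syn)
    if "file" in src:
        return read_cohort(src["file"])
    raise ConfigError("cohort_source must contain 'simulate' or 'file'")


def _rd_config(options: dict) -> RDConfig:
    known = {f.name for f in dataclasses.fields(RDConfig)}
    kw = {k: v for k, v in options.items() if k in known}
    if "covariates" in kw:
        kw["covariates"] = tuple(kw["covariates"])
    if "fixed_effects" in kw:
        kw["fixed_effects"] = tuple(kw["fixed_effects"])
    return RDConfig(**kw)


def _outcome_spec(analysis: AnalysisSpec) -> OutcomeSpec:
    opts = analysis.options
    return OutcomeSpec(
        name=analysis.outcome,
        follow_up_years=int(opts.get("follow_up_years", 9)),
        grace_period_weeks=int(opts.get("grace_period_weeks", 0)),
        index_date_policy=opts.get("index_date_policy", "program_start"),
        window_shift_years=int(opts.get("window_shift_years", 0)),
    )


def _run_one(persons: pd.DataFrame, analysis: AnalysisSpec) -> dict:
    opts = analysis.options
    cfg = _rd_config(opts)
    if analysis.estimator in ("rd_sharp", "rd_fuzzy", "rd_relative", "gender_interaction"):
        ac = build_analysis_cohort(
            persons, cohort=analysis.cohort, outcome=_outcome_spec(analysis),
            covariates=tuple(opts.get("covariates", ())),
            frequent_attenders_only=bool(opts.get("frequent_attenders", False)))
        if analysis.estimator == "rd_sharp":
            return rd_sharp(ac, config=cfg).to_dict()
        if analysis.estimator == "rd_fuzzy":
            return rd_fuzzy(ac, config=cfg).to_dict()
        if analysis.estimator == "rd_relative":
            estimand = opts.get("estimand", "eligibility")
            base = rd_fuzzy(ac, config=cfg) if estimand == "receipt" else rd_sharp(ac, config=cfg)
            return relative_effect(base, estimand=estimand).to_dict()
        return rd_gender_interaction(ac, config=cfg).to_dict()
    if analysis.estimator == "did":
        frame = build_did_frame(persons if analysis.cohort is None else
                                __cohort(persons, analysis.cohort), _outcome_spec(analysis))
        return did_2sls(frame).to_dict()
    if analysis.estimator == "falsification":
        report = falsification_suite(
            persons, outcome=analysis.outcome, cohort=analysis.cohort,
            control_outcomes=tuple(opts.get("control_outcomes", ())), config=cfg)
        return report.to_dict()
    if analysis.estimator == "robustness_grid":
        table = robustness_grid(persons, outcome=analysis.outcome, cohort=analysis.cohort,
                                grid=opts.get("grid"), config=cfg,
                                fuzzy=bool(opts.get("fuzzy", True)))
        return {"grid": table.to_dict(orient="records")}
    raise ConfigError(f"unhandled estimator {analysis.estimator!r}")


def __cohort(persons, which):
    from hzrd.cohort import build_cohort

    return build_cohort(persons, which)


def run(config: RunConfig) -> dict:
    """Execute every analysis in the config; write and return the bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    persons = _load_persons(config)
    index = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
             "n_persons": int(len(persons)), "analyses": {}}
    for analysis in config.analyses:
        entry = {"cohort": analysis.cohort, "outcome": analysis.outcome,
                 "estimator": analysis.estimator}
        try:
            payload = _run_one(persons, analysis)
            entry["status"] = "ok"
            path = outdir / f"{analysis.name}.json"
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
            entry["file"] = path.name
        except Exception as err:  # noqa: BLE001 - per-analysis isolation
            log.warning("analysis %s failed: %s", analysis.name, err)
            entry["status"] = "failed"
            entry["error"] = str(err)
        index["analyses"][analysis.name] = entry
    with open(outdir / "index.json", "w") as fh:
        json.dump(index, fh, indent=1)
    return index


def report(bundle_dir) -> pd.DataFrame:
    """Forest-style summary table (one row per analysis) from a results bundle."""
    outdir = pathlib.Path(bundle_dir)
    with open(outdir / "index.json") as fh:
        index = json.load(fh)
    rows = []
    for name, entry in index["analyses"].items():
        row = {"analysis": name, "estimator": entry["estimator"],
               "outcome": entry["outcome"], "status": entry["status"]}
        if entry["status"] == "ok":
            with open(outdir / entry["file"]) as fh:
                payload = json.load(fh)
            if "estimate" in payload:
                row.update(estimate=payload["estimate"],
                           ci_lo=payload.get("ci_robust", [None, None])[0],
                           ci_hi=payload.get("ci_robust", [None, None])[1],
                           p=payload.get("p_robust"),
                           n_eff=(payload.get("n_eff_left", 0) or 0)
                           + (payload.get("n_eff_right", 0) or 0))
            elif "beta_2sls" in payload:
                row.update(estimate=payload["beta_2sls"], ci_lo=payload["ci"][0],
                           ci_hi=payload["ci"][1], p=payload["p"], n_eff=payload["n"])
            elif "relative_estimate" in payload:
                row.update(estimate=payload["relative_estimate"], ci_lo=payload["ci"][0],
                           ci_hi=payload["ci"][1], p=payload["p"])
            elif "n_significant_at_05" in payload:
                row.update(estimate=payload["n_significant_at_05"],
                           n_eff=payload["n_tests"])
        else:
            row["error"] = entry.get("error", "")
        rows.append(row)
    return pd.DataFrame(rows)
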