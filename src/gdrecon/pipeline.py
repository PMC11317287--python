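"""End-to-end pipeline: validate -> summarize -> abundance -> stratify ->
associate -> outcomes, with a deterministic artifact bundle.

Artifacts are numeric CSV/JSON; every bundle carries a provenance record
with the configuration hash and seed, so two runs with the same inputs
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .association import association_matrix
from .cohort import Cohort, read_cohort, validate_cohort, write_cohort
from .outcomes import outcome_by_stratum
from .reconstitution import abundance_table, summarize_timepoints
from .simulate import GeneratorConfig, generate_cohort
from .stratify import stratify_cohort

log = logging.getLogger("gdrecon")

DEFAULT_SCOPES = ("day30", "day60", "day100", "day180", "day240", "timeavg")
DEFAULT_OUTCOMES = ("agvhd_2to4", "agvhd_skin", "ebv", "cmv", "adv")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one input mode: paths to the three cohort CSVs, or generator
    settings for a synthetic cohort.
    """

    patients_path: str | None = None
    panels_path: str | None = None
    outcomes_path: str | None = None
    generator: GeneratorConfig | None = None
    seed: int = 0
    scopes: tuple[str, ...] = DEFAULT_SCOPES
    outcome_names: tuple[str, ...] = DEFAULT_OUTCOMES
    min_group: int | None = None
    q_threshold: float = 0.1
    confounder_alpha: float = 0.05
    out_dir: str = "gdrecon_out"
    subsets: tuple[str, ...] = ("gd_t", "vd1", "vd2")

    def validate(self) -> None:
        paths = (self.patients_path, self.panels_path, self.outcomes_path)
        has_paths = all(p is not None for p in paths)
        if not has_paths and self.generator is None:
            raise ValueError("configure either the three input paths or a generator")
        for t, name in ((self.q_threshold, "q_threshold"),
                        (self.confounder_alpha, "confounder_alpha")):
            if not 0.0 < t < 1.0:
                raise ValueError(f"{name} must lie in (0,1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and d["generator"] is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for k in ("scopes", "outcome_names", "subsets"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(_analysis_params(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _analysis_params(config: "PipelineConfig") -> dict:
    """Config minus the output location: what determines the results."""
    d = _jsonable(config)
    d.pop("out_dir", None)
    return d


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def load_cohort(config: PipelineConfig) -> Cohort:
    if config.patients_path is not None:
        return read_cohort(config.patients_path, config.panels_path,
                           config.outcomes_path)
    return generate_cohort(config.generator, seed=config.seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write artifacts; return the report bundle.

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts of completed stages persist.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    stage = "load"
    try:
        cohort = load_cohort(config)
        log.info("loaded cohort with %d patients, %d panel rows",
                 cohort.n_patients, len(cohort.panels))
        if config.patients_path is None:
            write_cohort(cohort, out / "cohort")

        stage = "validate"
        report = validate_cohort(cohort)
        (out / "validation.json").write_text(report.to_json())
        if not report.ok:
            raise PipelineError("validate",
                                f"{len(report)} violation(s); first: "
                                f"{report.violations[0].to_dict()}")

        stage = "summarize"
        summary = summarize_timepoints(cohort)
        summary.to_csv(out / "summary.csv", index=False)
        bundle["summary"] = summary

        stage = "abundance"
        ab = abundance_table(cohort, subsets=config.subsets)
        ab.to_csv(out / "abundance.csv", index=False)
        bundle["abundance"] = ab

        stage = "stratify"
        splits = stratify_cohort(cohort, subsets=config.subsets,
                                 min_group=config.min_group)
        (out / "splits.json").write_text(json.dumps(
            {s: sp.to_dict() for s, sp in splits.items()}, indent=2,
            sort_keys=True))
        labels = pd.DataFrame(
            [(s, pid, lab) for s, sp in splits.items()
             for pid, lab in sorted(sp.labels.items())],
            columns=["subset", "patient_id", "stratum"])
        labels.to_csv(out / "strata.csv", index=False)
        bundle["splits"] = splits

        stage = "associate"
        matrices = {}
        for scope in config.scopes:
            m = association_matrix(cohort, scope,
                                   q_threshold=config.q_threshold,
                                   confounder_alpha=config.confounder_alpha)
            m.to_csv(out / f"association_{scope}.csv", index=False)
            matrices[scope] = m
            log.info("scope %s: %d significant of %d testable pairs", scope,
                     int(m["significant"].sum()),
                     int(m["p"].notna().sum()))
        bundle["association"] = matrices

        stage = "outcomes"
        results = {}
        for subset in config.subsets:
            for name in config.outcome_names:
                res = outcome_by_stratum(cohort, splits[subset], name)
                results[f"{subset}:{name}"] = res
                for lab, curve in res.curves.items():
                    curve.to_frame().to_csv(
                        out / f"cif_{subset}_{name}_{lab}.csv", index=False)
        (out / "outcomes.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in results.items()}, indent=2,
            sort_keys=True))
        bundle["outcomes"] = results

        stage = "provenance"
        (out / "provenance.json").write_text(json.dumps(
            {"config": _analysis_params(config),
             "config_hash": bundle["config_hash"],
             "seed": config.seed, "n_patients": cohort.n_patients},
            indent=2, sort_keys=True))
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(stage, str(exc)) from exc
    return bundle
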