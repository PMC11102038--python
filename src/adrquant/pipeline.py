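"""End-to-end orchestration: simulate -> qualify -> score -> grade ->
frequency -> evaluate -> associate.

Stages run in dependency order; severity precedes frequency because the
underreporting rate applied to a pair depends on its assigned grade.
Every run writes its artifacts plus a manifest (config hash, seed,
per-stage attrition, output checksums). Re-running the same config
reproduces identical outputs; with ``resume`` on, a run whose manifest
matches the config is reloaded instead of recomputed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .association import (
    DEFAULT_ZONE_THRESHOLDS,
    all_target_ors,
    build_entries,
    fatal_risk_targets,
    zone_assign,
)
from .disproportionality import add_ror, significance_filter
from .errors import PipelineError
from .evaluation import evaluate, model_grade_table
from .frequency import URRConfig, add_frequency, compute_aap, infer_aap_by_atc
from .qualification import (
    QualificationRules,
    build_pair_table,
    filter_by_support,
    normalize_adrs,
    normalize_drugs,
    qualify_reports,
)
from .records import (
    ADROntology,
    DrugDictionary,
    read_grade_table,
    read_prescriptions_csv,
    read_reports_jsonl,
    read_target_map,
    write_grade_table,
    write_prescriptions_csv,
    write_reports_jsonl,
    write_target_map,
)
from .severity import SeverityParams, grade_boundaries, score_pairs
from .simulate import (
    SimConfig,
    adr_catalog,
    drug_catalog,
    generate_ade_reports,
    generate_expert_grades,
    generate_prescriptions,
    generate_target_map,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qualify", "score", "frequency", "evaluate", "associate")


class InputPaths(BaseModel):
    """Optional file inputs; anything left unset is simulated."""

    reports: Optional[Path] = None
    prescriptions: Optional[Path] = None
    dictionary: Optional[Path] = None
    ontology: Optional[Path] = None
    expert_table: Optional[Path] = None
    target_map: Optional[Path] = None


class PipelineConfig(BaseModel):
    out_dir: Path = Path("adrquant_run")
    sim: SimConfig = Field(default_factory=SimConfig)
    inputs: InputPaths = Field(default_factory=InputPaths)
    rules: QualificationRules = Field(default_factory=QualificationRules)
    severity: SeverityParams = Field(default_factory=SeverityParams)
    scope: Literal["per_pair", "per_adr"] = "per_pair"
    alpha: float = 0.05
    urr: URRConfig = Field(default_factory=URRConfig)
    yr: float = 8.0
    zone_thresholds: tuple[float, float] = DEFAULT_ZONE_THRESHOLDS
    fatal_or_threshold: float = 2.0
    atc_inference: Literal["mean", "median"] = "mean"
    resume: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)

    def config_hash(self) -> str:
        payload = self.model_dump(mode="json", exclude={"out_dir", "resume"})
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    out_dir: Path
    pairs: pd.DataFrame
    manifest: dict
    evaluation: Optional[dict] = None
    fatal_targets: Optional[pd.DataFrame] = None
    paths: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_pipeline(
    config: PipelineConfig,
    seed: Optional[int] = None,
    until: str = "associate",
) -> PipelineResult:
    """Run the pipeline up to (and including) ``until``.

    ``seed`` overrides the simulation seed in the config. Raises
    :class:`PipelineError` carrying the failing stage's name.
    """
    if until not in STAGES:
        raise PipelineError("config", f"unknown stage {until!r}")
    if seed is not None:
        config = config.model_copy(
            update={"sim": config.sim.model_copy(update={"seed": seed})}
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stop = STAGES.index(until)
    manifest: dict = {
        "adrquant_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.sim.seed,
        "until": until,
        "stages": {},
        "outputs": {},
        "notices": [],
    }
    manifest_path = out / "manifest.json"
    if config.resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") == manifest["config_hash"] and previous.get(
            "until"
        ) == until:
            logger.info("resume: config unchanged, reloading existing artifacts")
            return _reload(out, previous)

    audit: dict = {}
    paths: dict[str, Path] = {}

    # -- simulate / load inputs ------------------------------------------
    try:
        if config.inputs.reports:
            reports = read_reports_jsonl(config.inputs.reports)
            truth = None
        else:
            reports, truth = generate_ade_reports(config.sim)
        dictionary = (
            DrugDictionary.from_json(config.inputs.dictionary)
            if config.inputs.dictionary
            else drug_catalog(config.sim)
        )
        ontology = (
            ADROntology.from_json(config.inputs.ontology)
            if config.inputs.ontology
            else adr_catalog(config.sim)
        )
        prescriptions = (
            read_prescriptions_csv(config.inputs.prescriptions)
            if config.inputs.prescriptions
            else generate_prescriptions(config.sim)
        )
        paths["reports"] = out / "reports.jsonl"
        write_reports_jsonl(reports, paths["reports"])
        paths["prescriptions"] = out / "prescriptions.csv"
        write_prescriptions_csv(prescriptions, paths["prescriptions"])
        paths["dictionary"] = out / "dictionary.json"
        dictionary.to_json(paths["dictionary"])
        paths["ontology"] = out / "ontology.json"
        ontology.to_json(paths["ontology"])
        if truth is not None:
            paths["ground_truth"] = out / "ground_truth.json"
            truth.to_json(paths["ground_truth"])
        audit["simulate"] = {"reports": len(reports),
                             "prescriptions": int(len(prescriptions))}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError("simulate", str(exc)) from exc
    if stop == STAGES.index("simulate"):
        return _finish(out, manifest, audit, paths, pd.DataFrame())

    # -- qualification ----------------------------------------------------
    try:
        qualified = qualify_reports(reports, config.rules, audit=audit)
        qualified = normalize_drugs(qualified, dictionary, audit=audit)
        qualified = normalize_adrs(qualified, ontology, audit=audit)
        pairs = build_pair_table(qualified)
        pairs = filter_by_support(pairs, config.rules, audit=audit)
        paths["pairs"] = out / "pairs.tsv"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qualify", str(exc)) from exc
    if stop == STAGES.index("qualify"):
        _write_tsv(pairs, paths["pairs"])
        return _finish(out, manifest, audit, paths, pairs)

    # -- ROR + severity ---------------------------------------------------
    try:
        if pairs.empty:
            raise PipelineError("score", "no pairs")
        pairs = add_ror(pairs, alpha=config.alpha)
        pairs = significance_filter(pairs, audit=audit)
        if pairs.empty:
            raise PipelineError("score", "no pairs")
        pairs = score_pairs(pairs, config.severity, scope=config.scope, audit=audit)
        bounds = grade_boundaries(config.severity)
        paths["boundaries"] = out / "boundaries.json"
        paths["boundaries"].write_text(
            json.dumps(
                {"edges": list(bounds.edges), "decimals": bounds.decimals}, indent=1
            )
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("score", str(exc)) from exc
    if stop == STAGES.index("score"):
        _write_tsv(pairs, paths["pairs"])
        return _finish(out, manifest, audit, paths, pairs)

    # -- frequency --------------------------------------------------------
    try:
        aap = compute_aap(
            prescriptions, dictionary, period=config.sim.years, audit=audit
        )
        aap = infer_aap_by_atc(
            aap, dictionary.atc_map(), method=config.atc_inference, audit=audit
        )
        paths["aap"] = out / "aap.tsv"
        _write_tsv(aap, paths["aap"])
        pairs = add_frequency(pairs, aap, yr=config.yr, urr=config.urr, audit=audit)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("frequency", str(exc)) from exc
    _write_tsv(pairs, paths["pairs"])
    if stop == STAGES.index("frequency"):
        return _finish(out, manifest, audit, paths, pairs)

    # -- evaluation -------------------------------------------------------
    evaluation_summary = None
    try:
        model_grading = model_grade_table(pairs)
        expert = None
        if config.inputs.expert_table:
            if Path(config.inputs.expert_table).exists():
                expert = read_grade_table(config.inputs.expert_table)
            else:
                manifest["notices"].append(
                    f"expert table {config.inputs.expert_table} missing: "
                    "evaluation skipped"
                )
        else:
            expert = generate_expert_grades(config.sim, model_grading)
            paths["expert_table"] = out / "expert_grades.json"
            write_grade_table(expert, paths["expert_table"])
        if expert is not None:
            evaluation_summary, detail = evaluate(model_grading, expert, audit=audit)
            paths["evaluation"] = out / "evaluation.json"
            paths["evaluation"].write_text(
                json.dumps(evaluation_summary, indent=1, sort_keys=True)
            )
            paths["evaluation_detail"] = out / "evaluation.tsv"
            _write_tsv(detail, paths["evaluation_detail"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("evaluate", str(exc)) from exc
    if stop == STAGES.index("evaluate"):
        return _finish(out, manifest, audit, paths, pairs, evaluation_summary)

    # -- association ------------------------------------------------------
    try:
        target_map = (
            read_target_map(config.inputs.target_map)
            if config.inputs.target_map
            else generate_target_map(config.sim)
        )
        paths["target_map"] = out / "target_map.json"
        write_target_map(target_map, paths["target_map"])
        entries = build_entries(pairs, target_map, audit=audit)
        ors = all_target_ors(entries, alpha=config.alpha)
        entries = entries.merge(ors, on=["adr_id", "target_id"], how="left")
        entries["zone"] = [
            zone_assign(o, f, config.zone_thresholds)
            for o, f in zip(entries["or_value"], entries["frequency"])
        ]
        paths["entries"] = out / "entries.tsv"
        _write_tsv(entries, paths["entries"])
        paths["target_ors"] = out / "target_ors.tsv"
        _write_tsv(ors, paths["target_ors"])
        fatal = fatal_risk_targets(
            entries[ENTRY_BASE_COLUMNS],
            or_threshold=config.fatal_or_threshold,
            alpha=config.alpha,
        )
        paths["fatal_targets"] = out / "fatal_targets.json"
        paths["fatal_targets"].write_text(
            json.dumps(
                {
                    "or_threshold": config.fatal_or_threshold,
                    "targets": fatal.to_dict(orient="records"),
                },
                indent=1,
                sort_keys=True,
            )
        )
        audit["association"] = {
            **audit.get("entries", {}),
            "fatal_risk_targets": int(len(fatal)),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("associate", str(exc)) from exc
    return _finish(out, manifest, audit, paths, pairs, evaluation_summary, fatal)


ENTRY_BASE_COLUMNS = ["drug_id", "adr_id", "target_id", "grade", "frequency"]


def _finish(
    out: Path,
    manifest: dict,
    audit: dict,
    paths: dict,
    pairs: pd.DataFrame,
    evaluation_summary: Optional[dict] = None,
    fatal: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    manifest["stages"] = audit
    manifest["outputs"] = {
        name: {"file": p.name, "sha256": _sha256(p)} for name, p in sorted(paths.items())
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        out_dir=out,
        pairs=pairs,
        manifest=manifest,
        evaluation=evaluation_summary,
        fatal_targets=fatal,
        paths={k: str(v) for k, v in paths.items()},
    )


def _reload(out: Path, manifest: dict) -> PipelineResult:
    pairs_path = out / "pairs.tsv"
    pairs = (
        pd.read_csv(pairs_path, sep="\t") if pairs_path.exists() else pd.DataFrame()
    )
    eval_path = out / "evaluation.json"
    evaluation = json.loads(eval_path.read_text()) if eval_path.exists() else None
    fatal_path = out / "fatal_targets.json"
    fatal = None
    if fatal_path.exists():
        fatal = pd.DataFrame(json.loads(fatal_path.read_text())["targets"])
    return PipelineResult(
        out_dir=out,
        pairs=pairs,
        manifest=manifest,
        evaluation=evaluation,
        fatal_targets=fatal,
        paths={k: str(out / v["file"]) for k, v in manifest.get("outputs", {}).items()},
    )
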