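"""End-to-end orchestration: simulate → extract → filter → classify /
regress → importance → report.

Every run writes its artifacts (manifests, feature CSVs, CV result JSONs,
importance table, exclusion report, log) into a run directory together with
the serialised configuration and master seed, so the same configuration
reproduces byte-identical outputs.  Completed stages leave a marker in
``state.json``; re-running a partially failed run resumes after the last
completed stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import apply_exclusions, select_contrast
from .ml_pipeline import CVConfig, CVResult, cv_classify, cv_regress, oob_importance
from .multiscale import (
    ExtractionConfig,
    FeatureMatrix,
    extract_features,
    filter_features,
    parse_feature_name,
)
from .synthetic_voice import CohortConfig, CohortManifest, generate_cohort, render_recording

__all__ = ["RunConfig", "run_pipeline", "report", "extract_cohort_features"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one end-to-end run.

    Round-trips through JSON without loss (``to_json`` / ``from_json``).
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    arm: str = "adhd_vs_hc"
    subset: Optional[str] = None
    regression_target: Optional[str] = "adhd_dc_total"
    min_unique: int = 100
    out_dir: str = "runs/run"
    seed: int = 0

    def to_json(self, path=None) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                d = dataclasses.asdict(obj)
                d.pop("span_grid", None)
                return d
            raise TypeError(type(obj))

        payload = dataclasses.asdict(self)
        payload["extraction"].pop("span_grid", None)
        text = json.dumps(payload, indent=2, default=enc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        cc = payload.get("cohort", {})
        for key in ("male_fraction", "education_probs", "excluded_reason_fractions"):
            if key in cc and isinstance(cc[key], dict):
                cc[key] = {k: tuple(v) if isinstance(v, list) else v
                           for k, v in cc[key].items()}
        for key in ("visit_probs", "age_range", "f0_base_male", "f0_base_female",
                    "syllable_rate", "pause_fraction_range"):
            if key in cc and isinstance(cc[key], list):
                cc[key] = tuple(cc[key])
        cv = payload.get("cv", {})
        if isinstance(cv.get("confound_names"), list):
            cv["confound_names"] = tuple(cv["confound_names"])
        return cls(
            cohort=CohortConfig(**cc),
            extraction=ExtractionConfig(**payload.get("extraction", {})),
            cv=CVConfig(**cv),
            arm=payload.get("arm", "adhd_vs_hc"),
            subset=payload.get("subset"),
            regression_target=payload.get("regression_target"),
            min_unique=payload.get("min_unique", 100),
            out_dir=payload.get("out_dir", "runs/run"),
            seed=payload.get("seed", 0),
        )


def extract_cohort_features(
    manifest: CohortManifest,
    extraction: Optional[ExtractionConfig] = None,
    master_seed: int = 0,
    progress: bool = False,
) -> FeatureMatrix:
    """Synthesise every manifest recording and extract its feature vector.

    Row metadata carries the participant id, group, label-relevant subtype
    and the confounds (sex, age, education) so the matrix can go straight
    into the CV machinery.
    """
    cfg = extraction or ExtractionConfig()
    parts = manifest.participants.set_index("id")
    rows, meta_rows, ids = [], [], []
    for _, rec in manifest.recordings.iterrows():
        waveforms = render_recording(manifest, rec["id"], master_seed)
        vec = extract_features(waveforms, cfg, recording_id=rec["id"])
        part = parts.loc[rec["participant_id"]]
        rows.append(vec)
        ids.append(rec["id"])
        meta_rows.append({
            "participant_id": rec["participant_id"], "group": part["group"],
            "adhd_subtype": part["adhd_subtype"], "sex": part["sex"],
            "age": part["age"], "education": part["education"],
            "on_medication": rec["on_medication"],
            "adhd_dc_total": part["adhd_dc_total"],
            "inattention": part["inattention"],
            "hyperactivity": part["hyperactivity"],
            "wurs_k": part["wurs_k"], "bdi": part["bdi"],
        })
        if progress and len(ids) % 20 == 0:
            log.info("extracted %d/%d recordings", len(ids), manifest.n_recordings)
    features = pd.DataFrame(rows, index=ids)
    meta = pd.DataFrame(meta_rows, index=ids)
    return FeatureMatrix(features, meta)


_STAGES = ("simulate", "exclusions", "extract", "filter", "classify",
           "regress", "importance", "report")


def _load_state(out: Path) -> Dict[str, bool]:
    state_path = out / "state.json"
    if state_path.exists():
        return json.loads(state_path.read_text())
    return {}


def _mark(out: Path, state: Dict[str, bool], stage: str) -> None:
    state[stage] = True
    (out / "state.json").write_text(json.dumps(state, indent=2))


def run_pipeline(config: RunConfig, resume: bool = True) -> Path:
    """Run the full simulate → report pipeline into ``config.out_dir``.

    Returns the run directory.  With ``resume=True`` completed stages
    (recorded in ``state.json``) are skipped, so a partially failed run can
    be continued.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    try:
        return _run_pipeline_inner(config, out, resume)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(config: RunConfig, out: Path, resume: bool) -> Path:
    config.to_json(out / "config.json")
    state = _load_state(out) if resume else {}

    if not state.get("simulate"):
        manifest = generate_cohort(config.cohort, config.seed)
        manifest.to_csv(out / "participants.csv", out / "recordings.csv")
        _mark(out, state, "simulate")
        log.info("simulated %d participants / %d recordings",
                 manifest.n_participants, manifest.n_recordings)
    manifest = CohortManifest.from_csv(out / "participants.csv", out / "recordings.csv")

    if not state.get("exclusions"):
        included, excl_report = apply_exclusions(manifest)
        included.to_csv(out / "participants_included.csv", out / "recordings_included.csv")
        excl_report.to_json(out / "exclusion_report.json")
        (out / "exclusion_report.txt").write_text(excl_report.to_text())
        _mark(out, state, "exclusions")
    included = CohortManifest.from_csv(
        out / "participants_included.csv", out / "recordings_included.csv")

    if not state.get("extract"):
        fm = extract_cohort_features(included, config.extraction, config.seed, progress=True)
        fm.to_csv(out / "features.csv", out / "features_meta.csv")
        name_dict = {c: parse_feature_name(c) for c in fm.features.columns}
        (out / "feature_names.json").write_text(json.dumps(name_dict, indent=2))
        _mark(out, state, "extract")
    features = pd.read_csv(out / "features.csv", index_col="recording_id")
    meta = pd.read_csv(out / "features_meta.csv", index_col="recording_id")
    fm = FeatureMatrix(features, meta)

    if not state.get("filter"):
        filtered, filt_report = filter_features(fm, min_unique=config.min_unique)
        filtered.to_csv(out / "features_filtered.csv")
        (out / "filter_report.json").write_text(json.dumps(filt_report.to_dict(), indent=2))
        _mark(out, state, "filter")
    filtered_features = pd.read_csv(out / "features_filtered.csv", index_col="recording_id")
    filtered = FeatureMatrix(filtered_features, fm.meta.loc[filtered_features.index])

    rows, labels = select_contrast(included, config.arm, config.subset)
    arm_ids = rows["id_x"] if "id_x" in rows.columns else rows["id"]
    arm_ids = [i for i in arm_ids if i in set(filtered.features.index)]
    sub = FeatureMatrix(filtered.features.loc[arm_ids], filtered.meta.loc[arm_ids])
    y = sub.meta["group"].eq("ADHD").to_numpy().astype(int)

    if not state.get("classify"):
        clf_result = cv_classify(sub, y, config.cv)
        clf_result.to_json(out / f"classification_{config.arm}.json")
        clf_result.per_repeat.to_csv(out / f"classification_{config.arm}_repeats.csv",
                                     index=False)
        _mark(out, state, "classify")

    if not state.get("regress") and config.regression_target:
        target = pd.to_numeric(filtered.meta[config.regression_target]).to_numpy()
        reg_result = cv_regress(filtered, target, config.cv)
        reg_result.to_json(out / f"regression_{config.regression_target}.json")
        reg_result.per_repeat.to_csv(
            out / f"regression_{config.regression_target}_repeats.csv", index=False)
        _mark(out, state, "regress")

    if not state.get("importance"):
        imp = oob_importance(sub, y, config.cv)
        imp.to_csv(out / "importance.csv")
        _mark(out, state, "importance")

    if not state.get("report"):
        (out / "report.md").write_text(report(out))
        _mark(out, state, "report")
    return out


def report(run_dir) -> str:
    """Markdown summary of a completed (or partial) run.

    Collects the exclusion flow, per-arm classification metrics, regression
    metrics, and the top-10 importance table with each feature's signal,
    task and time span parsed from its name.  Missing artifacts are listed
    and the rest of the report is still produced.
    """
    out = Path(run_dir)
    lines: List[str] = ["# Prosodic phenotyping run report", ""]
    missing: List[str] = []

    cfg_path = out / "config.json"
    if cfg_path.exists():
        cfg = json.loads(cfg_path.read_text())
        lines += [f"Seed: {cfg.get('seed')}  |  arm: {cfg.get('arm')}"
                  f"  |  subset: {cfg.get('subset')}", ""]

    excl = out / "exclusion_report.txt"
    if excl.exists():
        lines += ["## Exclusion flow", "", "```", excl.read_text(), "```", ""]
    else:
        missing.append(str(excl))

    lines += ["## Classification", ""]
    any_clf = False
    for path in sorted(out.glob("classification_*.json")):
        any_clf = True
        payload = json.loads(path.read_text())
        pooled = payload["pooled"]
        arm = path.stem.replace("classification_", "")
        lines += [f"| arm | AUC | precision | recall | F1 |",
                  f"|---|---|---|---|---|",
                  "| {} | {:.3f} | {:.3f} | {:.3f} | {:.3f} |".format(
                      arm, pooled.get("auc", float("nan")),
                      pooled.get("precision", float("nan")),
                      pooled.get("recall", float("nan")),
                      pooled.get("f1", float("nan"))), ""]
    if not any_clf:
        missing.append("classification_*.json")

    for path in sorted(out.glob("regression_*.json")):
        payload = json.loads(path.read_text())
        pooled = payload["pooled"]
        target = path.stem.replace("regression_", "")
        lines += [f"## Regression: {target}", "",
                  "pooled r = {:.3f}, MAE = {:.3f}".format(
                      pooled.get("r", float("nan")), pooled.get("mae", float("nan"))), ""]

    imp_path = out / "importance.csv"
    if imp_path.exists():
        imp = pd.read_csv(imp_path).head(10)
        lines += ["## Top-10 feature importance", "",
                  "| rank | feature | signal | task | span (s) | importance |",
                  "|---|---|---|---|---|---|"]
        cells: Dict[Tuple[str, str], int] = {}
        for _, row in imp.iterrows():
            info = parse_feature_name(row["feature"])
            cells[(info["signal"], info["task"])] = cells.get(
                (info["signal"], info["task"]), 0) + 1
            lines.append("| {} | {} | {} | {} | {:g} | {:.3f} |".format(
                row["rank"], row["feature"], info["signal"], info["task"],
                info["span_s"], row["importance"]))
        lines += ["", "Signal x task breakdown: " + ", ".join(
            f"{s}/{t}: {n}" for (s, t), n in sorted(cells.items())), ""]
    else:
        missing.append(str(imp_path))

    if missing:
        lines += ["## Missing artifacts", ""] + [f"- {m}" for m in missing]
    return "\n".join(lines)
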