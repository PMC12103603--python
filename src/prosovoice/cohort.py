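"""Participant- and recording-level exclusion flow with an audit trail.

The modelled study applies exclusions in two recording-level stages —
technically flawed or surplus recordings first, then recordings of
drug-screen-positive or subclinical participants and severe-cold recordings —
followed by dropping participants who either belong to the excluded group or
retain no recordings.  Multi-flagged records receive exactly one primary
reason under the priority order drug > technical > subclinical > cold, so the
reported counts are well-defined.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .synthetic_voice import CohortManifest

__all__ = ["ExclusionReport", "cap_recordings", "apply_exclusions",
           "select_contrast", "ARMS", "SUBSETS"]

REASON_PRIORITY = ("drug_screen", "technical", "subclinical", "severe_cold")


@dataclass
class StageReport:
    n_before: int
    n_removed: int
    reasons: Counter
    n_after: int

    def validate(self) -> None:
        assert self.n_after == self.n_before - self.n_removed
        assert sum(self.reasons.values()) == self.n_removed


@dataclass
class ExclusionReport:
    recording_stages: Dict[str, StageReport] = field(default_factory=dict)
    participant_stages: Dict[str, StageReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def enc(stages):
            return {
                name: {"n_before": s.n_before, "n_removed": s.n_removed,
                       "reasons": dict(s.reasons), "n_after": s.n_after}
                for name, s in stages.items()
            }
        return {"recordings": enc(self.recording_stages),
                "participants": enc(self.participant_stages)}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        """Human-readable CONSORT-style flow."""
        lines = []
        for kind, stages in (("Recordings", self.recording_stages),
                             ("Participants", self.participant_stages)):
            lines.append(f"{kind}:")
            for name, s in stages.items():
                reasons = ", ".join(f"{k}={v}" for k, v in sorted(s.reasons.items()))
                lines.append(
                    f"  {name}: {s.n_before} -> {s.n_after}"
                    f" (removed {s.n_removed}{': ' + reasons if reasons else ''})"
                )
        return "\n".join(lines)


def cap_recordings(manifest: CohortManifest, max_per_participant: int = 3) -> CohortManifest:
    """Keep at most the first ``max_per_participant`` recordings per
    participant, ordered by visit index with recording id as tie-break."""
    r = manifest.recordings
    if "visit_index" not in r.columns:
        raise ValueError("recordings need a visit_index column")
    kept = (
        r.sort_values(["participant_id", "visit_index", "id"])
        .groupby("participant_id", sort=False)
        .head(max_per_participant)
    )
    kept = r.loc[r["id"].isin(set(kept["id"]))]
    return CohortManifest(manifest.participants.copy(), kept.reset_index(drop=True))


_REQUIRED_REC_FLAGS = ("technical_ok", "surplus", "severe_cold")
_REQUIRED_PART_FLAGS = ("drug_screen_positive", "subclinical")


def apply_exclusions(manifest: CohortManifest) -> Tuple[CohortManifest, ExclusionReport]:
    """Two-stage recording exclusion plus participant-level drop.

    Stage 1 removes technically flawed and surplus recordings.  Stage 2
    removes recordings of drug-screen-positive participants, recordings of
    subclinical participants, and severe-cold recordings.  Participants in
    the excluded group or with no remaining recordings are then dropped.
    Reasons follow the priority drug > technical > subclinical > cold.
    """
    p, r = manifest.participants, manifest.recordings
    for col in _REQUIRED_REC_FLAGS:
        if col not in r.columns:
            raise ValueError(f"recordings are missing the flag column {col!r}")
        if len(r) and r[col].isna().any():
            raise ValueError(f"recording flag column {col!r} contains missing values")
    for col in _REQUIRED_PART_FLAGS:
        if col not in p.columns:
            raise ValueError(f"participants are missing the flag column {col!r}")

    report = ExclusionReport()

    # stage 1: technical / surplus recordings
    bad_tech = ~r["technical_ok"].astype(bool)
    bad_surplus = r["surplus"].astype(bool) & ~bad_tech
    stage1_mask = bad_tech | bad_surplus
    reasons1 = Counter()
    if len(r):
        reasons1["technical"] = int(bad_tech.sum())
        reasons1["surplus"] = int(bad_surplus.sum())
        reasons1 = Counter({k: v for k, v in reasons1.items() if v})
    r1 = r.loc[~stage1_mask]
    report.recording_stages["technical_surplus"] = StageReport(
        len(r), int(stage1_mask.sum()), reasons1, len(r1))

    # stage 2: participant drug screens / subclinical status, severe colds
    drug_ids = set(p.loc[p["drug_screen_positive"].astype(bool), "id"])
    sub_ids = set(p.loc[p["subclinical"].astype(bool), "id"])
    is_drug = r1["participant_id"].isin(drug_ids)
    is_sub = r1["participant_id"].isin(sub_ids) & ~is_drug
    is_cold = r1["severe_cold"].astype(bool) & ~is_drug & ~is_sub
    stage2_mask = is_drug | is_sub | is_cold
    reasons2 = Counter()
    if len(r1):
        for key, m in (("drug_screen", is_drug), ("subclinical", is_sub),
                       ("severe_cold", is_cold)):
            if int(m.sum()):
                reasons2[key] = int(m.sum())
    r2 = r1.loc[~stage2_mask].reset_index(drop=True)
    report.recording_stages["drug_subclinical_cold"] = StageReport(
        len(r1), int(stage2_mask.sum()), reasons2, len(r2))

    # participant drop: excluded group or no recordings left
    remaining = set(r2["participant_id"])
    removed_reason = {}
    for _, row in p.iterrows():
        pid = row["id"]
        excluded_group = row["group"] == "EXCLUDED"
        if pid in remaining and not excluded_group:
            continue
        if bool(row["drug_screen_positive"]):
            removed_reason[pid] = "drug_screen"
        elif excluded_group and not bool(row["subclinical"]):
            removed_reason[pid] = "technical"
        elif bool(row["subclinical"]):
            removed_reason[pid] = "subclinical"
        else:
            removed_reason[pid] = "no_recordings"
    p2 = p.loc[~p["id"].isin(removed_reason)].reset_index(drop=True)
    r2 = r2.loc[~r2["participant_id"].isin(removed_reason)].reset_index(drop=True)
    report.participant_stages["exclusion"] = StageReport(
        len(p), len(removed_reason), Counter(removed_reason.values()), len(p2))

    for s in report.recording_stages.values():
        s.validate()
    for s in report.participant_stages.values():
        s.validate()
    return CohortManifest(p2, r2), report


ARMS = ("adhd_vs_hc", "adhd_vs_pc")
SUBSETS = ("male", "female", "age_lt32", "age_ge32", "att", "com",
           "no_comorbid", "no_stimulants", "one_recording")

#: Age-band boundary: the median split is at 32 years; exactly 32.0 falls in
#: the older band.
AGE_SPLIT = 32.0


def select_contrast(
    manifest: CohortManifest,
    arm: str,
    subset: Optional[str] = None,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Recording rows and binary labels (patient group = 1) for one contrast.

    ``arm`` picks the comparison (ADHD vs HC or ADHD vs PC); ``subset``
    optionally restricts it (sex, age band, ADHD subtype, comorbidity,
    stimulant medication, one recording per participant).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if subset is not None and subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")
    m = manifest
    if subset == "one_recording":
        m = cap_recordings(m, 1)
    control = "HC" if arm == "adhd_vs_hc" else "PC"
    rows = m.recordings.merge(
        m.participants, left_on="participant_id", right_on="id",
        suffixes=("", "_participant"),
    )
    rows = rows.loc[rows["group"].isin(["ADHD", control])]
    if subset in ("male", "female"):
        rows = rows.loc[rows["sex"] == subset]
    elif subset == "age_lt32":
        rows = rows.loc[rows["age"] < AGE_SPLIT]
    elif subset == "age_ge32":
        rows = rows.loc[rows["age"] >= AGE_SPLIT]
    elif subset in ("att", "com"):
        keep = rows["group"].eq(control) | rows["adhd_subtype"].eq(subset.upper())
        rows = rows.loc[keep]
    elif subset == "no_comorbid":
        rows = rows.loc[rows["group"].eq(control) | ~rows["comorbid"].astype(bool)]
    elif subset == "no_stimulants":
        rows = rows.loc[~rows["on_medication"].astype(bool)]
    labels = rows["group"].eq("ADHD").to_numpy().astype(int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError(
            f"contrast {arm}/{subset} leaves an empty class "
            f"({labels.sum()} patients of {len(labels)} rows)"
        )
    return rows.reset_index(drop=True), labels
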