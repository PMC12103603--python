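"""Synthetic speech-like waveforms and a study-shaped cohort manifest.

Real clinical voice recordings of the kind this pipeline analyses are
proprietary, so every downstream stage is exercised on synthetic material
built here.  Two things are emulated:

* **Waveforms** — voiced harmonic segments (sum of the first 10 harmonics
  with 1/k roll-off) following an F0 trajectory ``f0_base * 2**(drift +
  micro)``, amplitude-modulated at syllable and phrase rates with a
  short-timescale envelope fluctuation, interleaved with pauses and overlaid
  with additive noise.  No attempt is made at intelligible speech; the aim is
  that loudness and F0 contours carry the same kinds of multi-timescale
  structure as real prosody.

* **Cohort structure** — participants in four groups (ADHD, psychiatric
  controls PC, healthy controls HC, and excluded), with symptom scores drawn
  to match published group summaries, confound structure (sex shifts the F0
  register, age raises the noise floor, education nudges voice-quality
  covariates), 1–3 recordings per participant, and exclusion flags (drug
  screen, technical, subclinical, severe cold, medication).

A latent severity theta — the participant's clinical-interview total,
standardised against the healthy-control mean — scales the short-timescale
loudness and F0 variability multiplicatively by ``(1 + g * theta)``.  The
gain ``g`` is the effect-size knob: ``g = 0`` is an exact null in which voice
parameters do not depend on group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.io import wavfile
from scipy.signal import fftconvolve

__all__ = [
    "VoiceParams",
    "ParticipantRecord",
    "RecordingRecord",
    "CohortManifest",
    "CohortConfig",
    "SYMPTOM_TARGETS",
    "HC_TOTAL_MEAN",
    "POOLED_TOTAL_SD",
    "synth_utterance",
    "sample_participant",
    "generate_cohort",
    "reference_cohort",
    "render_recording",
    "write_wav",
    "read_wav",
]

TASK_LABELS = ("free_speech", "counting", "vowels", "words")
GROUPS = ("ADHD", "PC", "HC", "EXCLUDED")

#: Published per-group symptom-score summaries (mean, SD) used as generator
#: targets: clinical-interview total (0-66), inattention and
#: hyperactivity/impulsivity scale scores (0-9), retrospective childhood
#: scale (WURS-k) and depression inventory (BDI-II).
SYMPTOM_TARGETS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "ADHD": {"total": (40.0, 8.3), "inattention": (7.0, 1.7),
             "hyperactivity": (4.9, 2.5), "wurs_k": (38.9, 12.9), "bdi": (13.3, 8.9)},
    "HC": {"total": (5.2, 4.4), "inattention": (0.5, 0.8),
           "hyperactivity": (0.5, 0.8), "wurs_k": (6.6, 6.5), "bdi": (3.2, 2.8)},
    "PC": {"total": (23.3, 12.2), "inattention": (3.3, 2.5),
           "hyperactivity": (2.7, 2.3), "wurs_k": (23.7, 13.8), "bdi": (14.9, 8.8)},
    "EXCLUDED": {"total": (35.9, 11.6), "inattention": (5.5, 2.4),
                 "hyperactivity": (4.5, 2.6), "wurs_k": (39.1, 15.4), "bdi": (16.5, 9.3)},
}
#: Subtype-specific hyperactivity targets within the ADHD group.
SUBTYPE_HYPERACTIVITY = {"ATT": (2.8, 1.6), "COM": (7.0, 1.1)}

HC_TOTAL_MEAN = SYMPTOM_TARGETS["HC"]["total"][0]
#: Pooled SD of the ADHD and HC clinical-interview totals; the severity
#: standardisation scale.
POOLED_TOTAL_SD = float(np.sqrt((8.3**2 + 4.4**2) / 2.0))

N_ITEMS = 22          # clinical-interview items, each rated 0-3
ITEM_MAX = 3
TOTAL_MAX = N_ITEMS * ITEM_MAX  # 66


@dataclass
class VoiceParams:
    """Parameters of one speaker's synthetic voice."""

    f0_base: float = 115.0        # Hz
    f0_drift_sd: float = 0.08     # octaves, slow phrase-level drift
    f0_micro_sd: float = 0.015    # octaves, frame-to-frame variation
    loud_base: float = 0.3        # amplitude in (0, 1]
    loud_micro_sd: float = 0.08   # relative SD of short-timescale envelope
    syllable_rate: float = 4.5    # Hz
    pause_fraction: float = 0.3   # fraction of utterance unvoiced
    hnr_noise: float = 0.01       # relative additive-noise amplitude

    def __post_init__(self) -> None:
        if not (60.0 <= self.f0_base <= 500.0):
            raise ValueError("f0_base must lie in [60, 500] Hz")
        for name in ("f0_drift_sd", "f0_micro_sd", "loud_micro_sd", "hnr_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.loud_base <= 1.0):
            raise ValueError("loud_base must lie in (0, 1]")
        if not (0.0 <= self.pause_fraction < 0.6):
            raise ValueError("pause_fraction must lie in [0, 0.6)")


@dataclass
class ParticipantRecord:
    id: str
    group: str
    adhd_subtype: str = "none"     # ATT | COM | none
    sex: str = "male"
    age: float = 34.0
    education: int = 3             # ordinal 1-5
    drug_screen_positive: bool = False
    subclinical: bool = False
    comorbid: bool = False
    adhd_dc_items: Tuple[int, ...] = ()
    adhd_dc_total: int = 0
    inattention: float = 0.0
    hyperactivity: float = 0.0
    wurs_k: float = 0.0
    bdi: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.adhd_dc_items:
            if len(self.adhd_dc_items) != N_ITEMS:
                raise ValueError(f"expected {N_ITEMS} items")
            if sum(self.adhd_dc_items) != self.adhd_dc_total:
                raise ValueError("adhd_dc_total must equal the item sum")
        if not (0 <= self.adhd_dc_total <= TOTAL_MAX):
            raise ValueError(f"adhd_dc_total must lie in [0, {TOTAL_MAX}]")


@dataclass
class RecordingRecord:
    id: str
    participant_id: str
    visit_index: int = 1
    tasks: Tuple[str, ...] = ("free_speech", "counting_1", "counting_2")
    technical_ok: bool = True
    surplus: bool = False
    on_medication: bool = False
    severe_cold: bool = False
    sample_rate: float = 22050.0
    duration_free_speech: float = 120.0
    duration_counting: float = 5.0


PARTICIPANT_COLUMNS = [
    "id", "group", "adhd_subtype", "sex", "age", "education",
    "drug_screen_positive", "subclinical", "comorbid",
    "adhd_dc_total", "inattention", "hyperactivity", "wurs_k", "bdi",
] + [f"adhd_dc_item_{i:02d}" for i in range(1, N_ITEMS + 1)] + [
    "voice_f0_base", "voice_f0_drift_sd", "voice_f0_micro_sd",
    "voice_loud_base", "voice_loud_micro_sd", "voice_syllable_rate",
    "voice_pause_fraction", "voice_hnr_noise",
]

RECORDING_COLUMNS = [
    "id", "participant_id", "visit_index", "tasks", "technical_ok", "surplus",
    "on_medication", "severe_cold", "sample_rate",
    "duration_free_speech", "duration_counting", "rec_num",
]


@dataclass
class CohortManifest:
    """Participants and recordings as two aligned tables."""

    participants: pd.DataFrame
    recordings: pd.DataFrame

    def __post_init__(self) -> None:
        p, r = self.participants, self.recordings
        if len(p) and p["id"].duplicated().any():
            raise ValueError("participant ids must be unique")
        if len(r):
            if r["id"].duplicated().any():
                raise ValueError("recording ids must be unique")
            missing = set(r["participant_id"]) - set(p["id"])
            if missing:
                raise ValueError(f"recordings reference unknown participants: {sorted(missing)[:5]}")

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_recordings(self) -> int:
        return len(self.recordings)

    def voice_params(self, participant_id: str) -> VoiceParams:
        row = self.participants.set_index("id").loc[participant_id]
        return VoiceParams(
            f0_base=row["voice_f0_base"], f0_drift_sd=row["voice_f0_drift_sd"],
            f0_micro_sd=row["voice_f0_micro_sd"], loud_base=row["voice_loud_base"],
            loud_micro_sd=row["voice_loud_micro_sd"],
            syllable_rate=row["voice_syllable_rate"],
            pause_fraction=row["voice_pause_fraction"], hnr_noise=row["voice_hnr_noise"],
        )

    def to_csv(self, participants_path, recordings_path) -> None:
        self.participants.to_csv(participants_path, index=False)
        self.recordings.to_csv(recordings_path, index=False)

    @classmethod
    def from_csv(cls, participants_path, recordings_path) -> "CohortManifest":
        p = pd.read_csv(participants_path)
        r = pd.read_csv(recordings_path)
        for col in ("drug_screen_positive", "subclinical", "comorbid"):
            p[col] = p[col].astype(bool)
        for col in ("technical_ok", "surplus", "on_medication", "severe_cold"):
            r[col] = r[col].astype(bool)
        return cls(p, r)


# ---------------------------------------------------------------------------
# Moment-matched truncated normals
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) whose [lo, hi]-truncation has the given moments.

    Plain truncation at the printed (mean, SD) would bias the moments (the
    healthy-control total, 1.2 SD above the floor, would gain ~1 point of
    mean), so the underlying parameters are solved for instead.  Returns None
    when the target is infeasible for a truncated normal (caller falls back
    to a clipped normal).
    """

    def moments(p):
        mu, log_sig = p
        sig = np.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(max(v, 1e-300)) - sd]

    try:
        sol = optimize.root(moments, [mean, np.log(sd)], method="hybr")
    except Exception:
        return None
    if not sol.success or max(abs(np.asarray(moments(sol.x)))) > 1e-6 * max(1.0, sd):
        return None
    mu, sig = sol.x[0], float(np.exp(sol.x[1]))
    return mu, sig


def _draw_bounded(u: float, mean: float, sd: float, lo: float, hi: float) -> float:
    """One bounded draw from a single uniform deviate.

    Moment-matched truncated normal when feasible; otherwise a normal at the
    printed moments, censored to [lo, hi].
    """
    params = _matched_truncnorm(mean, sd, lo, hi)
    if params is not None:
        mu, sig = params
        a, b = (lo - mu) / sig, (hi - mu) / sig
        return float(sps.truncnorm.ppf(u, a, b, loc=mu, scale=sig))
    return float(np.clip(sps.norm.ppf(u, loc=mean, scale=sd), lo, hi))


def _decompose_items(total: int, rng_free: bool = True) -> Tuple[int, ...]:
    """Split a 0-66 total onto 22 items in 0-3 by proportional assignment.

    Deterministic: start from the uniform share, round, then walk the items
    in index order nudging values inside [0, 3] until the sum matches.
    """
    if not (0 <= total <= TOTAL_MAX):
        raise ValueError("total out of range")
    items = np.full(N_ITEMS, total / N_ITEMS)
    items = np.clip(np.round(items).astype(int), 0, ITEM_MAX)
    diff = total - int(items.sum())
    i = 0
    while diff != 0:
        j = i % N_ITEMS
        if diff > 0 and items[j] < ITEM_MAX:
            items[j] += 1
            diff -= 1
        elif diff < 0 and items[j] > 0:
            items[j] -= 1
            diff += 1
        i += 1
    return tuple(int(v) for v in items)


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Generator settings; the defaults encode the modelled study's shape."""

    n_adhd: int = 387
    n_hc: int = 204
    n_pc: int = 100
    n_excluded: int = 76

    #: Severity gain on short-timescale variability, (1 + g * theta).
    effect_gain_loud: float = 0.5
    effect_gain_f0: float = 0.5

    #: P(1, 2, 3 visits); most participants record more than once.
    visit_probs: Tuple[float, float, float] = (0.45, 0.40, 0.15)

    #: Male fraction per group (published sample description).
    male_fraction: Dict[str, float] = field(default_factory=lambda: {
        "ADHD": 221 / 387, "HC": 75 / 204, "PC": 36 / 100, "EXCLUDED": 56 / 76,
    })
    #: Balanced-confound mode: one shared demographic distribution per group
    #: (used to verify the g = 0 null, where voice parameters must be
    #: identical in law across groups).
    balanced_confounds: bool = False

    age_mean: float = 34.4
    age_sd: float = 10.6
    age_range: Tuple[float, float] = (18.0, 59.0)
    #: P(education level 1-5) per group; HC skew higher.
    education_probs: Dict[str, Tuple[float, ...]] = field(default_factory=lambda: {
        "ADHD": (0.10, 0.25, 0.30, 0.25, 0.10),
        "PC": (0.08, 0.22, 0.30, 0.27, 0.13),
        "HC": (0.04, 0.16, 0.30, 0.30, 0.20),
        "EXCLUDED": (0.10, 0.25, 0.30, 0.25, 0.10),
    })
    comorbid_fraction_adhd: float = 201 / 387
    att_fraction: float = 198 / 387   # remaining ADHD are combined subtype

    #: Exclusion machinery (published proportions).
    excluded_reason_fractions: Dict[str, float] = field(default_factory=lambda: {
        "drug": 55 / 76, "technical": 7 / 76, "subclinical": 14 / 76,
    })
    technical_recording_rate: float = 17 / 953
    severe_cold_rate: float = 1 / 1029
    medication_rate: float = 71 / 554

    #: Voice-parameter bases and confound slopes.
    f0_base_male: Tuple[float, float] = (115.0, 12.0)     # (mean, sd) Hz
    f0_base_female: Tuple[float, float] = (210.0, 18.0)
    loud_base: float = 0.3
    loud_micro_base: float = 0.08
    f0_micro_base: float = 0.015
    f0_drift_base: float = 0.08
    syllable_rate: Tuple[float, float] = (4.5, 0.4)
    pause_fraction_range: Tuple[float, float] = (0.20, 0.40)
    hnr_base: float = 0.01
    hnr_age_gain: float = 1.0        # doubles the noise floor over 18-59 y
    education_drift_gain: float = 0.05

    #: Recording protocol.
    sample_rate: float = 22050.0
    free_speech_duration: float = 120.0
    counting_duration: float = 5.0

    def male_frac(self, group: str) -> float:
        if self.balanced_confounds:
            return 388 / 767
        return self.male_fraction[group]

    def edu_probs(self, group: str) -> Tuple[float, ...]:
        if self.balanced_confounds:
            return self.education_probs["ADHD"]
        return self.education_probs[group]


def severity_theta(adhd_dc_total: float) -> float:
    """Latent severity: interview total standardised against the HC mean."""
    return (adhd_dc_total - HC_TOTAL_MEAN) / POOLED_TOTAL_SD


def sample_participant(
    group: str,
    config: Optional[CohortConfig] = None,
    seed: Union[int, np.random.Generator, np.random.SeedSequence] = 0,
    participant_id: str = "P0000",
) -> Tuple[ParticipantRecord, VoiceParams]:
    """Draw one participant and their voice parameters.

    The random stream is consumed in a fixed order (one uniform per scalar),
    so with matching seeds and a balanced-confound config the voice
    parameters are identical across groups whenever the effect gain is zero.
    """
    cfg = config or CohortConfig()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    t = SYMPTOM_TARGETS[group]

    u_subtype = rng.uniform()
    total = int(round(_draw_bounded(rng.uniform(), *t["total"], 0, TOTAL_MAX)))
    inatt = _draw_bounded(rng.uniform(), *t["inattention"], 0, 9)
    subtype = "none"
    hyper_target = t["hyperactivity"]
    if group == "ADHD":
        subtype = "ATT" if u_subtype < cfg.att_fraction else "COM"
        hyper_target = SUBTYPE_HYPERACTIVITY[subtype]
    hyper = _draw_bounded(rng.uniform(), *hyper_target, 0, 9)
    wurs = _draw_bounded(rng.uniform(), *t["wurs_k"], 0, 84)
    bdi = _draw_bounded(rng.uniform(), *t["bdi"], 0, 63)
    u_comorbid = rng.uniform()  # always drawn: keeps streams aligned across groups
    comorbid = group == "ADHD" and u_comorbid < cfg.comorbid_fraction_adhd

    sex = "male" if rng.uniform() < cfg.male_frac(group) else "female"
    age = float(np.clip(sps.norm.ppf(rng.uniform(), cfg.age_mean, cfg.age_sd),
                        *cfg.age_range))
    edu_p = np.asarray(cfg.edu_probs(group))
    education = int(np.searchsorted(np.cumsum(edu_p), rng.uniform()) + 1)
    education = min(education, 5)

    f0_mean, f0_sd = cfg.f0_base_male if sex == "male" else cfg.f0_base_female
    f0_base = float(np.clip(sps.norm.ppf(rng.uniform(), f0_mean, f0_sd), 60.0, 500.0))
    syl = float(np.clip(sps.norm.ppf(rng.uniform(), *cfg.syllable_rate), 2.5, 7.0))
    pause = float(cfg.pause_fraction_range[0]
                  + rng.uniform() * (cfg.pause_fraction_range[1] - cfg.pause_fraction_range[0]))

    theta = severity_theta(total)
    lo, hi_age = cfg.age_range
    voice = VoiceParams(
        f0_base=f0_base,
        f0_drift_sd=cfg.f0_drift_base * (1 + cfg.education_drift_gain * (3 - education) / 2),
        f0_micro_sd=cfg.f0_micro_base * max(1 + cfg.effect_gain_f0 * theta, 0.1),
        loud_base=cfg.loud_base,
        loud_micro_sd=cfg.loud_micro_base * max(1 + cfg.effect_gain_loud * theta, 0.1),
        syllable_rate=syl,
        pause_fraction=pause,
        hnr_noise=cfg.hnr_base * (1 + cfg.hnr_age_gain * (age - lo) / (hi_age - lo)),
    )
    record = ParticipantRecord(
        id=participant_id, group=group, adhd_subtype=subtype, sex=sex, age=age,
        education=education,
        drug_screen_positive=False, subclinical=False, comorbid=comorbid,
        adhd_dc_items=_decompose_items(total), adhd_dc_total=total,
        inattention=inatt, hyperactivity=hyper, wurs_k=wurs, bdi=bdi,
    )
    return record, voice


def _participant_row(rec: ParticipantRecord, voice: VoiceParams) -> dict:
    row = {
        "id": rec.id, "group": rec.group, "adhd_subtype": rec.adhd_subtype,
        "sex": rec.sex, "age": rec.age, "education": rec.education,
        "drug_screen_positive": rec.drug_screen_positive,
        "subclinical": rec.subclinical, "comorbid": rec.comorbid,
        "adhd_dc_total": rec.adhd_dc_total, "inattention": rec.inattention,
        "hyperactivity": rec.hyperactivity, "wurs_k": rec.wurs_k, "bdi": rec.bdi,
    }
    items = rec.adhd_dc_items or _decompose_items(rec.adhd_dc_total)
    for i, v in enumerate(items, start=1):
        row[f"adhd_dc_item_{i:02d}"] = v
    row.update({
        "voice_f0_base": voice.f0_base, "voice_f0_drift_sd": voice.f0_drift_sd,
        "voice_f0_micro_sd": voice.f0_micro_sd, "voice_loud_base": voice.loud_base,
        "voice_loud_micro_sd": voice.loud_micro_sd,
        "voice_syllable_rate": voice.syllable_rate,
        "voice_pause_fraction": voice.pause_fraction,
        "voice_hnr_noise": voice.hnr_noise,
    })
    return row


def _recording_row(rec: RecordingRecord, rec_num: int) -> dict:
    return {
        "id": rec.id, "participant_id": rec.participant_id,
        "visit_index": rec.visit_index, "tasks": "|".join(rec.tasks),
        "technical_ok": rec.technical_ok, "surplus": rec.surplus,
        "on_medication": rec.on_medication, "severe_cold": rec.severe_cold,
        "sample_rate": rec.sample_rate,
        "duration_free_speech": rec.duration_free_speech,
        "duration_counting": rec.duration_counting, "rec_num": rec_num,
    }


def _empty_manifest() -> CohortManifest:
    return CohortManifest(
        pd.DataFrame(columns=PARTICIPANT_COLUMNS),
        pd.DataFrame(columns=RECORDING_COLUMNS),
    )


def generate_cohort(
    config: Optional[CohortConfig] = None, seed: int = 0
) -> CohortManifest:
    """Generate a full cohort manifest (waveforms are synthesised on demand).

    Deterministic in (config, seed).  Exclusion flags are assigned at the
    configured rates: excluded-group participants carry drug-screen /
    technical / subclinical reasons in the configured proportions; included
    participants may additionally lose recordings to technical flags or a
    severe cold, but never their last one.
    """
    cfg = config or CohortConfig()
    counts = {"ADHD": cfg.n_adhd, "HC": cfg.n_hc, "PC": cfg.n_pc,
              "EXCLUDED": cfg.n_excluded}
    if any(v < 0 for v in counts.values()):
        raise ValueError("group sizes must be >= 0")
    n_total = sum(counts.values())
    if n_total == 0:
        return _empty_manifest()

    root = np.random.SeedSequence(seed)
    part_ss, flag_ss = root.spawn(2)
    part_seeds = part_ss.spawn(n_total)
    flag_rng = np.random.default_rng(flag_ss)

    # excluded-group reason assignment: largest-remainder apportionment
    reasons: List[str] = []
    if cfg.n_excluded:
        fr = cfg.excluded_reason_fractions
        raw = {k: v * cfg.n_excluded for k, v in fr.items()}
        base = {k: int(np.floor(v)) for k, v in raw.items()}
        rest = cfg.n_excluded - sum(base.values())
        for k in sorted(raw, key=lambda k: raw[k] - base[k], reverse=True)[:rest]:
            base[k] += 1
        for k in ("drug", "technical", "subclinical"):
            reasons.extend([k] * base.get(k, 0))

    p_rows, r_rows = [], []
    rec_num = 0
    idx = 0
    for group in ("ADHD", "HC", "PC", "EXCLUDED"):
        for j in range(counts[group]):
            pid = f"{group[:1]}{idx:04d}"
            rec, voice = sample_participant(group, cfg, part_seeds[idx], pid)
            excl_reason = reasons[j] if group == "EXCLUDED" and j < len(reasons) else None
            if excl_reason == "drug":
                rec.drug_screen_positive = True
            elif excl_reason == "subclinical":
                rec.subclinical = True
            p_rows.append(_participant_row(rec, voice))

            n_visits = int(flag_rng.choice((1, 2, 3), p=cfg.visit_probs))
            flags = []
            for v in range(1, n_visits + 1):
                technical_ok = True
                severe_cold = False
                on_med = False
                if excl_reason == "technical":
                    technical_ok = False
                elif group != "EXCLUDED":
                    if n_visits > 1 and flag_rng.uniform() < cfg.technical_recording_rate:
                        technical_ok = False
                    elif n_visits > 1 and flag_rng.uniform() < cfg.severe_cold_rate:
                        severe_cold = True
                    if group == "ADHD" and flag_rng.uniform() < cfg.medication_rate:
                        on_med = True
                flags.append((technical_ok, severe_cold, on_med))
            # never flag away an included participant's every recording
            if group != "EXCLUDED" and all((not ok) or cold for ok, cold, _ in flags):
                flags[0] = (True, False, flags[0][2])
            for v, (technical_ok, severe_cold, on_med) in enumerate(flags, start=1):
                rec_num += 1
                r_rows.append(_recording_row(RecordingRecord(
                    id=f"R{rec_num:05d}", participant_id=pid, visit_index=v,
                    technical_ok=technical_ok, severe_cold=severe_cold,
                    on_medication=on_med, sample_rate=cfg.sample_rate,
                    duration_free_speech=cfg.free_speech_duration,
                    duration_counting=cfg.counting_duration,
                ), rec_num))
            idx += 1

    return CohortManifest(
        pd.DataFrame(p_rows, columns=PARTICIPANT_COLUMNS),
        pd.DataFrame(r_rows, columns=RECORDING_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Reference fixture: the printed recruitment / exclusion flow, exactly
# ---------------------------------------------------------------------------

def reference_cohort() -> CohortManifest:
    """Deterministic manifest encoding the published recruitment flow.

    767 participants (387 ADHD, 204 HC, 100 PC, 76 excluded) contribute 1029
    recordings.  24 recordings carry technical/surplus flags; of the
    remaining 1005, 60 belong to drug-screen-positive participants, 24 to
    subclinical participants and 1 has a severe-cold flag, leaving 920
    included recordings (554 ADHD + 247 HC + 119 PC; the ADHD-vs-HC contrast
    therefore spans 801 recordings, 71 of them made on medication).  The 76
    excluded participants split 55 drug / 7 technical / 14 subclinical.
    """
    p_rows, r_rows = [], []
    rec_num = 0

    def participant(pid, group, sex, age, education, total, subtype="none",
                    drug=False, subclinical=False, comorbid=False):
        t = SYMPTOM_TARGETS[group]
        rec = ParticipantRecord(
            id=pid, group=group, adhd_subtype=subtype, sex=sex, age=age,
            education=education, drug_screen_positive=drug,
            subclinical=subclinical, comorbid=comorbid,
            adhd_dc_items=_decompose_items(total), adhd_dc_total=total,
            inattention=t["inattention"][0], hyperactivity=t["hyperactivity"][0],
            wurs_k=t["wurs_k"][0], bdi=t["bdi"][0],
        )
        voice = VoiceParams(f0_base=115.0 if sex == "male" else 210.0)
        p_rows.append(_participant_row(rec, voice))

    def recording(pid, visit, technical_ok=True, on_med=False, cold=False):
        nonlocal rec_num
        rec_num += 1
        r_rows.append(_recording_row(RecordingRecord(
            id=f"R{rec_num:05d}", participant_id=pid, visit_index=visit,
            technical_ok=technical_ok, on_medication=on_med, severe_cold=cold,
        ), rec_num))

    def ages(i):  # deterministic 18-59 ramp
        return 18.0 + (i * 7) % 42

    def edu(i):
        return 1 + i % 5

    # --- ADHD: 387 participants, 554 included recordings -------------------
    n_med = 0
    for i in range(387):
        sex = "male" if i < 221 else "female"
        subtype = "ATT" if i % 2 == 0 else "COM"
        participant(f"A{i:04d}", "ADHD", sex, ages(i), edu(i),
                    total=35 + i % 11, subtype=subtype, comorbid=i % 2 == 1)
        n_recs = 2 if i < 167 else 1
        for v in range(1, n_recs + 1):
            on_med = n_med < 71
            n_med += int(on_med)
            recording(f"A{i:04d}", v, on_med=on_med)
        if i < 17:                       # extra technically flawed recording
            recording(f"A{i:04d}", n_recs + 1, technical_ok=False)
        if i == 17:                      # the one severe-cold recording
            recording(f"A{i:04d}", n_recs + 1, cold=True)

    # --- HC: 204 participants, 247 recordings ------------------------------
    for i in range(204):
        sex = "male" if i < 75 else "female"
        participant(f"H{i:04d}", "HC", sex, ages(i), edu(i), total=3 + i % 5)
        for v in range(1, (2 if i < 43 else 1) + 1):
            recording(f"H{i:04d}", v)

    # --- PC: 100 participants, 119 recordings ------------------------------
    for i in range(100):
        sex = "male" if i < 36 else "female"
        participant(f"P{i:04d}", "PC", sex, ages(i), edu(i), total=18 + i % 11)
        for v in range(1, (2 if i < 19 else 1) + 1):
            recording(f"P{i:04d}", v)

    # --- excluded: 55 drug (60 recs), 7 technical (7), 14 subclinical (24) -
    for i in range(55):
        sex = "male" if i < 41 else "female"
        participant(f"XD{i:03d}", "EXCLUDED", sex, ages(i), edu(i),
                    total=30 + i % 13, drug=True)
        for v in range(1, (2 if i < 5 else 1) + 1):
            recording(f"XD{i:03d}", v)
    for i in range(7):
        participant(f"XT{i:03d}", "EXCLUDED", "male" if i < 5 else "female",
                    ages(i), edu(i), total=30 + i % 13)
        recording(f"XT{i:03d}", 1, technical_ok=False)
    for i in range(14):
        participant(f"XS{i:03d}", "EXCLUDED", "male" if i < 10 else "female",
                    ages(i), edu(i), total=20 + i % 7, subclinical=True)
        for v in range(1, (2 if i < 10 else 1) + 1):
            recording(f"XS{i:03d}", v)

    return CohortManifest(
        pd.DataFrame(p_rows, columns=PARTICIPANT_COLUMNS),
        pd.DataFrame(r_rows, columns=RECORDING_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

_FRAME_HOP = 0.004  # parameter-track resolution, s


def _voicing_track(task: str, n_frames: int, hop: float,
                   pause_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean voiced mask on the frame grid."""
    if task == "vowels":
        return np.ones(n_frames, dtype=bool)
    mask = np.zeros(n_frames, dtype=bool)
    if task in ("counting", "words"):
        # ten short word bursts with brief gaps, scaled to the duration
        word = max(1, n_frames // 10)
        voiced_len = max(1, int(word * 0.7))
        for k in range(10):
            start = k * word
            mask[start: start + voiced_len] = True
        return mask
    # free speech: alternating voiced stretches and pauses
    pos = 0
    while pos < n_frames:
        voiced_len = int(round(rng.uniform(0.8, 2.0) / hop))
        mask[pos: pos + voiced_len] = True
        pos += voiced_len
        if pause_fraction > 0:
            pause = voiced_len * pause_fraction / (1 - pause_fraction)
            pos += int(round(pause * rng.uniform(0.7, 1.3)))
    return mask


def _smooth_noise(rng: np.random.Generator, n: int, kernel_frames: int,
                  target_sd: float) -> np.ndarray:
    """Low-passed Gaussian noise with the requested SD (zero if sd == 0)."""
    white = rng.standard_normal(n)  # always consumed: keeps streams aligned
    if target_sd == 0.0 or n == 1:
        return np.zeros(n)
    k = np.hanning(max(3, kernel_frames))
    sm = fftconvolve(white, k / k.sum(), mode="same")
    sd = sm.std()
    return sm * (target_sd / sd) if sd > 0 else np.zeros(n)


def _highpass_noise(rng: np.random.Generator, n: int, kernel_frames: int,
                    target_sd: float) -> np.ndarray:
    """Gaussian noise with its slow component removed, scaled to target SD.

    Micro-variability parameters describe *short-timescale* fluctuation, so
    the noise is white minus its own moving average over ``kernel_frames``;
    slower structure is the province of the syllable/phrase modulations.
    """
    white = rng.standard_normal(n)  # always consumed: keeps streams aligned
    if target_sd == 0.0 or n == 1:
        return np.zeros(n)
    k = np.ones(max(3, kernel_frames))
    high = white - fftconvolve(white, k / k.sum(), mode="same")
    sd = high.std()
    return high * (target_sd / sd) if sd > 0 else np.zeros(n)


def synth_utterance(
    task: str,
    voice: VoiceParams,
    duration: float,
    sample_rate: float = 22050.0,
    seed: Union[int, np.random.SeedSequence] = 0,
) -> np.ndarray:
    """Synthesise one speech-like utterance (mono float waveform in [-1, 1]).

    Voiced stretches are a sum of the first 10 harmonics with 1/k roll-off
    following the F0 trajectory ``f0_base * 2**(drift + micro)``; the
    amplitude envelope multiplies the base level, syllable-rate and
    phrase-rate modulations and a short-timescale fluctuation
    ``1 + micro``; additive white noise is scaled by ``hnr_noise``.
    Deterministic given (task, voice, duration, sample_rate, seed).
    """
    if task not in TASK_LABELS:
        raise ValueError(f"invalid task label {task!r}; expected one of {TASK_LABELS}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate < 16000:
        raise ValueError("sample_rate must be at least 16 kHz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    hop = _FRAME_HOP
    m = int(np.ceil(n / (hop * sample_rate))) + 1
    t_frames = np.arange(m) * hop
    t_samples = np.arange(n) / sample_rate

    voiced = _voicing_track(task, m, hop, voice.pause_fraction, rng)

    micro_kernel = int(round(0.3 / hop))
    drift = _smooth_noise(rng, m, int(round(1.0 / hop)), voice.f0_drift_sd)
    micro_f0 = _highpass_noise(rng, m, micro_kernel, voice.f0_micro_sd)
    f0_frames = voice.f0_base * 2.0 ** (drift + micro_f0)
    f0_frames = np.clip(f0_frames, 60.0, 500.0)

    phase0 = rng.uniform(0, 2 * np.pi, 2)
    syl = 0.55 + 0.45 * np.sin(2 * np.pi * voice.syllable_rate * t_frames + phase0[0])
    phrase = 0.85 + 0.15 * np.sin(2 * np.pi * 0.2 * t_frames + phase0[1])
    micro_env = np.clip(1.0 + _highpass_noise(rng, m, micro_kernel, voice.loud_micro_sd),
                        0.05, None)

    gate = fftconvolve(voiced.astype(float), np.ones(3) / 3.0, mode="same")
    env_frames = voice.loud_base * syl * phrase * micro_env * gate

    f0_s = np.interp(t_samples, t_frames, f0_frames)
    env_s = np.interp(t_samples, t_frames, env_frames)
    phi = 2.0 * np.pi * np.cumsum(f0_s) / sample_rate

    n_harm = max(1, min(10, int(0.45 * sample_rate / f0_frames.max())))
    amps = 1.0 / np.arange(1, n_harm + 1)
    harm = np.zeros(n)
    for k, a in enumerate(amps, start=1):
        harm += a * np.sin(k * phi)
    harm /= amps.sum()

    x = env_s * harm + voice.hnr_noise * voice.loud_base * rng.standard_normal(n)
    peak = np.abs(x).max()
    if peak > 1.0:
        x = x / peak
    return x


_TASK_CODE = {"free_speech": 1, "counting": 2, "vowels": 3, "words": 4}


def render_recording(
    manifest: CohortManifest,
    recording_id: str,
    master_seed: int = 0,
    tasks: Sequence[str] = ("free_speech", "counting", "counting"),
) -> Dict[str, object]:
    """Synthesise the waveforms of one manifest recording.

    Returns ``{"free_speech": waveform, "counting": [trial1, trial2]}`` (or
    the subset requested).  Waveform seeds derive from
    (master_seed, recording number, task, trial), so a manifest plus a master
    seed fully determines every sample.
    """
    row = manifest.recordings.set_index("id").loc[recording_id]
    voice = manifest.voice_params(row["participant_id"])
    sr = float(row["sample_rate"])
    out: Dict[str, object] = {}
    trial_count: Dict[str, int] = {}
    for task in tasks:
        trial = trial_count.get(task, 0)
        trial_count[task] = trial + 1
        dur = (row["duration_free_speech"] if task == "free_speech"
               else row["duration_counting"])
        ss = np.random.SeedSequence(
            (int(master_seed), int(row["rec_num"]), _TASK_CODE[task], trial)
        )
        wf = synth_utterance(task, voice, float(dur), sr, ss)
        if task == "counting":
            out.setdefault("counting", []).append(wf)
        else:
            out[task] = wf
    return out


# ---------------------------------------------------------------------------
# WAV I/O (16-bit PCM mono)
# ---------------------------------------------------------------------------

def write_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write a float waveform in [-1, 1] as mono 16-bit PCM."""
    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(sample_rate), np.round(x * 32767.0).astype(np.int16))


def read_wav(path) -> Tuple[np.ndarray, float]:
    """Read a mono 16-bit PCM WAV back to float in [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono WAV")
    return data.astype(float) / 32767.0, float(sr)
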