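"""Synthetic cohort generator: waveforms, participants, manifests."""

import numpy as np
import pytest

from prosovoice.audio_features import f0_contour
from prosovoice.multiscale import extract_features, parse_feature_name
from prosovoice.synthetic_voice import (
    CohortConfig,
    VoiceParams,
    generate_cohort,
    read_wav,
    reference_cohort,
    render_recording,
    sample_participant,
    synth_utterance,
    write_wav,
)

SR = 22050


def clean_voice(**kw):
    base = dict(f0_micro_sd=0.0, f0_drift_sd=0.0, hnr_noise=0.0,
                pause_fraction=0.0, loud_micro_sd=0.0)
    base.update(kw)
    return VoiceParams(**base)


class TestSynthUtterance:
    def test_deterministic_given_seed(self):
        v = VoiceParams()
        a = synth_utterance("free_speech", v, 2.0, SR, seed=3)
        b = synth_utterance("free_speech", v, 2.0, SR, seed=3)
        assert np.array_equal(a, b)

    def test_duration_and_no_clipping(self):
        v = VoiceParams(loud_base=0.9, loud_micro_sd=0.5)
        w = synth_utterance("free_speech", v, 1.5, SR, seed=1)
        assert len(w) == int(round(1.5 * SR))
        assert np.abs(w).max() <= 1.0

    @pytest.mark.parametrize("bad_task", ["reading", "", "FREE_SPEECH"])
    def test_invalid_task_rejected(self, bad_task):
        with pytest.raises(ValueError, match="task"):
            synth_utterance(bad_task, VoiceParams(), 1.0, SR, seed=0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            synth_utterance("counting", VoiceParams(), 0.0, SR, seed=0)

    def test_tracker_recovers_f0_base_on_clean_voice(self):
        v = clean_voice(f0_base=130.0)
        w = synth_utterance("free_speech", v, 2.0, SR, seed=2)
        c = f0_contour(w, SR)
        f0 = 100.0 * 2.0 ** c.values[c.valid_mask]
        close = np.abs(f0 - 130.0) / 130.0 < 0.02
        assert close.mean() >= 0.90

    def test_micro_variability_raises_short_span_derivative_sd(self):
        """Envelope fluctuation must surface in short-span loudness features."""
        wf = {}
        for name, sd in (("A", 0.3), ("B", 0.0)):
            v = clean_voice(loud_micro_sd=sd)
            wf[name] = {
                "free_speech": synth_utterance("free_speech", v, 8.0, SR, seed=4),
                "counting": [synth_utterance("counting", v, 4.0, SR, seed=5)],
            }
        fa = extract_features(wf["A"])
        fb = extract_features(wf["B"])
        names = [n for n in fa.index
                 if (lambda i: i["signal"] == "loudness" and i["layer"] == "derivative"
                     and i["stat"] == "sd" and i["span_s"] <= 0.252)(parse_feature_name(n))]
        assert (fa[names] > fb[names]).all()

    def test_wav_roundtrip(self, tmp_path):
        w = synth_utterance("counting", VoiceParams(), 1.0, SR, seed=6)
        path = tmp_path / "x.wav"
        write_wav(path, w, SR)
        back, sr = read_wav(path)
        assert sr == SR
        assert np.abs(back - w).max() < 1.0 / 32000


class TestVoiceParams:
    @pytest.mark.parametrize("kw", [
        dict(f0_base=50.0), dict(f0_base=600.0), dict(pause_fraction=0.7),
        dict(loud_base=0.0), dict(f0_micro_sd=-0.1),
    ])
    def test_invariants_enforced(self, kw):
        with pytest.raises(ValueError):
            VoiceParams(**kw)


class TestSampleParticipant:
    def test_hc_interview_total_moments(self):
        """1000 draws reproduce the healthy-control 5.2 +/- 4.4 summary."""
        totals = np.array([sample_participant("HC", seed=s)[0].adhd_dc_total
                           for s in range(1000)])
        assert abs(totals.mean() - 5.2) < 0.5
        assert abs(totals.std(ddof=1) - 4.4) < 0.5

    def test_adhd_interview_total_mean(self):
        totals = np.array([sample_participant("ADHD", seed=s)[0].adhd_dc_total
                           for s in range(1000)])
        assert abs(totals.mean() - 40.0) < 1.0

    def test_item_decomposition_invariants(self):
        for s in range(50):
            rec, _ = sample_participant("PC", seed=s)
            assert len(rec.adhd_dc_items) == 22
            assert all(0 <= v <= 3 for v in rec.adhd_dc_items)
            assert sum(rec.adhd_dc_items) == rec.adhd_dc_total
            assert 0 <= rec.adhd_dc_total <= 66

    def test_com_subtype_more_hyperactive_than_att(self):
        hyper = {"ATT": [], "COM": []}
        for s in range(400):
            rec, _ = sample_participant("ADHD", seed=s)
            hyper[rec.adhd_subtype].append(rec.hyperactivity)
        assert np.mean(hyper["COM"]) > np.mean(hyper["ATT"]) + 2.0

    def test_null_mode_voice_params_identical_across_groups(self):
        """g = 0 with balanced confounds: same seed -> same VoiceParams."""
        cfg = CohortConfig(effect_gain_loud=0.0, effect_gain_f0=0.0,
                           balanced_confounds=True)
        for s in range(30):
            voices = [sample_participant(g, cfg, seed=s)[1]
                      for g in ("ADHD", "HC", "PC")]
            assert voices[0] == voices[1] == voices[2]

    def test_effect_gain_monotone_in_group_separation(self):
        """Larger g -> larger ADHD-HC gap in micro-variability params."""
        gaps = []
        for g in (0.0, 0.25, 0.5):
            cfg = CohortConfig(effect_gain_loud=g, effect_gain_f0=g)
            a = np.mean([sample_participant("ADHD", cfg, seed=s)[1].loud_micro_sd
                         for s in range(200)])
            h = np.mean([sample_participant("HC", cfg, seed=s)[1].loud_micro_sd
                         for s in range(200)])
            gaps.append(a - h)
        assert gaps[0] == pytest.approx(0.0, abs=1e-12)
        assert gaps[0] < gaps[1] < gaps[2]

    def test_sex_shifts_f0_register(self):
        voices = [sample_participant("HC", seed=s) for s in range(300)]
        male = [v.f0_base for r, v in voices if r.sex == "male"]
        female = [v.f0_base for r, v in voices if r.sex == "female"]
        assert np.mean(female) - np.mean(male) > 60

    def test_age_raises_noise_floor(self):
        voices = [sample_participant("HC", seed=s) for s in range(300)]
        ages = np.array([r.age for r, _ in voices])
        hnr = np.array([v.hnr_noise for _, v in voices])
        assert np.corrcoef(ages, hnr)[0, 1] > 0.99

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            sample_participant("CONTROL", seed=0)


class TestGenerateCohort:
    def test_default_group_sizes_match_study(self):
        m = generate_cohort(seed=0)
        counts = m.participants["group"].value_counts()
        assert counts["ADHD"] == 387
        assert counts["HC"] == 204
        assert counts["PC"] == 100
        assert counts["EXCLUDED"] == 76

    def test_empty_config_gives_empty_manifest(self):
        m = generate_cohort(CohortConfig(n_adhd=0, n_hc=0, n_pc=0, n_excluded=0), 0)
        assert m.n_participants == 0 and m.n_recordings == 0

    def test_deterministic_in_seed(self):
        a = generate_cohort(CohortConfig(n_adhd=10, n_hc=10, n_pc=5, n_excluded=5), 3)
        b = generate_cohort(CohortConfig(n_adhd=10, n_hc=10, n_pc=5, n_excluded=5), 3)
        assert a.participants.equals(b.participants)
        assert a.recordings.equals(b.recordings)

    def test_most_participants_have_multiple_recordings(self):
        m = generate_cohort(CohortConfig(n_adhd=100, n_hc=50, n_pc=0, n_excluded=0), 1)
        per = m.recordings.groupby("participant_id").size()
        assert (per > 1).mean() > 0.5

    def test_render_recording_deterministic(self):
        cfg = CohortConfig(n_adhd=2, n_hc=2, n_pc=0, n_excluded=0,
                           free_speech_duration=1.0, counting_duration=0.5)
        m = generate_cohort(cfg, 5)
        rid = m.recordings["id"].iloc[0]
        a = render_recording(m, rid, master_seed=9)
        b = render_recording(m, rid, master_seed=9)
        assert np.array_equal(a["free_speech"], b["free_speech"])
        assert len(a["counting"]) == 2


class TestReferenceCohort:
    def test_headline_counts(self):
        m = reference_cohort()
        assert m.n_participants == 767
        assert m.n_recordings == 1029
        assert (m.participants["group"] == "EXCLUDED").sum() == 76

    def test_excluded_reasons_partition(self):
        m = reference_cohort()
        excl = m.participants[m.participants["group"] == "EXCLUDED"]
        drug = excl["drug_screen_positive"].sum()
        sub = excl["subclinical"].sum()
        tech = len(excl) - drug - sub
        assert (drug, tech, sub) == (55, 7, 14)

    def test_csv_roundtrip(self, tmp_path):
        from prosovoice.synthetic_voice import CohortManifest

        m = reference_cohort()
        m.to_csv(tmp_path / "p.csv", tmp_path / "r.csv")
        back = CohortManifest.from_csv(tmp_path / "p.csv", tmp_path / "r.csv")
        assert back.n_participants == m.n_participants
        assert back.recordings["technical_ok"].sum() == m.recordings["technical_ok"].sum()
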