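"""From waveform to multi-timescale prosodic features.

Renders one utterance, computes the loudness (relative sone) and log-F0
(octaves re 100 Hz) contours, then runs the full 24-span feature extraction
and shows how the short-span loudness-derivative features separate a
high-variability voice from a steady one.
"""

import numpy as np

from prosovoice import VoiceParams, extract_features, f0_contour, loudness_contour, stft_frames, synth_utterance
from prosovoice.multiscale import parse_feature_name

SR = 22050


def features_for(loud_micro_sd):
    # pause-free, noise-free voices isolate the envelope-fluctuation channel:
    # with pauses present, voiced/unvoiced transitions dominate the
    # derivative statistics for both speakers alike
    v = VoiceParams(loud_micro_sd=loud_micro_sd, pause_fraction=0.0,
                    hnr_noise=0.0, f0_drift_sd=0.0, f0_micro_sd=0.005)
    wf = {
        "free_speech": synth_utterance("free_speech", v, 8.0, SR, seed=11),
        "counting": [synth_utterance("counting", v, 3.0, SR, seed=12),
                     synth_utterance("counting", v, 3.0, SR, seed=13)],
    }
    return wf, extract_features(wf)


wf, steady = features_for(0.02)
loud = loudness_contour(stft_frames(wf["free_speech"], SR))
f0 = f0_contour(wf["free_speech"], SR)
print(f"loudness contour: {len(loud)} frames at {loud.frame_hop*1000:.0f} ms hop, "
      f"mean {loud.values.mean():.1f} sone (relative)")
print(f"F0 contour: {f0.valid_mask.mean():.0%} voiced, "
      f"median {100*2**np.nanmedian(f0.values[f0.valid_mask]):.0f} Hz")

_, variable = features_for(0.30)
print(f"\nfeature vector length: {len(steady)}")

def pick(stat, span):
    return next(n for n in steady.index
                if (lambda i: i["signal"] == "loudness" and i["task"] == "free_speech"
                    and i["layer"] == "derivative" and i["stat"] == stat
                    and abs(i["span_s"] - span) < 1e-9)(parse_feature_name(n)))

for stat in ("curvature", "sd"):
    name = pick(stat, 0.02)
    print(f"20 ms-span loudness derivative {stat}: "
          f"variable/steady ratio = {variable[name] / steady[name]:.1f}")
print("The shortest-span curvature is the cleanest readout of envelope "
      "micro-fluctuation (the syllable-rate modulation, common to both "
      "speakers, dilutes the derivative SD).")
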