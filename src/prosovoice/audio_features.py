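"""Base acoustic contours: perceived loudness and log-scaled fundamental frequency.

A recording is reduced to two uniformly sampled time series ("contours"):

* a loudness contour in relative sone, obtained from a short-time power
  spectrum by aggregating energy into the 24 Bark critical bands and applying
  Zwicker's stationary specific-loudness power law ``N'_b = (E_b/E_ref)**0.23``
  summed over bands;
* an F0 contour in octaves ``log2(F0 / 100 Hz)``, tracked with a YIN-style
  cumulative-mean-normalised difference function, with unvoiced frames masked
  out and short unvoiced gaps bridged by linear interpolation.

The loudness model deliberately implements only the per-band power law — no
spread of masking, no temporal post-masking.  Downstream features depend on the
*shape* of the contour, which the compressive power law captures; a full
ISO 532-B implementation can be substituted via the ``band_loudness`` hook of
:func:`loudness_contour`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Spectrogram",
    "Contour",
    "BARK_EDGES_HZ",
    "LOUDNESS_EXPONENT",
    "stft_frames",
    "reference_energy",
    "loudness_contour",
    "f0_contour",
    "contour_to_frame",
]

#: Critical-band (Bark) edges in Hz, 24 bands spanning 0–15.5 kHz.
BARK_EDGES_HZ = np.array(
    [0, 100, 200, 300, 400, 510, 630, 770, 920, 1080, 1270, 1480, 1720,
     2000, 2320, 2700, 3150, 3700, 4400, 5300, 6400, 7700, 9500, 12000, 15500],
    dtype=float,
)

#: Stevens/Zwicker compressive exponent for specific loudness.
LOUDNESS_EXPONENT = 0.23

#: Default analysis frame: 20 ms window, 4 ms hop.  The shortest smoothing
#: span downstream is 20 ms, and the hop must subdivide it.
DEFAULT_FRAME_LEN = 0.020
DEFAULT_FRAME_HOP = 0.004


@dataclass
class Spectrogram:
    """Short-time power spectrum, one row per frame.

    ``frame_power`` is scaled so that the sum over frequency bins equals the
    mean square of the Hann-windowed frame (a discrete Parseval convention).
    """

    frame_power: np.ndarray  # [n_frames, n_bins], linear power
    frame_hop: float         # s
    frame_len: float         # s
    sample_rate: float       # Hz

    def __post_init__(self) -> None:
        self.frame_power = np.asarray(self.frame_power, dtype=float)
        if self.frame_power.ndim != 2 or self.frame_power.shape[0] < 1:
            raise ValueError("frame_power must be a non-empty 2-D array")
        if np.any(self.frame_power < 0):
            raise ValueError("frame powers must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frame_power.shape[0]

    @property
    def bin_freqs(self) -> np.ndarray:
        n_fft = 2 * (self.frame_power.shape[1] - 1)
        return np.fft.rfftfreq(n_fft, d=1.0 / self.sample_rate)


@dataclass
class Contour:
    """A value-over-time series sampled at the frame hop.

    ``valid_mask`` is all-True for loudness; for F0 it marks voiced frames.
    Values may be finite on invalid frames (interpolated short unvoiced gaps)
    or NaN (long gaps / no voicing), which splits the contour into segments
    for smoothing.
    """

    values: np.ndarray
    frame_hop: float
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask length must match values length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_hop

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def to_csv(self, path) -> None:
        """Write (frame_time, value, valid) rows for inspection."""
        import pandas as pd

        pd.DataFrame(
            {"frame_time": self.times, "value": self.values,
             "valid": self.valid_mask.astype(int)}
        ).to_csv(path, index=False)


def _frame_signal(x: np.ndarray, frame_samps: int, hop_samps: int) -> np.ndarray:
    """Frames [t, t+frame_len) starting every hop; final frames zero-padded."""
    n = x.size
    n_frames = max(1, int(np.ceil(n / hop_samps)))
    padded = np.concatenate([x, np.zeros(frame_samps)])
    view = np.lib.stride_tricks.sliding_window_view(padded, frame_samps)
    return np.ascontiguousarray(view[:: hop_samps][:n_frames])


def stft_frames(
    waveform: np.ndarray,
    sample_rate: float,
    frame_len: float = DEFAULT_FRAME_LEN,
    frame_hop: float = DEFAULT_FRAME_HOP,
) -> Spectrogram:
    """Hann-windowed short-time power spectrum.

    Frames follow the half-open convention ``[t, t + frame_len)`` with one
    frame starting every ``frame_hop``; the trailing partial frame is
    zero-padded.  Bin powers sum to the mean square of the windowed frame.
    """
    x = np.asarray(waveform, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("waveform is empty")
    if not (frame_len >= frame_hop > 0):
        raise ValueError("need frame_len >= frame_hop > 0")
    frame_samps = int(round(frame_len * sample_rate))
    hop_samps = int(round(frame_hop * sample_rate))
    frames = _frame_signal(x, frame_samps, hop_samps)
    window = np.hanning(frame_samps)
    spec = np.fft.rfft(frames * window, axis=1)
    power = (np.abs(spec) ** 2) / frame_samps**2
    # fold negative frequencies into positive bins (rfft halves the spectrum)
    if frame_samps % 2 == 0:
        power[:, 1:-1] *= 2.0
    else:
        power[:, 1:] *= 2.0
    # Parseval: sum over bins now equals mean((window * frame)**2)
    return Spectrogram(power, frame_hop, frame_len, sample_rate)


def reference_energy(
    sample_rate: float,
    frame_len: float = DEFAULT_FRAME_LEN,
    target_loudness: float = 40.0,
) -> float:
    """Calibration energy ``E_ref`` for the loudness power law.

    Chosen so the windowed energy of a full-scale 1 kHz sine (mean square
    0.5), concentrated in one critical band, maps to specific loudness
    ``target_loudness`` in that band (spectral leakage into neighbouring
    bands adds a small compressed contribution on top).  Absolute level
    calibration (phon) is unavailable for the recordings this models, so any
    fixed reference is admissible: downstream features are covariant under a
    common rescaling.
    """
    window = np.hanning(int(round(frame_len * sample_rate)))
    sine_energy = 0.5 * np.mean(window**2)
    return sine_energy / target_loudness ** (1.0 / LOUDNESS_EXPONENT)


def _band_slices(bin_freqs: np.ndarray, nyquist: float) -> list[np.ndarray]:
    edges = np.minimum(BARK_EDGES_HZ, nyquist)
    masks = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            masks.append(np.zeros(bin_freqs.size, dtype=bool))
        else:
            masks.append((bin_freqs >= lo) & (bin_freqs < hi))
    return masks


def loudness_contour(
    spec: Spectrogram,
    calibration: Optional[float] = None,
    band_loudness: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> Contour:
    """Perceived-loudness contour (relative sone) from a spectrogram.

    Per frame: bin powers are aggregated into the 24 Bark critical bands
    (clipped to Nyquist), each band is compressed with the specific-loudness
    power law, and specific loudnesses are summed.  ``band_loudness`` may
    replace the per-band compressive map (hook for a full ISO 532-B model);
    it receives the [n_frames, 24] band-energy matrix already divided by
    ``E_ref`` and must return specific loudness of the same shape.
    """
    if calibration is None:
        calibration = reference_energy(spec.sample_rate, spec.frame_len)
    masks = _band_slices(spec.bin_freqs, spec.sample_rate / 2.0)
    band_energy = np.stack(
        [spec.frame_power[:, m].sum(axis=1) for m in masks], axis=1
    )
    rel = band_energy / calibration
    if band_loudness is None:
        specific = rel ** LOUDNESS_EXPONENT
    else:
        specific = np.asarray(band_loudness(rel), dtype=float)
    loud = specific.sum(axis=1)
    return Contour(loud, spec.frame_hop)


# ---------------------------------------------------------------------------
# F0 tracking (YIN-style cumulative-mean-normalised difference function)
# ---------------------------------------------------------------------------

def _yin_frame_block(
    frames: np.ndarray, tau_min: int, tau_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """CMNDF minima for a block of frames.

    ``frames`` has shape [n_frames, W + tau_max]; the difference function is
    d(tau) = sum_{j<W} (x_j - x_{j+tau})^2, computed with an FFT-based
    cross-correlation.  Returns (tau_star_float, cmndf_at_min).
    """
    from scipy.fft import irfft, next_fast_len, rfft

    n_frames, total = frames.shape
    w = total - tau_max
    # circular wrap-around only corrupts lags below w-1, outside the
    # [w-1, w-1+tau_max] region read below, so total-length transforms do
    n_fft = next_fast_len(total)
    fx = rfft(frames, n_fft, axis=1)
    head = frames[:, :w]
    fh = rfft(head[:, ::-1], n_fft, axis=1)
    corr_full = irfft(fx * fh, n_fft, axis=1)
    # corr(tau) = sum_j x_j * x_{j+tau} lives at index w-1+tau
    taus = np.arange(tau_max + 1)
    corr = corr_full[:, w - 1: w - 1 + tau_max + 1]

    sq = frames**2
    csum = np.concatenate(
        [np.zeros((n_frames, 1)), np.cumsum(sq, axis=1)], axis=1
    )
    e0 = csum[:, w] - csum[:, 0]                      # energy of x_j, j<W
    e_tau = csum[:, taus + w] - csum[:, taus]         # energy of x_{j+tau}
    d = e0[:, None] + e_tau - 2.0 * corr
    d = np.maximum(d, 0.0)

    # cumulative mean normalisation
    with np.errstate(divide="ignore", invalid="ignore"):
        cum = np.cumsum(d[:, 1:], axis=1)
        cmndf = np.empty_like(d)
        cmndf[:, 0] = 1.0
        denom = cum / np.arange(1, tau_max + 1)
        cmndf[:, 1:] = np.where(denom > 0, d[:, 1:] / denom, 1.0)

    search = cmndf[:, tau_min: tau_max + 1]
    idx = np.argmin(search, axis=1) + tau_min
    dmin = cmndf[np.arange(n_frames), idx]

    # parabolic interpolation around the minimum of the raw difference fn
    tau_f = idx.astype(float)
    interior = (idx > tau_min) & (idx < tau_max)
    i = np.where(interior)[0]
    if i.size:
        y0 = d[i, idx[i] - 1]
        y1 = d[i, idx[i]]
        y2 = d[i, idx[i] + 1]
        denom2 = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom2) > 1e-12, 0.5 * (y0 - y2) / np.where(denom2 == 0, 1, denom2), 0.0)
        tau_f[i] = idx[i] + np.clip(shift, -0.5, 0.5)
    return tau_f, dmin


def f0_contour(
    waveform: np.ndarray,
    sample_rate: float,
    frame_len: float = 0.040,
    frame_hop: float = DEFAULT_FRAME_HOP,
    fmin: float = 60.0,
    fmax: float = 400.0,
    voicing_threshold: float = 0.15,
    max_gap: float = 0.25,
    block_frames: int = 4000,
) -> Contour:
    """F0 contour in octaves ``log2(F0/100 Hz)`` with a voicing mask.

    YIN-style tracking: per frame the cumulative-mean-normalised difference
    function over lags ``[sr/fmax, sr/fmin]`` is minimised with parabolic
    refinement; frames whose minimum exceeds ``voicing_threshold`` are
    unvoiced.  Unvoiced gaps no longer than ``max_gap`` seconds are linearly
    interpolated (their mask stays False); longer gaps are left NaN, which
    splits the contour into segments for downstream smoothing.  A signal with
    no voiced frame at all yields an all-NaN, all-invalid contour.
    """
    x = np.asarray(waveform, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("waveform is empty")
    if not (fmin < fmax <= sample_rate / 2.0):
        raise ValueError("need fmin < fmax <= Nyquist")
    w = int(round(frame_len * sample_rate))
    hop = int(round(frame_hop * sample_rate))
    tau_min = max(2, int(np.floor(sample_rate / fmax)))
    tau_max = int(np.ceil(sample_rate / fmin))
    need = w + tau_max
    n_frames = max(1, int(np.ceil(x.size / hop)))
    padded = np.concatenate([x, np.zeros(need)])

    f0 = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(padded, need)[::hop]
    for start in range(0, n_frames, block_frames):
        stop = min(start + block_frames, n_frames)
        idx = np.arange(start, stop)
        block = np.ascontiguousarray(windows[start:stop])
        tau_f, dmin = _yin_frame_block(block, tau_min, tau_max)
        v = dmin <= voicing_threshold
        voiced[idx] = v
        with np.errstate(divide="ignore"):
            f = sample_rate / tau_f
        f0[idx[v]] = f[v]

    values = np.full(n_frames, np.nan)
    values[voiced] = np.log2(f0[voiced] / 100.0)

    if voiced.any():
        values = _bridge_short_gaps(values, voiced, int(round(max_gap / frame_hop)))
    return Contour(values, frame_hop, valid_mask=voiced)


def _bridge_short_gaps(values: np.ndarray, voiced: np.ndarray, max_frames: int) -> np.ndarray:
    """Linearly interpolate interior unvoiced runs of length <= max_frames."""
    out = values.copy()
    n = values.size
    idx = np.where(voiced)[0]
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if 0 < gap <= max_frames:
            out[a + 1: b] = np.interp(
                np.arange(a + 1, b), [a, b], [values[a], values[b]]
            )
    return out


def contour_to_frame(contour: Contour):
    """Contour as a pandas DataFrame (frame_time, value, valid)."""
    import pandas as pd

    return pd.DataFrame(
        {"frame_time": contour.times, "value": contour.values,
         "valid": contour.valid_mask}
    )
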