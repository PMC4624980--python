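"""Acoustic and musical descriptors of an audio waveform.

The regression target is the *power slope*: the first derivative of the
Gaussian-smoothed short-time power, which marks note onsets as positive
peaks.  Nine descriptors characterise each stimulus: sound intensity
(short-time power), sharpness (mean positive power derivative — the
density and salience of auditory edges), spectral centroid / entropy /
flux, fluctuation centroid / entropy (periodicity content of the
envelope, i.e. rhythm), pulse clarity (salience of the underlying
pulsation) and key clarity (salience of tonal key).  Pulse and key
clarity are deliberately simple composites: an autocorrelation peak
ratio and a Krumhansl-Kessler profile correlation; they are meant to
order stimuli, not to match any toolbox bit-exactly.

Short features use 50 ms frames with 50 % overlap (a 40 Hz series);
musical features use 3 s frames with 33 % overlap.  Frames are half-open
``[start, start + len)`` in samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import Waveform

__all__ = [
    "FeatureSeries",
    "frame_power",
    "power_slope",
    "sharpness",
    "spectral_features",
    "fluctuation_features",
    "pulse_clarity",
    "key_clarity",
    "resample_series",
    "global_profile",
    "extract_all_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "sound_intensity",
    "sharpness",
    "spectral_centroid",
    "spectral_entropy",
    "spectral_flux",
    "fluctuation_centroid",
    "fluctuation_entropy",
    "pulse_clarity",
    "key_clarity",
)

#: Krumhansl-Kessler tonal hierarchies (probe-tone ratings), C-based.
KK_MAJOR = np.array(
    [6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66, 2.29, 2.88]
)
KK_MINOR = np.array(
    [6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75, 3.98, 2.69, 3.34, 3.17]
)


@dataclass
class FeatureSeries:
    """A per-frame feature: values at ``rate == 1/frame_step`` Hz.

    ``start`` is the time of the first frame's *centre*; frame k covers
    ``[k*frame_step, k*frame_step + frame_len)`` seconds of audio.
    """

    name: str
    values: np.ndarray
    rate: float
    frame_len: float
    frame_step: float
    start: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    def __len__(self):
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(len(self.values)) / self.rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, self.name: self.values})


def _frame_starts(n_samples: int, frame: int, step: int) -> np.ndarray:
    if n_samples < frame:
        raise ValueError(
            f"input of {n_samples} samples is shorter than one {frame}-sample frame"
        )
    n_frames = (n_samples - frame) // step + 1
    return np.arange(n_frames) * step


def frame_power(
    w: Waveform, frame_len: float = 0.05, overlap: float = 0.5
) -> FeatureSeries:
    """Short-time power: mean squared amplitude per frame.

    With the defaults (50 ms frames, 50 % overlap) this is a 40 Hz series
    and doubles as the *sound intensity* feature.
    """
    frame = int(round(frame_len * w.rate))
    step = max(1, int(round(frame * (1 - overlap))))
    starts = _frame_starts(len(w.samples), frame, step)
    sq = w.samples**2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    vals = (csum[starts + frame] - csum[starts]) / frame
    return FeatureSeries(
        name="sound_intensity",
        values=vals,
        rate=w.rate / step,
        frame_len=frame / w.rate,
        frame_step=step / w.rate,
        start=frame / w.rate / 2,
    )


_GAUSS3 = np.exp(-0.5 * np.array([1.0, 0.0, 1.0]))
_GAUSS3 /= _GAUSS3.sum()  # 3-tap kernel, sigma = 1 sample, unit sum


def power_slope(
    p: FeatureSeries, eeg_rate: float = 100.0, duration: float | None = None
) -> FeatureSeries:
    """First derivative of the smoothed short-time power, on the EEG grid.

    The power series is smoothed with a three-sample Gaussian kernel,
    forward-differenced (scaled by the frame rate, units power/s) and
    linearly resampled to ``eeg_rate``.  Sign is kept: falling power
    yields negative slope.
    """
    if not eeg_rate > 0:
        raise ValueError("eeg_rate must be positive")
    sm = np.convolve(np.pad(p.values, 1, mode="edge"), _GAUSS3, mode="valid")
    d = np.diff(sm) * p.rate
    # derivative sample j sits between frame centres j and j+1
    d_times = p.times[:-1] + 0.5 / p.rate
    if duration is None:
        duration = p.frame_len + (len(p) - 1) * p.frame_step
    n_out = int(round(duration * eeg_rate))
    t_out = np.arange(n_out) / eeg_rate
    vals = np.interp(t_out, d_times, d, left=0.0, right=0.0)
    return FeatureSeries(
        name="power_slope",
        values=vals,
        rate=eeg_rate,
        frame_len=p.frame_len,
        frame_step=1 / eeg_rate,
    )


def sharpness(
    p: FeatureSeries, frame_len: float = 3.0, overlap: float = 1 / 3
) -> FeatureSeries:
    """Mean positive first difference of the power series per 3 s frame."""
    frame = int(round(frame_len * p.rate))
    step = max(1, int(round(frame * (1 - overlap))))
    starts = _frame_starts(len(p), frame, step)
    d = np.diff(p.values)
    rect = np.maximum(d, 0.0)
    vals = np.array([rect[s : s + frame - 1].mean() for s in starts])
    return FeatureSeries(
        name="sharpness",
        values=vals,
        rate=p.rate / step,
        frame_len=frame / p.rate,
        frame_step=step / p.rate,
        start=p.start + frame / p.rate / 2,
    )


def _spectra(w: Waveform, frame: int, step: int):
    starts = _frame_starts(len(w.samples), frame, step)
    win = np.hanning(frame)
    segs = np.stack([w.samples[s : s + frame] * win for s in starts])
    power = np.abs(np.fft.rfft(segs, axis=1)) ** 2
    freqs = np.fft.rfftfreq(frame, d=1 / w.rate)
    return starts, power[:, 1:], freqs[1:]  # DC bin excluded


def spectral_features(
    w: Waveform, frame_len: float = 0.05, overlap: float = 0.5
) -> tuple[FeatureSeries, FeatureSeries, FeatureSeries]:
    """Spectral centroid (Hz), normalised entropy in [0, 1], and flux.

    Centroid is the power-weighted mean frequency; entropy is the Shannon
    entropy of the normalised power spectrum divided by log(#bins); flux
    is the Euclidean distance between successive normalised spectra (the
    first frame is NaN).  All-zero frames yield NaN.
    """
    frame = int(round(frame_len * w.rate))
    if frame < 2:
        raise ValueError("frame length must span at least 2 samples")
    step = max(1, int(round(frame * (1 - overlap))))
    starts, power, freqs = _spectra(w, frame, step)
    total = power.sum(axis=1)
    ok = total > 0
    centroid = np.full(len(starts), np.nan)
    entropy = np.full(len(starts), np.nan)
    centroid[ok] = (power[ok] * freqs).sum(axis=1) / total[ok]
    q = power[ok] / total[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(q > 0, q * np.log(q), 0.0).sum(axis=1)
    entropy[ok] = h / np.log(power.shape[1])
    flux = np.full(len(starts), np.nan)
    qfull = np.where(ok[:, None], power / np.where(total[:, None] > 0, total[:, None], 1.0), np.nan)
    d = np.linalg.norm(qfull[1:] - qfull[:-1], axis=1)
    flux[1:] = d
    meta = dict(
        rate=w.rate / step,
        frame_len=frame / w.rate,
        frame_step=step / w.rate,
        start=frame / w.rate / 2,
    )
    return (
        FeatureSeries("spectral_centroid", centroid, **meta),
        FeatureSeries("spectral_entropy", entropy, **meta),
        FeatureSeries("spectral_flux", flux, **meta),
    )


def _envelope(seg: np.ndarray, rate: float, frame_len=0.05, overlap=0.5):
    """Short-time power of one segment at a fine step (40 Hz default)."""
    return frame_power(Waveform(seg, rate), frame_len=frame_len, overlap=overlap)


_SILENCE = 1e-12


def _long_frames(w: Waveform, frame_len: float, overlap: float):
    frame = int(round(frame_len * w.rate))
    step = max(1, int(round(frame * (1 - overlap))))
    starts = _frame_starts(len(w.samples), frame, step)
    meta = dict(
        rate=w.rate / step,
        frame_len=frame / w.rate,
        frame_step=step / w.rate,
        start=frame / w.rate / 2,
    )
    return frame, step, starts, meta


def fluctuation_features(
    w: Waveform, frame_len: float = 3.0, overlap: float = 1 / 3, band: float = 10.0
) -> tuple[FeatureSeries, FeatureSeries]:
    """Fluctuation centroid (Hz) and normalised fluctuation entropy.

    Per 3 s frame the amplitude envelope (fine short-time power) is
    Fourier-analysed in the 0-10 Hz band, DC excluded.  The centroid is
    the band's centre of mass; the entropy measures rhythmic complexity.
    Silent frames yield NaN; a purely constant envelope yields 0.
    """
    frame, step, starts, meta = _long_frames(w, frame_len, overlap)
    cent = np.full(len(starts), np.nan)
    ent = np.full(len(starts), np.nan)
    for i, s in enumerate(starts):
        seg = w.samples[s : s + frame]
        if np.max(np.abs(seg)) < _SILENCE:
            continue
        env = _envelope(seg, w.rate)
        e = env.values - env.values.mean()  # DC exclusion
        spec = np.abs(np.fft.rfft(e)) ** 2
        freqs = np.fft.rfftfreq(len(e), d=1 / env.rate)
        m = (freqs > 0) & (freqs <= band)
        p, f = spec[m], freqs[m]
        tot = p.sum()
        if tot <= _SILENCE * len(p):
            cent[i] = 0.0
            ent[i] = 0.0
            continue
        cent[i] = (p * f).sum() / tot
        q = p / tot
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(q > 0, q * np.log(q), 0.0).sum()
        ent[i] = h / np.log(len(q))
    return (
        FeatureSeries("fluctuation_centroid", cent, **meta),
        FeatureSeries("fluctuation_entropy", ent, **meta),
    )


def pulse_clarity(
    w: Waveform,
    frame_len: float = 3.0,
    overlap: float = 1 / 3,
    lag_range: tuple = (0.25, 2.0),
) -> FeatureSeries:
    """Autocorrelation-peak pulse clarity in [0, 1] per 3 s frame.

    The onset-strength envelope (half-wave rectified difference of the
    fine short-time power, mean removed) is autocorrelated; clarity is
    the highest autocorrelation in the 0.25-2 s lag range relative to lag
    zero.  Silent frames yield NaN; frames without onsets yield 0.
    """
    frame, step, starts, meta = _long_frames(w, frame_len, overlap)
    vals = np.full(len(starts), np.nan)
    for i, s in enumerate(starts):
        seg = w.samples[s : s + frame]
        if np.max(np.abs(seg)) < _SILENCE:
            continue
        env = _envelope(seg, w.rate)
        onset = np.maximum(np.diff(env.values), 0.0)
        onset = onset - onset.mean()
        r0 = float(onset @ onset)
        if r0 <= _SILENCE * float(env.values @ env.values):
            vals[i] = 0.0
            continue
        ac = np.correlate(onset, onset, mode="full")[len(onset) - 1 :] / r0
        lags = np.arange(len(ac)) / env.rate
        m = (lags >= lag_range[0]) & (lags <= lag_range[1])
        vals[i] = float(np.clip(ac[m].max(), 0.0, 1.0)) if m.any() else 0.0
    return FeatureSeries("pulse_clarity", vals, **meta)


def _chroma(seg: np.ndarray, rate: float) -> np.ndarray:
    win = np.hanning(len(seg))
    power = np.abs(np.fft.rfft(seg * win)) ** 2
    freqs = np.fft.rfftfreq(len(seg), d=1 / rate)
    m = (freqs >= 55.0) & (freqs <= 2000.0)
    pcs = np.mod(np.round(69 + 12 * np.log2(freqs[m] / 440.0)), 12).astype(int)
    chroma = np.zeros(12)
    np.add.at(chroma, pcs, power[m])
    return np.roll(chroma, -9)  # A-based midi classes -> C-based chroma


_KEY_PROFILES = np.stack(
    [np.roll(KK_MAJOR, k) for k in range(12)]
    + [np.roll(KK_MINOR, k) for k in range(12)]
)


def key_clarity(
    w: Waveform, frame_len: float = 3.0, overlap: float = 1 / 3
) -> FeatureSeries:
    """Maximum Pearson correlation of the frame chroma with the 24
    Krumhansl-Kessler major/minor key profiles, per 3 s frame.

    Uniform chroma gives 0; silent frames give NaN.
    """
    frame, step, starts, meta = _long_frames(w, frame_len, overlap)
    prof = _KEY_PROFILES - _KEY_PROFILES.mean(axis=1, keepdims=True)
    prof_norm = np.linalg.norm(prof, axis=1)
    vals = np.full(len(starts), np.nan)
    for i, s in enumerate(starts):
        seg = w.samples[s : s + frame]
        if np.max(np.abs(seg)) < _SILENCE:
            continue
        c = _chroma(seg, w.rate)
        mu = c.mean()
        c = c - mu
        n = np.linalg.norm(c)
        if n < 1e-6 * max(mu, _SILENCE):  # uniform chroma: no tonal profile
            vals[i] = 0.0
            continue
        vals[i] = float(np.max(prof @ c / (prof_norm * n)))
    return FeatureSeries("key_clarity", vals, **meta)


def resample_series(f: FeatureSeries, target_rate: float) -> FeatureSeries:
    """Linear interpolation of a feature series onto a new uniform grid.

    NaNs are propagated: an output sample bracketed by a NaN input sample
    is NaN, never interpolated across.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if np.isclose(target_rate, f.rate):
        return FeatureSeries(
            f.name, f.values.copy(), f.rate, f.frame_len, f.frame_step, f.start
        )
    t_in = f.times
    span = t_in[-1] - t_in[0] if len(f) > 1 else 0.0
    n_out = int(np.floor(span * target_rate)) + 1
    t_out = t_in[0] + np.arange(n_out) / target_rate
    finite = np.isfinite(f.values)
    filled = np.where(finite, f.values, 0.0)
    vals = np.interp(t_out, t_in, filled)
    # mark outputs whose bracketing inputs include a NaN
    idx_r = np.searchsorted(t_in, t_out, side="left")
    idx_r = np.clip(idx_r, 0, len(t_in) - 1)
    idx_l = np.clip(idx_r - 1, 0, len(t_in) - 1)
    exact = np.isclose(t_out, t_in[idx_r])
    bad = np.where(exact, ~finite[idx_r], ~finite[idx_l] | ~finite[idx_r])
    vals[bad] = np.nan
    return FeatureSeries(
        f.name, vals, target_rate, f.frame_len, 1 / target_rate, start=t_in[0]
    )


def global_profile(features: dict) -> pd.DataFrame:
    """NaN-ignoring mean of each feature per stimulus.

    ``features`` maps stimulus id to a dict ``{feature name: FeatureSeries}``;
    returns a stimuli x features DataFrame.  An all-NaN series is an error
    naming the offending feature.
    """
    rows = {}
    for stim, fdict in features.items():
        row = {}
        for name, series in fdict.items():
            vals = series.values if isinstance(series, FeatureSeries) else np.asarray(series, float)
            if not np.isfinite(vals).any():
                raise ValueError(
                    f"feature {name!r} of stimulus {stim!r} has no finite values"
                )
            row[name] = float(np.nanmean(vals))
        rows[stim] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def extract_all_features(w: Waveform) -> dict:
    """All nine descriptors of one waveform, keyed by feature name."""
    p = frame_power(w)
    sc, se, sf = spectral_features(w)
    fc, fe = fluctuation_features(w)
    return {
        "sound_intensity": p,
        "sharpness": sharpness(p),
        "spectral_centroid": sc,
        "spectral_entropy": se,
        "spectral_flux": sf,
        "fluctuation_centroid": fc,
        "fluctuation_entropy": fe,
        "pulse_clarity": pulse_clarity(w),
        "key_clarity": key_clarity(w),
    }
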