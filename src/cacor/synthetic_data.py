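"""Synthetic study material with known ground truth.

Three generators emulate the data the analysis chain consumes:

* ``synth_tone_sequence`` — an isochronous major-triad chord sequence
  (chord 350 ms including 17.5 ms linear rise/fall ramps, IOI 420 ms,
  root change after 7-11 repetitions), optionally with onset jitter.
* ``synth_eeg`` — a forward model: the audio power slope convolved with
  a biphasic N1-P2-like kernel (negative lobe near 100 ms, positive near
  180 ms) radiates through a fronto-central dipole field of the
  spherical head model; pink (1/f) channel noise and a common 10 Hz
  alpha component are added.  ``coupling`` in [0, 1] scales the planted
  response (0 = EEG independent of the stimulus) and ``snr`` sets the
  average per-channel signal-to-noise amplitude ratio at coupling 1.
* ``synth_ratings`` — groups of continuous tension ratings: each rater
  mixes a lagged shared latent course with an individual smooth random
  walk, plus sensor noise, clipped nonnegative (the joystick has a floor
  at its zero position).

All outputs are reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_features import frame_power, power_slope
from .data_io import STANDARD_61, EEGRecording, RatingSet, Waveform, standard_positions
from .pattern_decomposition import dipole_field

__all__ = [
    "KernelSpec",
    "SimScenario",
    "synth_tone_sequence",
    "synth_eeg",
    "synth_ratings",
    "kernel_taps",
    "kernel_pattern",
    "default_spatial_map",
    "graded_coupling_scenarios",
    "MONTAGE_19",
]

#: standard 10-20 montage used for the scaled-down benchmark studies.
MONTAGE_19 = (
    "Fp1 Fp2 F7 F3 Fz F4 F8 T7 C3 Cz C4 T8 P7 P3 Pz P4 P8 O1 O2".split()
)

#: benchmark coupling grades: nine stimulus conditions spanning the
#: detection transition of the regression (strong tracking down to none),
#: the synthetic analogue of a stimulus set ranging from an isochronous
#: chord sequence to unstructured soundscapes.
GRADED_COUPLINGS = (0.10, 0.065, 0.05, 0.04, 0.032, 0.025, 0.018, 0.010, 0.0)


def graded_coupling_scenarios(
    n_subjects: int = 3,
    n_presentations: int = 3,
    duration: float = 40.0,
    snr: float = 1.0,
    couplings=GRADED_COUPLINGS,
) -> list:
    """Nine-stimulus benchmark study with graded stimulus-EEG coupling."""
    return [
        SimScenario(
            stimulus_id=f"stim{i + 1}",
            coupling=c,
            snr=snr,
            duration=duration,
            n_subjects=n_subjects,
            n_presentations=n_presentations,
            jitter=0.05,
        )
        for i, c in enumerate(couplings)
    ]

#: fronto-central radial dipole (under FCz) used as the default source.
_SOURCE_DIPOLE = np.array([0.0, 0.35, 0.60])
#: posterior radial dipole radiating the common alpha component.
_ALPHA_DIPOLE = np.array([0.0, -0.45, 0.5])


@dataclass
class KernelSpec:
    """Biphasic onset-response kernel over the 0-300 ms latency span."""

    n1_latency: float = 0.10   # s
    p2_latency: float = 0.18   # s
    n1_amp: float = -1.0       # uV, negative lobe
    p2_amp: float = 1.0        # uV, positive lobe
    width: float = 0.03        # s, Gaussian lobe width
    span: float = 0.30         # s, kernel support == embedding span

    def __post_init__(self):
        for lat in (self.n1_latency, self.p2_latency):
            if not 0.0 <= lat <= self.span:
                raise ValueError("kernel latencies must lie within the lag span")


@dataclass
class SimScenario:
    """One synthetic stimulus condition."""

    stimulus_id: str = "stim"
    coupling: float = 1.0      # [0, 1], strength of the planted response
    snr: float = 1.0           # signal-to-noise amplitude ratio at coupling 1
    duration: float = 40.0     # s
    ioi: float = 0.42          # s, interonset interval
    chord_len: float = 0.35    # s
    rise_fall: float = 0.0175  # s
    jitter: float = 0.0        # fraction of the IOI
    audio_rate: float = 8000.0
    alpha_amp: float = 0.5     # common-mode 10 Hz amplitude
    n_subjects: int = 9
    n_presentations: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if not self.chord_len < self.ioi:
            raise ValueError("chord length must be below the IOI")


def kernel_taps(spec: KernelSpec, rate: float = 100.0) -> np.ndarray:
    """Kernel sampled on the EEG grid over its 0-300 ms support."""
    t = np.arange(int(round(spec.span * rate)) + 1) / rate
    g = lambda mu: np.exp(-0.5 * ((t - mu) / spec.width) ** 2)
    return spec.n1_amp * g(spec.n1_latency) + spec.p2_amp * g(spec.p2_latency)


def default_spatial_map(channel_labels) -> np.ndarray:
    """Unit-norm fronto-central dipole field on the given montage."""
    pos = standard_positions(channel_labels)
    v = dipole_field(pos, _SOURCE_DIPOLE, _SOURCE_DIPOLE / np.linalg.norm(_SOURCE_DIPOLE))
    return v / np.linalg.norm(v)


def kernel_pattern(
    spec: KernelSpec, channel_labels, rate: float = 100.0, spatial_map=None
) -> np.ndarray:
    """Ground-truth channels x lags pattern of the planted response."""
    m = default_spatial_map(channel_labels) if spatial_map is None else spatial_map
    return np.outer(m, kernel_taps(spec, rate))


# ---------------------------------------------------------------------------
# audio


_CHROMATIC_ROOTS = 220.0 * 2.0 ** (np.arange(12) / 12.0)  # A3-based roots


def synth_tone_sequence(
    ioi: float = 0.42,
    chord_len: float = 0.35,
    rise_fall: float = 0.0175,
    duration: float = 60.0,
    rate: float = 8000.0,
    jitter: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Isochronous major-triad chord sequence.

    Returns ``(Waveform, onset times)``.  One onset is emitted per
    complete IOI cycle (``floor(duration / ioi)`` onsets); the root note
    changes to a random chromatic root every 7-11 repetitions.
    ``jitter`` displaces each onset uniformly by up to ``jitter * ioi``.
    """
    if not chord_len < ioi:
        raise ValueError("chord length must be below the IOI")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_onsets = int(np.floor(duration / ioi))
    if n_onsets < 1:
        raise ValueError("duration shorter than one IOI")
    onsets = np.arange(n_onsets) * ioi
    if jitter > 0:
        onsets = onsets + rng.uniform(-jitter, jitter, n_onsets) * ioi
        onsets = np.clip(onsets, 0.0, duration - chord_len)
        onsets.sort()
    n = int(round(duration * rate))
    samples = np.zeros(n)
    n_chord = int(round(chord_len * rate))
    t = np.arange(n_chord) / rate
    ramp = np.minimum(1.0, np.minimum(t, chord_len - t) / max(rise_fall, 1e-9))
    root = _CHROMATIC_ROOTS[rng.integers(12)]
    until = rng.integers(7, 12)
    count = 0
    for onset in onsets:
        if count >= until:
            root = _CHROMATIC_ROOTS[rng.integers(12)]
            until = rng.integers(7, 12)
            count = 0
        chord = sum(
            np.sin(2 * np.pi * root * 2.0 ** (s / 12.0) * t) for s in (0, 4, 7)
        )
        i = int(round(onset * rate))
        seg = (0.9 / 3.0) * ramp * chord
        samples[i : i + n_chord] += seg[: max(0, n - i)]
        count += 1
    return Waveform(samples=samples, rate=rate), onsets


# ---------------------------------------------------------------------------
# EEG forward model


def _pink_noise(rng, n_ch, n, rate):
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1 / rate)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    out = np.fft.irfft(spec * scale, n=n, axis=1)
    rms = out.std(axis=1, keepdims=True)
    return out / np.where(rms > 0, rms, 1.0)


def synth_eeg(
    slope: np.ndarray,
    spec: KernelSpec | None = None,
    snr: float = 1.0,
    coupling: float = 1.0,
    channel_labels=STANDARD_61,
    rate: float = 100.0,
    alpha_amp: float = 0.5,
    seed: int | np.random.Generator = 0,
    subject_id: str = "S1",
    stimulus_id: str = "stim",
    presentation_index: int = 1,
    rectified: bool = False,
) -> EEGRecording:
    """One EEG presentation coupled to an audio power slope.

    The source time course is the (signed, or half-wave rectified when
    ``rectified``) slope convolved with the biphasic kernel, normalised
    to unit RMS; it radiates through the fronto-central dipole field and
    is scaled so the average per-channel signal-to-noise amplitude ratio
    equals ``coupling * snr`` against unit-RMS pink noise.  A common
    10 Hz alpha component with random phase radiates from a posterior
    dipole.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = spec or KernelSpec()
    slope = np.asarray(slope, dtype=float)
    n = len(slope)
    labels = list(channel_labels)
    n_ch = len(labels)
    pos = standard_positions(labels)
    drive = np.maximum(slope, 0.0) if rectified else slope
    source = np.convolve(drive, kernel_taps(spec, rate))[:n]
    rms = source.std()
    if rms > 0:
        source = source / rms
    smap = default_spatial_map(labels)
    data = _pink_noise(rng, n_ch, n, rate)
    alpha_topo = dipole_field(pos, _ALPHA_DIPOLE, _ALPHA_DIPOLE / np.linalg.norm(_ALPHA_DIPOLE))
    alpha_topo = alpha_topo / np.linalg.norm(alpha_topo)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / rate
    data += alpha_amp * np.sqrt(n_ch) * np.outer(
        alpha_topo, np.sin(2 * np.pi * 10.0 * t + phase)
    )
    data += coupling * snr * np.sqrt(n_ch) * np.outer(smap, source)
    return EEGRecording(
        data=data,
        rate=rate,
        channel_labels=labels,
        positions=pos,
        subject_id=subject_id,
        stimulus_id=stimulus_id,
        presentation_index=presentation_index,
    )


def slope_of(w: Waveform, eeg_rate: float = 100.0) -> np.ndarray:
    """Audio power slope of a waveform on the EEG grid (convenience)."""
    return power_slope(frame_power(w), eeg_rate, duration=w.duration).values


# ---------------------------------------------------------------------------
# ratings


def _smooth_walk(rng, n, rate, tau: float = 0.3):
    """Unit-variance smooth individual course (Gaussian-filtered noise).

    The ~``tau``-second smoothing matches joystick-like movement; keeping
    many effective degrees of freedom over a stimulus makes independent
    raters genuinely uncorrelated (a pure integrated walk would produce
    large spurious pairwise correlations).
    """
    from scipy.ndimage import gaussian_filter1d

    w = gaussian_filter1d(rng.standard_normal(n), sigma=tau * rate)
    sd = w.std()
    return (w - w.mean()) / (sd if sd > 0 else 1.0)


def synth_ratings(
    latent: np.ndarray,
    n_raters: int = 14,
    coupling: float = 0.8,
    noise_sd: float = 0.05,
    lag: float = 1.0,
    rate: float = 50.0,
    seed: int | np.random.Generator = 0,
    stimulus_id: str = "stim",
) -> RatingSet:
    """Group of continuous ratings tracking a shared latent course.

    Each rater is ``coupling * latent(t - lag) + (1 - coupling) * walk +
    noise`` (the walk is an individual smooth random process matched to
    the latent's scale), shifted to a positive baseline and clipped at
    the joystick's zero position.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = np.asarray(latent, dtype=float)
    n = len(latent)
    t = np.arange(n) / rate
    lagged = np.interp(t - lag, t, latent, left=latent[0])
    sd = lagged.std()
    z = (lagged - lagged.mean()) / (sd if sd > 0 else 1.0)
    rows = []
    for _ in range(n_raters):
        walk = _smooth_walk(rng, n, rate)
        r = coupling * z + (1.0 - coupling) * walk
        r = r + rng.normal(0.0, noise_sd, n)
        rows.append(np.clip(r + 2.0, 0.0, None))  # positive resting baseline
    return RatingSet(
        ratings=np.stack(rows), rate=rate, stimulus_id=stimulus_id
    )
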