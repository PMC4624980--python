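"""Run configuration: every tunable of the analysis chain with its default.

Defaults follow the published protocol wherever one is stated (50 ms audio
frames with 50 % overlap, 3 s musical-feature frames with 33 % overlap,
100 Hz EEG rate, 30 embedding lags = 0-300 ms latency span, 3 s / 90 %
time-resolved correlation windows, 2 s / 10 s autocorrelation horizons,
alpha = 0.05, FDR q < 0.05, 1 s / 50 % rating-activity windows, 0-3 s lag
grid in 10 ms steps with a 1 s fallback).  The remaining knobs (surrogate
counts, head-model grid density, stopping thresholds) are free choices
documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    # audio framing
    frame_len: float = 0.05          # s, short-time power frames
    frame_overlap: float = 0.5       # fraction
    long_frame_len: float = 3.0      # s, musical-feature frames
    long_frame_overlap: float = 1 / 3

    # EEG preprocessing / regression
    eeg_rate: float = 100.0          # Hz after decimation
    lowpass_pass: float = 42.0       # Hz, Chebyshev-I passband edge
    lowpass_stop: float = 49.0       # Hz, stopband edge
    highpass: float = 1.0            # Hz
    n_lags: int = 30                 # embedding lags -> 0..300 ms latency

    # significance
    n_surrogates: int = 999
    alpha: float = 0.05
    fdr_q: float = 0.05
    one_sided: bool = True           # positive-correlation alternative
    pyper_max_lag: float = 2.0       # s, autocorrelation horizon for CACor
    pyper_max_lag_partial: float = 10.0  # s, for partial correlations

    # time-resolved correlation
    tr_window: float = 3.0           # s
    tr_overlap: float = 0.9          # fraction -> 0.3 s step, 3.33 Hz

    # ratings
    rating_rate: float = 50.0        # Hz, joystick sampling
    rating_target_rate: float = 10 / 3  # Hz, time-resolved CACor grid
    lag_max: float = 3.0             # s, rating-vs-intensity search window
    lag_step: float = 0.01           # s
    lag_fallback: float = 1.0        # s, when no clear peak exists
    lag_prominence: float = 0.01     # correlation units above zero-lag
    activity_window: float = 1.0     # s
    activity_overlap: float = 0.5
    n_permutations: int = 999

    # pattern decomposition
    svd_var_frac: float = 0.98
    music_max_components: int = 4
    music_min_corr: float = 0.8
    grid_radii: tuple = (0.30, 0.45, 0.60, 0.75, 0.85)
    grid_spacing: float = 0.15       # fraction of head radius

    # reference-pattern selection
    reference_channel: str = "Fz"
    reference_window: tuple = (0.13, 0.28)  # s after tone onset
    reference_halfwidth: float = 0.01       # s, +-10 ms topography average

    seed: int = 0

    def to_file(self, path) -> None:
        """Write as a plain ``key = value`` text file."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.type in ("int", int):
                kwargs[f.name] = int(v)
            elif f.type in ("float", float):
                kwargs[f.name] = float(v)
            elif f.type in ("bool", bool):
                kwargs[f.name] = v.lower() in ("1", "true", "yes")
            elif f.type in ("tuple", tuple):
                kwargs[f.name] = tuple(
                    float(x) if "." in x else x for x in v.split(",")
                )
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only
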