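"""Shared fixtures: small montages, synthetic stimuli and recordings.

Expensive synthetic material is session-scoped so independent tests can
share it.  Everything is generated programmatically from fixed seeds.
"""

from __future__ import annotations

import struct

import numpy as np
import pytest

from cacor import synthetic_data as sd

MONTAGE_8 = ["Fz", "Cz", "Pz", "Oz", "F3", "F4", "C3", "C4"]
MONTAGE_19 = "Fp1 Fp2 F7 F3 Fz F4 F8 T7 C3 Cz C4 T8 P7 P3 Pz P4 P8 O1 O2".split()


@pytest.fixture(scope="session")
def montage8():
    return list(MONTAGE_8)


@pytest.fixture(scope="session")
def montage19():
    return list(MONTAGE_19)


@pytest.fixture(scope="session")
def chord_stimulus():
    """20 s default chord sequence with its onsets and power slope."""
    w, onsets = sd.synth_tone_sequence(duration=20.0, seed=11)
    return w, onsets, sd.slope_of(w)


@pytest.fixture(scope="session")
def coupled_recordings(chord_stimulus, montage8):
    """Three strongly coupled presentations on the small montage."""
    _, _, slope = chord_stimulus
    return [
        sd.synth_eeg(
            slope,
            snr=5.0,
            coupling=1.0,
            channel_labels=MONTAGE_8,
            alpha_amp=0.3,
            seed=50 + i,
            presentation_index=i + 1,
        )
        for i in range(3)
    ]


def write_minimal_edf(path, data, rate, labels):
    """Write a single-record 16-bit EDF file (test fixture helper)."""
    data = np.asarray(data, dtype=float)
    n_sig, n_samp = data.shape
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(s, n):
        return str(s)[:n].ljust(n).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("synthetic test subject", 80),
            pad("synthetic test recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 * (n_sig + 1), 8),
            pad("", 44),
            pad(1, 8),
            pad(n_samp / rate, 8),
            pad(n_sig, 4),
        ]
    )
    fields = [
        b"".join(pad(lab, 16) for lab in labels),
        b"".join(pad("AgAgCl electrode", 80) for _ in labels),
        b"".join(pad("uV", 8) for _ in labels),
        b"".join(pad(phys_min, 8) for _ in labels),
        b"".join(pad(phys_max, 8) for _ in labels),
        b"".join(pad(dig_min, 8) for _ in labels),
        b"".join(pad(dig_max, 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad(n_samp, 8) for _ in labels),
        b"".join(pad("", 32) for _ in labels),
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for row in digital:
            fh.write(struct.pack(f"<{n_samp}h", *row))
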