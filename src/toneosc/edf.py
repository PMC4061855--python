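"""Minimal EDF writer for epoched data: one data record per trial.

EDF stores 16-bit integers with a per-channel linear physical scaling, so a
round trip is exact only up to (phys_max - phys_min) / 65535 uV.  Reading
is done through :func:`mne.io.read_raw_edf`; only writing lives here.
Per-trial factor labels do not fit EDF and travel in a sidecar table.
"""

from __future__ import annotations

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text, width):
    b = str(text).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf_epochs(es, path) -> None:
    """Write an EpochSet as EDF with one record per trial (signals in uV)."""
    n_trials, n_channels, n_samples = es.data.shape
    duration = n_samples / es.fs

    phys_min = np.floor(es.data.min(axis=(0, 2)) - 1.0)
    phys_max = np.ceil(es.data.max(axis=(0, 2)) + 1.0)

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate 01-JAN-2000 X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * (1 + n_channels), 8),
        _field("", 44),
        _field(n_trials, 8),
        _field(f"{duration:g}", 8),
        _field(n_channels, 4),
    ])
    per = [
        b"".join(_field(name, 16) for name in es.channel_names),
        b"".join(_field("AgAgCl electrode", 80) for _ in range(n_channels)),
        b"".join(_field("uV", 8) for _ in range(n_channels)),
        b"".join(_field(f"{v:g}", 8) for v in phys_min),
        b"".join(_field(f"{v:g}", 8) for v in phys_max),
        b"".join(_field(_DIG_MIN, 8) for _ in range(n_channels)),
        b"".join(_field(_DIG_MAX, 8) for _ in range(n_channels)),
        b"".join(_field("", 80) for _ in range(n_channels)),
        b"".join(_field(n_samples, 8) for _ in range(n_channels)),
        b"".join(_field("", 32) for _ in range(n_channels)),
    ]

    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    dig = np.rint(
        (es.data - phys_min[None, :, None]) * scale[None, :, None] + _DIG_MIN
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.writelines(per)
        # records are trial-major; within a record, channel-major
        fh.write(dig.tobytes())


def quantization_step(es) -> np.ndarray:
    """Per-channel physical resolution of the EDF encoding, in uV."""
    phys_min = np.floor(es.data.min(axis=(0, 2)) - 1.0)
    phys_max = np.ceil(es.data.max(axis=(0, 2)) + 1.0)
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
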