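"""Epoched-EEG data model, readers/writers, re-referencing and screening.

An :class:`EpochSet` holds trials x channels x samples of scalp EEG in
microvolts, with a shared sampling rate, epoch time axis and per-trial
factor labels (tone, condition, block, session, subject, group).  Two
on-disk dialects are supported: a fixture container (single ``.npz`` with
a binary array plus JSON metadata) and EDF with one data record per trial
plus a tab-delimited sidecar carrying the per-trial factors EDF cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage

TONES = ("low-falling", "mid-level", "high-rising")
#: Tones entering the ROI/stats analyses (mid-level standards are carriers only).
ANALYSIS_TONES = ("low-falling", "high-rising")
CONDITIONS = ("standard", "deviant")
SESSIONS = ("pre", "post")
GROUPS = ("English", "Chinese", "Thai")

LABEL_COLUMNS = ("trial", "tone", "condition", "block", "session", "subject", "group")


class LabelledDataError(ValueError):
    """Trial labels missing, malformed, or referencing absent design cells."""


class FormatError(ValueError):
    """On-disk container violates the dialect's structural contract."""


@dataclass
class EpochSet:
    """Epoched multi-channel EEG with per-trial condition labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Scalp potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample relative to stimulus onset, in ms
        (negative = pre-stimulus).  Defaults give a half-open
        [-300, 700) ms epoch of 512 samples at 512 Hz.
    channel_names : list of str
    trial_labels : pandas.DataFrame
        One row per trial with columns ``trial, tone, condition, block,
        session, subject, group``.
    reject_mask : ndarray of bool, shape (n_trials,)
        True marks an artifact-contaminated trial.
    """

    data: np.ndarray
    fs: float
    t0: float
    channel_names: list
    trial_labels: pd.DataFrame
    reject_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError("data must be trials x channels x samples")
        n_trials, n_channels, _ = self.data.shape
        if len(self.channel_names) != n_channels:
            raise FormatError("channel_names length does not match data")
        self.channel_names = list(self.channel_names)
        missing = [c for c in LABEL_COLUMNS if c not in self.trial_labels.columns]
        if missing:
            raise LabelledDataError(f"trial labels missing columns: {missing}")
        if len(self.trial_labels) != n_trials:
            raise LabelledDataError("one label row per trial required")
        bad_tone = set(self.trial_labels["tone"]) - set(TONES)
        bad_cond = set(self.trial_labels["condition"]) - set(CONDITIONS)
        if bad_tone or bad_cond:
            raise LabelledDataError(f"labels outside vocabulary: {bad_tone | bad_cond}")
        if self.reject_mask is None:
            self.reject_mask = np.zeros(n_trials, dtype=bool)
        self.reject_mask = np.asarray(self.reject_mask, dtype=bool)
        if self.reject_mask.shape != (n_trials,):
            raise FormatError("reject_mask must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in ms: t0 + k/fs, k = 0..N-1 (half-open span)."""
        return self.t0 + np.arange(self.n_samples) * 1000.0 / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in EpochSet") from None

    def select_trials(self, mask_or_index) -> "EpochSet":
        idx = np.asarray(mask_or_index)
        labels = self.trial_labels.iloc[np.flatnonzero(idx) if idx.dtype == bool else idx]
        return replace(
            self,
            data=self.data[mask_or_index],
            trial_labels=labels.reset_index(drop=True),
            reject_mask=self.reject_mask[mask_or_index],
        )

    def accepted(self) -> "EpochSet":
        """The artifact-free subset."""
        return self.select_trials(~self.reject_mask)


# ---------------------------------------------------------------------------
# readers / writers

def write_epochs(es: EpochSet, path, dialect: str = "fixture") -> Path:
    """Write an EpochSet; ``read_epochs(write_epochs(es))`` round-trips.

    The fixture dialect preserves float64 exactly; EDF quantizes to 16 bit.
    """
    if es.n_trials == 0:
        raise FormatError("refusing to write an EpochSet with 0 trials")
    path = Path(path)
    if dialect == "fixture":
        meta = {
            "fs": es.fs,
            "t0": es.t0,
            "channel_names": es.channel_names,
            "trial_labels": es.trial_labels[list(LABEL_COLUMNS)].to_dict("list"),
            "units": "uV",
        }
        with open(path, "wb") as fh:
            np.savez(
                fh,
                data=es.data,
                reject_mask=es.reject_mask,
                meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            )
        return path
    if dialect == "edf":
        from . import edf

        edf.write_edf_epochs(es, path)
        sidecar = path.with_suffix(path.suffix + ".labels.tsv")
        tbl = es.trial_labels[list(LABEL_COLUMNS)].copy()
        tbl["rejected"] = es.reject_mask.astype(int)
        with open(sidecar, "w") as fh:
            fh.write(f"# t0_ms={es.t0:g}\n")
            tbl.to_csv(fh, sep="\t", index=False)
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


def read_epochs(path, dialect: str = "fixture") -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "fixture":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            data, mask = z["data"], z["reject_mask"]
        labels = pd.DataFrame(meta["trial_labels"])
        return EpochSet(
            data=data,
            fs=meta["fs"],
            t0=meta["t0"],
            channel_names=meta["channel_names"],
            trial_labels=labels,
            reject_mask=mask,
        )
    if dialect == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        sidecar = path.with_suffix(path.suffix + ".labels.tsv")
        if not sidecar.exists():
            raise LabelledDataError(f"sidecar label table not found: {sidecar}")
        t0 = -300.0
        with open(sidecar) as fh:
            first = fh.readline()
        if first.startswith("# t0_ms="):
            t0 = float(first.split("=", 1)[1])
        labels = pd.read_csv(sidecar, sep="\t", comment="#")
        missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
        if missing:
            raise LabelledDataError(f"sidecar missing columns: {missing}")
        n_trials = len(labels)
        sig = raw.get_data() * 1e6  # mne returns volts
        n_channels, total = sig.shape
        if total % n_trials:
            raise FormatError("EDF sample count not divisible by trial count")
        n_samples = total // n_trials
        data = sig.reshape(n_channels, n_trials, n_samples).transpose(1, 0, 2)
        mask = labels["rejected"].to_numpy(bool) if "rejected" in labels else None
        return EpochSet(
            data=data,
            fs=float(raw.info["sfreq"]),
            t0=t0,
            channel_names=list(raw.ch_names),
            trial_labels=labels,
            reject_mask=mask,
        )
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# preprocessing

def rereference_to_average_mastoids(es: EpochSet, montage: Montage) -> EpochSet:
    """Re-reference left-mastoid-referenced data to the averaged mastoids.

    With the left mastoid as the implicit zero channel, the averaged-mastoid
    re-reference subtracts half the right-mastoid signal from every channel:
    x' = x - M2/2.
    """
    m2 = montage.mastoids[1]
    if m2 not in es.channel_names:
        raise LabelledDataError(f"right mastoid channel {m2!r} not present")
    i = es.channel_index(m2)
    data = es.data - es.data[:, i : i + 1, :] / 2.0
    return replace(es, data=data)


def reject_artifacts(es: EpochSet, ptp_threshold: float = 150.0,
                     montage: Montage | None = None) -> EpochSet:
    """Mask trials whose peak-to-peak amplitude exceeds ``ptp_threshold`` uV.

    The criterion is evaluated on analysis channels (midline + lateral) when
    a montage is given, on all channels otherwise.  Data are unchanged; only
    ``reject_mask`` is set.
    """
    if not ptp_threshold > 0:
        raise ValueError("ptp_threshold must be positive")
    if montage is not None:
        chans = [c for c in montage.analysis_channels if c in es.channel_names]
        idx = [es.channel_index(c) for c in chans]
        seg = es.data[:, idx, :]
    else:
        seg = es.data
    ptp = seg.max(axis=2) - seg.min(axis=2)
    mask = (ptp > ptp_threshold).any(axis=1)
    return replace(es, reject_mask=mask)


def screen_subject(es: EpochSet, min_trials: int = 50) -> bool:
    """True iff every analysis (tone x condition) cell has >= min_trials
    artifact-free trials."""
    labels = es.trial_labels
    keep = ~es.reject_mask
    for tone in ANALYSIS_TONES:
        for cond in CONDITIONS:
            cell = (labels["tone"] == tone) & (labels["condition"] == cond)
            if not cell.any():
                raise LabelledDataError(f"design cell absent: ({tone}, {cond})")
            if int((cell.to_numpy() & keep).sum()) < min_trials:
                return False
    return True
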