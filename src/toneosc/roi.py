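"""Band x time-window ROI means over the midline/lateral region scheme.

Two analysis windows are extracted from every time-frequency map: early
alpha (8-13 Hz, 100-500 ms) and mid-latency gamma (28-50 Hz, 200-400 ms).
Frequency bins include both band edges on the 1 Hz grid; time windows are
half-open [start, end) on the epoch sample axis, so bin counts are
deterministic.  Channel means aggregate to five single-electrode midline
locations and ten lateral (anteriority x hemisphere) means of three
electrodes each, producing the long-format table the stats layer consumes.
Phase-locking is tabulated at lateral sites only, since it is computed
against a midline reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import ANTERIORITY_LEVELS, Montage

#: Midline electrode -> anteriority level, so midline and lateral analyses
#: share one within-subject location factor.
MIDLINE_ANTERIORITY = dict(zip(("Fz", "FCz", "Cz", "CPz", "Pz"), ANTERIORITY_LEVELS))

ROI_COLUMNS = (
    "subject", "group", "session", "tone", "condition", "measure", "band",
    "scheme", "location", "anteriority", "hemisphere", "value",
)


@dataclass(frozen=True)
class BandWindow:
    """A named frequency band x post-stimulus time window."""

    name: str
    f_range: tuple           # Hz, inclusive at both ends
    t_range: tuple           # ms, [start, end)
    reference: str = None    # PLS reference site, where applicable


ALPHA_BAND = BandWindow("alpha", (8.0, 13.0), (100.0, 500.0), reference="Cz")
GAMMA_BAND = BandWindow("gamma", (28.0, 50.0), (200.0, 400.0), reference="FCz")


def extract_band_mean(tfmap, bw: BandWindow, channels=None) -> pd.Series:
    """Mean over the band's frequency bins and time samples, per channel.

    ``tfmap`` is any object with ``values`` (channels x freqs x times),
    ``freqs`` (Hz), ``times`` (ms) and ``channel_names``.
    """
    freqs, times = np.asarray(tfmap.freqs), np.asarray(tfmap.times)
    fsel = (freqs >= bw.f_range[0] - 1e-9) & (freqs <= bw.f_range[1] + 1e-9)
    tsel = (times >= bw.t_range[0]) & (times < bw.t_range[1])
    if not fsel.any() or not tsel.any():
        raise ValueError(f"window {bw.name} outside map axes")
    if freqs[fsel].min() > bw.f_range[0] + 1e-9 or freqs[fsel].max() < bw.f_range[1] - 1e-9:
        raise ValueError(f"map does not cover the full {bw.name} band")
    vals = tfmap.values[:, fsel, :][:, :, tsel].mean(axis=(1, 2))
    names = list(tfmap.channel_names)
    if channels is not None:
        idx = [names.index(c) for c in channels]
        return pd.Series(vals[idx], index=list(channels))
    return pd.Series(vals, index=names)


def aggregate_regions(per_channel: pd.Series, montage: Montage, scheme: str) -> pd.DataFrame:
    """Collapse per-channel values into region means.

    midline -> 5 single-electrode locations; lateral -> 10 three-electrode
    (anteriority, hemisphere) means.
    """
    rows = []
    if scheme == "midline":
        for ch in montage.midline:
            if ch not in per_channel.index:
                raise KeyError(f"montage channel {ch!r} missing from map")
            rows.append((ch, MIDLINE_ANTERIORITY[ch], "mid", float(per_channel[ch])))
    elif scheme == "lateral":
        for (ant, hemi), chans in sorted(montage.lateral_regions.items()):
            missing = [c for c in chans if c not in per_channel.index]
            if missing:
                raise KeyError(f"montage channels missing from map: {missing}")
            rows.append((f"{ant}/{hemi}", ant, hemi,
                         float(per_channel[list(chans)].mean())))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return pd.DataFrame(rows, columns=["location", "anteriority", "hemisphere", "value"])


def build_roi_table(records, montage: Montage) -> pd.DataFrame:
    """Assemble the long-format subject x cell x location table.

    ``records`` is an iterable of dicts with keys ``subject, group, session,
    tone, condition, measure ('power'|'pls'), band`` and a per-channel
    ``values`` Series.  Power rows get both schemes, PLS rows lateral only.
    Raises when subjects do not share an identical cell set.
    """
    rows = []
    cells_by_subject = {}
    scheme_chans = {
        "midline": set(montage.midline),
        "lateral": {c for chs in montage.lateral_regions.values() for c in chs},
    }
    for rec in records:
        schemes = ("midline", "lateral") if rec["measure"] == "power" else ("lateral",)
        cell = (rec["session"], rec["tone"], rec["condition"], rec["measure"], rec["band"])
        cells_by_subject.setdefault((rec["group"], rec["subject"]), set()).add(cell)
        for scheme in schemes:
            present = scheme_chans[scheme] & set(rec["values"].index)
            if not present:
                continue  # scheme not computed in this (restricted-channel) run
            agg = aggregate_regions(rec["values"], montage, scheme)
            for r in agg.itertuples(index=False):
                rows.append(
                    (rec["subject"], rec["group"], rec["session"], rec["tone"],
                     rec["condition"], rec["measure"], rec["band"], scheme,
                     r.location, r.anteriority, r.hemisphere, r.value)
                )
    if not rows:
        raise ValueError("no records supplied")
    all_cells = set().union(*cells_by_subject.values())
    for subj, cells in cells_by_subject.items():
        gap = all_cells - cells
        if gap:
            raise ValueError(f"subject {subj} missing cells: {sorted(gap)}")
    table = pd.DataFrame(rows, columns=list(ROI_COLUMNS))
    key = ["subject", "session", "tone", "condition", "measure", "band", "scheme", "location"]
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate ROI rows")
    return table


def write_roi_table(table: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_roi_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
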