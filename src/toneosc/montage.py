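"""Electrode montage and region scheme.

The 39-channel montage follows the extended 10-10 system: five midline
analysis electrodes (Fz, FCz, Cz, CPz, Pz) and a 5 x 2 x 3 lateral scheme
(anteriority level x hemisphere x three electrodes per region), plus the
right mastoid (M2; the left mastoid M1 is the implicit recording reference
and carries no data channel) and three non-analysis spares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Anteriority levels, front to back.
ANTERIORITY_LEVELS = ("frontal", "fronto-central", "central", "centro-parietal", "parietal")

_MIDLINE = ("Fz", "FCz", "Cz", "CPz", "Pz")

_LATERAL = {
    ("frontal", "L"): ("F3", "F5", "F7"),
    ("frontal", "R"): ("F4", "F6", "F8"),
    ("fronto-central", "L"): ("FC3", "FC5", "FT7"),
    ("fronto-central", "R"): ("FC4", "FC6", "FT8"),
    ("central", "L"): ("C3", "C5", "T7"),
    ("central", "R"): ("C4", "C6", "T8"),
    ("centro-parietal", "L"): ("CP3", "CP5", "TP7"),
    ("centro-parietal", "R"): ("CP4", "CP6", "TP8"),
    ("parietal", "L"): ("P3", "P5", "P7"),
    ("parietal", "R"): ("P4", "P6", "P8"),
}

_SPARES = ("Fp1", "Fp2", "Oz")


@dataclass(frozen=True)
class Montage:
    """Named electrode set with its midline/lateral analysis grouping.

    Parameters
    ----------
    midline : tuple of str
        Exactly five midline analysis electrodes, front to back.
    lateral_regions : dict
        ``(anteriority, hemisphere)`` -> three channel names; exactly
        5 levels x 2 hemispheres x 3 electrodes = 30 channels.
    mastoids : (str, str)
        Left and right mastoid names.  The left mastoid is the recording
        reference and is usually absent from the data channels.
    spares : tuple of str
        Recorded channels outside the analysis scheme.
    """

    midline: tuple = _MIDLINE
    lateral_regions: dict = field(default_factory=lambda: dict(_LATERAL))
    mastoids: tuple = ("M1", "M2")
    spares: tuple = _SPARES

    def __post_init__(self):
        if len(self.midline) != 5:
            raise ValueError("montage must have exactly 5 midline channels")
        if len(self.lateral_regions) != 10 or any(
            len(chs) != 3 for chs in self.lateral_regions.values()
        ):
            raise ValueError("lateral scheme must be 5 anteriority x 2 hemisphere x 3 channels")
        allch = self.all_channels
        if len(allch) != len(set(allch)):
            raise ValueError("duplicate channel in montage")

    @property
    def lateral_channels(self) -> tuple:
        return tuple(ch for key in sorted(self.lateral_regions) for ch in self.lateral_regions[key])

    @property
    def analysis_channels(self) -> tuple:
        """Midline + lateral channels, the set entering power/PLS analyses."""
        return self.midline + self.lateral_channels

    @property
    def all_channels(self) -> tuple:
        return self.analysis_channels + (self.mastoids[1],) + self.spares

    def unmapped(self, channel_names) -> list:
        """Channels present in the data but not in this montage."""
        known = set(self.all_channels) | {self.mastoids[0]}
        return [ch for ch in channel_names if ch not in known]


def default_montage() -> Montage:
    """The 39-channel recording montage (35 analysis + M2 + 3 spares)."""
    return Montage()
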