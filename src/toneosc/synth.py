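"""Synthetic oddball-EEG generator with known ground truth.

Emulates a passive auditory oddball study of lexical-tone perception:
512 Hz EEG epochs of -300..700 ms, blocks of 1080 standards + 120 deviants
(10%), three language groups (10 English, 10 Chinese, 11 Thai subjects)
tested pre and post training.  Band-limited oscillations (alpha ~10 Hz,
gamma ~40 Hz) ride on 1/f background noise; their amplitude and the von
Mises concentration kappa of each channel's trialwise phase offset from a
reference electrode are set per (group, session, tone, condition) cell, so
every downstream estimate (band power, phase-locking) has a closed-form
target: the expected phase-locking statistic of a von Mises offset is the
Bessel ratio I1(kappa)/I0(kappa).

Determinism: a master seed spawns per-(subject, session, block) child
streams through ``numpy.random.SeedSequence([master, subj, sess, block])``,
so any subject or block can be regenerated in isolation.  Per-subject
amplitude scale factors use ``SeedSequence([master, subj])`` and are
therefore stable across that subject's sessions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import ANALYSIS_TONES, CONDITIONS, EpochSet, SESSIONS
from .montage import Montage, default_montage

#: kappa at or above this is treated as a zero phase offset (perfect locking).
KAPPA_CAP = 1e6

_RAMP_MS = 50.0  # cosine-square on/off ramp of injected oscillations


@dataclass(frozen=True)
class OscillationSpec:
    """One injected band-limited oscillation.

    amplitude is the peak amplitude in uV at the window centre; kappa is
    the von Mises concentration of the per-trial phase offset between each
    target channel and the reference channel (0 = no coupling, large =
    rigid phase locking).
    """

    band: str                      # "alpha" | "gamma"
    center_freq: float             # Hz
    amplitude: float               # uV at window centre
    window: tuple                  # (start, end) ms relative to onset
    kappa: float                   # von Mises concentration, >= 0
    target_channels: tuple
    reference_channel: str

    def __post_init__(self):
        if self.amplitude < 0 or self.kappa < 0:
            raise ValueError("amplitude and kappa must be non-negative")
        if self.window[1] <= self.window[0]:
            raise ValueError("window must be increasing")


@dataclass(frozen=True)
class BlockSpec:
    """One oddball block: which tone is frequent, which is rare."""

    standard_tone: str
    deviant_tone: str
    n_standards: int = 1080
    n_deviants: int = 120


@dataclass(frozen=True)
class StudyDesign:
    """Full study layout plus every generator parameter.

    ``cell_specs`` maps (group, session, tone, condition) to the list of
    oscillations injected on trials of that cell.  ``artifact_rate`` may be
    a single float or a per-group dict (the default mirrors per-group
    rejection fractions of 0.24 / 0.18 / 0.26 for Chinese / English / Thai).
    """

    groups: dict
    cell_specs: dict
    block_plan: tuple
    sessions: tuple = SESSIONS
    #: scalp EEG spectra fall steeper than 1/f above the alpha range; 1.5
    #: keeps the gamma-band noise floor closer to real recordings
    noise_exponent: float = 1.5
    noise_rms: float = 10.0        # uV per channel
    artifact_rate: object = field(
        default_factory=lambda: {"Chinese": 0.24, "English": 0.18, "Thai": 0.26}
    )
    subject_scale_sd: float = 0.1  # lognormal sd of per-subject amplitude factor
    fs: float = 512.0
    t0: float = -300.0
    n_samples: int = 512
    montage: Montage = field(default_factory=default_montage)
    #: optional channel subset to synthesize (desk-scale runs); None = all 39
    restrict_channels: tuple = None
    master_seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.groups.values()):
            raise ValueError("subject counts must be positive")

    @property
    def deviant_fraction(self) -> float:
        b = self.block_plan[0]
        return b.n_deviants / (b.n_standards + b.n_deviants)

    def rate_for(self, group: str) -> float:
        if isinstance(self.artifact_rate, dict):
            return self.artifact_rate[group]
        return float(self.artifact_rate)

    def subjects(self):
        for group, n in self.groups.items():
            for i in range(n):
                yield group, f"{group}-{i + 1:02d}"


# ---------------------------------------------------------------------------
# noise and oscillation primitives

def pink_noise(n_trials, n_channels, n_samples, exponent=1.0, rms=10.0, rng=None):
    """1/f^exponent background noise, exact per-trace RMS, zero mean.

    Shaped in the frequency domain: white Gaussian spectra are weighted by
    f^(-exponent/2) (DC removed), inverted, and each trial x channel trace
    rescaled to exactly ``rms``.
    """
    if rms <= 0:
        raise ValueError("rms must be positive")
    if not 0 <= exponent <= 2:
        raise ValueError("exponent must lie in [0, 2]")
    rng = np.random.default_rng(rng)
    nf = n_samples // 2 + 1
    spec = rng.standard_normal((n_trials, n_channels, nf)) + 1j * rng.standard_normal(
        (n_trials, n_channels, nf)
    )
    f = np.fft.rfftfreq(n_samples)
    w = np.zeros(nf)
    w[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * w, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    x *= rms / np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    return x


def _envelope(times_ms, window):
    start, end = window
    env = np.zeros_like(times_ms)
    ramp = min(_RAMP_MS, (end - start) / 2.0)
    inside = (times_ms >= start) & (times_ms < end)
    env[inside] = 1.0
    up = inside & (times_ms < start + ramp)
    env[up] = np.cos(np.pi / 2 * (times_ms[up] - (start + ramp)) / ramp) ** 2
    dn = inside & (times_ms >= end - ramp)
    env[dn] = np.cos(np.pi / 2 * (times_ms[dn] - (end - ramp)) / ramp) ** 2
    return env


def inject_oscillation(data, spec: OscillationSpec, times_ms, channel_names, rng=None):
    """Add a windowed sinusoid with von Mises cross-channel phase jitter.

    The reference channel draws a fresh uniform phase each trial; every
    target channel adds an independent von Mises(0, kappa) offset to it.
    Modifies ``data`` (trials x channels x samples) in place and returns it.
    """
    rng = np.random.default_rng(rng)
    times_ms = np.asarray(times_ms, float)
    dt = times_ms[1] - times_ms[0]
    if spec.window[0] < times_ms[0] - 1e-9 or spec.window[1] > times_ms[-1] + dt + 1e-9:
        raise ValueError("oscillation window outside epoch span")
    name_to_idx = {c: i for i, c in enumerate(channel_names)}
    try:
        ref_idx = name_to_idx[spec.reference_channel]
        tgt_idx = [name_to_idx[c] for c in spec.target_channels]
    except KeyError as e:
        raise KeyError(f"channel {e.args[0]!r} absent from data") from None

    n_trials = data.shape[0]
    env = _envelope(np.asarray(times_ms, float), spec.window)
    carrier_t = np.asarray(times_ms, float) / 1000.0
    phi_ref = rng.uniform(0, 2 * np.pi, size=n_trials)
    cols = [ref_idx] + tgt_idx
    phases = np.empty((n_trials, len(cols)))
    phases[:, 0] = phi_ref
    for j in range(len(tgt_idx)):
        if spec.kappa >= KAPPA_CAP:
            off = np.zeros(n_trials)
        else:
            off = rng.vonmises(0.0, spec.kappa, size=n_trials)
        phases[:, j + 1] = phi_ref + off
    wave = env * np.cos(
        2 * np.pi * spec.center_freq * carrier_t[None, None, :] + phases[:, :, None]
    )
    data[:, cols, :] += spec.amplitude * wave
    return data


# ---------------------------------------------------------------------------
# block / study generation

def _spike(rng, times_ms, amp=400.0, width_ms=100.0):
    t0 = rng.uniform(times_ms[0], times_ms[-1] - width_ms)
    x = (times_ms - t0) / width_ms
    pulse = np.where((x >= 0) & (x <= 1), np.sin(np.pi * np.clip(x, 0, 1)) ** 2, 0.0)
    return amp * pulse


def generate_block(design: StudyDesign, group, subject, session, block_index,
                   rng=None) -> EpochSet:
    """One oddball block for one subject and session.

    Trial order is randomized; oscillations follow the design's cell specs
    for the trial's (tone, condition); ``artifact_rate`` of trials receive a
    super-threshold transient so downstream rejection has work to do.
    """
    if group not in design.groups:
        raise KeyError(f"unknown group {group!r}")
    if session not in design.sessions:
        raise KeyError(f"unknown session {session!r}")
    block = design.block_plan[block_index]
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [design.master_seed, _subject_ordinal(design, group, subject),
                 design.sessions.index(session), block_index]
            )
        )
    mont = design.montage
    channels = list(design.restrict_channels or mont.all_channels)
    n = block.n_standards + block.n_deviants
    times = design.t0 + np.arange(design.n_samples) * 1000.0 / design.fs

    tones = np.array(
        [block.standard_tone] * block.n_standards + [block.deviant_tone] * block.n_deviants
    )
    conditions = np.array(["standard"] * block.n_standards + ["deviant"] * block.n_deviants)
    order = rng.permutation(n)
    tones, conditions = tones[order], conditions[order]

    data = pink_noise(
        n, len(channels), design.n_samples, design.noise_exponent, design.noise_rms, rng
    )

    sfac = _subject_scale(design, group, subject)
    for tone in np.unique(tones):
        for cond in np.unique(conditions):
            sel = np.flatnonzero((tones == tone) & (conditions == cond))
            if sel.size == 0:
                continue
            for spec in design.cell_specs.get((group, session, tone, cond), ()):
                targets = tuple(c for c in spec.target_channels if c in channels)
                if spec.reference_channel not in channels:
                    continue  # band not represented in a restricted run
                sub = data[sel]
                inject_oscillation(
                    sub,
                    replace(spec, amplitude=spec.amplitude * sfac, target_channels=targets),
                    times, channels, rng,
                )
                data[sel] = sub

    bad = np.flatnonzero(rng.random(n) < design.rate_for(group))
    for t in bad:
        ch = rng.choice(len(channels), size=3, replace=False)
        data[t, ch, :] += _spike(rng, times)

    labels = pd.DataFrame(
        {
            "trial": np.arange(n),
            "tone": tones,
            "condition": conditions,
            "block": block_index,
            "session": session,
            "subject": subject,
            "group": group,
        }
    )
    return EpochSet(data=data, fs=design.fs, t0=design.t0,
                    channel_names=channels, trial_labels=labels)


def _subject_ordinal(design, group, subject):
    for i, (g, s) in enumerate(design.subjects()):
        if g == group and s == subject:
            return i
    raise KeyError(f"unknown subject {subject!r}")


def _subject_scale(design, group, subject):
    ss = np.random.SeedSequence([design.master_seed, _subject_ordinal(design, group, subject)])
    g = np.random.default_rng(ss)
    return float(np.exp(g.normal(0.0, design.subject_scale_sd)))


def generate_session(design, group, subject, session) -> EpochSet:
    """All blocks of one session, concatenated into a single EpochSet."""
    blocks = [
        generate_block(design, group, subject, session, b)
        for b in range(len(design.block_plan))
    ]
    data = np.concatenate([b.data for b in blocks], axis=0)
    labels = pd.concat([b.trial_labels for b in blocks], ignore_index=True)
    labels["trial"] = np.arange(len(labels))
    first = blocks[0]
    return EpochSet(data=data, fs=first.fs, t0=first.t0,
                    channel_names=first.channel_names, trial_labels=labels)


def generate_study(design: StudyDesign):
    """Yield the whole study lazily, plus its ground-truth table.

    Returns ``(sessions, truth)`` where ``sessions`` is a generator of
    ``((group, subject, session), EpochSet)`` — lazy because a full-size
    study does not fit in memory at once — and ``truth`` is a DataFrame of
    every cell's true injected amplitude (after the per-subject scale
    factor) and kappa.
    """
    truth = ground_truth_table(design)

    def _iter():
        for group, subject in design.subjects():
            for session in design.sessions:
                yield (group, subject, session), generate_session(
                    design, group, subject, session
                )

    return _iter(), truth


def ground_truth_table(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for group, subject in design.subjects():
        sfac = _subject_scale(design, group, subject)
        for session, tone, cond in itertools.product(
            design.sessions, ANALYSIS_TONES, CONDITIONS
        ):
            for spec in design.cell_specs.get((group, session, tone, cond), ()):
                rows.append(
                    {
                        "group": group,
                        "subject": subject,
                        "session": session,
                        "tone": tone,
                        "condition": cond,
                        "band": spec.band,
                        "center_freq": spec.center_freq,
                        "amplitude": spec.amplitude * sfac,
                        "kappa": spec.kappa,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default study conditions

#: Gamma-band amplitude (uV) per (group, session): English strongest before
#: training and the only group with a marked post-training increase; Thai
#: intermediate with a modest increase; Chinese weakest and flat.
GAMMA_AMP = {
    ("English", "pre"): 1.2, ("English", "post"): 1.8,
    ("Thai", "pre"): 1.0, ("Thai", "post"): 1.25,
    ("Chinese", "pre"): 0.8, ("Chinese", "post"): 0.8,
}

#: Gamma phase-locking concentration per (session, condition): deviants more
#: phase-locked than standards, both rising after training.
GAMMA_KAPPA = {
    ("pre", "standard"): 0.8, ("pre", "deviant"): 1.5,
    ("post", "standard"): 1.3, ("post", "deviant"): 2.0,
}

#: Alpha amplitude (uV) per (group, session, tone, condition): standards
#: above deviants everywhere; Thai strongest and training-insensitive;
#: English show the widest low-falling standard-deviant gap before training,
#: which closes after training while overall alpha power drops.
ALPHA_AMP = {}
for _g in ("English", "Chinese", "Thai"):
    for _s in ("pre", "post"):
        for _t in ANALYSIS_TONES:
            std, dev = 2.6, 2.45
            if _g == "Thai":
                std, dev = 3.2, 2.9
            elif _g == "English" and _s == "pre" and _t == "low-falling":
                std, dev = 2.7, 2.15
            if _g in ("English", "Chinese") and _s == "post":
                std, dev = std * 0.85, dev * 0.85
            ALPHA_AMP[(_g, _s, _t)] = {"standard": std, "deviant": dev}

#: Alpha phase-locking concentration per (group, session, condition):
#: deviants above standards; all groups rise after training, English most.
ALPHA_KAPPA = {
    ("English", "pre"): {"standard": 0.6, "deviant": 1.2},
    ("Chinese", "pre"): {"standard": 0.6, "deviant": 1.2},
    ("Thai", "pre"): {"standard": 0.6, "deviant": 1.2},
    ("English", "post"): {"standard": 1.2, "deviant": 1.8},
    ("Chinese", "post"): {"standard": 0.9, "deviant": 1.5},
    ("Thai", "post"): {"standard": 1.0, "deviant": 1.6},
}

GAMMA_FREQ = 40.0
ALPHA_FREQ = 10.0
GAMMA_WINDOW = (150.0, 450.0)
ALPHA_WINDOW = (50.0, 550.0)


def default_cell_specs(montage: Montage | None = None) -> dict:
    """Per-cell oscillation specs realizing the default study conditions."""
    mont = montage or default_montage()
    gamma_targets = tuple(c for c in mont.analysis_channels if c != "FCz")
    alpha_targets = tuple(c for c in mont.analysis_channels if c != "Cz")
    specs = {}
    for group in ("English", "Chinese", "Thai"):
        for session in SESSIONS:
            for tone in ANALYSIS_TONES:
                for cond in CONDITIONS:
                    specs[(group, session, tone, cond)] = [
                        OscillationSpec(
                            band="gamma",
                            center_freq=GAMMA_FREQ,
                            amplitude=GAMMA_AMP[(group, session)],
                            window=GAMMA_WINDOW,
                            kappa=GAMMA_KAPPA[(session, cond)],
                            target_channels=gamma_targets,
                            reference_channel="FCz",
                        ),
                        OscillationSpec(
                            band="alpha",
                            center_freq=ALPHA_FREQ,
                            amplitude=ALPHA_AMP[(group, session, tone)][cond],
                            window=ALPHA_WINDOW,
                            kappa=ALPHA_KAPPA[(group, session)][cond],
                            target_channels=alpha_targets,
                            reference_channel="Cz",
                        ),
                    ]
    return specs


def default_block_plan() -> tuple:
    """Four oddball blocks: each analysis tone once as deviant against
    mid-level standards, once as standard with mid-level deviants."""
    return (
        BlockSpec("mid-level", "low-falling"),
        BlockSpec("low-falling", "mid-level"),
        BlockSpec("mid-level", "high-rising"),
        BlockSpec("high-rising", "mid-level"),
    )


def default_design(master_seed: int = 0) -> StudyDesign:
    """The study at its published scale: 10 English, 10 Chinese, 11 Thai
    subjects, two sessions, four 1200-trial blocks each."""
    return StudyDesign(
        groups={"English": 10, "Chinese": 10, "Thai": 11},
        cell_specs=default_cell_specs(),
        block_plan=default_block_plan(),
        master_seed=master_seed,
    )


def scaled_design(master_seed: int = 0, groups=None, n_standards=45, n_deviants=15,
                  gamma_only=False, artifact_rate=0.0, n_blocks=2,
                  restrict_channels=None, null_effects=False,
                  english_post_gamma_factor=None) -> StudyDesign:
    """A desk-scale variant for simulation studies: fewer subjects, one or
    two single-tone blocks, optional gamma-only injection and channel
    restriction.  Amplitude/kappa patterns follow the default conditions;
    ``null_effects`` levels every cell to the Chinese pre-training values
    (no group, session, tone or condition differences);
    ``english_post_gamma_factor`` overrides the English post-training gamma
    amplitude to factor x their pre-training value (the power suite's
    training-effect variant, e.g. 2.0 for a doubled amplitude)."""
    groups = groups or {"English": 6, "Chinese": 6}
    specs = default_cell_specs()
    if null_effects:
        ref = specs[("Chinese", "pre", "low-falling", "standard")]
        specs = {k: ref for k in specs}
    if gamma_only:
        specs = {k: [s for s in v if s.band == "gamma"] for k, v in specs.items()}
    if english_post_gamma_factor is not None:
        boosted = english_post_gamma_factor * GAMMA_AMP[("English", "pre")]
        specs = {
            k: [
                replace(s, amplitude=boosted)
                if s.band == "gamma" and k[0] == "English" and k[1] == "post"
                else s
                for s in v
            ]
            for k, v in specs.items()
        }
    specs = {k: v for k, v in specs.items() if k[0] in groups}
    plan = (
        BlockSpec("low-falling", "high-rising", n_standards, n_deviants),
        BlockSpec("high-rising", "low-falling", n_standards, n_deviants),
    )[:n_blocks]
    return StudyDesign(
        groups=groups,
        cell_specs=specs,
        block_plan=plan,
        artifact_rate=artifact_rate,
        restrict_channels=tuple(restrict_channels) if restrict_channels else None,
        master_seed=master_seed,
    )
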