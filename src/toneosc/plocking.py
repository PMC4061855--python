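"""Inter-site phase-locking statistic (PLS) across trials.

For each channel c, frequency f and timepoint t, the complex wavelet
coefficients are reduced to unit phasors u_c(t, f); the PLS against a
reference channel r is

    PLS_c(t, f) = | mean over trials of u_c(t, f) * conj(u_r(t, f)) |

i.e. the resultant length of the across-trial distribution of the phase
*difference* between the two sites.  It is bounded in [0, 1]: 0 means the
phase difference is uniformly random across trials, 1 perfectly stable.
Amplitudes never enter, so the statistic is invariant to trial-varying
gains and to any rotation common to all channels within a trial.

Reference sites follow band-specific conventions (FCz for gamma, Cz for
alpha, where the respective responses are maximal).  Because the resultant
length of n uniform phasors has positive expectation (~ sqrt(pi)/2 / sqrt(n),
the Rayleigh mean), comparisons across conditions with unequal trial counts
are biased; :func:`pls_bias` quantifies this and :func:`pls` can equalize
counts by seeded subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .wavelets import TFComplex


@dataclass
class PLSMap:
    """Per-channel phase locking against one reference site."""

    values: np.ndarray       # channels x frequencies x timepoints, in [0, 1]
    reference_channel: str
    n_trials: int
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list
    edge_mask: np.ndarray

    def channel_index(self, name):
        return list(self.channel_names).index(name)


def phase_normalize(tfc: TFComplex) -> TFComplex:
    """Map every coefficient to its unit phasor; exact zeros stay zero.

    Returns a new TFComplex; the count of zero coefficients encountered is
    reported via a warning (they carry no phase).
    """
    v = tfc.values
    mod = np.abs(v)
    zeros = int((mod == 0).sum())
    if zeros:
        warnings.warn(f"phase_normalize: {zeros} zero coefficients left at 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(mod == 0, 0.0 + 0.0j, v / np.where(mod == 0, 1.0, mod))
    return replace(tfc, values=u)


def pls(tfc: TFComplex, reference_channel: str, trial_subset=None,
        equalize_to: int | None = None, seed=None) -> PLSMap:
    """Phase-locking statistic of every channel against the reference.

    ``equalize_to`` subsamples (seeded, without replacement) to a fixed
    trial count so conditions with different n share the same Rayleigh
    bias; by default all trials are used and a differing-n caveat is the
    caller's to manage.
    """
    names = list(tfc.channel_names)
    if reference_channel not in names:
        raise KeyError(f"reference channel {reference_channel!r} absent")
    v = tfc.values if trial_subset is None else tfc.values[trial_subset]
    if equalize_to is not None:
        if equalize_to > v.shape[0]:
            raise ValueError("equalize_to exceeds available trials")
        rng = np.random.default_rng(seed)
        v = v[rng.choice(v.shape[0], size=equalize_to, replace=False)]
    n = v.shape[0]
    if n < 2:
        raise ValueError("PLS needs at least 2 trials")
    mod = np.abs(v)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(mod == 0, 0.0 + 0.0j, v / np.where(mod == 0, 1.0, mod))
    ref = u[:, names.index(reference_channel)]
    vals = np.abs((u * np.conj(ref)[:, None]).mean(axis=0))
    vals = np.clip(vals, 0.0, 1.0)
    return PLSMap(values=vals, reference_channel=reference_channel, n_trials=n,
                  freqs=tfc.freqs, times=tfc.times, channel_names=names,
                  edge_mask=tfc.edge_mask)


def pls_bias(n_trials: int) -> float:
    """Expected PLS of n independent uniform phase differences
    (Rayleigh mean, sqrt(pi)/2 / sqrt(n)); the finite-sample floor of the
    statistic.  Asymptotic: at n = 2 the exact value is 2/pi, ~1.6% above
    this approximation."""
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    return float(np.sqrt(np.pi) / 2.0 / np.sqrt(n_trials))


def expected_pls(kappa: float) -> float:
    """Population PLS of a von Mises(kappa) phase offset: I1(k)/I0(k)."""
    from scipy.special import i0e, i1e

    return float(i1e(kappa) / i0e(kappa))
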