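"""Complex Morlet wavelet family and single-trial time-frequency transform.

The family is generated in the time domain, one kernel per analysis
frequency f0 on an inclusive grid (default 8..80 Hz in 1 Hz steps):

    g(t) = A' * exp(-t^2 / (2 sigma_t^2)) * exp(i 2 pi f0 t)

with a constant ratio m = f0 / sigma_f (default 9) tying the spectral
width to the analysis frequency.  sigma_f is defined operationally as the
second-moment standard deviation of the kernel's Fourier *energy* spectrum,
which for a Gaussian envelope gives sigma_t = 1 / (2 sqrt(2) pi sigma_f).
A' normalizes every kernel to unit energy (sum |g|^2 dt = 1), so power is
comparable across frequencies.  Time-varying energy of a trial is the
squared modulus of the convolution of the cosine-square-tapered signal with
g; single-trial matrices average into the evolutionary spectrum, from which
the mean over a pre-stimulus baseline window is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.signal.windows import tukey

from .epochs import EpochSet

_MEM_CAP = 256 * 1024 * 1024  # bytes per FFT workspace chunk


@dataclass(frozen=True)
class WaveletFamily:
    """Sampled complex Morlet kernels indexed by analysis frequency."""

    f0s: np.ndarray          # analysis frequencies, Hz
    m: float                 # f0 / sigma_f
    fs: float                # sampling rate, Hz
    kernels: tuple           # complex arrays, odd lengths
    sigma_f: np.ndarray      # Hz, = f0 / m
    sigma_t: np.ndarray      # s
    a_prime: np.ndarray      # unit-energy normalization constants

    def kernel(self, f0: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.f0s - f0)))
        if abs(self.f0s[i] - f0) > 1e-9:
            raise KeyError(f"{f0} Hz not on the analysis grid")
        return self.kernels[i]


def build_wavelet_family(f_min=8.0, f_max=80.0, f_step=1.0, m=9.0, fs=512.0) -> WaveletFamily:
    """Construct the family on the inclusive grid f_min..f_max.

    Raises if the grid reaches the Nyquist frequency.  Each kernel is
    truncated at +/-4 sigma_t (odd length, <1e-4 energy loss) and has unit
    discrete energy within 1e-6.
    """
    if not (0 < f_min <= f_max):
        raise ValueError("need 0 < f_min <= f_max")
    if f_max >= fs / 2:
        raise ValueError(f"f_max={f_max} must stay below Nyquist ({fs / 2} Hz)")
    if m <= 0:
        raise ValueError("m must be positive")
    n = int(np.floor((f_max - f_min) / f_step + 1e-9)) + 1
    f0s = f_min + f_step * np.arange(n)
    sigma_f = f0s / m
    sigma_t = 1.0 / (2.0 * np.sqrt(2.0) * np.pi * sigma_f)
    kernels, a = [], []
    dt = 1.0 / fs
    for f0, st in zip(f0s, sigma_t):
        half = int(np.ceil(4.0 * st * fs))
        t = np.arange(-half, half + 1) * dt
        envelope = np.exp(-(t ** 2) / (2.0 * st ** 2))
        a_prime = 1.0 / np.sqrt((envelope ** 2).sum() * dt)
        kernels.append(a_prime * envelope * np.exp(2j * np.pi * f0 * t))
        a.append(a_prime)
    return WaveletFamily(
        f0s=f0s, m=float(m), fs=float(fs), kernels=tuple(kernels),
        sigma_f=sigma_f, sigma_t=sigma_t, a_prime=np.asarray(a),
    )


def measured_spectral_sigma(fam: WaveletFamily, f0: float, nfft: int = 1 << 16) -> float:
    """Second-moment spectral std of a kernel about f0, from its
    zero-padded discrete Fourier energy spectrum."""
    g = fam.kernel(f0)
    spec = np.abs(fft(g, nfft)) ** 2
    f = np.fft.fftfreq(nfft, 1.0 / fam.fs)
    return float(np.sqrt(np.sum(spec * (f - f0) ** 2) / np.sum(spec)))


def cosine_square_taper(signal: np.ndarray, taper_fraction: float = 0.1) -> np.ndarray:
    """Taper the last axis with cos^2 ramps over the first and last
    ``taper_fraction`` of samples (0.5 gives a full Hann window)."""
    if not 0 < taper_fraction <= 0.5:
        raise ValueError("taper_fraction must lie in (0, 0.5]")
    n = signal.shape[-1]
    w = tukey(n, alpha=2.0 * taper_fraction)
    return signal * w


@dataclass
class TFComplex:
    """Trial-level complex wavelet coefficients.

    values: trials x channels x frequencies x timepoints; ``edge_mask``
    flags (frequency, timepoint) estimates within 2 sigma_t of an epoch
    edge, where the kernel overlaps zero padding.
    """

    values: np.ndarray
    freqs: np.ndarray        # Hz
    times: np.ndarray        # ms
    channel_names: list
    edge_mask: np.ndarray    # bool, freqs x timepoints
    fs: float

    def channel_index(self, name):
        return list(self.channel_names).index(name)


@dataclass
class TFPower:
    """Trial-averaged evolutionary spectrum (uV^2), optionally baselined."""

    values: np.ndarray       # channels x frequencies x timepoints
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list
    edge_mask: np.ndarray
    n_trials: int
    baseline_applied: bool = False
    baseline_window: tuple = None

    def channel_index(self, name):
        return list(self.channel_names).index(name)


def tf_transform(es: EpochSet, fam: WaveletFamily, taper_fraction: float = 0.1,
                 channels=None, freqs=None, dtype=np.complex128) -> TFComplex:
    """Convolve every trial and channel with the wavelet family.

    Same-length output aligned to the epoch time axis (kernel centred on
    each sample; zero-padded FFT convolution).  ``channels`` / ``freqs``
    restrict the computation; ``dtype=np.complex64`` halves memory traffic
    for large simulation sweeps.  Raises when the lowest analysis frequency
    leaves no usable (unmasked) timepoint in the epoch.
    """
    if abs(es.fs - fam.fs) > 1e-9:
        raise ValueError("EpochSet and WaveletFamily sampling rates differ")
    if channels is None:
        channels = list(es.channel_names)
    ch_idx = [es.channel_index(c) for c in channels]
    if freqs is None:
        fsel = np.arange(len(fam.f0s))
    else:
        fsel = np.array([int(np.argmin(np.abs(fam.f0s - f))) for f in freqs])
        if np.any(np.abs(fam.f0s[fsel] - np.asarray(freqs)) > 1e-9):
            raise KeyError("requested frequency not on the analysis grid")

    times = es.times
    span_ms = es.n_samples * 1000.0 / es.fs
    edge_mask = np.zeros((len(fsel), es.n_samples), dtype=bool)
    for row, fi in enumerate(fsel):
        guard = 2.0 * fam.sigma_t[fi] * 1000.0
        edge_mask[row] = (times - times[0] < guard) | (times[-1] + 1000.0 / es.fs - times < guard)
        if edge_mask[row].all():
            raise ValueError(
                f"kernel at {fam.f0s[fi]:g} Hz masks the whole {span_ms:g} ms epoch; "
                "use longer epochs or a higher f_min"
            )

    x = cosine_square_taper(es.data[:, ch_idx, :], taper_fraction)
    n = es.n_samples
    max_klen = max(len(fam.kernels[fi]) for fi in fsel)
    nfft = next_fast_len(n + max_klen - 1)

    n_trials, n_ch = x.shape[0], len(ch_idx)
    if dtype == np.complex64:
        x = x.astype(np.float32)
    out = np.empty((n_trials, n_ch, len(fsel), n), dtype=dtype)
    kmat = np.zeros((len(fsel), nfft), dtype=dtype)
    leads = np.empty(len(fsel), dtype=int)
    for row, fi in enumerate(fsel):
        k = fam.kernels[fi]
        kmat[row, : len(k)] = k
        leads[row] = (len(k) - 1) // 2
    K = fft(kmat, axis=-1)
    chunk = max(1, int(_MEM_CAP // max(1, 16 * n_ch * len(fsel) * nfft)))
    for start in range(0, n_trials, chunk):
        sl = slice(start, min(start + chunk, n_trials))
        X = fft(x[sl], nfft, axis=-1)
        y = ifft(X[:, :, None, :] * K[None, None, :, :], axis=-1)
        for row in range(len(fsel)):
            out[sl, :, row, :] = y[:, :, row, leads[row] : leads[row] + n]
    return TFComplex(values=out, freqs=fam.f0s[fsel], times=times,
                     channel_names=list(channels), edge_mask=edge_mask, fs=es.fs)


def average_power(tfc: TFComplex, trial_subset=None) -> TFPower:
    """Mean over trials of |coefficient|^2 — the evolutionary spectrum."""
    v = tfc.values if trial_subset is None else tfc.values[trial_subset]
    if v.shape[0] == 0:
        raise ValueError("empty trial subset")
    power = (v.real ** 2 + v.imag ** 2).mean(axis=0)
    return TFPower(values=power, freqs=tfc.freqs, times=tfc.times,
                   channel_names=list(tfc.channel_names),
                   edge_mask=tfc.edge_mask, n_trials=v.shape[0])


def baseline_correct(tp: TFPower, window=(-280.0, -100.0)) -> TFPower:
    """Subtract the mean over the pre-stimulus window ([start, end) ms)
    from every timepoint, per channel and frequency."""
    if tp.baseline_applied:
        raise ValueError("baseline already applied")
    sel = (tp.times >= window[0]) & (tp.times < window[1])
    if not sel.any():
        raise ValueError("baseline window outside epoch")
    base = tp.values[:, :, sel].mean(axis=2, keepdims=True)
    return replace(tp, values=tp.values - base, baseline_applied=True,
                   baseline_window=tuple(window))
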