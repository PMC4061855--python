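# Methods

## Data model and preprocessing

Epochs span −300…700 ms around stimulus onset at 512 Hz, sampled at
t₀ + k/fs for k = 0…511 (half-open [−300, 700) ms, 512 samples). All
amplitudes are in µV. The 39-channel montage comprises 5 midline analysis
electrodes (Fz, FCz, Cz, CPz, Pz), 30 lateral analysis electrodes grouped
as 5 anteriority levels × 2 hemispheres × 3 electrodes, the right mastoid
M2, and 3 non-analysis spares (Fp1, Fp2, Oz); the left mastoid M1 is the
recording reference and carries no channel. Re-referencing to averaged
mastoids therefore subtracts M2/2 from every channel.

Artifact handling is deliberately simple and deterministic: a trial is
rejected when any analysis channel's peak-to-peak amplitude exceeds a
threshold (default 150 µV). The original study does not state its
rejection criterion; this one is chosen because it is reproducible and
directly testable against the generator's known contamination. Whether
rejection preceded re-referencing in the original is likewise unstated; the
pipeline re-references first (the criterion is nearly invariant to the
−M2/2 shift). Subjects need at least `min_trials` (default 50)
artifact-free trials in every analysed tone × condition cell; the pipeline
applies the rule to the cells a design actually contains, so scaled designs
with fewer blocks screen on their own cells.

Two on-disk dialects exist: a fixture container (`.npz`: float64 array +
JSON metadata; exact round trip) and EDF with one 16-bit data record per
trial (round trip exact to the per-channel quantization step) plus a
tab-delimited sidecar for the trial factors EDF cannot carry. EDF reading
goes through `mne`; the writer is a small self-contained EDF encoder.

## Wavelet transform

Complex Morlet kernels are generated in the time domain on an inclusive
frequency grid (default 8–80 Hz, 1 Hz steps):

    g(t) = A′ · exp(−t² / 2σₜ²) · exp(i 2π f₀ t)

with a constant ratio m = f₀/σ_f = 9. σ_f is defined *operationally* as
the second-moment standard deviation of the kernel's discrete Fourier
energy spectrum; for a Gaussian envelope that fixes σₜ = 1/(2√2 π σ_f),
and the package verifies the definition by direct FFT measurement (each
kernel's measured f₀/σ_f equals 9 within 2%). A′ normalizes every kernel
to unit discrete energy (Σ|g|²Δt = 1 within 10⁻⁶), making power comparable
across frequencies. Kernels are truncated at ±4σₜ with odd length
(< 10⁻⁴ energy loss).

One consequence of unit-energy normalization worth knowing: the response
of the filterbank to a pure tone is tilted by ≈ 1/f₀, so the discrete
power peak for a tone can land one 1-Hz bin below the true frequency.
This is a property of the normalization, not an implementation artifact.

Signals are cosine-square tapered (Tukey window; default 10% of the epoch
per edge, far outside the analysis windows) and convolved via zero-padded
FFT with same-length output aligned to the epoch time axis. Timepoints
within 2σₜ of an epoch edge are flagged in an edge mask — at the lowest
alpha frequencies the kernel outlasts the 1 s epoch, and estimates there
are flagged, never dropped; the transform refuses to run only when an
analysis frequency would leave no usable timepoint at all. Time-varying
energy is |coefficient|²; single-trial matrices average into the
evolutionary spectrum per channel and condition; the mean over the
−280…−100 ms pre-stimulus window (92 samples) is subtracted per channel ×
frequency, separately per condition. Subtraction only — no baseline
division or dB scaling. Power is kept at full sample resolution so window
means are exact.

## Phase-locking statistic

Complex coefficients are reduced to unit phasors (exact zeros stay zero
and are counted); for channel c and reference r,

    PLS_c(t, f) = | mean over trials of u_c(t, f) · conj(u_r(t, f)) |.

"Differencing against the reference" is implemented as conjugate
multiplication of unit phasors — the standard construction, equivalent to
subtracting phase angles; literal complex subtraction would not yield a
[0, 1]-bounded statistic. The reference is FCz for gamma and Cz for alpha
(where the respective responses are maximal), configurable. Normalization
precedes differencing; the reverse order is indistinguishable for unit
phasors.

Finite trial counts bias PLS upward: n uniform phase differences have
expected resultant √π/2 · n^(−1/2) (Rayleigh mean; the package returns
this asymptotic form — at n = 2 the exact value is 2/π, about 1.6%
higher). Because the bias depends on n, comparisons between conditions
with unequal trial counts (1080 standards vs 120 deviants) can use seeded
subsampling to a common count (`equalize_trials`); it is off by default to
mirror the original analysis, which compared conditions directly.

For a von Mises(κ) phase offset between target and reference the
population PLS is the Bessel ratio I₁(κ)/I₀(κ) — the generator and the
estimator meet at this closed form, which the test suite exploits across
κ ∈ {0, 0.5, 1, 2, 4}.

## ROI extraction

Two windows: alpha = 8–13 Hz × 100–500 ms, gamma = 28–50 Hz × 200–400 ms.
Frequency bins include both endpoints on the analysis grid (6 and 23 bins
at 1 Hz); time windows are half-open [start, end) on the sample axis (205
and 103 samples), so bin counts are deterministic. Means are plain
averages, so the frequency/time order of averaging is immaterial. Channel
values aggregate to 5 single-electrode midline locations and 10 lateral
(anteriority, hemisphere) means of 3 electrodes. PLS is tabulated at
lateral sites only, since it is measured against a midline reference. The
long-format table (subject, group, session, tone, condition, measure,
band, scheme, location, value) is the stats layer's sole input.

## Mixed repeated-measures ANOVA

The classical univariate decomposition, generic over any set of fully
crossed within-subject factors plus one between-subjects factor. For each
within effect W, the subject × cell matrix is projected onto an
orthonormal contrast basis (Kronecker product of Helmert contrasts for
factors in W, normalized averaging vectors elsewhere). W and W × group are
tested against W's own subject-level error term (pooled within-group
residual covariance S, df = k_W(N − g)); the between effect is tested on
subject averages. Greenhouse–Geisser ε̂ = (tr S)²/(k · tr S²) ∈ [1/k, 1]
multiplies both degrees of freedom, and is applied only to effects with
more than one numerator df — two-level factors are spherical by
construction (ε̂ ≡ 1). With unbalanced groups the within-effect sum of
squares uses the unweighted-group-means (Type III) form, which reduces to
the textbook formula when balanced. Strict p-monotonicity of the
correction is not a theorem: the corrected p can dip marginally below the
uncorrected p when F is small (p ≳ 0.09); in the rejection region the
correction is conservative, and a GG-significant effect is always
significant uncorrected. Huynh–Feldt is intentionally out of scope.

Follow-up ANOVAs after interactions slice the table by a factor level and
re-run without alpha adjustment, mirroring common practice. Pairwise
Bonferroni follow-ups multiply each p by the number of pairs (capped at
1), using paired t-tests when the factor is within-subject and pooled
independent t-tests otherwise. Spearman correlation uses average ranks for
ties, a t-approximation p for n ≥ 10 and the exact permutation
distribution below that (n! ≤ 362,880 permutations, enumerated).

Cross-validation: F and uncorrected p match `pingouin` to ~1e−9 on the
designs it supports; ε̂ matches exactly for pure-within designs. For mixed
designs pingouin derives ε̂ from an unpooled covariance while this package
pools within groups (the SPSS convention), so mixed-design ε̂ is checked
for bounds and behaviour rather than equality.

## Synthetic generator

Background noise is 1/f^α Gaussian noise shaped in the frequency domain,
normalized to an exact per-trace RMS. Defaults: α = 1.5, RMS = 10 µV —
scalp spectra fall steeper than 1/f above the alpha range, and α = 1 at
this RMS would put far more gamma-band noise on the scalp than real
recordings show.

Oscillations are windowed sinusoids with 50 ms cosine-squared on/off ramps
(amplitude exact at the window centre): alpha at 10 Hz over 50–550 ms,
gamma at 40 Hz over 150–450 ms, comfortably covering the analysis windows.
Each trial the reference channel draws a uniform phase; every target
channel adds an independent von Mises(0, κ) offset (κ ≥ 10⁶ is treated as
perfect locking). Per-cell amplitudes and κ encode the study's qualitative
pattern: gamma amplitude English > Thai > Chinese before training, rising
after training for English (×1.5) and mildly for Thai; alpha amplitude
standard > deviant, strongest for Thai, shrinking after training for
English/Chinese, with the English low-falling standard–deviant gap widest
before training and closed after; κ deviant > standard in both bands,
rising after training, most for English alpha. These magnitudes are
illustrative — the original work reports no effect sizes in generator
units — and are fixed constants in `toneosc.synth`.

Artifacts are 100 ms, 400 µV raised-cosine transients on three random
channels in a per-group fraction of trials (0.24 / 0.18 / 0.26 for
Chinese / English / Thai), sized to trip the 150 µV rejection filter so
the screening rule is exercised end to end. Subject heterogeneity is a
single lognormal amplitude scale factor (σ = 0.1) shared by all of a
subject's cells and sessions. Because one factor scales both bands, the
generator induces a *positive* across-subject alpha–gamma power coupling;
the negative correlation reported in real learners is a feature it does
not emulate, and passing tests say nothing about it. Other non-emulated
features: volume conduction and channel covariance (noise is independent
across channels), acoustic structure of the tones, ERP components, and
drifts or non-stationarities.

Determinism: `SeedSequence([master, subject, session, block])` spawns
every block's stream and `SeedSequence([master, subject])` the subject
scale factor, so any subset regenerates in isolation; identical configs
reproduce identical tables (the run manifest hashes every output).

## Problem sizes for simulation studies

The full published design (31 subjects × 2 sessions × 4 × 1200-trial
blocks × 39 channels) is generated and processed streamily but is far
larger than needed for validation, so the simulation suites use scaled
designs: the type-I/power suite runs 5 + 5 subjects, one 48-trial block
per session, gamma only, midline channels, 28–50 Hz at 2 Hz steps, with
the training effect expressed as a doubling of English post-session gamma
amplitude (power ≈ 1.0, null rate ≈ 0.05 over hundreds of replicates);
the worked analysis uses 3 × 4 subjects with two 45-trial blocks and both
bands at 1 Hz resolution. The wavelet path offers a single-precision mode
for these sweeps; estimates differ from float64 far below their Monte
Carlo noise. Spherical-null calibration of the ANOVA uses 10⁴ synthetic
12-subject, 4-level datasets (GG-corrected type-I ≤ 0.06, with the
uncorrected test inflating and GG restoring control on strongly
non-spherical data).

## Numerical choices

Unit-energy check at 10⁻⁶; kernel truncation ±4σₜ; FFT convolution with
`next_fast_len` padding, kernel centred ('same' alignment); edge mask at
2σₜ; streaming accumulation of power and phasor sums per 64-trial chunk
(bit-identical to the one-shot operators); PLS clipped to [0, 1] against
rounding; zero coefficients keep zero phasors and are counted; exact
per-trace RMS normalization of noise; Clopper–Pearson intervals on
rejection rates; all RNG through `numpy.random.Generator(PCG64)`.
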