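# Methods

## Model and assumptions

The package assumes the standard linear generative model of extracranial
and intracranial electrophysiology: electrode measurements
`X (t samples × k channels)` are an instantaneous linear superposition of
source activity `S` through a time-invariant forward model `A`, plus
additive background noise, `X = S Aᵀ + E`. Under this model a rhythm that
is invisible on any single electrode (because stronger sources overlap it
spatially) can still be recovered by a suitable spatial filter `w`, and any
waveform feature that originates from a single source — including harmonics
of a non-sinusoidal oscillation — shares that source's spatial profile.

Spatio-spectral decomposition (SSD) estimates filters by contrasting the
covariance of the data band-passed to a signal band against the covariance
of the data band-passed to two flanking bands. Writing `C_S` and `C_N` for
these covariances, filters maximize `wᵀC_S w / wᵀC_N w`; the full filter
set solves `C_S W = C_N W Λ`. Because the flanks sit only 1–2 Hz away, the
aperiodic 1/f background contributes almost equally to numerator and
denominator, so the quotient isolates the narrowband peak above the 1/f
floor rather than raw band power. The contrast is blind to source waveform
and time course; it only requires that rhythms sharing the band differ in
band-limited SNR (see Limitations).

Components are ordered by eigenvalue (achieved band-limited SNR), and the
filters are applied to the *unfiltered* broadband recording, which is what
preserves waveform shape downstream.

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| signal band | peak ± 2 Hz | oscillation band of interest |
| flanks | 1 Hz gap, 1 Hz wide each side | noise contrast bands |
| temporal filter | Butterworth order 4, zero-phase | applied forward+backward (magnitude squared, phase zero) |
| covariance edge trim | max(1 s, 3 cycles of lowest edge) | excludes filter transients |
| rank threshold | 1e-6 × largest eigenvalue | numerical rank of `C_S` |
| Welch | 3 s Hann windows, 0% overlap | 1/3 Hz resolution |
| spectral fit range | 1–45 Hz | below line noise; matches broadband band |
| peak width limits (σ) | 0.5–12 Hz | Gaussian bandwidth bounds |
| max peaks / threshold | 5 / 2.0 residual SD | peak acceptance |
| SNR retention | > 5 dB, strict | 10 × log10-power peak height above the aperiodic fit |
| spread radius | 25 mm | neighbor search around pattern maximum |
| narrowband (cycles) | peak ± 3 Hz, linear-phase FIR | anchors extrema search |
| broadband (cycles) | 1–45 Hz | where all cycle features are measured |
| burst criteria | amp fraction 0.75; consistency/monotonicity 0.5; ≥ 3 cycles | cycle-level burst classification |
| denoise band | noise ± 1.75 Hz vs (1 Hz, edge) and (edge, +40 Hz) | "keep everything else" contrast |

## Numerical choices

**Zero-phase filtering.** Only the filter family and order are inherent to
the method; forward-backward application is chosen so that filter phase
cannot masquerade as waveform asymmetry.

**Covariances** are computed after column mean removal, normalized by the
sample count, and symmetrized; the generalized eigenvalue problem is
invariant to those operations, which only stabilize conditioning. The noise
contribution is the sample-wise *sum* of the two flank-filtered series
(one `X_N`, matching the single-noise-term model), not two separate
covariances.

**Rank deficiency** (after re-referencing or component removal) is handled
by eigendecomposing `C_S`, keeping the `r` eigenvectors above threshold,
whitening (`M = V_{1:r} diag(1/√λ_i)`), solving the reduced problem and
mapping filters back (`W = M W̃`). Any invertible basis of the retained
subspace yields the same generalized eigenpairs; whitening is the
best-conditioned choice. The same path doubles as a fallback when `C_N` is
not positive definite. The rank threshold is relative (1e-6 of the largest
eigenvalue) so results do not depend on amplitude units.

**Filter/pattern sign.** A filter–pattern pair is defined only up to a
joint sign. Convention: the largest-magnitude entry of each pattern column
is made positive, with the filter column negated in tandem (their outer
product, hence all reconstructions, is unchanged). Deterministic and
idempotent, replacing per-figure manual flipping.

**Spectral parameterization** follows the iterative flatten-and-fit
scheme: (1) robust log-log line fit for the aperiodic seed, excluding
points more than 2.5 median absolute residuals above the line (candidate
peaks); (2) iterative extraction of Gaussian guesses from the flattened
spectrum, each accepted only if its height reaches 2.0 residual standard
deviations (and a strictly positive floor, so exact power laws yield zero
peaks); σ seeded from the half-height width and clipped to the width
limits; (3) joint bounded nonlinear least-squares refinement of all
Gaussians; (4) aperiodic refit on the peak-subtracted spectrum. The width
limits bound σ directly. The dB conversion behind the 5 dB retention
threshold is defined as 10 × (log10-power peak height above the aperiodic
fit): a peak of amplitude a corresponds to a 10^a-fold power elevation,
i.e. 10·a dB.

**Cycle segmentation** anchors cycle boundaries on rising zero-crossings of
the narrowband (peak ± 3 Hz) trace, which localizes one peak and one trough
per cycle robustly, then measures *all* timing and voltage features on the
broadband (1–45 Hz) trace: flank zero-crossings are re-detected on the
broadband signal between consecutive extrema, with the narrowband crossing
as fallback. This matters: a narrowband trace is near-sinusoidal by
construction, so its own zero crossings are duty-symmetric for any input
and would erase the very asymmetry being measured. Crossing times are
linearly interpolated between samples and extrema parabolically
interpolated; without sub-sample timing the one-sample quantization (2% of
a 10 Hz cycle at 1 kHz) would dominate near-symmetric cycles.
`rise_time` is defined as `period − decay_time`, making
`period = rise + decay` exact; on periodic signals it equals the
trough-to-next-peak time. Burst amplitude candidacy uses the 0.75 amplitude
quantile with a 1% tie tolerance (a homogeneous oscillation puts every
cycle numerically at the quantile; a strict comparison would split ties on
floating-point jitter). Amplitude/period consistency are minimum min/max
ratios across a cycle's own and adjacent rise/decay voltages and periods;
monotonicity is the fraction of sample steps moving in the expected
direction; all at threshold 0.5, with bursts requiring ≥ 3 consecutive
candidates.

**Noise removal** fits SSD with the artifact band (e.g. 60 ± 1.75 Hz) as
signal and a deliberately broadened contrast — 1 Hz up to the lower edge,
and the upper edge to noise + 40 Hz — representing "everything that should
remain". The upper cap keeps the contrast from crossing the artifact's own
harmonics at typical sampling rates. Removal is the linear subtraction
`X − Σ aⱼ sⱼ` with broadband component series; it costs one rank per
component but introduces no spectral notch. The automatic component count
is the number of components whose noise-band 1/f-corrected SNR exceeds
5 dB (minimum one).

## The synthetic scene

The default generator scene emulates the kind of clinical subdural-grid
recording the method targets: 20 electrodes drawn from an 8×8, 10 mm-pitch
grid; 1000 Hz; 180 s; three bursty alpha-band sources (9, 10.5, 11.5 Hz)
with Gaussian spatial profiles (15 mm scale) at distinct grid locations,
the 10.5 Hz one arc-shaped (duty-cycle asymmetry 0.3, mu-like); a bursty
16 Hz beta source; per-channel independent 1/f² noise (SD 0.5) with a
small white floor; optionally a spatially uniform 60 Hz line-noise source.
Bursts follow a Poisson process with raised-cosine onset/offset ramps
(0.25 s); ground-truth burst windows record the full-amplitude plateau.
The three alpha rhythms deliberately differ in amplitude (2.4/1.6/1.3) and
burst duration (4.0/1.5/0.9 s): rhythms sharing a band are separable by the
generalized eigenvalue contrast only when their band-limited SNRs differ
(equal-SNR rhythms make the top eigenvalues degenerate and the filters an
arbitrary rotation), and heterogeneous rhythm strength is what clinical
recordings show.

The arc waveform is a duty-warped sine whose longer positive half-cycle is
scaled down so the waveform is exactly zero-mean — a DC offset would not
survive the high-pass inherent in any recording chain and would silently
shift measured zero crossings. The sawtooth rises linearly over a fraction
(1 + asymmetry)/2 of the period. For both, the generator parameter equals
the waveform's nominal asymmetry *before* band-limiting; measuring on the
1–45 Hz trace truncates the harmonic series and biases recovered
asymmetries toward zero by roughly 0.03–0.1 depending on fundamental
frequency and duty (validation tests therefore use 5–6 Hz fundamentals,
where the bias is within 0.05).

What the generator does *not* emulate: volume-conductor head geometry
(mixing is phenomenological Gaussian/dipolar), spatially correlated
background noise (available via `shared_noise_frac` but off by default),
non-stationary peak frequencies, traveling waves, and line-noise frequency
drift. Passing tests therefore show that the algorithms are correct under
the linear, stationary model they assume — not that every clinical
recording satisfies that model.

## Problem sizes

Validation runs use the full 180 s default scene for source recovery, 120 s
for line-noise removal and burst-detection checks, 30–60 s for single-
source waveform checks, and 60 s pipeline runs for reproducibility checks;
these sizes put estimation error well below the tested tolerances while
keeping the whole suite under a minute of compute.

## Limitations

- Rhythms with equal band-limited SNR in the same band are not separable
  by this contrast (degenerate eigenvalues); a different contrast
  (e.g. task modulation) would be needed.
- The spatial model is time-invariant; traveling waves blur sharp waveform
  features in component space, biasing asymmetry magnitudes downward.
- Asymmetry measures on band-limited data systematically underestimate
  extreme duty cycles (see above); comparisons should hold the broadband
  band fixed.
- The spectral parameterization assumes separable aperiodic and Gaussian
  components with a knee-free 1/f; spectra with a knee need a restricted
  fit range.
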