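# Methods

`spindlesync` is a simulation-and-analysis pipeline for a question in
electrophysiological source imaging: when the same sleep spindles are
recorded simultaneously by EEG and MEG and localized with identical
distributed inverse methods, do the two modalities report the same
cortical sources?  The package synthesizes spindles from two generator
systems with known ground truth, renders them through analytic forward
models, inverts with noise-normalized minimum-norm estimation (dSPM), and
measures source-space synchrony.  Everything below is computed by the
code; no empirical human data enter the pipeline.

## Volume conductor and forward models

The head is three concentric spherical shells (inner skull 80 mm, outer
skull 85 mm, scalp 92 mm; conductivities 0.33 / 0.0042 / 0.33 S/m).  A
sphere replaces a subject-specific boundary-element model deliberately:
it admits exact analytic forward solutions while preserving the two
physical properties the analysis depends on — MEG's blindness to radial
currents, and cancellation between opposed dipoles on a folded surface.

**EEG.**  The scalp potential of a current dipole is a Legendre series
whose per-degree radial transfer coefficients come from solving the
interface conditions (continuity of potential and radial current,
insulating exterior) as a 5x5 linear system per degree.  With equal
conductivities the coefficients reduce to the classical homogeneous
values (2n+1)/n, which is how the implementation is cross-checked.  The
series is truncated at order 120 by default: the most superficial default
sources sit at b/R ~ 0.84 of the scalp radius, where order 120 brings the
relative series tail below 1e-6 (order 60, a common textbook default,
leaves a ~1e-3 tail there).  A convergence guard raises an error rather
than silently returning a truncated value.  Outputs are always
average-referenced.

**MEG.**  The magnetic field outside a spherically symmetric conductor is
the Sarvas closed form.  Magnetometers read the field component along
their radial coil normal; planar gradiometers read a two-point finite
difference of the radial component over a 16.8 mm baseline along their
tangential derivative direction, with the two gradiometers at each of the
102 sites orthogonal.  Sensor layouts are Fibonacci lattices (upper
hemisphere for the 60 EEG electrodes; the helmet region for the 102 MEG
sites, 25 mm outside the scalp) — no published montage coordinates are
assumed.

**Source space.**  2 x n dipoles quasi-uniformly sample a radially folded
sphere r(theta, phi) = r0 (1 + a sin(w theta) cos(w phi)), with dipole
orientations the outward normals of the folded surface, so normals on
opposite fold walls oppose like the walls of a sulcus.  Defaults: r0 = 70
mm (folds peak at 77 mm, inside the inner skull), a = 0.1, w = 12.  The
desk-scale analysis space is 642 dipoles per hemisphere (median
nearest-neighbour spacing ~7 mm, matching the spacing a decimated
cortical reconstruction would give at ~3200/hemisphere on real cortex);
the full-scale space (3200/hemisphere) is supported and tested for
geometry but not used in the default statistics runs, purely for compute
time.  Dipole components are expressed along three fixed global axes; the
dSPM power is invariant to that choice (tested).

## The two generator systems

Each simulated spindle (durations drawn from Beta(0.273, 0.460) rescaled
to [483, 1123] ms — the unique Beta of that support matching the 721 ms
mean and 235 ms SD; oscillation frequencies uniform in 10-15 Hz)
activates:

* **matrix system** — every source oscillates with one common frequency
  and phase under a Hann envelope, weighted by a smooth strictly positive
  spatial map (low-order harmonics of the generator seed, fixed per
  subject).  Default per-source moment 26 nAm (~35 nAm/cm^2 at the
  ~0.75 cm^2 effective area per source — within the physiological range
  of synaptic current densities for synchronously active cortex).
* **core system** — 3-6 focal patches per spindle (10 mm geodesic discs),
  each with independent frequency, phase, and active sub-interval
  (onset lag / offset lead up to 30% of the spindle), so the foci shift
  within a single spindle.  Patch centers are drawn from the tangentially
  oriented sources (|normal . radial| < 0.35, the sulcal-wall
  population): the focal system the analysis attributes to MEG is by
  hypothesis the one MEG's orientation selectivity can see.  Default
  per-source moment 10 nAm (net patch moment ~65 nAm, the classic scale
  of a focal equivalent current dipole).  The patch diameter is kept
  below the fold wavelength (~37 mm) so patches escape the cancellation
  that attenuates the diffuse system.

Every source also carries independent 1/f background noise (1 nAm,
flattened below 1 Hz), and channels carry white sensor noise — EEG 3.5
uV (a sleep-EEG noise floor including residual biological artifacts),
magnetometers 50 fT, gradiometers 40 fT/cm (instrument-spec figures over
a 250 Hz bandwidth).  The amplitude choices were made once, on the
physical grounds above, to embody the differential-visibility hypothesis
the generator exists to represent: the diffuse system dominates EEG and
is moderately visible to MEG; the focal system is visible to MEG and
sits at the EEG noise floor.  With these conditions the simulated scalp
EEG spindle is larger than real recordings (~100 uV rather than tens of
uV) because the spherical model with a fully coherent matrix map cancels
less than real cortex; the analysis statistics are all scale-invariant,
so this inflation affects no conclusion.

Recordings are 120 s per subject at 500 Hz (the recorded protocol's 1000
Hz downsampled by 2; 600 Hz is also accepted), 12 spindles and 100 quiet
600-ms epochs per subject, 7 subjects by default.  Simulation is
deterministic given the master seed (seed sequences spawned per subject
and stage).

## Inverse estimation

Noise covariances are strictly diagonal.  The baseline estimate averages
the ~100 band-passed (10-15 Hz, zero-phase 4th-order Butterworth) quiet
epochs sample-wise and takes per-channel variances of the averaged trace
— the averaged-baseline convention, which scales variances by ~1/K; since
the same covariance enters the operator and its normalization, the F
statistic stays internally calibrated.  An empty-room variance estimate
is available for MEG (and refused for EEG, which has no empty-room
analog).

The inverse is W = R G' (G R G' + lambda^2 C)^-1 with R = I (no depth
weighting) and lambda^2 = tr(whitened G R G') / (n_channels snr^2),
default snr = 1 for unaveraged single-trial data.  Computing lambda^2 on
the noise-whitened system (rather than as a ratio of unwhitened traces)
makes the operator invariant to consistent rescaling of any channel —
the form that keeps mixed-unit (T, T/m, V) systems well-posed.  The
combined EEG+MEG operator whitens each modality by its own covariance,
stacks, and inverts with C = I; it fits both modalities' spatial
patterns on a common noise-unit scale (their absolute amplitude ratio is
not separately calibrated).

dSPM normalization: F(i,t) = ||(W x_t)_i||^2 / sum_k diag(W C W')_{ik},
the local three-component current power divided by its expectation under
noise drawn from C, so E[F] = 1 under the null by construction.  The
stored estimate is sqrt(F).  Significance of the time-averaged F treats
T F_bar as the weighted chi-square sum_k lambda_k chi2_T over the
per-source component noise eigenvalues: with an effectively exact
covariance the p-value is computed by numerical inversion of the
characteristic function (Imhof's method, validated against closed forms
to ~1e-6), so null p-values are uniform even where one component is
noise-silent (MEG's radial direction); with finite noise dof a
three-cumulant chi-square match referred to F(nu, dof) is used, which
reduces to the classical F(3, dof) for equal components and one sample.

## Synchrony statistics

* **Within-modality synchrony**: mean zero-lag Pearson correlation over
  all n(n-1)/2 distinct source pairs (6500 sources would give the ~21.1
  million pairs of a full-scale run) within the spindle interval,
  computed via the O(nT) identity mean_r = (||sum_j z_j||^2/T - n) /
  (n(n-1)) on standardized rows; a brute-force double loop is kept and
  tested equal to 1e-12.  Constant rows are excluded and counted; above
  2000 sources a fixed-seed subsample of sources is used (logged).
  Computed on the nonnegative sqrt(F) time courses — the quantity the
  maps display.
* **Between-modality comparison**: per-source correlation and 10-15 Hz
  band coherence between the EEG- and MEG-derived estimates of the same
  source, averaged over sources.  These are computed on *signed*
  time courses (the three estimated components projected on the local
  cortical normal) rather than on magnitudes: a rectified 10-15 Hz
  oscillation carries its rhythmic content at twice the spindle
  frequency, outside the band, so magnitude coherence would measure only
  envelope sharing and the phase-sensitivity contrast between the two
  statistics — the analysis's stated rationale — would be lost.  Both
  variants are exposed (`apply_dspm` for magnitudes,
  `signed_normal_timecourses` for signed).
* **Coherence estimators**: Welch magnitude-squared coherence (Hann
  segments, 50% overlap; defaults 256 samples, shortened adaptively for
  sub-second spindles with at least two segments enforced), and
  Capon/MVDR coherence from L-tap covariance matrices with diagonal
  loading 1e-6 tr(R): S_x = 1/(a^H R_xx^-1 a) per distortionless filter,
  cross-spectrum h_x^H R_xy h_y, coherence bounded by 1 via
  Cauchy-Schwarz.  Default L = 64 for long series; inside the pipeline
  L = clip(samples/20, 8, 64) because a 20L-sample requirement cannot be
  met at L = 64 within a sub-second spindle.
* **Topography**: per-spindle maps of each source's maximum sqrt(F),
  averaged across spindles and normalized to unit maximum; map
  similarity is Pearson correlation over sources.

Aggregation is two-level — spindles within subject, then subjects — so
grand values are means (+/- SD) of subject means.  Reports are validated
pydantic models serialized to JSON (schema shipped in
`spindlesync/schemas/`), with the configuration hash and master seed
embedded; identical seeds give byte-identical reports.

## What the synthetic conditions do and do not show

Passing tests demonstrate that the *method* behaves as described on data
whose generating structure is known: the estimator is calibrated under
its own noise model, localizes isolated superficial sources to within
two grid spacings, and — given one diffuse synchronous and several focal
asynchronous generator systems with the stated differential visibility —
reproduces the qualitative dissociation (high within-EEG synchrony, low
within-MEG synchrony, near-zero between-modality correlation with
substantial band coherence, combined solution intermediate).  They do
not show that real spindles have this generator structure: the sphere
under-cancels relative to real cortical geometry, the background is
spatially white where real background is correlated, sensor noise is
white, no artifacts (cardiac, ocular, movement) are simulated, and
spindle detection is taken from ground-truth annotations rather than
expert scoring.  The numerical values of the synchrony statistics at
desk scale (e.g. within-EEG r ~ 1.0 at 642 sources/hemisphere under a
single noiseless-phase matrix system) are therefore more extreme than
the corresponding human-data values; it is the ordering and separation
of the conditions that the acceptance suite pins down.

## Numerical choices and degenerate inputs

Zero-variance rows are excluded from correlations (error if fewer than
two remain); all-zero gain column triplets abort operator construction
with the offending source indices; dipoles outside the inner shell, MEG
sensors inside the scalp, EEG empty-room requests, sub-10-epoch
covariances, single-segment Welch calls, and sub-8-tap MVDR calls all
raise.  MVDR covariances are ridge-loaded and rejected if still
ill-conditioned beyond 1e12.  Filters are applied forward-backward
(zero-phase) and refuse records shorter than ~3 impulse-response
lengths.  The duration Beta is sampled by inverse transform through
numpy's generator; seeds everywhere are integers below 2^31 derived from
spawned seed sequences.
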