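# Methods

## Problem and model

`nirstate` decodes a binary attentional state — working-memory engagement
(2-back task) versus relaxation — from continuous-wave fNIRS over prefrontal
cortex, and evaluates the decoding against what a random classifier could
achieve. The processing chain is:

1. **Optical density.** For each channel and wavelength,
   `OD_λ(t) = −log10(I_λ(t) / ⟨I_λ⟩_baseline)`, with the baseline taken as the
   arithmetic mean intensity over the first 5 s of the record. The mean is the
   standard estimator for this step; the window is configurable and is applied
   once per record.
2. **Modified Beer–Lambert inversion.** At each sample the two-wavelength OD
   vector is related linearly to chromophore concentration changes,
   `OD_λ = (ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR) · d · DPF_λ`, and the 2×2 system is
   solved exactly. Internals use cm⁻¹·M⁻¹, cm and mol/L; public values are µM
   and mm. Extinction coefficients are the bundled Gratzer/Prahl tabulation
   (760 nm: ε_HbO 586, ε_HbR 1548.52; 850 nm: 1058, 691.32 cm⁻¹·M⁻¹),
   overridable from a TSV; DPF defaults to 6.0 at both wavelengths, a common
   adult-forehead value. Every correctness property of this stage is a
   forward/inverse round trip, so nothing downstream depends on which
   tabulation is used.
3. **Epoching.** One epoch per block marker: an 8-s half-open window starting
   2 s after the marker (the hemodynamic response lags its stimulus by
   seconds). Sample indices use round-half-even; windows that would cross the
   end of the record are dropped and counted, never truncated.
4. **Temporal filtering.** 6th-order Butterworth low-pass, 0.6 Hz cutoff.
   Default application is zero-phase (forward–backward) on the continuous
   concentration series *before* epoching: an 8-s window is short relative to
   the impulse response of a 6th-order IIR at 0.6 Hz, and filtering inside the
   window would put edge transients into every epoch. Zero-phase application
   squares the single-pass magnitude `|H(f)| = 1/√(1 + (f/0.6)^12)`. The
   literal order — epoch first, then filter within epochs — is available via
   `filter_stage="epoch"` and is exercised in tests; neither order is asserted
   as ground truth.
5. **Gaussian-basis GLM features.** Each epoch trace is fitted by ordinary
   least squares to unit-peak Gaussians with σ = 1 s spaced 1 s apart, centers
   at 0.5 … 7.5 s (8 bells for the 8-s window — symmetric coverage with no
   center outside the data). Unit-peak (not unit-area) bells make the fitted
   β's equal the curve heights directly. Features are the heights,
   concatenated over the ten long channels and, by default, both chromophores
   (8 bells × 10 channels × 2 chromophores = 160 values per epoch);
   `chromophore={"hbo","hbr"}` exposes the single-species analyses. Short-separation channels measure scalp and contribute no
   features.
6. **Classification.** Per-feature z-scoring (mean and n−1 SD fitted on
   training rows only) followed by a linear SVM (C = 1 by default; the
   regularisation strength was never critical in our checks and is exposed).
   Evaluation is stratified 5-fold cross-validation — with ~21 epochs,
   unstratified splits can go single-class — refitting the normaliser inside
   every training fold. Headline accuracy is the mean over folds; the pooled
   per-epoch accuracy is also reported. A decision score of exactly zero
   predicts "relax", deterministically. Online replay trains once on all
   calibration epochs and streams per-epoch decisions over the online session
   in temporal order.

## Evaluation layer

**Chance bound.** For n trials and c classes the adjusted-Wald interval
around p₀ = 1/c uses `p̃ = (n·p₀ + z²/2)/(n + z²)` and half-width
`z·√(p̃(1−p̃)/(n + z²))`. For n = 20, c = 2, α = 0.05 the upper limit is
70.07%, displayed as 70% (raw value retained). The bound decreases strictly
in n and brackets 100/c.

**Wilcoxon signed-rank.** One-sample test against a reference accuracy µ:
values equal to µ are removed, |differences| ranked with midranks,
T⁺ = Σ ranks of positive differences, effect size
r_rb = (T⁺ − T⁻)/(T⁺ + T⁻). Two p-value routes, both reported with their
method label:

* *exact enumeration* (default for n ≤ 20): dynamic programming over all 2ⁿ
  sign assignments, valid in the presence of midrank ties; two-sided p =
  2·min(P(T ≤ t), P(T ≥ t)) capped at 1;
* *normal approximation*: tie-corrected variance
  `n(n+1)(2n+1)/24 − Σ(t³−t)/48` with a 0.5 continuity correction.

Desktop statistics packages default to the approximation; on the bundled
accuracy table the online-vs-70 comparison gives p = 0.1069 by the
approximation and p = 0.1016 by exact enumeration, and the reproduction
report prints both with a note of which matches the published figure. Tests
are two-sided throughout. The below-chance flag uses strict `<` against the
upper bound.

## Synthetic sessions

The generator emulates the statistical structure the pipeline assumes, not
any particular subject:

* **Design.** Alternating relax (20 s) and 2-back (40 s) blocks, starting and
  ending with relax; 10 task blocks by default → 21 block markers ≈ the
  20-trial regime of the 70% chance bound. Within-block stimulus lists carry
  3 targets and 7 non-targets in seeded random order.
* **Hemodynamics.** Unit-peak double-gamma HRF (peak 6 s, undershoot 16 s,
  ratio 1/6) convolved with the task boxcar; HbO amplitude 1 µM on all ten
  long channels; HbR = −1/3 × the HbO activation. Short channels receive
  noise only.
* **Noise** (per channel, µM): cardiac 0.2 at 1 Hz, respiration 0.1 at
  0.25 Hz, Mayer 0.1 at 0.1 Hz (seeded random phases), linear drift of
  0.001 µM/s with random sign, white noise SD 0.3. Sampling rate 10 Hz,
  typical for CW instruments. These levels make default-condition decoding
  succeed without saturating at 100%.
* **Forward optics.** Concentrations are projected to raw intensities by the
  exact inverse of the MBLL stage, so simulator + converter form a
  round-trip oracle.

What the generator does **not** emulate — and hence what green tests do not
demonstrate about real recordings: motion artifacts, optode-coupling drift,
scalp/partial-volume contamination of long channels, inter-session
nonstationarity (simulated online replay is therefore optimistic relative to
the published online accuracies), and any subject-level variability beyond
response amplitude.

A structural caveat worth stating: with a strictly periodic block design,
*any* slow drift — though generated independently of the task — is partially
collinear with the condition labels, and the pipeline contains no detrending
stage. Zero-activation sessions therefore show chance-level accuracy in
expectation (48% mean over 100 seeds) but with dispersion above the binomial
benchmark (SD ≈ 14.5 vs 10.9 percentage points for 21 Bernoulli trials).
This mirrors a genuine fNIRS confound rather than a pipeline defect; the
per-session null accuracy lands outside the 21-trial 95% chance interval
more often than the nominal 5% (≈ 19% of seeds), and about 8% even for
white-only noise, since the discrete Bin(21, ½) distribution itself places
7.8% of its mass outside that interval.

## Numerical choices

* OLS via `numpy.linalg.lstsq`; rank-deficient designs are rejected with the
  collinear columns named. The default 80×8 design has condition number ≈ 40.
* Butterworth design via bilinear transform (`scipy.signal.butter`). At the
  pipeline's 10 Hz sampling the digital response deviates from the analog
  magnitude formula near Nyquist (55% at 2 Hz); transfer-function tests
  therefore probe at 100 Hz sampling, where the measured response matches the
  analytic magnitude to < 1%, and separately verify > 100× single-pass
  attenuation of a 2 Hz tone at 10 Hz sampling.
* Zero-variance feature columns abort normalisation with the column named
  (they arise only from degenerate inputs, e.g. constant traces).
* All randomness flows from explicit integer seeds: the simulator seed fixes
  the recording byte-for-byte; the CV seed fixes fold assignment.
* Montage serialisation is plain text and round-trips bit-exactly.

## Design choices that were genuinely open

* Source–detector pairings beyond the stated counts (9 sources, 4 detectors,
  10 long channels split 4 L-DLPFC / 4 R-DLPFC / 2 MFG, short channels at
  F3/F4) are synthetic identifiers: downstream computation uses only distance
  and ROI. Short channels get dedicated emitters (S10/S11) so the 9/4 counts
  describe the long probe.
* Per-block epoch counts and stimulus-onset asynchrony are parameterised, not
  asserted: block durations default to 40 s task / 20 s relax.
* Both chromophores feed one feature matrix by default; the single-species
  analyses are one flag away.
* The per-subject accuracy table bundles group-level reference values so the
  reproduction report can print match/mismatch verdicts next to each
  recomputed number.

## Known limitations

* The evaluation layer reproduces published group statistics exactly; the
  decoding pipeline itself can only be validated against simulation, since
  the original recordings are not public.
* No short-channel regression is applied (none is described for the original
  pipeline); the hook exists but defaults off.
* The SNIRF reader/writer covers the minimal subset needed for cross-format
  checks, not the full specification.
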