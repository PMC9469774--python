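# Methods

## Pipeline

The denoiser chains four stages — empirical mode decomposition (EMD),
Hilbert instantaneous-frequency characterisation, a variance-ratio
F-test that classifies components as noise or signal, and partial
reconstruction — and exposes every intermediate artifact
(`Decomposition`, `FrequencySummary`, `CutoffDecision`) on the result
object so each stage can be inspected and tested in isolation.

### Empirical mode decomposition

Sifting follows the classical scheme: find strict interior extrema
(plateaus contribute their midpoint once), interpolate the maxima and
minima with natural cubic splines, subtract the envelope mean, repeat.
Conventions the classical formulation leaves open were fixed as follows.

* **Envelope end effects.** The two extrema nearest each record end are
  reflected about the endpoint before splining (`boundary_policy =
  "mirror"`); unanchored natural splines diverge beyond the outermost
  knot.  A `"clamp"` alternative pins both envelopes to the endpoint
  samples.
* **Sift stopping rule.** Huang's pointwise Cauchy criterion,
  Σ((h₋₁ − h)²/h₋₁²) < `sd_threshold` (default 0.2), with a small
  peak-scaled epsilon regularising near-zero samples, capped at
  `max_sift_iterations = 100`.  The aggregate variant
  Σ(h₋₁ − h)²/Σh₋₁² was evaluated and rejected: it fires after one or
  two sifts, which under-splits a 501-point noisy record into 5–6
  broadband, heavily mode-mixed IMFs, whereas the pointwise criterion
  recovers the expected ~log₂(n) dyadic bands (modal count 8).  The cap
  is reached on some components; `Decomposition.accepted_by` flags how
  each IMF exited the loop.
* **Decomposition termination.** Extraction continues while the residual
  has at least one maximum, one minimum and three interior extrema, and
  stops when the residual is monotone/single-extremum
  (`monotone_residual`), too featureless to envelope
  (`too_few_extrema`), or `max_imfs = 12` is hit (a safety cap,
  ~⌈log₂ 501⌉ plus margin).
* **IMF test.** `is_imf` implements the textbook definition —
  |#extrema − #zero-crossings| ≤ 1 and envelope mean within 5 % of the
  candidate's range (exact zero being unattainable in finite
  arithmetic).  Zero crossings count sign changes once, exact zeros
  taking the sign of the next nonzero sample.

Completeness (Σ IMFs + residual = input to 1e-9 relative) holds by
construction and is asserted over 100 random records in the test suite.

### Instantaneous frequency

The analytic signal is computed with the frequency-domain discrete
Hilbert transform (negative frequencies zeroed, positive doubled) on the
finite record, without windowing or padding; a constant record is the
documented degenerate case (quadrature 0, phase 0).  Frequency is the
central-difference derivative of the unwrapped phase divided by 2π, in
cycles per sample — axis-unit-agnostic.  The first and last two samples
are masked out of all statistics (edge artifacts); negative frequency
excursions are kept, since clipping would bias the dispersion statistics
the cut-off test consumes.

A component whose unwrapped phase advances by less than one full turn
(2π) over the record — the terminal residual trend, single humps — has
no meaningful oscillation rate; its phase derivative is numerical noise
at the 1e-5 cycles/sample level.  Such components take the degenerate
convention (mean 0, SD 0).  Without this rule the residual's spuriously
tiny SD makes the first scanned variance ratio enormous and the cut-off
would classify *every* IMF as noise.

### F-test cut-off

Per-component frequency SDs are scanned from the residual end toward
IMF₁.  Each consecutive pair contributes
F = SD²(higher-frequency member) / SD²(lower-frequency member); writing
the ratio the other way round would shrink below 1 exactly at a
noise/signal boundary and could never exceed an upper-tail critical
value, so the F ≥ 1 orientation is the only reading under which a
one-sided test is meaningful.  The critical value is the upper-tail
quantile of F(dof1=2, dof2=4) at confidence 0.9995 — for these
parameters 2(√2000 − 1) ≈ 87.44 — held fixed regardless of record
length.  Zero SDs (degenerate components) are floored to the smallest
positive SD in the list, making their ratios 1.  The first significant
pair sets k (IMF₁…IMF_k are removed); with none, k = 0 and
reconstruction returns the input unchanged.

The demanded single-step dispersion jump is √87.44 ≈ 9.35-fold.  Between
adjacent noise bands of a well-sifted decomposition the SD decays only
~2× per order (F ≈ 4–10), so the test fires only when a strongly
coherent component sits directly below the noise bands — the situation
in experimental spectra dominated by smooth intense bands, and in the
constructed-jump demonstration.  On the bundled synthetic family the
test is conservative: the modal outcome is k = 0 (no-op), never a
destructive misclassification.  This conservatism at 99.95 % confidence
with (2, 4) degrees of freedom is a property of the published
parameterisation, reported here as observed; users wanting a more eager
cut-off can lower `confidence`.

### Savitzky–Golay baseline and SNR

`sg_coefficients`/`sg_smooth` delegate to scipy's `savgol_coeffs` and
`savgol_filter` (mode `"interp"`: one-sided full-window polynomial fits
at the ends, preserving record length), with defaults window 13 and
quadratic order — the conventional choice when only a window size is
specified.  SNR is the reference-based power ratio
10·log₁₀(Σ ref²/Σ (est − ref)²) dB, with +∞ for a perfect estimate and
an error for a zero-energy reference; it is invariant to joint scaling.

## Synthetic study conditions

The generator emulates a weak chemical band cluster on record of
n = 501 samples (axis 1…501):

* pure signal y₁(i) = 2·exp(−(u − u_c)²/26)·|cos u − 1.2| with
  u = 0.15·i and the bell centred mid-record — a strictly positive
  envelope (|cos u − 1.2| ≥ 0.2) whose ~42-sample oscillation period and
  ~24-sample bell width give a handful of smooth peaks and a total
  energy of ≈315 (intensity², arbitrary units);
* noise y₂ = 0.05·(z + 1), z standard normal, seeded — i.e. unit-mean
  draws scaled by 0.05, so the noisy record carries a +0.05 offset
  besides the fluctuations.  Zero-mean noise is available via
  `noise_mean = 0`.

The cosine's argument scaling and the bell placement are not fixed by
the formula as published elsewhere in garbled form; they were fixed
once, by requiring the generated family to reproduce the documented
decomposition behaviour (eight IMFs from 501 points; SG-versus-raw SNR
gap set by the noise floor), and are part of the study conditions rather
than tuning knobs.  A `gaussian_mixture` form (three bands on a flat
baseline) provides richer test spectra.

What the generator does *not* emulate: heteroscedastic or correlated
instrument noise, baseline drift, cosmic-ray spikes, detector
saturation, and the very high-energy smooth bands of real XRD/XPS
spectra.  Passing tests on this family therefore demonstrate the
machinery (completeness, frequency statistics, test mechanics,
reconstruction) and the conservative no-op behaviour at low signal
energy; they do not by themselves certify denoising gains on
experimental spectra, where the strong-band regime that triggers the
cut-off is expected.

## Numerical choices and degenerate inputs

* Spectra require n ≥ 3, strictly increasing axes (never silently
  reordered), finite intensities; EMD requires n ≥ 5, the Hilbert
  transform n ≥ 8.
* Files are plain one- or two-column text; the delimiter (comma, tab,
  whitespace) is sniffed, a single non-numeric header line is accepted,
  and parse errors name the offending line.  Intensities are written at
  full double precision (%.17g); write→read round-trips are exact to 12
  significant digits.
* All pipeline stages are deterministic: identical input and
  configuration give bit-identical decompositions and decisions.
  Randomness exists only in the generator, driven by an explicit seed.

## Known limitations

* Plain EMD mode-mixes when a coherent component's amplitude is locally
  comparable to the noise; ensemble variants (EEMD, CEEMDAN) address
  this but are out of scope.
* The F(2, 4)/99.95 % cut-off rule has essentially no power against
  gradual dispersion decay (see above); it detects order-of-magnitude
  jumps only.
* Instantaneous frequency near record ends is unreliable for about as
  many samples as the local period; only two samples per end are masked,
  which is adequate for records of several hundred points but optimistic
  for very short ones.
* SNR evaluation requires a clean reference and is therefore confined to
  synthetic or spiked data.
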