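# hhtdenoise

Spectral denoising for one-dimensional analytical-chemistry signals
(XRD, XPS, optical spectra, chromatograms) built on the Hilbert–Huang
transform with an F-test cut-off, plus a Savitzky–Golay baseline for
comparison.

## The method

Measured spectra carry instrumental and operational noise on top of the
chemically meaningful bands.  Rather than smoothing with a fixed kernel,
this package separates noise from signal adaptively:

1. **Empirical mode decomposition (EMD).** The spectrum *x* is sifted
   into intrinsic mode functions IMF₁…IMFₙ plus a residual *r*, with
   *x* = Σᵢ IMFᵢ + *r* to machine precision.  Each IMF is a locally
   zero-mean oscillation band; IMF₁ is the fastest, later orders are
   slower.  Sifting subtracts the mean of natural cubic-spline envelopes
   through the local maxima and minima until Huang's pointwise Cauchy
   criterion Σ((h₋₁ − h)² / h₋₁²) < 0.2 is met.
2. **Hilbert instantaneous frequency.** For each component the analytic
   signal Z(t) = x(t) + iH(t) = a(t)·e^{iθ(t)} is formed with the
   discrete Hilbert transform, and the instantaneous frequency
   ω(t) = dθ/dt (in cycles per sample) is summarised by its mean and
   standard deviation.  Noise components have high, widely dispersed
   frequencies; coherent signal components are narrow.
3. **F-test cut-off.** Scanning consecutive components from the residual
   toward IMF₁, each squared ratio of frequency SDs
   F = SD²(higher-frequency) / SD²(lower-frequency) is compared with the
   upper-tail critical value of the F(2, 4) distribution at 99.95 %
   confidence (87.44).  The first significant jump marks the cut-off
   index *k*: IMF₁…IMF_k are classed as noise.
4. **Reconstruction.** The denoised spectrum is IMF_{k+1} + … + IMFₙ + *r*.
   When no ratio is significant, *k* = 0 and the spectrum is returned
   unchanged — the test is deliberately conservative.

The classical comparator, Savitzky–Golay smoothing, replaces each sample
by the centre value of a least-squares quadratic fitted over a sliding
window (default 13 points).  Denoising quality is measured as
SNR = 10·log₁₀(Σ ref² / Σ (est − ref)²) in dB against a clean reference.

## Worked example

```bash
python examples/denoise_synthetic.py
```

```
record: 501 points, noise scale 0.05
EMD: 8 IMFs + residual (stop: too_few_extrema)
F-test cut-off k = 0 (critical value 87.44, largest observed F 9.44)
removed IMFs: none
SNR(noisy)  =  21.87 dB
SNR(HHT)    =  21.87 dB
SNR(SG w13) =  24.51 dB
```

The bundled generator produces a smooth multi-peak signal of moderate
energy under additive Gaussian noise.  EMD splits it into 8 IMFs; the
dispersion of instantaneous frequency decays smoothly (about 2× per
order, F ≈ 4–10), so no adjacent ratio reaches the 99.95 % critical
value and the pipeline correctly declines to delete anything (k = 0,
output SNR equals the input).  `examples/cutoff_ftest_demo.py` shows the
complementary case — a 20-fold dispersion collapse between adjacent
components gives F = 400 ≫ 87.44 and the cut-off fires at exactly that
boundary, the regime typical of experimental spectra whose strong smooth
bands concentrate in the deep IMFs.  `examples/decompose_and_summarise.py`
prints the per-component frequency table that feeds the test.

The same operations are available from the shell:

```bash
hhtdenoise simulate --n 501 --seed 7 --out noisy.csv --pure-out pure.csv
hhtdenoise denoise --input noisy.csv --output denoised.csv --report cutoff.csv
hhtdenoise compare --input noisy.csv --reference pure.csv
```

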