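"""Denoise a synthetic noised spectrum and compare with SG smoothing.

Generates the default 501-point artificial spectrum (smooth multi-peak
signal plus seeded Gaussian noise), runs the HHT+F-test pipeline and a
Savitzky-Golay baseline, and prints reference-based SNRs.  A cut-off of
k=0 means the variance-ratio test found no significant dispersion jump
at the 99.95% level, so the pipeline left the spectrum untouched rather
than risk deleting signal.
"""

from hhtdenoise import (SGConfig, SynthParams, generate_noised, hht_denoise,
                        sg_smooth, snr_db)

noisy, pure, noise = generate_noised(SynthParams(seed=7))
print(f"record: {noisy.n} points, noise scale {0.05}")

result = hht_denoise(noisy)
d = result.decomposition
print(f"EMD: {d.n_imfs} IMFs + residual (stop: {d.stop_reason})")
print(f"F-test cut-off k = {result.decision.k} "
      f"(critical value {result.decision.f_critical:.2f}, "
      f"largest observed F {max(result.decision.f_values):.2f})")
print(f"removed IMFs: {result.removed_orders or 'none'}")

sg = sg_smooth(noisy, SGConfig(window=13, poly_order=2))
print(f"SNR(noisy)  = {snr_db(pure, noisy):6.2f} dB")
print(f"SNR(HHT)    = {snr_db(pure, result.denoised):6.2f} dB")
print(f"SNR(SG w13) = {snr_db(pure, sg):6.2f} dB")
print("Higher SNR means the estimate is closer to the clean reference.")
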