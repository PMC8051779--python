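"""Calibration-curve quantification and HPLC fingerprint summary.

Fits a gallic-acid standard curve (here simulated with realistic noise),
converts a sample absorbance into mg GAE per g of extract dry weight,
and renormalizes the published 13-peak HPLC table into percent area /
percent height.
"""

import phytorsm as pr

# five standards across the Folin-Ciocalteu working range, slight noise
standards = pr.simulate_calibration(slope=0.004, intercept=0.02, noise_sd=0.005, seed=5)
curve = pr.fit_calibration(standards["concentration"], standards["signal"])
print(f"calibration: signal = {curve.slope:.5f}*c + {curve.intercept:.4f}, R^2 = {curve.r2:.4f}")

absorbance = 0.52
content = pr.content_from_signal(
    absorbance, curve, extract_mass_g=1.0, volume_ml=25.0, dilution=10.0
)
# concentration is in ug/mL here, so content comes out in ug/g; report mg/g
print(f"sample A = {absorbance}: {content / 1000:.1f} mg GAE/g DW")

peaks = pr.peak_percentages(pr.datasets.hplc_peaks())
print("\nHPLC fingerprint (percent of total area / height):")
print(peaks[["id", "rt_min", "percent_area", "percent_height"]].round(3).to_string(index=False))
quercetin = pr.match_peak_by_rt(peaks, rt_min=4.544)
print(f"\nmarker peak at RT {quercetin['rt_min']} min carries "
      f"{quercetin['percent_area']:.1f}% of the fingerprint area")
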