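"""PCMR flow quantification on a synthetic velocity image series.

Synthesizes a phase-contrast-MR-like stack for one vertebral artery
(analytic pulsatile profile plus velocity noise), segments the lumen,
integrates the through-plane velocity into per-phase flow samples, and
resamples them to the 500-point pulse waveform used as a solver boundary
condition.
"""

import numpy as np

from vbsflow import (
    compute_flow_samples,
    detect_cycle_features,
    generate_pcmr_series,
    generate_vertebral_waveforms,
    make_subject_fixture,
    resample_waveform,
    segment_lumen,
)

fx = make_subject_fixture("C")
lv, rv = generate_vertebral_waveforms(fx)

series = generate_pcmr_series(lv, fx.vessel_radii["LV"], fx.imaging, seed=1)
mask = segment_lumen(series)
t, q = compute_flow_samples(series, mask)
wf = resample_waveform(t, q, fx.cycle_period, label="LV")

truth = series.truth.flow_ml_s
print(f"cardiac phases acquired : {series.n_phases}")
print(f"segmented lumen area    : {mask.area * 1e6:.2f} mm^2 "
      f"(true {np.pi * fx.vessel_radii['LV']**2 * 1e6:.2f} mm^2)")
print(f"max |flow error|        : {np.abs(q - truth).max():.3f} ml/s "
      f"({np.abs(q - truth).max() / truth.max():.1%} of peak)")
print(f"resampled waveform      : {wf.n_points} points, "
      f"mean {wf.mean():.2f} ml/s, peak {wf.peak()[1]:.2f} ml/s")

total = wf + resample_waveform(*compute_flow_samples(
    generate_pcmr_series(rv, fx.vessel_radii["RV"], fx.imaging, seed=2),
    segment_lumen(generate_pcmr_series(rv, fx.vessel_radii["RV"], fx.imaging,
                                       seed=2)),
), fx.cycle_period)
feats = detect_cycle_features(total)
print(f"peak systole at t = {feats.peak_systole:.3f} s, "
      f"end diastole at t = {feats.end_diastole:.3f} s")
print("\nThe flow error shows how faithfully segmentation + sub-pixel")
print("integration recover the known synthetic flow despite 2% VENC noise.")
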