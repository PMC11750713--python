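"""Aggregate panel signal, call detection, and predict the panel's LOD.

Works directly at the molecule-count level: 9 alt molecules across a
3-million-molecule panel with aggregate noise lambda = 0.3.
"""
from ctdna_mrd import TargetObservation, detect_sample, predict_panel_lod

observations = [
    TargetObservation("t1", total_molecules=1_000_000, alt_molecules=5,
                      noise_rate=1e-7),
    TargetObservation("t2", total_molecules=1_000_000, alt_molecules=4,
                      noise_rate=1e-7),
    TargetObservation("t3", total_molecules=1_000_000, alt_molecules=0,
                      noise_rate=1e-7),
]
result = detect_sample(observations, plasma_volume_ml=2.0, sample_id="s1")
print(f"k = {result.k} alt molecules of M = {result.M:,}")
print(f"ppm = {result.ppm:.2f}  (tumor fraction in parts per million)")
print(f"lambda = {result.lambda_noise:.2f} expected background molecules")
print(f"one-tailed Poisson p = {result.p_value:.2e} -> "
      f"{'DETECTED' if result.detected else 'not detected'}")
print(f"tumor molecules per ml plasma: {result.tumor_molecules_per_ml}")

est = predict_panel_lod(assumed_M=3e6, assumed_lambda=0.3)
print(f"\npredicted 95% LOD: {est.lod95_ppm:.2f} ppm "
      f"(critical count k_crit = {est.k_crit})")
# At this configuration >= 4 alt molecules are significant at p <= 0.001,
# and ~2.5 ppm of tumor fraction yields >= 4 molecules 95% of the time.
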