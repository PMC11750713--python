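"""Design a bespoke MRD panel from simulated tumor/normal somatic calls.

Builds a background error model from 200 simulated healthy plasma samples,
filters and ranks 2,500 somatic SNV candidates, and selects up to 1,800
targets plus 43 QA population SNVs.
"""
from ctdna_mrd import (
    design_panel,
    estimate_substitution_error_model,
    simulate_background_cohort,
    simulate_qa_snv_catalog,
    simulate_tumor_normal_variants,
)

cohort = simulate_background_cohort(n_samples=200, molecules_per_sample=1_000_000,
                                    seed=1)
model = estimate_substitution_error_model(cohort)
print("estimated background error rates (per unique molecule):")
for cls in ("C>T", "A>G", "C>A"):
    print(f"  {cls}: {model.rates[cls]:.2e}")

calls, exclusions, truth = simulate_tumor_normal_variants(2500, seed=2)
catalog = simulate_qa_snv_catalog(200, seed=3)
panel = design_panel("patient-001", calls, exclusions, model, catalog,
                     panel_cap=1800, seed=4)

print(f"\npanel: {len(panel.targets)} MRD targets "
      f"(cap 1800), {len(panel.qa_snvs)} QA SNVs")
best = panel.targets[0]
print(f"top-ranked target {best.target_id}: AF {best.tumor_af:.2f}, "
      f"error rate {best.error_rate:.1e}, score {best.rank_score:.2e}")
lam = panel.aggregate_noise_rate(molecules_per_target=1666)
print(f"aggregate noise mean at 1,666 molecules/target: lambda = {lam:.3f}")
# lambda is the expected count of background alt molecules across the whole
# panel in a tumor-free sample -- the mean of the Poisson null distribution.
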