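"""Deterministic exposure and risk from mean concentrations.

Chronic daily intake via ingestion and dermal contact, hazard quotients
(HQ = CDI/RfD), the hazard index HI = ΣHQ, and carcinogenic risk
CR = CDI × SF for the two carcinogens (As, Cd), for adult and child
drinking-water cohorts.
"""

import ptewater as pw

samples = pw.generate_samples(53, seed=42)
defaults = pw.load_defaults()
cohorts = {"adult": defaults.adult, "child": defaults.child}

risk = pw.assess_risk(samples, cohorts, defaults.toxicity)
print("Per-element risk at mean concentrations:")
print(risk.per_element.round(6).to_string(index=False))
for cohort in cohorts:
    print(
        f"\n{cohort}: HI = {risk.hi[cohort]:.3f} → {risk.hi_class[cohort]}; "
        f"TCR = {risk.tcr[cohort]:.2e} → {risk.tcr_class[cohort]}"
    )
print(
    "\nHI sums HQ over all eight elements (oral + dermal routes); values above 1 "
    "flag potential non-carcinogenic risk. TCR sums the oral carcinogenic risks "
    "of As and Cd; 1e-6 to 1e-4 is conventionally 'low' risk."
)
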