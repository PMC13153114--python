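"""Compute tracer uptake rates from a single simulated incubation.

Builds a 60-min incubation with a known true urea uptake rate, spikes the
substrate pool at 10% of ambient with 98 atom% 15N label, and recovers the
rate with the mass-balance estimator. With no regeneration and no noise the
estimate matches the planted truth to machine precision.
"""

from ntracer.isotope import NForm, specific_uptake, volumetric_uptake
from ntracer.simulate import IncubationScenario, simulate_incubation

scenario = IncubationScenario(
    v_true={NForm.UREA: 1.5, NForm.AMMONIUM: 0.8},  # umol N / L / h
    substrate_conc={NForm.UREA: 1.5, NForm.AMMONIUM: 2.0},  # ambient, umol N / L
    pon=300.0,  # particulate organic N, umol N / L
    duration_h=1.0,
    noise_sd=0.0,
    seed=1,
)
records, truth = simulate_incubation(scenario)

for rec in records:
    v = volumetric_uptake(rec)
    print(
        f"{rec.form.value:5s} substrate enriched to {float(rec.ap_enr):7.4f} atom%, "
        f"cells rose {float(rec.ap_post) - float(rec.na_pre):.4f} atom% -> "
        f"V = {v:.4f} umol N/L/h (true {truth.loc[rec.form.value, 'v_true']}), "
        f"specific = {specific_uptake(v, rec.pon):.5f} /d"
    )
# V is nitrogen assimilated per litre per hour; the specific rate normalizes
# by biomass (PON) and converts to per day.
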