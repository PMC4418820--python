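"""Translate whole-tumor uptake into particles per second per vessel segment.

A 1 cm^3 tumor at a vessel length density of 150 mm/mm^3 holds 150 m of
microvessels = 1.5 million segments of 100 um. Dividing the tumor uptake rate
k_epr N_bl(t) among them gives the local delivery rate a single capillary
stretch sees.
"""

from eprkit import (
    DOXIL_DRUG,
    DOXIL_PK,
    DOXORUBICIN_DRUG,
    DOXORUBICIN_PK,
    ModelState,
    SimulationGrid,
    VesselArchitecture,
    derive_rate_constants,
    segment_accumulation_rate,
    segment_count,
    simulate_closed_form,
    time_averaged_segment_rate,
    total_vessel_length,
)

vessels = VesselArchitecture()
print(f"total vessel length: {total_vessel_length(vessels):.0f} m "
      f"({segment_count(vessels):.2e} segments of {vessels.segment_length:.0f} um)")

k = derive_rate_constants(DOXIL_PK).with_epr(1e-3)
rate = time_averaged_segment_rate(k, DOXIL_PK.initial_amount, vessels, DOXIL_DRUG)
print(f"Doxil, k_epr/k_el = 1e-3: {rate:.1f} liposomes/s per segment "
      f"(averaged over the first hour)")

kd = derive_rate_constants(DOXORUBICIN_PK).with_epr(1e-3)
tc = simulate_closed_form(kd, ModelState(t=0, N_bl=DOXORUBICIN_PK.initial_amount),
                          SimulationGrid(t_end=48.0))
rates = segment_accumulation_rate(tc, kd, vessels, DOXORUBICIN_DRUG)
print(f"doxorubicin, same ratio: {rates[0]:.2e} molecules/s per segment at t = 0,")
i10min = (tc.t >= 1 / 6).argmax()
print(f"  falling to {rates[i10min]:.2e} molecules/s within 10 minutes as the")
print("  free drug distributes into normal tissue.")
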