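# eprkit

Compartmental pharmacokinetic modelling of tumor drug uptake by the
**enhanced permeation and retention (EPR) effect** — the leaky tumor
vasculature plus poor lymphatic drainage that lets macromolecules and
nanoparticles extravasate into solid tumors.

The package is for pharmacometric modellers and drug-delivery researchers
who want to ask: *given a drug's measured blood pharmacokinetics, how much of
it ends up in a tumor, how fast, and how sensitive is that to the leakiness
of the tumor vasculature and to back-flow into circulation?*

## The model

Blood (N_bl), peripheral tissue (N_p) and tumor (N_t) drug amounts (mg)
exchange by first-order kinetics:

```
dN_bl/dt = -(k_el + k_epr + k_p) N_bl + k_d N_p + k_b N_t
dN_p /dt =   k_p N_bl - k_d N_p
dN_t /dt =   k_epr N_bl - k_b N_t
```

- `k_p = k_12`, `k_d = k_21`: exchange with the peripheral compartment,
- `k_el`: elimination by kidneys, mononuclear phagocyte system, and every
  other non-tumor pathway,
- `k_epr`: extravasation into the tumor (the EPR effect),
- `k_b`: intravasation from the tumor back into circulation.

The system is dissipative — `d(N_bl+N_p+N_t)/dt = -k_el N_bl` — and, being
linear, is solved exactly as `N(t) = exp(Mt) N(0)`.

Blood disposition from clinical trials is reported as a biexponential fit
`N_bl(t) = A e^(-αt) + B e^(-βt)`; a standard two-compartment model maps it
onto the micro constants

```
k_21 = (βA + αB)/(A + B),    k_10 = αβ/k_21,    k_12 = α + β − k_21 − k_10,
```

and when `k_b = 0` the fitted total elimination splits as
`k_10 = k_el + k_epr` (≈ `k_el` whenever `k_epr ≪ k_el`). Bundled reference
parameter sets cover pegylated liposomal doxorubicin (Doxil: A = 34.5 mg,
B = 61.0 mg, α = 0.301 h⁻¹, β = 0.015 h⁻¹) and free doxorubicin
(A = 28.5 mg, B = 1.1 mg, α = 11.6 h⁻¹, β = 0.067 h⁻¹), both as blood
amounts for a 50 mg m⁻² dose, 1.8 m² body surface area, 5 L blood volume.

Beyond whole-tumor amounts, the tumor uptake rate `k_epr N_bl − k_b N_t` is
normalized to a single vessel segment: a 1 cm³ tumor at a vessel length
density of 150 mm mm⁻³ contains 150 m of microvessels — 1.5 × 10⁶ segments
of 100 µm — and mg/h convert to particles/s via the molar mass (543.52 g/mol
for doxorubicin) and the carrier payload (15,000 molecules per liposome).

## Worked example

```python
from eprkit import (DOXIL_PK, DOXIL_DRUG, VesselArchitecture, ModelState,
                    SimulationGrid, derive_rate_constants,
                    simulate_closed_form, time_averaged_segment_rate)

k = derive_rate_constants(DOXIL_PK)
print(k.k_p, k.k_d, k.k_10)
# 0.09547950097530544 0.1976806282722513 0.022839870752443255

# tumor uptake with leakiness 1/10 of all other elimination, no back-flow
k_epr = k.with_epr(0.1)
tc = simulate_closed_form(k_epr, ModelState(t=0, N_bl=DOXIL_PK.initial_amount),
                          SimulationGrid(t_end=240.0))
print(100 * tc.n_t.max() / DOXIL_PK.initial_amount)
# 8.92103430024895    -> ~9% of the dose in the tumor at the 10-day plateau

# local delivery rate per 100 um vessel segment, leakiness ratio 1e-3
rate = time_averaged_segment_rate(k.with_epr(1e-3), DOXIL_PK.initial_amount,
                                  VesselArchitecture(), DOXIL_DRUG)
print(rate)
# 28.222958476720034  -> ~28 liposomes per second in the first hour
```

The rate constants (h⁻¹) say Doxil exchanges with peripheral tissue about
five times faster than it is eliminated; the plateau says that even a very
leaky tumor (k_epr/k_el = 0.1) captures under 10% of the dose, because
uptake competes with clearance; the segment rate translates that global
number into tens of liposomes per second arriving along every
100 µm of tumor capillary.

The `examples/` directory contains narrative scripts for each capability
(rate-constant derivation, uptake sweeps, per-vessel fluxes, fitting and
synthetic-data generation); each prints its numbers with a short
interpretation.

## Command line

A thin CLI wraps the same functions:

```
epr derive --drug doxil
epr sweep --drug doxil --epr-ratios 1e-1,1e-2,1e-3 --back-ratios 0,10,100,1000 \
          --t-end 240 --out out/
epr microdose --drug doxil --epr-ratio 1e-3 --back-ratios 0,100 --out rates.csv
epr generate --drug doxil --noise-cv 0.1 --n-subjects 14 --seed 7 --out pk.csv
epr fit --data pk.csv
```

All tables are CSV; every run writes a provenance record (config hash,
version, seed) sufficient to reproduce it byte-for-byte.

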