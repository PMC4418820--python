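"""Derive two-compartment rate constants from published biexponential fits.

The clinical literature reports blood disposition as N_bl(t) = A e^(-alpha t)
+ B e^(-beta t); the micro rate constants k_12 (blood -> peripheral), k_21
(peripheral -> blood) and k_10 (total elimination) follow algebraically.
"""

from eprkit import DOXIL_PK, DOXORUBICIN_PK, derive_rate_constants

for name, pk in (("Doxil", DOXIL_PK), ("doxorubicin", DOXORUBICIN_PK)):
    k = derive_rate_constants(pk)
    print(f"{name}: A={pk.A} mg, B={pk.B} mg, alpha={pk.alpha}/h, beta={pk.beta}/h")
    print(f"  k_12 = {k.k_p:.4g} /h   k_21 = {k.k_d:.4g} /h   k_10 = {k.k_10:.4g} /h")

print()
print("k_10 is the total elimination rate from blood; the liposomal formulation")
print("clears ~70x slower than the free drug, which is what lets it accumulate")
print("in a tumor by the EPR effect.")
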