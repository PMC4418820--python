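"""Biexponential disposition parameters and two-compartment rate-constant algebra.

Clinical pharmacokinetic data for a drug in circulation are commonly reported
as a biexponential fit

    N_bl(t) = A e^(-alpha t) + B e^(-beta t)

with the amount in blood in mg (concentrations are converted with the blood
volume). A standard two-compartment disposition model (central = blood plus
highly perfused organs, peripheral = normal tissue) implies a one-to-one
mapping between (A, B, alpha, beta) and the micro rate constants:

    k_21 = (beta*A + alpha*B) / (A + B)      (peripheral -> blood, = k_d)
    k_10 = alpha*beta / k_21                 (total elimination from blood)
    k_12 = alpha + beta - k_21 - k_10        (blood -> peripheral, = k_p)

This module implements that algebra in both directions, the evaluation of the
biexponential itself, and the dose conventions (dose per body surface area,
concentration <-> amount via blood volume).

Internal units are fixed: hours for time, mg for amounts, h^-1 for rates,
litres for volumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BiexponentialParams",
    "RateConstants",
    "DoseSpec",
    "DrugProperties",
    "PKSummary",
    "derive_rate_constants",
    "rate_constants_to_biexponential",
    "blood_amount",
    "dose_to_amount",
    "pk_summaries",
    "DOXIL_PK",
    "DOXORUBICIN_PK",
    "DOXIL_DRUG",
    "DOXORUBICIN_DRUG",
    "DEFAULT_DOSE",
]


@dataclass(frozen=True)
class BiexponentialParams:
    """Empirical disposition fit N_bl(t) = A e^(-alpha t) + B e^(-beta t).

    ``A`` and ``B`` are amounts in mg; ``alpha`` and ``beta`` are rate
    constants in h^-1 with ``alpha`` the fast (distribution-phase) constant.
    Construction canonicalizes the ordering: if ``alpha < beta`` the pairs
    (A, alpha) and (B, beta) are swapped, because the rate-constant algebra
    is not symmetric under relabelling of the exponentials.
    """

    A: float
    B: float
    alpha: float
    beta: float

    def __post_init__(self):
        if self.A < 0 or self.B < 0:
            raise ValueError(f"amplitudes must be nonnegative, got A={self.A}, B={self.B}")
        if self.A + self.B <= 0:
            raise ValueError("A + B must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(
                f"rate constants must be positive, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.alpha < self.beta:
            A, B, a, b = self.A, self.B, self.alpha, self.beta
            object.__setattr__(self, "A", B)
            object.__setattr__(self, "B", A)
            object.__setattr__(self, "alpha", b)
            object.__setattr__(self, "beta", a)

    @property
    def initial_amount(self) -> float:
        """Blood amount at t = 0, A + B (mg)."""
        return self.A + self.B


@dataclass(frozen=True)
class RateConstants:
    """First-order rate constants (h^-1) of the three-compartment model.

    ``k_p`` (= k_12) and ``k_d`` (= k_21) exchange drug with the peripheral
    compartment; ``k_10`` is the total elimination constant of the fitted
    two-compartment model; ``k_el`` the non-tumor part of it; ``k_epr`` the
    extravasation constant into the tumor and ``k_b`` the intravasation
    constant back into circulation. With k_b = 0 the identity
    k_10 = k_el + k_epr holds; importing a clinical fit sets k_el = k_10 on
    the grounds that k_epr << k_el in the regimes of clinical interest.
    """

    k_p: float
    k_d: float
    k_10: float
    k_el: float
    k_epr: float = 0.0
    k_b: float = 0.0

    def __post_init__(self):
        for name in ("k_p", "k_d", "k_10", "k_el", "k_epr", "k_b"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"rate constant {name} must be nonnegative, got {v}")

    def with_epr(self, epr_ratio: float, back_ratio: float = 0.0) -> "RateConstants":
        """Return a copy with k_epr = epr_ratio * k_el and k_b = back_ratio * k_epr."""
        if epr_ratio < 0 or back_ratio < 0:
            raise ValueError("epr_ratio and back_ratio must be nonnegative")
        k_epr = epr_ratio * self.k_el
        return replace(self, k_epr=k_epr, k_b=back_ratio * k_epr)


@dataclass(frozen=True)
class DoseSpec:
    """Administered dose and the conversions that turn it into a blood amount.

    ``nominal_dose`` defaults to dose_per_area * body_surface_area.
    ``blood_volume`` converts measured concentrations (mg/L) to amounts (mg).
    """

    dose_per_area: float  # mg m^-2
    body_surface_area: float = 1.8  # m^2
    blood_volume: float = 5.0  # L
    nominal_dose: float = field(default=None)  # mg

    def __post_init__(self):
        for name in ("dose_per_area", "body_surface_area", "blood_volume"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"missing required dose field: {name}")
            if v <= 0:
                raise ValueError(f"dose field {name} must be positive, got {v}")
        if self.nominal_dose is None:
            object.__setattr__(
                self, "nominal_dose", self.dose_per_area * self.body_surface_area
            )
        elif self.nominal_dose <= 0:
            raise ValueError(f"nominal_dose must be positive, got {self.nominal_dose}")

    def concentration_to_amount(self, concentration_mg_per_L) -> float:
        """Convert a blood concentration (mg/L) to an amount (mg)."""
        return np.asarray(concentration_mg_per_L, dtype=float) * self.blood_volume


@dataclass(frozen=True)
class DrugProperties:
    """Molecular descriptors needed to turn mg into particle counts.

    ``payload_per_carrier`` is the number of drug molecules per carrier
    particle: ~10,000-15,000 doxorubicin molecules per Doxil liposome, 1 for
    a free small-molecule drug.
    """

    name: str
    molar_mass: float  # g mol^-1
    payload_per_carrier: int = 1

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")
        if int(self.payload_per_carrier) != self.payload_per_carrier or self.payload_per_carrier < 1:
            raise ValueError(
                f"payload_per_carrier must be a positive integer, got {self.payload_per_carrier}"
            )


def derive_rate_constants(p: BiexponentialParams) -> RateConstants:
    """Map a biexponential fit to two-compartment rate constants.

    Applies k_d = (beta*A + alpha*B)/(A + B), k_10 = alpha*beta/k_d and
    k_p = alpha + beta - k_d - k_10, then sets k_el = k_10 (the non-tumor
    elimination convention for an imported fit) with k_epr = k_b = 0.

    Raises ValueError if the implied k_p is negative, which signals an
    inconsistent (non-realizable) parameter set rather than a numerical
    problem.
    """
    k_d = (p.beta * p.A + p.alpha * p.B) / (p.A + p.B)
    k_10 = p.alpha * p.beta / k_d
    k_p = p.alpha + p.beta - k_d - k_10
    if k_p < 0:
        if k_p > -1e-12 * (p.alpha + p.beta):  # roundoff at the mono-exponential limit
            k_p = 0.0
        else:
            raise ValueError(
                f"derived k_p = {k_p:.6g} h^-1 is negative: the biexponential "
                f"parameters are not consistent with a two-compartment model"
            )
    return RateConstants(k_p=k_p, k_d=k_d, k_10=k_10, k_el=k_10)


def rate_constants_to_biexponential(k: RateConstants, n0: float) -> BiexponentialParams:
    """Inverse mapping: rate constants of a closed two-compartment system to (A, B, alpha, beta).

    alpha and beta are the roots of x^2 - (k_p + k_d + k_10) x + k_d k_10 = 0
    (alpha >= beta), and the amplitudes follow from N_bl(0) = n0, N_p(0) = 0:
    A = n0 (alpha - k_d)/(alpha - beta). Requires k_epr = k_b = 0; used as the
    round-trip oracle for :func:`derive_rate_constants`.
    """
    if k.k_epr != 0 or k.k_b != 0:
        raise ValueError("inverse mapping is defined for the closed system only (k_epr = k_b = 0)")
    if n0 <= 0:
        raise ValueError(f"initial amount must be positive, got {n0}")
    s = k.k_p + k.k_d + k.k_10
    prod = k.k_d * k.k_10
    disc = s * s - 4.0 * prod
    # disc = (k_d - k_10)^2 + k_p^2 + 2 k_p (k_d + k_10) >= 0 for nonnegative rates
    assert disc >= -1e-15 * s * s, "negative discriminant for nonnegative rates"
    root = math.sqrt(max(disc, 0.0))
    alpha = 0.5 * (s + root)
    # Vieta's product form avoids cancellation in the small root
    beta = prod / alpha if alpha > 0 else 0.5 * (s - root)
    if alpha == beta:
        # any split of n0 gives the same mono-exponential; use an even one
        warnings.warn("repeated exponents (alpha == beta): degenerate one-compartment limit")
        return BiexponentialParams(A=n0 / 2, B=n0 / 2, alpha=alpha, beta=beta)
    # beta <= k_d <= alpha for nonnegative rates, so both amplitudes are >= 0;
    # each is computed directly (never as n0 minus the other) to keep a tiny
    # amplitude accurate next to a dominant one
    A = n0 * (alpha - k.k_d) / (alpha - beta)
    B = n0 * (k.k_d - beta) / (alpha - beta)
    return BiexponentialParams(A=A, B=max(B, 0.0), alpha=alpha, beta=beta)


def blood_amount(p: BiexponentialParams, t) -> np.ndarray | float:
    """Evaluate N_bl(t) = A e^(-alpha t) + B e^(-beta t) at time(s) t (hours)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    out = p.A * np.exp(-p.alpha * t_arr) + p.B * np.exp(-p.beta * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def dose_to_amount(d: DoseSpec) -> float:
    """Administered amount in mg: dose_per_area * body_surface_area."""
    return d.dose_per_area * d.body_surface_area


@dataclass(frozen=True)
class PKSummary:
    """Standard secondary parameters of a biexponential disposition fit."""

    auc_mg_h: float  # area under the amount-time curve, A/alpha + B/beta
    clearance_L_per_h: float  # dose / AUC after amount -> concentration conversion
    t_half_beta_h: float  # terminal half-life, ln2 / beta
    v_d_L: float  # apparent distribution volume, dose/(A+B) * blood volume


def pk_summaries(p: BiexponentialParams, d: DoseSpec) -> PKSummary:
    """AUC, clearance, terminal half-life and distribution volume.

    AUC is computed on the amount scale (mg h); clearance converts it to the
    concentration scale with the blood volume, CL = dose * V_bl / AUC.
    """
    auc = p.A / p.alpha + p.B / p.beta
    cl = d.nominal_dose * d.blood_volume / auc
    return PKSummary(
        auc_mg_h=auc,
        clearance_L_per_h=cl,
        t_half_beta_h=math.log(2.0) / p.beta,
        v_d_L=d.nominal_dose / (p.A + p.B) * d.blood_volume,
    )


# Reference disposition parameters for pegylated liposomal doxorubicin (Doxil)
# and free doxorubicin, from the 50 mg m^-2 cohort of a human clinical trial,
# expressed as amounts using a 5 L blood volume.
DOXIL_PK = BiexponentialParams(A=34.5, B=61.0, alpha=0.301, beta=0.015)
DOXORUBICIN_PK = BiexponentialParams(A=28.5, B=1.1, alpha=11.6, beta=0.067)

DOXIL_DRUG = DrugProperties(name="Doxil", molar_mass=543.52, payload_per_carrier=15000)
DOXORUBICIN_DRUG = DrugProperties(name="doxorubicin", molar_mass=543.52, payload_per_carrier=1)

DEFAULT_DOSE = DoseSpec(dose_per_area=50.0, body_surface_area=1.8, blood_volume=5.0)
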