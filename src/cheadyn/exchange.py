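"""Four-state CheA-CheY binding equilibrium.

The histidine kinase CheA binds its response regulator CheY through two
sites: the P2 domain tethers CheY with sub-micromolar affinity, after which
the phosphotransfer (P1) domain of the *same* CheA molecule can dock onto
the tethered CheY, and at high CheY excess a *second* CheY can occupy the
P1 site instead.  Four states are distinguished:

=====  ==============================================================
state  meaning
=====  ==============================================================
A      free CheA + free CheY
B      binary complex, CheY on P2, P1 undocked ("P1-CheY unbound")
C      binary complex, P1 docked on the P2-tethered CheY ("P1-CheY bound")
D      ternary complex, a second CheY bound at the P1 site
=====  ==============================================================

Topology: A <-> B (bimolecular), B <-> C (unimolecular docking),
B <-> D (bimolecular; the second CheY binds the *undocked* P1, so D is
reached only from B).  Equilibrium constants are parameterised as
dissociation constants, ``K = k_off / k_on``:

* ``K0 = k_off0/k_on0`` (M)        A + Y <-> B
* ``K1 = k_off1/k_on1`` (unitless) B <-> C
* ``K2 = k_off2/k_on2`` (M)        B + Y <-> D

so the docked fraction of bound CheA is ``1/(1 + K1)`` in the absence of
the ternary state.  The forward rate constants are fixed, fast values used
only by the lineshape simulator (the equilibria are in fast exchange).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GAS_CONSTANT_KJ",
    "ExchangeScheme",
    "SpeciesState",
    "P1Populations",
    "TemperatureConditionPair",
    "solve_species_concentrations",
    "p1_environment_populations",
    "fast_exchange_shift",
    "one_to_one_isotherm",
    "vant_hoff_enthalpy",
    "interpolate_constants",
]

#: Molar gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = 8.314462618e-3

# Fast association rates (fast-exchange regime); dissociation rates follow
# from the equilibrium constants.
DEFAULT_K_ON0 = 2.0e8  # M^-1 s^-1, A + Y -> B
DEFAULT_K_ON1 = 1.0e4  # s^-1,      B -> C (docking)
DEFAULT_K_ON2 = 1.0e7  # M^-1 s^-1, B + Y -> D


@dataclass(frozen=True)
class ExchangeScheme:
    """Rate constants of the four-state scheme.

    Parameters are the six elementary rate constants; the equilibrium
    (dissociation) constants are exposed as properties.  Use
    :meth:`from_constants` to build a scheme from ``K0, K1, K2`` with the
    default fast association rates.
    """

    k_on0: float = DEFAULT_K_ON0   # M^-1 s^-1, A + Y -> B
    k_off0: float = 100.0          # s^-1,      B -> A
    k_on1: float = DEFAULT_K_ON1   # s^-1,      B -> C
    k_off1: float = 1.0e4          # s^-1,      C -> B
    k_on2: float = DEFAULT_K_ON2   # M^-1 s^-1, B + Y -> D
    k_off2: float = 1.0e4          # s^-1,      D -> B

    def __post_init__(self) -> None:
        for name in ("k_on0", "k_off0", "k_on1", "k_off1", "k_on2", "k_off2"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be positive and finite, got {value}")

    @classmethod
    def from_constants(
        cls,
        k0: float,
        k1: float,
        k2: float,
        *,
        k_on0: float = DEFAULT_K_ON0,
        k_on1: float = DEFAULT_K_ON1,
        k_on2: float = DEFAULT_K_ON2,
    ) -> "ExchangeScheme":
        """Build a scheme from dissociation constants ``K0 (M), K1 (-), K2 (M)``."""
        if min(k0, k1, k2) <= 0:
            raise ValueError("equilibrium constants must be positive")
        return cls(
            k_on0=k_on0, k_off0=k0 * k_on0,
            k_on1=k_on1, k_off1=k1 * k_on1,
            k_on2=k_on2, k_off2=k2 * k_on2,
        )

    @property
    def K0(self) -> float:
        """Dissociation constant of the P2 tether, M."""
        return self.k_off0 / self.k_on0

    @property
    def K1(self) -> float:
        """Undocking/docking ratio of the P1 domain (dimensionless)."""
        return self.k_off1 / self.k_on1

    @property
    def K2(self) -> float:
        """Dissociation constant of the second CheY at the P1 site, M."""
        return self.k_off2 / self.k_on2


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium species concentrations (all molar)."""

    free_chea: float
    complex_b: float
    complex_c: float
    complex_d: float
    free_chey: float
    temperature: float = 303.0

    def __post_init__(self) -> None:
        for name in ("free_chea", "complex_b", "complex_c", "complex_d", "free_chey"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total_chea(self) -> float:
        return self.free_chea + self.complex_b + self.complex_c + self.complex_d

    @property
    def total_chey(self) -> float:
        return self.free_chey + self.complex_b + self.complex_c + 2.0 * self.complex_d

    def as_array(self) -> np.ndarray:
        """State concentrations in A, B, C, D order."""
        return np.array(
            [self.free_chea, self.complex_b, self.complex_c, self.complex_d]
        )


class P1Populations(tuple):
    """Normalised P1-environment weights ``(free, docked, doubly)``.

    ``free`` is the fraction of CheA whose P1 domain is unengaged (states
    A and B), ``docked`` the fraction with P1 docked on the tethered CheY
    (state C) and ``doubly`` the fraction with a second CheY on the P1 site
    (state D).
    """

    __slots__ = ()

    def __new__(cls, free: float, docked: float, doubly: float):
        return super().__new__(cls, (free, docked, doubly))

    @property
    def free(self) -> float:
        return self[0]

    @property
    def docked(self) -> float:
        return self[1]

    @property
    def doubly(self) -> float:
        return self[2]

    @property
    def p_docked(self) -> float:
        """Fraction of CheA in the P1-docked state.

        This is the population that multiplies the CheA->CheY
        phosphotransfer rate in the signaling model (and whose complement
        multiplies autophosphorylation).
        """
        return self[1]


def solve_species_concentrations(
    scheme: ExchangeScheme,
    total_chea: float,
    total_chey: float,
    *,
    temperature: float = 303.0,
    xtol: float = 1e-30,
    rtol: float = 1e-12,
    maxiter: int = 200,
) -> SpeciesState:
    """Solve the unique equilibrium species set for given totals.

    Every complex concentration can be written in terms of the free CheY
    concentration ``y``: with ``a`` the free CheA,

    ``B = a*y/K0``, ``C = B/K1``, ``D = B*y/K2``,

    and the CheA mass balance fixes ``a`` for a given ``y``.  The CheY mass
    balance ``y + B + C + 2D = Y_tot`` is monotone increasing in ``y`` on
    ``[0, Y_tot]``, so a bracketed Brent search finds the root.
    """
    if total_chea < 0 or total_chey < 0:
        raise ValueError("totals must be non-negative")
    k0, k1, k2 = scheme.K0, scheme.K1, scheme.K2

    def species_at(y: float):
        denom = 1.0 + (y / k0) * (1.0 + 1.0 / k1 + y / k2)
        a = total_chea / denom
        b = a * y / k0
        c = b / k1
        d = b * y / k2
        return a, b, c, d

    def chey_balance(y: float) -> float:
        _, b, c, d = species_at(y)
        return y + b + c + 2.0 * d - total_chey

    if total_chey == 0.0 or total_chea == 0.0:
        y = total_chey
    else:
        # g(0) = -Y_tot < 0 and g(Y_tot) >= 0: guaranteed bracket.
        y = brentq(
            chey_balance, 0.0, total_chey, xtol=xtol, rtol=rtol, maxiter=maxiter
        )
    a, b, c, d = species_at(y)
    return SpeciesState(
        free_chea=a, complex_b=b, complex_c=c, complex_d=d,
        free_chey=y, temperature=temperature,
    )


def p1_environment_populations(species: SpeciesState) -> P1Populations:
    """Fractions of CheA in the three P1 environments.

    Returns ``(free, docked, doubly)`` weights that sum to one; the
    ``docked`` weight is the population modulating the signaling rates.
    """
    total = species.total_chea
    if total <= 0:
        raise ValueError("populations undefined for zero total CheA")
    free = (species.free_chea + species.complex_b) / total
    docked = species.complex_c / total
    doubly = species.complex_d / total
    return P1Populations(free, docked, doubly)


def fast_exchange_shift(weights, shifts) -> float:
    """Population-weighted average chemical shift (ppm).

    In fast exchange a single resonance appears at the weighted mean of the
    environment shifts.
    """
    w = np.asarray(weights, dtype=float)
    s = np.asarray(shifts, dtype=float)
    if w.shape != s.shape:
        raise ValueError("weights and shifts must have matching lengths")
    if w.size and not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("weights must be normalised")
    return float(w @ s)


def one_to_one_isotherm(kd: float, total_a, total_y):
    """Bound fraction of A for 1:1 binding, closed-form quadratic solution.

    ``[AY] = ((A+Y+Kd) - sqrt((A+Y+Kd)^2 - 4*A*Y)) / 2`` and the bound
    fraction is ``[AY]/A``.  Accepts scalars or arrays of totals.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    a = np.asarray(total_a, dtype=float)
    y = np.asarray(total_y, dtype=float)
    if np.any(a < 0) or np.any(y < 0):
        raise ValueError("totals must be non-negative")
    s = a + y + kd
    disc = np.clip(s * s - 4.0 * a * y, 0.0, None)
    complex_ = 0.5 * (s - np.sqrt(disc))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(a > 0, complex_ / np.where(a > 0, a, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac) if frac.ndim == 0 else frac


def vant_hoff_enthalpy(k_t1: float, k_t2: float, t1: float, t2: float) -> float:
    """Van't Hoff enthalpy (kJ/mol) of the reaction whose constant is K.

    ``dH = -R * ln(K(T2)/K(T1)) / (1/T2 - 1/T1)``.  The sign refers to the
    reaction direction in which K is written: an *association* constant
    that increases with temperature gives a positive (endothermic) dH for
    association.  Pass ``1/K`` to convert a dissociation constant to the
    association direction.
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("temperatures must be positive (K)")
    if t1 == t2:
        raise ValueError("temperatures must be distinct")
    if k_t1 <= 0 or k_t2 <= 0:
        raise ValueError("equilibrium constants must be positive")
    return -GAS_CONSTANT_KJ * math.log(k_t2 / k_t1) / (1.0 / t2 - 1.0 / t1)


@dataclass(frozen=True)
class TemperatureConditionPair:
    """Equilibrium constants of the scheme at two temperatures.

    Constants are dissociation constants ``(K0 [M], K1 [-], K2 [M])``.
    Defaults to the cold/warm conditions of the titration study, 283 K and
    303 K.
    """

    t_cold: float = 283.0
    t_warm: float = 303.0
    constants_cold: tuple = (0.5e-6, 2.5, 500e-6)
    constants_warm: tuple = (0.5e-6, 1.0, 900e-6)

    def __post_init__(self) -> None:
        if self.t_cold == self.t_warm:
            raise ValueError("temperatures must be distinct")
        if min(*self.constants_cold, *self.constants_warm) <= 0:
            raise ValueError("equilibrium constants must be positive")

    def constants_at(self, temperature: float) -> tuple:
        """Interpolated ``(K0, K1, K2)`` at ``temperature`` (ln K linear in 1/T)."""
        return interpolate_constants(self, temperature)

    def scheme_at(self, temperature: float) -> ExchangeScheme:
        return ExchangeScheme.from_constants(*self.constants_at(temperature))

    def vant_hoff(self, which: str = "K1", direction: str = "association") -> float:
        """Van't Hoff enthalpy (kJ/mol) for one of the constants.

        ``direction='association'`` (default) reports dH for the binding /
        docking direction, i.e. uses ``1/K`` since the stored constants are
        dissociation constants.
        """
        idx = {"K0": 0, "K1": 1, "K2": 2}[which]
        kc, kw = self.constants_cold[idx], self.constants_warm[idx]
        if direction == "association":
            kc, kw = 1.0 / kc, 1.0 / kw
        elif direction != "dissociation":
            raise ValueError("direction must be 'association' or 'dissociation'")
        return vant_hoff_enthalpy(kc, kw, self.t_cold, self.t_warm)


def interpolate_constants(pair: TemperatureConditionPair, temperature: float) -> tuple:
    """Interpolate ``(K0, K1, K2)`` to ``temperature`` with ln K linear in 1/T."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    x = (1.0 / pair.t_cold - 1.0 / temperature) / (
        1.0 / pair.t_cold - 1.0 / pair.t_warm
    )
    out = []
    for kc, kw in zip(pair.constants_cold, pair.constants_warm):
        out.append(math.exp((1.0 - x) * math.log(kc) + x * math.log(kw)))
    return tuple(out)
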