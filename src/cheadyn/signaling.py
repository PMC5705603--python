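"""Chemotaxis signaling model with docking-modulated phosphorylation.

A differential-algebraic model of the *E. coli* chemotaxis pathway:
receptors (Tar) carry 0-4 methyl groups; each methylation state is active
with probability ``p_i`` (ligand-free) or ``p_i^L`` (attractant-bound), so
the activity of state *i* at attractant concentration [L] is the
occupancy-weighted mean

    alpha_i = p_i^L [L]/(K_L+[L]) + p_i K_L/(K_L+[L]).

CheR methylates inactive receptors and phospho-CheB demethylates active
ones (Michaelis-Menten in the total inactive/active receptor pools),
moving the ladder T0 <-> ... <-> T4.  Active receptors drive CheA
autophosphorylation; CheA-P transfers its phosphoryl group to CheY and
CheB; CheY-P decays (intrinsic and CheZ-mediated), and binds FliM.

The modification specific to this model: the dynamic domain arrangement of
the CheA-CheY complex gates the phosphorylation chemistry.  With
``p_docked`` the fraction of CheA whose P1 domain is docked on the
tethered CheY (from :mod:`cheadyn.exchange`),

    d[Ap]/dt = k_auto [T^A][A] (1-p_docked)
               - k_ApY [Ap][Y] p_docked - k_ApB [Ap][B] (1-p_docked),

i.e. phosphotransfer to CheY requires the docked conformer while
autophosphorylation and transfer to CheB require the undocked one.
Temperature enters the model only through ``p_docked``.

Free-species concentrations are algebraic: ``[A] = [A]_tot - [Ap]``,
``[B] = [B]_tot - [Bp]``, ``[M] = [M]_tot - [MYp]`` and, so that total
CheY is conserved including the FliM-sequestered pool,
``[Y] = [Y]_tot - [Yp] - [MYp]``.

Integration is classical fixed-step 4th-order Runge-Kutta with the
algebraic relations re-evaluated inside every stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import root

from .exchange import (
    TemperatureConditionPair,
    p1_environment_populations,
    solve_species_concentrations,
)

__all__ = [
    "SignalingParameters",
    "SignalingState",
    "Trajectory",
    "receptor_activity",
    "time_derivatives",
    "integrate",
    "steady_state",
    "relative_yp_decrease",
    "p_docked_at",
    "temperature_step_response",
    "response_surface",
]

STATE_NAMES = ("T0", "T1", "T2", "T3", "T4", "Ap", "Yp", "MYp", "Bp")


@dataclass(frozen=True)
class SignalingParameters:
    """Rate constants, totals and activity ladder of the signaling model.

    Defaults are a coherent literature-seeded set for the *E. coli*
    pathway (totals in M, bimolecular rates in M^-1 s^-1, unimolecular in
    s^-1); see docs/methods.md for provenance and sensitivity notes.
    """

    # receptor activity ladder, methylation states 0..4
    p_active: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    p_active_ligand: tuple = (0.0, 0.05, 0.15, 0.40, 0.75)
    k_ligand: float = 10e-6        # K_L, attractant dissociation constant
    ligand: float = 0.0            # [L]

    # methylation / demethylation (Michaelis-Menten in receptor pools)
    k_r: float = 0.39              # CheR methylation kcat-like rate, s^-1
    big_k_r: float = 0.364e-6      # K_R, M
    k_b: float = 6.3               # CheB-P demethylation rate, s^-1
    big_k_b: float = 1.405e-6      # K_B, M
    cher_total: float = 0.2e-6     # [R]

    # phosphorylation chemistry
    k_auto: float = 1.0e6          # autophosphorylation, M^-1 s^-1
    k_apy: float = 1.0e8           # CheA-P -> CheY transfer
    k_apb: float = 1.0e7           # CheA-P -> CheB transfer
    k_yp: float = 0.04             # CheY-P intrinsic hydrolysis, s^-1
    k_ypz: float = 1.6             # CheZ-mediated CheY-P decay, s^-1
    k_bp: float = 1.0              # CheB-P decay, s^-1
    k_ypm: float = 5.0e6           # CheY-P + FliM association
    k_myp: float = 20.0            # FliM-CheY-P dissociation, s^-1

    # totals
    receptor_total: float = 5e-6
    chea_total: float = 10e-6
    chey_total: float = 10e-6
    cheb_total: float = 2e-6
    flim_total: float = 1.4e-6

    # population of the P1-docked conformer (gates the chemistry)
    p_docked: float = 0.35

    def __post_init__(self):
        probs = np.array(self.p_active + self.p_active_ligand + (self.p_docked,))
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("activity probabilities and p_docked must lie in [0, 1]")
        if any(pl > p for p, pl in zip(self.p_active, self.p_active_ligand)):
            raise ValueError("attractant-bound activities must not exceed ligand-free ones")
        rates = (
            self.k_ligand, self.k_r, self.big_k_r, self.k_b, self.big_k_b,
            self.k_auto, self.k_apy, self.k_apb, self.k_yp, self.k_ypz,
            self.k_bp, self.k_ypm, self.k_myp,
        )
        if any(r < 0 for r in rates):
            raise ValueError("rate constants must be non-negative")

    def with_condition(self, *, p_docked=None, ligand=None) -> "SignalingParameters":
        kw = {}
        if p_docked is not None:
            kw["p_docked"] = p_docked
        if ligand is not None:
            kw["ligand"] = ligand
        return replace(self, **kw)


@dataclass
class SignalingState:
    """Dynamic species of the model (all M)."""

    receptors: np.ndarray          # [T0..T4]
    chea_p: float
    chey_p: float
    flim_chey_p: float
    cheb_p: float

    def as_array(self) -> np.ndarray:
        return np.concatenate(
            [self.receptors, [self.chea_p, self.chey_p, self.flim_chey_p, self.cheb_p]]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "SignalingState":
        return cls(
            receptors=np.asarray(x[:5], float).copy(),
            chea_p=float(x[5]), chey_p=float(x[6]),
            flim_chey_p=float(x[7]), cheb_p=float(x[8]),
        )

    def derived(self, params: SignalingParameters) -> dict:
        """Algebraic companions: active/inactive receptor pools, free species."""
        alphas = receptor_activity(params, params.ligand)
        t_active = float(alphas @ self.receptors)
        return {
            "T_active": t_active,
            "T_inactive": params.receptor_total - t_active,
            "A": params.chea_total - self.chea_p,
            "Y": params.chey_total - self.chey_p - self.flim_chey_p,
            "B": params.cheb_total - self.cheb_p,
            "M": params.flim_total - self.flim_chey_p,
        }


def receptor_activity(params: SignalingParameters, ligand: float) -> np.ndarray:
    """Activity ``alpha_i`` of each methylation state at attractant ``[L]``."""
    if ligand < 0:
        raise ValueError("ligand concentration must be non-negative")
    occ = ligand / (params.k_ligand + ligand)
    p = np.asarray(params.p_active, float)
    pl = np.asarray(params.p_active_ligand, float)
    return pl * occ + p * (1.0 - occ)


def _rhs(x, p, a0, a1, a2, a3, a4):
    """Scalar right-hand side; alphas precomputed (they depend only on [L])."""
    t0, t1, t2, t3, t4, ap, yp, myp, bp = x
    t_act = a0 * t0 + a1 * t1 + a2 * t2 + a3 * t3 + a4 * t4
    t_inact = p.receptor_total - t_act
    a = p.chea_total - ap
    y = p.chey_total - yp - myp
    b = p.cheb_total - bp
    m = p.flim_total - myp

    meth = p.k_r * p.cher_total / (p.big_k_r + t_inact)
    demeth = p.k_b * bp / (p.big_k_b + t_act)

    up0 = (1.0 - a0) * meth * t0
    up1 = (1.0 - a1) * meth * t1
    up2 = (1.0 - a2) * meth * t2
    up3 = (1.0 - a3) * meth * t3
    dn1 = a1 * demeth * t1
    dn2 = a2 * demeth * t2
    dn3 = a3 * demeth * t3
    dn4 = a4 * demeth * t4

    pb = p.p_docked
    auto = p.k_auto * t_act * a * (1.0 - pb)
    to_y = p.k_apy * ap * y * pb
    to_b = p.k_apb * ap * b * (1.0 - pb)
    bind = p.k_ypm * m * yp
    unbind = p.k_myp * myp

    return (
        -up0 + dn1,
        -up1 + dn2 + up0 - dn1,
        -up2 + dn3 + up1 - dn2,
        -up3 + dn4 + up2 - dn3,
        up3 - dn4,
        auto - to_y - to_b,
        to_y - p.k_yp * yp - bind + unbind - p.k_ypz * yp,
        bind - unbind,
        to_b - p.k_bp * bp,
    )


def time_derivatives(state: SignalingState | np.ndarray, params: SignalingParameters) -> np.ndarray:
    """Time derivatives of ``(T0..T4, Ap, Yp, MYp, Bp)``."""
    x = state.as_array() if isinstance(state, SignalingState) else np.asarray(state, float)
    a0, a1, a2, a3, a4 = receptor_activity(params, params.ligand)
    return np.array(_rhs(tuple(x), params, a0, a1, a2, a3, a4))


@dataclass
class Trajectory:
    """Sampled RK4 trajectory with the running minimum of CheY-P."""

    times: np.ndarray
    states: np.ndarray             # (n_samples, 9)
    params: SignalingParameters
    min_chey_p: float
    clipped_steps: int = 0

    @property
    def chey_p(self) -> np.ndarray:
        return self.states[:, 6]

    def final_state(self) -> SignalingState:
        return SignalingState.from_array(self.states[-1])

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=STATE_NAMES)
        df.insert(0, "t", self.times)
        return df


def integrate(
    state0: SignalingState | np.ndarray,
    params: SignalingParameters,
    duration: float,
    dt: float = 1e-4,
    stride: int = 100,
) -> Trajectory:
    """Fixed-step classical RK4 integration.

    The algebraic free-species relations are re-evaluated inside every
    Runge-Kutta stage.  Concentrations that drift below zero by less than
    ``1e-12`` of the largest total are clipped (counted); larger negative
    excursions raise, signalling an unstable step size.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    x = tuple(
        float(v)
        for v in (state0.as_array() if isinstance(state0, SignalingState) else np.asarray(state0, float))
    )
    a0, a1, a2, a3, a4 = (float(a) for a in receptor_activity(params, params.ligand))
    n_steps = int(round(duration / dt))
    neg_tol = 1e-12 * max(
        params.receptor_total, params.chea_total, params.chey_total,
        params.cheb_total, params.flim_total, 1e-30,
    )

    times = [0.0]
    rows = [x]
    min_yp = x[6]
    clipped = 0
    h = dt
    for step in range(n_steps):
        k1 = _rhs(x, params, a0, a1, a2, a3, a4)
        k2 = _rhs(tuple(xi + 0.5 * h * ki for xi, ki in zip(x, k1)), params, a0, a1, a2, a3, a4)
        k3 = _rhs(tuple(xi + 0.5 * h * ki for xi, ki in zip(x, k2)), params, a0, a1, a2, a3, a4)
        k4 = _rhs(tuple(xi + h * ki for xi, ki in zip(x, k3)), params, a0, a1, a2, a3, a4)
        x = tuple(
            xi + (h / 6.0) * (a + 2.0 * b + 2.0 * c + d)
            for xi, a, b, c, d in zip(x, k1, k2, k3, k4)
        )
        if min(x) < 0.0:
            if min(x) < -neg_tol:
                raise RuntimeError(
                    f"negative concentration {min(x):.3e} at t={(step + 1) * h:.4f} s; "
                    "reduce dt"
                )
            x = tuple(max(xi, 0.0) for xi in x)
            clipped += 1
        if x[6] < min_yp:
            min_yp = x[6]
        if (step + 1) % stride == 0 or step == n_steps - 1:
            times.append((step + 1) * h)
            rows.append(x)
    if clipped:
        warnings.warn(f"clipped {clipped} slightly negative steps", RuntimeWarning, stacklevel=2)
    return Trajectory(
        times=np.array(times),
        states=np.array(rows),
        params=params,
        min_chey_p=min_yp,
        clipped_steps=clipped,
    )


def _default_start(params: SignalingParameters) -> np.ndarray:
    x = np.zeros(9)
    x[:5] = params.receptor_total / 5.0
    return x


def steady_state(
    params: SignalingParameters,
    x0: np.ndarray | None = None,
    tol: float = 1e-12,
) -> SignalingState:
    """Fixed point of the model, by Newton-type root search.

    Falls back to long RK4 relaxation if the root search leaves the
    physical region.
    """
    a = receptor_activity(params, params.ligand)

    def rhs(x):
        return np.array(_rhs(tuple(x), params, *a))

    def fun(x):
        # the ladder conserves total receptor exactly, which makes the
        # Jacobian singular along that direction; anchor it explicitly
        d = rhs(x)
        d[4] = x[:5].sum() - params.receptor_total
        return d

    guess = _default_start(params) if x0 is None else np.asarray(x0, float)
    # relax a little first so the Newton step starts near the attractor
    guess = integrate(guess, params, 2.0, dt=5e-4, stride=10_000).states[-1]
    sol = root(fun, guess, method="hybr", tol=tol)
    x = sol.x
    ok = sol.success and np.all(x > -1e-15) and np.all(np.abs(rhs(x)) < 1e-9)
    if not ok:
        traj = integrate(guess, params, 200.0, dt=5e-4, stride=10_000)
        x = traj.states[-1]
    return SignalingState.from_array(np.clip(x, 0.0, None))


def relative_yp_decrease(
    params_baseline: SignalingParameters,
    params_condition: SignalingParameters,
    *,
    duration: float = 10.0,
    dt: float = 1e-4,
    pre_equilibration: float = 10.0,
    x0: np.ndarray | None = None,
) -> float:
    """Fractional decrease of CheY-P upon switching conditions.

    The baseline condition is equilibrated (steady state, then a
    ``pre_equilibration``-long time course whose endpoint seeds the
    perturbed run); the response is ``1 - min [Yp](t) / [Yp](0)`` over the
    ``duration``-long time course under the new condition.
    """
    if x0 is None:
        base = steady_state(params_baseline)
        x0 = integrate(base, params_baseline, pre_equilibration, dt=dt).states[-1]
    yp0 = float(x0[6])
    if yp0 <= 0:
        raise ValueError("baseline CheY-P is zero; relative decrease undefined")
    traj = integrate(x0, params_condition, duration, dt=dt)
    return 1.0 - min(traj.min_chey_p, yp0) / yp0


def p_docked_at(
    pair: TemperatureConditionPair,
    temperature: float,
    chea_total: float = 10e-6,
    chey_total: float = 10e-6,
) -> float:
    """P1-docked population at a temperature, from interpolated constants."""
    scheme = pair.scheme_at(temperature)
    species = solve_species_concentrations(
        scheme, chea_total, chey_total, temperature=temperature
    )
    return p1_environment_populations(species).p_docked


def temperature_step_response(
    pair: TemperatureConditionPair | None = None,
    params: SignalingParameters | None = None,
    *,
    t_from: float | None = None,
    t_to: float | None = None,
    pb_from: float | None = None,
    pb_to: float | None = None,
    chea_total: float = 10e-6,
    chey_total: float = 10e-6,
    dt: float = 1e-4,
    duration: float = 10.0,
) -> dict:
    """CheY-P decrease for a temperature step at zero attractant.

    Maps the two temperatures to docked populations through the
    equilibrium constants (or uses explicitly supplied ``pb_from``/
    ``pb_to``), equilibrates at the starting temperature and integrates
    the step.  Returns the populations and the fractional decrease.
    """
    params = params or SignalingParameters()
    if pb_from is None or pb_to is None:
        if pair is None:
            raise ValueError("either a condition pair or explicit populations required")
        t_from = pair.t_cold if t_from is None else t_from
        t_to = pair.t_warm if t_to is None else t_to
        pb_from = p_docked_at(pair, t_from, chea_total, chey_total)
        pb_to = p_docked_at(pair, t_to, chea_total, chey_total)
    decrease = relative_yp_decrease(
        params.with_condition(p_docked=pb_from, ligand=0.0),
        params.with_condition(p_docked=pb_to, ligand=0.0),
        duration=duration,
        dt=dt,
    )
    return {"p_docked_from": pb_from, "p_docked_to": pb_to, "decrease": decrease}


def response_surface(
    pair: TemperatureConditionPair,
    temperatures,
    ligands,
    params: SignalingParameters | None = None,
    *,
    chea_total: float = 10e-6,
    chey_total: float = 10e-6,
    dt: float = 1e-4,
    duration: float = 10.0,
) -> dict:
    """CheY-P decrease over an attractant x temperature grid.

    The baseline cell is the coldest temperature at zero attractant; every
    grid cell reports the fractional CheY-P decrease of the corresponding
    step, all runs starting from the shared pre-equilibrated baseline.
    """
    params = params or SignalingParameters()
    temperatures = np.asarray(temperatures, float)
    ligands = np.asarray(ligands, float)
    if temperatures.size == 0 or ligands.size == 0:
        raise ValueError("grids must be non-empty")

    pb_base = p_docked_at(pair, temperatures.min(), chea_total, chey_total)
    baseline = params.with_condition(p_docked=pb_base, ligand=0.0)
    x0 = integrate(steady_state(baseline), baseline, 10.0, dt=dt).states[-1]

    surface = np.empty((temperatures.size, ligands.size))
    for i, t in enumerate(temperatures):
        pb = p_docked_at(pair, t, chea_total, chey_total)
        for j, lig in enumerate(ligands):
            cond = params.with_condition(p_docked=pb, ligand=float(lig))
            surface[i, j] = relative_yp_decrease(
                baseline, cond, duration=duration, dt=dt, x0=x0
            )
    return {"temperatures": temperatures, "ligands": ligands, "decrease": surface}
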