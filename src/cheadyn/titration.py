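"""Bayesian inference of the four-state equilibrium from titration shifts.

The observable is the position of a single fast-exchange resonance (1H and
13C) of a P1-domain methyl probe, recorded over a CheY titration at two
temperatures.  The model predicts peak positions from the four-state
equilibrium — either as the population-weighted average of the environment
shifts (``fast`` mode) or through the full lineshape simulate/process/fit
pipeline (``exact`` mode) — and scores them against the observed positions
with independent Gaussian errors of a single global sigma (default 1 Hz):

    log P = sum_k [ -(nu_k - nu_k,obs)^2 / (2 sigma^2) - log(sigma sqrt(2 pi)) ]

over all titration points and both nuclei.  Sampling is single-site
Metropolis: one randomly chosen parameter is perturbed per step and the
proposal is accepted with probability ``min(1, P(1)/P(0))``.  Priors are
flat: log10 of the dissociation constants within wide bounds, bound-state
shifts within the spectral window, and the inter-temperature shift
differences constrained to 0.01 ppm (1H) / 0.05 ppm (13C).

The entry point is :class:`FourStateTitrationModel`, whose :meth:`fit`
returns a :class:`TitrationResults` carrying the chain, the post-burn-in
means and standard deviations, and derived quantities (equilibrium
constants, van't Hoff enthalpies, certainty distributions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .exchange import (
    ExchangeScheme,
    TemperatureConditionPair,
    one_to_one_isotherm,
    p1_environment_populations,
    solve_species_concentrations,
)
from .lineshape import (
    Acquisition,
    SpinParameters,
    fit_lorentzian2d,
    process_to_spectrum,
    simulate_fid2d,
)

__all__ = [
    "ObservedTitration",
    "ParameterSpace",
    "PosteriorChain",
    "FourStateTitrationModel",
    "TitrationResults",
    "OneToOneFit",
    "fit_one_to_one_kd",
    "metropolis_accept",
    "run_mcmc",
    "certainty_distribution",
    "CertaintySummary",
]

# inter-temperature bound-state shift constraints, ppm
MAX_DSHIFT_H_PPM = 0.01
MAX_DSHIFT_C_PPM = 0.05


@dataclass
class ObservedTitration:
    """Observed peak positions over titration points and temperatures.

    Backed by a DataFrame with columns ``temperature_K``, ``chea_total_M``,
    ``chey_total_M``, ``shift_h_ppm``, ``shift_c_ppm`` and optional
    ``err_h_ppm``/``err_c_ppm``.
    """

    frame: pd.DataFrame

    REQUIRED = ("temperature_K", "chea_total_M", "chey_total_M", "shift_h_ppm", "shift_c_ppm")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"titration table missing columns: {missing}")
        f = self.frame
        if (f["chea_total_M"] <= 0).any() or (f["chey_total_M"] < 0).any():
            raise ValueError("concentrations must be positive (CheY may be zero)")
        for t, grp in f.groupby("temperature_K"):
            if len(grp) < 3:
                raise ValueError(f"need >= 3 titration points at {t} K, got {len(grp)}")
        self.frame = f.sort_values(["temperature_K", "chey_total_M"]).reset_index(drop=True)

    @property
    def temperatures(self) -> list:
        return sorted(self.frame["temperature_K"].unique())

    def at_temperature(self, t: float) -> pd.DataFrame:
        return self.frame[self.frame["temperature_K"] == t]

    def free_shifts(self, t: float) -> tuple:
        """(1H, 13C) shift of the zero-CheY point at temperature ``t``."""
        grp = self.at_temperature(t)
        zero = grp[grp["chey_total_M"] == 0.0]
        if zero.empty:
            zero = grp.nsmallest(1, "chey_total_M")
        row = zero.iloc[0]
        return float(row["shift_h_ppm"]), float(row["shift_c_ppm"])


class ParameterSpace:
    """Names, bounds and proposal scales of the sampled parameters.

    Per temperature: ``log10_k0``, ``log10_k1``, ``log10_k2`` and the 1H/13C
    shifts of the docked and doubly-bound environments.  Free-state shifts
    are anchored to the zero-CheY point unless ``fit_free_shifts``.
    """

    SHIFT_NAMES = ("dh_docked", "dc_docked", "dh_doubly", "dc_doubly")
    FREE_NAMES = ("dh_free", "dc_free")

    def __init__(
        self,
        temperatures,
        window_h_ppm: tuple,
        window_c_ppm: tuple,
        fit_free_shifts: bool = False,
        proposal_fraction: float = 0.05,
    ):
        self.temperatures = list(temperatures)
        self.fit_free_shifts = fit_free_shifts
        names, lo, hi = [], [], []
        for t in self.temperatures:
            tag = f"{int(round(t))}"
            names += [f"log10_k0_{tag}", f"log10_k1_{tag}", f"log10_k2_{tag}"]
            lo += [-9.0, -4.0, -9.0]
            hi += [0.0, 4.0, 0.0]
            shift_names = self.SHIFT_NAMES + (self.FREE_NAMES if fit_free_shifts else ())
            for sn in shift_names:
                names.append(f"{sn}_{tag}")
                win = window_h_ppm if sn.startswith("dh") else window_c_ppm
                lo.append(win[0])
                hi.append(win[1])
        self.names = names
        self.lower = np.array(lo)
        self.upper = np.array(hi)
        self.scales = proposal_fraction * (self.upper - self.lower)
        self.index = {n: i for i, n in enumerate(names)}
        # pairs constrained across temperatures: (i, j, max |diff| in ppm)
        self.pairs = []
        if len(self.temperatures) == 2:
            t0, t1 = (f"{int(round(t))}" for t in self.temperatures)
            for sn in self.SHIFT_NAMES + ((self.FREE_NAMES) if fit_free_shifts else ()):
                limit = MAX_DSHIFT_H_PPM if sn.startswith("dh") else MAX_DSHIFT_C_PPM
                self.pairs.append((self.index[f"{sn}_{t0}"], self.index[f"{sn}_{t1}"], limit))

    @property
    def n_params(self) -> int:
        return len(self.names)

    def in_support(self, theta: np.ndarray) -> bool:
        if np.any(theta < self.lower) or np.any(theta > self.upper):
            return False
        for i, j, limit in self.pairs:
            if abs(theta[i] - theta[j]) > limit:
                return False
        return True


@dataclass
class PosteriorChain:
    """Metropolis chain of parameter samples with log-posteriors."""

    samples: np.ndarray          # (n_sweeps + 1, n_params)
    log_probs: np.ndarray
    accepted: np.ndarray         # bool, per sweep (any update accepted)
    burn_in: int
    seed: int
    param_names: list
    update_acceptance: float | None = None

    def __post_init__(self):
        if len(self.samples) <= self.burn_in:
            raise ValueError("chain shorter than its burn-in")

    @property
    def acceptance_rate(self) -> float:
        """Fraction of accepted single-parameter updates."""
        if self.update_acceptance is not None:
            return self.update_acceptance
        return float(self.accepted.mean())

    @property
    def post_burn_in(self) -> np.ndarray:
        return self.samples[self.burn_in:]

    def to_dataframe(self, include_burn_in: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=self.param_names)
        df.insert(0, "step", np.arange(len(df)))
        df["log_posterior"] = self.log_probs
        df["accepted"] = np.concatenate([[True], self.accepted])
        return df if include_burn_in else df.iloc[self.burn_in:]


def metropolis_accept(logp_current: float, logp_proposal: float, rng) -> bool:
    """Metropolis rule: accept with probability ``min(1, P(1)/P(0))``."""
    if logp_proposal >= logp_current:
        return True
    if not np.isfinite(logp_proposal):
        return False
    return math.log(rng.random()) < logp_proposal - logp_current


class FourStateTitrationModel:
    """Four-state exchange model of a two-temperature CheY titration.

    Parameters
    ----------
    data : ObservedTitration
        Peak positions (ppm) per titration point and temperature.
    spins : dict, optional
        ``{temperature: SpinParameters}``; defaults to the per-temperature
        relaxation-rate presets.  Environment shifts in these objects are
        placeholders — the sampled shift parameters take precedence.
    sigma_hz : float
        Global observation error of the peak positions (Hz).
    mode : {'fast', 'exact'}
        ``fast`` predicts positions as population-weighted averages;
        ``exact`` runs the full lineshape simulate/process/fit pipeline.
    """

    def __init__(
        self,
        data: ObservedTitration,
        spins: dict | None = None,
        *,
        sigma_hz: float = 1.0,
        mode: str = "fast",
        fit_free_shifts: bool = False,
        acquisition: Acquisition | None = None,
        proposal_fraction: float = 0.05,
    ):
        if mode not in ("fast", "exact"):
            raise ValueError("mode must be 'fast' or 'exact'")
        self.data = data
        self.sigma_hz = float(sigma_hz)
        self.mode = mode
        self.temperatures = data.temperatures
        self.spins = spins or {
            t: SpinParameters.at_temperature(t) for t in self.temperatures
        }
        ref_spins = self.spins[self.temperatures[0]]
        self.obs_mhz = {"h": ref_spins.h_frequency_mhz, "c": ref_spins.c_frequency_mhz}
        self.free_shifts = {t: data.free_shifts(t) for t in self.temperatures}

        # spectral window in ppm for the shift priors
        shifts_h = data.frame["shift_h_ppm"]
        shifts_c = data.frame["shift_c_ppm"]
        acq = acquisition or Acquisition(
            carrier_h_ppm=float(shifts_h.mean()), carrier_c_ppm=float(shifts_c.mean())
        )
        self.acquisition = acq
        half_h = 0.5 * acq.sw_direct / self.obs_mhz["h"]
        half_c = 0.5 * acq.sw_indirect / self.obs_mhz["c"]
        self.space = ParameterSpace(
            self.temperatures,
            window_h_ppm=(acq.carrier_h_ppm - half_h, acq.carrier_h_ppm + half_h),
            window_c_ppm=(acq.carrier_c_ppm - half_c, acq.carrier_c_ppm + half_c),
            fit_free_shifts=fit_free_shifts,
            proposal_fraction=proposal_fraction,
        )

    # -- parameter plumbing -------------------------------------------------

    def _unpack(self, theta: np.ndarray, t: float) -> tuple:
        """(K0, K1, K2), env shifts ((h), (c)) at temperature ``t``."""
        idx = self.space.index
        tag = f"{int(round(t))}"
        k = tuple(10.0 ** theta[idx[f"log10_k{i}_{tag}"]] for i in range(3))
        if self.space.fit_free_shifts:
            free_h = theta[idx[f"dh_free_{tag}"]]
            free_c = theta[idx[f"dc_free_{tag}"]]
        else:
            free_h, free_c = self.free_shifts[t]
        env_h = (free_h, theta[idx[f"dh_docked_{tag}"]], theta[idx[f"dh_doubly_{tag}"]])
        env_c = (free_c, theta[idx[f"dc_docked_{tag}"]], theta[idx[f"dc_doubly_{tag}"]])
        return k, env_h, env_c

    def start_params(self) -> np.ndarray:
        """Data-driven starting point.

        K0 from a 1:1 fit of the 1H shifts, K1 = 1 (docked and undocked
        equally likely a priori), K2 from the high-excess 13C tail; docked
        shifts from the near-stoichiometric point, doubly-bound shifts
        extrapolated from the highest-excess point.
        """
        theta = np.zeros(self.space.n_params)
        idx = self.space.index
        for t in self.temperatures:
            tag = f"{int(round(t))}"
            grp = self.data.at_temperature(t)
            free_h, free_c = self.free_shifts[t]
            try:
                fit = fit_one_to_one_kd(
                    grp["chey_total_M"].to_numpy(),
                    grp["chea_total_M"].to_numpy(),
                    grp["shift_h_ppm"].to_numpy(),
                )
                k0 = min(max(fit.kd, 1e-8), 1e-3)
            except Exception:
                k0 = 1e-6
            theta[idx[f"log10_k0_{tag}"]] = math.log10(k0)
            theta[idx[f"log10_k1_{tag}"]] = 0.0
            theta[idx[f"log10_k2_{tag}"]] = math.log10(5e-4)
            near = grp.iloc[(grp["chey_total_M"] - grp["chea_total_M"]).abs().argmin()]
            last = grp.iloc[-1]
            # docked approx: at ~1:1 roughly half the complex is docked
            theta[idx[f"dh_docked_{tag}"]] = free_h + 2.0 * (near["shift_h_ppm"] - free_h)
            theta[idx[f"dc_docked_{tag}"]] = free_c + 2.0 * (near["shift_c_ppm"] - free_c)
            theta[idx[f"dh_doubly_{tag}"]] = last["shift_h_ppm"]
            theta[idx[f"dc_doubly_{tag}"]] = free_c + 2.0 * (last["shift_c_ppm"] - free_c)
            if self.space.fit_free_shifts:
                theta[idx[f"dh_free_{tag}"]] = free_h
                theta[idx[f"dc_free_{tag}"]] = free_c
        theta = np.clip(theta, self.space.lower, self.space.upper)
        # enforce the inter-temperature constraints at the start
        for i, j, limit in self.space.pairs:
            mid = 0.5 * (theta[i] + theta[j])
            theta[i] = theta[j] = mid
        return theta

    def polish_start(self, theta: np.ndarray | None = None, maxfev: int = 4000) -> np.ndarray:
        """Move the starting point to a local posterior maximum.

        Bounded Powell search on the negative log-posterior (constraint
        violations penalised).  Starting the chain at a posterior mode
        keeps the burn-in from drifting one-sidedly along the weakly
        identified directions of this model.
        """
        from scipy.optimize import minimize

        theta0 = self.start_params() if theta is None else np.asarray(theta, float)

        def objective(x):
            lp = self.log_posterior(x)
            return 1e12 if not np.isfinite(lp) else -lp

        res = minimize(
            objective,
            theta0,
            method="Powell",
            bounds=list(zip(self.space.lower, self.space.upper)),
            options={"maxfev": maxfev, "xtol": 1e-8, "ftol": 1e-10},
        )
        out = np.clip(res.x, self.space.lower, self.space.upper)
        return out if self.space.in_support(out) else theta0

    # -- likelihood ---------------------------------------------------------

    def _weights_at(self, t: float, constants: tuple) -> np.ndarray:
        """P1 environment weights (n_points, 3) at temperature ``t``."""
        scheme = ExchangeScheme.from_constants(*constants)
        grp = self.data.at_temperature(t)
        out = np.empty((len(grp), 3))
        for i, (_, row) in enumerate(grp.iterrows()):
            species = solve_species_concentrations(
                scheme, row["chea_total_M"], row["chey_total_M"], temperature=t
            )
            out[i] = p1_environment_populations(species)
        return out

    def _predict_fast(self, weights: np.ndarray, env_h, env_c) -> tuple:
        ppm_h = weights @ np.asarray(env_h)
        ppm_c = weights @ np.asarray(env_c)
        return ppm_h, ppm_c

    def _predict_exact(self, t: float, constants: tuple, env_h, env_c) -> tuple:
        scheme = ExchangeScheme.from_constants(*constants)
        spins = self.spins[t]
        spins = SpinParameters(
            shifts_h=tuple(env_h), shifts_c=tuple(env_c),
            r2_h_free=spins.r2_h_free, r2_h_bound=spins.r2_h_bound,
            r2_c_free=spins.r2_c_free, r2_c_bound=spins.r2_c_bound,
            h_frequency_mhz=spins.h_frequency_mhz,
        )
        acq = Acquisition.from_spins(spins)
        grp = self.data.at_temperature(t)
        ppm_h, ppm_c = [], []
        for _, row in grp.iterrows():
            species = solve_species_concentrations(
                scheme, row["chea_total_M"], row["chey_total_M"], temperature=t
            )
            fid = simulate_fid2d(scheme, species, spins, acq)
            fit = fit_lorentzian2d(process_to_spectrum(fid))
            ppm_h.append(fit.ppm_h)
            ppm_c.append(fit.ppm_c)
        return np.array(ppm_h), np.array(ppm_c)

    def predict(self, theta: np.ndarray, t: float) -> pd.DataFrame:
        """Predicted positions (ppm) at temperature ``t`` for ``theta``."""
        constants, env_h, env_c = self._unpack(theta, t)
        if self.mode == "fast":
            ppm_h, ppm_c = self._predict_fast(self._weights_at(t, constants), env_h, env_c)
        else:
            ppm_h, ppm_c = self._predict_exact(t, constants, env_h, env_c)
        grp = self.data.at_temperature(t)
        return pd.DataFrame(
            {
                "chey_total_M": grp["chey_total_M"].to_numpy(),
                "shift_h_ppm": ppm_h,
                "shift_c_ppm": ppm_c,
            }
        )

    def _gauss_loglike(self, resid_hz: np.ndarray) -> float:
        s = self.sigma_hz
        return float(-0.5 * np.sum((resid_hz / s) ** 2) - resid_hz.size * math.log(s * math.sqrt(2 * math.pi)))

    def loglike(self, theta: np.ndarray) -> float:
        total = 0.0
        for t in self.temperatures:
            pred = self.predict(theta, t)
            grp = self.data.at_temperature(t)
            res_h = (pred["shift_h_ppm"].to_numpy() - grp["shift_h_ppm"].to_numpy()) * self.obs_mhz["h"]
            res_c = (pred["shift_c_ppm"].to_numpy() - grp["shift_c_ppm"].to_numpy()) * self.obs_mhz["c"]
            total += self._gauss_loglike(res_h) + self._gauss_loglike(res_c)
        return total

    def log_posterior(self, theta: np.ndarray) -> float:
        """Flat prior inside the support, -inf outside."""
        theta = np.asarray(theta, dtype=float)
        if not self.space.in_support(theta):
            return -math.inf
        try:
            return self.loglike(theta)
        except Exception:
            return -math.inf

    # -- sampling -----------------------------------------------------------

    def fit(
        self,
        steps: int = 20000,
        burn_in: int = 10000,
        seed: int = 0,
        start_params: np.ndarray | None = None,
        adapt: bool = True,
        adapt_window: int = 250,
        target_acceptance: float = 0.3,
        polish: bool = True,
    ) -> "TitrationResults":
        """Run the single-parameter-update Metropolis sampler.

        Each of the ``steps`` iterations is a sweep: every parameter
        receives one Metropolis update (random order per sweep), and one
        sample is recorded per sweep.  Point estimates are the
        post-burn-in means, their errors the post-burn-in standard
        deviations.  The chain is deterministic for a given seed.

        With ``adapt`` (default), per-parameter proposal scales are tuned
        toward ``target_acceptance`` in windows of ``adapt_window`` sweeps
        during the burn-in only; the kernel is frozen before the retained
        samples begin, so the post-burn-in chain obeys detailed balance.
        Without adaptation the scales stay at the configured fraction of
        each prior range — too coarse for the weakly identified constant
        scale of this model (see docs/methods.md).
        """
        if burn_in >= steps:
            raise ValueError("burn_in must be smaller than steps")
        rng = np.random.default_rng(seed)
        space = self.space
        if start_params is None:
            theta = self.polish_start() if polish else self.start_params()
        else:
            theta = np.array(start_params, float)
        if not space.in_support(theta):
            raise ValueError("starting parameters outside the prior support")

        # incremental likelihood bookkeeping: per-temperature environment
        # weights only change when that temperature's constants move.
        idx = self.space.index
        const_idx = {
            t: [idx[f"log10_k{i}_{int(round(t))}"] for i in range(3)]
            for t in self.temperatures
        }
        obs = {
            t: (
                self.data.at_temperature(t)["shift_h_ppm"].to_numpy(),
                self.data.at_temperature(t)["shift_c_ppm"].to_numpy(),
            )
            for t in self.temperatures
        }

        def loglike_temp(t, weights, env_h, env_c):
            ppm_h, ppm_c = self._predict_fast(weights, env_h, env_c)
            oh, oc = obs[t]
            return self._gauss_loglike((ppm_h - oh) * self.obs_mhz["h"]) + self._gauss_loglike(
                (ppm_c - oc) * self.obs_mhz["c"]
            )

        weights = {}
        ll = {}
        for t in self.temperatures:
            constants, env_h, env_c = self._unpack(theta, t)
            if self.mode == "fast":
                weights[t] = self._weights_at(t, constants)
                ll[t] = loglike_temp(t, weights[t], env_h, env_c)
            else:
                ll[t] = self._loglike_exact_temp(theta, t, obs[t])
        logp = sum(ll.values())

        n_params = space.n_params
        samples = np.empty((steps + 1, n_params))
        log_probs = np.empty(steps + 1)
        accepted = np.zeros(steps, dtype=bool)
        samples[0] = theta
        log_probs[0] = logp

        scales = space.scales.copy()
        min_scale = 1e-5 * (space.upper - space.lower)
        prop_count = np.zeros(n_params, dtype=int)
        acc_count = np.zeros(n_params, dtype=int)

        temp_of_param = {}
        for t in self.temperatures:
            tag = f"{int(round(t))}"
            for name, i in idx.items():
                if name.endswith(f"_{tag}"):
                    temp_of_param[i] = t

        n_accepted_updates = 0
        n_updates = 0
        for step in range(steps):
            if adapt and 0 < step <= burn_in and step % adapt_window == 0:
                seen = prop_count > 0
                rate = np.where(seen, acc_count / np.maximum(prop_count, 1), target_acceptance)
                factor = np.exp(rate - target_acceptance)
                scales = np.where(seen, np.clip(scales * factor, min_scale, space.upper - space.lower), scales)
                prop_count[:] = 0
                acc_count[:] = 0
            any_accept = False
            for j in rng.permutation(n_params):
                j = int(j)
                prop_count[j] += 1
                n_updates += 1
                proposal = theta.copy()
                proposal[j] += rng.normal(0.0, scales[j])
                if not space.in_support(proposal):
                    continue
                t = temp_of_param[j]
                constants, env_h, env_c = self._unpack(proposal, t)
                if self.mode == "fast":
                    new_weights = (
                        self._weights_at(t, constants) if j in const_idx[t] else weights[t]
                    )
                    new_ll_t = loglike_temp(t, new_weights, env_h, env_c)
                else:
                    new_ll_t = self._loglike_exact_temp(proposal, t, obs[t])
                    new_weights = None
                new_logp = logp - ll[t] + new_ll_t
                if metropolis_accept(logp, new_logp, rng):
                    theta = proposal
                    logp = new_logp
                    ll[t] = new_ll_t
                    if self.mode == "fast":
                        weights[t] = new_weights
                    any_accept = True
                    acc_count[j] += 1
                    n_accepted_updates += 1
            accepted[step] = any_accept
            samples[step + 1] = theta
            log_probs[step + 1] = logp

        rate = float(acc_count.sum() / max(prop_count.sum(), 1)) if not adapt else float(
            n_accepted_updates / max(n_updates, 1)
        )
        if rate < 0.01 or rate > 0.99:
            import warnings

            warnings.warn(
                f"burn-in acceptance rate {rate:.3f}; proposal scales need tuning",
                RuntimeWarning,
                stacklevel=2,
            )
        chain = PosteriorChain(
            samples=samples,
            log_probs=log_probs,
            accepted=accepted,
            burn_in=burn_in,
            seed=seed,
            param_names=list(space.names),
            update_acceptance=rate,
        )
        return TitrationResults(model=self, chain=chain)

    def _loglike_exact_temp(self, theta, t, obs_pair):
        constants, env_h, env_c = self._unpack(theta, t)
        ppm_h, ppm_c = self._predict_exact(t, constants, env_h, env_c)
        oh, oc = obs_pair
        return self._gauss_loglike((ppm_h - oh) * self.obs_mhz["h"]) + self._gauss_loglike(
            (ppm_c - oc) * self.obs_mhz["c"]
        )


@dataclass
class CertaintySummary:
    """2D summary of the post-burn-in mass of two parameters."""

    hist: np.ndarray
    edges_x: np.ndarray
    edges_y: np.ndarray
    fraction_below_diagonal: float   # mass with y < x
    fraction_above_diagonal: float
    clustering: float                # mass inside the 95% HDR bounding box,
                                     # relative to that box / prior-range area


def certainty_distribution(
    chain: PosteriorChain, name_x: str, name_y: str, bins: int = 50,
    include_burn_in: bool = False,
) -> CertaintySummary:
    """Histogram the joint posterior of two parameters.

    Diagonal fractions report how much post-burn-in mass lies on either
    side of the ``y = x`` line (used to compare a constant across the two
    temperatures); the clustering statistic is the fraction of mass inside
    the bounding box of the 95% highest-density bins.
    """
    samples = chain.samples if include_burn_in else chain.post_burn_in
    if len(samples) == 0:
        raise ValueError("no samples after burn-in")
    ix = chain.param_names.index(name_x)
    iy = chain.param_names.index(name_y)
    x, y = samples[:, ix], samples[:, iy]
    hist, ex, ey = np.histogram2d(x, y, bins=bins)
    below = float(np.mean(y < x))
    above = float(np.mean(y > x))
    # 95% HDR: smallest set of bins holding 95% of the mass
    flat = np.sort(hist.ravel())[::-1]
    csum = np.cumsum(flat)
    threshold = flat[np.searchsorted(csum, 0.95 * csum[-1])]
    mask = hist >= max(threshold, 1e-300)
    xs, ys = np.where(mask)
    box_mass = float(
        hist[xs.min():xs.max() + 1, ys.min():ys.max() + 1].sum() / hist.sum()
    )
    return CertaintySummary(
        hist=hist, edges_x=ex, edges_y=ey,
        fraction_below_diagonal=below,
        fraction_above_diagonal=above,
        clustering=box_mass,
    )


class TitrationResults:
    """Posterior summaries of a fitted four-state titration model."""

    def __init__(self, model: FourStateTitrationModel, chain: PosteriorChain):
        self.model = model
        self.chain = chain
        post = chain.post_burn_in
        self.params = pd.Series(post.mean(axis=0), index=chain.param_names)
        self.bse = pd.Series(post.std(axis=0, ddof=1), index=chain.param_names)

    @property
    def acceptance_rate(self) -> float:
        return self.chain.acceptance_rate

    def constants(self, temperature: float) -> tuple:
        """Point estimates ``(K0, K1, K2)`` at one of the fit temperatures."""
        tag = f"{int(round(temperature))}"
        return tuple(10.0 ** self.params[f"log10_k{i}_{tag}"] for i in range(3))

    def condition_pair(self) -> TemperatureConditionPair:
        t_cold, t_warm = self.model.temperatures[0], self.model.temperatures[-1]
        return TemperatureConditionPair(
            t_cold=t_cold,
            t_warm=t_warm,
            constants_cold=self.constants(t_cold),
            constants_warm=self.constants(t_warm),
        )

    def vant_hoff(self, which: str = "K1", direction: str = "association") -> float:
        """Van't Hoff enthalpy (kJ/mol) from the two-temperature estimates."""
        return self.condition_pair().vant_hoff(which, direction)

    def p_docked_posterior(
        self,
        temperature: float,
        chea_total: float = 10e-6,
        chey_total: float = 10e-6,
        thin: int = 50,
    ) -> tuple:
        """Posterior mean and SD of the P1-docked population at given totals.

        Evaluated per thinned posterior sample (the docked population is a
        well-identified combination of the constants even where the
        individual constants are not) and averaged.
        """
        tag = f"{int(round(temperature))}"
        idx = [self.chain.param_names.index(f"log10_k{i}_{tag}") for i in range(3)]
        values = []
        for row in self.chain.post_burn_in[::thin]:
            scheme = ExchangeScheme.from_constants(*(10.0 ** row[i] for i in idx))
            species = solve_species_concentrations(
                scheme, chea_total, chey_total, temperature=temperature
            )
            values.append(p1_environment_populations(species).p_docked)
        values = np.asarray(values)
        return float(values.mean()), float(values.std(ddof=1))

    def certainty_distribution(self, name_x: str, name_y: str, bins: int = 50, **kw):
        return certainty_distribution(self.chain, name_x, name_y, bins=bins, **kw)

    def diagonal_fraction(self, which: str = "log10_k1") -> float:
        """Post-burn-in mass with the cold-temperature value above the warm one."""
        t_cold, t_warm = self.model.temperatures[0], self.model.temperatures[-1]
        post = self.chain.post_burn_in
        i = self.chain.param_names.index(f"{which}_{int(round(t_cold))}")
        j = self.chain.param_names.index(f"{which}_{int(round(t_warm))}")
        return float(np.mean(post[:, i] > post[:, j]))

    def summary(self) -> str:
        lines = [
            "Four-state CheA-CheY titration fit (single-site Metropolis)",
            f"  steps: {len(self.chain.samples) - 1}   burn-in: {self.chain.burn_in}"
            f"   acceptance: {self.acceptance_rate:.3f}   seed: {self.chain.seed}",
            f"  posterior mode: {self.model.mode}   sigma: {self.model.sigma_hz:g} Hz",
            "",
            f"  {'parameter':<18}{'mean':>12}{'sd':>12}",
        ]
        for name in self.chain.param_names:
            lines.append(f"  {name:<18}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}")
        lines.append("")
        for t in self.model.temperatures:
            k0, k1, k2 = self.constants(t)
            lines.append(
                f"  {t:.0f} K:  K0 = {k0 * 1e6:.3g} uM   K1 = {k1:.3g}   K2 = {k2 * 1e6:.3g} uM"
            )
        dh = self.vant_hoff("K1")
        lines.append(f"  van't Hoff docking enthalpy (K1): {dh:.1f} kJ/mol")
        return "\n".join(lines)

    def plot_certainty(self, which: str = "log10_k1", bins: int = 60, ax=None):
        """Certainty (post-burn-in) density of one constant, cold vs warm."""
        import matplotlib.pyplot as plt

        t_cold, t_warm = self.model.temperatures[0], self.model.temperatures[-1]
        nx = f"{which}_{int(round(t_warm))}"
        ny = f"{which}_{int(round(t_cold))}"
        post = self.chain.post_burn_in
        i = self.chain.param_names.index(nx)
        j = self.chain.param_names.index(ny)
        if ax is None:
            _, ax = plt.subplots()
        ax.hist2d(post[:, i], post[:, j], bins=bins, cmap="viridis")
        lim = [
            min(post[:, i].min(), post[:, j].min()),
            max(post[:, i].max(), post[:, j].max()),
        ]
        ax.plot(lim, lim, "w--", lw=1)
        ax.set_xlabel(f"{which} ({t_warm:.0f} K)")
        ax.set_ylabel(f"{which} ({t_cold:.0f} K)")
        return ax


def run_mcmc(
    observed: ObservedTitration,
    *,
    steps: int = 20000,
    burn_in: int = 10000,
    seed: int = 0,
    sigma_hz: float = 1.0,
    mode: str = "fast",
    start_params=None,
    **model_kwargs,
) -> TitrationResults:
    """Convenience wrapper: build the model and run the sampler."""
    model = FourStateTitrationModel(observed, sigma_hz=sigma_hz, mode=mode, **model_kwargs)
    return model.fit(steps=steps, burn_in=burn_in, seed=seed, start_params=start_params)


@dataclass
class OneToOneFit:
    """Apparent dissociation constant from a 1:1 binding fit."""

    kd: float
    kd_stderr: float | None
    ddmax: float
    shift_free: float
    ci95: tuple
    result: lmfit.minimizer.MinimizerResult


def fit_one_to_one_kd(
    ligand_totals,
    protein_totals,
    shifts,
    shift_errors=None,
) -> OneToOneFit:
    """Levenberg-Marquardt fit of the 1:1 binding isotherm to shift data.

    The observed shift is modelled as ``free + ddmax * f_bound(Kd)`` with
    the closed-form quadratic bound fraction.  Returns Kd with its standard
    error and a 95% interval; in the tight-binding regime the interval is
    legitimately wide (Kd barely identifiable below the protein
    concentration).
    """
    y = np.asarray(ligand_totals, float)
    a = np.asarray(protein_totals, float)
    obs = np.asarray(shifts, float)
    if len(y) < 4:
        raise ValueError("need >= 4 titration points for a 1:1 fit")
    err = np.ones_like(obs) if shift_errors is None else np.asarray(shift_errors, float)

    span = obs[np.argmax(y)] - obs[np.argmin(y)]
    params = lmfit.Parameters()
    params.add("log10_kd", value=math.log10(max(np.median(a), 1e-9)), min=-10, max=0)
    params.add("ddmax", value=span if span != 0 else 1e-3)
    params.add("free", value=float(obs[np.argmin(y)]))

    def residual(p):
        frac = one_to_one_isotherm(10.0 ** p["log10_kd"].value, a, y)
        model = p["free"].value + p["ddmax"].value * frac
        return (model - obs) / err

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    kd = 10.0 ** p["log10_kd"].value
    if p["log10_kd"].stderr is not None:
        log_sd = p["log10_kd"].stderr
        stderr = kd * math.log(10) * log_sd
        ci = (10.0 ** (p["log10_kd"].value - 1.96 * log_sd),
              10.0 ** (p["log10_kd"].value + 1.96 * log_sd))
    else:
        stderr = None
        ci = (0.0, math.inf)
    return OneToOneFit(
        kd=kd,
        kd_stderr=stderr,
        ddmax=float(p["ddmax"].value),
        shift_free=float(p["free"].value),
        ci95=ci,
        result=result,
    )
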