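"""Ground-truth titration generator for end-to-end testing of the inference.

Emulates the two-temperature CheY titration of a 100 uM segmentally
labelled CheA sample: at each titration point the four-state equilibrium
is solved, the fast-exchange peak position of the P1 methyl probe is
computed (or, in ``lineshape`` mode, a full 2D spectrum is simulated,
processed and fitted), and the positions are perturbed with Gaussian noise
of the stated sigma.  The generating truth travels in a sidecar mapping so
recovery can be scored blindly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exchange import (
    ExchangeScheme,
    TemperatureConditionPair,
    fast_exchange_shift,
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
from .titration import ObservedTitration, TitrationResults

__all__ = ["GroundTruth", "generate_titration", "recovery_report"]

# default CheY:CheA titration ratios; the top point drives the sample to
# ~0.9 mM CheY at 100 uM CheA, populating the doubly-bound state
DEFAULT_RATIOS = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 9.0)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of a synthetic two-temperature titration.

    The default constants are the study conditions: a 0.5 uM P2 tether, a
    docking ratio K1 of 1 at 303 K rising to 2.5 at 283 K (docking
    endothermic, ~33 kJ/mol), and a weak second-CheY site (0.9 mM at
    303 K, 0.5 mM at 283 K, the doubly-bound state more populated when
    cold).  Environment shifts put the docking perturbation mostly on 1H
    and the doubly-bound perturbation downfield on 13C.
    """

    pair: TemperatureConditionPair = TemperatureConditionPair()
    # {temperature: (free, docked, doubly)} shifts, ppm
    shifts_h: dict = field(
        default_factory=lambda: {283.0: (0.752, 0.605, 0.703), 303.0: (0.750, 0.600, 0.700)}
    )
    shifts_c: dict = field(
        default_factory=lambda: {283.0: (13.02, 13.32, 14.23), 303.0: (13.00, 13.30, 14.20)}
    )
    chea_total: float = 100e-6
    chey_ratios: tuple = DEFAULT_RATIOS
    noise_sigma_hz: float = 1.0
    h_frequency_mhz: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if 0.0 not in self.chey_ratios:
            raise ValueError("titration schedule must include a zero-CheY point")

    @property
    def temperatures(self) -> tuple:
        return (self.pair.t_cold, self.pair.t_warm)

    def spins(self, temperature: float) -> SpinParameters:
        return SpinParameters.at_temperature(
            temperature,
            shifts_h=tuple(self.shifts_h[temperature]),
            shifts_c=tuple(self.shifts_c[temperature]),
            h_frequency_mhz=self.h_frequency_mhz,
        )

    def constants(self, temperature: float) -> tuple:
        if temperature == self.pair.t_cold:
            return self.pair.constants_cold
        if temperature == self.pair.t_warm:
            return self.pair.constants_warm
        return self.pair.constants_at(temperature)

    def to_metadata(self) -> dict:
        """JSON-serialisable record of the generating truth."""
        return {
            "t_cold": self.pair.t_cold,
            "t_warm": self.pair.t_warm,
            "constants_cold": list(self.pair.constants_cold),
            "constants_warm": list(self.pair.constants_warm),
            "shifts_h": {str(k): list(v) for k, v in self.shifts_h.items()},
            "shifts_c": {str(k): list(v) for k, v in self.shifts_c.items()},
            "chea_total": self.chea_total,
            "chey_ratios": list(self.chey_ratios),
            "noise_sigma_hz": self.noise_sigma_hz,
            "h_frequency_mhz": self.h_frequency_mhz,
            "seed": self.seed,
        }


def _positions_fast(truth: GroundTruth, temperature: float) -> pd.DataFrame:
    scheme = ExchangeScheme.from_constants(*truth.constants(temperature))
    rows = []
    for ratio in truth.chey_ratios:
        chey = ratio * truth.chea_total
        species = solve_species_concentrations(
            scheme, truth.chea_total, chey, temperature=temperature
        )
        w = p1_environment_populations(species)
        rows.append(
            {
                "temperature_K": temperature,
                "chea_total_M": truth.chea_total,
                "chey_total_M": chey,
                "shift_h_ppm": fast_exchange_shift(w, truth.shifts_h[temperature]),
                "shift_c_ppm": fast_exchange_shift(w, truth.shifts_c[temperature]),
            }
        )
    return pd.DataFrame(rows)


def _positions_lineshape(truth: GroundTruth, temperature: float):
    scheme = ExchangeScheme.from_constants(*truth.constants(temperature))
    spins = truth.spins(temperature)
    acq = Acquisition.from_spins(spins)
    rows, spectra = [], []
    for ratio in truth.chey_ratios:
        chey = ratio * truth.chea_total
        species = solve_species_concentrations(
            scheme, truth.chea_total, chey, temperature=temperature
        )
        spec = process_to_spectrum(simulate_fid2d(scheme, species, spins, acq))
        fit = fit_lorentzian2d(spec)
        rows.append(
            {
                "temperature_K": temperature,
                "chea_total_M": truth.chea_total,
                "chey_total_M": chey,
                "shift_h_ppm": fit.ppm_h,
                "shift_c_ppm": fit.ppm_c,
            }
        )
        spectra.append(spec)
    return pd.DataFrame(rows), spectra


def generate_titration(
    truth: GroundTruth,
    mode: str = "fast",
    rng: np.random.Generator | None = None,
    return_spectra: bool = False,
):
    """Generate an :class:`ObservedTitration` from a ground truth.

    ``fast`` mode places peaks at the population-weighted positions;
    ``lineshape`` mode simulates, processes and fits full 2D spectra.
    Gaussian noise of ``truth.noise_sigma_hz`` is added to the positions in
    either mode.  Bit-reproducible for a fixed ``truth.seed``.
    """
    if mode not in ("fast", "lineshape"):
        raise ValueError("mode must be 'fast' or 'lineshape'")
    rng = rng or np.random.default_rng(truth.seed)
    frames, all_spectra = [], []
    for t in truth.temperatures:
        if mode == "fast":
            frame = _positions_fast(truth, t)
        else:
            frame, spectra = _positions_lineshape(truth, t)
            all_spectra.extend(spectra)
        n = len(frame)
        frame["shift_h_ppm"] += rng.normal(0.0, truth.noise_sigma_hz, n) / truth.h_frequency_mhz
        c_mhz = truth.spins(t).c_frequency_mhz
        frame["shift_c_ppm"] += rng.normal(0.0, truth.noise_sigma_hz, n) / c_mhz
        frame["err_h_ppm"] = truth.noise_sigma_hz / truth.h_frequency_mhz
        frame["err_c_ppm"] = truth.noise_sigma_hz / c_mhz
        frames.append(frame)
    observed = ObservedTitration(pd.concat(frames, ignore_index=True))
    if return_spectra:
        return observed, all_spectra
    return observed


def recovery_report(truth: GroundTruth, results: TitrationResults, z_max: float = 2.0) -> pd.DataFrame:
    """Score recovered equilibrium constants against the generating truth.

    One row per constant and temperature with the truth, the posterior
    mean and SD (on log10 scale, where the sampling happened), the z-score
    ``|mean - truth| / sd`` and a pass flag at ``z <= z_max``.
    """
    rows = []
    for t in truth.temperatures:
        tag = f"{int(round(t))}"
        true_k = truth.constants(t)
        for i in range(3):
            name = f"log10_k{i}_{tag}"
            if name not in results.params.index:
                raise KeyError(f"estimate for {name} missing from results")
            mean = float(results.params[name])
            sd = float(results.bse[name])
            true_log = float(np.log10(true_k[i]))
            if sd > 0:
                z = abs(mean - true_log) / sd
            else:
                z = 0.0 if mean == true_log else np.inf
            rows.append(
                {
                    "parameter": name,
                    "truth_log10": true_log,
                    "estimate_log10": mean,
                    "posterior_sd": sd,
                    "z": float(z),
                    "passed": bool(z <= z_max),
                }
            )
    return pd.DataFrame(rows)
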