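"""2D exchange NMR lineshape simulation and peak fitting.

Magnetization of a methyl probe on the P1 domain evolves under the
Bloch-McConnell equations: a complex evolution matrix per nucleus,

    L = 2*pi*i*diag(nu) - diag(R2) + K,

where ``nu`` are offset frequencies (Hz) of the exchange-connected states,
``R2`` their transverse relaxation rates and ``K`` the pseudo-first-order
exchange generator (zero column sums).  The free-induction decay is
propagated analytically by eigendecomposition, the two spectral dimensions
evolving independently from the same equilibrium populations:

    FID(t1, t2) = [1^T exp(L_13C t1) p] * [1^T exp(L_1H t2) p].

Spectra are produced by exponential apodization, zero filling and FFT, and
peaks are quantified with a separable absorptive 2D Lorentzian,

    A(nu_H, nu_C) = I * T2C/(1+(2 pi (nu_C-nu_kC) T2C)^2)
                      * T2H/(1+(2 pi (nu_H-nu_kH) T2H)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit
from scipy.linalg import expm

from .exchange import ExchangeScheme, SpeciesState

__all__ = [
    "GAMMA_RATIO_13C",
    "SpinParameters",
    "Acquisition",
    "FID2D",
    "Spectrum2D",
    "PeakFit",
    "PeakFitError",
    "evolution_matrix",
    "simulate_fid2d",
    "process_to_spectrum",
    "fit_lorentzian2d",
    "in_situ_shift_error",
]

#: gamma(13C)/gamma(1H); the 13C observe frequency is this times the 1H one.
GAMMA_RATIO_13C = 0.2514495

# P1 environments, in order: free (undocked), docked on the tethered CheY,
# occupied by a second CheY.  States A and B share the free environment.
ENV_OF_STATE = (0, 0, 1, 2)
# R2 class per state: free-state rates for A and B, bound-state for C and D.
BOUND_STATE = (False, False, True, True)


@dataclass(frozen=True)
class SpinParameters:
    """Per-environment shifts and per-temperature relaxation rates.

    ``shifts_h``/``shifts_c`` are the 1H/13C chemical shifts (ppm) of the
    three P1 environments ``(free, docked, doubly)``.  R2 values default to
    the 303 K study conditions; use :meth:`at_temperature` for the 283 K
    set (slower tumbling, broader lines).
    """

    shifts_h: tuple = (0.75, 0.60, 0.70)
    shifts_c: tuple = (13.0, 13.3, 14.2)
    r2_h_free: float = 45.0    # s^-1
    r2_h_bound: float = 60.0
    r2_c_free: float = 12.0
    r2_c_bound: float = 15.0
    h_frequency_mhz: float = 600.0

    #: R2 defaults (s^-1) keyed by temperature:
    #: {T: (1H free, 1H bound, 13C free, 13C bound)}.
    R2_DEFAULTS = {303.0: (45.0, 60.0, 12.0, 15.0), 283.0: (70.0, 100.0, 40.0, 60.0)}

    def __post_init__(self):
        if min(self.r2_h_free, self.r2_h_bound, self.r2_c_free, self.r2_c_bound) <= 0:
            raise ValueError("transverse relaxation rates must be positive")
        if len(self.shifts_h) != 3 or len(self.shifts_c) != 3:
            raise ValueError("three environment shifts required per nucleus")

    @classmethod
    def at_temperature(cls, temperature: float, **kwargs) -> "SpinParameters":
        """Defaults with the R2 set of the nearest tabulated temperature."""
        t = min(cls.R2_DEFAULTS, key=lambda tt: abs(tt - temperature))
        h_free, h_bound, c_free, c_bound = cls.R2_DEFAULTS[t]
        return cls(
            r2_h_free=h_free, r2_h_bound=h_bound,
            r2_c_free=c_free, r2_c_bound=c_bound, **kwargs,
        )

    @property
    def c_frequency_mhz(self) -> float:
        return self.h_frequency_mhz * GAMMA_RATIO_13C

    def observe_mhz(self, nucleus: str) -> float:
        if nucleus == "h":
            return self.h_frequency_mhz
        if nucleus == "c":
            return self.c_frequency_mhz
        raise ValueError("nucleus must be 'h' or 'c'")

    def shifts(self, nucleus: str) -> np.ndarray:
        return np.asarray(self.shifts_h if nucleus == "h" else self.shifts_c, float)

    def r2(self, nucleus: str) -> tuple:
        """``(free, bound)`` R2 for the nucleus, s^-1."""
        if nucleus == "h":
            return self.r2_h_free, self.r2_h_bound
        return self.r2_c_free, self.r2_c_bound


@dataclass(frozen=True)
class Acquisition:
    """Sampling of the two time dimensions (t1 = 13C, t2 = 1H)."""

    n_direct: int = 512        # complex points, 1H
    n_indirect: int = 128      # complex points, 13C
    sw_direct: float = 400.0   # spectral width, Hz
    sw_indirect: float = 600.0
    carrier_h_ppm: float = 0.7
    carrier_c_ppm: float = 13.5

    @classmethod
    def from_spins(cls, spins: SpinParameters, margin: float = 1.2, **kwargs):
        """Centre carriers on the environments, widths with >=20% margin."""
        def span(nucleus):
            s = spins.shifts(nucleus) * spins.observe_mhz(nucleus)
            return float(s.max() - s.min()), float(s.mean()) / spins.observe_mhz(nucleus)

        span_h, mid_h = span("h")
        span_c, mid_c = span("c")
        fields = dict(
            sw_direct=max(2.0 * margin * span_h, 400.0),
            sw_indirect=max(2.0 * margin * span_c, 600.0),
            carrier_h_ppm=mid_h,
            carrier_c_ppm=mid_c,
        )
        fields.update(kwargs)
        return cls(**fields)

    def times(self, axis: str) -> np.ndarray:
        if axis == "direct":
            return np.arange(self.n_direct) / self.sw_direct
        return np.arange(self.n_indirect) / self.sw_indirect

    def carrier_ppm(self, nucleus: str) -> float:
        return self.carrier_h_ppm if nucleus == "h" else self.carrier_c_ppm


@dataclass
class FID2D:
    """Complex time-domain matrix, shape ``(n_indirect, n_direct)``."""

    data: np.ndarray
    acquisition: Acquisition
    spins: SpinParameters

    def __post_init__(self):
        expected = (self.acquisition.n_indirect, self.acquisition.n_direct)
        if self.data.shape != expected:
            raise ValueError(f"FID shape {self.data.shape} != acquisition {expected}")


@dataclass
class Spectrum2D:
    """Real absorptive 2D spectrum with Hz and ppm axes.

    Axis 0 is the indirect (13C) dimension, axis 1 the direct (1H) one.
    Hz axes are offsets from the carriers.
    """

    data: np.ndarray
    hz_direct: np.ndarray
    hz_indirect: np.ndarray
    acquisition: Acquisition
    spins: SpinParameters

    @property
    def ppm_direct(self) -> np.ndarray:
        return self.acquisition.carrier_h_ppm + self.hz_direct / self.spins.h_frequency_mhz

    @property
    def ppm_indirect(self) -> np.ndarray:
        return self.acquisition.carrier_c_ppm + self.hz_indirect / self.spins.c_frequency_mhz


@dataclass
class PeakFit:
    """Separable 2D Lorentzian fit result."""

    intensity: float
    t2_h: float       # s
    t2_c: float
    nu_h: float       # Hz offset from carrier
    nu_c: float
    ppm_h: float
    ppm_c: float
    redchi: float


class PeakFitError(RuntimeError):
    pass


def _state_frequencies(spins: SpinParameters, acq: Acquisition, nucleus: str) -> np.ndarray:
    obs = spins.observe_mhz(nucleus)
    env_shift = spins.shifts(nucleus)
    carrier = acq.carrier_ppm(nucleus)
    return np.array([(env_shift[ENV_OF_STATE[s]] - carrier) * obs for s in range(4)])


def evolution_matrix(
    scheme: ExchangeScheme,
    species: SpeciesState,
    spins: SpinParameters,
    nucleus: str,
    acquisition: Acquisition | None = None,
) -> np.ndarray:
    """Bloch-McConnell evolution matrix over the four states.

    Pseudo-first-order exchange rates are evaluated at the current free
    CheY concentration: A->B at ``k_on0*[Y]``, B->D at ``k_on2*[Y]``; all
    dissociation and the docking/undocking steps are unimolecular.  The
    exchange part has exactly zero column sums (magnetization is conserved
    in the absence of relaxation).
    """
    if species.total_chea <= 0:
        raise ValueError("empty spin system: zero total CheA")
    acq = acquisition or Acquisition.from_spins(spins)
    y = species.free_chey
    k = np.zeros((4, 4))
    # K[i, j] = rate j -> i
    k[1, 0] = scheme.k_on0 * y   # A -> B
    k[0, 1] = scheme.k_off0      # B -> A
    k[2, 1] = scheme.k_on1       # B -> C
    k[1, 2] = scheme.k_off1      # C -> B
    k[3, 1] = scheme.k_on2 * y   # B -> D
    k[1, 3] = scheme.k_off2      # D -> B
    np.fill_diagonal(k, -k.sum(axis=0))

    nu = _state_frequencies(spins, acq, nucleus)
    r2_free, r2_bound = spins.r2(nucleus)
    r2 = np.array([r2_bound if b else r2_free for b in BOUND_STATE])
    return 2j * np.pi * np.diag(nu) - np.diag(r2) + k


def _propagate(matrix: np.ndarray, populations: np.ndarray, times: np.ndarray) -> np.ndarray:
    """``1^T exp(L t) p`` for all t, by eigendecomposition.

    Falls back to scaling-and-squaring matrix exponentials if the
    eigenvector matrix is numerically defective.
    """
    try:
        lam, vec = np.linalg.eig(matrix)
        coeff = vec.sum(axis=0) * np.linalg.solve(vec, populations.astype(complex))
        cond = np.linalg.cond(vec)
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError("defective evolution matrix")
        return np.exp(np.outer(times, lam)) @ coeff
    except np.linalg.LinAlgError:
        ones = np.ones(matrix.shape[0])
        return np.array([ones @ expm(matrix * t) @ populations for t in times])


def simulate_fid2d(
    scheme: ExchangeScheme,
    species: SpeciesState,
    spins: SpinParameters,
    acquisition: Acquisition | None = None,
) -> FID2D:
    """Analytical 2D FID of the exchanging system.

    Initial magnetization is distributed proportionally to the equilibrium
    populations (total one); both dimensions evolve under their own
    evolution matrix with the same populations.
    """
    acq = acquisition or Acquisition.from_spins(spins)
    pops = species.as_array()
    pops = pops / pops.sum()
    l_h = evolution_matrix(scheme, species, spins, "h", acq)
    l_c = evolution_matrix(scheme, species, spins, "c", acq)
    f_h = _propagate(l_h, pops, acq.times("direct"))
    f_c = _propagate(l_c, pops, acq.times("indirect"))
    return FID2D(data=np.outer(f_c, f_h), acquisition=acq, spins=spins)


def process_to_spectrum(
    fid: FID2D, *, line_broadening_hz: float = 2.0, zero_fill: int = 2
) -> Spectrum2D:
    """Apodize, zero-fill and Fourier transform to a real absorptive spectrum."""
    if zero_fill < 1:
        raise ValueError("zero_fill factor must be >= 1")
    acq = fid.acquisition
    data = fid.data.astype(complex).copy()
    # exponential window in both dimensions; half-weight first points so the
    # discrete FT approximates the half-line integral without a baseline
    # offset.
    win_t2 = np.exp(-math.pi * line_broadening_hz * acq.times("direct"))
    win_t1 = np.exp(-math.pi * line_broadening_hz * acq.times("indirect"))
    data *= win_t2[None, :]
    data *= win_t1[:, None]
    data[:, 0] *= 0.5
    data[0, :] *= 0.5

    n2 = acq.n_direct * zero_fill
    n1 = acq.n_indirect * zero_fill
    spec = np.fft.fft(data, n=n2, axis=1)
    spec = np.fft.fft(spec, n=n1, axis=0)
    spec = np.fft.fftshift(spec)
    hz_direct = np.fft.fftshift(np.fft.fftfreq(n2, d=1.0 / acq.sw_direct))
    hz_indirect = np.fft.fftshift(np.fft.fftfreq(n1, d=1.0 / acq.sw_indirect))
    return Spectrum2D(
        data=spec.real,
        hz_direct=hz_direct,
        hz_indirect=hz_indirect,
        acquisition=acq,
        spins=fid.spins,
    )


def _lorentzian2d(nu_h, nu_c, intensity, t2_h, t2_c, nu0_h, nu0_c):
    lh = t2_h / (1.0 + (2.0 * np.pi * (nu_h - nu0_h) * t2_h) ** 2)
    lc = t2_c / (1.0 + (2.0 * np.pi * (nu_c - nu0_c) * t2_c) ** 2)
    return intensity * lh * lc


def fit_lorentzian2d(
    spectrum: Spectrum2D,
    guess: tuple | None = None,
    window_hz: tuple | None = None,
) -> PeakFit:
    """Least-squares fit of a separable 2D Lorentzian around a peak.

    ``guess`` is an optional ``(nu_h, nu_c)`` Hz pair; by default the global
    maximum is used.  ``window_hz`` restricts the fitted region around the
    guess (defaults to +-8 linewidth-ish bins in each dimension).
    """
    data = spectrum.data
    hzd, hzi = spectrum.hz_direct, spectrum.hz_indirect
    if guess is None:
        ic, ih = np.unravel_index(np.argmax(data), data.shape)
    else:
        ih = int(np.argmin(np.abs(hzd - guess[0])))
        ic = int(np.argmin(np.abs(hzi - guess[1])))
    if ih in (0, len(hzd) - 1) or ic in (0, len(hzi) - 1):
        raise PeakFitError("peak maximum lies on the spectral window edge")

    if window_hz is None:
        wh = max(20.0, 0.1 * (hzd[-1] - hzd[0]))
        wc = max(30.0, 0.1 * (hzi[-1] - hzi[0]))
    else:
        wh, wc = window_hz
    sel_h = np.abs(hzd - hzd[ih]) <= wh
    sel_c = np.abs(hzi - hzi[ic]) <= wc
    sub = data[np.ix_(sel_c, sel_h)]
    grid_h, grid_c = np.meshgrid(hzd[sel_h], hzi[sel_c])

    height = float(data[ic, ih])
    t2_guess_h = 1.0 / (math.pi * 10.0)
    t2_guess_c = 1.0 / (math.pi * 10.0)
    params = lmfit.Parameters()
    params.add("intensity", value=height / (t2_guess_h * t2_guess_c), min=0)
    params.add("t2_h", value=t2_guess_h, min=1e-4)
    params.add("t2_c", value=t2_guess_c, min=1e-4)
    params.add("nu0_h", value=float(hzd[ih]), min=float(hzd[0]), max=float(hzd[-1]))
    params.add("nu0_c", value=float(hzi[ic]), min=float(hzi[0]), max=float(hzi[-1]))

    def residual(p):
        model = _lorentzian2d(
            grid_h, grid_c, p["intensity"], p["t2_h"], p["t2_c"], p["nu0_h"], p["nu0_c"]
        )
        return (model - sub).ravel()

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise PeakFitError(f"2D Lorentzian fit failed: {result.message}")
    p = result.params
    spins, acq = spectrum.spins, spectrum.acquisition
    return PeakFit(
        intensity=float(p["intensity"]),
        t2_h=float(p["t2_h"]),
        t2_c=float(p["t2_c"]),
        nu_h=float(p["nu0_h"]),
        nu_c=float(p["nu0_c"]),
        ppm_h=acq.carrier_h_ppm + float(p["nu0_h"]) / spins.h_frequency_mhz,
        ppm_c=acq.carrier_c_ppm + float(p["nu0_c"]) / spins.c_frequency_mhz,
        redchi=float(result.redchi),
    )


def in_situ_shift_error(
    *,
    nu_h: float,
    nu_c: float,
    r2_h: float,
    r2_c: float,
    snr: float,
    acquisition: Acquisition | None = None,
    spins: SpinParameters | None = None,
    n_replicates: int = 100,
    seed: int | np.random.Generator = 0,
    line_broadening_hz: float = 2.0,
) -> dict:
    """Monte Carlo estimate of the peak-position uncertainty.

    Replicates a single resonance with the observed relaxation rates and
    signal-to-noise ratio: complex white Gaussian noise is added to the
    time-domain signal, each replicate is processed identically to the data
    and fit with the 2D Lorentzian, and the standard deviations of the
    fitted centres are returned per nucleus (Hz and ppm).  ``snr`` is the
    processed-spectrum peak height over the spectral noise SD; ``inf``
    means no noise.
    """
    if n_replicates < 2:
        raise ValueError("at least two replicates are required")
    spins = spins or SpinParameters()
    acq = acquisition or Acquisition.from_spins(spins)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t2 = acq.times("direct")
    t1 = acq.times("indirect")
    fid = np.outer(
        np.exp((2j * np.pi * nu_c - r2_c) * t1),
        np.exp((2j * np.pi * nu_h - r2_h) * t2),
    )

    def process(arr):
        return process_to_spectrum(
            FID2D(arr, acq, spins), line_broadening_hz=line_broadening_hz
        )

    clean = process(fid)
    height = float(clean.data.max())
    if math.isinf(snr):
        sigma_t = 0.0
    else:
        # calibrate the time-domain noise scale against the processed
        # spectrum's noise floor
        probe = rng.standard_normal(fid.shape) + 1j * rng.standard_normal(fid.shape)
        noise_floor = float(process(probe).data.std())
        sigma_t = height / (snr * noise_floor)

    centers_h, centers_c = [], []
    for _ in range(n_replicates):
        noisy = fid + sigma_t * (
            rng.standard_normal(fid.shape) + 1j * rng.standard_normal(fid.shape)
        )
        fit = fit_lorentzian2d(process(noisy), guess=(nu_h, nu_c))
        centers_h.append(fit.nu_h)
        centers_c.append(fit.nu_c)
    centers_h = np.array(centers_h)
    centers_c = np.array(centers_c)
    return {
        "sd_h_hz": float(centers_h.std(ddof=1)),
        "sd_c_hz": float(centers_c.std(ddof=1)),
        "sd_h_ppm": float(centers_h.std(ddof=1)) / spins.h_frequency_mhz,
        "sd_c_ppm": float(centers_c.std(ddof=1)) / spins.c_frequency_mhz,
        "n": n_replicates,
    }
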