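# Methods

`cheadyn` models the dynamic domain arrangement of the bacterial
chemotaxis kinase CheA bound to its response regulator CheY, from the NMR
observable up to the signaling consequence. This note records the models,
the numerical choices, and — importantly — what the synthetic studies do
and do not establish.

## The four-state binding scheme

CheA tethers CheY through its P2 domain (sub-micromolar), after which the
phosphotransfer (P1) domain of the same molecule can dock onto the
tethered CheY; at high CheY excess a second CheY occupies the P1 site
instead. Four states: A (free), B (P2-tethered, P1 undocked), C (P1
docked; the phosphotransfer-competent conformer), D (ternary). The ternary
state is reached only from B — the second CheY binds the *undocked* P1 —
so there is no direct C–D edge. Equilibrium constants are dissociation
constants: `K0 = k_off0/k_on0` (M) for the tether, `K1 = k_off1/k_on1`
(dimensionless, unimolecular docking), `K2 = k_off2/k_on2` (M) for the
second CheY. Association rates are fixed, fast constants (2×10⁸ M⁻¹s⁻¹,
10⁴ s⁻¹, 10⁷ M⁻¹s⁻¹) used only by the lineshape simulator. CheA is treated
as a monomer (concentrations are monomer concentrations); dimer
cooperativity is out of scope.

Species concentrations come from a bracketed Brent search on free CheY
over [0, CheY_total] (relative tolerance 10⁻¹², ≤200 iterations); the
bracket is guaranteed because the CheY balance is monotone in free CheY.
Mass balances hold to relative 10⁻⁹ (property-tested over randomized
totals and constants, and against an independent bisection oracle).

## Lineshape simulation

A methyl probe on the P1 domain senses three environments: free (states A
and B), docked (C) and second-CheY-bound (D). Magnetization evolves under
the Bloch–McConnell matrix `L = 2πi·diag(ν) − diag(R2) + K`, with K the
pseudo-first-order exchange generator (zero column sums — magnetization is
conserved absent relaxation; eigenvalue real parts are ≤ −min R2). The 2D
FID is propagated analytically by eigendecomposition,
`FID(t1,t2) = [1ᵀexp(L_C t1)p]·[1ᵀexp(L_H t2)p]`, the two dimensions
evolving independently from the same equilibrium populations; exchange
during t1 uses the same topology as t2, and no mixing-time exchange is
modeled. A scaling-and-squaring matrix exponential is the fallback for
numerically defective matrices.

Transverse relaxation defaults are the study conditions: at 303 K,
¹H 45/60 s⁻¹ and ¹³C 12/15 s⁻¹ (free/bound); at 283 K, 70/100 and
40/60 s⁻¹. The spectrometer field is configurable (default ¹H 600 MHz;
¹³C frequency from the gyromagnetic ratio 0.25145). Acquisition defaults:
512×128 complex points, spectral widths spanning the environments with
≥20% margin, 2 Hz exponential apodization, twofold zero filling; first
FID points are half-weighted before the FFT. Peaks are quantified with the
separable absorptive 2D Lorentzian
`I · T2C/(1+(2π(ν_C−ν_kC)T2C)²) · T2H/(1+(2π(ν_H−ν_kH)T2H)²)` by
Levenberg–Marquardt (lmfit); noiseless peaks are recovered to 10⁻⁶
relative in all five parameters. The in-situ error analysis regenerates
a single resonance n = 100 times with complex white Gaussian time-domain
noise (S/N defined as spectrum peak height over spectral noise SD,
calibrated empirically), processes each identically, and reports the SD
of the fitted centres per nucleus.

### Exchange-regime caveat

At and above the 1:1 titration point the free-CheY concentration keeps
every step fast on the shift timescale and the simulated peak coincides
with the population-weighted position well within 1 Hz. *Below*
stoichiometry, free CheY is sub-micromolar, the bimolecular tether step
exchanges at k_on0·[Y] ≈ 10²–10³ s⁻¹ against a ~45 Hz free-vs-bound
shift difference, and the full simulation deviates from the fast-exchange
average by up to ~10 Hz — intermediate exchange is a real feature of
tight-binding titrations, not an artifact. The fast posterior mode uses
the population-weighted approximation consistently on both the generator
and the model side, so inference is internally coherent; the exact mode
(simulate → process → fit per evaluation) exists for validation at small
scale.

## Bayesian inference

The observables are the ¹H/¹³C positions of the probe's single
fast-exchange resonance over a seven-point CheY titration (0–9× a 100 µM
CheA sample) at 283 K and 303 K. The posterior is Gaussian in the
position residuals with one global σ (default 1 Hz), flat priors inside
bounds: log₁₀K0, log₁₀K2 ∈ [−9, 0] (M), log₁₀K1 ∈ [−4, 4], bound-state
shifts inside the spectral window, and the docked/doubly shifts
constrained to differ by ≤0.01 ppm (¹H) / 0.05 ppm (¹³C) between the two
temperatures. Free-state shifts are anchored to the zero-CheY point
(flag to fit them instead).

Sampling is single-parameter-update Metropolis: each of the 20,000
iterations is a sweep in which every parameter receives one Gaussian
proposal (random order), accepted with probability min(1, P(1)/P(0));
estimates and errors are the means and SDs of the last 10,000 sweeps.
Proposal scales start at 5% of each prior range and are adapted toward
~30% acceptance in 250-sweep windows *during burn-in only*; the kernel is
frozen before any retained sample, preserving detailed balance where it
matters. The chain is bit-reproducible given a seed. The default start is
data-driven (1:1 fit for K0, neutral docking K1 = 1, shift extrapolations
from the near-stoichiometric and highest-excess points) and then polished
to a local posterior maximum by bounded Powell search, which keeps the
burn-in from wandering one-sidedly along the model's flat direction
(below).

### Identifiability: what the titration does and does not determine

Because states A and B share the probe's free-environment shift, the
predicted positions depend only on six combinations per temperature:

    K_eff = K0/(1 + 1/K1),  K2_eff = K2·(1 + 1/K1),
    φ·Δδ_docked (¹H and ¹³C),  Δδ_doubly (¹H and ¹³C),

with φ = 1/(1+K1) the docked fraction of the tethered complex. One
likelihood direction per temperature is therefore *exactly* flat: a larger
docked fraction with a proportionally smaller docked-shift contrast is
indistinguishable. The inter-temperature shift constraints couple the two
temperatures and identify the *ordering* of K1 across temperature — the
cold-shifted docking equilibrium (K1 colder > K1 warmer) is recovered
with >95% certainty mass in every run — but they do not bound the joint
K1 → 0 side of the ridge. Consequently the absolute values of K1 (and,
through the effective-constant combinations, K0 and K2) are set by where
the finite chain happens to sit on the ridge, not by the data; posterior
SDs computed from a single 20,000-sweep chain understate the true
uncertainty of those absolute values, and derived quantities that need
absolute K1 at both temperatures (the van't Hoff enthalpy, the absolute
docked population) vary from seed to seed while ratio-flavoured,
identified quantities are stable. Tight "certainty clusters" in such a
chain indicate a frozen chain, not a unique solution. Users who need
absolute docking constants must add outside information (for example an
independently measured bound-state shift or a calorimetric constraint).

## Chemotaxis signaling model

Receptors carry 0–4 methyl groups; state *i* is active with probability
p_i (ligand-free) or p_iᴸ (attractant-bound), mixed by receptor occupancy
[L]/(K_L+[L]). CheR methylates inactive receptors and phospho-CheB
demethylates active ones (Michaelis–Menten in the pooled inactive/active
concentrations). Active receptors drive CheA autophosphorylation; CheA-P
phosphotransfers to CheY and CheB; CheY-P decays intrinsically and via a
CheZ-mediated first-order channel, and binds FliM. The docking population
gates the chemistry: phosphotransfer to CheY is proportional to p_docked
(the catalytic P1-on-CheY complex), while autophosphorylation and
transfer to CheB are proportional to (1 − p_docked). Temperature enters
*only* through p_docked via the van't Hoff-interpolated equilibrium
constants (no Arrhenius scaling of the kinetic constants).

Free species are algebraic: [A] = [A]ₜ−[Ap], [B] = [B]ₜ−[Bp],
[M] = [M]ₜ−[MYp], and [Y] = [Y]ₜ−[Yp]−[MYp] — the FliM-sequestered pool
is included in the CheY balance so that total CheY is conserved exactly
(the commonly printed [Y] = [Y]ₜ−[Yp] neglects sequestration and breaks
the balance at the 10⁻⁹ level demanded here).

Defaults (exposed, not hard-coded): activity ladder p = (0, 0.25, 0.5,
0.75, 1), pᴸ = (0, 0.05, 0.15, 0.40, 0.75), K_L = 10 µM; methylation
k_r = 0.39 s⁻¹, K_R = 0.364 µM, [CheR] = 0.2 µM; demethylation
k_b = 6.3 s⁻¹, K_B = 1.405 µM; k_auto = 10⁶ M⁻¹s⁻¹, k_ApY = 10⁸ M⁻¹s⁻¹,
k_ApB = 10⁷ M⁻¹s⁻¹; decays k_Yp = 0.04 s⁻¹ (intrinsic),
k_YpZ = 1.6 s⁻¹ (CheZ lumped), k_Bp = 1 s⁻¹; FliM k_YpM = 5×10⁶ M⁻¹s⁻¹,
k_MYp = 20 s⁻¹; totals receptor 5, CheA 10, CheY 10, CheB 2, FliM 1.4 µM.
These are a coherent set seeded from the standard chemotaxis-modelling
literature; they reproduce a resting CheY-P around 1–4 µM and
second-scale phosphorylation with ~minute-scale adaptation. They are
*not* the original study's (unpublished) table, so absolute response
magnitudes (e.g. the percent CheY-P change on a 20 K step) should be read
as order-of-magnitude, parameter-dependent outcomes.

Integration is classical fixed-step RK4 (default dt = 10⁻⁴ s) with the
algebraic relations re-evaluated inside every stage; halving dt moves a
10 s endpoint by <10⁻⁶ relative. Concentrations more than 10⁻¹²·(largest
total) below zero abort with an instability error; smaller excursions are
clipped and counted. The receptor ladder telescopes, so Σ[T_i] is
conserved analytically; the remaining conservation laws are structural.
Steady states are found by a Newton-type root search in which one ladder
equation is replaced by the receptor-total constraint (the ladder's exact
conservation makes the raw Jacobian singular), with long-relaxation
fallback. The response protocol follows the study: equilibrate at 283 K
without attractant (steady state, then a 10 s time course whose endpoint
seeds all other conditions), then integrate the perturbed condition and
report 1 − min[Yp](t)/[Yp](0).

Note on monotonicity: the CheB-P feedback partially clamps the steady
autophosphorylation flux, so the *fully adapted* steady CheY-P actually
rises with p_docked; the physiological thermal signal is the transient
minimum, which decreases strictly and monotonically with the size of the
docking step. All monotonicity checks therefore target the transient
readout.

## Synthetic data

The generator emulates the two-temperature titration design: CheA fixed
at 100 µM, CheY at 0, 0.25, 0.5, 1, 2, 4 and 9× (the top point reaches
0.9 mM and populates the ternary state), both 283 K and 303 K, positions
perturbed with 1 Hz Gaussian noise, seeds recorded in the sidecar
metadata and never embedded in the peak lists themselves. Ground-truth
constants are fixed once from the study's printed apparent constants:
K0 = 0.5 µM; K1 = 1.0 at 303 K (so K0·K1 matches the ~1.6 µM apparent
docked-branch constant after accounting for the tether) rising to 2.5 at
283 K (docking enthalpy +32.7 kJ/mol, inside the printed 10–40 kJ/mol);
K2 = 900 µM at 303 K (≈1 mM apparent ternary constant) and 500 µM at
283 K (ternary state more populated when cold). What passing recovery
tests show — and what they cannot: the generator shares the fast-exchange
approximation and the noise model with the inference, so recovery tests
validate the estimator's self-consistency and the identified parameter
combinations, not robustness to baseline distortions, peak overlap or
spectral artifacts, which are deliberately not emulated.

## Problem sizes

The bundled studies use the sizes above: 20,000-sweep chains (10,000
burn-in) on 14 titration points, 100-replicate error analyses, 10 s
signaling trajectories at dt = 10⁻⁴ s, and small response grids; these
choices keep a complete run of the test-suite and the acceptance script
in the minutes range on one core while exercising every code path at the
study's stated schedule.
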