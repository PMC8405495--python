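# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices, and what the reduced-scale
test scenarios do and do not demonstrate.

## Model structure

One agent is one cancer cell (monolayer mode) or one group of cells
(spheroid mode) on a square occupancy lattice, at most one agent per
site.  Agent behaviour is a clock-driven state machine rather than a
mechanistic ODE cell cycle: each agent draws an individual doubling time
τᵢ from 𝒩(μ, σ) truncated to positive values (at μ = 24 h, σ = 0.5 h the
truncation is inconsequential), and each cycle phase completes once the
agent's phase clock has accumulated that phase's share of τᵢ.

Shares: Θ_G1 = 11/24, Θ_S = 8/24, Θ_G2/M = 5/24.  The damaged-S (D-S)
residence Θ_DS = 0.03 **counts within the S share**: a cell routed through
D-S spends Θ_DS·τ there and, if it repairs, (Θ_S − Θ_DS)·τ in S, so every
surviving cycle lasts exactly τᵢ.  (The alternative reading — D-S time
added on top of S — would lengthen the cycle by ~3 %; the shares are
defined as fractions of the doubling time, which pins the implemented
choice.)  The fork into D-S is decided once per cycle, at G1 exit, with
probability Π_DS = 0.75.

Repair out of D-S succeeds with probability 1 − E(C) where E is the
sigmoid Emax effect of the local drug concentration sampled at the
agent's own site at the moment of the decision (no time-averaging over
the D-S residence).  A cell that fails repair is *sentenced*: it stays on
its site, is counted γH2AX-positive, and dies after the lethal delay
T_L→D = τᵢ.  Sentenced cells still consume oxygen and block space; they
never divide and never re-enter the cycle.  On death, monolayer corpses
keep their site forever; spheroid corpses are removed and the site freed.

γH2AX readout: the damaged pool is D-S plus sentenced agents.  The
denominator is the viable on-lattice population by default
(`gammaH2AX_include_dead` switches to counting corpses too).  With
corpses in the denominator the late-time damage fraction becomes
non-monotone in dose — the denominator fills with dead cells faster than
damage accrues — which contradicts the dose-ordered damage curves this
class of assay produces, hence the viable-only default.  Reported *cell
counts*, in contrast, do include monolayer corpses, since a well plate
retains them.

## Space

Daughters are placed by drawing Moore vs von Neumann with a fair coin per
division, then scanning rings of increasing order and choosing uniformly
among the free sites of the first non-full ring.  Monolayer mode allows
unbounded order (placement anywhere on the lattice; position does not
affect monolayer readouts), spheroid mode caps the order at ν̃ = 3, which
yields the quiescent-core / proliferating-rim architecture.  A G1 agent
with no empty site within Chebyshev radius ν̃ (the union of both ring
families through order ν̃) exits to G0, retaining its clock, and resumes
G1 when space reappears.  If a mitosis finds its neighbourhood filled in
the same step that the G1 gate was passed (a rare ordering race), the
division is deferred and re-attempted each step.  Agents are updated in a
freshly permuted order every step to avoid lattice-scan anisotropy.

The supply mask m(x, t) is 1 at empty sites with at least one empty
first-order Moore neighbour, the off-lattice side counting as empty — the
complement of the colony's filled hull, so supply comes "from outside the
spheroid boundary".

## Transport

Both fields use a conservative flux-form finite-difference discretisation
with harmonic-mean interface diffusivities and zero-flux boundaries.
Diffusivity is divided by 1.5 at occupied sites (applied to both oxygen
and drug by default; `slowdown_applies_to_drug` switches the drug off).

Oxygen (supply r_K on the mask, consumption φ_K at viable-cell sites)
equilibrates within seconds over the lattice while the cells change over
hours, so the engine treats it as quasi-steady: the steady state of the
same discretisation is solved directly (Jacobi-preconditioned conjugate
gradients, warm-started from the previous field, rtol 1e-5) every
`field_update_interval` (default 0.1 h; the scaled studies use 0.5–2 h,
over which the colony changes by well under 1 % of sites).  The explicit
transient solver remains the reference implementation and the test
oracle; a test verifies the CG steady state is its fixed point.  With no
consuming cells the steady problem is unbounded and the field is defined
as uniform (i.e. uniform normoxia after rescaling).

r_K and φ_K are not independently measurable here; only the *scaled*
profile K̂ = K/max(K)·h (h = 100) matters.  φ_K = 3·10⁻³ s⁻¹ sets the
oxygen penetration depth ℓ = √(D_K/1.5/φ_K) ≈ 0.074 cm so that colony
cross-sections above ≈0.28 cm radius (extrapolated volume ≈0.1 cm³)
develop a ≤10 % hypoxic core; r_K = 10⁻² a.u./s cancels in the rescaling.
Hypoxia stretches G1 via the delay factor G1DF (2 below 1 % oxygen,
a₁ + a₂/(a₃ + K̂) on [1 %, 10.5 %] with a₁ = 0.9209, a₂ = 0.8200,
a₃ = −0.2389, else 1), implemented by accumulating dt/G1DF on the G1
clock at the agent's current oxygen — a cell moving between oxygen levels
experiences a path-dependent G1.

The drug field is genuinely transient (daily pulses, 6 h half-life
elimination, η = ln 2/6 h⁻¹) and is co-integrated through every agent
step with a compiled explicit kernel at the stability step
dx²/(4·max D) ≈ 0.57 s.  The oral dose label maps to a supply amplitude
through one linear coefficient — the model's only bioavailability knob —
calibrated once so that 50 mg/kg daily produces net tumour regression and
25 mg/kg partial growth inhibition: 0.4 µM·h⁻¹ per mg/kg over a 1 h daily
window on mask sites.  Monolayer mode bypasses transport entirely: the
applied concentration ℂ appears everywhere at the treatment time T₀ and
never decays.

## Orchestration

A replicate starts from one agent (state G1, clock 0) at the lattice
centre, or — for scaled spheroid studies — from a pre-grown disc seeded
in the colony's attractor state (enclosed agents quiescent with uniform
G1 clocks, rim agents at uniform random cycle positions).  Treatment
begins when the trigger fires: population ≥1000 cells (monolayer) or
extrapolated volume ≥0.25 cm³ (midpoint of the 0.2–0.3 cm³ in vivo
range; spheroid).  Readouts are recorded on a post-treatment grid
(default 1 h monolayer, 6 h spheroid).  Agents step at dt = 0.1 h, which
resolves the shortest phase (Θ_DS·τ ≈ 0.72 h) with ~7 steps; phase
overshoot is carried into the next phase so long-run phase bookkeeping is
exact to one dt.  Experiments run n replicates (default 100) with seeds
master + i on independent PCG64 streams and report per-time-point means
and standard deviations; identical (config, params, seed) reproduce
byte-identical output.

## Scaled test scenarios

The acceptance-style checks run at sizes chosen to keep the suite's total
runtime in minutes while preserving the governing dimensionless scales:

- Monolayer dose response: the full 100×100 lattice and 1000-cell
  trigger, 25 replicates per concentration at {0, 0.3, 1, 3, 10}·EC₅₀.
- Spheroid study: a 200×200 lattice (0.8 cm box) with a pre-grown disc of
  radius 70 sites — deliberately at the hypoxia threshold size, since a
  smaller colony would simply (and correctly) not be hypoxic — and four
  days of daily dosing at one replicate per arm.  The full-scale
  1000×1000 / 100-replicate / 14-day experiment is the same code and an
  overnight job.

What the synthetic settings do not show: real monolayer cultures speed up
their doubling late in an experiment and real xenografts recruit
vasculature; the model's rules and parameters are fixed in time, so its
late-time trajectories are expected to diverge from such data.  The
packaged reference CSV is synthetic (see `src/atrabm/data/README.md`);
RMSE values against it demonstrate the comparison machinery only.

## Known limitations

- 2-D cross-section only; the disc-to-spheroid extrapolation
  (r = √(A/π), V = 4/3·π r³) is isolated in one function for replacement.
- No pharmacokinetic compartments, drug uptake or receptor dynamics; the
  supply-amplitude coefficient absorbs all bioavailability.
- No cell mechanics: daughters occupy free sites; cells are never pushed.
- Oxygen stands in for all nutrients; supply sits directly on the colony
  hull rather than on modelled vasculature.
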