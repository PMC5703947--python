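# Methods

## Model

Three tumor phenotypes compete within a metastatic prostate-cancer lesion
under continuous androgen deprivation: T+ cells that require exogenous
testosterone, testosterone-producing TP cells, and androgen-independent,
abiraterone-resistant T− cells. Abundances follow Lotka–Volterra
competition,

    dx_i/dt = r_i x_i (1 − Σ_j a_ij x_j / K_i),    i = 1 (T+), 2 (TP), 3 (T−),

with a unit-diagonal competition matrix (`a_ij` = per-capita effect of type
*j* on type *i*, off-diagonals strictly in (0, 1)) and serum PSA produced
at one unit per cell per day and cleared at 0.5/day, so PSA equilibrates at
exactly twice the total cell count. PSA units are arbitrary (no ng/ml
conversion is attempted); time is in days.

The drug acts instantaneously on carrying capacities only — it is unknown
whether abiraterone kills or merely arrests TP cells, and the model is
agnostic between the two:

| parameter | off-drug | on-drug | meaning |
|---|---|---|---|
| `K_1` | 1.5·x₂ | 0.5·x₂ | T+ cells live off TP-produced testosterone ("cheating") |
| `K_2` | 10 000 | 100 | abiraterone collapses the TP niche 100-fold |
| `K_3` | 10 000 | 10 000 | T− is unaffected by the drug |
| `r_i` | 0.1 × (0.278, 0.355, 0.665)/day | — | cell-line doubling times scaled to 10% for in-vivo realism |

When x₂ → 0 the T+ capacity vanishes and the logistic bracket diverges; we
replace the bracket by −1 whenever `K_i` < 10⁻⁹ cells (maximal per-capita
decline −r_i·x_i), which keeps the vector field Lipschitz and bounds the
decay rate by r_i. Growth rates do not affect untreated equilibrium
*frequencies*, only transient time scales.

## The admissible matrix space

Only the rank order of the six off-diagonal coefficients is clinically
constrained: T+ is the weakest competitor and T− presses harder on TP than
on T+, giving a31 > a21, a32 > a12, a13 > a23, a13 > a12, a23 > a21,
a32 > a31. Exactly 22 of the 720 rank permutations are linear extensions
of this partial order (verified by exhaustive enumeration; the enumeration
is canonical — lexicographic by rank tuple in label order a12, a13, a21,
a23, a31, a32 — so "ordering #k" is stable across runs). Ranks are mapped
to the strictly increasing value grid (0.4, 0.5, 0.6, 0.7, 0.8, 0.9); ties
are disallowed because the taxonomy below counts strict orderings. Each
ordering is one virtual patient; `sample_virtual_patient` draws uniformly
over the 22.

## Equilibria, ESS and the responder taxonomy

Because K₁ is proportional to x₂, every untreated steady state solves a
linear system (Σ_j a_ij x_j = K_i for present types, with K₁ replaced by
1.5·x₂). Candidate communities are the subsets of phenotypes that can
support their members (T+ never persists without TP). The evolutionarily
stable community is the feasible equilibrium that (i) no absent phenotype
can invade — invasion fitness is the bracket 1 − Σ_j a_ij x̂_j / K_i at the
resident equilibrium — and (ii) is internally stable (all eigenvalues of
the community Jacobian have non-positive real part; the Jacobian is
computed by central differences so the K₁–x₂ coupling is differentiated
through). Uniform rescaling of all K's rescales equilibria and leaves
frequencies, invasion signs and the taxonomy unchanged.

Patients are classified by the resistant clone's fate at the ESS:
T− strictly excluded → best responder; T− at ≥ 20% of cells →
non-responder; otherwise responder. On the default grid one ordering
(ranks 2, 6, 1, 4, 3, 5) has T− invasion fitness *exactly zero* at the
{T+, TP} boundary; we count neutral invasion as "not excluded" — a neutral
invader is not driven absent — which assigns it to the responder class and
yields the 12/4/6 partition. Numerically, "exclusion" means fitness below
−10⁻⁹ and the 20% frequency comparison carries a 10⁻⁹ slack, so these
knife-edge cases are decided deterministically. In simulation, "absence"
of a type is operationalized as final frequency < 10⁻⁴.

## Initialization and the resistant inoculum

Each run starts from the untreated ESS frequencies at 25% of the
equilibrium size, with PSA at 25% of its equilibrium value — a tumor
recently passed through a therapeutic bottleneck. For best-responder
patients the ESS contains no T−, yet resistance must be able to emerge
under therapy; we plant a fixed T− inoculum (default one cell) at t = 0.
It decays while therapy is off (negative invasion fitness) and is
competitively released under drug. The inoculum size is a configuration
parameter because every absolute milestone time of such patients depends
on it; an inoculum of zero keeps T− identically zero forever (LV dynamics
create no mass).

## Regimens

All regimens share the drug-free run-in until PSA first reaches 80% of its
untreated equilibrium — the trigger at which a physician would start
abiraterone. The PSA value at the trigger is the *baseline* to which the
adaptive thresholds refer.

* **untreated** — no drug, natural history.
* **mtd** — drug continuously from the trigger.
* **metronomic** — continuous induction block (240 days) from the trigger,
  then a fixed calendar cycle ignoring tumor state. The cycle lengths are
  a design choice, not an observation: 28 days on / 84 days off (25%
  on-time), with the off-block first since the induction itself ends a
  long on-block.
* **adaptive** — hysteresis rule: stop when PSA ≤ 50% of baseline, restart
  when PSA ≥ 100% of baseline, retain the current state inside the band.
  The two-threshold band excludes chattering by construction.

Decisions are evaluated continuously by default (threshold crossings are
solver events); an interval-monitoring mode evaluates them only every 28
days, mimicking 4-weekly clinic labs.

**Progression** is operationalized as the first day from which T− holds at
least 90% of cells *and* PSA stays at or above 50% of the baseline
continuously for 84 days (one imaging interval); it is undefined for
untreated runs. Cumulative dose is reported as a percentage of continuous
dosing over [trigger, min(progression, horizon)], so MTD is exactly 100%.

## Numerics

Integration uses LSODA (the TP collapse under drug is locally stiff) with
rtol 10⁻⁸, atol 10⁻¹⁰, max step 1 day, horizon 10 000 days; trajectories
are stored at ≤ 1-day spacing. Integration proceeds piecewise between drug
switches with the state handed across the discontinuity. Events (trigger,
adaptive switches, 5%/90% T− crossings) are located by the solver's root
finder on dense output, far inside the 10⁻³-day reporting tolerance;
milestones not reached by the horizon are reported as indefinite (`None`).
Sub-picocell negative abundances produced during the stiff collapse are
clamped to zero on output. Tightening both tolerances tenfold moves
milestone times by well under 0.1% (regression-tested). The engine always
integrates to the horizon; progression is detected in post-processing on
the stored series (1-day resolution) and dose windows are clipped to it.

## What the model does and does not predict

Robust, initialization-insensitive outputs: the 22-ordering combinatorics;
equilibrium communities, frequencies and the 12/4/6 taxonomy; the ordering
of regimens (adaptive delays every stage of competitive release relative
to continuous dosing and uses far less drug — for representative patient
#2, progression at day 2005 vs 134 with 0.33% of the continuous dose); and
the identity of the early 5%-T− crossing across regimens when it falls in
the shared run-in phase.

Absolute milestone days, by contrast, are strongly sensitive to
conventions the clinical narrative does not pin down — the initial tumor
fraction, the resistant inoculum, and especially the speed of the TP
collapse under drug: with K₂ falling 100-fold while PSA clears at 0.5/day,
the sensitive populations are reduced by several e-folds within days under
*any* policy, so even adaptive cycling produces deep, short drug pulses
(on for ~3 days, off for hundreds) rather than shallow oscillations, and
PSA undershoots the hysteresis band after switch-off because serum PSA
lags the collapsed populations. These are properties of the stated
equations, not solver artifacts; readers comparing against clinical cycle
lengths (months) should treat the on/off pulse structure as the model's
idealization of instantaneous drug effect.

## Sensitivity sweeps

`sensitivity_sweep` re-runs the 22-ordering classification along one axis:
`capacity_ratio` rescales K₃ relative to K₂ (testing the claim that
results are insensitive to relative capacity magnitudes), and
`coefficient_spread` applies a mean-preserving stretch to the value grid
(a wider spread should not increase the number of three-type-coexistence
orderings). Stretch factors are validated against the (0, 1) coefficient
bounds — for the default grid (mean 0.65, half-range 0.25) factors up to
1.4 are feasible.

## Limitations

No cell-level stochasticity or extinction of small populations (a 10⁻³-cell
T− population regrows deterministically); no spatial structure; no
pharmacokinetics (drug effect is an instantaneous capacity switch); no
mutation — resistance must be seeded explicitly; testosterone is not a
state variable (it is folded into the K₁–x₂ coupling); PSA is a noiseless
deterministic readout. The virtual-patient generator varies only the
competition matrix on a fixed six-value grid; growth rates and capacities
are shared across patients, so inter-patient variability in time scales is
not represented. The trial statistics module reproduces interim
contingency tests from embedded summary counts; it performs no survival
analysis, as individual event times are not part of the fixture.
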