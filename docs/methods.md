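# Methods

## Model structure

The system is a deterministic compartmental ODE model in amounts (mmol).
States are (compartment, substance) pairs; the default build has 38 states in
five components:

- **Gut lumen**, four segments in series (upper/lower proximal, upper/lower
  distal — nominally stomach, proximal small intestine, distal small
  intestine, colon), each holding ester, butanediol and BHB (12 states), plus
  one BHB enterocyte state for each of the three carrier-expressing segments
  (3 states).  First-order transit chains the segments and ends in a faeces
  sink; ester hydrolysis (ester → butanediol + BHB, first order) runs in
  every segment; passive first-order absorption moves all three species into
  the portal component from every segment.  In the three segments beyond the
  upper proximal one, BHB additionally crosses the apical membrane through
  two parallel saturable carriers — MCT1 (low affinity, high capacity) and
  SMCT1 (high affinity, low capacity) — into the enterocyte, and leaves
  basolaterally through saturable MCT4 into the portal blood.  Carrier
  V_max values are non-decreasing down the gut, mirroring distally increasing
  transporter expression; this monotonicity and the SMCT1-vs-MCT1 affinity
  ordering are asserted at build time.
- **Portal vein**: ester, butanediol, BHB; first-order transfer to liver.
- **Liver**: ester, butanediol, BHB, AcAc, acetone.  Ester hydrolysis,
  butanediol → BHB, reversible BHB ↔ AcAc, irreversible AcAc → acetone
  decarboxylation, and zero-order endogenous AcAc production under feedback
  (below).  BHB and AcAc exchange with blood through shared MCT1 carriers in
  both directions, modelled with the competitive form so each inhibits the
  other's transport; ester, butanediol and acetone move passively.
- **Blood**: the same five substances plus the lumped "other" state
  (glucose, insulin and similar circulating factors) that participates in
  feedback; ester and butanediol conversion to BHB, AcAc → acetone, renal
  first-order loss of BHB/AcAc and first-order acetone exhalation into an
  excretion sink.  Excretion is taken from blood because kidneys and lungs
  filter blood; the lumped tissue component has no excretion kinetics of its
  own.
- **Tissues**: saturable, mutually competitive uptake and back-transport of
  BHB and AcAc (MCT1/MCT2 lumped into one carrier per direction), conversion
  of both to acetyl-CoA and irreversible first-order consumption (Krebs
  cycle) into a terminal sink; ester, butanediol, acetone distribute
  passively.

Mass bookkeeping is structural: each process subtracts a fraction-weighted
flux from its source and adds stoichiometry-weighted amounts to its products
(hydrolysis of 1 mmol ester yields 1 mmol butanediol + 1 mmol BHB).  Sinks
account in BHB equivalents, with the ester counting two; with endogenous
production disabled the weighted total is exactly conserved, which the test
suite verifies to 1e-6 relative along dosed trajectories.  Processes that
split one physical fate may declare a named partition; validation requires
the fractions within a partition to sum to one.

The decomposition into 38 states is this package's canonical structure;
models serialized in the same JSON/YAML schema (including externally supplied
parameter tables for exact reproduction of a published variant) load through
the same fixture interface.

## Feedback law

Endogenous ketogenesis is zero-order with a saturable inhibition multiplier

    R = R₀ · (1 − I_max · S / (IC₅₀ + S)),   S = Σ w_i · A_i

over blood BHB, blood AcAc and the lumped "other" state (weights default to
1 and can be zeroed individually).  This is the simplest saturable inhibition
consistent with a feedback of circulating factors; it is isolated behind the
`FeedbackLaw` type so an alternative functional form can replace it without
touching the network code.

## Default parameterization

All kinetic quantities are amounts-based: k_m is the amount (mmol) at
half-maximal velocity; no volume scaling occurs inside flux laws.  Blood
volume (5 L), body weight (70 kg) and the ester molar mass (176.212 g/mol,
C₈H₁₆O₄) convert doses (mg/kg → mmol) and blood amounts to concentrations.
Transit constants follow fasted-state physiology (gastric emptying ≈ 2.8/h,
small-intestinal segments ≈ 1.2–1.5/h, colon 0.3/h).  The remaining rate
constants and capacities are the package's own calibrated plausible values
(provenance-tagged `literature`/`scaled`/`estimated`/`fixture-default` in
`data/fixture_default.json`), chosen once so that the default model
reproduces the qualitative behaviour the system is known for:

- an endogenous baseline of ≈ 0.16 mM blood BHB, below the 0.5 mM normal
  ceiling and above the assay LLOQ;
- a single early post-dose peak (≈ 1.5 mM at 1.1 h for 192 mg/kg; ≈ 5.8 mM
  at 1.6 h for 573 mg/kg), with superlinear dose–exposure;
- upper-proximal passive diffusion as the dominant early absorption route,
  negligible lower-proximal transport, and carrier capacity concentrated in
  the distal segments;
- a larger fractional exposure contribution of active transport and of the
  distal gut at the high dose.

Two couplings matter for that last, dose-dependent property and were the
main calibration levers: hepatic MCT1 export to blood must not be
capacity-limiting at the high dose (otherwise systemic exposure is pinned at
the export ceiling and all knockout fractions collapse at high dose), and
the endogenous baseline plus feedback de-suppression dilute low-dose
fractions more than high-dose ones.  Gut MCT1/MCT4 are parameterized as
genuinely high-capacity carriers (large V_max with large k_m), with SMCT1
supplying the small high-affinity component that saturates early.

## Simulation

Stiff integration uses LSODA with an analytic Jacobian assembled alongside
the right-hand side; default tolerances rtol 1e-8, atol 1e-10 mmol
(halving both moves the 6-h AUC by < 0.1%, verified in the tests).  Rate
laws clip amounts at zero so sub-tolerance negative excursions cannot feed
back into the dynamics; the Jacobian is one-sided at the clip boundary.
Baseline equilibration integrates the undosed system in growing chunks until
max |dA/dt| < 1e-9 mmol/h over the non-sink states (cap 1000 h), then zeroes
the sink states; the steady state is unique in practice (multistart check in
the suite).  Doses deposit the converted ester amount into the upper
proximal lumen with an integration restart at each event time.  The default
output grid is 0–6 h at 0.01 h, covering the early peak; both window and
resolution are configurable.

## Knockouts and assessment

Knockout variants gate whole processes by indicator, tagged at build time so
the variant-to-process mapping is auditable in one place.  Passive variants
gate lumen-to-portal passive absorption only — transit and hydrolysis are not
absorption — and apical/basolateral variants gate the carrier steps.  Gating
is trajectory-identical to deleting the process, idempotent, and commutes
across sets.

Assessment simulates full and knocked-out models from the same equilibrated
baseline.  AUC is the linear trapezoid of total (endogenous + exogenous)
blood BHB over the full grid, with no baseline subtraction — this is what
makes near-zero and negative AUC fractions interpretable.  T_max is read off
the dense solver grid (not a sparse sampling schedule), ties broken by the
earliest time, with a warning when the maximum sits on the grid boundary.

## Calibration

The extended-least-squares objective is

    Σ (y − ŷ)²/g + ln g,    g = (a + b·y)²

summed over all (dose, time) means, with the variance model evaluated at the
observed mean y.  Evaluating g at the prediction instead makes the ln g term
reward shrinking the predictions, so the noise-free optimum is displaced from
the data-generating parameters (a ≈ 2% bias in a one-parameter experiment);
with observation-based variance the objective is an exact weighted least
squares and recovery on noise-free data is exact to optimizer precision.
Defaults a = 0.05 mM (an LLOQ-scale floor) and b = 0.1.  Observations below
the LLOQ are excluded.

Minimization is bounded Nelder–Mead on the unit cube (parameters affinely
scaled by their bounds), with the first start at the cube midpoint and
further starts drawn uniformly from a generator seeded by the problem seed.
A derivative-free method was chosen because finite-difference gradients of an
ODE-solver objective are noise-dominated near the optimum; for the small free
sets used here (1–6 parameters) the simplex search converges in a few hundred
evaluations.  Fitting simulations default to rtol 1e-6 / atol 1e-9, which
keeps a full fit in seconds while leaving recovery error far below the
reported tolerances.

Local sensitivity ranks parameters by the RMS over the curve of the
elasticity S_p(t) = (∂C/∂p)(p/C), central differences with a 1% step
(one-sided with a warning for parameters at zero).  The blood-volume
elasticity is exactly 1 in magnitude (C = A/V), a built-in correctness
anchor.

## Synthetic study generator

The generator stands in for the unpublished clinical dataset.  It emulates a
balanced two-dose design: per dose (default 192 and 573 mg/kg) it simulates
the truth curve at the sampling schedule 0, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4,
6 h (dense early points to resolve an oral-absorption peak), draws n = 8
subjects per dose as truth·(1 + ε_prop) + ε_add with ε_prop ~ N(0, 0.1²) and
ε_add ~ N(0, 0.02² mM²), censors individual draws below the LLOQ
(default 0.1 mM), and reports per-time mean, SEM and surviving n.  All draws
come from one seeded generator.  The shipped `data/synthetic_study.csv` is
the default design at seed 1.

What it does **not** emulate: subject-level random effects shared across time
points (noise is independent per sample), covariates, dropout, assay
drift, or the four intermediate dose levels of the source study.  Passing
tests therefore demonstrate internal consistency of the estimation machinery
under the stated noise model, not agreement with real clinical variability.
One statistical consequence is worth noting: because the generating model is
also the fitted model, the fraction of means lying within one SEM of the
*truth* curve concentrates near 68% (the ±1 SEM coverage identity), and only
a fitted curve — which partially tracks the realized noise — reaches higher
within-SEM fractions.

## Problem sizes in the test suite

The suite runs the full model (38 states) throughout.  The heavier checks
use: 3-parameter recovery with 5 multistarts on noise-free data; 20 seeded
replicates of a 1-parameter fit at 10% proportional noise (median-bias
check); and one 6-parameter end-to-end fit to the shipped dataset.  These
sizes keep the whole suite in a few minutes while still exercising every
code path end to end.

## Known limitations

- The gut is compartmental, not spatially continuous; transit is first-order
  (no delay kinetics), which is also why removing a proximal absorption route
  can *increase* exposure through distal re-routing.
- No inter-individual variability or mixed-effects layer; all fits are to
  mean data.
- Parameters are not globally identifiable from two mean curves; the free
  sets used in examples and tests are deliberately small and bounded.
- Acetone has no exhalation kinetics of its own beyond a first-order loss,
  and sodium is not a state (SMCT1's Na⁺ coupling is implicit in its
  affinity).
- AcAc first appears in the liver; no luminal or portal AcAc is modelled.
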