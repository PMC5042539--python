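# ketoflux

A quantitative systems-pharmacology model of gastrointestinal absorption and
catabolism of the ketone monoester **(R)-3-hydroxybutyl (R)-3-hydroxybutyrate**,
with *in silico* knockout machinery for dissecting where and how ketones are
absorbed from the gut.

Oral ketone esters raise blood d-β-hydroxybutyrate (BHB) into the therapeutic
ketosis range, but the absorption process is complex: the ester hydrolyses to
butane-1,3-diol and BHB along the gut, BHB crosses the gut wall both passively
and through monocarboxylate transporters (MCT1/SMCT1 apically, MCT4
basolaterally) whose expression rises from proximal to distal gut, and blood
BHB is shaped by saturable tissue uptake, renal loss, interconversion with
acetoacetate (AcAc) and feedback-inhibited endogenous ketogenesis.  This
package is for modellers and pharmacologists who want to explore those
mechanisms computationally — in particular by *knocking out* individual
transport processes per gut region and measuring the consequences, an
experiment that is impossible to run in people.

## The model

Amount-valued states A_i (mmol) in five components (gut lumen in four
segments plus enterocytes, portal vein, liver, systemic circulation, lumped
tissues) are connected by flux processes of four kinds:

- first-order: J = k·A
- saturable carrier transport (amounts, not concentrations):
  J = V_max·A / (k_m + A)
- saturable transport with competitive inhibition by a second substrate
  (BHB and AcAc share MCT carriers):
  J = V_max·A_i / (k_m,i·(1 + A_i/k_m,i + A_j/k_m,j))
- zero-order endogenous AcAc production under saturable negative feedback
  from circulating factors: J = R₀·(1 − I_max·S/(IC₅₀ + S))

Every process carries an indicator I ∈ {0, 1}; a knockout variant is a model
clone with the indicators of one process group set to 0.  The ten variants
(passive diffusion per segment; apical and basolateral active transport for
the three carrier-expressing segments) and their fifteen explored
combinations are built in.  Knockout influence is quantified by

    AUC_fraction = 1 − AUC_knockout / AUC_full        (blood BHB, 0–6 h)
    ΔT_max      = T_max,knockout − T_max,full

Calibration against mean ± SEM concentration–time data uses extended least
squares with a combined additive/proportional variance model, a bounded
derivative-free optimizer with seeded multistart, and local sensitivity
analysis for choosing the free parameters.  Because the clinical dataset
behind the original study is unpublished, the package ships a synthetic-data
generator that emulates the balanced two-dose design (192 and 573 mg/kg,
every subject sampled at every time point, LLOQ censoring) from the model
itself, so every workflow is runnable end to end.

## Worked example

```sh
python examples/simulate_doses.py
```

prints

```
model: 5 components, 38 states, 77 processes
endogenous baseline: 0.163 mM blood BHB
  192 mg/kg: peak 1.47 mM at 1.07 h, AUC(0-6h) 5.76 mM*h
  573 mg/kg: peak 5.75 mM at 1.59 h, AUC(0-6h) 22.50 mM*h
```

The pre-dose baseline is the feedback-limited endogenous steady state (below
the 0.5 mM normal ceiling); the low dose produces a mild single early peak
while the tripled dose raises peak exposure almost four-fold — saturable
elimination and suppressed endogenous production make the response
superlinear.  Knockout assessment (`python examples/knockout_assessment.py`)
then shows the dose-dependent absorption pattern:

```
all-active knockout (set 13): 0.23 at 192 mg/kg vs 0.30 at 573 mg/kg
distal-gut knockout (set 15):  0.49 at 192 mg/kg vs 0.60 at 573 mg/kg
```

i.e. carrier-mediated transport and the distal gut carry a larger share of
the absorbed dose at the high dose, while knocking out upper-proximal passive
diffusion mainly *delays* the peak (ΔT_max ≈ +2 h) because downstream routes
compensate.  `examples/calibrate_to_synthetic_study.py` and
`examples/sensitivity_ranking.py` demonstrate the estimation and sensitivity
workflows; a thin CLI (`ketoflux simulate|knockout|assess|fit|synth|sensitivity`)
wraps the same functions for shell use.

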