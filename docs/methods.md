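# Methods

## Model structure

Parent (unconjugated) BPA is described by flow-limited, well-stirred
compartments: venous and arterial blood, liver, fat, richly perfused and
slowly perfused lumped tissues, plus a gastrointestinal chain (stomach,
gut lumen, enterocytes). Venous and arterial blood are explicit state
variables rather than algebraic venous-equilibration expressions; the two
formulations agree in the flow-limited regime, and the explicit form makes
an i.v. bolus an exact state increment and the molar mass balance exact.
Blood and serum concentrations are treated as equal (blood:serum ratio 1,
recorded as an assumption).

Hepatic conjugation acts on the liver venous concentration:
Michaelis–Menten in the rat (Vmax from IVIVE scaling of a microsomal rate
via MPPGL and liver mass; Km fixed at the in vitro value), first-order in
monkey and human. Metabolite formation equals parent metabolism
mole-for-mole; conjugates are tracked as total BPA-c without
glucuronide/sulfate speciation.

### Gut and enterohepatic recirculation (rat)

Oral absorption is first-order gastric emptying followed by first-order
lumen-to-enterocyte uptake. Enterocyte BPA either escapes to portal blood
(`k_enterocyte_passthrough`) or is conjugated; in the rat a single
composite constant conjugates and delivers BPA-c to the systemic conjugate
pool instantaneously, while monkey/human models hold an explicit
enterocyte conjugate pool that empties first-order into systemic
circulation (basolateral MRP3-like transport).

Hepatically formed BPA-c in the rat splits at formation: 99.5% to bile,
0.5% directly systemic (the packaged value keeps the systemic bypass under
the 1% bound). Circulating conjugate is additionally excreted into bile by
a capacity-limited transporter acting on the central conjugate
concentration, so systemic conjugate recirculates. Bile passes through
three first-order transit compartments to the terminal small intestine,
where bacterial deconjugation liberates parent BPA. The liberated parent
is partitioned at the rate level: 90% re-conjugated (to the systemic
conjugate pool), 2% reabsorbed, 8% to feces unconjugated. The rate-level
partition makes the cumulative 90/10 split exact at any horizon. The
reabsorbed fraction enters venous blood directly (systemic reabsorption,
not portal): this matches the described physiology and is what sustains
the shallow serum tail that lets fat re-equilibrate by 2 h. Unconverted
terminal conjugate passes to feces in competition with deconjugation; this
fecal-conjugate route carries the ~45% of an i.v. dose that the printed
urinary (6–8%) and fecal-parent (46–49%) recoveries leave unaccounted.
Parking that remainder in slowly exchanging body pools instead was
rejected: a loop slow enough to retain 45% at 96 h cannot reach the 0.1%
daily-AUC steady-state criterion within 14 days of repeated dosing.

### Conjugate disposition

Monkey and human use one conjugate compartment; the rat adds two slowly
exchanging peripheral compartments (symmetric distribution clearances)
that prolong the circulating-conjugate terminal phase. Urinary excretion
is linear filtration on the central concentration. In the monkey a
Michaelis–Menten reabsorption flux, capped at filtration so urine flux can
never go negative, returns filtered conjugate: at high concentration the
transporter saturates and clearance approaches filtration, at low
concentration reabsorption nearly cancels filtration, producing the slow
terminal decline and a 96-h urinary recovery of ~80%. Renal reabsorption
is removed for humans. A small first-order fecal clearance (monkey)
represents minor non-urinary loss (<3% of dose).

## Parameters

Internal units are nmol, L, h; μg/L appears only at reporting boundaries
(molecular weights: d6-BPA 234.33 g/mol, native BPA 228.29 g/mol; the
models are linear at the simulated doses, so μg/L dose metrics do not
depend on which is used). Physiology uses standard reference values for a
0.25 kg rat, 5 kg monkey, 70 kg adult and 3.5 kg newborn human. The fat
partition coefficients are measured values (rat 5.0, human 3.3); other
tissue partition coefficients and all kinetic constants not printed in the
source literature are calibrated against the reported mass-balance
fractions, the 2-h fat:serum ratio, the ontogeny fold-differences and the
newborn-human steady state, and are tagged `calibrated` or `assumed` in
the YAML provenance maps. The adult-monkey hepatic first-order constant
is pinned by requiring the extrapolated newborn-human steady-state average
(1 μg/kg/day oral) to equal 0.002 μg/L.

### Ontogeny and extrapolation

Life-stage sets derive from adult sets by fixed allometric exponents
(volumes 1.0, flows/capacities 0.75, first-order rates −0.25 on the
body-weight ratio) and maturation fractions (hepatic UGT, gut-wall
conjugation, biliary MRP2) stored as CSV data. Scaling is compositional:
stage-to-stage transformations divide out the source stage's row. Hepatic
fractions were chosen so the capacity fold-differences versus the adult
equal 282 at rat PND3 (100 at PND10, 20 at PND21) and lie in 8–15 for all
infant monkey stages; because the allometric component shrinks faster than
maturation grows, the monkey fractions are not monotone in age even though
the folds are. Monkey gut fractions (0.8–0.95) are far higher than rat
pup gut fractions (0.05–0.5), encoding the much earlier GI-tract
maturation in primates that drives the species difference in infant
exposure. The monkey→human extrapolation substitutes human physiology,
rescales first-order constants by (BW ratio)^−0.25, scales clearances by
BW^0.75 and volumes by BW, and removes renal reabsorption.

## Numerics

LSODA with rtol 1e-8, atol 1e-10 nmol; conjugation is fast relative to
perfusion, so the system is stiff. Boluses are state jumps with solver
restart. The dense output grid (default 0.05 h) is refined geometrically
for ~0.6 h after each dose so that trapezoid AUCs on the grid agree with
the ODE-integrated AUC state within 0.1% even across the post-bolus mixing
spike; `dose_metrics` enforces that agreement and refines Cmax with a
local parabola. A fixed-step RK4 integrator (dt 1e-4 h over an 8-h
window) serves as an independent oracle for the stiff solver in the test
suite. Steady state under repeated daily dosing is the first day whose
serum-parent AUC changes by <0.1% relative (error if not reached in 14
days; all packaged sets reach it by day ~10). Calibration is bounded
least squares on log parameters with hinge losses for range targets and a
finite-difference step (1e-3) chosen to sit well above the ODE solver's
noise floor. Sensitivity coefficients are ±1% central differences,
one-at-a-time (perturbing a single flow intentionally ignores the
flow-balance invariant, as is standard for local sensitivity).

## Synthetic data

The generator emulates a sparse PK study: sampling at
{0.25, 0.5, 1, 2, 4, 8, 24, 48, 96} h, median-preserving multiplicative
lognormal noise (σ² = ln(1+CV²)), and LOD censoring (values floored at
the LOD and flagged). It reproduces the model's own structure, so
parameter-recovery results demonstrate identifiability under the assumed
error model only — they say nothing about structural misspecification,
inter-animal variability, or real assay artefacts. Recovery experiments
pre-screen free parameters by sensitivity (|coefficient| ≥ 0.01) and flag
the rest non-identifiable rather than fitting them.

## Choices made where the design was open

- Terminal log-linearity of serum parent is assessed over 12–24 h; earlier
  windows straddle the β-phase → recirculation-tail crossover.
- The excretion-fraction horizon is 96 h (the radiolabel collection window
  is an assumption).
- Three bile transit compartments: the minimal chain giving a distinct
  delay between biliary excretion and terminal-ileum deconjugation.
- The 2-h fat:serum ratio evaluates to 5.67 with PC 5.0: with hepatic
  extraction near the perfusion limit, serum at 2 h retains a small
  β-phase component, so the ratio sits somewhat above the partition
  coefficient; reproducing 5.0 exactly would require diffusion-limited
  fat uptake, which is out of scope.
- Problem sizes: single-dose scenarios run 96 h on ~2000 output points;
  repeated-dosing scenarios run 14 days; the recovery suite uses 20
  replicates at 5% CV.

## Limitations

No glucuronide/sulfate split, no mouse model, no pregnancy/fetal
sub-model, no diffusion-limited tissues, no plasma-protein binding, no
microbiome kinetics (deconjugation is a lumped first-order rate), no
bladder-void timing. The immature parameter sets are constrained by
capacity fold-differences and steady-state endpoints, not by infant
serum time courses, which do not exist for humans; predictions for
newborns are extrapolations.
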