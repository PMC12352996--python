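# Methods

## Scope and model overview

`henapbpk` implements a whole-body physiologically-based pharmacokinetic
(PBPK) model for henagliflozin, a selective SGLT2 inhibitor cleared almost
entirely by glucuronidation (UGT1A9 > UGT2B7 > UGT1A3) with a small
oxidative (CYP3A4-family) contribution and ~2–3% renal excretion of
unchanged drug. On top of the PK engine sit: virtual-population builders
(reference East Asian adult, Child-Pugh hepatic impairment, ICH pediatric
subgroups with enzyme ontogeny), an empirical Emax exposure–response model
for 24-h urinary glucose excretion (UGE), model-qualification statistics
(FE/AFE/AAFE/AAPE with fold-band classification), local and global
sensitivity analysis (one-at-a-time, Morris, EFAST), exposure-matched
pediatric dose selection, and a synthetic "observed data" generator that
emulates digitized clinical profiles so the qualification and fitting
pipelines are testable without any external data.

## PBPK structure

Sixteen perfusion-limited tissue compartments (lung, brain, heart, kidney,
muscle, adipose, skin, bone, gonads, stomach, small and large intestine,
spleen, pancreas, liver, rest-of-body) are connected through arterial,
venous and portal blood pools; the lung sits in series between the venous
and arterial pools. The gut lumen carries six states (solid and dissolved
drug in stomach, small and large intestine) and terminal sinks collect
urine, feces and one metabolite pool per enzyme pathway (31 states total).
Each organ is a single well-stirred compartment; intra-organ subcompartment
gradients (vascular/interstitial/cellular) are deliberately lumped, which
is accurate for plasma PK of a perfusion-limited small molecule but places
intra-tissue concentration profiles out of contract.

The system is linear in the state. Amounts are integrated as fractions of
one dose, which makes solver tolerances scale-free and renders dose
proportionality exact by construction (useful as a structural check, and
consistent with the clinically observed dose-proportional exposure).

### Absorption

Dissolution follows a Weibull cumulative curve whose median is the tabulated
"time to 50% dissolved" (87 min) with shape 1.70, implemented as a
time-since-dose hazard applied to lumen solid in all segments and restarted
at each administration (residual solid from earlier doses is negligible at
once-daily dosing because the dissolution median is ~1.5 h). Gastric
emptying is first-order (fasted half-scale 0.25 h; a 1000 kcal meal doubles
the emptying time — the only fed-state effect modeled). Dissolved drug is
absorbed from the small intestine with ka = 2·Peff/r (r = 1.25 cm), giving
3.9 h⁻¹ at Peff = 6.7e-4 cm/s, and from the colon at a quarter of the
small-intestinal surface efficiency. Unabsorbed material transits to the
feces sink. The fraction absorbed emerges from dissolution, transit and
permeability rather than being imposed; the default parameterization
absorbs ~95% of an oral dose, which is higher than the ~50% fecal recovery
reported in mass-balance studies — the engine reports the simulated fecal
fraction rather than forcing agreement (the mechanism behind the reported
fecal fraction, e.g. biliary excretion of parent, is not modeled).

### Distribution

Tissue:plasma partition coefficients use the composition-based
Poulin–Theil equations: the solvency ratio of tissue to plasma computed
from water, neutral-lipid and phospholipid fractions with P = 10^logP
(vegetable-oil scale, log D = 1.115·logP − 1.35, for adipose), corrected by
fu_p/fu_t with fu_t = 1/(1 + 0.5(1−fu_p)/fu_p) for non-adipose tissues and
fu_t = 1 for adipose. At fu = 0.05 this places muscle Kp (≈1.6) above
adipose Kp (≈0.4) — the binding correction dominates the lipid solvency for
a highly bound, moderately lipophilic compound. Bone composition is that of
perfused cortical/trabecular tissue without marrow fat; including marrow
lipid in a perfusion-limited lumped model would credit the skeleton with a
large, rapidly accessible lipid depot it does not have. The resulting
steady-state distribution volume is ~82 L (plasma-referenced).

### Metabolism and excretion

Liver and kidney metabolism is well-stirred: elimination rate
fu_b·CLint·C_out with fu_b = fu/(B:P). Whole-organ intrinsic clearances
come from the in vitro values via microsomal protein scaling (40 mg/g
liver) for UGTs, via the enzyme reference concentration (4.32 µmol/L
liver) for the lumped CYP pathway, and a fixed 90:10 liver:kidney split of
UGT capacity anchored at the reference anatomy. Renal excretion is
filtration of unbound drug, gfr_fraction (0.70) × GFR × fu.

**IVIVE calibration.** Direct microsomal scaling of the tabulated intrinsic
clearances yields a reference-adult plasma clearance of ~11.7 L/h and a
terminal half-life of 5.4 h, well below the clinically reported 9.1–14.0 h.
A single empirical in-vitro-to-in-vivo scaling factor of 0.40, applied
uniformly to all metabolic pathways (preserving the fraction-metabolized
split), was calibrated once against the reported half-life; the calibrated
model gives t½ = 11.3 h, CL ≈ 5.4 L/h, and steady-state exposure within
the conventional twofold acceptance band of the published adult operating
point (Cmax,ss 53.6 vs 88.1 ng/mL; AUC_ss 787 vs 592 ng·h/mL at 5 mg once
daily). This plays the same role as the original model's Monte Carlo
parameter optimization against clinical profiles. The simulated time of
peak (~3 h) is later than the observed 1–2 h window; a lumped
perfusion-limited model distributes faster than one with cellular
permeability barriers, flattening the peak — this is the known cost of the
lumping decision and is tracked as a soft property, not an error.

### Retrograde clearance translation

Given a clearance budget (pathway fm values and a total plasma clearance
target), the well-stirred equation is inverted per organ:
fu_b·CLint = Q·CL_b/(Q − CL_b). Renal clearance is fixed mechanistically at
gfr_fraction·GFR·fu and the metabolic fm values are renormalized onto the
remainder (the published fractions sum to ~0.99; the residual allocation is
not stated, so proportional renormalization is used). The kidney share of
each UGT pathway is anchored through the liver inversion via the 90:10
split, leaving a <2% residual in the recovered total. The forward
round-trip (simulate, then recover fm from pathway-resolved elimination)
agrees with the budget elementwise within 0.01; the residual distortion is
hepatic first-pass extraction (~10%), which gives hepatic pathways a
slightly larger share of an oral dose than their systemic clearance share.

## Virtual physiology

The reference individual is a 30-year-old East Asian male (63 kg, 170 cm,
cardiac output 340 L/h) with ICRP-style organ volumes and flow fractions
(packaged as CSV). Age scaling uses sex-specific growth tables (East Asian
anthropometry), organ-specific age factors for brain, liver, kidney, muscle
and adipose (organs deviating from weight-proportionality in childhood),
allometric cardiac output (W^0.75) with organ flows preserving reference
specific perfusion and renormalized to cardiac output, and GFR maturation
as a Hill function of postmenstrual age (TM50 47.7 weeks, slope 3.4) on a
BSA-normalized adult value of 110 mL/min.

Enzyme ontogeny uses Hill functions of postmenstrual age (UGT1A9: TM50 60
wk, slope 3; UGT2B7: 50 wk, 2.5; UGT1A3: 55 wk, 3; CYP3A4: 60 wk, 2),
literature-informed stand-ins for proprietary ontogeny databases, all
exposed in configuration. Factors are clamped to exactly 1 from age 18.
Plasma-protein ontogeny scales fu through an albumin factor
(fu = 1/(1 + alb·(1−fu_ref)/fu_ref)); neonates start at alb ≈ 0.75.

Hepatic impairment applies the Child-Pugh scaler table exactly as
published: portal, hepatic-arterial, renal and other-organ flow fractions
(brain unchanged), liver volume fraction, hematocrit, albumin/AGP factors,
enzyme reference-concentration multipliers (CP-A keeps UGT factors at 1, as
printed, despite being biologically surprising) and a GFR fraction. Cardiac
output is recomputed as the post-scaling systemic flow sum (hyperdynamic
circulation). Exposure at 20 mg rises strictly healthy → CP-A → CP-B →
CP-C because hepatic capacity (liver volume × enzyme factors) falls faster
than the unbound fraction rises.

Population sampling: deterministic sex split (floor(n·ratio) females),
uniform ages within the subgroup range (the generating age distribution is
not reported; uniform is the least-informative choice), and mean-1
lognormal variability with default CVs of 12% on weight, 20% on organ
volumes and flows (renormalized to a perturbed cardiac output), 20% on GFR
and 30% on enzyme expression. The reported population spreads are published
only as summary SDs, not generating CVs; these defaults produce comparable
dispersion (e.g. adult AUC_ss CV ≈ 27% vs the published 25%).

## Exposure–response (UGE)

E = Emax·X/(EC50 + X) with the clinically determined parameter pairs:
Emax 48.8 g / EC50 62.0 ng/mL on the Cmax,ss scale and Emax 48.2 g /
EC50 356 ng·h/mL on the AUC_ss scale. Population summaries apply the
transform per individual before averaging (the concave transform makes
this differ from transforming the mean; published operating-point tables
are mean-level and are reproduced exactly at the mean). Whether the
published UGE SDs are per-individual or delta-method is not stated;
per-individual SDs are reported here. No covariate effects on Emax/EC50:
the adult exposure–response is assumed to transfer to children, a
limitation inherited from the source analysis (renal glucose thresholds
may differ in young children).

## Qualification metrics

FE = predicted/observed; AFE = 10^(mean log10 FE); AAFE = 10^(mean |log10
FE|); AAPE = mean |pred−obs|/obs. AAPE is stored as a fraction and printed
as percent (the published tables mix conventions for urine-recovery rows).
Fold bands are inclusive on the favorable side ([0.8, 1.25] strict band,
[0.5, 2] twofold band, both AFE and AAFE must qualify); AAPE bands are
<20% satisfactory (strict), 20–50% acceptable, ≥50% poor. Observations at
or below the quantification limit are excluded with a count (the metrics
are undefined at observed = 0) rather than imputed.

## Dose selection

`recommend_dose` picks, for one adult reference, the candidate dose
minimizing |log(AUC_ss geometric-mean ratio)| with ties to the lower dose.
`recommendation_table` additionally enforces dose-scaling consistency:
because the PK is dose-linear in every population, the exposure ratio
depends only on the candidate/reference dose factor, so one factor is
selected per group (minimizing the mean |log ratio| across the adult
references) and applied to all references, falling back to per-reference
selection when the factor-mapped dose falls outside the twofold window.
The consistency rule is what reproduces the published infant mapping
(1.25 mg ↔ adult 5 mg therefore 2.5 mg ↔ adult 10 mg) even though the
infants' supra-linear exposure makes 1.25 mg numerically closer to the
adult 10 mg operating point; the fallback recovers the published neonate
choice (1.25 mg for adult 10 mg, outside the twofold window, flagged).

## Sensitivity analysis

Local: central-difference normalized coefficients at baseline (default
±10%). Morris: p = 4 levels, step δ = p/(2(p−1)), r = 10 randomized
trajectories by default; μ* = mean |elementary effect| in unit-hypercube
coordinates, σ = SD of effects. EFAST: Saltelli's extended FAST with
interference factor M = 4, N = 257 points per curve, 2 random-phase
resamples; S_i from the M harmonics of the driving frequency, S_Ti as one
minus the low-frequency (complementary) variance share. Both methods
recover closed-form indices on linear and pure-interaction test functions
(additive-linear S_i to ±0.05 at these budgets). Default parameter ranges
are ±50% on a linear scale (log scale for clearances); sensitivity runs use
a single representative individual per age group to keep budgets at desk
scale. A structural note: because renal excretion is only ~2% of total
clearance, GFR cannot rank among the top drivers of AUC in this model —
UGT expression and gastrointestinal transit dominate, with perfusion of
non-eliminating organs (e.g. brain) structurally inert.

## Synthetic observed data

The generator reproduces the statistical structure of digitized clinical
profiles: per-subject multiplicative lognormal residual error with median 1
(log-SD √ln(1+CV²)), default LLOQ 0.5 ng/mL with censoring flags, seeded
and byte-reproducible, study labels namespaced `synthetic:`. The default
suite mirrors the clinical design space (single doses 2.5–200 mg fasted,
once-daily 1.25–100 mg, fed variants). What it does not emulate: real
digitization error, inter-study heterogeneity in analytical methods,
between-subject PK variability within a study arm (noise is residual-only
around the reference-individual profile), or model misspecification — so
null-calibration results (AFE → 1, AAFE → analytic lognormal expectation)
validate the metric pipeline, not the model's fidelity to real data.

## Numerical choices and problem sizes

LSODA with analytic Jacobian; default tolerances rtol 1e-8 / atol 1e-10 on
dose-normalized states with a 0.1 h output grid for single-individual
runs; population and sensitivity runs use rtol 1e-6 / 0.25 h, which changes
summary exposures by <0.1%. Mass balance closes to machine precision by
construction and is asserted to 0.1% of dose. Terminal half-life is fitted
log-linearly on the final declining segment, starting from the last five
points and extending backwards until two estimated half-lives are spanned.
Steady state is declared when consecutive interval AUCs agree within 1%
(the default adult reaches it in 4 daily doses; neonates, with the longest
half-life, within ~10). Exposure summaries simulate 14 once-daily doses so
every subgroup is at steady state. Populations of n = 100 per subgroup
(50% female) are the standard study condition; the random-search fitter
uses budgets of 100–500 evaluations on coarse grids. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`.

## Known limitations

- Plasma-profile shape near the peak is flatter than observed (lumped
  perfusion-limited distribution); Cmax-based quantities inherit a low
  bias within the twofold band.
- Fecal recovery of unchanged drug is under-predicted (see Absorption).
- Ontogeny curves and population CVs are literature-informed defaults, not
  the (unpublished) values behind the original analysis; pediatric
  absolute exposures should be read as order-of-magnitude consistent
  (means fall within ~1.7-fold of the published pediatric table) with the
  ordering and dose-mapping structure robust.
- No enterohepatic recirculation, metabolite kinetics, transporter-mediated
  renal secretion, saturable metabolism, or disease effects beyond the
  Child-Pugh scalers and the T2DM age-range shift.
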