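# Methods

`dmpkit` implements the computational half of a small-molecule DMPK study
of an NAMPT-inhibitor drug candidate (Daporinad / FK866, C24H29N3O2): the
exact-mass reasoning that turns an accurate-mass peak list into a
metabolite characterization table, the bioanalytical statistics behind a
fit-for-purpose LC-MS quantification assay, and the non-compartmental
analysis of IV-bolus mouse pharmacokinetics. This note records the models,
the defaults and why, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Exact-mass arithmetic

Monoisotopic atomic masses are pinned constants (H 1.00782503207, C 12
exactly, N 14.0030740048, O 15.9949146196, plus S, P, Cl, F, Na, K) so
results are bit-reproducible with no external lookup. The protonated
adduct uses the proton mass 1.00727646 Da (electron-corrected), not the
hydrogen-atom mass; this is what reproduces the study's 4-decimal m/z
table exactly. Internal arithmetic keeps full double precision; reported
m/z rounds half-up to 4 decimal places. ppm error is signed:
`(obs - theo)/theo * 1e6`.

Formula strings are parsed after stripping whitespace and underscores, so
subscript-mangled renderings (`C_16_H_23_NO_2_`) can be pasted verbatim
into fixtures. Parsing rejects unknown element symbols and malformed
tokens with a message naming the offender.

## Biotransformation chains and annotation

The default rule set is the phase-I chemistry observed for this scaffold:

| rule | delta | max multiplicity | category |
| --- | --- | --- | --- |
| oxidation | +O | 3 | oxidative |
| desaturation | −H2 | 2 | desaturative |
| saturation | +H2 | 1 | reductive |
| amide hydrolysis | −C8H5NO | 1 | hydrolytic |
| amide hydrolysis → carboxylation | −C8H8N2, +O | 1 | hydrolytic |
| amide hydrolysis → hydroxylation | −C8H6N2 | 1 | hydrolytic |

Chain enumeration takes all multisets of rule applications up to
`max_steps = 3` (tri-oxidation is the deepest observed chain),
prunes chains whose net formula would go negative, deduplicates by net
element delta keeping the fewest steps (so saturation + desaturation
collapses onto the parent), and sorts by theoretical m/z. Annotation
accepts every chain within `tol_ppm = 5` of a peak and ranks candidates by
(fewer steps, then smaller |ppm|); all survivors are kept, never silently
dropped. 5 ppm was chosen because the study instrument's observed errors
are all ≤ 2.8 ppm, and 5 ppm leaves headroom without cross-talk between
candidate masses on this scaffold. Positional isomers (the five
mono-oxidation peaks, for example) are deliberately distinguished only by
retention time: the engine assigns the same chain to each and lets rt
label them.

## Moiety localization

Daporinad cleaves at its amide bond into two diagnostic fragment series:
the 4-butylpiperidine ("amine side") ions at m/z 261.1961 (C16H24N2O + H),
244.1696 (−NH3) and 140.1434 (C9H17N + H), and the pyridine-acryloyl
("acyl side") ions at 132.0444 (C8H5NO + H), 105.0335 (−HCN) and 104.0495
(−CO). These are stored as formulas with moiety tags; m/z is derived.

`localize` brute-forces every partition of a chain's steps between the two
moieties, predicts each template fragment shifted by the mass of the steps
assigned to its moiety, and scores the partition by how many predictions
are observed within `frag_tol_mda = 10` (fragments are published at 2
decimal places, so 10 mDa is the natural matching window). The
best-scoring partition's pattern (amine_side / acyl_side / both) is
returned; ties between conflicting patterns, or a best score below two
matched fragments, yield `unlocalized`. For chains of ≤ 3 steps this
count-partition search is provably equivalent to enumerating every
per-step assignment, which the test suite checks against an independent
brute-force oracle. Amide-cleavage chains lose the acyl moiety entirely,
so the template logic does not apply and they come out unlocalized by
construction.

## TiCl3 N-oxide differential

TiCl3 reduces an N-oxide back to its parent amine. The detector takes
paired control/treated peak lists and, for every annotation containing at
least one oxidative step, requires two pieces of evidence:

1. **drop** — the annotation's peak retains at most
   `1 − drop_fraction` (default 20%) of its control intensity under
   treatment;
2. **gain** — summed intensity at the reduced-partner mass
   (m/z − 15.9949) increases under treatment, searched within the rt
   window (default 0.2 min) around the annotation's own rt and around the
   parent's rt.

Both thresholds are design choices, not published values: the study
reports the outcome of the test but no quantitative intensity criterion.
`drop_fraction = 0.8` is conservative against run-to-run intensity
variability, and "gain" means any increase because the reduction yield is
unknown. Non-oxidative annotations are `untested`; an annotation with no
matching control peak is `untested` with a warning. Running the detector
with control = treated yields zero flags regardless of thresholds.

## Calibration and qualification statistics

The response model is `ratio = a·x² + b·x + c` fitted by weighted least
squares with weights 1/x² (x = nominal concentration — weighting by
nominal, not fitted, concentration). The reported correlation coefficient
is the Pearson correlation between observed and fitted ratios; it equals 1
in the noiseless case and is the conventional figure of merit on
bioanalytical reports. The qualified range is [min, max] of the fitted
levels, by default the study's 1.02–2220 ng/mL.

Back-calculation inverts the quadratic and keeps the real root in
[0, 2·ULOQ], preferring the root inside [LLOQ, ULOQ] when two qualify;
anything still ambiguous raises rather than guessing. Results below/above
the range are flagged BLQ/ALQ without clamping, and the dilution factor
multiplies the in-assay concentration.

Accuracy is mean(measured)/nominal × 100; precision is the sample (n−1)
CV. The acceptance band is ±25% at every level including the LLOQ (the
study applies one uniform fit-for-purpose criterion). Intra-run statistics
are computed per run and level; inter-run pools all replicates of all
runs. Dilution-integrity and stability assessments reuse the same
arithmetic grouped by dilution factor or storage-condition label
(condition labels are free text). Reported percentages round to 3
significant figures; note that 6220/6670 = 93.25% prints as 93.3 under
round-half-up, one digit above the truncated value on the original report.

## Non-compartmental analysis

Linear trapezoid throughout (not log-down): the simplest defensible
reading of a generic NCA configuration. λz comes from OLS of ln(conc) on
time over candidate terminal windows (last k points, k ≥ 3, Tmax excluded,
zeros dropped), selecting the window with maximal adjusted R², ties broken
toward more points; a window with no decline is skipped, and if no window
has a negative slope the terminal phase is undefined and the computation
errors loudly. For IV bolus the AUC from 0 to the first sample uses
log-linear back-extrapolation of C0 from the first two positive
concentrations (configurable off). BLQ handling: leading BLQs set to 0,
trailing BLQs dropped. Then

    AUC_inf  = AUC_last + C_last/λz
    AUMC_inf = AUMC_last + C_last·t_last/λz + C_last/λz²
    CL = Dose/AUC_inf,  MRT = AUMC_inf/AUC_inf,  Vss = CL·MRT

with dose in mg/kg converted to ng/kg, giving CL in mL/min/kg and Vss in
mL/kg. CL uses AUC_inf (the WinNonlin convention). Dose proportionality
reports dose-normalized AUC ratios between consecutive dose levels
(supra-proportional above a 1.25 threshold) plus the power-model exponent
from OLS of ln(AUC) on ln(dose).

Hamilton pooling assigns each time point a plasma volume proportional to
its trapezoidal time weight (half the span of the neighbouring intervals,
half-intervals at the ends), normalized to 1. The contract — and the
test — is the identity pooled concentration = AUC_last/(t_last − t_first)
for any profile; the original reference describes the principle (pooled
concentration proportional to AUC) rather than a formula, and the
trapezoid weights are the unique linear rule with that property on an
arbitrary grid.

## Synthetic-data generators

All noise is multiplicative lognormal with mean 1 and a specified CV
(concentrations and intensities are positive; additive Gaussian noise was
rejected because it can go negative). Every generator takes a seed;
identical configuration means byte-identical output.

* **Calibration batches** — duplicate standards at the study's eight
  levels (1.02–2220 ng/mL) and triplicate QCs at 15.0/165/1820 ng/mL from
  a quadratic forward model (a = −3·10⁻⁷, b = 3·10⁻³, c = 2·10⁻³ — a
  gently saturating curve whose vertex lies safely above the ULOQ, with
  area ratios of order 10⁰ at the top level) with 5% CV noise by default.
* **PK profiles** — two-compartment IV-bolus curves, per-unit-dose
  macro-constants A = 900, B = 230 ng/mL per mg/kg and α = 0.08,
  β = 0.0131 min⁻¹ (β chosen to give the observed ≈53 min terminal
  half-life; A, B scaled so Cmax and exposure magnitudes match the 5 mg/kg
  group), sampled at the study grid 2–420 min, 10% CV noise, doses
  5/10/30 mg/kg × 3 subjects. A saturable mode shrinks β above a 10 mg/kg
  threshold (β·(10/dose)^0.7), reproducing supra-proportional AUC at the
  top dose while Cmax stays dose-proportional.
* **Peak tables + MS2** — each entry of the shipped ground-truth table
  becomes a peak at its theoretical m/z with Gaussian ppm jitter
  (σ = 1.5 ppm, the observed mass-accuracy scale) at its reference rt;
  fragment spectra are the template shifted by the truth's moiety
  partition. Relative intensities are arbitrary fixed values (the study
  reports none); no result depends on them. In the TiCl3 table each
  N-oxide keeps 5% of its intensity and a reduced partner (one oxygen
  lighter, 90% of the lost intensity) appears at the parent's retention
  time. Placing the partner at the parent's rt is a simplification: the
  reduction happens in solution before injection and the product's true
  elution position is species-specific and unknowable without standards.

The shipped reference table (`data/daporinad_metabolites.csv`) carries
both the published formula column and a corrected one: three rows'
published formulas are internally inconsistent with their own m/z and
transformation name (the hydrolysis product at 261.1961 matches C16H24N2O,
and the two di-desaturation rows at 388.2020 match C24H25N3O2); the m/z
and transformation name are treated as authoritative and the `note` column
records each correction. The table's m/z column is demonstrably
theoretical (it reproduces from the formulas at 4 dp), whereas its ppm
column refers to unprinted observed masses and is therefore not
reproducible; nothing asserts against it.

What the generators do **not** emulate: chromatographic peak shape and
integration, isotope envelopes, matrix effects, in-source fragmentation,
inter-animal PK variability structure beyond i.i.d. lognormal noise, and
realistic metabolite abundance ratios. Passing tests therefore demonstrate
the correctness of the arithmetic and decision logic on idealized inputs,
not robustness to raw-data artefacts.

## Problem sizes and sampling designs used in tests

The stochastic parameter-recovery test for CL runs 10 seeds × 3 subjects
at 10% noise on a rich 2-min sampling grid, where the trapezoid
estimator's own bias is negligible and recovery within 5% is a property of
the estimator. On the study's sparse 7-point grid the linear trapezoid
systematically overestimates a bi-exponential AUC by ≈9% (segments up to
3 h wide against a ≈53 min half-life); that bias is real, inherent to the
design, and covered by its own test asserting monotone error growth as the
grid is thinned (dense → 14-point → 7-point). Group means of per-animal
parameters on the sparse grid consequently cannot be matched to a few
percent by any trapezoid-based reimplementation without the raw
concentrations, which are not published.

## Known limitations

* Only the [M+H]+ adduct is built in; other adducts are pluggable via
  `AdductSpec` but unexercised. No isotope-pattern simulation.
* Phase II conjugates (glucuronide, GSH) are absent from the default rule
  set — the study found phase-I metabolism only — but the rule set is
  data, not code, and can be extended via JSON.
* The N-oxide differential depends on thresholds the original experiment
  never quantified; on real data the `drop_fraction` should be tuned to
  the assay's intensity repeatability.
* Structure elucidation stops at moiety-level localization; no SMILES or
  atom-level reasoning.
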