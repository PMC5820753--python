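# Methods

## Scope and model

`racemkit` predicts second-order rate constants k_gb (M⁻¹ s⁻¹) for
general-base-catalyzed racemization of stereogenic C–H centers, and converts
them into physiological half-lives and fractions racemized. The mechanistic
picture is S_E1: rate-determining deprotonation of the single α-H by a
buffer base to a planar (or configurationally unstable) carbanion, followed
by non-stereospecific reprotonation. Everything downstream assumes
first-order loss of enantiomeric excess, ee(t) = ee(0)·exp(−k_obs t), so
"fraction racemized" means 1 − ee(t)/ee(0) and the half-life is the time
for the ee to halve. k_gb throughout is the ee-loss rate constant, not the
single-molecule enantiomerization constant (which is half of it); this
convention is what reproduces the physiological percent-racemized figures.

Quantum-chemical deprotonation energies are *inputs*; the package never
runs electronic-structure calculations.

## Stereocenter perception and substituent typing

Candidates are carbons with exactly one hydrogen (implicit + explicit) and
four mutually distinguishable branches, found with RDKit's potential-
stereocenter perception (`FindMolChiralCenters` with unassigned centers
included, non-legacy implementation). Drawn stereochemistry is deliberately
ignored: the risk belongs to the center, not the depiction, and input
dialects differ in whether wedges survive.

Substituents are classified by an ordered rule list
(`data/substituent_patterns.json`), each rule a *single-atom recursive
SMARTS* matched against the neighbor atom as seen from the center. The
single-atom form matters: multi-atom SMARTS lose symmetric ring matches to
substructure-match uniquification, which silently mislabels one of two
equivalent aryl attachments. First match wins; order is specificity-first
(thiourea-type nitrogen before generic N-thioamide; imide nitrogen before
amide nitrogen; acid before ester before ketone on carbonyl carbons). A
neighbor matching nothing is labelled `other` with rule id `fallback`. The
`alkyl` rule excludes halogen-bearing sp³ carbons, so perhalogenated groups
like CF₃ — electronically nothing like an alkyl — fall through to `other`
rather than being misscored.

Ring substituents contribute both ring neighbors separately (a hydantoin C5
sees the ring through an N-linked amide on one side and a C-linked amide on
the other). Two naming conventions carry real chemistry: a *reversed*
secondary amide is attached through the N of R–NH–C(=O)–R′ (inductive
stabilizer, non-delocalizing), an *acidic* secondary amide through the
carbonyl carbon of –C(=O)–NH– (π-acceptor, delocalizing). The
`aminothiooxo_imide` type is interpreted as a nitrogen bonded to a
thiocarbonyl carbon that carries a second nitrogen (the N1 of a
2-thiohydantoin); the generic N-linked thioamide rule catches the rest.
The full published substituent taxonomy is far larger than the shipped
~16 rules; user pattern files with the same JSON schema extend or replace
the built-ins, applied strictly in file order.

The center-type catalogue (`data/center_types.json`) maps unordered label
triples to the letter codes A–N; anything else is `unclassified`.

## Aromatic-anion assessment

Centers whose conjugate carbanion is a cyclic aromatic anion racemize on a
separate, steeper calibration line. The default decision is a Hückel count
on each ring of size ≤ 6 through the center: the carbanion contributes one
electron pair; each endocyclic double bond contributes a pair; a ring atom
with only an exocyclic double bond (a ring C=O carbon) contributes an empty
p orbital (0 electrons); a saturated N/O/S contributes a lone pair; a
saturated ring carbon other than the center breaks conjugation and vetoes
the ring. A total of 4n+2 electrons marks the anion aromatic. This
correctly marks cyclopentadienide (6 π) and hydantoin-5-yl anions
(carbanion pair + two N lone pairs + two carbonyl carbons = 6 π) as
aromatic, and glutarimide-type centers (sp³ CH₂ in the ring) as not.
Because the heuristic cannot capture every subtlety (e.g. strongly twisted
rings), a per-center-type override map in `data/center_types.json` wins over
the heuristic; it ships empty.

## Group-contribution score

ΣΔΔG sums the three per-substituent contributions ΔΔG(R,H,H) (kcal/mol,
negative = carbanion-stabilizing). Cross-conjugation correction, mode
`scale_all_but_strongest` (default): if ≥ 2 substituents carry the
`delocalizing` flag, the most negative keeps full weight and every other
delocalizing contribution is multiplied by a factor in [0,1], default 0.5;
non-delocalizing contributions always count in full. Ties for "strongest"
are broken lexicographically by type label, which does not change the value
(the corrected sum is factor·Σ_deloc + (1−factor)·min_deloc) but keeps the
bookkeeping deterministic. The correction reduces to the plain sum at
factor = 1 or mode `none`, and the corrected sum is monotone in every
individual contribution — both property-tested.

The shipped per-type table is *provisional*: placeholder magnitudes in a
chemically sensible order (π-acceptors strongest, alkyl weakest), flagged
`provenance=provisional`, present so the structure pipeline runs end to
end. Quantitative structure-level screening requires loading a computed
table. No quantitative claim in the tests or the acceptance script depends
on these placeholder values; all calibrated predictions take ΣΔΔG (or QM
ΔΔG) directly.

## Calibration lines and refitting

Three fixed lines map energy to log₁₀ k_gb (see README table). Prediction
uncertainty is multiplicative: bounds k·10^±RMSE; the QM line's RMSE of
0.61 log units is the "factor of ≈4". Refits use ordinary least squares
(scipy); when `aggregate_by_class` is set, all points sharing a class label
are first collapsed to their (mean x, mean y) so a heavily replicated
center type cannot dominate the slope — duplicating class members is then
provably a no-op, which is tested. Points flagged `excluded` (e.g. a
compound with unusable experimental uncertainties) never enter a fit; the
flag is a data attribute, never a hard-coded compound name. RMSE uses
denominator n (`rmse_ddof=0`), the common convention in QSPR reporting;
configurable. R² is the ordinary coefficient of determination.

The Hammett utility fits log k against user-supplied σ and σ⁻ and reports
both slopes (ρ) and R²; the better-correlating scale is flagged, with ties
going to σ⁻ (with a warning). No constant tables are shipped — σ values are
reference data, not package substance.

## Kinetic analysis chain

- **Trace fits.** `cd_decay`: y = baseline + amplitude·e^(−kt);
  `hd_exchange`: y = plateau·(1 − e^(−kt)). Nonlinear least squares
  (scipy `curve_fit`) with k bounded ≥ 0 and analytically seeded initial
  guesses (log-linear regression on the baseline-subtracted signal), so
  convergence is reproducible; the k standard error comes from the fit
  covariance. Non-convergence raises an error carrying the initial guesses.
- **Hydrolysis correction.** Parallel first-order channels subtract:
  k_rac = k_obs − k_hyd. A negative difference within the combined reported
  SEs floors at 0 with a warning; beyond it, the inputs are inconsistent
  and the call raises.
- **Buffer-dilution plots.** OLS of k_obs vs [base]; slope = k_gb,
  intercept = buffer-independent background. A negative slope is returned
  with a warning flag, never silently clipped.
- **Normalization.** Arrhenius temperature transfer
  k·exp((Ea/R)(1/T_obs − 1/T_ref)) with R in kcal/(mol·K), and
  protonation-state scaling k/f_reactive for substrates only partly in the
  deprotonatable form. These serve lab-data normalization; the
  physiological prediction pipeline applies *no* temperature correction —
  the calibration is used as-is, which is the configuration that reproduces
  the published physiological percentages.

## Physiological scenario

Blood is modelled as a 0.15 M total phosphate buffer at pH 7.2. Phosphate
pKa₂ defaults to 6.80 (its value at physiological ionic strength rather
than the thermodynamic 7.21), giving [HPO₄²⁻] = 0.15/(1+10^(6.80−7.2)) ≈
0.1073 M by Henderson–Hasselbalch with a single relevant ionization.
Exposure defaults to 24 h at 310.15 K. Risk classes bucket the 24 h
fraction racemized: < 1% low, 1–10% medium (upper bound inclusive), > 10%
high; thresholds are configuration.

## Synthetic data

Generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`, and every fitting pathway is tested against
them. Decay traces use log-spaced times over [0, 5/k] with a t = 0 anchor
(dense early sampling where an exponential carries its information) and
additive Gaussian noise, the standard observational model for CD
ellipticity. Buffer series use *homoscedastic* Gaussian noise with sd equal
to a stated fraction of the series' mean clean k_obs: the OLS analysis
these series feed assumes equal variance, and a proportional-noise option
(`relative_noise=True`) exists separately for stress-testing
heteroscedastic data. Calibration datasets draw class centers uniformly
over ΣΔΔG ∈ [−75, −35] kcal/mol (the occupied region of the rate/energy
plots) with members offset by ±0.5 kcal/mol and Gaussian scatter in log k.

What the generators do *not* emulate: instrument drift and baseline
wander, correlated residuals, non-exponential (biphasic) decays from
competing reactions, and speciation of polyprotic buffers beyond one
ionization. Passing recovery tests therefore demonstrates correctness of
the estimators under their stated model, not robustness to every real
trace.

## Problem sizes and numerical choices

Default test problem sizes: 40–50-point traces, 6-concentration buffer
series, 12-class/2-member calibration sets; replicate counts 200 (bias
checks) and 500 (slope-recovery rate), chosen to make stochastic assertions
stable at comfortable margins. Noiseless round-trips are asserted to 1e−9
relative; line refits to 1e−10 absolute; the closed-form ee decay is
checked against numerical ODE integration to 1e−8 relative. Exponential
fits enforce k ≥ 0 via bounds rather than post-hoc clipping. Fraction
computations use `expm1` to stay accurate for very slow rates.

## Known limitations

- Only carbon stereocenters with exactly one H; no stereocenters at
  heteroatoms, no atropisomers, no 3D/conformer effects, no tautomer
  enumeration (a SMILES drawn as a non-reactive tautomer is scored as
  drawn).
- Acid-catalyzed and hydroxide-only (specific-base) racemization are out of
  scope; the intercept of a buffer-dilution plot absorbs them in analysis
  but the prediction pipeline ignores them.
- The shipped rule set covers the substituent types of the A–N catalogue;
  exotic substituents fall to `other` (contribution 0 in lenient mode,
  error in strict mode) and should be added via a pattern file.
- The Hückel aromatic-anion heuristic is a two-dimensional electron count;
  the override map exists precisely because it cannot be right for every
  ring system.
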