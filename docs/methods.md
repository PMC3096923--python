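# Methods

This note documents the models behind `mixscreen`: the binding equilibrium,
the measurement chain, the estimators and their validity conditions, the
planners, and what the synthetic generator does and does not emulate.

## Competitive binding model

A binding system of volume `V` contains an immobilized target carrying one
class of `S_tot` binding sites (pmol) and a mixture of ligands, each with an
association constant `K_i` (M⁻¹) and total concentration `C_i` (mol/L).
At equilibrium, mass action in concentrations gives per ligand

    bound_i = K_i · S_free · C_i / (1 + K_i · S_free)

and `S_free` is the unique root of the site-conservation closure

    S_tot/V = S_free + Σ_i K_i · S_free · C_i / (1 + K_i · S_free).

The right-hand side is strictly increasing in `S_free`, so the root is
bracketed by `[0, S_tot/V]`. The solver uses Brent's method with a
log-spaced pre-bracketing pass when `max(K_i)·S_tot/V > 1e6` (in the
femtomolar-K regime the root can lie twenty orders of magnitude below
`S_tot/V`), followed by a short Newton polish with the analytic derivative.
The default residual tolerance is 1e-10 relative; in practice the polish
reaches machine precision, and both ligand and site conservation hold to
~1e-15 relative even in the stoichiometric (tight-binding) limit. A
single-ligand closed form — the stable root of the binding quadratic,
`x = 2LS / (b + sqrt(b² − 4LS))` with `b = L + S + K_d` — serves as an
independent oracle in the tests.

Assumptions: one site class, no cooperativity, no kinetics (the incubation
is taken to reach equilibrium), no vessel adsorption. Nonspecific binders
are modelled either as specific binders with a very small `K` (default
1e6 M⁻¹) or through an occupancy-independent `nonspecific_fraction` that
survives target denaturation — the latter reproduces the behaviour of weak
matrix binders in denatured-target controls. Streptavidin's tetravalency is
deliberately **not** modelled (single-site approximation); see Limitations.

Units: amounts in pmol, suspension/extract/injection volumes in µL, system
volumes in mL, concentrations in mol/L; conversions happen once at type
construction.

## Measurement chain

Each SIM channel responds linearly, `area = slope·q + intercept`, up to a
linear-range ceiling (default 30 pmol, the calibrated upper limit of the
model system). Quantities above the ceiling saturate at the ceiling area
and are flagged rather than raised, because the composition optimizers
intentionally probe across the boundary. Intercepts may be negative; all
threshold checks use `|intercept|`.

Forward model of one screen, per ligand: the extract injection carries
`bound · RR · V_inj / V_extract` pmol (with `RR` the overall recovery ratio
of the pull-down/extraction/concentration chain) and the PMFS injection
carries `C_total · V_inj` pmol. The latter embodies the **dilution
convention**: PMFS (total) measurements are interpreted at the
binding-system concentration scale, i.e. the PMFS is diluted by
`V_system / V_PMFS` before injection. Under the standard protocol
(`V_PMFS = V_extract = 40 µL`, injection 5 µL) this factor equals
`CR = 1000·V_system/V_extract`, which is the only convention under which
`BR = A_B/(RR·CR·A_T)` is dimensionally exact. Deviating protocols are
handled through the explicit per-record `dilution` field and the
estimator's `dilution_correction` parameter.

Noise is multiplicative log-normal with unit mean and a configurable
per-injection CV (default 10%, consistent with the model system's reported
duplicate CVs of ≤12%); every analysis is simulated in duplicate (default)
and the duplicate mean recorded, mirroring the calibration protocol. All
randomness flows through explicit seeds.

Recovery ratios are calibrated by saturation binding (target in large
excess, so the mixture binds quantitatively):
`RR = A_extract / (CR · A_mixture)`, both areas required to pass the
five-intercepts and linear-range rules.

## Estimators and their biases

The ratio (depletion-corrected) and dilute forms are given in the README.
Two exact relations drive the validity design:

* `BR_i = K_i·S_free/(1 + K_i·S_free)` — a ligand's binding ratio depends
  on its own concentration only through competition for sites;
* `dilute = ratio_form · (1 − BR_X)/(1 − BR_A)` — the dilute form
  **under**-estimates a candidate stronger than the reference (`BR_X >
  BR_A`) and **over**-estimates a weaker one, with the bias vanishing as
  both ratios fall below the 10% rule.

Hence, escalating a strong candidate's concentration drives its binding
ratio down and the dilute-form estimate monotonically **up** onto a plateau
at the truth; a weak candidate's plateau sits a few percent **above** its
truth when the reference is operated at its design binding ratio of ~10%.
Simulations of the model system reproduce both effects at the few-percent
level (strong candidate ≈ −8%, weak ≈ +11% at their optimized
compositions), the same directions and magnitudes separating the
dilute-form determinations from the homogeneous-assay determinations in the
model system's published characterization. The positive intercepts add a
second, partially self-cancelling bias (areas in numerator and denominator
are inflated alike — the covariance that makes the method robust to
systematic sensitivity errors); operating all areas well above five
intercepts keeps it small.

Prerequisite validation evaluates, in order: linear range per
(ligand, kind); area ≥ `area_multiple`·|intercept| (default 5); estimated
BR < `br_limit` (default 0.10) for both ligands. Same-site evidence is a
tri-state; `untested` counts as satisfied because site identity can only be
judged (via excess-competitor displacement ≥40% plus absent binding to a
denatured target), not optimized. Estimated binding ratios above 1 are
reported with an implausibility flag rather than raised — noise near the
validity boundary can produce them.

## Planners

*Parameter-dependent sizing*: per ligand, the smallest injected quantity
clearing the five-intercepts rule is `q_inj = 4·|i|/s` (for positive
intercepts; an `intercept_floor`, default 0.5 pmol, covers non-positive
ones), chained through `q_extract = q_inj·V_extract/V_inj`,
`q_bound = q_extract/RR`, `v_target = q_bound/site_density`, summed over
same-site ligands, times a safety factor (default 2; universal
applicability across mixtures argues for more). Full precision is carried
internally; a `rounding='table'` policy reproduces how a printed sizing
table chains rounded one-decimal cells. The default planning site density
is 4.0 pmol/µL (the value consistent with the published sizing column),
with the titrated capacity 4.2 pmol/µL used for simulation geometry; the
two are both exposed and the discrepancy is deliberate. Note the published
sizing table's low-recovery column contains an internally inconsistent
bound-minimum cell (31.5 ≠ 16.8/0.57 = 29.5); the implementation follows
the formula.

*Experimental sizing*: extract areas are fitted linearly against titrated
target volumes and solved for the five-intercepts threshold per ligand; the
maximum of the per-ligand minima is the optimized quantity. Thresholds not
bracketed by the tested volumes raise unless extrapolation is enabled.

*Fine optimization*: the dilute-form estimate is computed at every step of
a strictly increasing composition schedule without validity gating; the
trajectory is stable from the first of `plateau_len` (default 2)
consecutive steps whose successive relative changes are below
`plateau_rel_tol` (default 10%) while prerequisites hold. The stable value
is the mean over the plateau. The "stable" criterion is a design choice —
the procedure it formalizes says only that estimates become stable.

*Rough optimization*: exponential escalation (default factor 4, the one
worked escalation of the model system) until the prerequisite report is
valid; all attempts and their failure lists are returned. The escalation
axis is chosen from a pilot estimate: reference axis when the pilot ratio
exceeds 3 (the "much greater" threshold, unquantified in the source
protocol; ties break toward the mixture axis).

## Synthetic scenarios

The generator emulates the biotin/streptavidin model system: reference
K_d = 100 fM (within the sub-200-fM regime), candidate constants scaled by
the true relative-affinity fixtures; published calibrations for the
single-candidate channel set; synthetic calibrations for the multi-ligand
set chosen to satisfy the published qualitative orderings (negative
intercept for one channel, lowest slope for another). Geometries default
to 2.0 mL/50 µL suspension (single candidate) or 4.0 mL/200 µL (multiple
candidates) at 4.2 pmol sites/µL. Mixture preparations: `pooled` (exact
fractions), `pcs_single` (one candidate at approximate content, default
50%), `spsag` (fractions tracking amine inputs with log-normal yield
jitter, default CV 15%, reproducing nominal-vs-realized ratio deviations of
the 3:1-vs-3.0:1 kind). Scenario bundles write estimator-facing CSVs plus a
sealed truth JSON in a separate directory.

Simulated acceptance studies use the reporting unit of the published
characterization: a screening campaign of 4 independent binding systems,
each analyzed in duplicate at 10% per-injection CV, with the campaign
estimate the mean — single assays have a structural ~14% SD (four areas at
~7% effective CV each), so campaign means are the right scale for
band-level comparisons. Problem sizes in the test suite (200 campaigns for
parameter recovery, 50 randomized systems for solver checks, 6 assays for
discrimination) were chosen to keep Monte-Carlo error well below the
tolerances they certify.

What the generator does **not** emulate, and hence what passing tests do
not show about real screens: multivalent/avidity binding (streptavidin is
tetrameric; real low-occupancy data can show apparently *higher* candidate
affinities at low concentrations than the single-site model predicts),
chromatographic peak-shape and integration artifacts, retention-time
drifts, unresolved co-eluting interferences (resolved contaminant peaks are
supported as separate records), ionization suppression in mixtures, and
slow binding kinetics.

## Numerical choices and degenerate inputs

* Solver: Brent + Newton polish as above; zero-ligand or denatured systems
  short-circuit; bracketing failures raise naming the system.
* Linear fits: ordinary least squares (`scipy.stats.linregress`);
  degenerate abscissae raise; `linear_upper` from a 3-residual-SD band.
* Saturated areas: flagged, never raised; the linear-range check is strict
  at the ceiling (a saturated channel reports exactly the ceiling area).
* Duplicate handling: areas are duplicate means; SDs propagate into
  diagnostics only.
* Tie-breaks: pilot ratio exactly at the axis threshold escalates the
  mixture; experimental sizing with all areas above threshold returns the
  smallest tested volume, flagged.

## Known limitations

Single site class only; no absolute affinities (the method determines
ratios; absolute constants would require the free-site quantity in absolute
units); the dilute-form residual bias (depletion factor and intercept
terms) is a few percent even inside the validity region — the
depletion-corrected form removes the first term when `CR` and the
calibrations are trusted; outlier rejection across assays is out of scope.
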