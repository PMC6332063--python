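# Methods

## Thermodynamic model

All energies are in kcal/mol, concentrations in M, volumes in L; the
only unit conversion inside a model is the calibrated 4.18 kJ→kcal
factor of the hydrogen-bond descriptor equation, which is part of that
model, not a configurable constant. Binding free energies use
ΔG = −RT ln K with R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹ and T = 298.0 K by
default. These exact constants reproduce every tabulated −ΔG from the
corresponding K to two decimals; 298.15 K would match equally well at
that precision, and 298.0 was fixed once as the reporting convention.
ITC experiments are physically run near 293 K; the experiment
temperature is stored on the experiment object while reporting defaults
to 298 K so that NMR- and ITC-derived free energies are directly
comparable in one table.

The single-hydrogen-bond predictor is Hunter's descriptor model,
`ΔG_HB = [−(α − α_s)(β − β_s) + 6]/4.18`. It applies to one
point-to-point hydrogen bond in a competing solvent only; it is not
used (and not valid) for the four-fold NH···O array of the actual
complexes, where it serves solely to rank the two guests' acceptor
strengths and motivate the reference subtraction.

## 1:1 speciation and forward models

The complex concentration solves `K(H0 − x)(G0 − x) = x`. The root is
evaluated in the conjugate form `x = 2·H0·G0 / (b + √(b² − 4·H0·G0))`,
`b = H0 + G0 + 1/K`, which has no subtractive cancellation for any K
(the naive quadratic formula loses all precision when `b² ≫ 4·H0·G0`).
A guarded bisection refinement runs only if the mass-balance residual
ever exceeds 1 × 10⁻¹⁰ relative; property tests sweep six orders of
magnitude in (H0, G0, K) against an independent root-bracketing oracle.

Fast-exchange NMR shifts are population averages,
`δ_obs = δ_free + f_bound (δ_bound − δ_free)`, with `f_bound = [HG]/H0`
for host nuclei and `[HG]/G0` for guest nuclei. Guest signals are
undefined at G0 = 0 and carried as NaN; fits mask them.

ITC heats use the overfilled-cell (perfusion) convention: each
injection of volume `v` into active volume `V0` scales pre-existing
concentrations by `(1 − v/V0)` before adding titrant, and

    q_i = ΔH · V0 · ([HG]_i − [HG]_{i−1} · (1 − v_i/V0)),

with the site concentration `n·[H]_total` in the speciation call. The
displaced-volume factor means a fully saturating run recovers slightly
less than `n·ΔH·(host moles)` in total — host expelled before binding
never contributes — which the tests account for by saturating early.
The first injection is excluded from fits by default (the usual
syringe-tip artefact); this is configurable.

## Fitting

Both fitters optimise log₁₀K, which enforces positivity and keeps the
Jacobian well scaled from 10⁰ to 10⁸ M⁻¹. For any trial K the remaining
parameters enter linearly (δ_free/δ_bound per signal; ΔH), so a
log-spaced eight-point grid scan with the linear parameters profiled in
closed form locates the basin cheaply; Levenberg–Marquardt then refines
from the best starts. NMR fits share one K across all signals with
equal weighting (no weighting scheme is implied by the data model) and
report asymptotic standard errors from the residual-scaled covariance,
`σ_K = ln 10 · K · σ_log₁₀K`, `σ_ΔG = RT · σ_K / K`. A
residual-resampling bootstrap (deterministic under its seed) is
available as a cross-check; on well-conditioned synthetic data it
agrees with the asymptotic errors within a factor of two. A titration
in which every signal is flat below the noise floor (default 0.01 ppm)
raises an unidentifiable-K error rather than returning an arbitrary
constant.

**ITC stoichiometry.** The default fixes n = 1 rather than floating it.
The study's injection protocol (0.2 mM cell, 1.4 mL, 25 × 3 µL of a 7×
syringe solution) reaches only ~0.38 molar equivalents, and on such a
pre-equivalence isotherm (n, K, ΔH) are jointly near-degenerate: dense
global profiling of the fit surface shows that even the exact global
minimum of the floating-n problem scatters the recovered K over orders
of magnitude at 0.1 µcal noise, while fixing n at the independently
established 1:1 stoichiometry recovers K to a few percent. Fixing n
when the run does not bracket the equivalence point is standard
calorimetric practice; `float_n=True` remains available and warns when
used on a < 1-equivalent run. A warning is also emitted when the
Wiseman parameter c = n·K·[cell] leaves [1, 1000].

## Decomposition, per-contact energies, LFER

ΔΔG subtracts the zero-wall reference result for the same guest at the
same reporting temperature; σ's combine in quadrature (the two
measurements are independent). Internally ΔG and ΔΔG are negative
(favourable); report tables print −ΔG/−ΔΔG. Contact counts default to
one methyl-to-ring contact per wall (2 or 4) and can be overridden from
geometry output or per host in the run config. The quoted per-contact
value of ~1.1 kcal/mol arises from the mean four-wall *N*-oxide
magnitude (4.49, 4.32 → 4.4) divided by four contacts; the averaging
convention is explicit in the code rather than implied.

The LFER regresses −ΔΔG on ring-centroid ESP by ordinary least squares
(scipy's linear regression), reporting the slope's standard error and
two-sided t-test against zero on n − 2 degrees of freedom; an
inverse-variance-weighted variant (σ treated as known, covariance
unscaled) is optional. With two points the fit is exact interpolation
and the p-value is NaN. The two-wall series has only three ESP levels,
so "slope indistinguishable from zero" is a statement at very low
power; the package reports the slope with its SE and p rather than a
binary verdict.

## Geometry

Ring planes are total-least-squares fits (SVD of centred ring
coordinates); the normal is the smallest-singular-value direction, with
its sign chosen toward a query atom when one is given, and planarity is
reported as the largest out-of-plane deviation. The CH-π descriptors
follow the common computational-chemistry convention: `d` from the
donor hydrogen (or carbon, in heavy-atom mode) to the centroid, `Θ` the
C–H···centroid angle at H, and `Φ` the angle between the
centroid→donor vector and the ring normal, so Φ ∈ [0°, 90°] with 0°
directly over the ring face. These conventions are stated rather than
assumed universal — published figures often label (d, Φ, Θ) without
defining them — and the contact criterion (C_methyl···centroid ≤ 4.0 Å,
heavy-atom mode) is configurable. All outputs are invariant under
rigid motions to 10⁻⁹ Å / 10⁻⁷ °, enforced by tests.

Experimental crystal structures of the inclusion complexes exist in the
CCDC (entries 1417349–1417350) and can be fed through the same
functions as an external validation; they are deliberately not bundled
or downloaded, so the default test suite relies only on constructed
fixtures with known ground truth.

## Synthetic data: what it does and does not emulate

Generators draw from one seeded generator per call (pure functions of
scenario + seed). The NMR default design is 1.6 mM host, 14 points from
0 to 12 equivalents (saturation needs > 10 equivalents at the two-wall
affinities), an NH signal moving 7.4 → 9.4 ppm, and i.i.d. Gaussian
shift noise of 0.005 ppm; guest methyl signals (3.1 → 2.6 ppm upfield)
are available but not fitted by default. The ITC default mirrors the
study protocol above with 0.1 µcal heat noise. Both noise defaults are
typical instrument precision (400 MHz spectrometer; VP-ITC), chosen
once since no measurement-noise figures are tabulated. Host dilution
during guest addition is supported (guest stock at 100 × H0 by
default) but off by default, matching the constant-host idealisation.

The generators produce i.i.d. Gaussian noise on an exactly correct 1:1
model. Real titrations add baseline drift, concentration errors in
both stocks (which bias K multiplicatively rather than adding shift
noise), heat-of-dilution residuals and possible higher-order binding.
Passing recovery tests therefore demonstrates the correctness and
conditioning of the estimators under the stated designs, not the
absence of systematic error in the laboratory data.

Problem sizes used by the recovery checks — 50 NMR replicates and 20
ITC replicates at the two designs above — match the replicate counts
the medians are defined over.

## Known limitations

* Only 1:1 binding; no 2:1/1:2 models and no slow-exchange lineshape
  quantitation (slow-exchange systems are handled by ITC, as in
  practice).
* One tabulated −ΔΔG cell (the NO₂ two-wall host with the *N*-oxide
  guest) is mutually inconsistent with its own tabulated K values by
  ~0.045 kcal/mol; recomputation reproduces the K-derived value, and
  the corresponding check documents the discrepancy rather than
  papering over it.
* The descriptor table ships only the species needed here; users supply
  CSVs for anything else.
* ESP values are consumed as inputs; no quantum-chemical calculation of
  potential surfaces is performed.
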