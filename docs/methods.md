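# Methods

## Valuation model

The package implements the classical value-coefficient (benefit-transfer)
formulation of ecosystem-service valuation: the landscape is partitioned
into land-cover classes; each class *k* has an area *A_k* in hectares and a
vector of per-hectare annual value coefficients *VC_kf* (USD ha⁻¹ yr⁻¹)
over service functions *f*, and every reported quantity is a partial sum of
the bilinear form `ESV = Σ_k Σ_f A_k · VC_kf`. The model assumes value per
hectare is homogeneous within a class, additive across functions, and
constant in area (no congestion or scarcity effects) — standard, strong
assumptions of benefit transfer; results should be read as first-order
policy-screening numbers, not welfare estimates.

Missing (class, function) coefficients mean "service not provided" and
enter as zero. Genetic-resource provision sits under provisioning because
the packaged summary table places it there, although some classifications
treat it as supporting; the table as shipped governs.

### Coefficient assembly

`assemble_coefficient_table` unions three sources and rejects duplicate
(class, function) pairs:

* **Value-transfer records.** Each record stores the original unit value,
  an explicit per-record adjustment factor, and the adjusted value. A CPI
  lookup is deliberately *not* built in: the source studies span different
  years and indices, so implied factors differ per record (≈1.23 for the
  2018 erosion-control values, ≈1.43 for pollination, 1.31 for the 2013
  wetland provisioning value). When an adjusted value is supplied (e.g.
  transcribed from a published table) it must agree with original × factor
  to 0.5% relative, which absorbs print rounding.
* **Carbon profiles.** Stock (t C ha⁻¹) × 44/12 × SCC (USD per t CO₂).
  The molar-mass ratio is kept exact — it reproduces every published
  CO₂-equivalent entry at two decimals, whereas the rounded 3.67 does not.
  The packaged SCC is 1.47 USD/t CO₂ (an annualized social-cost estimate);
  it is a scalar parameter and can be replaced per run.
* **Direct values.** E.g. coffee: net value = production rate (t ha⁻¹ yr⁻¹)
  × market price (USD t⁻¹) × (1 − cost fraction). With the packaged inputs
  (0.84, 4685, 0.13) the product is 3423.80 USD ha⁻¹ yr⁻¹; the source
  literature prints 3423.57, an unexplained 0.007% discrepancy we keep
  visible rather than patch.

All arithmetic is double precision; rounding (2 dp for per-hectare values,
3 dp for millions) happens only at serialization.

### Two area sets

The source material prints two per-class area tables that disagree for
several classes (remnant forest 146,251.59 vs 146,929.5 ha; savanna
28,720.98 vs 113,093.5 ha). The package never reconciles them: they ship as
separate fixtures, `"carbon"` (used in the carbon-sequestration accounting)
and `"valuation"` (used in the ESV accounting), and the run configuration
names which one a run reproduces. Class shares of the full 472,118-ha
mapped region use that study total as an explicit denominator, since the
listed vegetation classes do not exhaust the map (built-up land is mapped
but not valued).

## Sensitivity analysis

`CS = |(ΔESV/ESV) / (ΔVC/VC)|` under a uniform (1 + δ) scaling of one
class's coefficients, default δ = ±0.5. The elasticity is evaluated by
recomputation, not by a closed form, but the algebra is exact either way:

* **per_class mode** (default): ESV is the perturbed class's own value, so
  CS ≡ 1 for any class, any δ ≠ 0 — the complete-elasticity result. This
  mode is the default because it is the reading under which the published
  single CS value is exactly reproduced.
* **total mode**: ESV is the grand total, and CS equals the class's share
  of total value, independent of δ; shares sum to 1 across classes. This is
  the informative variant for ranking coefficient uncertainty.

The perturbation scales *all* functions of the target class uniformly; a
per-function perturbation would be a different (Monte-Carlo) exercise and
is out of scope.

## Accuracy assessment

The confusion matrix is oriented rows = map labels, columns = reference
labels (the conventional remote-sensing layout). Overall accuracy is
trace/total; Cohen's kappa is `(p_o − p_e)/(1 − p_e)` with `p_e` from the
marginals, undefined when `p_e = 1`; producer accuracy is diagonal/column
total, user accuracy diagonal/row total. Per-class metrics with an empty
row/column are reported as NaN, never 0 — a class that was never mapped has
no commission rate. No kappa variance or area-weighted (Olofsson-style)
estimation is provided; the metrics are plain counts. The implementation is
cross-checked in the test suite against scikit-learn's `cohen_kappa_score`
on random matrices to 1e-12.

## Synthetic landscape generator

The generator replaces the satellite/classification stage for testing and
has three parts, all driven by one integer seed (sub-streams derived via
`SeedSequence([seed, k])`, so artifacts are independently reproducible):

* **Land cover**: i.i.d. multinomial cells with the target class
  proportions. Default proportions are the published class shares of the
  study landscape (eight classes led by remnant forest at 30.98%); they are
  transcribed percentages summing to 100.01% and are renormalized on load
  (constructor tolerance 1e-3, stricter sums pass through unchanged).
  An optional 3×3 majority filter adds spatial patchiness (ties break
  toward the lower class index); it is off by default because only the
  i.i.d. scheme makes proportion convergence exact — downstream valuation
  depends only on areas, not on spatial arrangement.
* **Band pair**: red reflectance is fixed at 0.08; per-cell NDVI is drawn
  Gaussian around the class target (clipped to ±0.999) and NIR solved as
  `red·(1+v)/(1−v)`, keeping both bands strictly positive and NDVI inside
  (−1, 1). Default per-class NDVI means are the published class means (0.83
  coffee … 0.53 savanna); built-up is set to 0.20 and every per-class SD to
  0.05 — the source reports no variances, so these are arbitrary,
  documented defaults.
* **Reference points**: per class, `points_per_class` distinct cells of
  that class, each map label drawn from the class's row of a row-normalized
  confusion matrix. The default confusion puts the published per-class
  producer accuracies on the diagonal and spreads the remainder uniformly —
  a caricature of real error structure (real confusions are concentrated
  among spectrally similar classes), sufficient for recovery testing but
  not for simulating realistic error correlation. Default 100 points per
  class, the usual minimum for accuracy assessment of large complex maps.

What passing tests show: the estimators recover the generating parameters
at the expected √n rates. What they do not show: robustness to spatial
autocorrelation, mixed pixels, atmospheric effects, or classifier bias —
none of which the generator emulates.

## Numerical and design choices

* Hectare conversion fixed at 1 ha = 10⁴ m²; pixel areas are flat squares
  (no geodesic correction), matching how the published hectares were
  reported. Coordinates are (row, col), 0-based, row 0 at top.
* NDVI cells with NIR + red = 0 are masked (NaN) and excluded from class
  statistics; substituting 0 would bias class means toward zero.
* Per-class NDVI SD uses the population convention (ddof = 0), so a
  constant field reports SD exactly 0.
* AreaTable requires its declared total to equal the entry sum (1e-6
  relative); shares of a larger region are requested explicitly via a
  reference total, never by silently inflating the table.
* Pipeline runs are deterministic and idempotent: the same configuration
  and seed rewrite byte-identical CSV/JSON artifacts; inputs are logged
  with SHA-256 checksums.
* Problem sizes in the test suite and the reproduction script (grids of
  300–1000 cells per side, 100–1000 reference points per class) are chosen
  so every statistical check sits well inside its 3-standard-error band
  while the whole suite runs in seconds.

## Known limitations

* Benefit transfer inherits the source-site values; no original valuation
  (willingness-to-pay, avoided cost) is performed, and no currency
  discounting beyond the explicit per-record factors.
* The two printed area sets are mutually inconsistent and with the mapped
  class shares; the package treats areas as input data and reproduces
  whichever set a run names.
* Accuracy metrics carry no confidence intervals.
* The synthetic generator does not emulate sensor radiometry, clouds, or
  spatially correlated classification error.
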