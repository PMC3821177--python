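# Methods

This note documents the models, parameter choices and numerical
decisions behind `pvstereo`, in the spirit of a statistical package's
model documentation.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. The stereological estimator

### Counting frame

Cells are counted in a square unbiased counting frame.  The inclusion
convention is "entirely within the frame, or touching the top or right
edge"; the exclusion convention is implemented as the classical
*forbidden line*: the left edge extended upward to infinity, the bottom
edge, and the downward extension of the right edge.  A profile
(modeled as a disc; radius 0 gives the unique-point rule) is counted
iff it intersects the closed frame and does not touch the forbidden
line.

The infinite extensions are not pedantry.  With only the four finite
edges, a disc straddling a tiling corner is either counted by up to
three frames (if it contains the corner) or by none (if it crosses both
adjacent cut lines without containing the corner).  With the forbidden
line, an exhaustive tiling of the plane counts every disc exactly once;
the test suite verifies this per-object by brute force over random
scatters.  Oversized profiles (footprint larger than the frame) are
counted under the same rule and flagged with a warning.

### Optical disector

A disector is the frame swept through the guarded core of a section:
with section thickness *t* and guard fraction *g* per face, the core is
[*z*₀ + *gt*, *z*₁ − *gt*] and the disector volume is
V_dis = frame_area × *t*(1 − 2*g*).  A cell is counted iff its
**centroid** lies in the core and passes the frame rule in the section
plane.  Counting by the unique centroid point makes an exhaustive
tiling of a slab recover its point count exactly and keeps the
estimator unbiased for any thickness: fragments (cells whose soma
sphere is cut by a knife plane) can never contribute, because a
fragment's centroid lies in another slab.

### Fractionator and Cavalieri volume

Numerical density is N_v = ΣQ / ΣV_dis,ᵢ over an animal ×
subdivision's disectors — the ratio-of-sums generalization of
ΣQ/(n · V_dis), to which it reduces when all disectors share one
volume.  The reference volume is the Cavalieri estimate
V_ref = Σ(points_hit × area_per_point) × spacing over sections; a
single common spacing is part of the estimator's contract and unequal
spacing is rejected, not approximated.  When no point-counting data
exist, V_ref falls back to the summed disector volume and the output is
labeled `sampled-volume` mode.  The estimated total is E_n = N_v ×
V_ref and the reported density E_n/V_ref ≡ N_v; the identity is
enforced on every `DensityEstimate` to 10⁻⁹ relative.  A simple
Poisson standard error of N_v (√ΣQ / ΣV_dis) is carried; no Gundersen
coefficient-of-error machinery is provided.

Units: lengths in files are μm, frame areas mm², volumes mm³
internally, densities cells/mm³ everywhere; all conversions live in
`pvstereo.units`.

No shrinkage correction is applied at any stage.

## 2. The synthetic-tissue generator

The generator emulates the data-generating process the analysis
assumes, with known ground truth:

* **Point process.** Homogeneous Poisson by default — the minimal
  assumption for soma positions.  A Matérn-II hard-core option
  (minimum separation 2 × soma radius) serves as a realism check; its
  proposal intensity is solved from the target intensity by inverting
  the Matérn-II retention formula, so the realized density matches the
  request up to a small boundary excess (pairs straddling the box face
  are not thinned by outside neighbours).  Hard-core counts are
  underdispersed (variance/mean < 1), Poisson counts are not; both are
  asserted in tests.  A scene stores its *realized* density (points per
  box volume), so estimator bias is always judged against what is in
  the box.
* **Sectioning.** Slabs tile the block along the cutting axis; a
  remainder becomes a thinner final slab.  Somata are spheres (default
  radius 6 μm, a typical thalamic soma scale); every slab face counts
  as a knife plane, so the expected fragmented fraction per slab is
  2r/t.  Each slab also records the "caps" — centroids of neighbouring
  cells whose sphere pokes into it — which is what a naive observer
  sees as extra profiles.
* **Disector sampling.** Square frames are placed uniformly at random
  without overlap (dart throwing with restarts; a systematic-random
  grid is available).  An impossible request fails with the limiting
  dimension named.
* **Naive comparator.** The biased method counts every visible profile
  (members + caps, at the equatorial radius) with no guard zones and
  divides by frame area × thickness.  Its expectation is inflated by
  ≈ (t + 2r)/t, so 25 μm sections overestimate more than 50 μm ones —
  the artifact the guarded disector exists to remove.  The acceptance
  suite reproduces this ordering over 500 paired replicates while the
  guarded estimates at the two thicknesses agree within 5%.
* **Cohort layer.** Per animal, region density is
  baseline + slope × (age − min age) + N(0, animal_sd), floored at 0 —
  linear with additive Gaussian between-animal noise, matching the
  model class the inference stage fits.  Ages are evenly spaced over
  the configured range.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| animals | 7 | the cohort size of the motivating study design (3 middle-aged + 4 aged) |
| age range | 180–420 months | 15–35 monkey-years, the stated cohort span |
| baseline density | 4000 cells/mm³ | plausible PV+ density scale in geniculate nuclei |
| slope | 10.5 cells/mm³ per month | with the noise below, population r ≈ 0.86 at n = 7 (b·σ_age/√(b²σ²_age + σ²) with σ_age = 77.5 months) |
| animal_sd | 500 cells/mm³ | ~12% between-animal scatter |
| section thickness | 40 μm (choices 25/40/50) | the study's thickness set; other values require an explicit override |
| guard fraction | 0.2 per face | guards exceed the soma radius at every configured thickness ("optimal guard spaces" are otherwise unquantified) |
| frame area | 0.5 mm² | the "0.5 mm² grid" read as an area; a side-length reading is runnable by setting frame_area = 0.25 mm² |
| sections × disectors | 8 × 4 per region | **invented** — no per-animal sampling effort is reported anywhere for the original study |
| soma radius | 6 μm | any positive value demonstrates the thickness bias; 6 μm is a typical soma scale |

Two generation routes exist.  The `points` route builds full 3D scenes
and counts them.  The `counts` route draws Q ~ Poisson(λ·V_dis)
directly — for the homogeneous Poisson process with non-overlapping
frames this is the *same distribution*, not an approximation, and a
test compares the two routes.  `synthesize_animal_densities` applies
the same identity one level up (ΣQ ~ Poisson(λ·ΣV_dis)) for
replicate-heavy studies.  Replicate counts used by the test and
acceptance suites (500 scenes per density, 100 recovery cohorts, 1000
zero-slope cohorts, 60-replicate smoke versions in unit tests) are the
package's chosen problem sizes: large enough that Monte Carlo error is
small against the tolerances asserted, small enough to run routinely.

### What the generator does not emulate

Staining intensity and antibody specificity; spatially inhomogeneous or
anisotropic cell distributions (densities are uniform within a region);
tissue shrinkage and section-thickness variability; observer error in
recognizing a stained soma; anatomical delineation of region borders.
Passing tests therefore demonstrate correctness of the estimator and
inference chain under the stated sampling model — not robustness to
histological artifacts the model excludes.

## 3. The inference procedure

* **Age conversion.** Human-equivalent years = months/4 (1 monkey year
  = 3 human years).  Displayed ages round to the nearest integer (half
  away from zero) except exact half-integers, which are preserved —
  the only rule consistent with conventionally printed values such as
  306 → 76.5 and 243 → 61.  An input table carrying a printed human age
  keeps it as authoritative, with a warning when it disagrees with the
  months/4 rule (the bundled seven-animal table contains one such
  internally inconsistent row, 417 months / 37 years).
* **Grouping.** Aged iff human-equivalent age ≥ 65 (21.66 monkey
  years).  The boundary goes to the aged group; no boundary animal
  exists in the bundled cohort, so either tie direction reproduces its
  3/4 split.
* **Unit of analysis.** Multiple density estimates per animal are
  averaged (unweighted) before any test; regressions and t-tests
  operate on animals, not measurements.  Missing region values warn
  and propagate as explicit missing rows, never silent drops.
* **t-test.** Student's pooled-variance unpaired t-test (the generic
  "unpaired t-test"), two-sided, α = 0.01; Welch by flag.  Identical
  constant groups return t = 0, p = 1 rather than NaN.
* **Regression.** Pearson r, least-squares slope/intercept
  (scipy.stats.linregress); the parametric p is the two-sided
  t-transform t = r√((n−2)/(1−r²)) on n−2 df, which the tests verify
  against the closed form.  Zero variance in either vector is an
  error, never a silent r = 0.  The age axis is monkey-years; the
  slope is reported per monkey-year and per human-equivalent year
  (÷3) since the rescaling leaves r and p unchanged.
* **Permutation test.** The density vector is shuffled against the
  fixed age vector; p = #{r_perm ≥ r_obs}/n_iter with n_iter = 1000 by
  default and no +1 correction (a (k+1)/(n+1) flag exists).  The
  signed tail is the literal procedure and the default; note it makes
  a strongly *negative* observed r trivially non-significant (p ≈ 1),
  so an absolute-value tail is available by flag — documented, not
  silently substituted.  Ties at r_obs are counted as extreme, with a
  10⁻¹² tolerance so the identity permutation's float round-trip
  cannot drop out.  Permutations are animal-level, mirroring the unit
  of analysis.
* **Dual criterion.** significant ⇔ (r > 0.7) ∧ (p_param ≤ 0.01) ∧
  (p_mc ≤ 0.05).  The conjunction is monotone in its thresholds
  (property-tested) and conservative: with nine regions and n = 7 its
  per-region type-I rate is below 1% (the two-sided p ≤ 0.01 plus
  r > 0 effectively halves the level before the Monte Carlo step).
  No multiple-testing correction is applied across regions — the
  stringent per-test criteria are the design.
* **Ratio normalization.** Per region, mean(aged)/mean(middle-aged);
  > 1 indicates an age-related increase; a zero middle-aged mean is an
  error (undefined normalization).
* **Observer agreement.** Per-section agreement
  1 − |A−B|/max(A,B) (1 when both zero); the calibration criterion is
  a run of 20 consecutive sections at ≥ 0.95, found by sliding window;
  a paired t-test compares the observers (p = 1 for identical counts;
  NaN for a constant non-zero difference, where t is undefined).

### Model/Results surface

`PVAgingModel(densities, demographics)` holds the data and the region
vocabulary (nine regions plus pooled `LGN_magno` = layers 1–2 and
`LGN_parvo` = layers 3–6, each pooled as the per-animal mean of member
layers).  `fit()` runs the three steps for every region and returns a
`PVAgingResults` with `regressions`, `group_comparisons`, `ratios`
tables, `summary()`, and `save()` (TSVs + JSON run log recording seed,
iteration count, tail mode and all thresholds).  Permutation seeds are
split per region from the fit seed with `SeedSequence`, so results are
independent of region order and individually reproducible.

## 4. Pipeline and reproducibility

`RunConfig` names either input files (counting records, optional
Cavalieri records, demographics) or a simulate block — never both.
`run_pipeline` validates inputs (machine-readable violation list:
table, row, rule, message; referential integrity between counts and
demographics), then estimates and infers, writing every intermediate
table plus a manifest (config echo, SHA-256 config hash, seed, row
counts, version).  All randomness descends from the single root seed;
identical config + seed reproduces byte-identical tables.  Unknown
region labels are errors, not warnings.

## 5. Known limitations

* The motivating study's per-animal densities exist only as figure
  points, so its exact correlation values cannot be — and are not —
  reproduction targets; the package reproduces the *procedure* and the
  printed, derivable numbers (age conversions, group split, formula
  arithmetic).
* At the default calibration (population r ≈ 0.86, n = 7 animals) the
  sampling error of a fitted slope is ≈ 25% of its value, so the
  median relative recovery error sits near 15% by construction; this
  is a property of seven-animal cross-sectional designs, not of the
  estimator.
* `sampled-volume` mode makes V_ref proportional to sampling effort;
  its E_n is not an estimate of the nucleus's total neuron number
  (density remains valid, which is why density is the primary output).
* The Matérn-II realized density runs slightly above target near box
  faces (unthinned boundary pairs); negligible for the box sizes used
  but visible in very small boxes.
* The signed permutation tail is one-sided by construction; for
  two-sided questions use `tail="absolute"`.
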