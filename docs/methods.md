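# Methods

## The exposure model and its assumptions

The package estimates how much of the TiO₂ embedded in mask textile fibers
is located at the fiber surface, and compares that mass with an acceptable
inhalable amount per mask.

**Geometry.** Synthetic fibers (polyester, polyamide, thermobonded
non-woven) are modelled as cylinders of circular cross-section with median
diameter d_f (µm). TiO₂ occurs as agglomerates of near-spherical
constituent particles; the agglomerate population is summarized by the
median minimum Feret diameter d_a (nm). Assuming agglomerates are
distributed homogeneously over the cross-section — plausible because the
particles are mixed into the polymer melt during fiber production — an
agglomerate can reach the surface exactly when its disc of diameter d_a
touches the boundary, i.e. when its center falls in the outer ring of
thickness d_a/2. The surface fraction is the ring-to-disc area ratio

    F = (d_f² − (d_f − d_a)²) / d_f² ,

evaluated per layer with the *median* diameters (not means, matching how
such survey tables are reported; a distribution-level sensitivity analysis
is available through the Monte Carlo sampler). F is clamped to [0, 1]: for
d_a ≥ d_f the formula turns non-monotone and the physical answer is that
the ring covers the disc. The model warns when the clamp engages; the
survey data never reach that regime.

**Bi-component microfibers** have a segmented-pie cross-section of two
polymers and hence more exposed perimeter per cross-section than a plain
cylinder. Their ring area is scaled by the ratio of summed wedge
perimeters to the fiber perimeter (≥ 1), then clamped as above. The ratio
is a required input for bicomponent layers; the packaged survey carries a
nominal assumed value of 3.0 because the underlying wedge measurements are
not part of the survey table.

**Mass.** The per-mask surface mass is M_sf = Σ_ℓ F_ℓ·M_ℓ over
TiO₂-containing layers, where the M_ℓ allocate the ICP-OES total M_tot
(total Ti × 79.88/47.88, the TiO₂/Ti molar-mass ratio). When layers were
digested separately the measured per-layer masses are used; otherwise the
default is an equal split among TiO₂-containing layers, with
`proportional_to_F` as an alternative. The choice is surfaced as a model
argument rather than hidden, because multi-layer masks digested whole
leave the split genuinely unknown; equal split is the least-informative
default. This is why recomputed M_sf values can differ by ~10–20 % from a
survey's own reported numbers, which may also have used unrounded medians.
The measurement uncertainty of M_tot is stored and reported (it motivates
the note that a release of the order of the acceptable level could not be
detected as a before/after mass difference) but is not propagated into F.

**Risk characterization.** The acceptable exposure level per mask
(AEL_mask) defaults to the documented 3.6 µg, anchored on a NOAEC of
0.5 mg/m³ for lung inflammation (repeated-dose rat inhalation) and an
intensive-use scenario of 2 masks per 8-h period. Because the full
derivation chain (inhaled volume, deposition, duration and interspecies
adjustments) is not published alongside the survey table, the
configuration deliberately offers two modes: the documented per-mask
override, and an explicit chain AEL_mask = NOAEC × V_inhaled × 1000 / AF /
masks_per_period in which all adjustments are collapsed into a single
assessment factor AF — a scaffold for sensitivity analysis, not a
reconstruction of the original derivation. The exceedance ratio
M_sf/AEL_mask is reported both at full precision and rounded half away
from zero (the convention that reproduces printed survey cells; note the
survey's own 1220 cell corresponds to 1220.6 from its printed inputs, so
tests treat it as a lower bound).

## Imaging stage

Cross-section micrographs are dark-field-like: dark embedding background,
mid-gray fiber disc, bright high-Z particles.

- **Fiber mask:** Otsu's threshold on the full frame, largest connected
  component, holes filled. Guards reject frames with no plausible fiber
  (foreground below 0.5 % of the frame, or foreground/background contrast
  below 6 background SD — a pure-noise Otsu split fails both).
- **Particle threshold:** Otsu on the fiber-interior gray levels, refined
  to the midpoint of the two class medians so that particle edges are cut
  at half height of the blurred intensity step; measured disc diameters
  then match the true diameter to within about a pixel. A floor of
  median + 6 robust SD (MAD-based) of the interior makes blank fibers
  yield zero detections instead of noise speckle. 8-connected components
  below 9 px are discarded.
- **Constituent splitting:** agglomerate regions are split by marker-based
  watershed on the Euclidean distance transform, with distance peaks at
  least 30 nm apart as markers. This is an automated stand-in for manual
  constituent delineation; 30 nm (vs constituent diameters of ~90–190 nm)
  splits touching pairs without fragmenting single discs. Its residual
  bias — small constituents swallowed by larger cluster members — is
  quantified against synthetic truth in the test suite (median bias well
  under 10 %).
- **Sizing:** minimum/maximum Feret diameters by rotating calipers on the
  convex hull of pixel-*corner* coordinates (corners avoid the systematic
  half-pixel underestimation of center-based hulls; the minimum width of a
  convex polygon is attained flush against a hull edge, so scanning edge
  normals is exact). Verified against a brute-force 0.1° angular scan.
  Border-touching regions are flagged and excluded from size summaries by
  default, since truncation biases the minimum Feret downward.
- **Summaries:** median and IQR (linear-interpolation quantiles, the
  common default, fixed here for cross-language agreement) and the
  number fraction below 100 nm; a population with ≥ 50 % of constituents
  under 100 nm is classified as a nanomaterial under the EC number-based
  definition (boundary inclusive).

## Synthetic data: what it emulates and what it does not

The generator renders whole-fiber cross-sections: anti-aliased fiber disc
and constituent discs, Gaussian blur (1 px), additive Gaussian noise
(SD 0.03 on a [0, 1] gray scale), intensities 0.05/0.45/0.95. Defaults
were chosen once as realistic study conditions: a 4.5 µm fiber at 4 nm/px
keeps the whole fiber in a 1280² frame while a 130 nm particle spans
~33 px; constituent diameters are lognormal (median 130 nm, GSD 1.6,
inside the 89–184 nm range of reported survey medians); agglomerate
membership is geometric with mean 1.6 ("single and agglomerated"
particles), rendered as chains of overlapping discs with 20 % overlap.
The cluster-size distribution is a free parameter, not a physical
aggregation model. Ground truth records every constituent's diameter and
center and each agglomerate's composite minimum Feret (angular scan of
the union of member discs).

Not emulated: detector physics (MTF, Z-contrast), section-thickness
projection effects, polymer texture, EDX identity of particles, and
real agglomerate morphology. Passing the parameter-recovery tests
therefore shows the measurement chain is unbiased on idealized imagery of
known truth — not that it matches manual measurements on real
micrographs.

The Monte Carlo sampler places agglomerate centers in the cross-section
disc (uniform over area for `homogeneous`; `surface_enriched` /
`core_enriched` bias outward/inward) and counts centers within d_a/2 of
the boundary. For homogeneous placement this event's probability *equals*
the ring-area ratio, so the sampler is an exact independent oracle for
the closed form rather than an approximation; the enriched placements
document the sensitivity of the homogeneity assumption (they bracket the
analytic F strictly).

## Numerical choices and degenerate inputs

- Rounding for report parity with printed survey tables: half away from
  zero, fractions to integer percent, masses to integer µg; full precision
  retained everywhere internally.
- Tables: CSV, UTF-8, `NA` for absent values, fixed units per column
  (µm/nm/µg) validated at read time; thousands separators normalized at
  ingest. Layers in which TiO₂ was not observed carry
  `contains_tio2=false` and no sizes.
- Degenerate inputs: all-constant images yield zero regions (not an
  error); an absent fiber is a detection error only where a fiber is
  required; empty measurement sets after filtering raise a validation
  error naming the filter; a mask with positive M_tot but no
  TiO₂-containing layer is an inconsistency error; writing an empty
  report is refused.
- Determinism: one integer seed per artifact drives a dedicated
  `numpy.random.Generator`; identical seeds give bit-identical images,
  fixtures and reports.

## Problem sizes used in the checks

The Monte Carlo/closed-form equivalence is checked on a 3×3 grid spanning
d_f ∈ [7, 35] µm × d_a ∈ [110, 450] nm at 10⁵ samples per point (3
binomial SE criterion); parameter recovery pools three default images
(~220 constituents after border exclusion), chosen to keep the whole
suite fast while leaving the statistical criteria well-powered.

## Known limitations

- The model estimates surface *presence*, not release: no abrasion,
  detachment or migration kinetics (sub-5 nm migration is excluded by the
  polymer physics and not modelled).
- Medians in, medians out: F from median d_f and d_a is not the
  population mean of F over the joint size distributions.
- The equal-split mass allocation is a convention, not a measurement.
- The watershed constituent splitter under-segments heavily overlapping
  clusters; its bias is measured, not zero.
- The AEL chain's assessment factor is a single collapsed number; no
  probabilistic risk assessment and no vulnerable-population adjustment.
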