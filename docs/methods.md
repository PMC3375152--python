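# Methods

## Input model and coordinate conventions

An annotation of one digitized lateral lumbar radiograph consists of, per
image and observer session: four vertebral landmark sets (L1–L4, four
corners ordered anterior-superior → posterior-superior →
posterior-inferior → anterior-inferior, plus two mid-edge points), an
anterior and a posterior abdominal-aorta wall polyline ordered cranial →
caudal, and any number of closed simple polygons outlining calcified
deposits. Coordinates are image-style — origin top-left, x increasing
anterior → posterior, y increasing cranial → caudal — and are converted
from pixels to millimetres on read using the stored pixel size (default
0.0446 mm, the pitch of film digitized at 44.6 µm). All downstream
computation is in mm, which makes every marker independent of the
digitization resolution. Deposit rings are stored open; readers accept a
duplicated closure vertex. The mid-edge landmarks are stored and validated
but unused by the markers; they serve vertebral morphometry only.

## The aortic region

All markers refer to the lumbar aortic region adjacent to L1–L4. The
annotation is first rotated into a canonical frame in which the vertebral
axis (L1 superior endplate midpoint → L4 inferior endplate midpoint) points
caudally; this single step makes the whole marker panel invariant under
rigid motions of the annotation, which is also how the invariance is
tested. In that frame:

* the cranial and caudal cuts are the horizontal levels of the L1 superior
  and L4 inferior endplates (mean y of the respective corner pairs);
* each wall is clipped to that band (walls must be y-monotone — hand-drawn
  aortic walls are — and must span the vertebral range);
* the region boundary is the polygon enclosed by the two clipped walls;
* each wall is cut into four sections at the mid-levels between
  consecutive vertebrae's facing endplates. The section boundaries
  partition each wall's arclength exactly (checked to 1e-6 mm). Where one
  vertebra's "adjacent" aortic section ends is not anatomically defined;
  the landmark mid-level rule is symmetric and reproducible, which is why
  it was chosen.

The longitudinal axis used by the length marker is the chain of midpoints
of fractional-arclength pairs on the two clipped walls (201 samples),
smoothed by a 9-sample moving average with reflected ends. Smoothing
matters: the raw midpoint chain inherits the walls' annotation jitter, and
nearest-point projection onto a kinked polyline is ill-conditioned — points
a hair apart can project several tenths of a millimetre apart around a
concave kink. The smoothed axis preserves the vessel's global curvature
(the only property the marker needs) while making projections stable.

## Markers

**Projection and wall coverage.** Deposits are projected by nearest-point
projection, each sampled point (boundary densified at 0.05 mm plus a
0.2 mm interior grid) going to the *nearer* wall, so mid-lumen lesions
split between walls; a sample counts as belonging to a wall only if it is
at least 15% nearer to it than to the other wall, and closer-to-tie
samples are treated as internal and not projected (exactly at a tie the
projected arclength is discontinuous, so tie-zone samples would make the
footprint depend on sampling noise). A deposit's footprint on a wall is
the interval hull (min-to-max arclength span) of its projected samples —
the wall stretch shadowed by the lesion. The hull is used rather than the
raw union of projected points because the nearest-point map onto a rough
polyline skips sub-millimetre arcs around concave kinks; the raw image's
gap structure is therefore a sampling artefact, while the hull endpoints
are well conditioned (implementation and brute-force oracle agree within
2% on wall coverage on all but ~1 in 300 random fixtures; with
run-merging semantics the two routes disagreed by up to 11% depending on
sampling density). A residual instability of roughly ±0.3 mm per deposit
remains wherever the 15% dominance contour crosses a flat stretch of the
wall-distance function — an intrinsic conditioning limit of any
nearest-point split, worth knowing when comparing independent
re-implementations. Footprints are unioned across deposits and clipped to
the in-region arclength. The standalone `project_deposit_to_wall`
operation additionally offers the merged-run form of the projection image
for callers that want it.

**AC24.** For each of the eight sections the covered fraction f of the
section's arclength is graded 0 (f = 0), 1 (f < 1/3), 2 (1/3 ≤ f < 2/3),
3 (f ≥ 2/3) and the grades are summed. Grade boundaries are closed from
below — a section covered on exactly one third grades 2 — with a 1e-9
tolerance absorbing float round-off at the tie points. With no deposits the
score is 0 by construction.

**Area and simulated area.** Plain polygon area of the deposit union
intersected with the region, as a percentage of the region area. The
simulated-plaque variant first dilates the deposit union with a disc of
radius 8.92 mm (200 px × 0.0446 mm) — the Minkowski sum, computed as a
polygon buffer with a 256-segment circle approximation (area error of the
disc ≈ 0.01%). Radiographs show only the calcified core of a plaque; the
dilation emulates the surrounding inflamed tissue, whose histological
extent (≈ 3–10 mm) brackets the radius. The dilated footprint is clipped
to the region by default (`clip_sim_to_region=False` reports the unclipped
ratio, which can exceed 100). Dilation of a raster mask with a disc
footprint is also provided; polygon and raster routes agree within 1% in
area at 0.05 mm resolution.

**Thickness.** Stations are placed every 0.5 mm of arclength along each
clipped wall, at interval midpoints so that no station chord degenerates
onto the cranial/caudal cut lines (where a chord would run collinearly
with a clipped deposit edge and the measure would be ambiguous). At each
station the cross-aorta chord runs to the nearest point of the opposite
wall; the marker is the mean over *all* stations of calcified chord length
over chord length. Averaging over all stations — not only calcified ones —
is what makes the marker a whole-aorta burden measure; zero-inclusive
averaging is also the only reading under which typical cohort thickness
distributions (means far below any plausible per-lesion thickness ratio)
are reproducible. Stations with near-zero width (touching walls) are
skipped with a warning.

**Length.** Each in-region deposit part projects onto the smoothed midline
and contributes its span; the marker is the union length of the spans over
the midline length.

**NCD.** Deposit outlines whose closed footprints intersect *or touch* are
merged (union–find over a spatial index); the count is the number of
merged components intersecting the region. Touch-merging makes the count —
and through shared projection semantics the whole panel — invariant to
subdividing one deposit into abutting outlines, and avoids
raster-resolution artefacts. Deposits partly outside the region contribute
only their in-region parts to area/thickness/length; a component counts
toward NCD if any part intersects the region.

## Agreement statistics

* **Jaccard**: intersection-over-union of the rasterized deposit unions of
  two annotations of the same image, on a shared frame at the marker
  raster resolution (0.05 mm). Two empty annotations score 1 (agreement
  that nothing is calcified); empty vs non-empty scores 0. Pixel-wise
  Cohen's κ is deliberately not offered: the huge non-calcified class
  would dominate it.
* **Mean CV**: per image, the coefficient of variation (sd/mean, n−1
  denominator) of a marker across repeated annotations; intra-observer
  pairs sessions within observer (then averages over observers), inter-
  observer pairs observers within session (then averages over sessions);
  the statistic is the mean over images, in percent. Zero-mean groups are
  excluded with a warning (CV undefined). The pairing scheme is
  configurable in the sense that both modes are exposed; other groupings
  are defensible.
* **Kendall's W**: W = 12S / (m²(n³−n) − mΣT) with mid-ranks for ties and
  the per-rater tie correction T = Σ(t³−t). Constant ratings by all raters
  make the denominator vanish and raise a degeneracy error.

## Survival evaluation

Hazard ratios are reported per one-SD change of the raw marker; the SD is
the full analysis cohort's (zero-calcification subjects included), so the
HR is invariant to affine rescaling of the marker. Deaths outside the
chosen endpoint (CVD, CVD+cancer, or all-cause) are right-censored at the
death time; relabelling out-of-endpoint deaths as censored reproduces the
endpoint fit exactly, which is tested. Fits use lifelines'
`CoxPHFitter` (Efron tie approximation, Wald tests, 95% normal CIs). Two
consequences are documented rather than fought: duplicating every subject
creates ties and thus moves the Efron estimate by O(1e-3) (exact
duplication invariance holds only for Breslow), and an exactly collinear
composite/marker pair makes the partial likelihood singular — the fit then
warns and adds a small L2 ridge (1e-2) so the attenuation behaviour stays
observable.

Composite biological adjustment fits the biological set alone, combines it
into one variable with the fitted β-weights, and refits marker +
composite. Note that hazard ratios are non-collapsible: adjusting for a
truly prognostic covariate shifts even an independent marker's estimate
upward; exact invariance under adjustment is expected (and tested) only
when the biological set has no true effect.

Backwards stepwise deletion standardizes all markers, drops perfectly
collinear later-listed duplicates with a warning, then repeatedly removes
the marker with the largest Wald p ≥ α (one per iteration, no re-entry)
until all remaining markers are significant or none remain.

## Synthetic data

The generator emulates the geometry of annotated lumbar radiographs, not
their pixel content. Defaults, chosen as typical study conditions:

| parameter | default | note |
|---|---|---|
| vertebra heights | 4 × 35 mm | lumbar body heights; region length 140 mm |
| aortic width | 6 mm (±8% modulation) | wall polylines 3–8 mm apart |
| curvature amplitude | 3 mm | gentle lateral bow |
| wall roughness | 0.15 mm | hand-tracing jitter on 2 mm vertex spacing |
| zero-calcification fraction | 0.39 | subjects with an empty panel |
| deposits per calcified subject | 1 + Poisson(5), max 40 | longitudinally clustered |
| deposit extent | log-normal, median 2.2 mm, clipped 0.5–10 mm | perturbed-ellipse outlines |
| wall affinity | 0.45 / 0.45 / 0.10 | anterior / posterior / internal |
| covariates | age 60.3 ± 7.5 yr, smoking 37%, triglycerides 1.24 ± 0.75 mmol/L, cholesterol 6.44 ± 1.19 mmol/L, systolic BP 127 ± 21 mmHg, HDL-C 1.77 ± 0.48 mmol/L, hypertension 16%, SCORE 2.60 ± 2.58, Framingham 14.75 ± 3.54 | published postmenopausal reference moments; composites share a latent risk factor with their ingredients |
| survival | exponential, baseline 0.02/yr, censoring 8.5 yr | closed-form event fraction 1−e^(−0.17) ≈ 15.7% at null |
| causes of death | CVD 0.385 / cancer 0.519 / other 0.096 | fixed mixture, independent of the linear predictor |

Re-annotation noise applies smooth radial jitter (low-frequency Fourier
perturbation plus a centroid shift) to each deposit outline, lateral-only
smooth jitter to the walls (preserving y-monotonicity), stochastic deposit
dropping and spurious small additions; landmarks stay fixed. Expected
overlap with the original decreases monotonically in the jitter amplitude.

Cohorts come in two modes. `annotation` mode draws an annotation per
subject and runs the full marker pipeline — the end-to-end path, used for
the determinism/smoke checks at n = 300. `parametric` mode draws the
marker panel directly from a zero-inflated log-normal model (shared latent
severity, correlation 0.7; zero fraction 0.39) — orders of magnitude
faster, used for the estimator-calibration studies (100 replicates at
n = 1000), where the hazard model, not the marker provenance, is under
test. Event times are exponential under a linear predictor of z-scored
columns, so coefficients are per SD by construction; survival times are
optionally Weibull-free by design — constant baseline hazard keeps every
calibration check closed-form.

What passing tests on synthetic data do **not** show: fidelity of any
marker to real radiographic appearance, observer behaviour beyond the
jitter model (real observers disagree systematically, not radially), or
cause-specific hazards (causes are a label mixture here; competing-risks
modelling is out of scope).

## Numerical choices

* Raster resolution 0.05 mm (≈ native pixel pitch), frames padded by the
  dilation radius so dilation never clips; masks count cell centres inside
  the polygon union (even-odd rule); > 1e8 cells is an error.
* Deposit sampling for projections: boundary densified at 0.2 mm, interior
  grid at the same step (a mid-lumen deposit's far-wall strip can be
  arbitrarily thin); length-marker spans use a 0.05 mm boundary step
  because span endpoints inherit the sampling error directly.
* The brute-force cross-check route shares no geometry code with the
  implementation: matplotlib-path point-in-polygon rasterization,
  `scipy.ndimage` distance transforms (dilation) and labelling
  (components), k-d-tree nearest-neighbour projection refined to exact
  segment projection, and exact segment–polygon crossing arithmetic for
  chord clipping.
* AC24 tie tolerance 1e-9; interval pruning threshold 1e-9 mm; buffer
  circle approximation 64 quadrant segments.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global state. Identical seeds give
  byte-identical serialized outputs.

## Limitations

* The markers operate on manual outlines; automated calcification
  detection is out of scope.
* Wall-coverage spans (the interval-hull semantics) slightly overcount
  coverage for strongly concave lesions relative to the raw projection
  image; the difference is below the geometric validation tolerance on
  realistic shapes.
* The Cox layer censors out-of-endpoint deaths rather than modelling
  competing risks (no Fine–Gray), and SCORE/Framingham are consumed as
  given columns, never computed from raw risk factors.
* The dilation radius default (8.92 mm) is a fixed physical constant of
  the method; the parameter study that would justify re-deriving it on new
  data is not part of the package.
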