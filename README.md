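# aacmorph

Morphometric scoring of **abdominal aortic calcification (AAC)** from
manually annotated lateral lumbar radiographs.

Calcified deposits in the abdominal aorta are a strong, cheaply observable
predictor of cardiovascular mortality: they are visible on the same lateral
spine films acquired for osteoporosis screening. The standard severity
grade, **AC24**, scores the calcified coverage of the anterior and
posterior aortic wall next to each lumbar vertebra L1–L4 on a 0–3 scale and
sums the eight grades (0–24). `aacmorph` computes AC24 from outline
annotations, plus six continuous morphometric markers that capture size,
shape and spread of the lesions, and provides the statistical machinery to
evaluate such markers: observer-agreement statistics for repeated
annotations and Cox proportional-hazards models for right-censored
mortality follow-up.

## Markers

Given one annotation — vertebral corner/mid landmarks for L1–L4, anterior
and posterior aortic wall polylines, and closed deposit outlines, all in mm
— the package builds the lumbar aortic region between the walls (cranial
cut at the L1 superior endplate, caudal cut at the L4 inferior endplate)
and computes:

| marker | definition |
|---|---|
| `ac24` | Σ over 8 wall sections of grade(f): 0 if f = 0, 1 if f < 1/3, 2 if 1/3 ≤ f < 2/3, 3 if f ≥ 2/3, where f is the covered fraction of the section's arclength under nearest-wall projection of the deposits |
| `area_pct` | 100 · area(deposits ∩ region) / area(region) |
| `sim_area_pct` | as `area_pct` after morphological dilation of the deposits with a disc of radius 8.92 mm (Minkowski sum), simulating the inflamed plaque surrounding the calcified core |
| `thickness_pct` | mean over cross-aorta stations (every 0.5 mm of wall arclength) of calcified chord length / lumen width |
| `wall_pct` | 100 · covered wall arclength / total wall arclength (both walls) |
| `length_pct` | 100 · longitudinal extent of deposits along the (smoothed) aortic midline / midline length |
| `ncd` | number of distinct deposits (touching or overlapping outlines merge) |

Agreement statistics: the **Jaccard index** |A₁∩A₂| / |A₁∪A₂| of two
rasterized outlines, mean **coefficients of variation** of markers over
repeated annotations (inter-/intra-observer pairings), and **Kendall's
coefficient of concordance W** with mid-rank tie correction.

Survival evaluation: hazard ratios per SD of each marker from Cox
regression (Efron ties, Wald tests), composite biological adjustment (a
β-weighted combination of biological covariates entered alongside the
marker), and backwards stepwise deletion until all retained markers have
p < α.

Because no radiograph set ships with the package, a synthetic module
generates annotations (curved, roughly parallel walls 3–8 mm apart spanning
L1–L4, zero-inflated deposit counts, log-normal deposit sizes), blinded
re-annotations (outline jitter, deposit drop/add), and survival cohorts
with known log-hazard coefficients — every computation is testable against
ground truth and against an independent brute-force raster oracle.

## Worked example

```python
from aacmorph import (gen_annotation, perturb_annotation, compute_panel,
                      jaccard_annotations)
from aacmorph.synthetic import CohortSpec, gen_cohort
from aacmorph.survival import fit_marker_cox

a = gen_annotation(seed=2)                      # one synthetic radiograph annotation
print(compute_panel(a).as_dict())
# {'ac24': 6, 'area_pct': 7.81, 'sim_area_pct': 56.19, 'thickness_pct': 8.17,
#  'wall_pct': 14.58, 'length_pct': 18.9, 'ncd': 7}

b = perturb_annotation(a, boundary_noise_mm=0.4, seed=3, observer_id="obs2")
print(jaccard_annotations(a, b))                # 0.771

cohort = gen_cohort(CohortSpec(n=1000, beta={"ncd": 0.7}, seed=11))
res = fit_marker_cox(cohort, "ncd", endpoint="all")
print(res.hr, res.ci95, res.n_events)           # 2.00 (1.80, 2.23) 186
```

The panel says: deposits cover 7.8% of the aortic region area, and after
simulating the surrounding inflamed plaque by an 8.92 mm dilation, 56% of
the region; eight wall sections sum to AC24 = 6; seven distinct deposits.
The re-annotation with 0.4 mm outline jitter overlaps the original with
Jaccard 0.77. In the simulated cohort (true log-hazard 0.7 per SD of the
deposit count, i.e. HR e^0.7 ≈ 2.01), the fitted hazard ratio per SD is
2.00 with 95% CI 1.80–2.23 over 186 deaths.

The same steps are available from the shell:

```sh
aacmorph simulate annotations --n 8 --repeats 3 --seed 1 --out ann/
aacmorph validate ann/img-000_obs1_s1.json
aacmorph markers ann/img-000_obs1_s1.json --out panel.csv
aacmorph reliability ann/ --mode inter --out agreement.csv
aacmorph simulate cohort --n 300 --seed 1 --beta '{"ncd": 0.7}' --out cohort.csv
aacmorph survival cohort.csv --endpoint all --adjust bio --stepwise --out cox.csv
```

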