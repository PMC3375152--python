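"""Synthetic annotations, noisy re-annotations and survival cohorts.

No study radiographs are distributed with the package, so every downstream
module is exercised on synthetic data with known ground truth:

* :func:`gen_annotation` draws one plausible lumbar annotation — four
  stacked vertebrae, two roughly parallel, gently curved aortic wall
  polylines a few mm apart, and a configurable number of convex-ish
  calcified-deposit outlines attached near a wall or mid-lumen;
* :func:`perturb_annotation` emulates blinded re-annotation of the same
  radiograph: smooth radial jitter of the deposit outlines, smooth lateral
  wall jitter, and stochastic deposit dropping/spurious addition;
* :func:`gen_cohort` builds a survival cohort: marker panels (either
  computed from per-subject synthetic annotations or drawn from a
  zero-inflated log-normal marker model), biological covariates
  parameterized to published postmenopausal reference means/SDs, and
  exponential proportional-hazards event times with administrative
  censoring at 8.5 years and a fixed cause-of-death mixture.

All randomness flows from explicit integer seeds; identical seeds give
byte-identical serialized outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .annotation import (
    AnnotationSet,
    DepositOutline,
    VertebraLandmarks,
    WallPolyline,
    DEFAULT_PIXEL_SIZE_MM,
)
from .markers import MARKER_NAMES, MarkerConfig, compute_panel


class SpecError(ValueError):
    """A synthetic specification is internally infeasible."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AortaSpec:
    """Geometry of the synthetic lumbar aorta and vertebral column (mm)."""

    vertebra_heights_mm: tuple = (35.0, 35.0, 35.0, 35.0)
    mean_width_mm: float = 6.0
    curvature_mm: float = 3.0
    roughness_mm: float = 0.15
    endplate_inset_mm: float = 1.0

    @property
    def length_mm(self) -> float:
        return float(sum(self.vertebra_heights_mm))

    def __post_init__(self):
        if self.mean_width_mm <= 0:
            raise SpecError("aorta width must be positive")
        if any(h <= 0 for h in self.vertebra_heights_mm) or len(self.vertebra_heights_mm) != 4:
            raise SpecError("need 4 positive vertebra heights")


@dataclass(frozen=True)
class DepositSpec:
    """Distributional model of calcified deposits on one radiograph.

    By default ~39% of subjects carry no calcification at all; calcified
    subjects carry a truncated-Poisson number of deposits of log-normal
    extent 0.5-10 mm, preferentially attached to a wall and longitudinally
    clustered.
    """

    count: int | None = None          # fixed count overriding the distribution
    zero_prob: float = 0.39
    mean_count: float = 6.0
    max_count: int = 40
    size_log_mu: float = math.log(2.2)
    size_log_sigma: float = 0.55
    size_range_mm: tuple = (0.5, 10.0)
    affinity: tuple = (0.45, 0.45, 0.10)   # anterior, posterior, internal
    cluster_rate: float = 1.5
    cluster_sd_mm: float = 12.0
    min_separation_mm: float = 0.0

    def __post_init__(self):
        if self.count is not None and self.count < 0:
            raise SpecError("deposit count must be >= 0")
        if self.size_range_mm[0] <= 0:
            raise SpecError("deposit sizes must be positive")
        if abs(sum(self.affinity) - 1.0) > 1e-9:
            raise SpecError("affinity probabilities must sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic survival cohort with known log-hazard coefficients.

    ``beta`` maps marker/covariate column names to true log-hazard
    coefficients per SD.  Administrative censoring at 8.5 years emulates an
    8-9 year follow-up window; the cause mixture defaults to the observed
    CVD/cancer/other split of deaths in such cohorts (roughly 20:27:5).
    """

    n: int = 300
    beta: dict = field(default_factory=dict)
    baseline_hazard_per_yr: float = 0.02
    censor_years: float = 8.5
    cause_mix: tuple = (0.385, 0.519, 0.096)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise SpecError("cohort size must be >= 1")
        if self.censor_years <= 0 or self.baseline_hazard_per_yr <= 0:
            raise SpecError("censoring time and baseline hazard must be positive")
        if abs(sum(self.cause_mix) - 1.0) > 1e-9:
            raise SpecError("cause mixture must sum to 1")


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

def _wall_x(y: np.ndarray, aorta: AortaSpec, phase: float, width_phase: float):
    """Centreline and local width of the synthetic aorta at heights y."""
    L = aorta.length_mm
    centre = 8.0 + aorta.curvature_mm * np.sin(np.pi * y / L + phase)
    width = aorta.mean_width_mm * (1.0 + 0.08 * np.sin(2 * np.pi * y / L + width_phase))
    return centre, width


def _lumen_polygon(walls: dict[str, WallPolyline]) -> Polygon:
    ring = np.vstack([walls["anterior"].points, walls["posterior"].points[::-1]])
    return Polygon(ring)


def _deposit_polygon(rng: np.random.Generator, centre: np.ndarray,
                     half_w: float, half_l: float, n_vert: int = 16) -> Polygon:
    """Perturbed-ellipse outline: convex-ish, simple, positive area."""
    theta = np.linspace(0.0, 2 * np.pi, n_vert, endpoint=False)
    mod = np.ones_like(theta)
    for h in (2, 3, 4):
        mod += rng.uniform(0.0, 0.10) * np.cos(h * theta + rng.uniform(0, 2 * np.pi))
    mod = np.clip(mod, 0.5, 1.5)
    xy = np.column_stack([centre[0] + half_w * mod * np.cos(theta),
                          centre[1] + half_l * mod * np.sin(theta)])
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _largest_polygon(geom) -> Polygon | None:
    if geom.is_empty:
        return None
    if isinstance(geom, Polygon):
        return geom
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    return max(polys, key=lambda g: g.area) if polys else None


def _draw_count(dep: DepositSpec, rng: np.random.Generator) -> int:
    if dep.count is not None:
        return dep.count
    if rng.random() < dep.zero_prob:
        return 0
    c = 1 + rng.poisson(max(dep.mean_count - 1.0, 0.0))
    return int(min(c, dep.max_count))


def gen_annotation(aorta: AortaSpec = AortaSpec(),
                   dep: DepositSpec = DepositSpec(),
                   seed: int = 0,
                   image_id: str | None = None,
                   observer_id: str = "sim",
                   session_id: str = "1") -> AnnotationSet:
    """Draw one synthetic annotation; deterministic for a fixed seed.

    The returned annotation passes :func:`~aacmorph.annotation.validate_annotation`
    with zero violations; its deposit outlines are the ground truth for the
    marker computations.
    """
    rng = np.random.default_rng(seed)
    L = aorta.length_mm
    levels = np.concatenate([[0.0], np.cumsum(aorta.vertebra_heights_mm)])
    inset = aorta.endplate_inset_mm

    # vertebral column posterior (larger x) of the aorta
    vx_a, vx_p = 18.0, 48.0
    vertebrae: dict[str, VertebraLandmarks] = {}
    for k, lab in enumerate(("L1", "L2", "L3", "L4")):
        y_top, y_bot = levels[k] + inset, levels[k + 1] - inset
        j = rng.uniform(-0.3, 0.3, size=(4, 2))
        corners = np.array([
            [vx_a, y_top], [vx_p, y_top], [vx_p, y_bot], [vx_a, y_bot],
        ]) + j
        mids = np.array([[vx_a, (y_top + y_bot) / 2], [vx_p, (y_top + y_bot) / 2]])
        mids = mids + rng.uniform(-0.3, 0.3, size=(2, 2))
        vertebrae[lab] = VertebraLandmarks(lab, corners, mids)

    phase = rng.uniform(-0.3, 0.3)
    width_phase = rng.uniform(0, 2 * np.pi)
    y_grid = np.arange(-6.0, L + 6.0 + 1e-9, 2.0)
    centre, width = _wall_x(y_grid, aorta, phase, width_phase)
    noise_a = rng.normal(0.0, aorta.roughness_mm, size=len(y_grid))
    noise_p = rng.normal(0.0, aorta.roughness_mm, size=len(y_grid))
    ant = np.column_stack([centre - width / 2 + noise_a, y_grid])
    post = np.column_stack([centre + width / 2 + noise_p, y_grid])
    walls = {"anterior": WallPolyline("anterior", ant),
             "posterior": WallPolyline("posterior", post)}
    lumen = _lumen_polygon(walls).buffer(-0.05)

    n_dep = _draw_count(dep, rng)
    max_size = min(dep.size_range_mm[1], 0.95 * aorta.mean_width_mm
                   if dep.size_range_mm[0] > aorta.mean_width_mm else dep.size_range_mm[1])
    if dep.size_range_mm[0] > aorta.mean_width_mm * 2:
        raise SpecError("deposits larger than the lumen cannot be placed")

    n_clusters = max(1, 1 + rng.poisson(dep.cluster_rate))
    cluster_centres = rng.uniform(5.0, L - 5.0, size=n_clusters)

    deposits: list[DepositOutline] = []
    placed: list[Polygon] = []
    attempts = 0
    while len(deposits) < n_dep and attempts < 40 * max(n_dep, 1):
        attempts += 1
        y_c = float(np.clip(cluster_centres[rng.integers(n_clusters)]
                            + rng.normal(0.0, dep.cluster_sd_mm), 2.0, L - 2.0))
        size = float(np.clip(rng.lognormal(dep.size_log_mu, dep.size_log_sigma),
                             dep.size_range_mm[0], max_size))
        half_l = size / 2.0
        c_x, w_loc = _wall_x(np.array([y_c]), aorta, phase, width_phase)
        c_x, w_loc = float(c_x[0]), float(w_loc[0])
        half_w = min(size / 2.0 * rng.uniform(0.3, 0.8), 0.45 * w_loc)
        side = rng.choice(3, p=dep.affinity)
        if side == 0:       # anterior
            cx = c_x - w_loc / 2 + half_w * rng.uniform(0.9, 1.3)
        elif side == 1:     # posterior
            cx = c_x + w_loc / 2 - half_w * rng.uniform(0.9, 1.3)
        else:               # internal / mid-lumen
            cx = c_x + rng.uniform(-0.2, 0.2) * w_loc
        poly = _deposit_polygon(rng, np.array([cx, y_c]), half_w, half_l)
        poly = _largest_polygon(poly.intersection(lumen))
        if poly is None or poly.area < 0.05:
            continue
        if dep.min_separation_mm > 0 and placed:
            buffered = poly.buffer(dep.min_separation_mm)
            if any(buffered.intersects(p) for p in placed):
                continue
        placed.append(poly)
        verts = np.asarray(poly.exterior.coords)[:-1]
        deposits.append(DepositOutline(verts))
    if len(deposits) < n_dep:
        warnings.warn(f"placed only {len(deposits)}/{n_dep} deposits "
                      f"(separation/lumen constraints)")

    return AnnotationSet(
        image_id=image_id or f"sim-{seed:08d}",
        observer_id=observer_id,
        session_id=session_id,
        pixel_size_mm=DEFAULT_PIXEL_SIZE_MM,
        vertebrae=vertebrae,
        walls=walls,
        deposits=deposits,
    )


# ---------------------------------------------------------------------------
# Re-annotation perturbation
# ---------------------------------------------------------------------------

def _jitter_outline(rng: np.random.Generator, vertices: np.ndarray,
                    noise_mm: float) -> np.ndarray:
    """Smooth radial jitter plus a small centroid shift of a closed outline."""
    centroid = vertices.mean(axis=0)
    rel = vertices - centroid
    r = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    disp = np.zeros_like(r)
    for h in (1, 2, 3):
        disp += rng.normal(0.0, noise_mm / math.sqrt(3)) * np.cos(h * theta + rng.uniform(0, 2 * np.pi))
    shift = rng.normal(0.0, noise_mm / 2.0, size=2)
    r_new = np.maximum(r + disp, 0.05)
    out = centroid + shift + np.column_stack([r_new * np.cos(theta),
                                              r_new * np.sin(theta)])
    poly = Polygon(out)
    if not poly.is_valid:
        poly = _largest_polygon(poly.buffer(0))
        if poly is None:
            return vertices
        out = np.asarray(poly.exterior.coords)[:-1]
    return out


def perturb_annotation(a: AnnotationSet,
                       boundary_noise_mm: float = 0.3,
                       drop_rate: float = 0.0,
                       add_rate: float = 0.0,
                       seed: int = 0,
                       wall_noise_mm: float | None = None,
                       session_id: str | None = None,
                       observer_id: str | None = None) -> AnnotationSet:
    """Simulate a blinded re-annotation of the same radiograph.

    Deposit outlines receive smooth radial jitter of amplitude
    ``boundary_noise_mm``; each deposit is dropped with probability
    ``drop_rate`` and spurious small deposits are added at rate
    ``add_rate`` per existing deposit.  Walls receive a smooth lateral
    (x-only) perturbation of amplitude ``wall_noise_mm`` (default half the
    boundary noise), preserving their cranio-caudal monotonicity.
    Landmarks are left fixed.  Expected overlap with the original decreases
    monotonically with the boundary noise.
    """
    if boundary_noise_mm < 0:
        raise ValueError("boundary noise must be >= 0")
    rng = np.random.default_rng(seed)
    if wall_noise_mm is None:
        wall_noise_mm = boundary_noise_mm / 2.0

    walls = {}
    for side, w in a.walls.items():
        pts = w.points.copy()
        if wall_noise_mm > 0:
            y = pts[:, 1]
            span = max(y.max() - y.min(), 1.0)
            dx = np.zeros_like(y)
            for h in (1, 2, 3):
                dx += rng.normal(0.0, wall_noise_mm / math.sqrt(3)) \
                    * np.sin(2 * np.pi * h * (y - y.min()) / span + rng.uniform(0, 2 * np.pi))
            pts[:, 0] = pts[:, 0] + dx
        walls[side] = WallPolyline(side, pts)

    deposits: list[DepositOutline] = []
    for d in a.deposits:
        if drop_rate > 0 and rng.random() < drop_rate:
            continue
        if boundary_noise_mm > 0:
            deposits.append(DepositOutline(_jitter_outline(rng, d.vertices,
                                                           boundary_noise_mm)))
        else:
            deposits.append(DepositOutline(d.vertices.copy()))

    if add_rate > 0:
        n_add = rng.poisson(add_rate * max(1, len(a.deposits)))
        lumen = _lumen_polygon(walls).buffer(-0.05)
        ys = a.walls["anterior"].points[:, 1]
        for _ in range(n_add):
            y_c = rng.uniform(ys.min() + 2.0, ys.max() - 2.0)
            size = float(np.clip(rng.lognormal(0.0, 0.4), 0.5, 3.0))
            xs = np.interp(y_c, a.walls["anterior"].points[:, 1],
                           a.walls["anterior"].points[:, 0])
            xp = np.interp(y_c, a.walls["posterior"].points[:, 1],
                           a.walls["posterior"].points[:, 0])
            side = rng.random() < 0.5
            half_w = min(size / 2 * 0.6, 0.4 * (xp - xs))
            cx = xs + half_w * 1.1 if side else xp - half_w * 1.1
            poly = _deposit_polygon(rng, np.array([cx, y_c]), half_w, size / 2)
            poly = _largest_polygon(poly.intersection(lumen))
            if poly is not None and poly.area >= 0.05:
                deposits.append(DepositOutline(np.asarray(poly.exterior.coords)[:-1]))

    return AnnotationSet(
        image_id=a.image_id,
        observer_id=observer_id or a.observer_id,
        session_id=session_id or a.session_id,
        pixel_size_mm=a.pixel_size_mm,
        vertebrae=a.vertebrae,
        walls=walls,
        deposits=deposits,
    )


# ---------------------------------------------------------------------------
# Covariates and parametric marker model
# ---------------------------------------------------------------------------

#: (mean, sd) of the biological covariates; published postmenopausal
#: reference values (age in years, lipids mmol/L, BP mmHg)
COVARIATE_MOMENTS = {
    "age": (60.3, 7.5),
    "total_cholesterol": (6.44, 1.19),
    "systolic_bp": (127.0, 21.0),
    "hdl_c": (1.77, 0.48),
    "score": (2.60, 2.58),
    "framingham": (14.75, 3.54),
}
SMOKING_PREVALENCE = 0.37
HYPERTENSION_PREVALENCE = 0.16
TRIGLYCERIDES_MEAN_SD = (1.24, 0.75)

#: mean of each marker among calcified subjects in the log-normal marker
#: model (zero-inflation handles the non-calcified fraction)
_MARKER_CALCIFIED_MEANS = {
    "ac24": 2.7, "area_pct": 1.0, "sim_area_pct": 18.0, "thickness_pct": 18.0,
    "wall_pct": 1.7, "length_pct": 12.0, "ncd": 6.0,
}
_MARKER_LOG_SIGMA = 0.8
_MARKER_LATENT_CORR = 0.7


def gen_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Biological covariates with realistic marginal moments and a shared
    risk structure feeding the composite scores."""
    m = COVARIATE_MOMENTS
    age = rng.normal(*m["age"], size=n)
    smoking = (rng.random(n) < SMOKING_PREVALENCE).astype(int)
    mu_t, sd_t = TRIGLYCERIDES_MEAN_SD
    sig2 = math.log(1.0 + (sd_t / mu_t) ** 2)
    trig = rng.lognormal(math.log(mu_t) - sig2 / 2, math.sqrt(sig2), size=n)
    chol = rng.normal(*m["total_cholesterol"], size=n)
    bp = rng.normal(*m["systolic_bp"], size=n)
    hdl = rng.normal(*m["hdl_c"], size=n)
    hyper = (rng.random(n) < HYPERTENSION_PREVALENCE).astype(int)

    z_age = (age - m["age"][0]) / m["age"][1]
    z_chol = (chol - m["total_cholesterol"][0]) / m["total_cholesterol"][1]
    z_bp = (bp - m["systolic_bp"][0]) / m["systolic_bp"][1]
    z_smoke = (smoking - SMOKING_PREVALENCE) / 0.48
    z_hdl = (hdl - m["hdl_c"][0]) / m["hdl_c"][1]

    latent = 0.45 * z_age + 0.30 * z_smoke + 0.25 * z_chol + 0.25 * z_bp
    score_z = latent + 0.60 * rng.normal(size=n)
    score_z = (score_z - score_z.mean()) / max(score_z.std(ddof=1), 1e-9)
    score = np.maximum(m["score"][0] + m["score"][1] * score_z, 0.0)
    fram_z = latent - 0.20 * z_hdl + 0.25 * hyper + 0.55 * rng.normal(size=n)
    fram_z = (fram_z - fram_z.mean()) / max(fram_z.std(ddof=1), 1e-9)
    framingham = m["framingham"][0] + m["framingham"][1] * fram_z

    return pd.DataFrame({
        "age": age, "smoking": smoking, "triglycerides": trig,
        "total_cholesterol": chol, "systolic_bp": bp, "hdl_c": hdl,
        "hypertension": hyper, "score": score, "framingham": framingham,
    })


def gen_marker_values(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Zero-inflated log-normal marker panel draws.

    A ~39% non-calcified fraction has all markers exactly zero; calcified
    subjects share a latent severity, producing the right-skewed,
    zero-inflated marker distributions (large SD relative to mean) that
    real cohorts show.
    """
    zero = rng.random(n) < 0.39
    latent = rng.normal(size=n)
    out = {}
    for name, mean in _MARKER_CALCIFIED_MEANS.items():
        eps = rng.normal(size=n)
        z = _MARKER_LATENT_CORR * latent + math.sqrt(1 - _MARKER_LATENT_CORR ** 2) * eps
        mu = math.log(mean) - _MARKER_LOG_SIGMA ** 2 / 2
        vals = np.exp(mu + _MARKER_LOG_SIGMA * z)
        if name.endswith("_pct"):
            vals = np.minimum(vals, 100.0)
        if name in ("ncd", "ac24"):
            vals = np.maximum(np.rint(vals), 1)
            if name == "ac24":
                vals = np.minimum(vals, 24)
        vals[zero] = 0.0
        out[name] = vals
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Survival simulation
# ---------------------------------------------------------------------------

def simulate_survival(df: pd.DataFrame, beta: dict, rng: np.random.Generator,
                      baseline_hazard_per_yr: float = 0.02,
                      censor_years: float = 8.5,
                      cause_mix: tuple = (0.385, 0.519, 0.096)) -> pd.DataFrame:
    """Attach exponential proportional-hazards outcomes to a covariate frame.

    The linear predictor is sum of ``beta[name] * z(df[name])`` with z-scores
    computed on the frame itself, so coefficients are per SD.  Deaths get a
    cause label drawn from ``cause_mix`` (cvd, cancer, other); everyone
    else is censored at ``censor_years``.
    """
    n = len(df)
    lp = np.zeros(n)
    for name, b in beta.items():
        if b == 0:
            continue
        x = df[name].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd <= 0:
            raise SpecError(f"column {name!r} is constant; cannot apply beta per SD")
        lp += b * (x - x.mean()) / sd
    rate = baseline_hazard_per_yr * np.exp(lp)
    t = rng.exponential(1.0 / rate)
    event = t <= censor_years
    if not event.any():
        warnings.warn("simulated cohort has no events")
    causes = np.where(event,
                      rng.choice(["cvd", "cancer", "other"], size=n, p=list(cause_mix)),
                      "none")
    out = df.copy()
    out["followup_years"] = np.minimum(t, censor_years)
    out["event"] = causes
    return out


def gen_cohort(cs: CohortSpec,
               mode: str = "parametric",
               aorta: AortaSpec = AortaSpec(),
               dep: DepositSpec = DepositSpec(),
               config: MarkerConfig = MarkerConfig()) -> pd.DataFrame:
    """Generate a full synthetic cohort table, deterministic per seed.

    ``mode='annotation'`` draws a synthetic annotation per subject and runs
    the full marker pipeline on it; ``mode='parametric'`` draws the marker
    panel from the zero-inflated log-normal model directly (orders of
    magnitude faster, used for large simulation studies of the survival
    estimators).
    """
    rng = np.random.default_rng(cs.seed)
    covs = gen_covariates(cs.n, rng)
    if mode == "parametric":
        markers = gen_marker_values(cs.n, rng)
    elif mode == "annotation":
        seeds = rng.integers(0, 2**31 - 1, size=cs.n)
        rows = []
        for i, s in enumerate(seeds):
            ann = gen_annotation(aorta, dep, seed=int(s), image_id=f"subj-{i:05d}")
            rows.append(compute_panel(ann, config).as_dict())
        markers = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    df = pd.concat([markers.reset_index(drop=True),
                    covs.reset_index(drop=True)], axis=1)
    df.insert(0, "subject_id", [f"S{i:05d}" for i in range(cs.n)])
    return simulate_survival(df, cs.beta, rng,
                             baseline_hazard_per_yr=cs.baseline_hazard_per_yr,
                             censor_years=cs.censor_years,
                             cause_mix=cs.cause_mix)
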