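"""Observer-agreement statistics for repeated annotations.

Implements the three statistics used to assess how reproducibly the
calcification outlines and the derived markers can be established:

* the Jaccard index |A1 ∩ A2| / |A1 ∪ A2| of two binary annotation masks,
* mean coefficients of variation (CV) of marker values over repeated
  annotations of the same images, in inter- and intra-observer pairings,
* Kendall's coefficient of concordance W (with mid-rank tie correction)
  between two or more raters scoring the same items.

Cohen's kappa is deliberately not offered: with lesions covering a tiny
fraction of the image, pixel-wise kappa is dominated by the huge
non-calcified class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from shapely.ops import unary_union

from .annotation import AnnotationSet
from .geometry import DEFAULT_RASTER_RES_MM, BinaryMask, rasterize


class AlignmentError(ValueError):
    """Two masks do not share frame/resolution and cannot be compared."""


class DegenerateRatingsError(ValueError):
    """All raters gave constant ratings; concordance is undefined."""


@dataclass
class AgreementReport:
    """Per-image values and summary of one agreement statistic."""

    statistic: str
    per_image: dict[str, float]
    mean: float
    sd: float
    range: tuple[float, float]


def _summarize(statistic: str, per_image: dict[str, float]) -> AgreementReport:
    vals = np.array(list(per_image.values()), dtype=float)
    return AgreementReport(
        statistic=statistic,
        per_image=per_image,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        range=(float(vals.min()), float(vals.max())),
    )


# ---------------------------------------------------------------------------
# Jaccard index
# ---------------------------------------------------------------------------

def jaccard(m1: BinaryMask, m2: BinaryMask) -> float:
    """Intersection-over-union of two binary masks on the same frame.

    Two empty masks agree that nothing is calcified and score 1; an empty
    versus a non-empty mask scores 0.
    """
    if not m1.same_frame(m2):
        raise AlignmentError("masks differ in origin, resolution or shape")
    inter = int(np.logical_and(m1.grid, m2.grid).sum())
    union = int(np.logical_or(m1.grid, m2.grid).sum())
    if union == 0:
        return 1.0
    return inter / union


def jaccard_annotations(a1: AnnotationSet, a2: AnnotationSet,
                        resolution: float = DEFAULT_RASTER_RES_MM) -> float:
    """Jaccard index of the rasterized deposit unions of two annotations of
    the same image, on a common frame covering both."""
    polys1 = [d.polygon for d in a1.deposits]
    polys2 = [d.polygon for d in a2.deposits]
    bounds = [p.bounds for p in polys1 + polys2]
    if not bounds:
        return 1.0
    arr = np.array(bounds)
    frame = (arr[:, 0].min() - resolution, arr[:, 1].min() - resolution,
             arr[:, 2].max() + resolution, arr[:, 3].max() + resolution)
    m1 = rasterize(polys1, frame, resolution)
    m2 = rasterize(polys2, frame, resolution)
    return jaccard(m1, m2)


# ---------------------------------------------------------------------------
# Mean coefficient of variation
# ---------------------------------------------------------------------------

def _cv(values: np.ndarray) -> float | None:
    """sd/mean with n-1 denominator; None for zero mean (undefined)."""
    m = values.mean()
    if abs(m) < 1e-12:
        return None
    return float(values.std(ddof=1) / m)


def mean_cv(measures: pd.DataFrame, mode: str = "inter") -> AgreementReport:
    """Mean coefficient of variation of a marker over repeated annotations.

    ``measures`` has columns ``image_id``, ``observer_id``, ``session_id``
    and ``value`` — one row per annotation of an image.

    * ``intra``: per image and observer, the CV across that observer's
      sessions; averaged over observers, then over images.
    * ``inter``: per image and session, the CV across observers; averaged
      over sessions, then over images.

    Images whose eligible values have zero mean are excluded with a
    warning.  Returns the mean CV as a percentage.
    """
    if mode not in ("inter", "intra"):
        raise ValueError(f"mode must be 'inter' or 'intra', got {mode!r}")
    group_key = "observer_id" if mode == "intra" else "session_id"
    per_image: dict[str, float] = {}
    excluded = []
    for image_id, img in measures.groupby("image_id"):
        cvs = []
        for _, grp in img.groupby(group_key):
            vals = grp["value"].to_numpy(dtype=float)
            if len(vals) < 2:
                continue
            cv = _cv(vals)
            if cv is None:
                excluded.append(image_id)
            else:
                cvs.append(cv)
        if cvs:
            per_image[str(image_id)] = float(np.mean(cvs))
    if excluded:
        warnings.warn(f"mean_cv: excluded zero-mean groups on images {sorted(set(excluded))}")
    if not per_image:
        raise ValueError("mean_cv: no image has >=2 eligible repeated values")
    report = _summarize(f"{mode}-observer CV", per_image)
    report.mean *= 100.0
    report.sd *= 100.0
    report.range = (report.range[0] * 100.0, report.range[1] * 100.0)
    report.per_image = {k: v * 100.0 for k, v in report.per_image.items()}
    return report


def cv_percent(values) -> float:
    """CV (sd/mean, n-1 denominator) of one set of repeats, in percent."""
    vals = np.asarray(values, dtype=float)
    cv = _cv(vals)
    if cv is None:
        raise ValueError("CV undefined for zero-mean values")
    return 100.0 * cv


# ---------------------------------------------------------------------------
# Kendall's coefficient of concordance
# ---------------------------------------------------------------------------

def kendall_w(ratings) -> float:
    """Kendall's W for an (n items x m raters) score table, with mid-rank
    tie correction:

        W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j),

    where S is the sum of squared deviations of the item rank sums from
    their mean and T_j = sum over tie groups of rater j of (t^3 - t).
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2:
        raise ValueError("ratings must be a 2-D items x raters table")
    n, m = table.shape
    if n < 2 or m < 2:
        raise ValueError(f"need >=2 items and >=2 raters, got {n}x{m}")
    ranks = np.column_stack([rankdata(table[:, j]) for j in range(m)])
    rank_sums = ranks.sum(axis=1)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    ties = 0.0
    for j in range(m):
        _, counts = np.unique(table[:, j], return_counts=True)
        ties += float((counts ** 3 - counts).sum())
    denom = m ** 2 * (n ** 3 - n) - m * ties
    if denom <= 0:
        raise DegenerateRatingsError(
            "all raters gave constant ratings; concordance undefined")
    return 12.0 * s / denom


# ---------------------------------------------------------------------------
# Repeated-annotation convenience pipeline
# ---------------------------------------------------------------------------

def pairwise_jaccard(annotations: list[AnnotationSet], mode: str = "inter",
                     resolution: float = DEFAULT_RASTER_RES_MM) -> AgreementReport:
    """Mean pairwise Jaccard index across repeated annotations per image.

    ``inter`` pairs annotations by different observers; ``intra`` pairs
    sessions of the same observer.
    """
    per_image: dict[str, float] = {}
    by_image: dict[str, list[AnnotationSet]] = {}
    for a in annotations:
        by_image.setdefault(a.image_id, []).append(a)
    for image_id, group in by_image.items():
        vals = []
        for a1, a2 in itertools.combinations(group, 2):
            same_obs = a1.observer_id == a2.observer_id
            if (mode == "intra") != same_obs:
                continue
            vals.append(jaccard_annotations(a1, a2, resolution))
        if vals:
            per_image[image_id] = float(np.mean(vals))
    if not per_image:
        raise ValueError(f"no eligible {mode}-observer pairs")
    return _summarize(f"{mode}-observer Jaccard", per_image)


def marker_cv_table(panels: pd.DataFrame, marker_names,
                    mode: str = "inter") -> pd.DataFrame:
    """Mean CV per marker from a table of repeated marker panels.

    ``panels`` has columns ``image_id``, ``observer_id``, ``session_id``
    plus one column per marker.  Returns a DataFrame indexed by marker with
    a ``cv_pct`` column.
    """
    rows = {}
    for name in marker_names:
        df = panels[["image_id", "observer_id", "session_id", name]].rename(
            columns={name: "value"})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows[name] = mean_cv(df, mode=mode).mean
        except ValueError:
            rows[name] = np.nan
    return pd.DataFrame({"cv_pct": rows})
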