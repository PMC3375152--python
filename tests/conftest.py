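import numpy as np
import pytest

from aacmorph.annotation import (
    AnnotationSet,
    DepositOutline,
    VertebraLandmarks,
    WallPolyline,
)

LABELS = ("L1", "L2", "L3", "L4")


def rect(x0, y0, x1, y1):
    """Axis-aligned rectangle as an open vertex ring."""
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


def make_straight_annotation(width=6.0, heights=(30.0, 30.0, 30.0, 30.0),
                             deposits=(), x_centre=10.0, wall_overhang=5.0,
                             wall_step=5.0):
    """Idealized annotation: two parallel vertical walls ``width`` mm apart
    and four stacked vertebrae whose endplates sit exactly at the running
    sum of ``heights`` (so the aortic region spans y in [0, sum(heights)]
    and wall arclength equals y)."""
    heights = tuple(float(h) for h in heights)
    total = sum(heights)
    xa, xp = x_centre - width / 2.0, x_centre + width / 2.0
    ys = np.arange(-wall_overhang, total + wall_overhang + 1e-9, wall_step)
    ant = np.column_stack([np.full(ys.shape, xa), ys])
    post = np.column_stack([np.full(ys.shape, xp), ys])
    levels = np.concatenate([[0.0], np.cumsum(heights)])
    vertebrae = {}
    for k, lab in enumerate(LABELS):
        yt, yb = levels[k], levels[k + 1]
        corners = np.array([[20.0, yt], [40.0, yt], [40.0, yb], [20.0, yb]])
        mids = np.array([[20.0, (yt + yb) / 2], [40.0, (yt + yb) / 2]])
        vertebrae[lab] = VertebraLandmarks(lab, corners, mids)
    return AnnotationSet(
        image_id="toy", observer_id="obs", session_id="1",
        pixel_size_mm=0.0446,
        vertebrae=vertebrae,
        walls={"anterior": WallPolyline("anterior", ant),
               "posterior": WallPolyline("posterior", post)},
        deposits=[DepositOutline(np.asarray(d, dtype=float)) for d in deposits],
    )


def rotate_annotation(a: AnnotationSet, angle_deg: float,
                      centre=(7.0, 31.0), shift=(3.5, -2.0)) -> AnnotationSet:
    """Rigid motion of a whole annotation (rotation + translation)."""
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c = np.asarray(centre)
    t = np.asarray(shift)
    return a.transformed(lambda pts: (pts - c) @ rot.T + c + t)


@pytest.fixture
def straight_annotation():
    return make_straight_annotation()
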