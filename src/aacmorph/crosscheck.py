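"""Side-by-side evaluation of the polygon pipeline and the brute-force
oracle on one annotation.

Used by the validation suite: runs the marker computation and the
independent raster/k-d-tree oracle on identical inputs and returns paired
values for the five continuous geometric markers.
"""

from __future__ import annotations

import numpy as np

from . import oracle as orc
from .annotation import AnnotationSet
from .geometry import build_aorta_region, canonicalize
from .markers import MarkerConfig, compute_panel

GEOMETRIC_MARKERS = ("area_pct", "sim_area_pct", "wall_pct", "length_pct",
                     "thickness_pct")


def marker_pairs(a: AnnotationSet,
                 config: MarkerConfig = MarkerConfig()) -> dict[str, tuple[float, float]]:
    """(implementation, oracle) value pairs for one annotation.

    The oracle rasterizes at ``config.raster_res_mm`` on a frame padded by
    the dilation radius so the simulated-plaque dilation never clips.
    """
    res = config.raster_res_mm
    panel = compute_panel(a, config)
    ac = canonicalize(a)
    region = build_aorta_region(ac.walls, ac.vertebrae)
    region_ring = np.asarray(region.boundary.exterior.coords)
    dep_rings = [d.vertices for d in ac.deposits]

    minx, miny, maxx, maxy = region.boundary.bounds
    r = config.se_radius_mm
    frame = (minx - r - 1, miny - r - 1, maxx + r + 1, maxy + r + 1)
    reg_grid = orc.raster_mask([region_ring], frame, res)
    dep_grid = orc.raster_mask(dep_rings, frame, res)
    dep_in = dep_grid & reg_grid

    area_o = 100.0 * dep_in.sum() / reg_grid.sum()
    sim_o = 100.0 * (orc.dilate_mask_edt(dep_grid, res, r) & reg_grid).sum() / reg_grid.sum()

    ant = region.walls["anterior"].points
    post = region.walls["posterior"].points
    wc = orc.wall_coverage_lengths(dep_rings, ant, post, res)
    wall_total = region.walls["anterior"].length + region.walls["posterior"].length
    wall_o = 100.0 * (wc["anterior"] + wc["posterior"]) / wall_total

    mid = np.asarray(region.midline.coords)
    len_o = 100.0 * orc.midline_coverage_length(dep_rings, mid, region_ring,
                                                res) / region.midline.length
    th_o = 100.0 * orc.thickness_ratio(dep_rings, ant, post, region_ring,
                                       config.station_step_mm, res)
    return {
        "area_pct": (panel.area_pct, area_o),
        "sim_area_pct": (panel.sim_area_pct, sim_o),
        "wall_pct": (panel.wall_pct, wall_o),
        "length_pct": (panel.length_pct, len_o),
        "thickness_pct": (panel.thickness_pct, th_o),
    }
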