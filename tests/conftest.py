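"""Shared fixtures: small rendered fields with ground truth.

Everything is generated at test time from fixed seeds; session scope keeps
the rendering cost paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

import hepcyto as hc


@pytest.fixture(scope="session")
def quiet_field():
    """Noise-free, sparse, all-live field in which every rule passes."""
    cfg = hc.clean_quiet_config(seed=5)
    field, truth = hc.generate_field(cfg)
    return cfg, field, truth


@pytest.fixture(scope="session")
def quiet_analysis(quiet_field):
    """Segmentation + ROIs + raw measurements of the quiet field."""
    cfg, field, truth = quiet_field
    label_map, nuclei = hc.segment_nuclei(
        field.channel("hoechst"), cfg.pixel_size_um
    )
    rois = hc.build_cytosol_rois(label_map, cfg.pixel_size_um)
    records = hc.measure_cells(field, rois, nuclei)
    return cfg, field, truth, label_map, nuclei, rois, records


@pytest.fixture(scope="session")
def clean_field():
    """The standard clean benchmark: ~300 live cells, realistic noise."""
    cfg = hc.standard_clean_config(seed=1)
    field, truth = hc.generate_field(cfg)
    return cfg, field, truth


@pytest.fixture(scope="session")
def small_timelapse():
    """Small renderable movie with a handful of deaths."""
    cfg = hc.demo_timelapse_config(seed=3, n_frames=13)
    fields, truth = hc.generate_timelapse(cfg)
    return cfg, fields, truth


def match_to_truth(nuclei, truth, pixel_size_um):
    """Greedy centroid matching: a nucleus matches the nearest unclaimed
    true cell whose centre lies within one true nucleus radius."""
    tx = truth.centroid_x_px.to_numpy()
    ty = truth.centroid_y_px.to_numpy()
    r_px = truth.radius_um.to_numpy() / pixel_size_um
    matches = {}
    for n in nuclei:
        d = np.hypot(tx - n.centroid_x_px, ty - n.centroid_y_px)
        j = int(np.argmin(d))
        if d[j] <= r_px[j] and j not in matches.values():
            matches[n.label] = j
    return matches
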