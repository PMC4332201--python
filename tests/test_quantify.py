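"""Measurement, background subtraction, exclusion and death-call tests."""

import copy
import dataclasses

import numpy as np
import pytest

import hepcyto as hc
from hepcyto.core import (
    ConfigurationError,
    EmptyInputError,
    InvalidParameterError,
    MissingChannelError,
)
from hepcyto.quantify import (
    CellRecord,
    ChannelStats,
    TimelapseTrace,
    accumulation_ruleset,
    detect_death,
    timelapse_ruleset,
    viability_ruleset,
)
from hepcyto.segment import RoiPair

from conftest import match_to_truth


def make_record(label=1, *, area=90.0, circ=0.95, stats=None, field="f0"):
    rec = CellRecord(label=label, field_id=field, area_um2=area, circularity=circ)
    for key, (mean, sd) in (stats or {}).items():
        rec.stats[key] = ChannelStats(mean=mean, sd=sd, integrated=mean * 100,
                                      pixel_count=100)
    return rec


def random_records(rng, n):
    """Randomised records covering all statistics the rulesets read."""
    recs = []
    for i in range(n):
        recs.append(
            make_record(
                label=i + 1,
                area=float(rng.uniform(10, 500)),
                circ=float(rng.uniform(0.0, 1.3)),
                stats={
                    ("anion", "cytosol"): (rng.uniform(0, 800), rng.uniform(0, 400)),
                    ("lysotracker", "cytosol"): (rng.uniform(0, 400), rng.uniform(0, 200)),
                    ("lysotracker", "nuclear"): (rng.uniform(0, 400), rng.uniform(0, 200)),
                    ("hoechst", "nuclear"): (rng.uniform(10, 600), rng.uniform(0, 300)),
                    ("pi", "nuclear"): (rng.uniform(0, 400), rng.uniform(0, 50)),
                    ("pi", "cytosol"): (rng.uniform(0, 400), rng.uniform(0, 50)),
                },
            )
        )
    return recs


def brute_force_flags(records, ruleset):
    """Independent re-evaluation of every rule, one plain loop per rule."""
    expected = {rec.label: set() for rec in records}
    for rule in ruleset.rules:
        vals = {
            rec.label: rec.value(rule.statistic, rule.channel, rule.roi)
            for rec in records
        }
        if rule.relative:
            ref = sum(vals.values()) / len(vals)
            bound = rule.bound * ref
        else:
            bound = rule.bound
        for rec in records:
            v = vals[rec.label]
            if (rule.relation == "gt" and v > bound) or (
                rule.relation == "lt" and v < bound
            ):
                expected[rec.label].add(rule.flag)
    return expected


# ---------------------------------------------------------------------------
# measurement


def test_uniform_annulus_measures_mean_with_zero_sd():
    img = np.full((20, 20), 7, dtype=np.uint16)
    yy, xx = np.mgrid[0:20, 0:20]
    nuc = np.argwhere((yy - 10) ** 2 + (xx - 10) ** 2 <= 9)
    ann = np.argwhere(
        ((yy - 10) ** 2 + (xx - 10) ** 2 > 9)
        & ((yy - 10) ** 2 + (xx - 10) ** 2 <= 36)
    )
    img[tuple(ann.T)] = 100
    field = hc.ImageField(channels={"anion": img}, pixel_size_um=1.0)
    roi = RoiPair(label=1, nuclear_rc=nuc, cytosol_rc=ann)
    (rec,) = hc.measure_cells(field, [roi])
    st = rec.stats[("anion", "cytosol")]
    assert st.mean == pytest.approx(100.0)
    assert st.sd == 0.0
    assert st.pixel_count == len(ann)


def test_integrated_equals_mean_times_pixel_count(quiet_analysis):
    *_, records = quiet_analysis
    for rec in records:
        for st in rec.stats.values():
            assert st.integrated == pytest.approx(st.mean * st.pixel_count)


def test_measured_stats_match_direct_numpy(quiet_analysis):
    cfg, field, _, _, _, rois, records = quiet_analysis
    img = field.channel("hoechst")
    roi, rec = rois[0], records[0]
    vals = img[roi.nuclear_index()].astype(float)
    st = rec.stats[("hoechst", "nuclear")]
    assert st.mean == pytest.approx(vals.mean())
    assert st.sd == pytest.approx(vals.std(ddof=1))


def test_roi_outside_image_bounds_errors():
    field = hc.ImageField(
        channels={"anion": np.zeros((10, 10), np.uint16)}, pixel_size_um=1.0
    )
    roi = RoiPair(label=1, nuclear_rc=np.array([[2, 2]]),
                  cytosol_rc=np.array([[11, 3]]))
    with pytest.raises(InvalidParameterError):
        hc.measure_cells(field, [roi])


def test_noisy_fixture_cytosol_means_recover_truth(clean_field):
    """Pipeline-measured annulus means agree with generator truth within
    3 noise-predicted SE for at least 99% of cells."""
    cfg, field, truth = clean_field
    lm, nuclei = hc.segment_nuclei(field.channel("hoechst"), cfg.pixel_size_um)
    nuclei = [n for n in nuclei if n.area_um2 >= 36.0]
    rois = {r.label: r for r in hc.build_cytosol_rois(lm, cfg.pixel_size_um)}
    records = hc.measure_cells(field, [rois[n.label] for n in nuclei], nuclei)
    matches = match_to_truth(nuclei, truth, cfg.pixel_size_um)
    by_label = {r.label: r for r in records}
    ok = total = 0
    for label, j in matches.items():
        st = by_label[label].stats[("anion", "cytosol")]
        true_v = truth.true_anion_cytosol.iloc[j]
        se = hc.predicted_cytosol_se(cfg, true_v, st.pixel_count)
        z = (st.mean - cfg.background_level - true_v) / se
        total += 1
        ok += abs(z) <= 3.0
    assert total >= 250
    assert ok / total >= 0.99


# ---------------------------------------------------------------------------
# background subtraction


def test_subtract_backgrounds_anion_and_mode():
    img_an = np.full((8, 8), 500, np.uint16)
    img_h = np.full((8, 8), 40, np.uint16)  # image mode 40
    img_h[2:5, 2:5] = 200  # the nucleus
    field = hc.ImageField(
        channels={"anion": img_an, "hoechst": img_h}, pixel_size_um=1.0
    )
    roi = RoiPair(
        label=1,
        nuclear_rc=np.argwhere(img_h == 200),
        cytosol_rc=np.argwhere(img_an == 500)[:10],
    )
    (rec,) = hc.measure_cells(field, [roi])
    hc.subtract_backgrounds([rec], field, control_mean_anion=120.0)
    assert rec.corrected[("anion", "cytosol")] == pytest.approx(380.0)
    assert rec.corrected[("hoechst", "nuclear")] == pytest.approx(160.0)


def test_missing_vehicle_control_is_configuration_error(quiet_analysis):
    _, field, _, _, _, _, records = quiet_analysis
    with pytest.raises(ConfigurationError):
        hc.subtract_backgrounds(copy.deepcopy(records), field)


def test_vehicle_fixture_as_its_own_control_centres_on_zero():
    cfg = dataclasses.replace(hc.clean_quiet_config(seed=8), vehicle=True,
                              noise_poisson=True, noise_read_sd=3.0)
    field, _ = hc.generate_field(cfg)
    lm, nuclei = hc.segment_nuclei(field.channel("hoechst"), cfg.pixel_size_um)
    rois = hc.build_cytosol_rois(lm, cfg.pixel_size_um)
    records = hc.measure_cells(field, rois, nuclei)
    control = float(np.mean([r.stats[("anion", "cytosol")].mean for r in records]))
    hc.subtract_backgrounds(records, field, control)
    corrected = [r.corrected[("anion", "cytosol")] for r in records]
    assert abs(np.mean(corrected)) < 1e-9  # centred on zero by construction
    assert np.std(corrected) < 5.0


# ---------------------------------------------------------------------------
# exclusion rules


def test_accumulation_rules_flag_absolute_thresholds():
    rng = np.random.default_rng(5)
    records = random_records(rng, 20)
    # pin three sentinel records
    records[0].area_um2 = 40.0  # < 47 µm²
    records[1].circularity = 0.55  # < 0.6
    records[2].area_um2 = 400.0  # > 360 µm²
    out = hc.apply_exclusions(records, accumulation_ruleset())
    assert "area_small" in out[0].flags
    assert "circularity_low" in out[1].flags
    assert "area_large" in out[2].flags


def test_record_at_population_means_is_retained():
    stats = {
        ("anion", "cytosol"): (300.0, 50.0),
        ("lysotracker", "cytosol"): (200.0, 40.0),
        ("lysotracker", "nuclear"): (50.0, 10.0),
        ("hoechst", "nuclear"): (300.0, 60.0),
        ("pi", "nuclear"): (10.0, 5.0),
    }
    records = [make_record(label=i + 1, stats=stats) for i in range(5)]
    out = hc.apply_exclusions(records, accumulation_ruleset())
    assert all(r.retained for r in out)


def test_apply_exclusions_agrees_with_brute_force(n=300, seed=31):
    rng = np.random.default_rng(seed)
    records = random_records(rng, n)
    for ruleset in (accumulation_ruleset(), viability_ruleset(),
                    timelapse_ruleset()):
        out = hc.apply_exclusions(copy.deepcopy(records), ruleset)
        expected = brute_force_flags(records, ruleset)
        for rec in out:
            assert rec.flags == expected[rec.label]


def test_apply_exclusions_idempotent_and_order_independent():
    rng = np.random.default_rng(41)
    records = random_records(rng, 40)
    once = hc.apply_exclusions(copy.deepcopy(records), accumulation_ruleset())
    twice = hc.apply_exclusions(copy.deepcopy(once), accumulation_ruleset())
    assert [r.flags for r in once] == [r.flags for r in twice]
    shuffled = copy.deepcopy(records)
    rng.shuffle(shuffled)
    out_s = hc.apply_exclusions(shuffled, accumulation_ruleset())
    by_label = {r.label: r.flags for r in out_s}
    for rec in once:
        assert rec.flags == by_label[rec.label]


def test_apply_exclusions_empty_and_singleton_errors():
    with pytest.raises(EmptyInputError):
        hc.apply_exclusions([], accumulation_ruleset())
    with pytest.raises(InvalidParameterError):
        hc.apply_exclusions([make_record()], accumulation_ruleset())


# ---------------------------------------------------------------------------
# viability scoring


def test_pi_positive_nucleus_is_nonviable():
    stats = {("pi", "nuclear"): (250.0, 5.0), ("hoechst", "nuclear"): (300.0, 50.0)}
    good = {("pi", "nuclear"): (20.0, 5.0), ("hoechst", "nuclear"): (300.0, 50.0)}
    records = [make_record(label=1, stats=stats)] + [
        make_record(label=i, stats=good) for i in range(2, 6)
    ]
    counts = hc.score_viability(records)
    assert records[0].viable is False
    assert counts == {"f0": 4}


def test_small_nucleus_not_counted_viable():
    good = {("pi", "nuclear"): (20.0, 5.0), ("hoechst", "nuclear"): (300.0, 50.0)}
    records = [make_record(label=i, stats=good) for i in range(1, 5)]
    records[0].area_um2 = 30.0  # below the 36 µm² qualifying bound
    hc.score_viability(records)
    assert records[0].viable is False
    assert all(r.viable for r in records[1:])


def test_score_viability_requires_pi_channel():
    records = [make_record(stats={("hoechst", "nuclear"): (300.0, 50.0)})]
    with pytest.raises(MissingChannelError):
        hc.score_viability(records)


def test_adding_pi_positive_cell_never_increases_viable_count():
    rng = np.random.default_rng(53)
    records = random_records(rng, 30)
    base = sum(hc.score_viability(copy.deepcopy(records)).values())
    extra = make_record(label=99, stats={
        ("pi", "nuclear"): (350.0, 5.0),
        ("hoechst", "nuclear"): (300.0, 50.0),
    })
    with_extra = sum(
        hc.score_viability(copy.deepcopy(records) + [extra]).values()
    )
    assert with_extra <= base + 0  # PI-positive cell cannot count as viable


# ---------------------------------------------------------------------------
# ratio to Hoechst


def test_fba_over_hoechst_ratio_and_undefined_case():
    rec = make_record()
    rec.corrected[("anion", "cytosol")] = 300.0
    rec.corrected[("hoechst", "nuclear")] = 150.0
    rec0 = make_record(label=2)
    rec0.corrected[("anion", "cytosol")] = 300.0
    rec0.corrected[("hoechst", "nuclear")] = 0.0
    hc.compute_fba_over_hoechst([rec, rec0])
    assert rec.fba_over_hoechst == pytest.approx(2.0)
    assert rec0.fba_over_hoechst is None
    assert "undefined_fba_ratio" in rec0.flags


# ---------------------------------------------------------------------------
# time-lapse traces and death calls


def test_static_timelapse_traces_are_flat_within_noise():
    cfg = dataclasses.replace(
        hc.demo_timelapse_config(seed=6, n_frames=5),
        death_marginal_p=0.0, dead_fraction=0.0,
    )
    fields, _ = hc.generate_timelapse(cfg)
    lm, nuclei = hc.segment_nuclei(fields[0].channel("hoechst"), cfg.pixel_size_um)
    rois = [r for r in hc.build_cytosol_rois(lm, cfg.pixel_size_um)
            if len(r.cytosol_rc) > 50]
    traces = hc.link_and_trace(fields, rois)
    assert traces, "no traces built"
    for tr in traces:
        assert np.ptp(tr.pi_cell_fluorescence) < 50.0
        assert detect_death(tr) is None


def test_death_traced_from_ground_truth_frame(small_timelapse):
    cfg, fields, truth = small_timelapse
    lm, nuclei = hc.segment_nuclei(fields[0].channel("hoechst"), cfg.pixel_size_um)
    nuclei = [n for n in nuclei if n.area_um2 >= 36.0]
    rois = {r.label: r for r in hc.build_cytosol_rois(lm, cfg.pixel_size_um)}
    traces = hc.link_and_trace(fields, [rois[n.label] for n in nuclei])
    matches = match_to_truth(nuclei, truth, cfg.pixel_size_um)
    import pandas as pd

    checked = 0
    for tr in traces:
        if tr.cell_id not in matches:
            continue
        tf = truth.death_frame.iloc[matches[tr.cell_id]]
        expected = None if pd.isna(tf) else int(tf)
        assert detect_death(tr) == expected
        checked += 1
    assert checked >= 10


def test_frame_dimension_mismatch_errors(small_timelapse):
    cfg, fields, _ = small_timelapse
    bad = hc.ImageField(
        channels={ch: np.zeros((64, 64), np.uint16) for ch in hc.CHANNELS},
        pixel_size_um=cfg.pixel_size_um,
        frame=2,
    )
    with pytest.raises(InvalidParameterError):
        hc.link_and_trace([fields[0], bad], [])


def test_detect_death_direct_rule_and_scan_oracle():
    trace = TimelapseTrace(
        cell_id=1,
        frame_times_min=np.array([0.0, 10.0, 20.0]),
        pi_cell_fluorescence=np.array([80.0, 130.0, 150.0]) - 40.0,
        fba_cytosol=np.zeros(3),
    )
    assert detect_death(trace) == 3  # excess [40, 90, 110] crosses at frame 3
    zero = TimelapseTrace(1, np.arange(5.0), np.zeros(5), np.zeros(5))
    assert detect_death(zero) is None
    rng = np.random.default_rng(61)
    for _ in range(300):
        pi = rng.uniform(0, 200, rng.integers(1, 40))
        tr = TimelapseTrace(1, np.arange(float(len(pi))), pi, np.zeros(len(pi)))
        expected = None
        for k, v in enumerate(pi):  # linear-scan oracle
            if v > 100.0:
                expected = k + 1
                break
        assert detect_death(tr) == expected


def test_death_call_invariant_to_appended_frames():
    rng = np.random.default_rng(67)
    pi = rng.uniform(0, 150, 20)
    tr = TimelapseTrace(1, np.arange(20.0), pi, np.zeros(20))
    call = detect_death(tr)
    if call is not None:
        extended = TimelapseTrace(
            1, np.arange(30.0), np.concatenate([pi, rng.uniform(0, 500, 10)]),
            np.zeros(30),
        )
        assert detect_death(extended) == call


def test_detect_death_empty_trace_errors():
    tr = TimelapseTrace(1, np.array([]), np.array([]), np.array([]))
    with pytest.raises(EmptyInputError):
        detect_death(tr)
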