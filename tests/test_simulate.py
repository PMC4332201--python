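"""Generator tests: determinism, statistical structure, hazard coupling."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import hepcyto as hc
from hepcyto.core import InvalidConfigError
from hepcyto.quantify import accumulation_ruleset
from hepcyto.simulate import _hazard_alpha, _sample_death_frames


def hazard_mc_oracle(cfg, n, seed):
    """Direct Monte-Carlo of the per-frame logistic hazard, written
    independently of the generator's geometric-sampling shortcut."""
    rng = np.random.default_rng(seed)
    fba = rng.lognormal(cfg.fba_lognormal_mu, cfg.fba_lognormal_sigma, n)
    alpha = _hazard_alpha(cfg)
    h = expit(alpha + cfg.death_coupling_beta * np.log(fba))
    died = np.zeros(n, dtype=bool)
    frame = np.zeros(n, dtype=int)
    for step in range(1, cfg.n_frames):  # one hazard draw per inter-frame step
        u = rng.random(n)
        new = (~died) & (u < h)
        died |= new
        frame[new] = step + 1
    return fba, died, frame


# ---------------------------------------------------------------------------
# determinism and basic structure


def test_identical_seed_and_config_gives_bit_identical_fields():
    cfg = hc.demo_timelapse_config(seed=21, n_frames=3)
    fields_a, truth_a = hc.generate_timelapse(cfg)
    fields_b, truth_b = hc.generate_timelapse(cfg)
    for fa, fb in zip(fields_a, fields_b):
        for ch in hc.CHANNELS:
            assert np.array_equal(fa.channel(ch), fb.channel(ch))
    pd.testing.assert_frame_equal(truth_a, truth_b)


def test_pixel_values_are_16bit_nonnegative_integers(clean_field):
    _, field, _ = clean_field
    for ch in hc.CHANNELS:
        arr = field.channel(ch)
        assert arr.dtype == np.uint16


def test_expected_cell_count_matches_plating_density():
    """1200 cells/mm² over a 0.25 mm² field gives 300 ± Poisson error."""
    counts = []
    for seed in range(6):
        cfg = hc.standard_clean_config(seed=seed)
        _, truth = hc.generate_field(cfg)
        counts.append(len(truth))
    expected = 1200.0 * hc.standard_clean_config().field_area_mm2
    assert expected == pytest.approx(300, abs=2)
    mean = np.mean(counts)
    tol = 3.0 * math.sqrt(expected / len(counts))
    assert abs(mean - expected) <= tol


def test_lognormal_cv_matches_closed_form():
    """sigma chosen for CV 15% yields a sample CV within 10% relative."""
    sigma = math.sqrt(math.log(1 + 0.15**2))
    vals = []
    for seed in range(4):
        cfg = dataclasses.replace(
            hc.standard_clean_config(seed=seed),
            fba_lognormal_sigma=sigma,
            fba_lognormal_mu=math.log(500.0) - sigma**2 / 2,
        )
        _, truth = hc.generate_field(cfg)
        vals.append(truth.true_anion_cytosol.to_numpy())
    vals = np.concatenate(vals)
    assert len(vals) >= 1000
    cv = hc.coefficient_of_variation(vals)
    assert cv == pytest.approx(15.0, rel=0.10)


def test_invalid_configs_are_rejected():
    with pytest.raises(InvalidConfigError):
        hc.SimulationConfig(field_width_px=0)
    with pytest.raises(InvalidConfigError):
        hc.SimulationConfig(pixel_size_um=-0.65)
    with pytest.raises(InvalidConfigError):
        hc.SimulationConfig(dead_fraction=1.5)
    with pytest.raises(InvalidConfigError):
        hc.generate_timelapse(hc.SimulationConfig(n_frames=1))


def test_field_too_small_for_one_cell_errors():
    with pytest.raises(InvalidConfigError):
        hc.generate_field(hc.SimulationConfig(field_width_px=4, field_height_px=4))


# ---------------------------------------------------------------------------
# rendered intensities vs truth


def test_clean_noisefree_field_passes_every_exclusion_rule(quiet_analysis):
    import copy

    cfg, field, truth, _, _, _, records = quiet_analysis
    records = copy.deepcopy(records)
    hc.subtract_backgrounds(records, field, float(cfg.background_level))
    hc.apply_exclusions(records, accumulation_ruleset())
    assert all(r.retained for r in records)
    counts = hc.score_viability(records)
    assert sum(counts.values()) == int(truth.viable_at_t0.sum())


def test_ideal_mask_measurement_recovers_true_intensity(clean_field):
    """Annulus means measured with the ground-truth geometry sit within
    noise-predicted error of the drawn per-cell intensities."""
    cfg, field, truth = clean_field
    px = cfg.pixel_size_um
    img = field.channel("anion").astype(float)
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    z = []
    for _, row in truth.iloc[:80].iterrows():
        d_um = np.hypot(yy - row.centroid_y_px, xx - row.centroid_x_px) * px
        ideal = (d_um >= row.radius_um + 0.5) & (d_um <= row.radius_um + 3.0)
        meas = img[ideal].mean() - cfg.background_level
        se = hc.predicted_cytosol_se(cfg, row.true_anion_cytosol, int(ideal.sum()))
        z.append((meas - row.true_anion_cytosol) / se)
    z = np.asarray(z)
    assert np.mean(np.abs(z) <= 3.0) >= 0.95
    assert abs(z.mean()) < 0.5


def test_dead_fraction_converges_to_configured_probability():
    cfg = dataclasses.replace(
        hc.standard_clean_config(seed=11), dead_fraction=0.25
    )
    _, truth = hc.generate_field(cfg)
    n = len(truth)
    dead = int((~truth.viable_at_t0).sum())
    # binomial 99% interval around p = 0.25
    tol = 2.58 * math.sqrt(0.25 * 0.75 / n)
    assert dead / n == pytest.approx(0.25, abs=tol)


# ---------------------------------------------------------------------------
# time-lapse mode


def test_timelapse_span_is_30_hours_at_default_cadence():
    cfg = hc.SimulationConfig(n_frames=181, frame_interval_min=10.0)
    assert hc.timelapse_span_hours(cfg) == pytest.approx(30.0)


def test_death_frames_within_movie_and_pi_rendered_above_threshold(
    small_timelapse,
):
    cfg, fields, truth = small_timelapse
    df = truth.death_frame
    assert (df.dropna() <= cfg.n_frames).all()
    assert (df.dropna() >= 2).all()
    # after the death frame the PI cell fluorescence exceeds bg + 100
    px = cfg.pixel_size_um
    last = fields[-1].channel("pi").astype(float)
    h, w = last.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for _, row in truth[df.notna()].iterrows():
        d_um = np.hypot(yy - row.centroid_y_px, xx - row.centroid_x_px) * px
        annulus = (d_um > row.radius_um) & (d_um <= row.radius_um + 3.0)
        assert last[annulus].mean() > cfg.background_level + 100.0


def test_marginal_death_probability_converges_to_target():
    cfg = hc.SimulationConfig(n_frames=181, death_marginal_p=0.4)
    cohort = hc.simulate_death_cohort(cfg, 40000, seed=13)
    p = cohort.died.mean()
    tol = 3.0 * math.sqrt(0.4 * 0.6 / len(cohort))
    assert p == pytest.approx(0.4, abs=tol)


def test_null_coupling_gives_equal_tertile_death_fractions():
    cfg = hc.SimulationConfig(
        n_frames=181, death_marginal_p=0.4, death_coupling_beta=0.0
    )
    cohort = hc.simulate_death_cohort(cfg, 3000, seed=17)
    labels = hc.stratify_by_fba(cohort.fba_true)
    from scipy.stats import chi2_contingency

    table = [
        [
            int(cohort.died[labels == g].sum()),
            int((~cohort.died[labels == g]).sum()),
        ]
        for g in ("low", "mid", "high")
    ]
    _, p, *_ = chi2_contingency(table)
    assert p > 0.01


def test_positive_coupling_matches_direct_monte_carlo_oracle():
    """log FBA correlates positively with death; the correlation agrees
    with an independent per-frame Bernoulli simulation of the hazard."""
    cfg = hc.SimulationConfig(n_frames=181, death_marginal_p=0.4,
                              death_coupling_beta=3.0)
    cohort = hc.simulate_death_cohort(cfg, 1500, seed=19)
    r_pkg, _ = hc.correlate_per_cell(
        np.log(cohort.fba_true), cohort.died.astype(float)
    )
    assert r_pkg > 0.1
    rs = []
    for k in range(8):
        fba, died, _ = hazard_mc_oracle(cfg, 1500, seed=1000 + k)
        rs.append(np.corrcoef(np.log(fba), died.astype(float))[0, 1])
    assert r_pkg == pytest.approx(np.mean(rs), abs=4 * np.std(rs, ddof=1))


def test_geometric_sampling_distribution_matches_bernoulli_oracle():
    """The generator's geometric shortcut and a frame-by-frame Bernoulli
    loop produce the same death-frame distribution."""
    cfg = hc.SimulationConfig(n_frames=25, death_marginal_p=0.5,
                              death_coupling_beta=3.0)
    rng = np.random.default_rng(23)
    fba = rng.lognormal(cfg.fba_lognormal_mu, cfg.fba_lognormal_sigma, 20000)
    frames_pkg = _sample_death_frames(fba, cfg, np.random.default_rng(3))
    _, died_mc, frames_mc = hazard_mc_oracle(cfg, 20000, seed=4)
    p_pkg = (frames_pkg > 0).mean()
    p_mc = died_mc.mean()
    assert p_pkg == pytest.approx(p_mc, abs=4 * math.sqrt(0.25 / 20000) * 2)
    # compare mean death frame among the dead
    m_pkg = frames_pkg[frames_pkg > 0].mean()
    m_mc = frames_mc[frames_mc > 0].mean()
    assert m_pkg == pytest.approx(m_mc, rel=0.05)


def test_vehicle_field_has_no_anion_signal():
    cfg = dataclasses.replace(hc.clean_quiet_config(seed=2), vehicle=True)
    field, truth = hc.generate_field(cfg)
    assert (truth.true_anion_cytosol == 0).all()
    an = field.channel("anion").astype(float)
    assert abs(an.mean() - cfg.background_level) < 1.0
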