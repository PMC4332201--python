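"""Synthetic hepatocyte fields and time-lapse sequences with ground truth.

The generator emulates the statistical structure of cultured primary
hepatocyte fields that the analysis pipeline assumes:

* cells placed at a configurable plating density (default 1200 cells/mm²)
  with non-overlapping nuclei (rejection sampling, minimum centre distance
  = sum of radii + 1 µm, plus an optional extra margin);
* per-cell cytosolic fluorescent-bile-acid (FBA/anion) intensity drawn
  from a lognormal law (cell-to-cell CV is a config choice, default 15%);
* Hoechst nuclei rendered as soft-edged disks; the anion and Lysotracker
  signals as a flat annular "cytoplasm" around each nucleus, tiled by
  nearest-nucleus territories so confluent cells never sum;
* dead/damaged cells (fragmented bright-variable nuclei, high propidium
  iodide) and sub-nuclear debris that trip the pipeline's exclusion rules;
* additive background, optional Poisson shot noise and Gaussian read
  noise, quantised to 16-bit camera counts;
* 10-min-interval / 30-h time-lapse mode in which each cell's per-frame
  death hazard increases with its log FBA (logistic link, slope
  ``death_coupling_beta``); the hazard intercept is calibrated by
  Gauss–Hermite quadrature so the marginal death probability equals
  ``death_marginal_p``.

Every generated object is recorded in a ground-truth table (one row per
rendered cell or debris object) so downstream measurements can be tested
against the values that were actually drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .core import ImageField, InvalidConfigError
from .stats import stratify_by_fba

__all__ = [
    "SimulationConfig",
    "generate_field",
    "generate_timelapse",
    "simulate_death_cohort",
    "predicted_cytosol_se",
    "timelapse_span_hours",
    "clean_quiet_config",
    "standard_clean_config",
    "standard_field_config",
    "demo_timelapse_config",
]

# cytoplasm ring geometry, in µm relative to the nuclear radius:
# ramp up over [-2, -1], flat over [-1, +5.5], ramp down over [5.5, 7].
# The flat span comfortably covers the 3 µm measurement band even when the
# segmented nuclear boundary misses the true one by a pixel or two.
_RING_IN0, _RING_IN1 = -2.0, -1.0
_RING_OUT0, _RING_OUT1 = 5.5, 7.0
_EDGE_UM = 0.65  # half-width of the soft nuclear edge

_PI_DEAD_NUCLEAR = 400.0  # a.u. above background, trips the <200 viability rule
_PI_DEAD_CYTOSOL = 300.0  # a.u. above background, trips the 100 a.u. death rule


@dataclass
class SimulationConfig:
    """All knobs of the synthetic microscope.

    Intensities are in arbitrary camera units (a.u.); lengths in µm;
    the rendered field covers ``field_width_px × field_height_px`` pixels
    at ``pixel_size_um`` µm/pixel.
    """

    field_width_px: int = 768
    field_height_px: int = 768
    pixel_size_um: float = 0.65
    cell_density_per_mm2: float = 1200.0
    nucleus_radius_um_mean: float = 4.5
    nucleus_radius_um_sd: float = 0.5
    #: per-cell true cytosolic anion intensity ~ lognormal(mu, sigma);
    #: defaults give mean 500 a.u. with 15% cell-to-cell CV.
    fba_lognormal_mu: float = math.log(500.0) - 0.14916 ** 2 / 2
    fba_lognormal_sigma: float = 0.14916
    hoechst_mean: float = 300.0
    hoechst_sd: float = 6.0
    lysotracker_mean: float = 200.0
    lysotracker_cv: float = 0.20
    dead_fraction: float = 0.0
    #: log-odds of per-frame death per unit log-FBA (time-lapse mode)
    death_coupling_beta: float = 3.0
    #: marginal probability of death within the movie; the hazard
    #: intercept is calibrated so the population converges to this.
    death_marginal_p: float = 0.4
    frame_interval_min: float = 10.0
    n_frames: int = 181
    noise_read_sd: float = 3.0
    noise_poisson: bool = True
    debris_rate_per_mm2: float = 0.0
    background_level: float = 100.0
    rng_seed: int = 0
    #: vehicle control: no fluorescent anion added (background only)
    vehicle: bool = False
    #: allow touching nuclei (stress mode for the segmentation rules)
    allow_touching: bool = False
    #: extra centre-to-centre clearance beyond (r_i + r_j + 1 µm)
    extra_separation_um: float = 0.0
    #: correlation (on the log scale) between the Lysotracker-slot signal
    #: and the anion signal; used when that slot plays the role of an
    #: immunofluorescence marker in correlation experiments
    marker_rho_with_anion: float = 0.0

    def __post_init__(self) -> None:
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise InvalidConfigError("field dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise InvalidConfigError("pixel_size_um must be positive")
        if self.cell_density_per_mm2 <= 0:
            raise InvalidConfigError("cell_density_per_mm2 must be positive")
        if self.nucleus_radius_um_mean <= 0 or self.nucleus_radius_um_sd < 0:
            raise InvalidConfigError("nucleus radius parameters out of range")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise InvalidConfigError("dead_fraction must lie in [0, 1]")
        if not 0.0 <= self.death_marginal_p < 1.0:
            raise InvalidConfigError("death_marginal_p must lie in [0, 1)")
        if self.frame_interval_min <= 0 or self.n_frames < 1:
            raise InvalidConfigError("frame parameters out of range")
        if self.noise_read_sd < 0 or self.debris_rate_per_mm2 < 0:
            raise InvalidConfigError("noise/debris rates must be nonnegative")
        if self.background_level < 0:
            raise InvalidConfigError("background_level must be nonnegative")

    @property
    def field_area_mm2(self) -> float:
        return (
            self.field_width_px
            * self.field_height_px
            * (self.pixel_size_um / 1000.0) ** 2
        )


def timelapse_span_hours(config: SimulationConfig) -> float:
    """Observation span of the movie: (n_frames − 1) × interval, in hours."""
    return (config.n_frames - 1) * config.frame_interval_min / 60.0


# ---------------------------------------------------------------------------
# sampling


def _sample_radii(cfg: SimulationConfig, n: int, rng: np.random.Generator):
    r = rng.normal(cfg.nucleus_radius_um_mean, cfg.nucleus_radius_um_sd, n)
    # truncate to keep nuclear areas inside the biologically plausible
    # window the exclusion rules assume (no sub-debris or giant nuclei)
    lo = max(cfg.nucleus_radius_um_mean - 2.0 * cfg.nucleus_radius_um_sd, 3.6)
    hi = cfg.nucleus_radius_um_mean + 2.5 * cfg.nucleus_radius_um_sd
    return np.clip(r, lo, hi)


def _place_cells(cfg: SimulationConfig, rng: np.random.Generator):
    """Dart-throwing placement of non-overlapping nuclei.

    Expected count = density × field area (Poisson); each accepted centre
    keeps its nucleus fully inside the field and, unless
    ``allow_touching``, at least (r_i + r_j + 1 µm + extra) from every
    previously accepted centre.
    """
    n_target = int(rng.poisson(cfg.cell_density_per_mm2 * cfg.field_area_mm2))
    w_um = cfg.field_width_px * cfg.pixel_size_um
    h_um = cfg.field_height_px * cfg.pixel_size_um
    xs: list[float] = []
    ys: list[float] = []
    rs: list[float] = []
    attempts = 0
    max_attempts = 400 * max(n_target, 1)
    while len(xs) < n_target and attempts < max_attempts:
        attempts += 1
        r = float(_sample_radii(cfg, 1, rng)[0])
        margin = r + 1.0
        if w_um <= 2 * margin or h_um <= 2 * margin:
            raise InvalidConfigError("field too small to hold a single nucleus")
        x = rng.uniform(margin, w_um - margin)
        y = rng.uniform(margin, h_um - margin)
        if xs and not cfg.allow_touching:
            dx = np.asarray(xs) - x
            dy = np.asarray(ys) - y
            min_d = np.asarray(rs) + r + 1.0 + cfg.extra_separation_um
            if np.any(dx * dx + dy * dy < min_d * min_d):
                continue
        xs.append(x)
        ys.append(y)
        rs.append(r)
    return np.asarray(xs), np.asarray(ys), np.asarray(rs)


def _place_debris(cfg, rng, cell_x, cell_y, cell_r):
    n = int(rng.poisson(cfg.debris_rate_per_mm2 * cfg.field_area_mm2))
    w_um = cfg.field_width_px * cfg.pixel_size_um
    h_um = cfg.field_height_px * cfg.pixel_size_um
    xs, ys, rs = [], [], []
    attempts = 0
    while len(xs) < n and attempts < 400 * max(n, 1):
        attempts += 1
        r = rng.uniform(0.8, 2.0)
        x = rng.uniform(r + 1, w_um - r - 1)
        y = rng.uniform(r + 1, h_um - r - 1)
        if len(cell_x) and np.any(
            (cell_x - x) ** 2 + (cell_y - y) ** 2 < (cell_r + r + 3.0) ** 2
        ):
            continue  # keep debris off the nuclei so components never merge
        xs.append(x)
        ys.append(y)
        rs.append(r)
    return np.asarray(xs), np.asarray(ys), np.asarray(rs)


def _sample_cell_intensities(cfg: SimulationConfig, n: int, rng):
    z_anion = rng.standard_normal(n)
    if cfg.vehicle:
        anion = np.zeros(n)
    else:
        anion = np.exp(
            cfg.fba_lognormal_mu + cfg.fba_lognormal_sigma * z_anion
        )
    sig_l = math.sqrt(math.log(1.0 + cfg.lysotracker_cv**2))
    mu_l = math.log(cfg.lysotracker_mean) - sig_l**2 / 2
    rho = cfg.marker_rho_with_anion
    z_l = rho * z_anion + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n)
    lyso = np.exp(mu_l + sig_l * z_l)
    hoechst = np.maximum(rng.normal(cfg.hoechst_mean, cfg.hoechst_sd, n), 10.0)
    return anion, lyso, hoechst


# ---------------------------------------------------------------------------
# death hazard


def _hazard_alpha(cfg: SimulationConfig) -> float:
    """Intercept of the per-frame logistic hazard.

    Solves E_F[1 − (1 − expit(alpha + beta·log F))^(n_frames−1)] =
    death_marginal_p over the lognormal FBA law (64-node Gauss–Hermite).
    """
    if cfg.death_marginal_p == 0.0:
        return -np.inf
    n_steps = max(cfg.n_frames - 1, 1)
    beta = 0.0 if cfg.vehicle else cfg.death_coupling_beta
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    w = weights / weights.sum()
    x = cfg.fba_lognormal_mu + cfg.fba_lognormal_sigma * nodes

    def marginal(alpha: float) -> float:
        h = expit(alpha + beta * x)
        return float(np.sum(w * (1.0 - (1.0 - h) ** n_steps)))

    return float(brentq(lambda a: marginal(a) - cfg.death_marginal_p, -60.0, 30.0))


def _sample_death_frames(
    anion_true: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """First frame (1-based) at which each cell is dead; 0 = survives.

    The hazard applies per inter-frame step, so the earliest possible
    death frame is 2 and deaths beyond ``n_frames`` are censored.
    """
    alpha = _hazard_alpha(cfg)
    n = len(anion_true)
    if not np.isfinite(alpha):
        return np.zeros(n, dtype=int)
    beta = 0.0 if cfg.vehicle else cfg.death_coupling_beta
    x = np.log(np.maximum(anion_true, 1e-12))
    h = expit(alpha + beta * x)
    steps = rng.geometric(h)  # 1-based index of the first lethal step
    frames = 1 + steps
    frames[frames > cfg.n_frames] = 0
    return frames.astype(int)


def simulate_death_cohort(
    config: SimulationConfig, n_cells: int, seed: int | None = None
) -> pd.DataFrame:
    """Trace-level cohort simulation of the FBA-coupled death hazard.

    Samples ``n_cells`` true FBA intensities and death frames from
    exactly the sampling path the renderer uses, without rendering
    pixels.  Returns a frame with columns ``cell_id``, ``fba_true``,
    ``death_frame`` (0 = survived) and ``died``.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    fba = rng.lognormal(
        config.fba_lognormal_mu, config.fba_lognormal_sigma, n_cells
    )
    frames = _sample_death_frames(fba, config, rng)
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "fba_true": fba,
            "death_frame": frames,
            "died": frames > 0,
        }
    )


# ---------------------------------------------------------------------------
# rendering


def _ring_frac(q: np.ndarray) -> np.ndarray:
    """Cytoplasm radial profile vs distance-to-nuclear-border q (µm)."""
    up = (q - _RING_IN0) / (_RING_IN1 - _RING_IN0)
    down = (_RING_OUT1 - q) / (_RING_OUT1 - _RING_OUT0)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


class _FieldGeometry:
    """Static per-field geometry: territories and nuclear footprints."""

    def __init__(self, cfg: SimulationConfig, cx, cy, r):
        self.cfg = cfg
        self.cx, self.cy, self.r = cx, cy, r
        h, w, px = cfg.field_height_px, cfg.field_width_px, cfg.pixel_size_um
        self.best_q = np.full((h, w), np.inf)
        self.best_i = np.full((h, w), -1, dtype=np.int32)
        self.patches = []  # (slice_r, slice_c, d_um) per cell
        pad = int(np.ceil(_RING_OUT1 / px)) + 1
        for i in range(len(cx)):
            rr = int(round(cy[i] / px))
            cc = int(round(cx[i] / px))
            half = int(np.ceil(r[i] / px)) + pad
            r0, r1 = max(rr - half, 0), min(rr + half + 1, h)
            c0, c1 = max(cc - half, 0), min(cc + half + 1, w)
            ys = (np.arange(r0, r1) + 0.0)[:, None] * px
            xs = (np.arange(c0, c1) + 0.0)[None, :] * px
            d_um = np.hypot(ys - cy[i], xs - cx[i])
            self.patches.append((slice(r0, r1), slice(c0, c1), d_um))
            q = d_um - r[i]
            win_q = self.best_q[r0:r1, c0:c1]
            win_i = self.best_i[r0:r1, c0:c1]
            upd = q < win_q
            win_q[upd] = q[upd]
            win_i[upd] = i

    def add_cytosol(self, img: np.ndarray, values: np.ndarray) -> None:
        """Paint per-cell cytoplasm values over the territory map."""
        owned = self.best_i >= 0
        frac = _ring_frac(self.best_q[owned])
        img[owned] += values[self.best_i[owned]] * frac

    def add_soft_disk(self, img, x_um, y_um, radius_um, amp, sl=None):
        cfg = self.cfg
        px = cfg.pixel_size_um
        h, w = img.shape
        half = int(np.ceil((radius_um + 2 * _EDGE_UM) / px)) + 1
        rr, cc = int(round(y_um / px)), int(round(x_um / px))
        r0, r1 = max(rr - half, 0), min(rr + half + 1, h)
        c0, c1 = max(cc - half, 0), min(cc + half + 1, w)
        if r0 >= r1 or c0 >= c1:
            return
        ys = (np.arange(r0, r1) + 0.0)[:, None] * px
        xs = (np.arange(c0, c1) + 0.0)[None, :] * px
        d = np.hypot(ys - y_um, xs - x_um)
        s = np.clip((radius_um + _EDGE_UM - d) / (2 * _EDGE_UM), 0.0, 1.0)
        img[r0:r1, c0:c1] += amp * s

    def add_nucleus(self, img, i, amp):
        self.add_soft_disk(img, self.cx[i], self.cy[i], self.r[i], amp)

    def add_fragments(self, img, i, amp, frag_geom):
        """Fragmented (apoptotic) nucleus: several off-centre sub-disks."""
        for dx, dy, fr, fa in frag_geom:
            self.add_soft_disk(
                img, self.cx[i] + dx, self.cy[i] + dy, fr, amp * fa
            )


def _quantize(channels: dict, cfg: SimulationConfig, rng) -> dict:
    out = {}
    for name in ("hoechst", "anion", "lysotracker", "pi"):
        img = channels[name]
        if cfg.noise_poisson:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        if cfg.noise_read_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_read_sd, img.shape)
        out[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return out


def _render(cfg, geom, anion, lyso, hoechst, dead_now, frag_geoms,
            anion_factor, debris, rng) -> dict:
    """Render all four channels for one time point, noise included."""
    h, w = cfg.field_height_px, cfg.field_width_px
    bg = cfg.background_level
    chans = {k: np.full((h, w), bg, dtype=float) for k in
             ("hoechst", "anion", "lysotracker", "pi")}
    n = len(geom.cx)
    pi_cyto = np.where(dead_now, _PI_DEAD_CYTOSOL, 0.0)
    geom.add_cytosol(chans["anion"], anion * anion_factor)
    geom.add_cytosol(chans["lysotracker"], lyso)
    geom.add_cytosol(chans["pi"], pi_cyto)
    for i in range(n):
        if frag_geoms[i] is not None:
            geom.add_fragments(chans["hoechst"], i, hoechst[i], frag_geoms[i])
        else:
            geom.add_nucleus(chans["hoechst"], i, hoechst[i])
        if dead_now[i]:
            geom.add_nucleus(chans["pi"], i, _PI_DEAD_NUCLEAR)
    dbx, dby, dbr, damp = debris
    for x, y, r0, a in zip(dbx, dby, dbr, damp):
        geom.add_soft_disk(chans["hoechst"], x, y, r0, a)
    return _quantize(chans, cfg, rng)


def _make_truth(cfg, cx, cy, r, anion, lyso, hoechst, viable, death_frame,
                dbx, dby, dbr) -> pd.DataFrame:
    n = len(cx)
    px = cfg.pixel_size_um
    tert = np.array([None] * n, dtype=object)
    vi = np.flatnonzero(viable)
    if len(vi) >= 3:
        tert[vi] = stratify_by_fba(anion[vi])
    rows = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "is_cell": True,
            "centroid_x_px": cx / px,
            "centroid_y_px": cy / px,
            "radius_um": r,
            "true_nucleus_area_um2": np.pi * r**2,
            "true_anion_cytosol": anion,
            "true_lysotracker_cytosol": lyso,
            "true_hoechst_nuclear": hoechst,
            "true_pi_cytosol": np.where(viable, 0.0, _PI_DEAD_CYTOSOL),
            "viable_at_t0": viable,
            "death_frame": pd.array(
                np.where(death_frame > 0, death_frame, pd.NA), dtype="Int64"
            ),
            "tertile_true": tert,
        }
    )
    if len(dbx):
        deb = pd.DataFrame(
            {
                "cell_id": np.arange(n + 1, n + 1 + len(dbx)),
                "is_cell": False,
                "centroid_x_px": dbx / px,
                "centroid_y_px": dby / px,
                "radius_um": dbr,
                "true_nucleus_area_um2": np.pi * dbr**2,
                "true_anion_cytosol": 0.0,
                "true_lysotracker_cytosol": 0.0,
                "true_hoechst_nuclear": 0.0,
                "true_pi_cytosol": 0.0,
                "viable_at_t0": False,
                "death_frame": pd.array([pd.NA] * len(dbx), dtype="Int64"),
                "tertile_true": None,
            }
        )
        rows = pd.concat([rows, deb], ignore_index=True)
    return rows


def _frag_geometry(cfg, r_i, rng):
    k = 3
    ang = rng.uniform(0, 2 * np.pi, k)
    off = r_i * 0.6
    fr = r_i * 0.45
    fa = rng.uniform(0.4, 1.9, k)
    return [
        (off * np.cos(a), off * np.sin(a), fr, f) for a, f in zip(ang, fa)
    ]


def _setup(cfg: SimulationConfig, rng):
    cx, cy, r = _place_cells(cfg, rng)
    if len(cx) == 0:
        raise InvalidConfigError("field too small/dense settings yielded no cells")
    anion, lyso, hoechst = _sample_cell_intensities(cfg, len(cx), rng)
    viable = rng.random(len(cx)) >= cfg.dead_fraction
    dbx, dby, dbr = _place_debris(cfg, rng, cx, cy, r)
    geom = _FieldGeometry(cfg, cx, cy, r)
    frag = [None if v else _frag_geometry(cfg, r[i], rng)
            for i, v in enumerate(viable)]
    # debris appear in the Hoechst channel as small bright specks; they are
    # rendered directly (no cytoplasm) and flagged non-cell in the truth.
    debris_amp = rng.uniform(2.0, 4.0, len(dbx)) * cfg.hoechst_mean
    return geom, anion, lyso, hoechst, viable, dbx, dby, dbr, debris_amp, frag


def generate_field(
    config: SimulationConfig,
) -> tuple[ImageField, pd.DataFrame]:
    """Render one four-channel field plus its ground-truth table.

    Identical config (including ``rng_seed``) gives bit-identical output.
    """
    rng = np.random.default_rng(config.rng_seed)
    (geom, anion, lyso, hoechst, viable,
     dbx, dby, dbr, damp, frag) = _setup(config, rng)
    dead_now = ~viable
    chans = _render(config, geom, anion, lyso, hoechst, dead_now, frag,
                    np.ones(len(anion)), (dbx, dby, dbr, damp), rng)
    death_frame = np.zeros(len(geom.cx), dtype=int)
    field = ImageField(
        channels=chans,
        pixel_size_um=config.pixel_size_um,
        field_id="sim_000",
        condition="vehicle" if config.vehicle else "treated",
        frame=1,
    )
    truth = _make_truth(config, geom.cx, geom.cy, geom.r, anion, lyso,
                        hoechst, viable, death_frame, dbx, dby, dbr)
    return field, truth


def generate_timelapse(
    config: SimulationConfig,
) -> tuple[list[ImageField], pd.DataFrame]:
    """Render a death time-lapse: one four-channel field per frame.

    Cells viable at frame 1 die with a per-frame hazard increasing with
    their log true FBA; from the death frame on, propidium iodide is
    rendered well above the 100 a.u. death threshold and the cell's FBA
    signal declines.  Cells dead at t0 (``dead_fraction``) show the
    fragmented-nucleus phenotype from the start.
    """
    if config.n_frames < 2:
        raise InvalidConfigError("time-lapse needs n_frames >= 2")
    rng = np.random.default_rng(config.rng_seed)
    (geom, anion, lyso, hoechst, viable,
     dbx, dby, dbr, damp, frag) = _setup(config, rng)
    n = len(geom.cx)
    death_frame = np.zeros(n, dtype=int)
    idx = np.flatnonzero(viable)
    death_frame[idx] = _sample_death_frames(anion[idx], config, rng)
    fields: list[ImageField] = []
    for f in range(1, config.n_frames + 1):
        dead_now = (~viable) | ((death_frame > 0) & (death_frame <= f))
        anion_factor = np.where(
            viable & (death_frame > 0) & (death_frame <= f), 0.5, 1.0
        )
        chans = _render(config, geom, anion, lyso, hoechst, dead_now, frag,
                        anion_factor, (dbx, dby, dbr, damp), rng)
        fields.append(
            ImageField(
                channels=chans,
                pixel_size_um=config.pixel_size_um,
                field_id="sim_000",
                condition="vehicle" if config.vehicle else "treated",
                time_h=(f - 1) * config.frame_interval_min / 60.0,
                frame=f,
            )
        )
    truth = _make_truth(config, geom.cx, geom.cy, geom.r, anion, lyso,
                        hoechst, viable, death_frame, dbx, dby, dbr)
    return fields, truth


def predicted_cytosol_se(
    config: SimulationConfig, true_value: float, pixel_count: int
) -> float:
    """Noise-model standard error of an annulus mean intensity.

    Shot noise contributes variance ≈ (background + signal) when Poisson
    noise is on; Gaussian read noise adds its variance; quantisation adds
    1/12.  The SE of the mean over ``pixel_count`` pixels follows.
    """
    var = config.noise_read_sd**2 + 1.0 / 12.0
    if config.noise_poisson:
        var += config.background_level + true_value
    return math.sqrt(var / max(pixel_count, 1))


# ---------------------------------------------------------------------------
# config factories (named study conditions)


def standard_field_config(seed: int = 0) -> SimulationConfig:
    """The default mixed field: live cells plus dead cells and debris."""
    return SimulationConfig(
        dead_fraction=0.05, debris_rate_per_mm2=40.0, rng_seed=seed
    )


def standard_clean_config(seed: int = 0) -> SimulationConfig:
    """~300 well-separated live cells at 1200/mm² with realistic noise.

    The clean benchmark keeps enough clearance between cells that every
    3 µm annulus lies inside its own cell's cytoplasm territory, so the
    measured cytosol mean is identifiable with the drawn true intensity;
    proximity artifacts are probed separately via ``allow_touching`` and
    the default mixed config.
    """
    return SimulationConfig(rng_seed=seed, extra_separation_um=7.0)


def clean_quiet_config(seed: int = 0) -> SimulationConfig:
    """Noise-free sparse field in which every object passes every rule.

    Lower density plus extra separation keeps each annulus inside its own
    cell's territory, so with noise off every cytosolic SD is exactly
    zero and no population-relative rule can fire.
    """
    return SimulationConfig(
        cell_density_per_mm2=350.0,
        extra_separation_um=12.0,
        lysotracker_cv=0.05,
        noise_read_sd=0.0,
        noise_poisson=False,
        rng_seed=seed,
    )


def demo_timelapse_config(seed: int = 0, n_frames: int = 13) -> SimulationConfig:
    """Small renderable movie (256 px field) for demos and smoke tests."""
    return SimulationConfig(
        field_width_px=256,
        field_height_px=256,
        n_frames=n_frames,
        rng_seed=seed,
    )
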