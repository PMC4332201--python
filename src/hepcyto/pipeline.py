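"""End-to-end workflow: simulate → segment → measure → exclude → summarise.

Four assay variants mirror the experimental designs the pipeline serves:

``accumulation``
    Vehicle-control plus treated fields; per-cell cytosolic anion
    intensity corrected by the vehicle mean, accumulation outlier rules,
    condition means and cell-to-cell CV.
``viability``
    Toxin-exposure endpoint imaging: viable-cell counts per field from
    nuclear area, propidium iodide, Hoechst-SD and circularity rules.
``timelapse``
    30-h death movie: frame-1 ROIs frozen, per-frame PI traces, death
    calls, FBA-tertile stratification and group death fractions.
``if_correlation``
    Immunofluorescence correlation: per-cell marker intensity (in the
    Lysotracker slot) versus FBA, Pearson r.

Every run directory is self-describing: resolved config copy, cell
tables, JSON report and a per-rule exclusion log.  A fixed seed makes the
whole run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import io as hio
from .core import ConfigurationError, ImageField
from .quantify import (
    RULESETS,
    CellRecord,
    ExclusionRuleset,
    apply_exclusions,
    compute_fba_over_hoechst,
    detect_death,
    link_and_trace,
    measure_cells,
    score_viability,
    subtract_backgrounds,
)
from .segment import SegmentationParams, build_cytosol_rois, segment_nuclei
from .simulate import SimulationConfig, generate_field, generate_timelapse
from .stats import (
    coefficient_of_variation,
    correlate_per_cell,
    fold_fba_dying_vs_surviving,
    group_summaries,
    stratify_by_fba,
)

__all__ = ["run_pipeline", "ASSAYS", "DEFAULT_CONFIG", "demo_config"]

ASSAYS = ("accumulation", "viability", "timelapse", "if_correlation")

#: fluorescence below this is annotated as too low for robust scoring
LOW_SIGNAL_AU = 75.0

DEFAULT_CONFIG: dict = {
    "assay": "accumulation",
    "seed": 0,
    "outdir": "hepcyto_run",
    "n_fields": 1,
    "band_um": 3.0,
    "death_threshold_au": 100.0,
    "segmentation": {"mode": "smooth", "sigma_um": 3.2},
    "simulation": {},
    "ruleset": None,  # assay default
    "ruleset_overrides": {},
    "marker_rho": 0.2,
    "pi_roi": "cytosol",
}

_ASSAY_RULESET = {
    "accumulation": "accumulation_assay",
    "viability": "viability_assay",
    "timelapse": "timelapse_assay",
    "if_correlation": "timelapse_assay",  # shape-only QC before correlating
}

_ASSAY_SIM_DEFAULTS = {
    "accumulation": {"dead_fraction": 0.05, "debris_rate_per_mm2": 40.0},
    "viability": {"dead_fraction": 0.3, "debris_rate_per_mm2": 40.0,
                  "vehicle": True},
    "timelapse": {"field_width_px": 256, "field_height_px": 256,
                  "n_frames": 13},
    "if_correlation": {},
}


def _merge_config(config: dict | str | Path | None, outdir, seed) -> dict:
    if isinstance(config, (str, Path)):
        config = hio.load_config(config)
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    cfg["segmentation"] = {**DEFAULT_CONFIG["segmentation"],
                           **(cfg.get("segmentation") or {})}
    cfg["simulation"] = dict(cfg.get("simulation") or {})
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    if seed is not None:
        cfg["seed"] = int(seed)
    if cfg["assay"] not in ASSAYS:
        raise ConfigurationError(
            f"unknown assay {cfg['assay']!r}; valid: {', '.join(ASSAYS)}"
        )
    return cfg


def _derive_seed(base: int, k: int) -> int:
    return int((base * 100003 + 7919 * k) % (2**31 - 1))


def _sim_config(cfg: dict, seed: int, **extra) -> SimulationConfig:
    params = {**_ASSAY_SIM_DEFAULTS[cfg["assay"]], **cfg["simulation"], **extra}
    params["rng_seed"] = seed
    return SimulationConfig(**params)


def _ruleset(cfg: dict) -> ExclusionRuleset:
    name = cfg["ruleset"] or _ASSAY_RULESET[cfg["assay"]]
    if name not in RULESETS:
        raise ConfigurationError(
            f"unknown ruleset {name!r}; valid: {', '.join(RULESETS)}"
        )
    rs = RULESETS[name]()
    overrides = cfg.get("ruleset_overrides") or {}
    if overrides:
        rules = []
        for rule in rs.rules:
            if rule.flag in overrides:
                rule = dataclasses.replace(rule, bound=float(overrides[rule.flag]))
            rules.append(rule)
        rs = ExclusionRuleset(name=rs.name, rules=tuple(rules))
    return rs


def _segment_and_measure(
    field: ImageField, cfg: dict
) -> tuple[np.ndarray, list[CellRecord]]:
    seg = SegmentationParams(**cfg["segmentation"])
    label_map, nuclei = segment_nuclei(
        field.channel("hoechst"), field.pixel_size_um, seg
    )
    rois = build_cytosol_rois(label_map, field.pixel_size_um, cfg["band_um"])
    records = measure_cells(field, rois, nuclei)
    return label_map, records


def _census(records: Sequence[CellRecord]) -> dict[str, int]:
    census: dict[str, int] = {}
    for rec in records:
        for f in rec.flags:
            census[f] = census.get(f, 0) + 1
    return census


def _exclusion_log_lines(records: Sequence[CellRecord]) -> list[str]:
    lines = []
    for rec in records:
        if rec.flags:
            lines.append(
                f"excluded field={rec.field_id} label={rec.label} "
                f"rules={','.join(sorted(rec.flags))}"
            )
    return lines


def _write_outputs(outdir: Path, cfg: dict, records, report: dict,
                   label_maps: dict[str, np.ndarray], log_lines) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    hio.save_config(cfg, outdir / "config.yaml")
    cells = hio.records_to_frame(records)
    cells.to_csv(outdir / "cells.csv", index=False)
    hio.write_json(report, outdir / "report.json")
    for fid, lm in label_maps.items():
        tifffile.imwrite(outdir / f"labels_{fid}.tif", lm.astype(np.uint16))
    (outdir / "exclusions.log").write_text("\n".join(log_lines) + "\n")
    return {
        "outdir": str(outdir),
        "cells_csv": str(outdir / "cells.csv"),
        "report_json": str(outdir / "report.json"),
        "report": report,
        "records": list(records),
    }


# ---------------------------------------------------------------------------
# assay drivers


def _run_accumulation(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    vehicle_cfg = _sim_config(cfg, _derive_seed(seed, 0), vehicle=True)
    vehicle_field, _ = generate_field(vehicle_cfg)
    vehicle_field.field_id = "vehicle_000"
    _, vrecords = _segment_and_measure(vehicle_field, cfg)
    control_mean = float(
        np.mean([r.stats[("anion", "cytosol")].mean for r in vrecords])
    )
    ruleset = _ruleset(cfg)
    all_records: list[CellRecord] = []
    label_maps: dict[str, np.ndarray] = {}
    per_field = []
    for k in range(int(cfg["n_fields"])):
        sim = _sim_config(cfg, _derive_seed(seed, k + 1))
        field, _ = generate_field(sim)
        field.field_id = f"field_{k:03d}"
        lm, records = _segment_and_measure(field, cfg)
        subtract_backgrounds(records, field, control_mean)
        apply_exclusions(records, ruleset)
        compute_fba_over_hoechst(records)
        retained = [r for r in records if r.retained]
        fba = [r.corrected[("anion", "cytosol")] for r in retained]
        mean_fba = float(np.mean(fba)) if fba else float("nan")
        per_field.append(
            {
                "field_id": field.field_id,
                "n_segmented": len(records),
                "n_retained": len(retained),
                "mean_fba_au": mean_fba,
                "cv_pct": coefficient_of_variation(fba) if len(fba) > 1 else None,
                "below_robust_scoring": bool(mean_fba <= LOW_SIGNAL_AU),
            }
        )
        label_maps[field.field_id] = lm
        all_records.extend(records)
    report = {
        "assay": "accumulation",
        "seed": seed,
        "control_mean_anion_au": control_mean,
        "fields": per_field,
        "exclusion_census": _census(all_records),
    }
    return _write_outputs(outdir, cfg, all_records, report, label_maps,
                          _exclusion_log_lines(all_records))


def _run_viability(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    all_records: list[CellRecord] = []
    label_maps: dict[str, np.ndarray] = {}
    for k in range(int(cfg["n_fields"])):
        sim = _sim_config(cfg, _derive_seed(seed, k + 1))
        field, _ = generate_field(sim)
        field.field_id = f"field_{k:03d}"
        lm, records = _segment_and_measure(field, cfg)
        subtract_backgrounds(records, field, anion_control_required=False)
        label_maps[field.field_id] = lm
        all_records.extend(records)
    counts = score_viability(all_records)
    for rec in all_records:  # census of failed viability criteria
        if not rec.viable:
            rec.flags.add("nonviable")
    report = {
        "assay": "viability",
        "seed": seed,
        "viable_counts_per_field": counts,
        "n_segmented": len(all_records),
        "n_viable": int(sum(counts.values())),
    }
    return _write_outputs(outdir, cfg, all_records, report, label_maps,
                          _exclusion_log_lines(all_records))


def _run_timelapse(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    sim = _sim_config(cfg, _derive_seed(seed, 1))
    fields, truth = generate_timelapse(sim)
    for f in fields:
        f.field_id = "movie_000"
    lm, records = _segment_and_measure(fields[0], cfg)
    subtract_backgrounds(records, fields[0], anion_control_required=False)
    apply_exclusions(records, _ruleset(cfg))
    retained_labels = {r.label for r in records if r.retained}
    rois = build_cytosol_rois(lm, fields[0].pixel_size_um, cfg["band_um"])
    rois = [r for r in rois if r.label in retained_labels]
    traces = link_and_trace(fields, rois, pi_roi=cfg["pi_roi"])
    thr = float(cfg["death_threshold_au"])
    for tr in traces:
        detect_death(tr, thr)
    # cells must be alive at frame 1 to enter the stratification
    live0 = [tr for tr in traces if tr.pi_cell_fluorescence[0] <= thr]
    fba0 = np.array([tr.fba_cytosol[0] for tr in live0])
    died = np.array([tr.death_frame is not None for tr in live0])
    labels = stratify_by_fba(fba0)
    groups = group_summaries(fba0, died, labels)
    whole = next(g for g in groups if g.group == "whole")
    group_table = []
    for g in groups:
        group_table.append(
            {
                **dataclasses.asdict(g),
                "death_minus_whole_pct_points": g.death_pct - whole.death_pct,
                "death_over_whole_relative": (g.death_pct / whole.death_pct)
                if whole.death_pct > 0
                else None,
            }
        )
    try:
        fold = fold_fba_dying_vs_surviving(fba0, died)
    except Exception:
        fold = None
    trace_rows = pd.DataFrame(
        {
            "cell_id": [tr.cell_id for tr in live0],
            "fba_t0_au": fba0,
            "tertile": labels,
            "death_frame": [tr.death_frame or 0 for tr in live0],
            "died": died,
        }
    )
    trace_rows.to_csv(outdir_mk(outdir) / "traces.csv", index=False)
    report = {
        "assay": "timelapse",
        "seed": seed,
        "n_frames": sim.n_frames,
        "span_hours": (sim.n_frames - 1) * sim.frame_interval_min / 60.0,
        "n_traced": len(traces),
        "n_stratified": len(live0),
        "groups": group_table,
        "fold_fba_dying_vs_surviving": fold,
        "exclusion_census": _census(records),
    }
    return _write_outputs(outdir, cfg, records, report,
                          {"movie_000": lm}, _exclusion_log_lines(records))


def _run_if_correlation(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    vehicle_cfg = _sim_config(cfg, _derive_seed(seed, 0), vehicle=True)
    vfield, _ = generate_field(vehicle_cfg)
    _, vrecords = _segment_and_measure(vfield, cfg)
    control_mean = float(
        np.mean([r.stats[("anion", "cytosol")].mean for r in vrecords])
    )
    sim = _sim_config(
        cfg, _derive_seed(seed, 1),
        marker_rho_with_anion=float(cfg["marker_rho"]),
    )
    field, _ = generate_field(sim)
    field.field_id = "field_000"
    lm, records = _segment_and_measure(field, cfg)
    subtract_backgrounds(records, field, control_mean)
    apply_exclusions(records, _ruleset(cfg))
    retained = [r for r in records if r.retained]
    fba = [r.corrected[("anion", "cytosol")] for r in retained]
    marker = [r.corrected[("lysotracker", "cytosol")] for r in retained]
    r_val, n = correlate_per_cell(marker, fba)
    report = {
        "assay": "if_correlation",
        "seed": seed,
        "pearson_r": r_val,
        "n_cells": n,
        "configured_marker_rho": float(cfg["marker_rho"]),
        "exclusion_census": _census(records),
    }
    return _write_outputs(outdir, cfg, records, report,
                          {"field_000": lm}, _exclusion_log_lines(records))


def outdir_mk(outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def demo_config(assay: str = "timelapse") -> dict:
    """The packaged demo: a small field that runs in seconds.

    30-h cadence compressed to 13 frames on a 256 px field; all other
    parameters at their assay defaults.
    """
    return {
        "assay": assay,
        "seed": 0,
        "simulation": {"field_width_px": 256, "field_height_px": 256},
    }


def run_pipeline(
    config: dict | str | Path | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Run one assay end-to-end and write a self-describing run directory.

    ``config`` may be a mapping or a YAML path; ``outdir`` and ``seed``
    override the config values.  Returns a dict with the report, the
    record list and the paths of the written artifacts.
    """
    cfg = _merge_config(config, outdir, seed)
    out = Path(cfg["outdir"])
    driver = {
        "accumulation": _run_accumulation,
        "viability": _run_viability,
        "timelapse": _run_timelapse,
        "if_correlation": _run_if_correlation,
    }[cfg["assay"]]
    return driver(cfg, out)
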