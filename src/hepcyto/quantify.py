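"""Per-cell measurement, background subtraction, exclusion rules, death calls.

This module houses the quantitative heart of the assay:

* :func:`measure_cells` — mean / SD / integrated intensity / pixel count per
  channel per ROI (nuclear mask and cytosolic annulus), no filtering;
* :func:`subtract_backgrounds` — anion intensities are corrected by the
  vehicle-control (no-anion) mean; Hoechst, Lysotracker and propidium
  iodide by the field's histogram mode.  Negative corrected values are
  kept (not clamped);
* :func:`apply_exclusions` — the declarative outlier/viability rulesets
  that remove damaged cells and debris.  Three named variants exist, one
  per assay mode, with the thresholds of the original screen;
* :func:`score_viability` — viable-cell counting (qualifying nuclear area,
  propidium iodide below threshold, Hoechst SD window, circularity);
* :func:`link_and_trace` / :func:`detect_death` — fixed-ROI time-lapse
  traces and the first-frame-above-threshold death call.

Population-relative bounds (the "mean ×k / mean ÷k" rules) compare each
cell's statistic to the mean of that statistic over all candidate records,
computed once before any flagging, so flagging is deterministic,
idempotent and order-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

import numpy as np

from .core import (
    ConfigurationError,
    EmptyInputError,
    ImageField,
    InvalidParameterError,
    MissingChannelError,
)
from .imageops import histogram_mode
from .segment import NucleusRecord, RoiPair

__all__ = [
    "ChannelStats",
    "CellRecord",
    "Rule",
    "ExclusionRuleset",
    "accumulation_ruleset",
    "viability_ruleset",
    "timelapse_ruleset",
    "measure_cells",
    "subtract_backgrounds",
    "apply_exclusions",
    "score_viability",
    "compute_fba_over_hoechst",
    "TimelapseTrace",
    "link_and_trace",
    "detect_death",
    "DEATH_THRESHOLD_AU",
]

ROIS = ("nuclear", "cytosol")

#: propidium-iodide excess (a.u. above background) that marks cell death
DEATH_THRESHOLD_AU = 100.0


@dataclass
class ChannelStats:
    """Raw intensity statistics of one channel inside one ROI."""

    mean: float
    sd: float
    integrated: float
    pixel_count: int


@dataclass
class CellRecord:
    """Everything measured for one cell in one field.

    ``stats[(channel, roi)]`` holds raw statistics; ``corrected`` holds
    background-subtracted means (filled by
    :func:`subtract_backgrounds`).  ``flags`` collects the identifiers of
    every violated exclusion rule; a record is retained iff ``flags`` is
    empty.
    """

    label: int
    field_id: str = ""
    stats: dict = dc_field(default_factory=dict)
    corrected: dict = dc_field(default_factory=dict)
    area_um2: float = float("nan")
    max_feret_um: float = float("nan")
    circularity: float = float("nan")
    centroid_x_px: float = float("nan")
    centroid_y_px: float = float("nan")
    fba_over_hoechst: float | None = None
    flags: set = dc_field(default_factory=set)
    viable: bool | None = None

    @property
    def retained(self) -> bool:
        return not self.flags

    def value(self, statistic: str, channel: str | None, roi: str | None) -> float:
        """Value a rule reads: corrected means when available, raw SDs."""
        if statistic == "area_um2":
            return self.area_um2
        if statistic == "circularity":
            return self.circularity
        key = (channel, roi)
        if key not in self.stats:
            raise MissingChannelError(
                f"statistic {statistic} of {channel}/{roi} was never measured"
            )
        if statistic == "sd":
            return self.stats[key].sd
        if statistic == "mean":
            return self.corrected.get(key, self.stats[key].mean)
        raise InvalidParameterError(f"unknown statistic {statistic!r}")


@dataclass(frozen=True)
class Rule:
    """One declarative exclusion rule.

    Absolute rules compare the statistic to ``bound`` directly; relative
    rules compare it to ``bound × population mean`` of the same statistic
    over all candidate records.
    """

    flag: str
    statistic: Literal["sd", "mean", "area_um2", "circularity"]
    channel: str | None
    roi: str | None
    relation: Literal["gt", "lt"]
    bound: float
    relative: bool = False


@dataclass
class ExclusionRuleset:
    name: str
    rules: tuple[Rule, ...]


def accumulation_ruleset() -> ExclusionRuleset:
    """Outlier rules of the anion-accumulation assay.

    Pixel-SD windows per dye (anion ×15/÷15 in the cytosol, Lysotracker
    ×10/÷5 in the cytosol, Hoechst ×2.5/÷5 in the nucleus — each dye's
    target compartment), nuclear Lysotracker intensity ×1.5, nuclear area
    47–360 µm², circularity ≥ 0.6.
    """
    return ExclusionRuleset(
        name="accumulation_assay",
        rules=(
            Rule("anion_sd_high", "sd", "anion", "cytosol", "gt", 15.0, True),
            Rule("anion_sd_low", "sd", "anion", "cytosol", "lt", 1 / 15.0, True),
            Rule("lyso_sd_high", "sd", "lysotracker", "cytosol", "gt", 10.0, True),
            Rule("lyso_sd_low", "sd", "lysotracker", "cytosol", "lt", 1 / 5.0, True),
            Rule("hoechst_sd_high", "sd", "hoechst", "nuclear", "gt", 2.5, True),
            Rule("hoechst_sd_low", "sd", "hoechst", "nuclear", "lt", 1 / 5.0, True),
            Rule("lyso_nuclear_high", "mean", "lysotracker", "nuclear", "gt", 1.5, True),
            Rule("area_small", "area_um2", None, None, "lt", 47.0),
            Rule("area_large", "area_um2", None, None, "gt", 360.0),
            Rule("circularity_low", "circularity", None, None, "lt", 0.6),
        ),
    )


def viability_ruleset() -> ExclusionRuleset:
    """Viable-cell scoring rules: qualifying nuclei (36–468 µm²) with
    nuclear propidium iodide < 200, Hoechst SD within ×2/÷2 of the
    population mean, and the circularity exclusion."""
    return ExclusionRuleset(
        name="viability_assay",
        rules=(
            Rule("area_small", "area_um2", None, None, "lt", 36.0),
            Rule("area_large", "area_um2", None, None, "gt", 468.0),
            Rule("pi_high", "mean", "pi", "nuclear", "gt", 200.0),
            Rule("hoechst_sd_high", "sd", "hoechst", "nuclear", "gt", 2.0, True),
            Rule("hoechst_sd_low", "sd", "hoechst", "nuclear", "lt", 0.5, True),
            Rule("circularity_low", "circularity", None, None, "lt", 0.6),
        ),
    )


def timelapse_ruleset() -> ExclusionRuleset:
    """Looser outlier rules of the death time-lapse (day-0 cells):
    nuclear area 36–252 µm² and circularity ≥ 0.05."""
    return ExclusionRuleset(
        name="timelapse_assay",
        rules=(
            Rule("area_small", "area_um2", None, None, "lt", 36.0),
            Rule("area_large", "area_um2", None, None, "gt", 252.0),
            Rule("circularity_low", "circularity", None, None, "lt", 0.05),
        ),
    )


RULESETS = {
    "accumulation_assay": accumulation_ruleset,
    "viability_assay": viability_ruleset,
    "timelapse_assay": timelapse_ruleset,
}


def _roi_stats(values: np.ndarray) -> ChannelStats:
    values = values.astype(float)
    n = values.size
    mean = float(values.mean()) if n else float("nan")
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return ChannelStats(mean=mean, sd=sd, integrated=float(values.sum()), pixel_count=n)


def measure_cells(
    field: ImageField,
    rois: Sequence[RoiPair],
    nuclei: Sequence[NucleusRecord] | None = None,
) -> list[CellRecord]:
    """Apply nuclear and annular ROIs to every channel of a field.

    Returns one :class:`CellRecord` per ROI pair with raw statistics for
    every channel present in the field; shape metrics are merged in from
    ``nuclei`` when given.  No filtering happens here.
    """
    h, w = field.shape
    by_label = {n.label: n for n in (nuclei or [])}
    records = []
    for roi in rois:
        for rc in (roi.nuclear_rc, roi.cytosol_rc):
            if len(rc) and (
                rc[:, 0].min() < 0 or rc[:, 1].min() < 0
                or rc[:, 0].max() >= h or rc[:, 1].max() >= w
            ):
                raise InvalidParameterError(
                    f"ROI {roi.label} extends outside the {h}x{w} image"
                )
        rec = CellRecord(label=roi.label, field_id=field.field_id)
        for ch in field.channels:
            img = field.channel(ch)
            rec.stats[(ch, "nuclear")] = _roi_stats(img[roi.nuclear_index()])
            rec.stats[(ch, "cytosol")] = _roi_stats(img[roi.cytosol_index()])
        nuc = by_label.get(roi.label)
        if nuc is not None:
            rec.area_um2 = nuc.area_um2
            rec.max_feret_um = nuc.max_feret_um
            rec.circularity = nuc.circularity
            rec.centroid_x_px = nuc.centroid_x_px
            rec.centroid_y_px = nuc.centroid_y_px
        records.append(rec)
    return records


def subtract_backgrounds(
    records: Sequence[CellRecord],
    field: ImageField,
    control_mean_anion: float | None = None,
    anion_control_required: bool = True,
) -> list[CellRecord]:
    """Background-correct the measured means, in place.

    Anion means are reduced by the vehicle-control mean cytosolic
    intensity; Hoechst, Lysotracker and propidium iodide by the mode of
    the corresponding channel image.  Negative corrected values are kept.
    """
    modes = {
        ch: float(histogram_mode(field.channel(ch)))
        for ch in field.channels
        if ch != "anion"
    }
    if field.has_channel("anion"):
        if control_mean_anion is None:
            if anion_control_required:
                raise ConfigurationError(
                    "anion channel present but no vehicle-control mean supplied"
                )
            control_mean_anion = 0.0
    for rec in records:
        for (ch, roi), st in rec.stats.items():
            bg = control_mean_anion if ch == "anion" else modes[ch]
            rec.corrected[(ch, roi)] = st.mean - bg
    return list(records)


def _population_means(
    records: Sequence[CellRecord], ruleset: ExclusionRuleset
) -> dict:
    refs = {}
    for rule in ruleset.rules:
        if not rule.relative:
            continue
        key = (rule.statistic, rule.channel, rule.roi)
        if key not in refs:
            vals = [r.value(*key) for r in records]
            refs[key] = float(np.mean(vals))
    return refs


def apply_exclusions(
    records: Sequence[CellRecord],
    ruleset: ExclusionRuleset,
    pixel_size_um: float | None = None,
) -> list[CellRecord]:
    """Flag every record that violates any rule of the ruleset.

    Population-relative reference values are computed once over all
    candidate records before flagging, so the result is independent of
    record order and of repeated application.  Retained ⇔ no flags.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("cannot apply exclusions to an empty record list")
    if any(r.relative for r in ruleset.rules) and len(records) < 2:
        raise InvalidParameterError(
            "population-relative rules need at least two candidate records"
        )
    refs = _population_means(records, ruleset)
    for rec in records:
        rec.flags = {f for f in rec.flags if f == "undefined_fba_ratio"}
        for rule in ruleset.rules:
            v = rec.value(rule.statistic, rule.channel, rule.roi)
            bound = rule.bound
            if rule.relative:
                bound = rule.bound * refs[(rule.statistic, rule.channel, rule.roi)]
            hit = v > bound if rule.relation == "gt" else v < bound
            if hit:
                rec.flags.add(rule.flag)
    return records


def score_viability(
    records: Sequence[CellRecord], pixel_size_um: float | None = None
) -> dict[str, int]:
    """Count viable cells per field and set each record's ``viable`` flag.

    A cell is viable when it passes every rule of the viability ruleset.
    Requires the propidium-iodide channel to have been measured.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("cannot score viability of an empty record list")
    if any(("pi", "nuclear") not in r.stats for r in records):
        raise MissingChannelError("propidium iodide channel missing from records")
    rs = viability_ruleset()
    refs = _population_means(records, rs)
    counts: dict[str, int] = {}
    for rec in records:
        ok = True
        for rule in rs.rules:
            v = rec.value(rule.statistic, rule.channel, rule.roi)
            bound = rule.bound * refs[(rule.statistic, rule.channel, rule.roi)] \
                if rule.relative else rule.bound
            if (v > bound if rule.relation == "gt" else v < bound):
                ok = False
                break
        rec.viable = ok
        counts[rec.field_id] = counts.get(rec.field_id, 0) + int(ok)
    return counts


def compute_fba_over_hoechst(records: Sequence[CellRecord]) -> list[CellRecord]:
    """Cytosolic anion over nuclear Hoechst, on corrected means.

    Cells with non-positive corrected Hoechst get ``None`` and the
    ``undefined_fba_ratio`` flag (the ratio is undefined; the record is
    excluded downstream).
    """
    for rec in records:
        fba = rec.corrected.get(("anion", "cytosol"))
        hoechst = rec.corrected.get(("hoechst", "nuclear"))
        if fba is None or hoechst is None or hoechst <= 0:
            rec.fba_over_hoechst = None
            rec.flags.add("undefined_fba_ratio")
        else:
            rec.fba_over_hoechst = float(fba / hoechst)
    return list(records)


@dataclass
class TimelapseTrace:
    """Background-subtracted per-cell time series of PI and FBA."""

    cell_id: int
    frame_times_min: np.ndarray
    pi_cell_fluorescence: np.ndarray
    fba_cytosol: np.ndarray
    fba_over_hoechst: float | None = None
    death_frame: int | None = None


def link_and_trace(
    fields: Sequence[ImageField],
    rois_at_t0: Sequence[RoiPair],
    pi_roi: Literal["cytosol", "nuclear"] = "cytosol",
) -> list[TimelapseTrace]:
    """Measure fixed frame-1 ROIs across a time-ordered field sequence.

    Hepatocytes are essentially non-motile over the 30-h movie, so ROIs
    are frozen from frame 1 (no re-segmentation or tracking).  Per frame
    the PI "cell fluorescence" (default: the cytosolic annulus, the
    cellular ROI) and cytosolic FBA are measured with the frame's image
    mode subtracted.  ``fba_over_hoechst`` is computed at frame 1; cells
    whose corrected Hoechst is non-positive are dropped.
    """
    fields = list(fields)
    if len(fields) < 2:
        raise InvalidParameterError("time-lapse needs at least two frames")
    shape0 = fields[0].shape
    for f in fields[1:]:
        if f.shape != shape0:
            raise InvalidParameterError("frame dimensions differ across the movie")
    times = np.array([f.time_h * 60.0 for f in fields])
    if np.any(np.diff(times) <= 0):  # fall back to frame index spacing
        times = np.arange(len(fields), dtype=float)
    n = len(rois_at_t0)
    pi_tr = np.zeros((n, len(fields)))
    fba_tr = np.zeros((n, len(fields)))
    for j, f in enumerate(fields):
        pi_img = f.channel("pi")
        an_img = f.channel("anion")
        pi_mode = float(histogram_mode(pi_img))
        an_mode = float(histogram_mode(an_img))
        for i, roi in enumerate(rois_at_t0):
            idx = roi.cytosol_index() if pi_roi == "cytosol" else roi.nuclear_index()
            pi_tr[i, j] = float(pi_img[idx].mean()) - pi_mode
            fba_tr[i, j] = float(an_img[roi.cytosol_index()].mean()) - an_mode
    h_img = fields[0].channel("hoechst")
    h_mode = float(histogram_mode(h_img))
    traces = []
    for i, roi in enumerate(rois_at_t0):
        hoechst0 = float(h_img[roi.nuclear_index()].mean()) - h_mode
        if hoechst0 <= 0:
            continue  # ratio undefined; record excluded
        traces.append(
            TimelapseTrace(
                cell_id=roi.label,
                frame_times_min=times.copy(),
                pi_cell_fluorescence=pi_tr[i],
                fba_cytosol=fba_tr[i],
                fba_over_hoechst=float(fba_tr[i, 0] / hoechst0),
            )
        )
    return traces


def detect_death(
    trace: TimelapseTrace, threshold_au: float = DEATH_THRESHOLD_AU
) -> int | None:
    """First frame (1-based) whose PI excess exceeds the threshold.

    Returns ``None`` if the trace never crosses; also records the call on
    the trace.  Appending frames after a detected death can never change
    the call.
    """
    pi = np.asarray(trace.pi_cell_fluorescence, dtype=float)
    if pi.size == 0:
        raise EmptyInputError("empty propidium-iodide trace")
    above = np.flatnonzero(pi > threshold_au)
    trace.death_frame = int(above[0]) + 1 if above.size else None
    return trace.death_frame
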