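"""Shared containers and error types.

A :class:`ImageField` is one multi-channel microscopy field at one time
point: a dict of single-plane grayscale arrays keyed by channel name, plus
the pixel size and acquisition metadata the pipeline needs (condition,
treatment, culture time, frame index).  Channel names are fixed to the four
dyes of the assay; file-level aliasing happens in :mod:`hepcyto.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Canonical channel names: Hoechst 33342 (nuclear stain), the fluorescent
#: organic anion (FBA or related fluorophore), Lysotracker (vital dye) and
#: propidium iodide (death marker).
CHANNELS = ("hoechst", "anion", "lysotracker", "pi")


class HepcytoError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(HepcytoError, ValueError):
    """A simulation or pipeline configuration value is out of range."""


class InvalidParameterError(HepcytoError, ValueError):
    """An operator parameter violates its precondition."""


class DegenerateHistogramError(HepcytoError, ValueError):
    """Histogram has fewer than two nonzero bins; no threshold exists."""


class MissingChannelError(HepcytoError, KeyError):
    """A required fluorescence channel is absent from the field."""


class ConfigurationError(HepcytoError, ValueError):
    """The requested analysis lacks a required input (e.g. vehicle control)."""


class EmptyInputError(HepcytoError, ValueError):
    """An operation received an empty image, mask, trace or record list."""


@dataclass
class ImageField:
    """One multi-channel field at one time point.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2-D integer array (camera counts).
        All channels must share the same shape.
    pixel_size_um
        Lateral pixel size in micrometres per pixel.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float
    field_id: str = "field_000"
    condition: str = ""
    treatment: str = ""
    time_h: float = 0.0
    frame: int = 1

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise InvalidConfigError("pixel_size_um must be positive")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise InvalidConfigError(f"channel shapes differ: {shapes}")
        for arr in self.channels.values():
            if np.asarray(arr).ndim != 2:
                raise InvalidConfigError("channels must be single-plane 2-D images")

    @property
    def shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return np.asarray(arr).shape  # type: ignore[return-value]

    def channel(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.channels[name])
        except KeyError:
            raise MissingChannelError(
                f"channel {name!r} not present in field {self.field_id!r} "
                f"(have {sorted(self.channels)})"
            ) from None

    def has_channel(self, name: str) -> bool:
        return name in self.channels
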