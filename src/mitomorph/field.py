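"""Core container for one imaged field: three channels plus metadata."""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np

__all__ = ["FluorescenceField"]


@dataclass
class FluorescenceField:
    """One multi-channel fluorescence field.

    Channels (identical shape, finite, non-negative):

    * ``calcium_channel`` — Fluo-4 calcium indicator,
    * ``mito_channel``    — MitoTracker mitochondrial marker,
    * ``er_channel``      — ER-Tracker endoplasmic-reticulum marker.

    ``pixel_size`` is the pixel edge in micrometres.  Condition labels
    (``katp_level``, ``rotenone``, ``replicate_id``, ``field_id``) identify
    the field's place in the factorial design.  ``controls`` optionally maps
    channel name ("calcium"/"mito"/"er") to a negative-control image of the
    same stain.  ``truth`` carries the generating ground truth for synthetic
    fields (masks, compartment levels, network topology) and is ``None``
    for real data.
    """

    calcium_channel: np.ndarray
    mito_channel: np.ndarray
    er_channel: np.ndarray
    pixel_size: float = 0.1
    katp_level: str = "ctrl"
    rotenone: str = "veh"
    replicate_id: str = "r1"
    field_id: str = "f1"
    controls: dict[str, np.ndarray] | None = None
    truth: dict[str, Any] | None = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        chans = {
            "calcium": self.calcium_channel,
            "mito": self.mito_channel,
            "er": self.er_channel,
        }
        shapes = {name: np.asarray(c).shape for name, c in chans.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, c in chans.items():
            arr = np.asarray(c, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} channel contains non-finite values")
            if (arr < 0).any():
                raise ValueError(f"{name} channel contains negative values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mito_channel.shape

    @property
    def labels(self) -> dict[str, str]:
        return {
            "field_id": self.field_id,
            "replicate": self.replicate_id,
            "katp_level": self.katp_level,
            "rotenone": self.rotenone,
        }
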