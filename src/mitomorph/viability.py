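"""MTT viability normalization and image-based cell-count aggregation.

MTT absorbances are expressed as percent of the untreated-control mean
(the control mean maps to exactly 100 %); cell counts are averaged over
all images of a biological replicate, which then serves as that
replicate's single representative value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["mtt_percent", "replicate_cell_count", "viability_table"]


def mtt_percent(
    absorbances_by_group: dict[str, "np.ndarray | list[float]"],
    control_label: str,
    blank: float = 0.0,
) -> dict[str, np.ndarray]:
    """Per-well viability as percent of the control group's mean absorbance.

    ``blank`` (optional, default 0) is subtracted from every well before
    normalization.  The control group's mean maps to exactly 100.
    """
    if control_label not in absorbances_by_group:
        raise ValueError(f"control group {control_label!r} missing")
    groups = {
        k: np.asarray(v, dtype=float) - blank
        for k, v in absorbances_by_group.items()
    }
    ctrl = groups[control_label]
    if ctrl.size == 0:
        raise ValueError("control group is empty")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise ValueError(f"control mean absorbance must be > 0, got {ctrl_mean}")
    return {k: 100.0 * v / ctrl_mean for k, v in groups.items()}


def replicate_cell_count(counts_per_image) -> float:
    """Arithmetic mean cell count over a replicate's images."""
    counts = np.asarray(counts_per_image, dtype=float)
    if counts.size == 0:
        raise ValueError("no image counts supplied")
    return float(counts.mean())


def viability_table(
    mtt_wells: pd.DataFrame,
    cell_counts: pd.DataFrame,
    control_katp: str = "ctrl",
    control_rotenone: str = "veh",
) -> pd.DataFrame:
    """Tidy replicate-level viability records from well/image tables.

    ``mtt_wells`` needs columns replicate, katp_level, rotenone,
    absorbance; ``cell_counts`` the same with ``count``.  MTT is
    normalized to the untreated control condition's mean absorbance;
    counts are averaged per replicate.
    """
    ctrl = mtt_wells[
        (mtt_wells["katp_level"] == control_katp)
        & (mtt_wells["rotenone"] == control_rotenone)
    ]["absorbance"]
    if ctrl.empty:
        raise ValueError("no control wells found for MTT normalization")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise ValueError("control mean absorbance must be > 0")

    mtt = (
        mtt_wells.assign(mtt_percent=100.0 * mtt_wells["absorbance"] / ctrl_mean)
        .groupby(["katp_level", "rotenone", "replicate"], sort=False)["mtt_percent"]
        .mean()
        .reset_index()
    )
    counts = (
        cell_counts.groupby(["katp_level", "rotenone", "replicate"], sort=False)["count"]
        .mean()
        .reset_index()
        .rename(columns={"count": "cell_count"})
    )
    return mtt.merge(counts, on=["katp_level", "rotenone", "replicate"], how="outer")
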