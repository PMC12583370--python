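"""Shared analysis configuration and per-dataset measurement driver."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

__all__ = ["AnalysisConfig", "measure_dataset"]


@dataclass
class AnalysisConfig:
    """Knobs of the measurement pipeline.

    ``threshold_method`` is "negative_control" (threshold at the control's
    ``control_percentile``) or "otsu".  ``min_object_px`` removes speckle
    components before skeletonization; ``prune_spur_px`` removes short
    junction-attached spurs left by thinning.  ``alpha`` is the
    significance level used downstream.
    """

    threshold_method: str = "negative_control"
    control_percentile: float = 99.5
    min_object_px: int = 5
    prune_spur_px: int = 3
    pixel_size: float | None = None  # None: take each field's own
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def measure_dataset(fields, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Morphology + compartment calcium for every field, tidy one-row-per-field.

    QC flags are carried in the ``qc_flag`` column, never dropped; a field
    that fails a stage still contributes a (flagged) row.
    """
    from . import calcium as ca
    from . import morphometry

    cfg = config or AnalysisConfig()
    rows = []
    for fld in fields:
        row = dict(fld.labels)
        flags = []
        morpho = morphometry.measure_field(fld, cfg)
        row.update(
            branch_count=morpho.branch_count,
            junction_count=morpho.junction_count,
            rod_count=morpho.rod_count,
            fragmentation=morpho.fragmentation,
            branching=morpho.branching,
            mean_branch_length_um=morpho.mean_branch_length_um,
        )
        if morpho.qc_flag:
            flags.append(f"morpho:{morpho.qc_flag}")
        comp = ca.measure_calcium(fld, fld.controls, cfg)
        row.update(
            ca_whole_cell=comp.mean_whole_cell,
            ca_mito=comp.mean_mito,
            ca_er=comp.mean_er,
            background=comp.background_used,
            mito_area_px=comp.mask_areas.get("mito", 0),
            er_area_px=comp.mask_areas.get("er", 0),
        )
        if comp.qc_flag:
            flags.append(f"calcium:{comp.qc_flag}")
        row["qc_flag"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)
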