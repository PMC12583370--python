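"""Background-corrected Fluo-4 intensity in whole-cell / mitochondrial / ER
compartments.

Compartment calcium is the mean calcium-channel intensity restricted to a
marker-derived mask, minus a per-field scalar background (negative-control
median, or the channel's 5th percentile without a control), clipped at
zero.  The mitochondrial and ER masks come from thresholding their marker
channels; the whole-cell mask is the filled, morphologically closed union
of all three channel masks, so the organelle masks are contained in it by
construction.  Pixels where the masks overlap contribute to both
compartment means — the masks are marker-defined and overlap is physical.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from . import preprocess

__all__ = [
    "CompartmentCalcium",
    "compartment_masks",
    "corrected_mean",
    "measure_calcium",
    "manders_coefficients",
]


@dataclass
class CompartmentCalcium:
    """Per-field compartmental calcium record."""

    mean_whole_cell: float
    mean_mito: float
    mean_er: float
    background_used: float
    mask_areas: dict[str, int] = dc_field(default_factory=dict)
    qc_flag: str = ""


def compartment_masks(field_obj, controls=None, config=None):
    """(cell, mito, ER) masks for one field.

    Mito/ER masks threshold their marker channels; the cell mask is the
    union of all channel masks, morphologically closed and hole-filled.
    Returns ``(cell_mask, mito_mask, er_mask, flags)`` where ``flags``
    lists empty compartments.
    """
    from .pipeline import AnalysisConfig

    cfg = config or AnalysisConfig()
    controls = controls if controls is not None else (field_obj.controls or {})
    flags: list[str] = []

    def _mask(channel, name):
        # detection threshold from the control (bounds false positives),
        # refined upward to Otsu when the channel is clearly bimodal: the
        # control percentile sits far below a blurred structure's half-max,
        # so on its own it would swallow the PSF skirt and dilute the
        # compartment mean
        channel = np.asarray(channel, dtype=float)
        if cfg.threshold_method == "negative_control":
            ctrl = controls.get(name)
            thr = preprocess.threshold_value(
                channel, ctrl, "negative_control", cfg.control_percentile
            )
            # refine marker channels only: on the calcium channel Otsu could
            # separate organelle from cytosol rather than cell from
            # background, truncating the whole-cell mask
            if name in ("mito", "er") and np.ptp(channel) > 0:
                thr = max(thr, preprocess.threshold_value(channel, method="otsu"))
            m = channel > thr
        else:
            m = preprocess.threshold_mask(channel, method=cfg.threshold_method)
        m = preprocess.clean_mask(m, cfg.min_object_px)
        if not m.any():
            flags.append(f"empty_{name}_mask")
        return m

    mito_mask = _mask(field_obj.mito_channel, "mito")
    er_mask = _mask(field_obj.er_channel, "er")
    ca_mask = _mask(field_obj.calcium_channel, "calcium")

    union = mito_mask | er_mask | ca_mask
    if union.any():
        closed = ndimage.binary_closing(union, structure=disk(3))
        cell_mask = ndimage.binary_fill_holes(closed) | union
    else:
        cell_mask = union
        flags.append("empty_cell_mask")
    return cell_mask, mito_mask, er_mask, flags


def corrected_mean(calcium_channel, mask, background: float) -> float:
    """Masked mean of the calcium channel minus background, clipped at 0."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: corrected mean undefined")
    val = float(np.mean(np.asarray(calcium_channel, dtype=float)[mask])) - background
    return max(val, 0.0)


def measure_calcium(field_obj, controls=None, config=None) -> CompartmentCalcium:
    """All three compartment means with a shared background estimate.

    Background comes from the calcium channel's negative control (median)
    when available, else from the channel's own low percentile.  Empty
    compartments yield NaN means plus a QC flag rather than an exception.
    """
    controls = controls if controls is not None else (field_obj.controls or {})
    background = preprocess.estimate_background(
        field_obj.calcium_channel, controls.get("calcium")
    )
    cell_mask, mito_mask, er_mask, flags = compartment_masks(
        field_obj, controls, config
    )
    means = {}
    areas = {}
    for name, m in (("cell", cell_mask), ("mito", mito_mask), ("er", er_mask)):
        areas[name] = int(m.sum())
        means[name] = (
            corrected_mean(field_obj.calcium_channel, m, background)
            if m.any()
            else float("nan")
        )
    return CompartmentCalcium(
        mean_whole_cell=means["cell"],
        mean_mito=means["mito"],
        mean_er=means["er"],
        background_used=background,
        mask_areas=areas,
        qc_flag=";".join(flags),
    )


def manders_coefficients(channel_a, channel_b, mask_a, mask_b) -> tuple[float, float]:
    """Optional Manders M1/M2 overlap coefficients (off the default path).

    M1: fraction of channel-A intensity inside B's mask; M2 vice versa.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    ta = a[mask_a].sum()
    tb = b[mask_b].sum()
    m1 = float(a[mask_a & mask_b].sum() / ta) if ta > 0 else float("nan")
    m2 = float(b[mask_a & mask_b].sum() / tb) if tb > 0 else float("nan")
    return m1, m2
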