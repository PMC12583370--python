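"""Raw channel -> background estimate -> binary mask -> 1-px skeleton.

All binary operations use the 8-connected (foreground) convention and the
(row, col), origin-top-left coordinate frame.  Thresholds derive either
from a negative-control image of the same stain (the default: pixels above
the control's 99.5th percentile are signal, bounding the false-positive
rate at 0.5 % under the control distribution) or from Otsu's method.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

from .field import FluorescenceField  # noqa: F401  (re-export, canonical home)

__all__ = [
    "FluorescenceField",
    "estimate_background",
    "threshold_value",
    "threshold_mask",
    "clean_mask",
    "skeletonize",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

DEFAULT_CONTROL_PERCENTILE = 99.5
BACKGROUND_PERCENTILE = 5.0


def estimate_background(
    channel: np.ndarray, negative_control: np.ndarray | None = None
) -> float:
    """Scalar background intensity for one channel of one field.

    With a negative-control image, the background is its median; without
    one, the 5th percentile of the channel itself (a robust floor under
    sparse signal).
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("channel is empty")
    if negative_control is not None:
        return float(np.median(np.asarray(negative_control, dtype=float)))
    return float(np.percentile(channel, BACKGROUND_PERCENTILE))


def threshold_value(
    channel: np.ndarray,
    negative_control: np.ndarray | None = None,
    method: str = "negative_control",
    control_percentile: float = DEFAULT_CONTROL_PERCENTILE,
) -> float:
    """Scalar threshold for one channel under the chosen policy.

    ``method="negative_control"`` reads the control's ``control_percentile``
    (default 99.5); ``method="otsu"`` maximizes between-class variance on
    the channel itself.  A constant channel under Otsu gets an infinite
    threshold (nothing is foreground).
    """
    channel = np.asarray(channel, dtype=float)
    if method == "negative_control":
        if negative_control is None:
            raise ValueError(
                "threshold method 'negative_control' requires a control image"
            )
        return float(
            np.percentile(np.asarray(negative_control, dtype=float), control_percentile)
        )
    if method == "otsu":
        if np.ptp(channel) == 0:
            return float("inf")
        return float(threshold_otsu(channel))
    raise ValueError(f"unknown threshold method: {method!r}")


def threshold_mask(
    channel: np.ndarray,
    negative_control: np.ndarray | None = None,
    method: str = "negative_control",
    control_percentile: float = DEFAULT_CONTROL_PERCENTILE,
) -> np.ndarray:
    """Binary foreground mask; pixels strictly above the threshold are true."""
    channel = np.asarray(channel, dtype=float)
    thr = threshold_value(channel, negative_control, method, control_percentile)
    if np.isinf(thr):
        return np.zeros(channel.shape, dtype=bool)
    return channel > thr


def clean_mask(mask: np.ndarray, min_object_px: int = 1) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_object_px`` pixels."""
    if min_object_px < 1:
        raise ValueError("min_object_px must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if min_object_px == 1 or not mask.any():
        return mask.copy()
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes >= min_object_px
    return keep[lab]


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask or skeleton as an 8-bit TIFF (0/255)."""
    import tifffile

    tifffile.imwrite(
        path, (np.asarray(mask, dtype=bool) * np.uint8(255)),
        photometric="minisblack",
    )


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a 1-px-wide skeleton.

    Component count is preserved and the operation is idempotent on
    already-thin input.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=bool)
    return _sk_skeletonize(mask)
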