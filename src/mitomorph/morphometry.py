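"""Skeleton graph extraction and mitochondrial morphology metrics.

A thinned (1-pixel-wide) binary skeleton of the mitochondrial network is
decomposed into a typed graph:

* **junction** pixels have three or more 8-connected skeleton neighbours;
  8-adjacent junction pixels are merged into a single junction node, so a
  small cluster of high-degree pixels produced by thinning counts once;
* **endpoint** pixels have at most one neighbour;
* **branches** are the maximal runs of non-junction pixels, each terminating
  at junction nodes and/or endpoints (a closed loop is a single branch whose
  two ends coincide);
* a **solitary rod** is a connected component of the skeleton that contains
  no junction node — a fragmented, unbranched mitochondrion.  An isolated
  single pixel is a 1-px rod.

From the graph three per-cell morphology statistics are computed:

* ``fragmentation``   = rods / branches  (each rod is itself one branch, so
  the ratio lies in [0, 1]),
* ``branching``       = junction nodes / branches,
* ``mean_branch_length`` = mean over branches of pixel count x pixel size,
  where a branch's pixel count includes the junction pixel at each attached
  end (a shared terminal is counted once per branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SkeletonGraph",
    "MorphologyMetrics",
    "build_graph",
    "fragmentation",
    "branching",
    "mean_branch_length",
    "prune_spurs",
    "measure_field",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested for a graph with zero branches."""


def neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    """Number of 8-connected skeleton neighbours at each skeleton pixel."""
    skel = np.asarray(skeleton, dtype=bool)
    counts = ndimage.convolve(
        skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant", cval=0
    )
    counts[~skel] = 0
    return counts


@dataclass
class SkeletonGraph:
    """Typed topology of a 1-px-wide skeleton.

    Attributes
    ----------
    branch_pixel_counts
        Per-branch pixel counts, junction terminals included (one per
        attached junction node).
    branch_slices
        Per-branch arrays of (row, col) pixel coordinates of the branch
        interior (junction terminal pixels excluded; endpoints included).
    branch_count, junction_count, rod_count, endpoint_count
        The counts B, J, R and the number of endpoint pixels.
    component_count
        Number of 8-connected components of the full skeleton.
    """

    branch_pixel_counts: list[int] = field(default_factory=list)
    branch_slices: list[np.ndarray] = field(default_factory=list)
    branch_count: int = 0
    junction_count: int = 0
    rod_count: int = 0
    endpoint_count: int = 0
    component_count: int = 0

    @property
    def is_empty(self) -> bool:
        return self.branch_count == 0


def build_graph(skeleton: np.ndarray) -> SkeletonGraph:
    """Decompose a 1-px-wide skeleton into branches, junctions and rods.

    Pixels are classified by 8-neighbour count (<=1 endpoint, 2 path
    interior, >=3 junction).  Adjacent junction pixels merge into one
    junction node.  Branches are the 8-connected components of the
    non-junction pixels; each attaches to at most two junction nodes.  A
    component of the skeleton containing no junction pixel is a solitary
    rod (and exactly one branch).
    """
    skel = np.asarray(skeleton, dtype=bool)
    if skel.ndim != 2:
        raise ValueError("skeleton must be a 2-D boolean array")
    if not skel.any():
        return SkeletonGraph()

    counts = neighbor_counts(skel)
    junction_px = skel & (counts >= 3)
    endpoint_count = int(np.count_nonzero(skel & (counts <= 1)))

    jlab, n_jclusters = ndimage.label(junction_px, structure=_STRUCT8)
    seg_mask = skel & ~junction_px
    slab, n_seg = ndimage.label(seg_mask, structure=_STRUCT8)
    clab, n_comp = ndimage.label(skel, structure=_STRUCT8)

    # rods: skeleton components without any junction pixel
    has_junction = np.zeros(n_comp + 1, dtype=bool)
    if n_jclusters:
        has_junction[np.unique(clab[junction_px])] = True
    rod_count = int(n_comp - np.count_nonzero(has_junction[1:]))

    # attachment of branch segments to junction clusters: inspect the
    # 8-neighbourhood of every junction pixel (few of them) in slab
    attached: dict[int, set[int]] = {s: set() for s in range(1, n_seg + 1)}
    if n_jclusters:
        jr, jc = np.nonzero(junction_px)
        h, w = skel.shape
        for r, c, jid in zip(jr, jc, jlab[jr, jc]):
            r0, r1 = max(r - 1, 0), min(r + 2, h)
            c0, c1 = max(c - 1, 0), min(c + 2, w)
            for s in np.unique(slab[r0:r1, c0:c1]):
                if s:
                    attached[int(s)].add(int(jid))

    seg_sizes = ndimage.sum_labels(
        seg_mask, slab, index=np.arange(1, n_seg + 1)
    ).astype(int)

    branch_pixel_counts: list[int] = []
    branch_slices: list[np.ndarray] = []
    objects = ndimage.find_objects(slab)
    for s in range(1, n_seg + 1):
        n_terminals = len(attached[s])  # 0, 1 or 2 junction-node ends
        branch_pixel_counts.append(int(seg_sizes[s - 1]) + n_terminals)
        sl = objects[s - 1]
        rr, cc = np.nonzero(slab[sl] == s)
        branch_slices.append(
            np.column_stack([rr + sl[0].start, cc + sl[1].start])
        )

    return SkeletonGraph(
        branch_pixel_counts=branch_pixel_counts,
        branch_slices=branch_slices,
        branch_count=n_seg,
        junction_count=int(n_jclusters),
        rod_count=rod_count,
        endpoint_count=endpoint_count,
        component_count=int(n_comp),
    )


def fragmentation(graph: SkeletonGraph) -> float:
    """Solitary rods over total branches, in [0, 1]."""
    if graph.branch_count == 0:
        raise UndefinedMetricError("fragmentation undefined: no branches")
    return graph.rod_count / graph.branch_count


def branching(graph: SkeletonGraph) -> float:
    """Junction nodes over total branches."""
    if graph.branch_count == 0:
        raise UndefinedMetricError("branching undefined: no branches")
    return graph.junction_count / graph.branch_count


def mean_branch_length(graph: SkeletonGraph, pixel_size: float = 1.0) -> float:
    """Mean branch length (pixel count x pixel size).

    ``pixel_size`` is the pixel edge in micrometres; pass 1 for lengths in
    pixels.
    """
    if graph.branch_count == 0:
        raise UndefinedMetricError("mean branch length undefined: no branches")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return float(np.mean(graph.branch_pixel_counts)) * pixel_size


def prune_spurs(skeleton: np.ndarray, max_px: int) -> np.ndarray:
    """Remove endpoint-bearing branches shorter than ``max_px`` pixels.

    Thinning a rendered tube occasionally leaves a 1-2 px spur at a
    junction; these inflate the branch count.  A spur is a branch segment
    attached to at least one junction node, carrying an endpoint, with
    fewer than ``max_px`` interior pixels.  Solitary rods are never pruned.
    Applied once (not iterated), so genuine short branches at most lose one
    round of spurs.
    """
    skel = np.asarray(skeleton, dtype=bool).copy()
    if max_px <= 0 or not skel.any():
        return skel
    counts = neighbor_counts(skel)
    junction_px = skel & (counts >= 3)
    if not junction_px.any():
        return skel
    seg_mask = skel & ~junction_px
    slab, n_seg = ndimage.label(seg_mask, structure=_STRUCT8)
    endpoint_px = skel & (counts <= 1)
    # segments that touch a junction: dilate junction pixels by one
    near_junction = ndimage.binary_dilation(junction_px, structure=_STRUCT8)
    touching = np.unique(slab[near_junction & seg_mask])
    sizes = ndimage.sum_labels(seg_mask, slab, index=np.arange(1, n_seg + 1))
    with_endpoint = np.unique(slab[endpoint_px])
    removed = False
    for s in touching:
        if s and s in with_endpoint and sizes[s - 1] < max_px:
            skel[slab == s] = False
            removed = True
    if removed:
        # re-thin: a pruned junction can leave a 2-px-wide bump behind
        from .preprocess import skeletonize

        skel = skeletonize(skel)
    return skel


@dataclass
class MorphologyMetrics:
    """Per-field morphology record with QC flag."""

    branch_count: int
    junction_count: int
    rod_count: int
    fragmentation: float
    branching: float
    mean_branch_length_um: float
    qc_flag: str = ""

    @classmethod
    def undefined(cls, reason: str) -> "MorphologyMetrics":
        return cls(0, 0, 0, float("nan"), float("nan"), float("nan"), reason)

    @property
    def is_defined(self) -> bool:
        return self.branch_count > 0


def measure_field(field_obj, config=None) -> MorphologyMetrics:
    """Full morphology pipeline for one imaged field.

    Thresholds the mitochondrial channel, cleans speckle, thins to a
    skeleton, prunes short spurs, builds the graph and evaluates the three
    metrics.  A blank or threshold-failing field yields a flagged record
    rather than an exception.
    """
    from . import preprocess
    from .pipeline import AnalysisConfig

    cfg = config or AnalysisConfig()
    mito = field_obj.mito_channel
    control = (field_obj.controls or {}).get("mito") if cfg.threshold_method == "negative_control" else None
    try:
        mask = preprocess.threshold_mask(
            mito, control, method=cfg.threshold_method,
            control_percentile=cfg.control_percentile,
        )
    except ValueError as exc:
        return MorphologyMetrics.undefined(f"threshold_failed:{exc}")
    mask = preprocess.clean_mask(mask, cfg.min_object_px)
    if not mask.any():
        return MorphologyMetrics.undefined("empty_mask")
    skel = preprocess.skeletonize(mask)
    skel = prune_spurs(skel, cfg.prune_spur_px)
    graph = build_graph(skel)
    if graph.is_empty:
        return MorphologyMetrics.undefined("empty_skeleton")
    return MorphologyMetrics(
        branch_count=graph.branch_count,
        junction_count=graph.junction_count,
        rod_count=graph.rod_count,
        fragmentation=fragmentation(graph),
        branching=branching(graph),
        mean_branch_length_um=mean_branch_length(graph, field_obj.pixel_size),
    )
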