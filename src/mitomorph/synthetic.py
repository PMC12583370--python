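"""Synthetic ground-truth networks, rendered fields, and factorial datasets.

The generator emulates what the analysis assumes about the data, with known
truth at every level:

* **Network geometry.**  A mitochondrial network is a set of skeleton
  components drawn on the pixel grid: solitary rods (straight 8-connected
  digital lines) and branched tree components.  A tree component is a
  diagonal backbone carrying degree-3/4 junctions, each sprouting one or two
  perpendicular-diagonal teeth.  The direction sets are chosen so that no
  two arms of a junction have 8-adjacent first pixels: every junction is a
  single pixel with exactly its arms as neighbours, and the graph builder's
  neighbour rule recovers the requested (branch, junction, rod) counts
  exactly.  A component with j junctions and e extra (second) teeth has
  2j + 1 + e branches.
* **Rendering.**  The mitochondrial channel is the skeleton dilated to a
  tube, blurred by a Gaussian PSF, plus a constant background and additive
  Gaussian noise.  The calcium channel is piecewise constant over the true
  compartment masks (cytosol level solved so the whole-cell mask mean equals
  the requested level exactly), plus noise.  The ER channel renders a blob
  texture.  Negative-control images (background + noise only) accompany
  each field.
* **Experiment design.**  A balanced 2 (rotenone) x k (KATP treatment)
  factorial: per-condition means, replicate-level latent means drawn around
  them (between-replicate sd), and per-field values drawn around the
  replicate mean (within-replicate sd).  Default effect directions mirror
  the biology being modelled: rotenone raises fragmentation and lowers
  branching and calcium in all compartments; KATP modulators lengthen
  branches; agonists lower and antagonists raise organelle calcium.

Identical seeds reproduce identical outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import convex_hull_image, disk


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=disk(radius))

from .field import FluorescenceField

__all__ = [
    "GroundTruthNetwork",
    "RenderSpec",
    "ERTextureSpec",
    "CalciumLevels",
    "EffectSpec",
    "ExperimentData",
    "InfeasiblePackingError",
    "generate_network",
    "render_field",
    "generate_experiment",
    "sample_latent_table",
]

# Unit steps whose pairwise Chebyshev distance is >= 2: arms of a junction
# drawn along these directions never have mutually adjacent first pixels,
# so no spurious junction clusters arise.
_NE = (-1, 1)   # backbone "up"
_SW = (1, -1)   # backbone "down"
_NW = (-1, -1)  # tooth side A
_SE = (1, 1)    # tooth side B

_ROD_DIRS = [(-1, 0), (1, 0), (0, -1), (0, 1), _NE, _SW, _NW, _SE]


class InfeasiblePackingError(RuntimeError):
    """Requested topology cannot be placed in the given image shape."""


@dataclass
class GroundTruthNetwork:
    """A generated skeleton with its exact topology.

    ``skeleton`` is the boolean image; the ``true_*`` fields are the counts
    and per-branch pixel lengths (junction terminal pixels included, one per
    attached junction) the graph builder must recover.
    """

    skeleton: np.ndarray
    true_branch_count: int
    true_junction_count: int
    true_rod_count: int
    true_branch_lengths: list[int]

    @property
    def skeleton_pixels(self) -> set[tuple[int, int]]:
        return set(zip(*map(list, np.nonzero(self.skeleton))))

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.skeleton.shape

    @property
    def true_fragmentation(self) -> float:
        return self.true_rod_count / self.true_branch_count

    @property
    def true_branching(self) -> float:
        return self.true_junction_count / self.true_branch_count

    @property
    def true_mean_branch_length(self) -> float:
        return float(np.mean(self.true_branch_lengths))


def _allocate_components(
    n_tree_branches: int, n_junctions: int
) -> list[tuple[int, int]]:
    """Split (branches, junctions) into per-component (j, extra_teeth).

    Each tree component with j junctions and e extra teeth (0 <= e <= j)
    carries 2j + 1 + e branches.  Returns a list of (j, e) per component or
    raises if no split exists.
    """
    bp, j_total = n_tree_branches, n_junctions
    if j_total == 0:
        if bp != 0:
            raise InfeasiblePackingError(
                "branched components require at least one junction"
            )
        return []
    feasible_c = [
        c
        for c in range(1, j_total + 1)
        if 0 <= bp - 2 * j_total - c <= j_total
    ]
    if not feasible_c:
        raise InfeasiblePackingError(
            f"no component split for {bp} tree branches with {j_total} "
            f"junctions (need 2J+1 <= branches <= 4J)"
        )
    # prefer more, smaller components: easier to pack, smaller bboxes
    n_comp = feasible_c[-1]
    extra_total = bp - 2 * j_total - n_comp
    js = [j_total // n_comp + (1 if i < j_total % n_comp else 0) for i in range(n_comp)]
    extras = [0] * n_comp
    i = 0
    remaining = extra_total
    while remaining > 0:
        room = js[i] - extras[i]
        take = min(room, remaining)
        extras[i] += take
        remaining -= take
        i += 1
    return list(zip(js, extras))


def _line_pixels(start: tuple[int, int], step: tuple[int, int], n_steps: int):
    """Pixels of a straight digital line: start plus n_steps unit steps."""
    r, c = start
    dr, dc = step
    return [(r + k * dr, c + k * dc) for k in range(n_steps + 1)]


def _build_tree_component(
    j: int, extra: int, lengths: list[int]
) -> tuple[list[list[tuple[int, int]]], list[int]]:
    """Pixel paths of one tree component in local coordinates.

    ``lengths`` supplies 2j + 1 + extra branch pixel lengths (terminals
    included).  Backbone runs along NE; junction k sprouts a NW or SE tooth
    (alternating), plus the opposite tooth when it has an extra arm.
    Returns (branch pixel lists, branch lengths) in construction order.
    """
    n_branches = 2 * j + 1 + extra
    assert len(lengths) == n_branches
    seg_lengths = lengths[: j + 1]          # backbone segments
    tooth_lengths = lengths[j + 1:]         # j + extra teeth
    extra_flags = [1] * extra + [0] * (j - extra)

    branches: list[list[tuple[int, int]]] = []
    out_lengths: list[int] = []
    # backbone: endpoints and junction pixels along NE
    pos = (0, 0)
    junction_pts: list[tuple[int, int]] = []
    for k in range(j + 1):
        steps = seg_lengths[k] - 1
        px = _line_pixels(pos, _NE, steps)
        branches.append(px)
        out_lengths.append(len(px))
        pos = px[-1]
        if k < j:
            junction_pts.append(pos)
    ti = 0
    for k, jp in enumerate(junction_pts):
        first_dir = _NW if k % 2 == 0 else _SE
        dirs = [first_dir]
        if extra_flags[k]:
            dirs.append(_SE if first_dir is _NW else _NW)
        for d in dirs:
            steps = tooth_lengths[ti] - 1
            ti += 1
            px = _line_pixels(jp, d, steps)
            branches.append(px)
            out_lengths.append(len(px))
    return branches, out_lengths


def _normalize_piece(branches: list[list[tuple[int, int]]]):
    """Shift a piece's branch paths to non-negative local coordinates."""
    all_px = np.array([p for br in branches for p in br])
    rmin, cmin = all_px.min(axis=0)
    shifted = [
        [(r - rmin, c - cmin) for (r, c) in br] for br in branches
    ]
    h = int(all_px[:, 0].max() - rmin) + 1
    w = int(all_px[:, 1].max() - cmin) + 1
    return shifted, (h, w)


def generate_network(
    n_branches: int,
    n_junctions: int,
    n_rods: int,
    length_range: tuple[int, int] = (8, 16),
    image_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    min_spacing: int = 6,
    max_tries: int = 500,
) -> GroundTruthNetwork:
    """Generate a skeleton with exactly the requested topology.

    Parameters
    ----------
    n_branches, n_junctions, n_rods
        Requested totals; ``n_rods <= n_branches`` and the tree part must
        satisfy ``2J + 1 <= n_branches - n_rods <= 4J`` (or equal 0 when
        ``n_junctions == 0``).
    length_range
        Inclusive bounds on per-branch pixel length (terminals included).
    min_spacing
        Minimum Chebyshev gap enforced between component bounding boxes so
        that rendering (tube dilation + PSF) never merges components.

    Raises
    ------
    InfeasiblePackingError
        If the counts are incompatible or random placement fails after
        ``max_tries`` attempts per component.
    """
    if n_rods > n_branches:
        raise InfeasiblePackingError("n_rods cannot exceed n_branches")
    if min(n_branches, n_junctions, n_rods) < 0:
        raise ValueError("counts must be non-negative")
    lo, hi = length_range
    if lo < 2 and (n_branches - n_rods) > 0:
        raise ValueError("tree branch lengths must be >= 2 px")
    rng = np.random.default_rng(seed)

    comps = _allocate_components(n_branches - n_rods, n_junctions)

    # build pieces in local coordinates
    pieces: list[tuple[list[list[tuple[int, int]]], list[int], tuple[int, int]]] = []
    for j, extra in comps:
        nb = 2 * j + 1 + extra
        lengths = rng.integers(lo, hi + 1, size=nb).tolist()
        branches, blens = _build_tree_component(j, extra, lengths)
        branches, bbox = _normalize_piece(branches)
        pieces.append((branches, blens, bbox))
    for _ in range(n_rods):
        ln = int(rng.integers(lo, hi + 1))
        d = _ROD_DIRS[int(rng.integers(len(_ROD_DIRS)))]
        px = _line_pixels((0, 0), d, ln - 1)
        branches, bbox = _normalize_piece([px])
        pieces.append((branches, [ln], bbox))

    # place larger pieces first; bbox-level exclusion with min_spacing margin
    order = sorted(range(len(pieces)), key=lambda i: -(pieces[i][2][0] * pieces[i][2][1]))
    H, W = image_shape
    placed: list[tuple[int, int, int, int]] = []  # r0, c0, r1, c1 (exclusive)
    offsets: dict[int, tuple[int, int]] = {}
    m = int(min_spacing)
    for idx in order:
        h, w = pieces[idx][2]
        if h > H or w > W:
            raise InfeasiblePackingError(
                f"component of size {h}x{w} exceeds image {H}x{W}"
            )
        for _ in range(max_tries):
            r0 = int(rng.integers(0, H - h + 1))
            c0 = int(rng.integers(0, W - w + 1))
            r1, c1 = r0 + h, c0 + w
            ok = all(
                not (r0 < pr1 + m and pr0 - m < r1 and c0 < pc1 + m and pc0 - m < c1)
                for (pr0, pc0, pr1, pc1) in placed
            )
            if ok:
                placed.append((r0, c0, r1, c1))
                offsets[idx] = (r0, c0)
                break
        else:
            raise InfeasiblePackingError(
                f"could not place component {h}x{w} after {max_tries} tries; "
                f"image too small for requested topology"
            )

    skeleton = np.zeros(image_shape, dtype=bool)
    all_lengths: list[int] = []
    for idx, (branches, blens, _) in enumerate(pieces):
        r0, c0 = offsets[idx]
        for br in branches:
            for (r, c) in br:
                skeleton[r + r0, c + c0] = True
        all_lengths.extend(blens)

    return GroundTruthNetwork(
        skeleton=skeleton,
        true_branch_count=n_branches,
        true_junction_count=n_junctions,
        true_rod_count=n_rods,
        true_branch_lengths=all_lengths,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderSpec:
    """How a ground-truth network becomes a multi-channel image.

    ``psf_sigma`` (px) blurs the marker channels; ``tube_radius`` (px)
    thickens the skeleton into a tube; ``background_level`` and ``noise_sd``
    are intensity AU; ``pixel_size`` is um/px.  The calcium channel is not
    PSF-blurred by default (``calcium_psf_sigma = 0``) so compartment means
    stay exactly at their requested levels; Poisson shot noise is available
    but off by default, keeping variance accounting purely Gaussian.
    """

    psf_sigma: float = 0.8
    tube_radius: int = 1
    background_level: float = 10.0
    noise_sd: float = 5.0
    pixel_size: float = 0.1
    seed: int = 0
    mito_amplitude: float = 150.0
    er_amplitude: float = 120.0
    calcium_psf_sigma: float = 0.0
    poisson_noise: bool = False
    cell_margin_px: int = 5

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.tube_radius < 1:
            raise ValueError("tube_radius must be >= 1")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass(frozen=True)
class ERTextureSpec:
    """Blob texture for the ER channel: smoothed-noise threshold blobs
    covering ``coverage`` of the cell area, disjoint from the mitochondrial
    tube by default."""

    smooth_sigma: float = 4.0
    coverage: float = 0.10
    exclude_mito: bool = True


@dataclass(frozen=True)
class CalciumLevels:
    """True mean raw calcium intensity per compartment (AU, background
    included: the corrected mean is level minus background)."""

    whole_cell: float = 40.0
    mito: float = 100.0
    er: float = 60.0


def _add_noise(img: np.ndarray, spec: RenderSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def render_field(
    network: GroundTruthNetwork,
    er_spec: ERTextureSpec | None = None,
    calcium_levels: CalciumLevels | None = None,
    render_spec: RenderSpec | None = None,
    labels: dict[str, str] | None = None,
) -> FluorescenceField:
    """Render a three-channel field (calcium / mito / ER) from a network.

    The returned field records the generating truth (compartment masks,
    calcium levels, background, topology counts) under ``field.truth`` and
    carries per-channel negative-control images under ``field.controls``.
    """
    er_spec = er_spec or ERTextureSpec()
    levels = calcium_levels or CalciumLevels()
    spec = render_spec or RenderSpec()
    rng = np.random.default_rng(spec.seed)
    shape = network.image_shape
    bg = spec.background_level

    for name, lv in dataclasses.asdict(levels).items():
        if lv < bg:
            raise ValueError(f"calcium level {name}={lv} below background {bg}")

    skel = network.skeleton
    mito_mask = _dilate(skel, spec.tube_radius) if skel.any() else skel.copy()
    if mito_mask.any():
        cell_mask = _dilate(convex_hull_image(mito_mask), spec.cell_margin_px)
    else:
        cell_mask = np.zeros(shape, dtype=bool)

    # ER blobs inside the cell, by default clear of the mitochondrial tube
    texture = ndimage.gaussian_filter(
        rng.standard_normal(shape), er_spec.smooth_sigma
    )
    er_region = cell_mask.copy()
    if er_spec.exclude_mito:
        er_region &= ~_dilate(mito_mask, 1)
    er_mask = np.zeros(shape, dtype=bool)
    if er_region.any() and er_spec.coverage > 0:
        thr = np.quantile(texture[er_region], 1.0 - er_spec.coverage)
        er_mask = er_region & (texture > thr)

    mito_img = spec.mito_amplitude * ndimage.gaussian_filter(
        mito_mask.astype(float), spec.psf_sigma
    ) + bg
    er_img = spec.er_amplitude * ndimage.gaussian_filter(
        er_mask.astype(float), spec.psf_sigma
    ) + bg

    # calcium: piecewise constant; cytosol level solved so that the mean
    # over the whole-cell mask equals the requested whole-cell level
    ca_img = np.full(shape, bg, dtype=float)
    a_cell = int(cell_mask.sum())
    a_mito = int((mito_mask & cell_mask).sum())
    a_er = int((er_mask & cell_mask).sum())
    cyto_mask = cell_mask & ~mito_mask & ~er_mask
    a_cyto = int(cyto_mask.sum())
    if a_cell:
        if a_cyto == 0:
            raise ValueError("cell mask has no cytosol pixels")
        v_cyto = (
            levels.whole_cell * a_cell - levels.mito * a_mito - levels.er * a_er
        ) / a_cyto
        if v_cyto < 0:
            raise ValueError(
                "whole-cell calcium level infeasible: implied cytosol "
                f"intensity {v_cyto:.2f} < 0"
            )
        ca_img[cyto_mask] = v_cyto
        ca_img[mito_mask & cell_mask] = levels.mito
        ca_img[er_mask] = levels.er
    if spec.calcium_psf_sigma > 0:
        ca_img = ndimage.gaussian_filter(ca_img, spec.calcium_psf_sigma)

    ca_img = _add_noise(ca_img, spec, rng)
    mito_img = _add_noise(mito_img, spec, rng)
    er_img = _add_noise(er_img, spec, rng)

    controls = {
        name: _add_noise(np.full(shape, bg, dtype=float), spec, rng)
        for name in ("calcium", "mito", "er")
    }

    truth = {
        "mito_mask": mito_mask,
        "er_mask": er_mask,
        "cell_mask": cell_mask,
        "calcium_levels": dataclasses.asdict(levels),
        "background": bg,
        "branch_count": network.true_branch_count,
        "junction_count": network.true_junction_count,
        "rod_count": network.true_rod_count,
        "branch_lengths": list(network.true_branch_lengths),
    }
    labels = labels or {}
    return FluorescenceField(
        calcium_channel=ca_img,
        mito_channel=mito_img,
        er_channel=er_img,
        pixel_size=spec.pixel_size,
        katp_level=labels.get("katp_level", "ctrl"),
        rotenone=labels.get("rotenone", "veh"),
        replicate_id=labels.get("replicate", "r1"),
        field_id=labels.get("field_id", "f1"),
        controls=controls,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# factorial experiment
# ---------------------------------------------------------------------------

MORPHOLOGY_VARS = ["fragmentation", "branching", "mean_branch_length_um"]
CALCIUM_VARS = ["ca_whole_cell", "ca_mito", "ca_er"]
VIABILITY_VARS = ["mtt_percent", "cell_count"]
ALL_VARS = MORPHOLOGY_VARS + CALCIUM_VARS + VIABILITY_VARS

_DEFAULT_BASELINES = {
    "fragmentation": 0.30,
    "branching": 0.25,
    "mean_branch_length_um": 1.2,
    "ca_whole_cell": 40.0,
    "ca_mito": 100.0,
    "ca_er": 60.0,
    "mtt_percent": 100.0,
    "cell_count": 120.0,
}
_DEFAULT_BETWEEN_SD = {
    "fragmentation": 0.04,
    "branching": 0.03,
    "mean_branch_length_um": 0.10,
    "ca_whole_cell": 3.0,
    "ca_mito": 6.0,
    "ca_er": 4.0,
    "mtt_percent": 8.0,
    "cell_count": 10.0,
}
_DEFAULT_WITHIN_SD = {
    "fragmentation": 0.05,
    "branching": 0.04,
    "mean_branch_length_um": 0.15,
    "ca_whole_cell": 4.0,
    "ca_mito": 8.0,
    "ca_er": 6.0,
    "mtt_percent": 6.0,
    "cell_count": 12.0,
}


def _default_shifts() -> dict[str, dict[str, float]]:
    """Per-level additive mean shifts, two between-replicate sd in
    magnitude, mirroring the modelled effect directions."""
    b = _DEFAULT_BETWEEN_SD
    return {
        "rot": {
            "fragmentation": +2 * b["fragmentation"],
            "branching": -2 * b["branching"],
            "ca_whole_cell": -2 * b["ca_whole_cell"],
            "ca_mito": -2 * b["ca_mito"],
            "ca_er": -2 * b["ca_er"],
            "mtt_percent": -2 * b["mtt_percent"],
            "cell_count": -2 * b["cell_count"],
        },
        "agonist": {
            "mean_branch_length_um": +2 * b["mean_branch_length_um"],
            "ca_mito": -2 * b["ca_mito"],
            "ca_er": -2 * b["ca_er"],
            "cell_count": +2 * b["cell_count"],
        },
        "antagonist": {
            "mean_branch_length_um": +2 * b["mean_branch_length_um"],
            "ca_mito": +2 * b["ca_mito"],
            "ca_er": +2 * b["ca_er"],
            "cell_count": +2 * b["cell_count"],
        },
    }


@dataclass
class EffectSpec:
    """Design and effect structure of a simulated factorial experiment.

    Factor A is the KATP treatment (default ctrl / agonist / antagonist),
    factor B the rotenone condition (veh / rot).  ``shifts`` maps a factor
    level to additive mean shifts per measured variable; a missing entry
    means no shift.  Replicate latent means are drawn around the condition
    mean with ``between_sd``; field values around the replicate mean with
    ``within_sd``.
    """

    factor_a_levels: tuple[str, ...] = ("ctrl", "agonist", "antagonist")
    factor_b_levels: tuple[str, ...] = ("veh", "rot")
    baselines: dict[str, float] = dc_field(default_factory=lambda: dict(_DEFAULT_BASELINES))
    shifts: dict[str, dict[str, float]] = dc_field(default_factory=_default_shifts)
    between_sd: dict[str, float] = dc_field(default_factory=lambda: dict(_DEFAULT_BETWEEN_SD))
    within_sd: dict[str, float] = dc_field(default_factory=lambda: dict(_DEFAULT_WITHIN_SD))
    n_replicates: int = 5
    fields_per_replicate: int = 5
    seed: int = 0
    # rendering knobs (used when the dataset is rendered to images)
    network_branches: int = 16
    image_shape: tuple[int, int] = (192, 192)
    render: RenderSpec = dc_field(default_factory=RenderSpec)

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.fields_per_replicate < 1:
            raise ValueError("fields_per_replicate must be >= 1")
        for d in (self.between_sd, self.within_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be >= 0")

    @classmethod
    def null(cls, **kw) -> "EffectSpec":
        """All effects zero: for type-I-error calibration."""
        return cls(shifts={}, **kw)

    def condition_mean(self, var: str, a_level: str, b_level: str) -> float:
        mu = self.baselines[var]
        mu += self.shifts.get(a_level, {}).get(var, 0.0)
        mu += self.shifts.get(b_level, {}).get(var, 0.0)
        return mu


def sample_latent_table(spec: EffectSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-field latent values for every measured variable (tidy layout).

    One row per (katp_level, rotenone, replicate, field); the hierarchical
    draw is condition mean -> replicate mean -> field value.  Ratio-type
    variables are clipped into their natural range.
    """
    rows = []
    for a in spec.factor_a_levels:
        for b in spec.factor_b_levels:
            for r in range(1, spec.n_replicates + 1):
                rep_means = {
                    v: rng.normal(
                        spec.condition_mean(v, a, b), spec.between_sd[v]
                    )
                    for v in ALL_VARS
                }
                for f in range(1, spec.fields_per_replicate + 1):
                    row = {
                        "katp_level": a,
                        "rotenone": b,
                        "replicate": f"{a}_{b}_r{r}",
                        "field_id": f"{a}_{b}_r{r}_f{f}",
                    }
                    for v in ALL_VARS:
                        row[v] = rng.normal(rep_means[v], spec.within_sd[v])
                    row["fragmentation"] = float(np.clip(row["fragmentation"], 0.0, 1.0))
                    row["branching"] = float(np.clip(row["branching"], 0.0, None))
                    row["mean_branch_length_um"] = float(
                        np.clip(row["mean_branch_length_um"], 0.3, None)
                    )
                    for v in CALCIUM_VARS + VIABILITY_VARS:
                        row[v] = float(np.clip(row[v], 0.0, None))
                    rows.append(row)
    return pd.DataFrame(rows)


def _topology_for_targets(
    frag: float, branch: float, n_branches: int
) -> tuple[int, int, int]:
    """Integer (B, J, R) realizing target fragmentation/branching ratios.

    Quantization to feasible integers adds a small extra layer of
    within-field noise; the tree part needs at least three branches, so a
    remainder of one or two non-rod branches is folded into the rods.
    """
    B = n_branches
    R = int(np.clip(round(frag * B), 0, B))
    bp = B - R
    if 0 < bp < 3:
        R = B - 3 if B >= 3 else B
        bp = B - R
    if bp == 0:
        return B, 0, R
    j_lo = int(np.ceil(bp / 4))
    j_hi = (bp - 1) // 2
    J = int(np.clip(round(branch * B), j_lo, j_hi))
    return B, J, R


def _render_row(
    row: pd.Series, spec: EffectSpec, seed: int
) -> FluorescenceField:
    """Render one field whose ground truth realizes the row's latent
    morphology and calcium targets."""
    px = spec.render.pixel_size
    target_len = row["mean_branch_length_um"] / px
    lo = max(6, int(round(target_len)) - 3)
    hi = max(lo + 1, int(round(target_len)) + 3)
    B, J, R = _topology_for_targets(
        row["fragmentation"], row["branching"], spec.network_branches
    )
    net = generate_network(
        B, J, R,
        length_range=(lo, hi),
        image_shape=spec.image_shape,
        seed=seed,
    )
    bg = spec.render.background_level
    floor = bg + 2.0
    levels = CalciumLevels(
        whole_cell=max(row["ca_whole_cell"], floor),
        mito=max(row["ca_mito"], floor),
        er=max(row["ca_er"], floor),
    )
    rspec = dataclasses.replace(spec.render, seed=seed + 1)
    return render_field(
        net,
        calcium_levels=levels,
        render_spec=rspec,
        labels={
            "katp_level": row["katp_level"],
            "rotenone": row["rotenone"],
            "replicate": row["replicate"],
            "field_id": row["field_id"],
        },
    )


@dataclass
class ExperimentData:
    """One simulated factorial experiment.

    ``field_table`` holds the latent per-field values (the generating
    truth); ``fields`` the rendered images (``None`` when tabular-only);
    ``mtt_wells`` well-level absorbances and ``cell_counts`` image-level
    counts for the viability layer; ``truth_means`` the condition-mean
    table the effects were drawn from.
    """

    spec: EffectSpec
    field_table: pd.DataFrame
    fields: list[FluorescenceField] | None
    mtt_wells: pd.DataFrame
    cell_counts: pd.DataFrame
    truth_means: pd.DataFrame


_MTT_CONTROL_ABSORBANCE = 0.6  # raw A570 of the untreated control mean


def generate_experiment(spec: EffectSpec, render: bool = False) -> ExperimentData:
    """Simulate one balanced factorial experiment.

    With ``render=False`` only the latent tables are produced (fast path
    for statistical calibration); with ``render=True`` every field is also
    rendered to a three-channel image whose ground truth realizes that
    field's latent morphology and calcium values.
    """
    rng = np.random.default_rng(spec.seed)
    table = sample_latent_table(spec, rng)

    # viability tables: replicate-level latent -> well / image observations
    mtt_rows, count_rows = [], []
    rep_table = (
        table.groupby(["katp_level", "rotenone", "replicate"], sort=False)[ALL_VARS]
        .mean()
        .reset_index()
    )
    a0 = _MTT_CONTROL_ABSORBANCE
    for _, rr in rep_table.iterrows():
        for w in range(1, spec.fields_per_replicate + 1):
            absorb = rng.normal(
                rr["mtt_percent"] / 100.0 * a0,
                spec.within_sd["mtt_percent"] / 100.0 * a0,
            )
            mtt_rows.append(
                {
                    "well_id": f"{rr['replicate']}_w{w}",
                    "replicate": rr["replicate"],
                    "katp_level": rr["katp_level"],
                    "rotenone": rr["rotenone"],
                    "absorbance": max(absorb, 0.0),
                }
            )
            count = rng.normal(rr["cell_count"], spec.within_sd["cell_count"])
            count_rows.append(
                {
                    "image_id": f"{rr['replicate']}_i{w}",
                    "replicate": rr["replicate"],
                    "katp_level": rr["katp_level"],
                    "rotenone": rr["rotenone"],
                    "count": max(count, 0.0),
                }
            )

    fields = None
    if render:
        fields = []
        for _, row in table.iterrows():
            fseed = int(rng.integers(0, 2**31 - 2))
            fields.append(_render_row(row, spec, fseed))

    truth_rows = [
        {
            "katp_level": a,
            "rotenone": b,
            **{v: spec.condition_mean(v, a, b) for v in ALL_VARS},
        }
        for a in spec.factor_a_levels
        for b in spec.factor_b_levels
    ]
    return ExperimentData(
        spec=spec,
        field_table=table,
        fields=fields,
        mtt_wells=pd.DataFrame(mtt_rows),
        cell_counts=pd.DataFrame(count_rows),
        truth_means=pd.DataFrame(truth_rows),
    )
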