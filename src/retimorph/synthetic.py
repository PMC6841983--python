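"""Synthetic fixtures: exact-dimension fractals and retinal-like vascular trees.

Two families of generators make every pipeline stage testable without any
image download:

* :func:`make_fractal` builds deterministic rasters whose limiting
  box-counting dimension is known exactly (line → 1, filled square → 2,
  Koch curve → log4/log3 ≈ 1.2619, Sierpiński carpet → log8/log3 ≈ 1.8928).
* :func:`simulate_tree` grows a stochastic branching tree with tapering
  calibers and rasterizes it, returning both the ground-truth
  :class:`~retimorph.calibration.VesselTree` (with generations assigned by
  the same diameter rules the analysis implements) and the binary mask.
  A positive ``faz_radius`` keeps a central disc avascular, emulating the
  foveal avascular zone of macula-centred windows.

Default tree parameters emulate fundus-camera scale vasculature: trunk
calibers around 20 px (≈ 97 μm at 4.86 μm/px), tapering towards ≈ 4–6 px
(≈ 21–28 μm) over about five branching generations, with skeleton coverage
in the percent range.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .calibration import TreeNode, TreeSegment, VesselTree
from .mask_io import BinaryMask, DatasetManifest, ManifestRecord, RoiSpec, write_manifest, write_mask

FRACTAL_KINDS = ("line", "filled_square", "koch_curve", "sierpinski_carpet")

#: Theoretical box-counting dimension of each fixture's limiting set.
THEORETICAL_DIMENSION = {
    "line": 1.0,
    "filled_square": 2.0,
    "koch_curve": math.log(4) / math.log(3),
    "sierpinski_carpet": math.log(8) / math.log(3),
}


@dataclass(frozen=True)
class FractalFixtureSpec:
    kind: str
    order: int = 0
    side: int = 243

    def __post_init__(self) -> None:
        if self.kind not in FRACTAL_KINDS:
            raise ValueError(f"kind must be one of {FRACTAL_KINDS}, got {self.kind!r}")
        if self.order < 0:
            raise ValueError(f"order must be >= 0, got {self.order}")
        if self.side < 2:
            raise ValueError(f"side must be >= 2, got {self.side}")
        if self.kind == "sierpinski_carpet":
            k = round(math.log(self.side, 3))
            if 3**k != self.side or k < self.order:
                raise ValueError(
                    f"carpet requires side = 3^k with k >= order; got side={self.side}, order={self.order}"
                )


def _koch_polyline(order: int) -> list[tuple[float, float]]:
    pts = [(0.0, 0.0), (1.0, 0.0)]
    c60, s60 = 0.5, math.sqrt(3) / 2
    for _ in range(order):
        new: list[tuple[float, float]] = []
        for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
            dx, dy = x2 - x1, y2 - y1
            a = (x1 + dx / 3, y1 + dy / 3)
            b = (x1 + 2 * dx / 3, y1 + 2 * dy / 3)
            peak = (a[0] + (dx / 3) * c60 + (dy / 3) * s60, a[1] - (dx / 3) * s60 + (dy / 3) * c60)
            new += [(x1, y1), a, peak, b]
        new.append(pts[-1])
        pts = new
    return pts


def make_fractal(spec: FractalFixtureSpec) -> BinaryMask:
    """Rasterize a deterministic fractal fixture of known dimension.

    The Koch curve is rasterized from its order-``order`` vector polyline
    with 1-px strokes; finite order and rasterization bias its measured
    dimension slightly, so validations against it use a widened tolerance.
    """
    side = spec.side
    m = np.zeros((side, side), dtype=bool)
    if spec.kind == "line":
        m[side // 2, :] = True
    elif spec.kind == "filled_square":
        m[:, :] = True
    elif spec.kind == "sierpinski_carpet":
        m[:, :] = True
        idx = np.arange(side)
        for o in range(spec.order):
            cell = side // 3 ** (o + 1)
            digit = (idx // cell) % 3
            m &= ~((digit[:, None] == 1) & (digit[None, :] == 1))
    else:  # koch_curve
        pts = _koch_polyline(spec.order)
        sc = side - 1
        base_row = int(round(side * 0.7))
        for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
            r1, c1 = int(round(base_row - y1 * sc)), int(round(x1 * sc))
            r2, c2 = int(round(base_row - y2 * sc)), int(round(x2 * sc))
            rr, cc = draw_line(r1, c1, r2, c2)
            ok = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
            m[rr[ok], cc[ok]] = True
    return BinaryMask(m, name=f"{spec.kind}-o{spec.order}-s{side}")


@dataclass(frozen=True)
class AsymmetryParams:
    """Daughter-caliber ratio distribution at bifurcations.

    With probability ``p_symmetric`` the bifurcation is symmetric and the
    smaller/larger ratio is uniform on ``symmetric_range``; otherwise it is
    asymmetric with the ratio of the side branch to the parent taper drawn
    uniformly from ``asymmetric_range``.  Both ranges are kept away from
    the generation-rule threshold so ground-truth generations are
    unambiguous.
    """

    p_symmetric: float = 0.35
    symmetric_range: tuple[float, float] = (0.86, 1.0)
    asymmetric_range: tuple[float, float] = (0.45, 0.70)


@dataclass(frozen=True)
class TreeSimParams:
    """Parameters of the stochastic vascular-tree generator."""

    root_caliber: float = 20.0  # px; ~97 μm at 4.86 μm/px
    taper: float = 0.73  # caliber shrink per advancing generation
    max_generations: int = 5
    branch_prob: float = 0.85
    continue_prob: float = 0.10  # chance a tip extends without branching
    asymmetry: AsymmetryParams = field(default_factory=AsymmetryParams)
    branch_angle_deg: tuple[float, float] = (32.0, 8.0)  # mean, spread
    segment_length: tuple[float, float] = (55.0, 12.0)  # px mean, spread
    faz_radius: float = 0.0  # px; 0 = no avascular zone
    faz_centre: tuple[float, float] | None = None  # (row, col); None -> window centre
    window: int = 512
    seed: int = 0
    n_roots: int = 4
    root_origin: tuple[float, float] | None = None  # (row, col); None -> centred layout
    root_direction_deg: float | None = None  # None -> full fan
    root_ring_radius: float | None = None  # ring layout radius; None -> just outside FAZ
    root_inward: bool = False  # ring roots grow towards the centre (arcade-like)
    symmetry_ratio: float = 0.8  # generation-rule threshold for ground truth
    prune_prob: float = 0.0  # chance each terminal segment is removed (vascular pruning)

    def __post_init__(self) -> None:
        if not 0 < self.taper < 1:
            raise ValueError(f"taper must be in (0, 1), got {self.taper}")
        if self.max_generations < 1:
            raise ValueError(f"max_generations must be >= 1, got {self.max_generations}")
        if self.window < 64:
            raise ValueError(f"window must be >= 64 px, got {self.window}")
        for name in ("branch_prob", "continue_prob", "prune_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.faz_radius < 0 or self.root_caliber <= 0 or self.n_roots < 1:
            raise ValueError("faz_radius >= 0, root_caliber > 0, n_roots >= 1 required")


def _truncated_normal(rng: np.random.Generator, mean: float, spread: float, lo: float) -> float:
    # truncated to mean ± 2 spread and floored at lo
    v = rng.normal(mean, spread)
    v = min(max(v, mean - 2 * spread), mean + 2 * spread)
    return max(v, lo)


def _segment_clear_of_faz(
    p1: np.ndarray, p2: np.ndarray, centre: np.ndarray, radius: float, caliber: float
) -> bool:
    if radius <= 0:
        return True
    d = p2 - p1
    t = float(np.clip(np.dot(centre - p1, d) / max(np.dot(d, d), 1e-9), 0.0, 1.0))
    nearest = p1 + t * d
    return float(np.linalg.norm(centre - nearest)) >= radius + caliber / 2 + 1.0


def _stroke(mask: np.ndarray, p1: np.ndarray, p2: np.ndarray, caliber: float) -> None:
    rad = max(caliber / 2.0, 0.5)
    shape = mask.shape
    rr, cc = draw_disk((p1[0], p1[1]), rad, shape=shape)
    mask[rr, cc] = True
    rr, cc = draw_disk((p2[0], p2[1]), rad, shape=shape)
    mask[rr, cc] = True
    d = p2 - p1
    norm = float(np.hypot(*d))
    if norm < 1e-6:
        return
    n = np.array([-d[1], d[0]]) / norm * rad
    corners_r = [p1[0] + n[0], p1[0] - n[0], p2[0] - n[0], p2[0] + n[0]]
    corners_c = [p1[1] + n[1], p1[1] - n[1], p2[1] - n[1], p2[1] + n[1]]
    rr, cc = draw_polygon(corners_r, corners_c, shape=shape)
    mask[rr, cc] = True


def simulate_tree(params: TreeSimParams) -> tuple[VesselTree, BinaryMask]:
    """Grow and rasterize a stochastic vascular tree.

    Trunks start at ``root_origin`` (or a centred layout: the window centre
    when there is no avascular zone, else a ring just outside it) and grow
    outward in segments of truncated-normal length.  At each tip the vessel
    bifurcates with probability ``branch_prob``: the asymmetry draw fixes
    the daughter calibers, and the ground-truth generation of each daughter
    follows the same diameter rules as
    :func:`retimorph.calibration.assign_generations`.  Caliber floor is
    1.2 px; growth also stops at the window edge and when a branch would
    exceed ``max_generations``.  Segments never enter the avascular zone,
    which is additionally carved from the raster, so each trunk rasterizes
    to a single 8-connected component.

    Fully reproducible: the same ``params`` (including ``seed``) give a
    bit-identical mask and tree.
    """
    rng = np.random.default_rng(params.seed)
    win = params.window
    centre = np.array([win / 2.0, win / 2.0])
    faz_centre = (
        np.array(params.faz_centre, dtype=float) if params.faz_centre is not None else centre.copy()
    )
    nodes: list[TreeNode] = []
    segments: list[TreeSegment] = []

    def add_node(pos: np.ndarray) -> int:
        nid = len(nodes)
        nodes.append(TreeNode(nid, (float(pos[0]), float(pos[1]))))
        return nid

    # root layout
    tips: list[tuple[int, np.ndarray, np.ndarray, float, int]] = []  # node, pos, dir, caliber, gen
    if params.root_origin is not None:
        origin = np.array(params.root_origin, dtype=float)
        base = (
            math.radians(params.root_direction_deg)
            if params.root_direction_deg is not None
            else None
        )
        nid = add_node(origin)
        for k in range(params.n_roots):
            if base is None:
                theta = 2 * math.pi * k / params.n_roots + rng.uniform(-0.2, 0.2)
            else:
                fan = math.radians(100.0)
                theta = base + fan * (k / max(params.n_roots - 1, 1) - 0.5) + rng.uniform(-0.1, 0.1)
            tips.append((nid, origin.copy(), np.array([math.sin(theta), math.cos(theta)]), params.root_caliber, 1))
    elif params.faz_radius > 0 or params.root_ring_radius is not None:
        ring = (
            params.root_ring_radius
            if params.root_ring_radius is not None
            else params.faz_radius + params.root_caliber + 6.0
        )
        for k in range(params.n_roots):
            theta = 2 * math.pi * k / params.n_roots + rng.uniform(-0.25, 0.25)
            radial = np.array([math.sin(theta), math.cos(theta)])
            pos = faz_centre + ring * radial
            direction = -radial if params.root_inward else radial
            if params.root_inward:
                # skew off the exact radial so arcades sweep past the centre
                skew = rng.uniform(0.5, 0.9) * (1 if k % 2 == 0 else -1)
                ca, sa = math.cos(skew), math.sin(skew)
                direction = np.array(
                    [direction[0] * ca + direction[1] * sa, -direction[0] * sa + direction[1] * ca]
                )
            tips.append((add_node(pos), pos, direction, params.root_caliber, 1))
    else:
        nid = add_node(centre)
        for k in range(params.n_roots):
            theta = 2 * math.pi * k / params.n_roots + rng.uniform(-0.2, 0.2)
            tips.append((nid, centre.copy(), np.array([math.sin(theta), math.cos(theta)]), params.root_caliber, 1))

    angle_mean, angle_spread = params.branch_angle_deg
    len_mean, len_spread = params.segment_length
    margin = 2.0
    max_segments = 6000

    while tips and len(segments) < max_segments:
        node_id, pos, direction, caliber, gen = tips.pop()
        length = _truncated_normal(rng, len_mean, len_spread, 6.0)
        jitter = math.radians(rng.normal(0.0, 5.0))
        ca, sa = math.cos(jitter), math.sin(jitter)
        direction = np.array(
            [direction[0] * ca + direction[1] * sa, -direction[0] * sa + direction[1] * ca]
        )
        end = pos + direction * length
        # steer around the avascular zone
        if not _segment_clear_of_faz(pos, end, faz_centre, params.faz_radius, caliber):
            for turn in (25.0, -25.0, 50.0, -50.0, 80.0, -80.0):
                a = math.radians(turn)
                cand = np.array(
                    [
                        direction[0] * math.cos(a) + direction[1] * math.sin(a),
                        -direction[0] * math.sin(a) + direction[1] * math.cos(a),
                    ]
                )
                if _segment_clear_of_faz(pos, pos + cand * length, faz_centre, params.faz_radius, caliber):
                    direction = cand
                    end = pos + cand * length
                    break
            else:
                continue  # boxed in: terminate tip
        # clip to the window
        terminal = False
        lo, hi = margin, win - 1 - margin
        if np.any(end < lo) or np.any(end > hi):
            ts = [1.0]
            for axis in range(2):
                d = end[axis] - pos[axis]
                if abs(d) > 1e-9:
                    for bound in (lo, hi):
                        t = (bound - pos[axis]) / d
                        if 0 < t < 1:
                            ts.append(t)
            t = min(ts)
            end = pos + (end - pos) * t
            terminal = True
            if float(np.linalg.norm(end - pos)) < 4.0:
                continue
        end_id = add_node(end)
        segments.append(TreeSegment(parent=node_id, child=end_id, caliber_px=caliber, generation=gen))
        if terminal or caliber < 1.2:
            continue
        u = rng.uniform()
        asym = params.asymmetry
        if u < params.branch_prob:
            if rng.uniform() < asym.p_symmetric:
                # symmetric: both daughters advance a generation
                if gen + 1 > params.max_generations:
                    continue
                ratio = rng.uniform(*asym.symmetric_range)
                larger, smaller = caliber * params.taper, caliber * params.taper * ratio
                gens = (gen + 1, gen + 1)
            else:
                # asymmetric: the larger daughter continues the parent vessel
                if gen + 1 > params.max_generations:
                    continue
                ratio = rng.uniform(*asym.asymmetric_range)
                larger, smaller = caliber * 0.98, caliber * params.taper * ratio
                gens = (gen, gen + 1)
            split = math.radians(_truncated_normal(rng, angle_mean, angle_spread, 10.0))
            side = 1.0 if rng.uniform() < 0.5 else -1.0
            if smaller < 1.0:
                # below the raster floor: the survivor is a plain continuation,
                # so by the generation rules it keeps the parent's generation
                if larger >= 1.0:
                    tips.append((end_id, end.copy(), direction, larger, gen))
                continue
            for cal, g, ang in (
                (larger, gens[0], -side * split * 0.45),
                (smaller, gens[1], side * split),
            ):
                ca, sa = math.cos(ang), math.sin(ang)
                d = np.array(
                    [direction[0] * ca + direction[1] * sa, -direction[0] * sa + direction[1] * ca]
                )
                tips.append((end_id, end.copy(), d, cal, g))
        elif u < params.branch_prob + params.continue_prob:
            tips.append((end_id, end.copy(), direction, caliber * 0.99, gen))
        # else: terminate

    # vascular pruning: drop terminal segments with prune_prob
    if params.prune_prob > 0 and segments:
        has_child = {s.parent for s in segments}
        kept = [
            s
            for s in segments
            if s.child in has_child or rng.uniform() >= params.prune_prob
        ]
        segments = kept

    # drop orphaned nodes
    used = {s.parent for s in segments} | {s.child for s in segments}
    id_map = {old: new for new, old in enumerate(sorted(used))}
    tree = VesselTree(
        nodes=[TreeNode(id_map[n.id], n.position) for n in nodes if n.id in used],
        segments=[
            TreeSegment(id_map[s.parent], id_map[s.child], s.caliber_px, s.generation)
            for s in segments
        ],
    )

    mask = np.zeros((win, win), dtype=bool)
    pos_of = {n.id: np.array(n.position) for n in tree.nodes}
    for s in tree.segments:
        _stroke(mask, pos_of[s.parent], pos_of[s.child], s.caliber_px)
    if params.faz_radius > 0:
        rr, cc = draw_disk((faz_centre[0], faz_centre[1]), params.faz_radius, shape=mask.shape)
        mask[rr, cc] = False
    return tree, BinaryMask(mask, name=f"tree-seed{params.seed}")


def disc_like_params(seed: int = 0, window: int = 512) -> TreeSimParams:
    """Optic-disc-like preset: a dense radial cluster of tapering trunks.

    Twelve generation-1 trunks radiate from the window centre and branch
    densely over short segments, reproducing the centre-heavy, gappy
    geometry of a disc-centred window: skeleton density around 11% with
    lacunarity around 0.6 at the default window.
    """
    s = window / 512.0
    return TreeSimParams(
        root_caliber=20.0,
        taper=0.76,
        branch_prob=1.0,
        continue_prob=0.0,
        segment_length=(16.0 * s, 4.0 * s),
        faz_radius=0.0,
        window=window,
        seed=seed,
        n_roots=12,
        max_generations=7,
    )


def macula_like_params(seed: int = 0, window: int = 512) -> TreeSimParams:
    """Macula-like preset: fine arcade vessels around a central avascular zone.

    Small-caliber roots enter from a peripheral ring and sweep across the
    window (steering around the avascular zone), giving an evenly covered
    field: skeleton density around 8% with lacunarity around 0.4 — both
    below the disc-like preset, the healthy-retina regional pattern.
    """
    s = window / 512.0
    return TreeSimParams(
        root_caliber=6.0,
        taper=0.82,
        branch_prob=0.85,
        continue_prob=0.1,
        segment_length=(30.0 * s, 7.0 * s),
        faz_radius=26.0 * s,
        window=window,
        seed=seed,
        n_roots=10,
        root_ring_radius=215.0 * s,
        root_inward=True,
        max_generations=5,
    )


@dataclass(frozen=True)
class CohortPreset:
    """Per-group generator pair: one disc-like and one macula-like window."""

    disc: TreeSimParams
    macula: TreeSimParams


def default_cohort_presets(window: int = 512) -> dict[str, CohortPreset]:
    """Per-group presets for an HRF-style synthetic cohort.

    Each cohort image is a ``window × 2·window`` canvas holding a
    disc-like tile on the left and a macula-like tile on the right.  The
    healthy (H) preset pair is the baseline; glaucoma (G) is a mild global
    attenuation; diabetic retinopathy (DR) prunes terminal macular
    branches and enlarges the avascular zone (macular complexity and
    density drop) while its disc tile grows fewer, clumpier trunks
    (optic-disc lacunarity rises).
    """
    disc = disc_like_params(window=window)
    mac = macula_like_params(window=window)
    s = window / 512.0
    return {
        "H": CohortPreset(disc=disc, macula=mac),
        "G": CohortPreset(
            disc=dataclasses.replace(disc, n_roots=11),
            macula=dataclasses.replace(mac, branch_prob=0.83),
        ),
        "DR": CohortPreset(
            disc=dataclasses.replace(
                disc,
                root_caliber=24.0,
                taper=0.80,
                segment_length=(13.0 * s, 3.0 * s),
                max_generations=8,
            ),
            macula=dataclasses.replace(
                mac, prune_prob=0.5, faz_radius=40.0 * s, branch_prob=0.80
            ),
        ),
    }


def make_cohort(
    presets: dict[str, CohortPreset],
    n_per_group: int,
    seed: int,
    out_dir: str | Path,
    roi_size: int | None = None,
) -> DatasetManifest:
    """Write a synthetic cohort (masks + manifest CSV) to ``out_dir``.

    Each image is a ``window × 2·window`` canvas: the group's disc-like
    tile on the left, its macula-like tile on the right.  The manifest's
    optic-disc and macula centres are the tile centres, so the default
    ROI (``roi_size = window``) recovers each tile exactly.  Per-image
    seeds derive deterministically from ``seed`` and the (group,
    replicate, tile) indices, so the same arguments reproduce identical
    directory contents.  The ground-truth trees of both tiles are merged
    (macula-node positions shifted to canvas coordinates) and written as
    JSON next to each mask; the masks double as the "image" column (no
    raw photographs exist for synthetic data).
    """
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    out_dir = Path(out_dir)
    mask_dir = out_dir / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    records: list[ManifestRecord] = []
    for gi, (group, preset) in enumerate(presets.items()):
        if preset.disc.window != preset.macula.window:
            raise ValueError(f"group {group}: disc and macula windows must match")
        for i in range(n_per_group):
            seeds = [
                int(np.random.SeedSequence([seed, gi, i, t]).generate_state(1)[0] % 2**31)
                for t in (0, 1)
            ]
            disc_tree, disc_mask = simulate_tree(dataclasses.replace(preset.disc, seed=seeds[0]))
            mac_tree, mac_mask = simulate_tree(dataclasses.replace(preset.macula, seed=seeds[1]))
            win = preset.disc.window
            canvas = np.concatenate([disc_mask.pixels, mac_mask.pixels], axis=1)
            name = f"{group}_{i:02d}"
            mask_path = mask_dir / f"{name}.png"
            write_mask(BinaryMask(canvas, name=name), mask_path)
            offset = len(disc_tree.nodes)
            merged = VesselTree(
                nodes=list(disc_tree.nodes)
                + [
                    TreeNode(n.id + offset, (n.position[0], n.position[1] + win))
                    for n in mac_tree.nodes
                ],
                segments=list(disc_tree.segments)
                + [
                    TreeSegment(s.parent + offset, s.child + offset, s.caliber_px, s.generation)
                    for s in mac_tree.segments
                ],
            )
            merged.to_json(mask_dir / f"{name}.tree.json")
            size = roi_size if roi_size is not None else win
            records.append(
                ManifestRecord(
                    image=str(mask_path),
                    mask=str(mask_path),
                    group=group,
                    optic_disc=RoiSpec("optic_disc", win // 2, win // 2, size=size),
                    macula=RoiSpec("macula", win + win // 2, win // 2, size=size),
                )
            )
    manifest = DatasetManifest(records)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
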