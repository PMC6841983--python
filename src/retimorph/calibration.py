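"""Pixel-to-micrometer calibration, vessel caliber, branching generations.

The pixel scale is derived from the optic disc: known average disc
dimensions in μm are divided by the measured disc dimensions in pixels and
the two ratios averaged.  Vessel caliber is measured from the binary mask
via the Euclidean distance transform at the centreline.  Branching
generations follow diameter-based rules: trunks at the optic disc are
generation 1; at an asymmetric bifurcation the larger daughter continues
the parent's generation while the smaller daughter starts the next one;
when the daughters have relatively equal diameters both advance a
generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .errors import StructureError
from .geometry import SkeletonMask, skeletonize
from .mask_io import BinaryMask

DEFAULT_SYMMETRY_RATIO = 0.8


@dataclass(frozen=True)
class PixelScale:
    um_per_px: float

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be positive, got {self.um_per_px}")


@dataclass(frozen=True)
class CaliberMeasurement:
    point: tuple[int, int]  # queried (row, col)
    centreline_point: tuple[int, int]  # nearest skeleton pixel actually measured
    width_px: float
    width_um: float


def estimate_pixel_scale(
    disc_width_px: float,
    disc_height_px: float,
    ref_width_um: float,
    ref_height_um: float,
) -> PixelScale:
    """Pixel scale from measured vs reference optic-disc dimensions.

    ``um_per_px`` is the mean of the horizontal and vertical μm/px ratios.
    The reference disc dimensions are inputs, not constants: population
    averages differ between studies.
    """
    for label, v in (
        ("disc_width_px", disc_width_px),
        ("disc_height_px", disc_height_px),
        ("ref_width_um", ref_width_um),
        ("ref_height_um", ref_height_um),
    ):
        if v <= 0:
            raise ValueError(f"{label} must be positive, got {v}")
    return PixelScale((ref_width_um / disc_width_px + ref_height_um / disc_height_px) / 2.0)


def _local_skeleton_direction(
    sk_coords: np.ndarray, centre: np.ndarray, radius: float = 5.0
) -> np.ndarray | None:
    """Principal direction of the skeleton pixels near ``centre``, or None."""
    d = np.linalg.norm(sk_coords - centre, axis=1)
    local = sk_coords[d <= radius].astype(float)
    if len(local) < 3:
        return None
    cov = np.cov((local - local.mean(axis=0)).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, int(np.argmax(eigvals))]
    if eigvals.max() <= 1e-9:
        return None
    return direction / np.linalg.norm(direction)


def measure_caliber(
    mask: BinaryMask,
    point: tuple[int, int],
    scale: PixelScale,
    skeleton: SkeletonMask | None = None,
) -> CaliberMeasurement:
    """Vessel caliber at (or nearest to) a foreground point.

    The measurement is taken at the skeleton pixel closest to ``point``:
    the local vessel direction is estimated from the principal axis of the
    surrounding skeleton pixels, and the caliber is the foreground chord
    along the perpendicular through that pixel (fine ray-marching with
    nearest-pixel membership).  An axis-aligned bar of width w reads
    exactly w; oblique bars read the rasterized chord, within about half
    a pixel of the drawn width.  Where no local direction exists (an
    isolated centreline point) the caliber falls back to the distance
    transform: ``2·EDT − 1``.

    On binary masks the external-wall/lumen distinction collapses: the
    reported caliber is the mask width.
    """
    r, c = int(point[0]), int(point[1])
    if not (0 <= r < mask.height and 0 <= c < mask.width) or not mask.pixels[r, c]:
        raise ValueError(f"point ({r}, {c}) is not a foreground pixel")
    if skeleton is None:
        skeleton = skeletonize(mask)
    sk_coords = np.argwhere(skeleton.pixels)
    if sk_coords.size == 0:
        raise ValueError("mask skeletonizes to nothing; cannot locate a centreline")
    _, idx = cKDTree(sk_coords).query([r, c])
    sr, sc = (int(v) for v in sk_coords[idx])
    centre = np.array([sr, sc], dtype=float)
    direction = _local_skeleton_direction(sk_coords, centre)
    if direction is None:
        edt = ndi.distance_transform_edt(mask.pixels)
        width_px = max(1.0, 2.0 * float(edt[sr, sc]) - 1.0)
    else:
        normal = np.array([-direction[1], direction[0]])
        pixels, (h, w) = mask.pixels, mask.pixels.shape
        step = 0.1
        limit = float(h + w)
        # average the chord over a few parallel normals: a single digital
        # line can thread a staircase notch of an oblique vessel edge
        chords = []
        for along in (-0.8, -0.4, 0.0, 0.4, 0.8):
            start = centre + along * direction
            ri, ci = int(round(start[0])), int(round(start[1]))
            if not (0 <= ri < h and 0 <= ci < w) or not pixels[ri, ci]:
                continue
            reach = []
            for sign in (1.0, -1.0):
                t = 0.0
                while t < limit:
                    t += step
                    pos = start + sign * t * normal
                    ri, ci = int(round(pos[0])), int(round(pos[1]))
                    if not (0 <= ri < h and 0 <= ci < w) or not pixels[ri, ci]:
                        break
                reach.append(t - step / 2)  # boundary lies within one step
            chords.append(reach[0] + reach[1])
        width_px = max(1.0, float(np.mean(chords)))
    return CaliberMeasurement(
        point=(r, c),
        centreline_point=(sr, sc),
        width_px=float(width_px),
        width_um=float(width_px) * scale.um_per_px,
    )


@dataclass(frozen=True)
class TreeNode:
    id: int
    position: tuple[float, float]  # (row, col) px


@dataclass
class TreeSegment:
    parent: int  # node id at the upstream end
    child: int  # node id at the downstream end
    caliber_px: float  # sampled at the segment midpoint
    generation: int | None = None


@dataclass
class VesselTree:
    """A forest of vessel segments with calibers and branching generations."""

    nodes: list[TreeNode] = field(default_factory=list)
    segments: list[TreeSegment] = field(default_factory=list)

    def node_by_id(self) -> dict[int, TreeNode]:
        return {n.id: n for n in self.nodes}

    def roots(self) -> list[int]:
        """Node ids with no incoming segment."""
        children = {s.child for s in self.segments}
        return [n.id for n in self.nodes if n.id not in children]

    def outgoing(self) -> dict[int, list[TreeSegment]]:
        out: dict[int, list[TreeSegment]] = {}
        for s in self.segments:
            out.setdefault(s.parent, []).append(s)
        return out

    def validate(self) -> None:
        """Raise :class:`StructureError` unless segments form a forest."""
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise StructureError("duplicate node ids")
        known = set(ids)
        seen_children: set[int] = set()
        parent_of: dict[int, int] = {}
        for s in self.segments:
            if s.parent not in known or s.child not in known:
                raise StructureError(f"segment {s.parent}->{s.child} references unknown node")
            if s.child in seen_children:
                raise StructureError(f"node {s.child} has multiple parents")
            seen_children.add(s.child)
            parent_of[s.child] = s.parent
        for start in parent_of:
            node, hops = start, 0
            while node in parent_of:
                node = parent_of[node]
                hops += 1
                if hops > len(self.segments):
                    raise StructureError("cycle detected in vessel tree")

    def max_generation(self) -> int:
        gens = [s.generation for s in self.segments if s.generation is not None]
        return max(gens) if gens else 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "nodes": [{"id": n.id, "position": list(n.position)} for n in self.nodes],
            "segments": [
                {
                    "parent": s.parent,
                    "child": s.child,
                    "caliber_px": s.caliber_px,
                    "generation": s.generation,
                }
                for s in self.segments
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "VesselTree":
        text = Path(source).read_text() if isinstance(source, Path) else source
        payload = json.loads(text)
        return cls(
            nodes=[TreeNode(n["id"], tuple(n["position"])) for n in payload["nodes"]],
            segments=[
                TreeSegment(s["parent"], s["child"], s["caliber_px"], s.get("generation"))
                for s in payload["segments"]
            ],
        )


def assign_generations(
    tree: VesselTree, symmetry_ratio: float = DEFAULT_SYMMETRY_RATIO
) -> VesselTree:
    """Assign branching generations from segment calibers.

    Root segments get generation 1.  Where a segment simply continues
    (single child) the generation is unchanged.  At a bifurcation let
    ``r = smaller / larger`` daughter caliber: if ``r < symmetry_ratio``
    the branching is asymmetric — the larger daughter keeps the parent's
    generation and the smaller daughter gets the next one; otherwise the
    daughters are relatively equal and both advance a generation.  With
    more than two daughters the largest is compared against the second
    largest.

    Returns a new tree; the input is not modified.
    """
    tree.validate()
    out = VesselTree(
        nodes=list(tree.nodes),
        segments=[replace(s) for s in tree.segments],
    )
    outgoing = out.outgoing()

    def descend(segs: list[TreeSegment], parent_gen: int) -> None:
        if not segs:
            return
        if len(segs) == 1:
            segs[0].generation = parent_gen
        else:
            ranked = sorted(segs, key=lambda s: -s.caliber_px)
            r = ranked[1].caliber_px / ranked[0].caliber_px
            if r < symmetry_ratio:
                ranked[0].generation = parent_gen
                for s in ranked[1:]:
                    s.generation = parent_gen + 1
            else:
                for s in ranked:
                    s.generation = parent_gen + 1
        for s in segs:
            descend(outgoing.get(s.child, []), s.generation)

    for root in out.roots():
        for trunk in outgoing.get(root, []):
            trunk.generation = 1
            descend(outgoing.get(trunk.child, []), 1)
    return out
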