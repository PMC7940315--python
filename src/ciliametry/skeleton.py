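"""Per-cilium centerline extraction.

Each cilium object is rendered into a tight 8-bit volume, upscaled
threefold with trilinear interpolation, blurred (the requested sigma is
tripled to match the upscaled grid), re-binarized at half maximum, and
thinned to a one-voxel-wide medial axis.  The thinned voxel set is
analyzed as a graph: connected skeletons are counted, the largest is
decomposed into branches, and the cilium centerline is defined as the
*largest shortest path* — over all pairs of skeleton endpoints, the
longest of the pairwise shortest on-skeleton paths.  All geometry is
computed in calibrated µm with voxel anisotropy folded into the edge
weights, so z-steps are not confused with in-plane steps.

Skeleton counts, branch counts, and tree length act as quality
parameters: more than one skeleton or many side branches indicate an
unreliable reconstruction and hence unreliable length measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from ._thinning import thin_volume
from .image import CalibratedImage
from .reconstruct import CiliumObject

__all__ = [
    "SkeletonGraph",
    "CenterlinePath",
    "object_volume_image",
    "upscale_threefold",
    "blur_for_skeleton",
    "thin_3d",
    "analyze_skeleton",
    "largest_shortest_path",
    "orient_path",
    "extract_centerline",
]

UPSCALE = 3


@dataclass
class CenterlinePath:
    """Ordered sub-voxel centerline points with cumulative arc length.

    ``points`` has columns (x, y, z) in µm; ``arc_length`` starts at 0 and
    is strictly increasing.  After orientation the first point is the
    ciliary base and the last the tip.
    """

    points: np.ndarray
    arc_length: np.ndarray
    oriented: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.arc_length = np.atleast_1d(np.asarray(self.arc_length, dtype=np.float64))

    @property
    def length(self) -> float:
        """Total arc length in µm (the "cilia length" parameter)."""
        return float(self.arc_length[-1])

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def reversed(self) -> "CenterlinePath":
        pts = self.points[::-1].copy()
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        return CenterlinePath(
            points=pts, arc_length=arc, oriented=self.oriented, flags=list(self.flags)
        )


@dataclass
class SkeletonGraph:
    """Graph view of a thinned voxel set (26-adjacency, calibrated weights)."""

    graph: nx.Graph  # nodes: (z, y, x) in the upscaled grid
    n_skeletons: int
    n_branches: int
    tree_length: float  # µm, largest skeleton
    endpoints: list[tuple[int, int, int]]  # of the largest skeleton
    largest_nodes: set[tuple[int, int, int]]
    node_position_um: dict[tuple[int, int, int], np.ndarray]  # (x, y, z) µm
    flags: list[str] = field(default_factory=list)


def object_volume_image(cilium: CiliumObject, timepoint: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one object at one timepoint as an 8-bit volume.

    Returns the volume (tight bounding box plus a 1-voxel pad, object
    voxels at 255) and the (z, y, x) index of the volume origin in the
    full image grid.
    """
    if timepoint not in cilium.voxels or cilium.voxels[timepoint].shape[0] == 0:
        raise ValueError(f"object {cilium.id} has no voxels at timepoint {timepoint}")
    vox = cilium.voxels[timepoint]
    lo = vox.min(axis=0) - 1
    hi = vox.max(axis=0) + 1
    shape = hi - lo + 1
    volume = np.zeros(shape, dtype=np.uint8)
    local = vox - lo
    volume[local[:, 0], local[:, 1], local[:, 2]] = 255
    return volume, lo


def upscale_threefold(volume: np.ndarray) -> np.ndarray:
    """Trilinear threefold upscaling in all three dimensions."""
    return ndimage.zoom(
        np.asarray(volume, dtype=np.float64), UPSCALE, order=1, grid_mode=True, mode="nearest"
    )


def blur_for_skeleton(volume: np.ndarray, sigma_xy: float, sigma_z: float = 0.0) -> np.ndarray:
    """3D Gaussian blur prior to thinning.

    Sigmas are given in original-scale pixels; three times the requested
    sigma is applied because the volume is threefold upscaled.  The z
    sigma is configurable separately (0 disables z mixing, the common
    choice for confocal stacks).
    """
    if sigma_xy < 0 or sigma_z < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_xy == 0 and sigma_z == 0:
        return np.asarray(volume, dtype=np.float64).copy()
    sig = (UPSCALE * sigma_z, UPSCALE * sigma_xy, UPSCALE * sigma_xy)
    # the object sits in zero background; the volume border must not
    # reflect intensity back in, or large sigmas inflate the object
    return ndimage.gaussian_filter(
        np.asarray(volume, dtype=np.float64), sigma=sig, mode="constant", cval=0.0
    )


def thin_3d(volume: np.ndarray, binarize_at: float = 128.0) -> np.ndarray:
    """Topology-preserving medial-axis thinning.

    The volume is binarized at ``binarize_at`` (default: half of 255) and
    thinned to a one-voxel-wide, 26-connected skeleton.  Returns an
    (n, 3) array of (z, y, x) skeleton coordinates (empty for empty
    foreground).
    """
    binary = np.asarray(volume) >= binarize_at
    if not binary.any():
        return np.empty((0, 3), dtype=np.int64)
    if int(binary.sum()) == 1:
        return np.argwhere(binary)
    return np.argwhere(thin_volume(binary))


def _branch_count(tree: nx.Graph) -> int:
    """Branches of the pruned decomposition: segments between nodes of
    degree != 2 (end-to-junction, junction-to-junction, end-to-end)."""
    if tree.number_of_nodes() <= 1:
        return 0 if tree.number_of_edges() == 0 else 1
    special_deg = [d for _, d in tree.degree if d != 2]
    if not special_deg:  # cycle
        return 1
    return int(sum(special_deg) // 2)


def analyze_skeleton(
    skeleton_voxels: np.ndarray,
    voxel_sizes_zyx: tuple[float, float, float],
    origin_zyx: np.ndarray | tuple[int, int, int] = (0, 0, 0),
) -> SkeletonGraph:
    """Build and analyze the skeleton graph of a thinned voxel set.

    Skeleton voxels live in the threefold-upscaled grid; edge weights are
    Euclidean step lengths with per-axis spacing ``voxel_size / 3``, so
    diagonal and anisotropic steps are measured correctly.  Components
    are counted as separate skeletons; the largest (by tree length) is
    decomposed into branches.  Tree length and the branch decomposition
    are measured on a deterministic minimum spanning tree of the
    component, which removes the redundant diagonal shortcuts a
    26-adjacency graph contains along a one-voxel-wide chain.
    """
    spacing = np.asarray(voxel_sizes_zyx, dtype=np.float64) / UPSCALE
    origin = np.asarray(origin_zyx, dtype=np.float64)
    skeleton_voxels = np.asarray(skeleton_voxels)
    g = nx.Graph()
    flags: list[str] = []
    if skeleton_voxels.shape[0] == 0:
        return SkeletonGraph(
            graph=g,
            n_skeletons=0,
            n_branches=0,
            tree_length=0.0,
            endpoints=[],
            largest_nodes=set(),
            node_position_um={},
            flags=["empty_skeleton"],
        )

    voxset = {tuple(v) for v in skeleton_voxels.tolist()}
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    g.add_nodes_from(voxset)
    for v in voxset:
        for off in offsets:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in voxset and v < w:
                dist = float(np.linalg.norm(np.asarray(off) * spacing))
                g.add_edge(v, w, weight=dist)

    components = list(nx.connected_components(g))
    trees = []
    for comp in components:
        sub = g.subgraph(comp)
        mst = nx.minimum_spanning_tree(sub, weight="weight")
        length = float(sub.size(weight="weight")) if mst.number_of_edges() == 0 else float(
            mst.size(weight="weight")
        )
        trees.append((length, mst, comp))
    trees.sort(key=lambda item: (-item[0], sorted(item[2])[0]))
    tree_length, largest_mst, largest = trees[0]

    endpoints = sorted(n for n, d in largest_mst.degree if d == 1)
    if largest_mst.number_of_nodes() == 1:
        endpoints = sorted(largest)
        flags.append("single_voxel_skeleton")

    positions = {}
    for node in g.nodes:
        zyx = origin * np.asarray(voxel_sizes_zyx) + (np.asarray(node) + 0.5) * spacing
        positions[node] = zyx[::-1].copy()  # store as (x, y, z)

    return SkeletonGraph(
        graph=g,
        n_skeletons=len(components),
        n_branches=_branch_count(largest_mst),
        tree_length=tree_length,
        endpoints=endpoints,
        largest_nodes=set(largest),
        node_position_um=positions,
        flags=flags,
    )


def largest_shortest_path(skel: SkeletonGraph) -> CenterlinePath:
    """Select the centerline as the longest among all endpoint-pair
    shortest paths on the largest skeleton.

    Ties are broken by the lexicographically smallest endpoint pair, so
    repeated runs return the same path.
    """
    if skel.n_skeletons == 0:
        raise ValueError("empty skeleton has no centerline")
    if len(skel.endpoints) == 1 or len(skel.largest_nodes) == 1:
        node = skel.endpoints[0]
        return CenterlinePath(
            points=skel.node_position_um[node][None, :],
            arc_length=np.array([0.0]),
            flags=["degenerate_single_point"],
        )
    sub = skel.graph.subgraph(skel.largest_nodes)
    best: tuple[float, tuple, tuple] | None = None
    best_path: list | None = None
    for i, src in enumerate(skel.endpoints):
        dists, paths = nx.single_source_dijkstra(sub, src, weight="weight")
        for dst in skel.endpoints[i + 1 :]:
            if dst not in dists:
                continue
            key = (-dists[dst], src, dst)
            if best is None or key < best:
                best = key
                best_path = paths[dst]
    if best_path is None:  # endpoints exist but unreachable: fall back
        best_path = [skel.endpoints[0]]
    points = np.array([skel.node_position_um[n] for n in best_path])
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    return CenterlinePath(points=points, arc_length=arc)


def orient_path(
    path: CenterlinePath, basal_centroid: np.ndarray | None = None
) -> CenterlinePath:
    """Orient the centerline base → tip using a basal-stain centroid.

    The path end nearer to the basal centroid becomes the first point.
    Without a basal stain the deterministic fallback ordering (endpoint
    with the smaller (z, y, x) tuple first) is kept and the path flagged
    ``unoriented`` — consumers then know the orientation-vector sign is
    arbitrary.
    """
    if basal_centroid is None:
        out = CenterlinePath(
            points=path.points.copy(),
            arc_length=path.arc_length.copy(),
            oriented=False,
            flags=list(path.flags) + ["unoriented"],
        )
        return out
    basal = np.asarray(basal_centroid, dtype=np.float64)
    d_first = float(np.linalg.norm(path.points[0] - basal))
    d_last = float(np.linalg.norm(path.points[-1] - basal))
    if np.isclose(d_first, d_last):
        out = CenterlinePath(
            points=path.points.copy(),
            arc_length=path.arc_length.copy(),
            oriented=False,
            flags=list(path.flags) + ["orientation_tie"],
        )
        return out
    out = path.reversed() if d_last < d_first else CenterlinePath(
        points=path.points.copy(), arc_length=path.arc_length.copy(), flags=list(path.flags)
    )
    out.oriented = True
    return out


def extract_centerline(
    cilium: CiliumObject,
    image: CalibratedImage,
    timepoint: int,
    sigma_xy: float = 1.0,
    sigma_z: float = 0.0,
    basal_centroid: np.ndarray | None = None,
) -> tuple[SkeletonGraph, CenterlinePath | None]:
    """Full chain: render → upscale → blur → thin → analyze → path → orient."""
    volume, origin = object_volume_image(cilium, timepoint)
    up = upscale_threefold(volume)
    blurred = blur_for_skeleton(up, sigma_xy, sigma_z)
    skel_vox = thin_3d(blurred, binarize_at=128.0)
    graph = analyze_skeleton(skel_vox, image.voxel_sizes_zyx, origin_zyx=origin)
    if graph.n_skeletons == 0:
        return graph, None
    path = largest_shortest_path(graph)
    path = orient_path(path, basal_centroid)
    return graph, path
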