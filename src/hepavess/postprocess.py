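"""Cost-based connection of predicted vessel fragments into one tree.

Voxelwise vessel predictions — from a segmentation network or any other
probabilistic detector — are typically fragmented: thin arteries drop below
threshold at contrast dips, leaving islands.  The post-processing implemented
here reconstructs a single connected vessel tree:

1. combine a *fine* (sensitive, 0.8 mm grid) and a *coarse* (large-vessel,
   2.0 mm grid) probability map by voxelwise maximum on the fine grid;
2. threshold to a binary mask;
3. pick a root point: the skeleton voxel with the largest associated radius
   in the large-vessel output, which in an abdominal scan is practically
   always inside the aorta;
4. connect every 26-connected component to the root via the cheapest path
   under edge weights derived from the *inverse* raw probability, and prune
   components whose connection cost exceeds ``max_cost``.

The edge weight between neighbouring voxels u, v is
``(1 − (p(u) + p(v))/2) · |u − v|_mm``: free through confident vessel
voxels, expensive through background, and resolution-robust because it
scales with the physical step length.  Paths may traverse voxels outside
the binary mask — that is what lets the algorithm bridge genuine gaps.
``max_cost`` is the pruning dial: too small and true intrahepatic branches
are discarded when the trunk prediction has a gap; larger values restore
them at the risk of attaching bright false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .errors import EmptyInputError, GeometryError, ParameterError, SeedError
from .volume import Mask, Volume, resample

__all__ = [
    "Skeleton",
    "ConnectionReport",
    "ComponentRecord",
    "combine_model_outputs",
    "skeletonize_with_radii",
    "select_root",
    "connect_to_root",
    "postprocess",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Skeleton:
    """Centerline voxels of a mask, each with a local radius estimate.

    Radii come from the Euclidean distance transform of the source mask
    (spacing-aware, in mm), i.e. the distance to the nearest boundary.
    """

    voxels: np.ndarray  # (n, 3) int voxel indices
    radii: np.ndarray  # (n,) mm
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass
class ComponentRecord:
    component_id: int
    size: int
    cost: float
    kept: bool
    is_root: bool = False


@dataclass
class ConnectionReport:
    """Per-component connection costs and pruning decisions."""

    components: list[ComponentRecord]
    max_cost: float

    def kept_ids(self) -> list[int]:
        return [c.component_id for c in self.components if c.kept]


def combine_model_outputs(fine: Volume, coarse: Volume) -> Volume:
    """Voxelwise maximum of the two model outputs on the fine grid.

    The coarse map is linearly resampled onto the fine grid first.  The
    fine model contributes thin, sensitive fragments; the coarse model
    contributes reliable large vessels (aorta, trunk).
    """
    f_ext = np.asarray(fine.origin) + np.asarray(fine.shape) * np.asarray(fine.spacing)
    c_ext = np.asarray(coarse.origin) + np.asarray(coarse.shape) * np.asarray(coarse.spacing)
    if np.any(np.asarray(coarse.origin) >= f_ext) or np.any(np.asarray(fine.origin) >= c_ext):
        raise GeometryError("fine and coarse maps cover disjoint physical extents")
    if coarse.same_grid(fine):
        c_data = coarse.data
    else:
        c_on_fine = resample(coarse, fine.spacing, order=1)
        c_data = np.zeros(fine.shape, dtype=np.float32)
        sl = tuple(slice(0, min(a, b)) for a, b in zip(fine.shape, c_on_fine.shape))
        c_data[sl] = c_on_fine.data[sl]
    return Volume(
        np.maximum(fine.data, c_data).astype(np.float32), fine.spacing, fine.origin
    )


def skeletonize_with_radii(m: Mask) -> Skeleton:
    """3D-thinning skeleton of a mask with per-voxel radius in mm."""
    if not m.data.any():
        raise EmptyInputError("cannot skeletonize an empty mask")
    skel = skeletonize(m.data.astype(bool))
    if not skel.any():  # thinning can erase single-voxel masks
        skel = m.data.astype(bool)
    dist = ndimage.distance_transform_edt(m.data > 0, sampling=m.spacing)
    voxels = np.argwhere(skel)
    return Skeleton(
        voxels=voxels,
        radii=dist[tuple(voxels.T)].astype(float),
        shape=m.shape,
        spacing=m.spacing,
    )


def select_root(s: Skeleton) -> tuple[int, int, int]:
    """Skeleton voxel with the largest radius; ties by smallest linear index.

    In practice this lands in the aorta — the thickest bright structure —
    and serves as the Dijkstra target for fragment connection.
    """
    if len(s) == 0:
        raise EmptyInputError("cannot select a root from an empty skeleton")
    linear = np.ravel_multi_index(tuple(s.voxels.T), s.shape)
    best = np.flatnonzero(s.radii == s.radii.max())
    winner = best[np.argmin(linear[best])]
    return tuple(int(c) for c in s.voxels[winner])


def _grid_graph(prob: np.ndarray, spacing) -> sparse.csr_matrix:
    """Sparse undirected 26-neighbourhood graph with inverse-probability weights."""
    shape = prob.shape
    n = prob.size
    p = np.clip(prob, 0.0, 1.0).astype(np.float32).ravel()
    idx = np.arange(n, dtype=np.int64).reshape(shape)
    spacing = np.asarray(spacing, dtype=float)
    rows, cols, data = [], [], []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    # half the offsets suffice for an undirected graph
    offsets = [o for o in offsets if o > (0, 0, 0)]
    for off in offsets:
        step = float(np.linalg.norm(spacing * np.asarray(off)))
        src_sl = tuple(
            slice(None, -d) if d > 0 else slice(-d, None) if d < 0 else slice(None)
            for d in off
        )
        dst_sl = tuple(
            slice(d, None) if d > 0 else slice(None, d) if d < 0 else slice(None)
            for d in off
        )
        u = idx[src_sl].ravel()
        v = idx[dst_sl].ravel()
        w = (1.0 - 0.5 * (p[u] + p[v])) * step
        rows.append(u)
        cols.append(v)
        data.append(np.maximum(w, 0.0))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data).astype(np.float32)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def connect_to_root(
    raw: Volume, binary: Mask, root: tuple[int, int, int], max_cost: float
) -> tuple[Mask, ConnectionReport]:
    """Connect every component of ``binary`` to the root or prune it.

    For each 26-connected component the cheapest path from any of its
    voxels to the root's component is found by Dijkstra on the full voxel
    grid (paths may leave the mask).  Components whose cost is within
    ``max_cost`` are kept and their bridging path voxels added; the rest
    are removed.  The result is a single 26-connected component containing
    the root.
    """
    if max_cost < 0:
        raise ParameterError("max_cost must be >= 0")
    if not raw.same_grid(binary):
        raise GeometryError("raw probabilities and binary mask must share one grid")
    root = tuple(int(c) for c in root)
    if binary.data[root] == 0:
        raise SeedError(f"root voxel {root} lies outside the binary mask")

    labels, n_comp = ndimage.label(binary.data, structure=_STRUCT26)
    root_label = labels[root]
    out = labels == root_label
    records = [
        ComponentRecord(
            int(root_label),
            int(np.sum(labels == root_label)),
            0.0,
            True,
            is_root=True,
        )
    ]
    other = [l for l in range(1, n_comp + 1) if l != root_label]
    if not other:
        return Mask.from_bool(out, binary.spacing, binary.origin), ConnectionReport(
            records, max_cost
        )

    graph = _grid_graph(raw.data, raw.spacing)
    sources = np.flatnonzero((labels == root_label).ravel())
    dist, pred, _ = dijkstra(
        graph,
        directed=False,
        indices=sources,
        min_only=True,
        return_predecessors=True,
    )
    flat_labels = labels.ravel()
    for lab in other:
        vox = np.flatnonzero(flat_labels == lab)
        local = np.argmin(dist[vox])
        cost = float(dist[vox[local]])
        kept = cost <= max_cost
        records.append(ComponentRecord(int(lab), len(vox), cost, kept))
        if kept:
            out |= labels == lab
            node = int(vox[local])  # walk the predecessor chain to the root set
            path = []
            while node >= 0:
                path.append(node)
                node = int(pred[node])
            out.ravel()[path] = True
    return Mask.from_bool(out, binary.spacing, binary.origin), ConnectionReport(
        records, max_cost
    )


def postprocess(
    fine: Volume,
    coarse: Volume | None,
    threshold: float = 0.5,
    max_cost: float = 10.0,
) -> tuple[Mask, ConnectionReport]:
    """Full post-processing chain: combine → threshold → root → connect.

    The root is selected from the skeleton of the thresholded *coarse*
    (large-vessel) output; when no coarse map is supplied the joined map is
    used as fallback.  Deterministic.
    """
    if not (0 <= threshold <= 1):
        raise ParameterError("threshold must lie in [0, 1]")
    combined = fine if coarse is None else combine_model_outputs(fine, coarse)
    binary = Mask.from_bool(combined.data >= threshold, combined.spacing, combined.origin)
    if not binary.data.any():
        raise EmptyInputError("no voxel reaches the probability threshold")
    if coarse is not None:
        c_on_fine = combine_model_outputs(
            Volume(np.zeros(combined.shape, np.float32), combined.spacing, combined.origin),
            coarse,
        )
        root_mask = Mask.from_bool(
            c_on_fine.data >= threshold, combined.spacing, combined.origin
        )
        if not root_mask.data.any():
            root_mask = binary
    else:
        root_mask = binary
    root = select_root(skeletonize_with_radii(root_mask))
    if binary.data[root] == 0:  # coarse skeleton voxel can thin off the joint mask
        root_candidates = np.argwhere(binary.data)
        d = np.linalg.norm(
            (root_candidates - np.asarray(root)) * np.asarray(binary.spacing), axis=1
        )
        root = tuple(int(c) for c in root_candidates[np.argmin(d)])
    return connect_to_root(combined, binary, root, max_cost)
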