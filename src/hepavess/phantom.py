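"""Synthetic arterial-phase abdominal CT phantoms with ground truth.

A phantom emulates the structures that matter for hepatic-artery (HA)
segmentation: a bright vertical aorta, a celiac trunk branching into left
and right hepatic arteries with recursively tapering sub-branches down to
the small calibers typical of the HA (≈ 2.5 mm radius and below), a liver
region enclosing the intrahepatic branches, and — optionally — the bright
confounders that intensity-driven pipelines are known to pick up: a vein
running parallel to a hepatic branch, a kidney-like blob touching the
aorta, and an isolated gallstone-like speck.

Everything is a pure function of :class:`PhantomParams` including its seed,
so benchmark sets are bit-reproducible.  Vessels are straight (optionally
sinusoidally perturbed) swept tubes, which keeps analytic volume oracles
available for testing.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .volume import Mask, Volume

__all__ = [
    "VesselTree",
    "PhantomParams",
    "PhantomCase",
    "generate_tree",
    "rasterize_case",
    "generate_benchmark_set",
    "CONFOUNDER_LABELS",
]

#: labels used in PhantomCase.confounder_mask
CONFOUNDER_LABELS = {"vein": 1, "kidney": 2, "speck": 3}


@dataclass
class VesselTree:
    """Geometric branching model: nodes with position (mm) and radius (mm).

    ``edges`` are (parent, child) index pairs forming a tree rooted at
    ``root``; ``generation[i]`` counts binary branchings below the celiac
    trunk (aorta and trunk nodes are generation 0).
    """

    positions: np.ndarray  # (n, 3) world mm
    radii: np.ndarray  # (n,) mm
    edges: list[tuple[int, int]]
    root: int
    generation: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        n = len(self.positions)
        if len(self.edges) != n - 1:
            raise ParameterError("a tree must have |nodes| - 1 edges")
        if np.any(self.radii <= 0):
            raise ParameterError("all radii must be positive")
        for p, c in self.edges:
            if self.radii[c] > self.radii[p] + 1e-9:
                raise ParameterError("child radius must not exceed parent radius")

    @property
    def n_nodes(self) -> int:
        return len(self.positions)


@dataclass
class PhantomParams:
    """All knobs of the phantom; the seed makes every output deterministic."""

    shape: tuple[int, int, int] = (128, 128, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    aorta_radius: float = 9.0  # mm
    trunk_radius: float = 4.0  # mm
    depth: int = 3  # binary branching generations below the trunk
    branch_angle_range: tuple[float, float] = (25.0, 50.0)  # degrees
    taper: float = 0.7  # radius ratio per generation
    vessel_contrast: float = 200.0  # HU above parenchyma
    parenchyma_level: float = 60.0  # HU
    noise_sigma: float = 10.0  # HU, additive Gaussian after blur
    blur_fwhm: float = 1.0  # mm
    wiggle_amplitude: float = 0.0  # mm sinusoidal centerline perturbation
    confounders: tuple[str, ...] = ()
    norm_variant: bool = False  # one branch arises directly from the trunk
    with_tumor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ParameterError("branching depth must be >= 1")
        if not (0 < self.taper <= 1):
            raise ParameterError("taper ratio must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ParameterError("noise sigma must be >= 0")
        if self.trunk_radius * self.taper**self.depth < 0.1:
            raise ParameterError(
                "depth/taper drive branch radii below 0.1 mm; reduce depth"
            )
        unknown = set(self.confounders) - set(CONFOUNDER_LABELS)
        if unknown:
            raise ParameterError(f"unknown confounders: {sorted(unknown)}")

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


@dataclass
class PhantomCase:
    """One synthetic case: image, ground truth, and provenance."""

    image: Volume
    vessel_mask: Mask
    centerline_mask: Mask
    radius_map: Volume  # mm at centerline voxels, 0 elsewhere
    liver_mask: Mask
    tumor_mask: Mask | None
    confounder_mask: Volume  # labels per CONFOUNDER_LABELS, 0 elsewhere
    tree: VesselTree
    params: PhantomParams
    seed: int


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about unit axis by angle (radians)."""
    axis = axis / np.linalg.norm(axis)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * np.dot(axis, v) * (1 - math.cos(angle))
    )


def generate_tree(p: PhantomParams) -> VesselTree:
    """Build the aorta / celiac trunk / hepatic-artery tree for a phantom.

    The aorta is a vertical (z-axis) segment; the celiac trunk leaves it
    laterally and splits into left and right hepatic arteries, each
    branching recursively for ``p.depth`` generations with radius tapering
    by ``p.taper`` per generation.  In norm-variant mode one
    first-generation branch is rerouted to originate directly at the celiac
    trunk's takeoff instead of its tip, mimicking the common anatomical
    variant in which a tumor-feeding artery arises from the trunk itself.
    """
    rng = np.random.default_rng(p.seed)
    ex, ey, ez = p.extent

    positions: list[np.ndarray] = []
    radii: list[float] = []
    edges: list[tuple[int, int]] = []
    generation: list[int] = []

    def add_node(pos, radius, gen, parent=None) -> int:
        positions.append(np.asarray(pos, dtype=float))
        radii.append(float(radius))
        generation.append(int(gen))
        idx = len(positions) - 1
        if parent is not None:
            edges.append((parent, idx))
        return idx

    ax, ay = 0.22 * ex, 0.50 * ey
    root = add_node((ax, ay, 0.08 * ez), p.aorta_radius, 0)
    a_mid = add_node((ax, ay, 0.50 * ez), p.aorta_radius, 0, root)
    add_node((ax, ay, 0.92 * ez), p.aorta_radius, 0, a_mid)

    # celiac trunk: leaves the aorta laterally toward the liver (+x)
    trunk_dir = np.array([1.0, 0.0, 0.0])
    trunk_len = 0.18 * ex
    trunk_tip = add_node(
        positions[a_mid] + trunk_dir * trunk_len, p.trunk_radius, 0, a_mid
    )

    lo, hi = np.deg2rad(p.branch_angle_range)
    base_len = 0.22 * ex

    def grow(parent_idx: int, direction: np.ndarray, gen: int) -> None:
        if gen > p.depth:
            return
        radius = p.trunk_radius * p.taper**gen
        length = base_len * 0.75 ** (gen - 1)
        for sign in (+1, -1):
            angle = sign * rng.uniform(lo, hi)
            # rotation axis tilts out of plane so branches fill 3D
            axis = np.array([0.0, math.sin(rng.uniform(-0.6, 0.6)), 1.0])
            d = _rotate(direction, axis, angle)
            d[0] = abs(d[0]) + 0.2  # keep heading into the liver half-space
            d = d / np.linalg.norm(d)
            child = add_node(
                positions[parent_idx] + d * length, radius, gen, parent_idx
            )
            grow(child, d, gen + 1)

    grow(trunk_tip, trunk_dir, 1)

    if p.norm_variant:
        # reroute the last first-generation branch to the trunk takeoff
        gen1 = [i for i, g in enumerate(generation) if g == 1]
        if gen1:
            moved = gen1[-1]
            edges[:] = [
                (a_mid, c) if c == moved else (par, c) for par, c in edges
            ]
            shift = positions[a_mid] - positions[trunk_tip]
            # translate the rerouted subtree so it stays attached
            stack, sub = [moved], []
            children = {}
            for par, c in edges:
                children.setdefault(par, []).append(c)
            while stack:
                i = stack.pop()
                sub.append(i)
                stack.extend(children.get(i, []))
            for i in sub:
                positions[i] = positions[i] + shift * 0.5

    return VesselTree(
        positions=np.asarray(positions),
        radii=np.asarray(radii),
        edges=edges,
        root=root,
        generation=np.asarray(generation),
    )


def _segment_points(p0, p1, step, wiggle, phase):
    """Points along a segment, optionally sinusoidally perturbed."""
    length = np.linalg.norm(p1 - p0)
    n = max(2, int(math.ceil(length / step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    if wiggle > 0 and length > 0:
        d = (p1 - p0) / length
        perp = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        pts = pts + (wiggle * np.sin(2 * math.pi * t + phase))[:, None] * perp[None, :]
    return pts, t


def _paint_tube(inside, radius_at, vol_shape, spacing, pts, radii):
    """Mark voxels within the local radius of a polyline (dense sweep)."""
    spacing = np.asarray(spacing)
    rmax = float(np.max(radii))
    lo = np.maximum(np.floor((pts.min(0) - rmax) / spacing).astype(int) - 1, 0)
    hi = np.minimum(
        np.ceil((pts.max(0) + rmax) / spacing).astype(int) + 2, np.asarray(vol_shape)
    )
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(
        *[np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)], indexing="ij"
    )
    box = np.stack([g.ravel() for g in grids], axis=1)  # (m, 3) voxel centres mm
    best = np.full(len(box), np.inf)
    best_r = np.zeros(len(box))
    for a, b, ra, rb in zip(pts[:-1], pts[1:], radii[:-1], radii[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            continue
        t = np.clip((box - a) @ ab / denom, 0.0, 1.0)
        closest = a[None, :] + t[:, None] * ab[None, :]
        d = np.linalg.norm(box - closest, axis=1)
        r = ra + t * (rb - ra)
        upd = d - r < best - best_r
        best[upd] = d[upd]
        best_r[upd] = r[upd]
    hit = best <= best_r
    idx = np.unravel_index(np.nonzero(hit)[0], tuple(hi - lo))
    inside[tuple(i + l for i, l in zip(idx, lo))] = True
    if radius_at is not None:
        pass  # radius map is painted along centerlines, not tubes


def _ellipsoid_mask(shape, spacing, center, semi_axes):
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def rasterize_case(tree: VesselTree, p: PhantomParams) -> PhantomCase:
    """Rasterize a vessel tree into a full CT-like phantom case.

    A voxel belongs to the vessel mask iff its centre lies within the local
    radius of a swept segment.  The centerline mask voxelizes the node-path
    polylines; the radius map carries the local radius at those voxels.
    The image is parenchyma + contrast inside vessels (and confounders),
    Gaussian-blurred to the configured FWHM, with seeded additive Gaussian
    noise.  The liver is a smooth ellipsoid enclosing the intrahepatic
    subtree, so intrahepatic centerline voxels always lie inside it.
    """
    extent = p.extent
    if np.any(tree.positions < 0) or np.any(tree.positions >= extent[None, :]):
        raise GeometryError("vessel tree does not fit inside the grid's extent")

    shape = tuple(p.shape)
    spacing = tuple(p.spacing)
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0xC0FFEE]))

    vessel = np.zeros(shape, dtype=bool)
    center = np.zeros(shape, dtype=bool)
    radmap = np.zeros(shape, dtype=np.float32)
    step = 0.25 * min(spacing)
    min_radius = 0.5 * min(spacing)  # ground-truth radii never below half a voxel

    for ei, (a, b) in enumerate(tree.edges):
        p0, p1 = tree.positions[a], tree.positions[b]
        r0 = max(tree.radii[a], min_radius)
        r1 = max(tree.radii[b], min_radius)
        pts, t = _segment_points(p0, p1, step, p.wiggle_amplitude, phase=ei)
        radii = r0 + t * (r1 - r0)
        _paint_tube(vessel, None, shape, spacing, pts, radii)
        idx = np.rint(pts / np.asarray(spacing)).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        center[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        cur = radmap[idx[:, 0], idx[:, 1], idx[:, 2]]
        radmap[idx[:, 0], idx[:, 1], idx[:, 2]] = np.maximum(cur, radii)

    center &= vessel  # rounding at tube tips must not escape the mask
    radmap[~center] = 0.0

    # liver: convex ellipsoid covering every node below the first branching,
    # hence (by convexity) every intrahepatic segment
    intra = tree.positions[tree.generation >= 1]
    margin = 10.0
    lo, hi = intra.min(0) - margin, intra.max(0) + margin
    liver_center = (lo + hi) / 2
    liver_axes = np.maximum((hi - lo) / 2, 12.0)
    liver = _ellipsoid_mask(shape, spacing, liver_center, liver_axes)

    confounder = np.zeros(shape, dtype=np.uint8)
    if "vein" in p.confounders:
        gen1 = [(a, b) for a, b in tree.edges if tree.generation[b] == 1]
        if gen1:
            a, b = gen1[0]
            p0, p1 = tree.positions[a], tree.positions[b]
            d = (p1 - p0) / np.linalg.norm(p1 - p0)
            perp = np.cross(d, [0.0, 0.0, 1.0])
            perp /= np.linalg.norm(perp)
            r_vein = 2.5
            offset = perp * (tree.radii[b] + r_vein + 2.5)
            pts = np.stack([p0 + offset + d * 2.0, p1 + offset + d * 12.0])
            pts = np.clip(pts, 1.0, extent - 1.0)
            vein = np.zeros(shape, dtype=bool)
            _paint_tube(vein, None, shape, spacing, pts, np.full(2, r_vein))
            confounder[vein & ~vessel] = CONFOUNDER_LABELS["vein"]
    if "kidney" in p.confounders:
        a_pos = tree.positions[tree.root]
        c = np.clip(
            a_pos + np.array([0.0, p.aorta_radius + 9.0, 18.0]), 0, extent - 1
        )
        kidney = _ellipsoid_mask(shape, spacing, c, (11.0, 10.0, 15.0))
        confounder[kidney & ~vessel] = CONFOUNDER_LABELS["kidney"]
    if "speck" in p.confounders:
        c = np.clip(liver_center + np.array([0.0, liver_axes[1] * 0.6, 0.0]),
                    1.0, extent - 1.0)
        speck = _ellipsoid_mask(shape, spacing, c, (1.6, 1.6, 1.6))
        confounder[speck & ~vessel] = CONFOUNDER_LABELS["speck"]

    tumor = None
    if p.with_tumor:
        leaf = tree.positions[tree.generation == tree.generation.max()][-1]
        c = np.clip(leaf + np.array([4.0, 4.0, 0.0]), 1.0, extent - 1.0)
        tumor = Mask.from_bool(
            _ellipsoid_mask(shape, spacing, c, (6.0, 6.0, 6.0)), spacing
        )

    image = np.full(shape, p.parenchyma_level, dtype=np.float32)
    image[vessel] += p.vessel_contrast
    image[confounder > 0] += p.vessel_contrast
    if p.blur_fwhm > 0:
        sigma_vox = (p.blur_fwhm / 2.3548) / np.asarray(spacing)
        image = ndimage.gaussian_filter(image, sigma=sigma_vox)
    if p.noise_sigma > 0:
        image = image + rng.normal(0.0, p.noise_sigma, size=shape).astype(np.float32)

    return PhantomCase(
        image=Volume(image.astype(np.float32), spacing),
        vessel_mask=Mask.from_bool(vessel, spacing),
        centerline_mask=Mask.from_bool(center, spacing),
        radius_map=Volume(radmap, spacing),
        liver_mask=Mask.from_bool(liver, spacing),
        tumor_mask=tumor,
        confounder_mask=Volume(confounder, spacing),
        tree=tree,
        params=p,
        seed=p.seed,
    )


def generate_case(p: PhantomParams) -> PhantomCase:
    """Convenience: generate_tree + rasterize_case."""
    return rasterize_case(generate_tree(p), p)


def generate_benchmark_set(
    n: int, p: PhantomParams, seed: int
) -> tuple[list[PhantomCase], dict]:
    """Generate ``n`` reproducible cases with per-case seeds from ``seed``.

    Returns the cases and a manifest recording every parameter, mirroring a
    multi-case clinical test set at phantom scale.
    """
    if n < 1:
        raise ParameterError("need at least one case")
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(n)]
    cases = []
    manifest = {"master_seed": int(seed), "n": int(n), "cases": []}
    for i, cs in enumerate(case_seeds):
        variant = (i % 3 == 2)  # roughly one third anatomical norm variants
        pi = replace(p, seed=cs, norm_variant=variant or p.norm_variant)
        cases.append(generate_case(pi))
        entry = asdict(pi)
        entry["case_id"] = f"case_{i:03d}"
        manifest["cases"].append(entry)
    return cases, manifest
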