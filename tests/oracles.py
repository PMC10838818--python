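"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: shortest paths are
computed by exhaustive Bellman-Ford-style relaxation sweeps, ball counts by
direct lattice enumeration, and the signed-rank null by enumerating all
sign assignments.
"""

from __future__ import annotations

import itertools

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def relaxation_shortest_paths(
    prob: np.ndarray, spacing, sources: np.ndarray
) -> np.ndarray:
    """All-voxel shortest-path costs from a source set by exhaustive
    relaxation sweeps (edge weight: mean inverse probability x step mm)."""
    p = np.clip(np.asarray(prob, dtype=np.float64), 0, 1)
    spacing = np.asarray(spacing, dtype=float)
    dist = np.full(p.shape, np.inf)
    dist[tuple(np.asarray(sources).T)] = 0.0
    while True:
        prev = dist.copy()
        for off in OFFSETS_26:
            step = float(np.linalg.norm(spacing * np.asarray(off)))
            src = tuple(
                slice(None, -d) if d > 0 else slice(-d, None) if d < 0 else slice(None)
                for d in off
            )
            dst = tuple(
                slice(d, None) if d > 0 else slice(None, d) if d < 0 else slice(None)
                for d in off
            )
            w = (1.0 - 0.5 * (p[src] + p[dst])) * step
            cand = dist[src] + w
            dist[dst] = np.minimum(dist[dst], cand)
            cand = dist[dst] + w
            dist[src] = np.minimum(dist[src], cand)
        if np.allclose(prev, dist, rtol=0, atol=1e-12, equal_nan=True):
            return dist


def ball_lattice_count(radius: float, spacing) -> int:
    """Number of lattice points with physical distance <= radius."""
    spacing = np.asarray(spacing, dtype=float)
    r = np.ceil(radius / spacing).astype(int)
    count = 0
    for idx in itertools.product(*[range(-m, m + 1) for m in r]):
        if np.sum((np.asarray(idx) * spacing) ** 2) <= radius**2 + 1e-12:
            count += 1
    return count


def exact_signed_rank_pvalue(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    n = len(d)
    w_plus = ranks[d > 0].sum()
    w_obs = min(w_plus, ranks.sum() - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if min(wp, ranks.sum() - wp) <= w_obs + 1e-12:
            count += 1
    return count / 2**n
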