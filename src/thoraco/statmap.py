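"""Per-triangle two-group comparison maps (exact Wilcoxon-Mann-Whitney).

For each triangle of the shared mesh topology, a per-subject scalar (the
mean absolute modulus of its three vertices) is compared between two
groups with the exact two-sided rank-sum test. Triangles below the alpha
threshold are painted red where group 1 moves more on average and blue
where group 2 does; the map lives on an averaged, centered model of all
subjects. No multiplicity correction is applied by default (the analysis
is exploratory, one test per triangle); Benjamini-Hochberg FDR is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb, erfc, sqrt

import numpy as np

from .mesh import TriangleMesh
from .vector_field import VectorField

EXACT_LIMIT = 20  # exact permutation distribution up to this combined n


class StatMapError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Exact Mann-Whitney (rank-sum form)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _ranksum_counts(n: int, ranks2: tuple[int, ...]) -> np.ndarray:
    """Number of n-subsets of the doubled mid-ranks ``ranks2`` achieving
    each possible rank sum (index = sum of doubled ranks). Subset-sum DP;
    this is the exact permutation distribution of the rank-sum statistic
    and handles ties through the doubled mid-ranks."""
    total = sum(ranks2)
    dp = np.zeros((n + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        dp[1:, r:] = dp[1:, r:] + dp[:-1, :total + 1 - r]
    return dp[n]


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mwu_exact(x, y) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact (permutation distribution of the rank sum, mid-rank ties,
    doubled smaller tail capped at 1) when n + m <= 20; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise StatMapError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n].sum())

    if n + m <= EXACT_LIMIT:
        ranks2 = tuple(sorted(int(round(2 * r)) for r in ranks))
        counts = _ranksum_counts(n, ranks2)
        total = comb(n + m, n)
        w2 = int(round(2 * w))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        return float(min(1.0, 2.0 * min(p_le, p_ge)))

    # normal approximation with tie correction
    N = n + m
    mean = n * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    d = w - mean
    d = d - 0.5 * np.sign(d)  # continuity correction toward the mean
    z = d / sqrt(var)
    return float(min(1.0, erfc(abs(z) / sqrt(2.0))))


# ---------------------------------------------------------------------------
# Triangle statistics and maps
# ---------------------------------------------------------------------------

def triangle_magnitudes(vf: VectorField) -> np.ndarray:
    """Per-triangle scalar: mean of the three vertices' |modulus| (cm)."""
    return np.abs(vf.modulus_cm)[vf.faces].mean(axis=1)


def average_model(meshes: list[TriangleMesh]) -> TriangleMesh:
    """Vertex-wise mean of topologically identical meshes, each centered
    first (centroid of the reference-level-row markers at the origin, or
    of all original markers when level rows are not recorded)."""
    if not meshes:
        raise StatMapError("no meshes to average")
    ref = meshes[0]
    for m in meshes[1:]:
        if not ref.same_topology(m):
            raise StatMapError("meshes have mismatched topology")
    acc = np.zeros_like(ref.vertices)
    for m in meshes:
        ids = m.provenance.get("level_marker_vertex_ids")
        if ids:
            sel = np.array(sorted({i for v in ids.values() for i in v}), dtype=int)
        else:
            origin = m.provenance.get("origin_ids")
            sel = (np.fromiter(origin.values(), dtype=int)
                   if origin else np.arange(m.n_vertices))
        acc += m.vertices - m.vertices[sel].mean(axis=0)
    return TriangleMesh(acc / len(meshes), ref.faces.copy(),
                        {"averaged_from": len(meshes)})


@dataclass
class SignificanceMap:
    base_mesh: TriangleMesh
    p_values: np.ndarray            # per triangle, in (0, 1]
    direction: np.ndarray           # per triangle: +1 group1>, -1 group2>, 0 none
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.direction != 0

    def fraction_significant(self) -> float:
        return float(np.mean(self.direction != 0))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def significance_map(group1: list[VectorField], group2: list[VectorField],
                     alpha: float = 0.05, fdr: bool = False,
                     base_meshes: list[TriangleMesh] | None = None
                     ) -> SignificanceMap:
    """Per-triangle exact MWU comparison of two groups' displacement maps.

    Samples are per-subject triangle magnitudes; direction compares group
    mean magnitudes. ``base_meshes`` (one start mesh per subject) builds
    the averaged uncolored model; when omitted, start meshes are rebuilt
    from the fields.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise StatMapError("need at least 2 subjects per group")
    faces = group1[0].faces
    for f in group1 + group2:
        if f.faces.shape != faces.shape or not np.array_equal(f.faces, faces):
            raise StatMapError("fields have mismatched topology")
    m1 = np.stack([triangle_magnitudes(f) for f in group1])  # (n1, T)
    m2 = np.stack([triangle_magnitudes(f) for f in group2])

    ntri = m1.shape[1]
    p = np.empty(ntri)
    for t in range(ntri):
        p[t] = mwu_exact(m1[:, t], m2[:, t])
    p_eff = _bh_adjust(p) if fdr else p

    direction = np.zeros(ntri, dtype=int)
    sig = p_eff < alpha
    diff = m1.mean(axis=0) - m2.mean(axis=0)
    direction[sig & (diff > 0)] = 1
    direction[sig & (diff < 0)] = -1

    if base_meshes is None:
        base_meshes = [
            TriangleMesh(f.start_points.copy(), f.faces.copy())
            for f in group1 + group2
        ]
    base = average_model(base_meshes)
    return SignificanceMap(base_mesh=base, p_values=p, direction=direction,
                           alpha=alpha)
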