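import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from thoraco import (TriangleMesh, average_model, mwu_exact,
                     significance_map, triangle_magnitudes)
from thoraco.statmap import StatMapError, _midranks
from thoraco.vector_field import VectorField


def _enumeration_p(x, y):
    """Exhaustive oracle: two-sided p over all group-1 label assignments."""
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n)]
    total = len(sums)
    p_le = sum(1 for s in sums if s <= w_obs + 1e-9) / total
    p_ge = sum(1 for s in sums if s >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def test_worked_values():
    assert mwu_exact([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
    assert mwu_exact([1, 2, 3, 4], [5, 6, 7, 8]) == pytest.approx(2 / 70)
    assert mwu_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == pytest.approx(2 / 252)


def test_symmetry_and_bounds():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        p = mwu_exact(x, y)
        assert 0 < p <= 1
        assert mwu_exact(y, x) == pytest.approx(p)


def test_matches_exhaustive_enumeration_small_samples():
    rng = np.random.default_rng(1)
    cases = 0
    while cases < 200:
        n = rng.integers(2, 6)
        m = rng.integers(2, 6)
        if n + m > 10:
            continue
        x = np.round(rng.normal(size=n), 1)  # rounding makes ties frequent
        y = np.round(rng.normal(size=m), 1)
        assert mwu_exact(x, y) == pytest.approx(_enumeration_p(x, y), abs=1e-12)
        cases += 1


def test_matches_scipy_exact_no_ties():
    rng = np.random.default_rng(2)
    for _ in range(50):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert mwu_exact(x, y) == pytest.approx(ref, abs=1e-12)


def test_large_sample_normal_approximation_close_to_scipy():
    rng = np.random.default_rng(3)
    x = rng.normal(size=15)
    y = rng.normal(0.5, 1.0, size=16)
    ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    assert mwu_exact(x, y) == pytest.approx(ref, rel=1e-6)


def test_empty_group_rejected():
    with pytest.raises(StatMapError):
        mwu_exact([], [1, 2])


def _field_from(mesh, scale, subject=""):
    moved = TriangleMesh(mesh.vertices * scale, mesh.faces.copy())
    vec = moved.vertices - mesh.vertices
    return VectorField(
        start_points=mesh.vertices.copy(),
        end_points=moved.vertices.copy(),
        modulus_cm=np.linalg.norm(vec, axis=1) * 0.1,
        faces=mesh.faces.copy(),
        phase_pair="FRC:TLC",
        subject_id=subject,
    )


def test_triangle_magnitudes_mean_of_vertices(trunk0):
    vf = _field_from(trunk0, 1.05)
    mags = triangle_magnitudes(vf)
    assert mags.shape == (trunk0.n_faces,)
    k = 17
    expected = np.abs(vf.modulus_cm)[trunk0.faces[k]].mean()
    assert mags[k] == pytest.approx(expected)


def test_average_model_centers_and_averages(trunk0):
    shifted = TriangleMesh(trunk0.vertices + [100.0, -50.0, 30.0],
                           trunk0.faces.copy(), dict(trunk0.provenance))
    avg = average_model([trunk0, shifted])
    # translation is removed by centering, so the average equals the
    # centered original
    ids = trunk0.provenance["level_marker_vertex_ids"]
    sel = np.array(sorted({i for v in ids.values() for i in v}))
    centered = trunk0.vertices - trunk0.vertices[sel].mean(axis=0)
    np.testing.assert_allclose(avg.vertices, centered, atol=1e-9)


def test_significance_map_detects_group_difference(trunk0):
    g1 = [_field_from(trunk0, 1.10 + 0.001 * k) for k in range(5)]
    g2 = [_field_from(trunk0, 1.01 + 0.001 * k) for k in range(5)]
    smap = significance_map(g1, g2, alpha=0.05)
    # fully separated groups: the exact p is 2/252 < 0.05 everywhere
    assert smap.fraction_significant() == pytest.approx(1.0)
    assert np.all(smap.direction == 1)
    swapped = significance_map(g2, g1, alpha=0.05)
    assert np.all(swapped.direction == -1)


def test_significance_map_identical_groups_null(trunk0):
    g1 = [_field_from(trunk0, 1.05) for _ in range(5)]
    g2 = [_field_from(trunk0, 1.05) for _ in range(5)]
    smap = significance_map(g1, g2, alpha=0.05)
    # all samples tied: p = 1 everywhere
    assert smap.fraction_significant() == 0.0
    np.testing.assert_allclose(smap.p_values, 1.0)


def test_significance_map_requires_two_per_group(trunk0):
    f = _field_from(trunk0, 1.05)
    with pytest.raises(StatMapError):
        significance_map([f], [f, f], alpha=0.05)


def test_fdr_adjustment_never_more_significant(trunk0):
    rng = np.random.default_rng(5)
    g1 = [_field_from(trunk0, 1.0 + 0.1 * rng.random()) for _ in range(5)]
    g2 = [_field_from(trunk0, 1.0 + 0.1 * rng.random()) for _ in range(5)]
    raw = significance_map(g1, g2, alpha=0.2, fdr=False)
    adj = significance_map(g1, g2, alpha=0.2, fdr=True)
    assert adj.significant.sum() <= raw.significant.sum()
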