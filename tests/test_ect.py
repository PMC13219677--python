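"""Euler characteristic transform: complex construction, curves, kernel PCA.

The brute-force oracle below enumerates every cell of the dual cubical
complex explicitly (vertices per foreground voxel, edges/squares/cubes from
adjacent blocks), assigns each cell the maximum vertex height, and counts
the alternating sum cell by cell — entirely independent of the vectorised
closed-form path used by the implementation.
"""

import itertools

import numpy as np
import pytest

from ablaq.accs import ACCSVolume
from ablaq.ect import (
    anova_kernel,
    anova_kernel_matrix,
    build_complex,
    ect_transform,
    euler_curve,
    fibonacci_sphere,
    fit_shape_space,
    project,
)

from conftest import make_ball, make_ellipsoid


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_cells(vox):
    """Explicit cell list [(dim, [vertex index tuples])] of the dual complex."""
    fg = {tuple(p) for p in np.argwhere(vox)}
    cells = [(0, [v]) for v in fg]
    for v in fg:
        for o in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
            w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if w in fg:
                cells.append((1, [v, w]))
        for axes in [(0, 1), (0, 2), (1, 2)]:
            corners = []
            ok = True
            for da, db in itertools.product([0, 1], repeat=2):
                c = list(v)
                c[axes[0]] += da
                c[axes[1]] += db
                c = tuple(c)
                if c not in fg:
                    ok = False
                    break
                corners.append(c)
            if ok:
                cells.append((2, corners))
        corners = []
        ok = True
        for d in itertools.product([0, 1], repeat=3):
            c = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if c not in fg:
                ok = False
                break
            corners.append(c)
        if ok:
            cells.append((3, corners))
    return cells


def oracle_euler_curve(vox, direction, thresholds, spacing=1.0):
    centre = np.array(vox.shape) // 2
    cells = oracle_cells(vox)
    curve = np.zeros(len(thresholds))
    for dim, verts in cells:
        coords = (np.array(verts) - centre) * spacing
        value = (coords @ direction).max()
        present = value <= np.asarray(thresholds) + 1e-9
        curve += ((-1) ** dim) * present
    return curve


# ---------------------------------------------------------------------------
# complex construction


def test_single_voxel_counts():
    vox = np.zeros((8, 8, 8), np.uint8)
    vox[3, 3, 3] = 1
    cx = build_complex(ACCSVolume(vox))
    assert cx.counts == (1, 0, 0, 0)
    assert cx.euler_characteristic == 1


def test_solid_2x2x2_block():
    vox = np.zeros((8, 8, 8), np.uint8)
    vox[3:5, 3:5, 3:5] = 1
    cx = build_complex(ACCSVolume(vox))
    assert cx.counts == (8, 12, 6, 1)
    assert cx.euler_characteristic == 1


def test_solid_ball_chi_one(ball12):
    assert build_complex(ball12).euler_characteristic == 1


def test_hollow_shell_chi_two():
    ax = np.arange(32) - 16
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = x**2 + y**2 + z**2
    shell = (r2 <= 100) & (r2 >= 36)  # ~2+ voxel thick spherical shell
    cx = build_complex(ACCSVolume(shell.astype(np.uint8)))
    assert cx.euler_characteristic == 2


def test_chi_additive_over_separated_components():
    vox = np.zeros((16, 16, 16), np.uint8)
    vox[2:4, 2:4, 2:4] = 1
    vox[10:13, 10:13, 10:13] = 1
    cx = build_complex(ACCSVolume(vox))
    assert cx.euler_characteristic == 2


# ---------------------------------------------------------------------------
# Euler curves


def test_single_voxel_curve_steps_at_zero():
    vox = np.zeros((8, 8, 8), np.uint8)
    vox[4, 4, 4] = 1  # voxel centre at the origin
    cx = build_complex(ACCSVolume(vox))
    thr = np.array([-2.0, -0.5, 0.0, 0.5, 2.0])
    for d in [np.array([0, 0, 1.0]), np.array([1.0, 0, 0]),
              np.array([1, 1, 1.0]) / np.sqrt(3)]:
        curve = euler_curve(cx, d, thr)
        assert np.array_equal(curve, [0, 0, 1, 1, 1])


def test_final_sample_equals_total_chi(ball12):
    cx = build_complex(ball12)
    thr = np.linspace(-60, 60, 16)
    for d in fibonacci_sphere(5):
        assert euler_curve(cx, d, thr)[-1] == cx.euler_characteristic


def test_curves_match_brute_force_oracle():
    """Vectorised filtration equals explicit cell enumeration on >= 200
    random small masks x 10 directions at every threshold."""
    rng = np.random.default_rng(7)
    dirs = fibonacci_sphere(10)
    thr = np.linspace(-7.0, 7.0, 9)
    n_checked = 0
    for trial in range(220):
        side = int(rng.integers(2, 7))
        vox = (rng.random((side, side, side)) < rng.uniform(0.2, 0.8))
        if not vox.any():
            continue
        av = ACCSVolume(vox.astype(np.uint8))
        cx = build_complex(av)
        for d in dirs:
            expected = oracle_euler_curve(av.voxels, d, thr)
            got = euler_curve(cx, d, thr)
            assert np.array_equal(got, expected), f"trial {trial}"
        n_checked += 1
    assert n_checked >= 200


def test_all_tiny_3x3x3_masks_match_oracle_chi():
    """Total Euler characteristic equals the oracle on hundreds of random
    3x3x3 occupancy patterns."""
    rng = np.random.default_rng(3)
    for _ in range(250):
        vox = (rng.random((3, 3, 3)) < 0.5)
        if not vox.any():
            continue
        cx = build_complex(ACCSVolume(vox.astype(np.uint8)))
        cells = oracle_cells(vox)
        chi = sum((-1) ** dim for dim, _ in cells)
        assert cx.euler_characteristic == chi


# ---------------------------------------------------------------------------
# ECT vectors


def test_default_vector_length(ball12):
    vec = ect_transform(ball12)
    assert len(vec.values) == 16384


def test_vector_length_product_rule(ball12):
    vec = ect_transform(ball12, n_directions=8, n_thresholds=4)
    assert len(vec.values) == 32


def test_ect_ends_at_one_for_contractible_solid(ball12):
    vec = ect_transform(ball12, n_directions=16, n_thresholds=32)
    assert np.array_equal(vec.curves()[:, -1], np.ones(16))


def test_translation_shifts_curve_in_threshold():
    """Translating a shape by +2 mm along a direction shifts that direction's
    Euler curve by 2 mm in threshold."""
    base = make_ball(6.0, center=(0, 0, 0), size=48)
    moved = make_ball(6.0, center=(0, 0, 2.0), size=48)
    d = np.array([0.0, 0.0, 1.0])
    thr = np.arange(-20.0, 21.0, 1.0)
    c_base = euler_curve(build_complex(base), d, thr)
    c_moved = euler_curve(build_complex(moved), d, thr)
    assert np.array_equal(c_moved[2:], c_base[:-2])


# ---------------------------------------------------------------------------
# ANOVA kernel and shape space


def test_kernel_self_value_and_symmetry(rng):
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    assert anova_kernel(x, x, sigma=0.7, degree=2) == pytest.approx(50.0**2)
    assert anova_kernel(x, y, 0.7, 2) == pytest.approx(anova_kernel(y, x, 0.7, 2))
    with pytest.raises(ValueError):
        anova_kernel(x, y[:10])


def test_kernel_matrix_psd(rng):
    X = rng.normal(size=(6, 30))
    K = anova_kernel_matrix(X, X, sigma=0.5, degree=2)
    w = np.linalg.eigvalsh(K)
    assert w.min() >= -1e-10 * np.trace(K)


def test_projection_of_fitted_members_reproduces_scores(rng):
    X = rng.normal(size=(8, 40))
    space = fit_shape_space(list(X))
    proj = project(space, list(X))
    assert np.allclose(proj, space.scores, atol=1e-8)


def test_matches_sklearn_kernel_pca(rng):
    """Independent cross-check: our double-centered eigendecomposition agrees
    with sklearn's KernelPCA on a precomputed ANOVA kernel (up to sign)."""
    from sklearn.decomposition import KernelPCA

    X = rng.normal(size=(10, 25))
    space = fit_shape_space(list(X), sigma=0.3)
    K = anova_kernel_matrix(X, X, sigma=0.3, degree=1)
    sk = KernelPCA(n_components=2, kernel="precomputed").fit(K)
    ours = space.scores
    theirs = sk.transform(K)
    for c in range(2):
        sign = np.sign(np.dot(ours[:, c], theirs[:, c])) or 1.0
        assert np.allclose(ours[:, c], sign * theirs[:, c], atol=1e-6)


def test_shape_families_separate_in_shape_space():
    """Spheres and 3:1 ellipsoids form well-separated clusters on PC1-PC2."""
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(2)
    vecs, labels = [], []
    for i in range(6):
        r = 8.0 + rng.uniform(-1, 1)
        c = rng.uniform(-0.5, 0.5, 3)
        vecs.append(ect_transform(make_ball(r, c, size=48),
                                  n_directions=32, n_thresholds=24))
        labels.append(0)
    for i in range(6):
        a = 15.0 + rng.uniform(-1, 1)
        c = rng.uniform(-0.5, 0.5, 3)
        vecs.append(ect_transform(make_ellipsoid(a, a / 3, a / 3, c, size=48),
                                  n_directions=32, n_thresholds=24))
        labels.append(1)
    space = fit_shape_space(vecs)
    assert silhouette_score(space.scores, labels) > 0.5


def test_vendor_ellipsoids_occupy_tight_region():
    """The four vendor ellipsoids cluster tightly relative to a lobulated
    synthetic cohort's spread when projected into its shape space."""
    from scipy.spatial.distance import pdist

    from ablaq.synth import CohortSpec, simulate_ablation_mask, simulate_records
    from ablaq.pipeline import measure_ablation
    from ablaq.vendor import default_vendor_table, interpolate_vendor, \
        synthesize_ellipsoid_mask

    rng = np.random.default_rng(4)
    spec = CohortSpec(n_patients=9, lobulation_amplitude=0.12)
    recs = simulate_records(spec, rng)
    vecs = []
    for _, rec in recs.iloc[:10].iterrows():
        mask, app, _ = simulate_ablation_mask(spec, rec, rng)
        _, av = measure_ablation(mask, app)
        vecs.append(ect_transform(av, n_directions=32, n_thresholds=24))
    space = fit_shape_space(vecs)
    table = default_vendor_table()
    vendor_vecs = [
        ect_transform(synthesize_ellipsoid_mask(interpolate_vendor(table, 65.0, d)),
                      n_directions=32, n_thresholds=24)
        for d in (2.0, 4.0, 5.0, 6.0)
    ]
    vproj = project(space, vendor_vecs)
    assert np.max(pdist(vproj)) < np.median(pdist(space.scores))


# ---------------------------------------------------------------------------
# property-based oracle check

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=80, deadline=None)
@given(st.integers(min_value=1, max_value=2**27 - 1))
def test_chi_matches_oracle_on_arbitrary_3x3x3_patterns(bits):
    """Euler characteristic equals explicit cell enumeration for arbitrary
    3x3x3 occupancy patterns."""
    vox = np.array([(bits >> i) & 1 for i in range(27)], np.uint8).reshape(3, 3, 3)
    if not vox.any():
        return
    cx = build_complex(ACCSVolume(vox))
    chi = sum((-1) ** dim for dim, _ in oracle_cells(vox))
    assert cx.euler_characteristic == chi
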