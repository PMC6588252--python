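"""GLCM / DTCWT texture features: oracles, invariants, and the 86-vector."""

import math

import numpy as np
import pytest

from octexture import (
    MVFImage,
    aggregate_quadrants,
    block_features,
    downsample_quantize,
    dtcwt_features,
    extract_features,
    feature_names,
    feature_origins,
    glcm,
    glcm_metrics,
)
from octexture.texture import (
    BLOCK_PX,
    DIRECTION_OFFSETS,
    DIRECTIONS,
    METRIC_NAMES,
    N_LEVELS,
    QUADRANT_BLOCKS,
    QUADRANTS,
    BlockGrid,
)


def _img(values, layer="GCL"):
    return MVFImage(np.asarray(values, dtype=float), layer, "right", normalised=True)


def glcm_bruteforce(block, direction, levels=16):
    """Exhaustive pair-enumeration oracle for the symmetric normalised GLCM."""
    dr, dc = DIRECTION_OFFSETS[direction]
    m = np.zeros((levels, levels))
    rows, cols = block.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                m[block[r, c], block[r2, c2]] += 1
                m[block[r2, c2], block[r, c]] += 1
    return m / m.sum()


def metrics_textbook(P):
    """Independent scalar-loop implementation of the 20 metrics."""
    L = P.shape[0]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sig_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sig_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))
    p_sum = np.zeros(2 * L - 1)
    p_diff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]
    ent2 = lambda p: -sum(v * math.log2(v) for v in np.ravel(p) if v > 0)
    entn = lambda p: -sum(v * math.log(v) for v in np.ravel(p) if v > 0)
    out = {}
    out["autocorrelation"] = sum(i * j * P[i, j] for i in range(L) for j in range(L))
    out["contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    out["correlation"] = (
        (out["autocorrelation"] - mu_x * mu_y) / (sig_x * sig_y)
        if sig_x * sig_y > 0 else 0.0
    )
    out["cluster_prominence"] = sum(
        (i + j - mu_x - mu_y) ** 4 * P[i, j] for i in range(L) for j in range(L))
    out["cluster_shade"] = sum(
        (i + j - mu_x - mu_y) ** 3 * P[i, j] for i in range(L) for j in range(L))
    out["dissimilarity"] = sum(abs(i - j) * P[i, j] for i in range(L) for j in range(L))
    out["energy"] = float((P ** 2).sum())
    out["entropy"] = ent2(P)
    out["homogeneity"] = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    out["maximum_probability"] = float(P.max())
    out["variance"] = sum((i - mu_x) ** 2 * P[i, j] for i in range(L) for j in range(L))
    sa = sum(k * p_sum[k] for k in range(2 * L - 1))
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * p_sum[k] for k in range(2 * L - 1))
    out["sum_entropy"] = ent2(p_sum)
    da = sum(k * p_diff[k] for k in range(L))
    out["difference_variance"] = sum((k - da) ** 2 * p_diff[k] for k in range(L))
    out["difference_entropy"] = ent2(p_diff)
    hx, hy, hxy = entn(px), entn(py), entn(P)
    hxy1 = -sum(P[i, j] * math.log(px[i] * py[j])
                for i in range(L) for j in range(L) if px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log(px[i] * py[j])
                for i in range(L) for j in range(L) if px[i] * py[j] > 0)
    out["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    out["inverse_difference_normalized"] = sum(
        P[i, j] / (1 + abs(i - j) / L) for i in range(L) for j in range(L))
    out["inverse_difference_moment_normalized"] = sum(
        P[i, j] / (1 + (i - j) ** 2 / L ** 2) for i in range(L) for j in range(L))
    return out


class TestDownsampleQuantize:
    def test_constant_maps_to_level_zero(self):
        q = downsample_quantize(_img(np.full((256, 256), 7.0)))
        assert q.levels.dtype == np.uint8
        assert np.all(q.levels == 0)

    def test_linear_ramp_gives_equal_width_bands(self):
        ramp = np.tile(np.linspace(0, 1, 128), (128, 1))
        q = downsample_quantize(_img(ramp))
        row = q.levels[0]
        assert row[0] == 0 and row[-1] == 15
        assert np.all(np.diff(row.astype(int)) >= 0)  # monotone level map
        widths = np.bincount(row, minlength=16)
        assert widths.min() >= 7 and widths.max() <= 9  # 128/16 = 8 ± rounding

    @pytest.mark.parametrize("shape", [(128, 512), (128, 256), (64, 100)])
    def test_output_shape_contract(self, shape, rng):
        q = downsample_quantize(_img(rng.normal(size=shape)))
        assert q.levels.shape == (128, 128)

    def test_non_finite_rejected(self):
        bad = np.full((128, 128), 1.0)
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            downsample_quantize(_img(bad))

    def test_unnormalised_image_rejected(self):
        img = MVFImage(np.zeros((128, 128)), "GCL", "left", normalised=False)
        with pytest.raises(ValueError):
            downsample_quantize(img)


class TestGLCM:
    def test_uniform_2x2_block(self):
        m = glcm(np.zeros((2, 2), dtype=int), 0)
        assert m[0, 0] == pytest.approx(1.0)
        assert m.sum() == pytest.approx(1.0)

    def test_hand_enumerated_2x2(self):
        """[[0,1],[2,3]] horizontally: pairs (0,1) and (2,3) symmetrised."""
        m = glcm(np.array([[0, 1], [2, 3]]), 0)
        expect = {(0, 1): 0.25, (1, 0): 0.25, (2, 3): 0.25, (3, 2): 0.25}
        for (i, j), v in expect.items():
            assert m[i, j] == pytest.approx(v)
        assert m.sum() == pytest.approx(1.0)

    def test_diagonal_direction_semantics(self):
        """45° pairs each pixel with its upper-right neighbour."""
        m = glcm(np.array([[0, 1], [2, 3]]), 45)
        assert m[1, 2] == pytest.approx(0.5)
        assert m[2, 1] == pytest.approx(0.5)
        m135 = glcm(np.array([[0, 1], [2, 3]]), 135)
        assert m135[0, 3] == pytest.approx(0.5)

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_matches_bruteforce_on_random_blocks(self, direction, rng):
        for _ in range(100):
            block = rng.integers(0, 16, size=(8, 8))
            assert np.allclose(glcm(block, direction),
                               glcm_bruteforce(block, direction))

    def test_symmetry_and_normalisation(self, rng):
        for direction in DIRECTIONS:
            m = glcm(rng.integers(0, 16, size=(18, 18)), direction)
            assert np.allclose(m, m.T)
            assert m.sum() == pytest.approx(1.0)

    def test_degenerate_block_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.zeros((1, 5), dtype=int), 90)


class TestGLCMMetrics:
    def test_single_entry_matrix(self):
        P = np.zeros((16, 16))
        P[0, 0] = 1.0
        m = glcm_metrics(P)
        assert m["energy"] == pytest.approx(1.0)
        assert m["entropy"] == pytest.approx(0.0)
        assert m["contrast"] == pytest.approx(0.0)
        assert m["maximum_probability"] == pytest.approx(1.0)

    def test_uniform_matrix_closed_form(self):
        P = np.full((16, 16), 1 / 256)
        m = glcm_metrics(P)
        assert m["energy"] == pytest.approx(1 / 256)
        assert m["entropy"] == pytest.approx(8.0)  # log2(256) bits

    def test_metric_count_and_names(self):
        m = glcm_metrics(np.full((16, 16), 1 / 256))
        assert tuple(m) == METRIC_NAMES
        assert len(m) == 20

    def test_matches_independent_textbook_implementation(self, rng):
        for _ in range(25):
            block = rng.integers(0, 16, size=(12, 12))
            P = glcm(block, int(rng.choice(DIRECTIONS)))
            ours = glcm_metrics(P)
            ref = metrics_textbook(P)
            for name in METRIC_NAMES:
                assert ours[name] == pytest.approx(ref[name], abs=1e-10), name

    def test_checkerboard_block(self):
        block = np.indices((8, 8)).sum(axis=0) % 2 * 15
        P = glcm(block, 0)
        ours = glcm_metrics(P)
        ref = metrics_textbook(P)
        for name in METRIC_NAMES:
            assert ours[name] == pytest.approx(ref[name], abs=1e-10)
        assert ours["contrast"] == pytest.approx(225.0)  # all pairs differ by 15

    def test_bounded_metrics(self, rng):
        for _ in range(20):
            P = glcm(rng.integers(0, 16, size=(10, 10)), 90)
            m = glcm_metrics(P)
            assert 0 < m["energy"] <= 1
            assert m["entropy"] >= 0
            assert 0 < m["maximum_probability"] <= 1

    def test_unnormalised_matrix_rejected(self):
        with pytest.raises(ValueError):
            glcm_metrics(np.ones((16, 16)))


class TestBlockFeatures:
    def test_constant_image_all_blocks_degenerate(self):
        q = downsample_quantize(_img(np.full((128, 128), 3.0)))
        grid = block_features(q)
        assert np.allclose(grid.metric("energy"), 1.0)
        assert np.allclose(grid.metric("entropy"), 0.0)

    def test_striped_image_contrast_supremum_is_vertical(self):
        """Horizontal stripes: the vertical (90°) direction sees maximal
        contrast; the supremum must equal that direction's value."""
        stripes = np.tile((np.arange(128) % 2)[:, None] * 100.0, (1, 128))
        q = downsample_quantize(_img(stripes))
        work = q.working()
        blk = work[:BLOCK_PX, :BLOCK_PX]
        per_dir = {d: glcm_metrics(glcm(blk, d))["contrast"] for d in DIRECTIONS}
        grid = block_features(q)
        assert grid.metric("contrast")[0, 0] == pytest.approx(max(per_dir.values()))
        # attained in the vertical direction; the horizontal one sees none
        assert grid.metric("contrast")[0, 0] == pytest.approx(per_dir[90])
        assert per_dir[90] > per_dir[0]

    def test_supremum_dominates_every_direction(self, rng):
        q = downsample_quantize(_img(rng.normal(size=(128, 128))))
        grid = block_features(q)
        work = q.working()
        for bi, bj in [(0, 0), (3, 3), (6, 2)]:
            blk = work[bi * BLOCK_PX:(bi + 1) * BLOCK_PX,
                       bj * BLOCK_PX:(bj + 1) * BLOCK_PX]
            for d in DIRECTIONS:
                md = glcm_metrics(glcm(blk, d))
                for m, name in enumerate(METRIC_NAMES):
                    assert grid.values[bi, bj, m] >= md[name] - 1e-12


class TestQuadrantAggregation:
    def test_identical_blocks_pass_through(self):
        grid = BlockGrid(np.full((7, 7, 20), 3.14))
        out = aggregate_quadrants(grid)
        assert len(out) == 80
        assert all(v == pytest.approx(3.14) for v in out.values())

    def test_corner_indicator(self):
        values = np.zeros((7, 7, 20))
        values[0:3, 0:3, :] = 5.0  # superior-temporal corner
        out = aggregate_quadrants(BlockGrid(values))
        for name in METRIC_NAMES:
            assert out[f"glcm_superior_temporal_{name}"] == pytest.approx(5.0)
            assert out[f"glcm_inferior_nasal_{name}"] == pytest.approx(0.0)

    def test_centre_row_and_column_excluded(self, rng):
        values = rng.normal(size=(7, 7, 20))
        out = aggregate_quadrants(BlockGrid(values))
        for quad in QUADRANTS:
            rs, cs = QUADRANT_BLOCKS[quad]
            rows = range(rs.start, rs.stop)
            cols = range(cs.start, cs.stop)
            assert 3 not in rows and 3 not in cols
            for m, name in enumerate(METRIC_NAMES):
                oracle = np.mean([values[r, c, m] for r in rows for c in cols])
                assert out[f"glcm_{quad}_{name}"] == pytest.approx(oracle)


class TestDTCWT:
    def test_constant_image_zero_variances(self):
        out = dtcwt_features(_img(np.full((128, 128), 9.0)))
        assert all(v == pytest.approx(0.0, abs=1e-18) for v in out.values())

    def test_additive_offset_invariance(self, rng):
        base = rng.normal(size=(128, 128))
        a = dtcwt_features(_img(base))
        b = dtcwt_features(_img(base + 500.0))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-8, abs=1e-12)

    @pytest.mark.parametrize("deg,band,mirror", [
        (15, "p15", "m15"), (45, "p45", "m45"), (75, "p75", "m75"),
        (105, "m75", "p75"), (135, "m45", "p45"), (165, "m15", "p15"),
    ])
    def test_orientation_selectivity(self, deg, band, mirror):
        """A grating whose wavefronts lie at one of the six subband
        orientations must put its energy dominantly in that subband."""
        n = 128
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        th = np.deg2rad(deg + 90)  # frequency vector normal to wavefronts
        img = np.cos(2 * np.pi * 0.42 * (xx * np.cos(th) + yy * np.sin(th)))
        out = dtcwt_features(_img(img))
        values = {k.removeprefix("dtcwt_var_"): v for k, v in out.items()}
        assert max(values, key=values.get) == band
        assert values[band] > 1.5 * values[mirror]

    def test_odd_dimensions_padded(self, rng):
        out = dtcwt_features(_img(rng.normal(size=(127, 129))))
        assert len(out) == 6

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            dtcwt_features(_img(np.zeros((4, 4))))


class TestExtractFeatures:
    def test_vector_structure(self, rng):
        fv = extract_features(_img(rng.normal(100, 10, size=(128, 256))))
        assert len(fv.values) == 86
        assert sum(o == "global" for o in fv.origins) == 6
        assert sum(o != "global" for o in fv.origins) == 80
        assert len(set(fv.names)) == 86
        assert fv.names == feature_names()
        assert fv.origins == feature_origins()

    def test_mirror_pair_consistency(self, rng):
        """A left eye that is the exact mirror of a right eye yields the
        same features once orientation-normalised."""
        from octexture import normalise_orientation
        right_vals = rng.normal(100, 10, size=(128, 128))
        right = normalise_orientation(MVFImage(right_vals, "GCL", "right"))
        left = normalise_orientation(MVFImage(right_vals[:, ::-1], "GCL", "left"))
        fr = extract_features(right)
        fl = extract_features(left)
        assert np.allclose(fr.values, fl.values)

    def test_names_stable_across_runs(self):
        assert feature_names() == feature_names()
        assert feature_names()[0].startswith("glcm_superior_temporal_")
        assert feature_names()[-1] == "dtcwt_var_m15"
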