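import numpy as np
import pytest
from scipy import ndimage as ndi

from retimorph import (
    BinaryMask,
    FractalFixtureSpec,
    box_count,
    disc_like_params,
    is_unit_width,
    lacunarity,
    make_fractal,
    simulate_tree,
    skeletonize,
    vessel_density,
)
from retimorph.errors import ConfigurationError, DegenerateInputError

from .conftest import brute_force_box_count

EIGHT = np.ones((3, 3), dtype=int)


class TestSkeletonize:
    def test_unit_width_curve_unchanged(self):
        m = np.zeros((60, 60), dtype=bool)
        rr = np.arange(50)
        m[rr + 5, (5 + 0.4 * rr).astype(int)] = True
        sk = skeletonize(BinaryMask(m))
        assert np.array_equal(sk.pixels, m)

    def test_solid_bar_thins_to_centreline(self):
        bar = np.zeros((13, 106), dtype=bool)
        bar[3:10, 3:103] = True
        sk = skeletonize(BinaryMask(bar))
        ys, xs = np.nonzero(sk.pixels)
        assert set(ys) == {6}  # centre row of rows 3..9
        # thinning may retreat up to half the bar width at each end
        assert 100 - 7 <= len(xs) <= 100
        assert is_unit_width(sk.pixels)

    def test_empty_mask_gives_empty_skeleton(self):
        sk = skeletonize(BinaryMask(np.zeros((20, 20), dtype=bool)))
        assert sk.foreground_count == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_contract_on_simulated_trees(self, seed):
        _, mask = simulate_tree(disc_like_params(seed=seed, window=256))
        sk = skeletonize(mask)
        assert is_unit_width(sk.pixels)
        assert ndi.label(mask.pixels, EIGHT)[1] == ndi.label(sk.pixels, EIGHT)[1]
        # centreline containment: skeleton within the 1-px dilated source
        dilated = ndi.binary_dilation(mask.pixels, EIGHT.astype(bool))
        assert not np.any(sk.pixels & ~dilated)


class TestBoxCount:
    def test_counts_non_increasing_and_slope_sane(self):
        m = make_fractal(FractalFixtureSpec("sierpinski_carpet", order=4, side=243))
        fit = box_count(m)
        assert fit.per_origin_db.shape == (12,)
        for origin_counts in fit.counts:
            # monotone up to one box of integer-cover quantization
            assert np.all(np.diff(origin_counts) <= 1)
            assert origin_counts[0] > origin_counts[-1]
        assert 0 <= fit.db <= 2

    def test_single_origin_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        blobs = rng.random((64, 64)) > 0.9
        blobs[30:34, 10:40] = True
        fixtures = [
            blobs,
            make_fractal(FractalFixtureSpec("sierpinski_carpet", order=3, side=81)).pixels,
        ]
        for pixels in fixtures:
            sizes = [2, 3, 5, 9, 17]
            fit = box_count(BinaryMask(pixels), origins=1, sizes=sizes)
            for size, count in zip(fit.sizes, fit.counts[0]):
                assert count == brute_force_box_count(pixels, int(size), 0)

    def test_translation_invariance_single_origin(self):
        base = np.zeros((128, 128), dtype=bool)
        base[20:40, 20:44] = np.random.default_rng(5).random((20, 24)) > 0.5
        sizes = [2, 4, 8]
        fit_a = box_count(BinaryMask(base), origins=1, sizes=sizes)
        shifted = np.roll(base, (8, 16), axis=(0, 1))  # multiple of every size
        fit_b = box_count(BinaryMask(shifted), origins=1, sizes=sizes)
        assert np.array_equal(fit_a.counts, fit_b.counts)

    def test_rotation_and_flip_invariance(self):
        m = make_fractal(FractalFixtureSpec("sierpinski_carpet", order=4, side=243))
        db0 = box_count(m).db
        for transform in (np.rot90, np.fliplr, np.flipud):
            db_t = box_count(BinaryMask(transform(m.pixels))).db
            assert abs(db_t - db0) <= 0.02

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError):
            box_count(BinaryMask(np.zeros((64, 64), dtype=bool)))
        one = np.zeros((64, 64), dtype=bool)
        one[10, 10] = True
        with pytest.raises(DegenerateInputError):
            box_count(BinaryMask(one))
        line = np.zeros((8, 8), dtype=bool)
        line[4] = True
        with pytest.raises(ConfigurationError):
            box_count(BinaryMask(line))  # too small for 3 distinct sizes

    def test_deterministic(self):
        m = make_fractal(FractalFixtureSpec("sierpinski_carpet", order=3, side=81))
        a, b = box_count(m), box_count(m)
        assert a.db == b.db
        assert np.array_equal(a.counts, b.counts)


class TestLacunarity:
    def test_full_mask_lambda_zero(self):
        prof = lacunarity(BinaryMask(np.ones((100, 100), dtype=bool)))
        assert prof.lambda_mean == 0.0

    def test_one_hot_closed_form(self):
        m = np.zeros((100, 100), dtype=bool)
        m[37, 61] = True
        prof = lacunarity(BinaryMask(m), origins=1, sizes=[10])
        # 100 boxes, mu=0.01, sigma^2=0.0099 -> lambda=99
        assert prof.lambda_by_size_origin[0, 0] == pytest.approx(99.0)

    def test_checkerboard_closed_form(self, checkerboard):
        prof = lacunarity(checkerboard, origins=1, sizes=[10])
        assert prof.lambda_by_size_origin[0, 0] == pytest.approx(1.0)

    def test_lambda_nonnegative_and_empty_raises(self, rng):
        m = BinaryMask(rng.random((80, 80)) > 0.6)
        prof = lacunarity(m)
        assert np.all(prof.lambda_by_size_origin[~np.isnan(prof.lambda_by_size_origin)] >= 0)
        with pytest.raises(DegenerateInputError):
            lacunarity(BinaryMask(np.zeros((50, 50), dtype=bool)))

    def test_uniform_infill_reduces_lacunarity(self):
        """Adding uniformly random foreground to a sparse clumped mask makes
        it more homogeneous in expectation."""
        base = np.zeros((96, 96), dtype=bool)
        base[10:25, 10:25] = True  # one clump
        lam_base = lacunarity(BinaryMask(base)).lambda_mean
        drops = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            filled = base | (rng.random((96, 96)) > 0.9)
            if lacunarity(BinaryMask(filled)).lambda_mean < lam_base:
                drops += 1
        assert drops == n_seeds

    def test_deterministic(self, checkerboard):
        a, b = lacunarity(checkerboard), lacunarity(checkerboard)
        assert np.array_equal(
            a.lambda_by_size_origin, b.lambda_by_size_origin, equal_nan=True
        )


class TestVesselDensity:
    def test_density_arithmetic(self):
        m = np.zeros((1000, 1000), dtype=bool)
        flat = np.zeros(1000 * 1000, dtype=bool)
        flat[:114_100] = True
        m = flat.reshape(1000, 1000)
        res = vessel_density(skeletonize(BinaryMask(np.zeros((10, 10), dtype=bool))))
        assert res.density_pct == 0.0
        from retimorph.geometry import SkeletonMask

        res = vessel_density(SkeletonMask(m))
        assert res.density_pct == pytest.approx(11.41)

    def test_full_window_accepted_with_warning(self, caplog):
        from retimorph.geometry import SkeletonMask

        with caplog.at_level("WARNING"):
            res = vessel_density(SkeletonMask(np.ones((20, 20), dtype=bool)))
        assert res.density_pct == 100.0
        assert any("unit-width" in r.message for r in caplog.records)
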