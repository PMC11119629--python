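import numpy as np
import pytest
from PIL import Image

from conftest import TOY_PARAMS, random_recurrence
from oracles import naive_recurrence
from rpcross.embedding import EmbeddingParams, embed
from rpcross.errors import ConfigurationError
from rpcross.recurrence import (
    lambda_for_rate,
    pairwise_distances,
    recurrence_matrix,
    render_plot,
)
from rpcross.synthetic import SyntheticSpec, generate
from rpcross.timeseries import TimeSeries

SQRT_HALF = np.sqrt(0.5)


class TestPairwiseDistances:
    def test_toy_values(self, toy_dist):
        assert toy_dist.entries[0, 2] == 0.0  # identical sub-series
        assert toy_dist.entries[0, 1] == pytest.approx(SQRT_HALF)  # sqrt(2*(1/2)^2)
        assert np.all(toy_dist.entries == toy_dist.entries.T)
        assert np.all(np.diag(toy_dist.entries) == 0)

    def test_max_norm_below_euclidean(self):
        s = generate(SyntheticSpec("iid_noise", 100, 0)).series
        emb = embed(s, EmbeddingParams(tau=1, dim=2))
        de = pairwise_distances(emb, norm="euclidean").entries
        dm = pairwise_distances(emb, norm="max").entries
        assert np.all(dm <= de + 1e-12)

    def test_unknown_norm(self, toy):
        emb = embed(toy, TOY_PARAMS)
        with pytest.raises(ConfigurationError):
            pairwise_distances(emb, norm="mahalanobis")


class TestRecurrenceMatrix:
    def test_toy_lambda_01_entry_for_entry(self, toy_m01):
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        np.testing.assert_array_equal(toy_m01.entries, expected)
        assert toy_m01.recurrence_rate == pytest.approx(5 / 9)

    def test_toy_lambda_09_all_recurrent(self, toy_m09):
        np.testing.assert_array_equal(toy_m09.entries, np.zeros((3, 3)))
        assert toy_m09.recurrence_rate == 1.0

    def test_lambda_at_max_entry_gives_rate_one(self):
        s = generate(SyntheticSpec("iid_noise", 60, 1)).series
        dist = pairwise_distances(embed(s, EmbeddingParams(tau=1, dim=1)))
        M = recurrence_matrix(dist, float(dist.entries.max()))
        assert M.recurrence_rate == 1.0

    def test_negative_lambda_rejected(self, toy_dist):
        with pytest.raises(ConfigurationError):
            recurrence_matrix(toy_dist, -0.1)

    def test_symmetry_zero_diagonal_always(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = TimeSeries(rng.normal(size=50), is_increment=True)
            dist = pairwise_distances(embed(s, EmbeddingParams(tau=2, dim=1)))
            M = recurrence_matrix(dist, float(rng.uniform(0, 2)))
            assert np.array_equal(M.entries, M.entries.T)
            assert np.all(np.diag(M.entries) == 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        s = TimeSeries(rng.normal(size=int(rng.integers(10, 52))),
                       is_increment=True)
        dist = pairwise_distances(embed(s, EmbeddingParams(tau=1, dim=1)))
        lam = float(rng.uniform(0, 2))
        M = recurrence_matrix(dist, lam)
        np.testing.assert_array_equal(M.entries,
                                      naive_recurrence(dist.entries, lam))


class TestLambdaForRate:
    def test_toy_target_five_ninths(self, toy_dist):
        thr = lambda_for_rate(toy_dist, 5 / 9)
        assert thr.lam == 0.0  # smallest entry value attaining the target
        assert thr.achieved_rate == pytest.approx(5 / 9)

    def test_toy_target_one(self, toy_dist):
        thr = lambda_for_rate(toy_dist, 1.0)
        assert thr.lam == pytest.approx(SQRT_HALF)
        assert recurrence_matrix(toy_dist, thr.lam).recurrence_rate == 1.0

    def test_achieved_rate_at_least_target(self):
        rng = np.random.default_rng(2)
        s = TimeSeries(rng.normal(size=80), is_increment=True)
        dist = pairwise_distances(embed(s, EmbeddingParams(tau=1, dim=2)))
        for target in [0.05, 0.09, 0.3, 0.77, 1.0]:
            thr = lambda_for_rate(dist, target)
            assert thr.achieved_rate >= target - 1e-12
            M = recurrence_matrix(dist, thr.lam)
            assert M.recurrence_rate == pytest.approx(thr.achieved_rate)

    def test_below_minimum_clamps_with_warning(self, toy_dist):
        with pytest.warns(UserWarning):
            thr = lambda_for_rate(toy_dist, 1e-4)
        assert thr.clamped
        assert thr.lam == 0.0

    def test_rate_nondecreasing_in_lambda(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            s = TimeSeries(rng.normal(size=60), is_increment=True)
            dist = pairwise_distances(embed(s, EmbeddingParams(tau=1, dim=1)))
            lams = np.sort(rng.uniform(0, dist.entries.max() * 1.1, size=15))
            rates = [recurrence_matrix(dist, l).recurrence_rate for l in lams]
            assert np.all(np.diff(rates) >= 0)


class TestPipelineScaleInvariance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_affine_transform_leaves_matrix_unchanged(self, seed):
        """x -> a*x + b cancels in row differences; rate targeting scales lambda."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=150)
        a = float(rng.uniform(0.1, 5.0)) * (-1 if seed % 2 else 1)
        b = float(rng.uniform(-10, 10))

        def matrix(vals):
            dist = pairwise_distances(
                embed(TimeSeries(vals, is_increment=True), TOY_PARAMS)
            )
            return recurrence_matrix(dist, lambda_for_rate(dist, 0.09).lam)

        np.testing.assert_array_equal(matrix(x).entries,
                                      matrix(a * x + b).entries)


class TestRenderPlot:
    def _pixels(self, path):
        return np.asarray(Image.open(path).convert("L"))

    def test_toy_01_has_four_black_pixels(self, toy_m01, tmp_path):
        out = tmp_path / "m01.png"
        render_plot(toy_m01, out)
        px = self._pixels(out)
        assert px.shape == (3, 3)
        assert np.count_nonzero(px == 0) == 4
        assert px[0, 1] == 0 and px[1, 0] == 0  # ones sit off-diagonal

    def test_toy_09_all_white(self, toy_m09, tmp_path):
        out = tmp_path / "m09.png"
        render_plot(toy_m09, out)
        assert np.all(self._pixels(out) == 255)

    def test_all_ones_renders_black(self, toy_m01, tmp_path):
        from rpcross.recurrence import RecurrenceMatrix

        M = RecurrenceMatrix(entries=np.ones((4, 4), dtype=np.uint8), lam=0.0,
                             recurrence_rate=0.0, norm_name="euclidean")
        out = tmp_path / "ones.png"
        render_plot(M, out)
        assert np.all(self._pixels(out) == 0)

    def test_upscale_and_overlay(self, toy_m01, tmp_path):
        from rpcross.crosses import detect_crosses

        det = detect_crosses(toy_m01, threshold_sigma=1.0, k_grid=[1])
        out = tmp_path / "overlay.png"
        render_plot(toy_m01, out, overlays=[det], upscale=10)
        rgb = np.asarray(Image.open(out))
        assert rgb.shape == (30, 30, 3)
        greenish = (rgb[..., 1] > 150) & (rgb[..., 0] < 100)
        assert np.any(greenish)
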