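"""Stimulus generator: glyph rendering, mirror construction, labellers, schedule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp

from biasloop import stimuli as st
from biasloop._rng import spawn_rng
from biasloop.stimuli import (
    CLASS_BOUNDARY,
    MORE_HAPPY,
    MORE_SAD,
    CalibrationError,
    FaceArray,
    SimHumanParams,
    build_balanced_set,
    calibrate_sim_human,
    compose_array,
    dataset_to_frame,
    load_dataset_csv,
    make_label_set,
    make_rdk_schedule,
    mirror_array,
    mouth_curvature,
    p_more_sad,
    render_face,
    sample_array,
    save_dataset_csv,
    simulate_human_classification,
)

ranks_strategy = st_hyp.lists(st_hyp.integers(1, 50), min_size=12, max_size=12).filter(
    lambda r: sum(r) / 12 != CLASS_BOUNDARY
)


class TestRenderFace:
    def test_deterministic(self):
        assert np.array_equal(render_face(30, 64), render_face(30, 64))

    @pytest.mark.parametrize("bad", [0, 51, -3])
    def test_rank_out_of_range(self, bad):
        with pytest.raises(ValueError):
            render_face(bad, 64)

    def test_size_too_small(self):
        with pytest.raises(ValueError):
            render_face(10, 8)

    def test_intensities_in_unit_interval(self):
        img = render_face(1, 24)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_mouth_position_strictly_monotone_in_rank(self):
        # independent oracle: the vertical centre of mass of the mouth band
        # must increase strictly with rank, matching the closed-form
        # rank -> curvature map (smiles push the mouth centre down).
        size = 64
        ys = []
        band = slice(int(0.55 * size), int(0.9 * size))
        col = slice(int(0.4 * size), int(0.6 * size))
        rows = (np.arange(size) + 0.5)[band]
        for rank in range(1, 51):
            roi = render_face(rank, size)[band, col]
            ys.append(float((roi.sum(axis=1) * rows).sum() / roi.sum()))
        assert np.all(np.diff(ys) > 0)
        kappa = mouth_curvature(np.arange(1, 51))
        assert np.corrcoef(ys, kappa)[0, 1] > 0.995


class TestComposeArray:
    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            compose_array([25] * 11, 16)

    def test_identical_ranks_give_identical_tiles(self):
        img = compose_array([30] * 12, 16)
        pad = 8
        tiles = [img[pad + r * 16:pad + (r + 1) * 16, c * 16:(c + 1) * 16]
                 for r in range(3) for c in range(4)]
        for t in tiles[1:]:
            assert np.array_equal(t, tiles[0])

    def test_permuting_ranks_permutes_tiles(self):
        ranks = [1, 5, 10, 15, 20, 25, 26, 30, 35, 40, 45, 50]
        img_a = compose_array(ranks, 16)
        swapped = ranks.copy()
        swapped[0], swapped[7] = swapped[7], swapped[0]
        img_b = compose_array(swapped, 16)

        def tile(img, i):
            r, c = divmod(i, 4)
            return img[8 + r * 16:8 + (r + 1) * 16, c * 16:(c + 1) * 16]

        assert np.array_equal(tile(img_a, 0), tile(img_b, 7))
        assert np.array_equal(tile(img_a, 7), tile(img_b, 0))
        assert np.array_equal(tile(img_a, 3), tile(img_b, 3))


class TestSampling:
    def test_ranks_valid_and_off_boundary(self):
        rng = spawn_rng(7, "sampling")
        for _ in range(200):
            a = sample_array(rng)
            assert all(1 <= r <= 50 for r in a.ranks)
            assert a.mean_rank != CLASS_BOUNDARY

    def test_seeded_reproducibility(self):
        a = sample_array(np.random.default_rng(42))
        b = sample_array(np.random.default_rng(42))
        assert a.ranks == b.ranks

    def test_mean_of_means_matches_uniform_expectation(self):
        # oracle: mean of uniform{1..50} is 25.5
        rng = spawn_rng(11, "mc_mean")
        means = [sample_array(rng).mean_rank for _ in range(30_000)]
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - 25.5) < 4 * se + 1e-9


class TestMirror:
    def test_printed_example(self):
        a = FaceArray((21, 44, 3, 7, 14, 18, 33, 39, 42, 47, 49, 25))
        m = mirror_array(a)
        assert m.ranks[0] == 30 and m.ranks[1] == 7 and m.ranks[-1] == 26

    @given(ranks_strategy)
    @settings(derandomize=True, max_examples=50)
    def test_involution_and_mean_sum(self, ranks):
        a = FaceArray(tuple(ranks))
        m = mirror_array(a)
        assert mirror_array(m).ranks == a.ranks
        assert a.mean_rank + m.mean_rank == pytest.approx(51.0)
        assert m.objective_class != a.objective_class


class TestBalancedSet:
    @pytest.mark.parametrize("n_pairs", [1, 7, 50])
    def test_counts_balanced_and_mirrors_present(self, n_pairs):
        arrays = build_balanced_set(n_pairs, spawn_rng(3, "bal", n_pairs))
        assert len(arrays) == 2 * n_pairs
        classes = [a.objective_class for a in arrays]
        assert classes.count(MORE_SAD) == n_pairs
        ranks = {a.ranks for a in arrays}
        for a in arrays:
            assert mirror_array(a).ranks in ranks

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            build_balanced_set(0, np.random.default_rng(0))


class TestSimHuman:
    def test_noise_free_limit_is_objective(self, balanced_100):
        p = SimHumanParams(sensitivity_sd=0.0)
        rng = np.random.default_rng(0)
        for a in balanced_100:
            assert simulate_human_classification(a, p, rng) == a.objective_class

    def test_full_lapse_is_coin_flip(self, balanced_100):
        p = SimHumanParams(sensitivity_sd=5.0, lapse=1.0)
        probs = p_more_sad([a.mean_rank for a in balanced_100], p)
        assert np.allclose(probs, 0.5)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            SimHumanParams(sensitivity_sd=-1.0)

    def test_calibration_hits_target_rates(self, balanced_5000):
        # Monte-Carlo check of the 63%-accuracy / 3 pp-bias calibration
        params = calibrate_sim_human(0.63, 3.0, balanced_5000)
        means = np.array([a.mean_rank for a in balanced_5000])
        classes = np.array([a.objective_class for a in balanced_5000])
        probs = p_more_sad(means, params)
        rng = np.random.default_rng(5)
        draws = rng.random((20, probs.size)) < probs      # 100k labels
        sad_rate = draws.mean()
        acc = np.where(classes == MORE_SAD, draws, ~draws).mean()
        assert abs(acc - 0.63) < 0.01
        assert abs(sad_rate - 0.53) < 0.01

    def test_perfect_accuracy_returns_lower_noise_bound(self, balanced_5000):
        params = calibrate_sim_human(1.0, 0.0, balanced_5000)
        assert params.sensitivity_sd <= 1e-3
        assert abs(params.criterion) < 0.5

    def test_below_chance_target_fails_loudly(self, balanced_5000):
        with pytest.raises(CalibrationError):
            calibrate_sim_human(0.4, 0.0, balanced_5000)


class TestLabelSchemes:
    def test_objective_is_exact(self, balanced_100):
        ds = make_label_set(balanced_100, "objective", 0)
        assert np.array_equal(ds.labels, ds.objective_classes)
        assert ds.sad_share == 0.5

    def test_bias3_drives_exact_share(self, balanced_5000):
        ds = make_label_set(balanced_5000, "objective_bias3", 1)
        assert int((ds.labels == MORE_SAD).sum()) == 2650      # 53% of 5000
        # flips only happy -> sad: every objective sad array keeps its label
        obj = ds.objective_classes
        assert np.all(ds.labels[obj == MORE_SAD] == MORE_SAD)

    def test_random_bias3_uninformative_but_biased(self, balanced_5000):
        ds = make_label_set(balanced_5000, "random_bias3", 2)
        assert int((ds.labels == MORE_SAD).sum()) == 2650
        acc = np.mean(ds.labels == ds.objective_classes)
        assert abs(acc - 0.5) < 0.03     # independence of labels and classes

    def test_unknown_scheme_rejected(self, balanced_100):
        with pytest.raises(ValueError):
            make_label_set(balanced_100, "bogus", 0)

    def test_csv_round_trip(self, tmp_path, balanced_100):
        ds = make_label_set(balanced_100, "objective_bias3", 7)
        path = tmp_path / "ds.csv"
        save_dataset_csv(ds, path)
        back = load_dataset_csv(path)
        assert [a.ranks for a in back.arrays] == [a.ranks for a in ds.arrays]
        assert np.array_equal(back.labels, ds.labels)
        assert back.scheme == ds.scheme and back.seed == 7


class TestRdkSchedule:
    def test_schedule_contract(self):
        ev = make_rdk_schedule()
        assert len(ev) == 30
        assert ev.count(50) == 2
        assert round(float(np.mean(ev)), 2) == 50.13
        assert all(0 <= v <= 100 for v in ev)
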