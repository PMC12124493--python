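"""The iterative decomposition loop: merging, proposals, acceptance, passes."""

import numpy as np
import pytest

from kaizen import (
    EngineConfig,
    InternalState,
    ObjectPrediction,
    OraclePredictor,
    SceneParams,
    generate_scene,
    kaizen_multipass,
    kaizen_pass,
    merge,
    propose_points,
    try_accept,
)


def brute_force_propose(error, n_points, kernel=7, suppression=32):
    """Independent reference: naive kernel sums + sequential suppression."""
    h, w = error.shape
    score = np.zeros_like(error)
    half = kernel // 2
    for r in range(h):
        for c in range(w):
            rs, re = max(r - half, 0), min(r + half + 1, h)
            cs, ce = max(c - half, 0), min(c + half + 1, w)
            score[r, c] = error[rs:re, cs:ce].sum()
    points = []
    lo, hi = suppression // 2, suppression - suppression // 2
    for _ in range(n_points):
        r, c = np.unravel_index(np.argmax(score), score.shape)
        if score[r, c] <= 0:
            break
        points.append((int(r), int(c)))
        score[max(r - lo, 0): r + hi, max(c - lo, 0): c + hi] = 0.0
    return points


class TestMerge:
    def test_merge_onto_empty_internal_copies_patch(self):
        pred = ObjectPrediction(patch=np.full((4, 4), 0.3), anchor=(4, 4))
        out = merge(np.zeros((10, 10)), pred)
        np.testing.assert_array_equal(out[2:6, 2:6], 0.3)
        assert out.sum() == pytest.approx(0.3 * 16)

    def test_max_merge_is_idempotent(self, rng):
        pred = ObjectPrediction(patch=rng.random((4, 4)), anchor=(5, 5))
        once = merge(np.zeros((12, 12)), pred)
        np.testing.assert_array_equal(merge(once, pred), once)

    def test_overlapping_patches_take_pointwise_max(self, rng):
        a = ObjectPrediction(patch=rng.random((4, 4)), anchor=(4, 4))
        b = ObjectPrediction(patch=rng.random((4, 4)), anchor=(5, 5))
        out = merge(merge(np.zeros((12, 12)), a), b)
        # overlap of the two footprints
        full_a = merge(np.zeros((12, 12)), a)
        full_b = merge(np.zeros((12, 12)), b)
        np.testing.assert_array_equal(out, np.maximum(full_a, full_b))

    def test_out_of_bounds_footprint_rejected(self):
        pred = ObjectPrediction(patch=np.ones((6, 6)), anchor=(1, 1))
        with pytest.raises(ValueError):
            merge(np.zeros((10, 10)), pred)


class TestProposePoints:
    def test_all_zero_error_proposes_nothing(self):
        assert propose_points(np.zeros((64, 64)), 10) == []

    def test_single_positive_pixel_found_within_kernel_reach(self):
        error = np.zeros((64, 64))
        error[30, 41] = 1.0
        points = propose_points(error, 5)
        assert len(points) == 1
        r, c = points[0]
        assert abs(r - 30) <= 3 and abs(c - 41) <= 3
        assert brute_force_propose(error, 5) == points

    def test_two_distant_blobs_both_returned(self):
        error = np.zeros((64, 150))
        error[20, 20] = error[20, 120] = 2.0
        points = propose_points(error, 2)
        assert len(points) == 2
        assert points == brute_force_propose(error, 2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_error_images(self, seed):
        rng = np.random.default_rng(seed)
        error = rng.normal(0.0, 1.0, size=(64, 64))
        assert propose_points(error, 10) == brute_force_propose(error, 10)

    def test_negative_error_never_proposed(self):
        assert propose_points(-np.ones((40, 40)), 3) == []

    def test_border_maximum_clamped_to_feasible_anchor(self):
        error = np.zeros((64, 64))
        error[2, 2] = 5.0
        (r, c), = propose_points(error, 1, valid_margin=16)
        assert (r, c) == (16, 16)  # nearest anchor whose window fits


class TestTryAccept:
    def test_exact_residual_prediction_zeroes_footprint_error(self):
        image = np.zeros((20, 20))
        image[8:12, 8:12] = 0.6
        state = InternalState(input=image)
        pred = ObjectPrediction(patch=image[6:14, 6:14].copy(), anchor=(10, 10))
        assert try_accept(state, pred)
        assert state.loss == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(state.error[6:14, 6:14], 0.0)

    def test_zero_prediction_rejected(self):
        state = InternalState(input=np.ones((16, 16)))
        pred = ObjectPrediction(patch=np.zeros((8, 8)), anchor=(8, 8))
        assert not try_accept(state, pred)
        assert not state.objects

    def test_overshooting_already_explained_region_rejected(self):
        """Hand-computed 5x5 toy: P=I on the footprint, patch exceeds I."""
        image = np.full((5, 5), 0.5)
        state = InternalState(input=image, internal=image.copy())
        assert state.loss == 0.0
        pred = ObjectPrediction(patch=np.full((3, 3), 0.9), anchor=(2, 2))
        # delta loss = 9 * 0.4 / 25 > 0
        assert not try_accept(state, pred)
        assert state.loss == 0.0

    def test_footprint_delta_matches_full_recomputation(self, rng):
        image = rng.random((30, 30))
        state = InternalState(input=image)
        for _ in range(10):
            anchor = tuple(rng.integers(4, 26, size=2))
            pred = ObjectPrediction(patch=rng.random((8, 8)), anchor=anchor)
            before = state.loss
            accepted = try_accept(state, pred)
            full = float(np.mean(np.abs(state.input - state.internal)))
            assert state.loss == pytest.approx(full, abs=1e-12)
            if accepted:
                assert state.loss < before


class TestKaizenPass:
    def test_blank_image_terminates_immediately(self, engine_config):
        calls = []

        class Never:
            patch_size = 32

            def predict(self, point, image):
                calls.append(point)
                return np.zeros((32, 32))

        state = kaizen_pass(np.zeros((96, 96)), Never(), engine_config)
        assert state.loss == 0.0
        assert not state.objects
        assert not calls  # no positive error mass, so no proposals at all

    def test_oracle_recovers_every_cell_with_zero_loss(self, clean_scene,
                                                       oracle, engine_config):
        from kaizen.patches import pad_for_inference
        padded = pad_for_inference(clean_scene.image, 32)
        state = kaizen_pass(padded, oracle, engine_config)
        assert len(state.objects) == clean_scene.n_cells
        assert state.loss < 1e-6

    def test_iteration_cap_limits_acceptances(self, clean_scene, oracle):
        cfg = EngineConfig(patch_size=32, n_points=1, max_iter=1)
        from kaizen.patches import pad_for_inference
        state = kaizen_pass(pad_for_inference(clean_scene.image, 32), oracle, cfg)
        assert len(state.objects) <= 1

    def test_predictor_call_budget(self, clean_scene, oracle, engine_config):
        calls = 0
        inner = oracle.predict

        def counting(point, image=None):
            nonlocal calls
            calls += 1
            return inner(point, image)

        oracle.predict = counting
        from kaizen.patches import pad_for_inference
        kaizen_pass(pad_for_inference(clean_scene.image, 32), oracle, engine_config)
        assert calls <= engine_config.max_iter * engine_config.n_points


class BlindedOracle:
    """Test double: refuses to predict one label during pass 1."""

    def __init__(self, oracle, blind_label):
        self._oracle = oracle
        self.blind_label = blind_label
        self.patch_size = oracle.patch_size
        self.current_pass = 1

    def begin_pass(self, idx):
        self.current_pass = idx

    def predict(self, point, image=None):
        if (self.current_pass == 1
                and self._oracle.labels[point] == self.blind_label):
            return np.zeros((self.patch_size, self.patch_size))
        return self._oracle.predict(point, image)


class TestMultipass:
    def test_fully_explained_scene_stops_after_two_passes(self, clean_scene,
                                                          oracle, engine_config):
        state = kaizen_multipass(clean_scene.image, oracle, engine_config)
        passes = {o.source_pass for o in state.objects}
        assert passes == {1}
        assert state.loss < 1e-6

    def test_cell_missed_in_pass_one_recovered_in_pass_two(self, clean_scene,
                                                           oracle, engine_config):
        blinded = BlindedOracle(oracle, blind_label=2)
        state = kaizen_multipass(clean_scene.image, blinded, engine_config)
        assert state.loss < 1e-6
        assert max(o.source_pass for o in state.objects) == 2

    def test_loss_monotone_across_acceptances_and_passes(self, noisy_scene,
                                                         engine_config):
        oracle = OraclePredictor(noisy_scene, 32)
        losses = []
        original = try_accept

        import kaizen.engine as eng

        def tracking(state, prediction, min_improvement=0.0, rule="max"):
            out = original(state, prediction, min_improvement, rule)
            losses.append(state.loss)
            return out

        eng.try_accept = tracking
        try:
            kaizen_multipass(noisy_scene.image, oracle, engine_config)
        finally:
            eng.try_accept = original
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_completeness_on_random_scenes(self, seed):
        rng = np.random.default_rng(seed)
        scene = generate_scene(SceneParams(
            n_cells=int(rng.integers(5, 16)), background_noise_sd=0.0, seed=seed,
        ))
        oracle = OraclePredictor(scene, 32)
        state = kaizen_multipass(scene.image, oracle, EngineConfig(patch_size=32))
        assert state.loss < 1e-6
        assert len(state.objects) == scene.n_cells
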