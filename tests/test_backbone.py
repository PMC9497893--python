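"""Backbone tests: parameter accounting of the baseline and substituted
classifiers, stride skipping, flip-ensemble inference and smoke training."""

import numpy as np
import pytest

from igpconv import (
    SubnetConfig, apply_stride_skip, build_baseline, effnet_b0,
    generate_synthetic_set, hflip_ensemble_predict, smoke_train,
    substitute_pointwise,
)


def _baseline(num_classes):
    return build_baseline(effnet_b0(num_classes), rng=np.random.default_rng(0))


class TestBaselineCounts:
    @pytest.mark.parametrize("classes,expected", [
        (10, 4_020_358),
        (2, 4_010_110),
        (8, 4_017_796),
    ])
    def test_trainable_parameters(self, classes, expected):
        assert _baseline(classes).n_params() == expected

    def test_head_arithmetic_between_class_counts(self):
        # only the dense head depends on the class count: 8 x (1280 + 1)
        diff = _baseline(10).n_params() - _baseline(2).n_params()
        assert diff == 8 * (1280 + 1)


class TestSubstitutedCounts:
    @pytest.mark.parametrize("classes,ch,expected", [
        (10, 32, 950_650),   # matches the published 32ch total exactly
        (10, 16, 623_202),
        (10, 8, 444_346),
        (10, 4, 354_818),
        (10, 2, 311_994),
        (2, 16, 612_954),
    ])
    def test_trainable_parameters(self, classes, ch, expected):
        model, _ = substitute_pointwise(effnet_b0(classes), ch,
                                        rng=np.random.default_rng(0))
        assert model.n_params() == expected

    def test_accounting_identity(self):
        # substituted total == baseline - sum(original slots) + sum(new slots)
        model, report = substitute_pointwise(effnet_b0(10), 16,
                                             rng=np.random.default_rng(0))
        delta = sum(r["original_params"] - r["new_params"]
                    for r in report.rows)
        assert report.substituted_total == report.baseline_total - delta

    def test_params_strictly_increase_with_ch(self):
        totals = []
        for ch in (2, 4, 8, 16, 32):
            model, _ = substitute_pointwise(effnet_b0(10), ch,
                                            rng=np.random.default_rng(0))
            totals.append(model.n_params())
        assert totals == sorted(totals)
        assert len(set(totals)) == len(totals)

    def test_headline_savings_fraction(self):
        model, report = substitute_pointwise(effnet_b0(10), 32,
                                             rng=np.random.default_rng(0))
        saving = 100.0 * (1 - report.substituted_total / report.baseline_total)
        assert saving == pytest.approx(76.4, abs=0.1)

    def test_huge_ch_leaves_model_untouched(self):
        model, report = substitute_pointwise(effnet_b0(10), 10_000,
                                             rng=np.random.default_rng(0))
        assert model.n_params() == report.baseline_total

    def test_se_substitution_switch(self):
        with_se, _ = substitute_pointwise(effnet_b0(10), 16,
                                          rng=np.random.default_rng(0))
        without_se, _ = substitute_pointwise(effnet_b0(10), 16,
                                             substitute_se=False,
                                             rng=np.random.default_rng(0))
        assert without_se.n_params() > with_se.n_params()

    def test_no_l_ablation_has_fewer_parameters(self):
        full, _ = substitute_pointwise(effnet_b0(10), 16,
                                       rng=np.random.default_rng(0))
        no_l, _ = substitute_pointwise(effnet_b0(10), 16,
                                       SubnetConfig(enable_l=False),
                                       rng=np.random.default_rng(0))
        assert no_l.n_params() == 584_550 < full.n_params()


class TestForward:
    def test_output_shapes_match_baseline(self):
        desc = effnet_b0(6, input_size=32)
        base = build_baseline(desc, rng=np.random.default_rng(0))
        sub, _ = substitute_pointwise(desc, 8, rng=np.random.default_rng(0))
        x = np.random.default_rng(0).random((2, 32, 32, 3)).astype(np.float32)
        assert base(x).data.shape == sub(x).data.shape == (2, 6)


class TestStrideSkip:
    def test_zero_is_identity(self):
        desc = effnet_b0(10)
        assert apply_stride_skip(desc, 0) == desc

    def test_first_four_strided_convs_run_at_stride_one(self):
        desc = apply_stride_skip(effnet_b0(10, input_size=32), 4)
        model = build_baseline(desc, rng=np.random.default_rng(0))
        assert model.stem.stride == 1
        strides = [b.dw.stride for b in model.blocks]
        # canonical downsampling blocks sit at stage starts 2, 3, 4, 6;
        # the first three are skipped, the stage-6 one survives
        assert sum(s == 2 for s in strides) == 1

    def test_parameter_count_invariant_under_skip(self):
        for k in (0, 2, 5):
            desc = apply_stride_skip(effnet_b0(10, input_size=32), k)
            model = build_baseline(desc, rng=np.random.default_rng(0))
            assert model.n_params() == 4_020_358

    def test_too_many_skips_rejected(self):
        with pytest.raises(ValueError):
            apply_stride_skip(effnet_b0(10), 6)


@pytest.fixture(scope="module")
def small_model():
    model, _ = substitute_pointwise(effnet_b0(4, input_size=16), 8,
                                    rng=np.random.default_rng(3))
    return model


class TestHFlipEnsemble:

    def test_scores_sum_to_two(self, small_model, rng):
        x = rng.random((3, 16, 16, 3)).astype(np.float32)
        scores = hflip_ensemble_predict(small_model, x)
        assert np.allclose(scores.sum(axis=-1), 2.0, atol=1e-5)

    def test_symmetric_input_doubles_single_run(self, small_model, rng):
        half = rng.random((2, 16, 8, 3)).astype(np.float32)
        x = np.concatenate([half, half[:, :, ::-1, :]], axis=2)
        single = small_model.predict_proba(x)
        assert np.allclose(hflip_ensemble_predict(small_model, x),
                           2.0 * single, rtol=1e-4, atol=1e-6)

    def test_prediction_invariant_under_input_flip(self, small_model, rng):
        x = rng.random((3, 16, 16, 3)).astype(np.float32)
        a = hflip_ensemble_predict(small_model, x)
        b = hflip_ensemble_predict(small_model, x[:, :, ::-1, :])
        assert np.allclose(a, b, rtol=1e-4, atol=1e-6)


class TestSmokeTrain:
    def test_learns_above_chance_within_five_epochs(self):
        data = generate_synthetic_set(4, 64, 32, seed=1)
        model, _ = substitute_pointwise(effnet_b0(4, input_size=32), 8,
                                        rng=np.random.default_rng(42))
        history = smoke_train(model, data.images, data.labels,
                              epochs=5, seed=42)
        assert max(history["accuracy"]) > 0.25

    def test_zero_epochs_is_a_no_op(self):
        data = generate_synthetic_set(2, 8, 16, seed=0)
        model, _ = substitute_pointwise(effnet_b0(2, input_size=16), 4,
                                        rng=np.random.default_rng(0))
        before = [p.data.copy() for p in model.parameters()]
        history = smoke_train(model, data.images, data.labels,
                              epochs=0, seed=0)
        assert history == {"loss": [], "accuracy": []}
        for p, b in zip(model.parameters(), before):
            assert np.array_equal(p.data, b)

    def test_same_seed_reproduces_loss_trace(self):
        data = generate_synthetic_set(2, 16, 16, seed=5)
        traces = []
        for _ in range(2):
            model, _ = substitute_pointwise(effnet_b0(2, input_size=16), 4,
                                            rng=np.random.default_rng(9))
            h = smoke_train(model, data.images, data.labels,
                            epochs=2, seed=9)
            traces.append(h["loss"])
        assert traces[0] == traces[1]
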