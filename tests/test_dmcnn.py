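import numpy as np
import pytest

from dmclibs import (DMCNNConfig, ModelError, TrainConfig,
                     TrainingDivergence, backward_difference, build_model,
                     evaluate, residual_forward, se_forward, split_dataset,
                     train)
from dmclibs.dmcnn import _ResBlock

rng = np.random.default_rng(0)


# --------------------------------------------------------------------------
# backward difference
# --------------------------------------------------------------------------

def test_backward_difference_constant_is_zero():
    assert np.allclose(backward_difference(np.full(10, 3.0), 1), 0.0)


def test_backward_difference_ramp():
    assert np.allclose(backward_difference(np.array([0.0, 2, 4, 6]), 1),
                       [0.0, 2.0, 2.0, 2.0])


def test_backward_difference_matches_elementwise_recomputation():
    y = rng.normal(size=50)
    h = 2
    out = backward_difference(y, h)
    for k in range(len(y)):
        expect = 0.0 if k < h else (y[k] - y[k - h]) / h
        assert out[k] == pytest.approx(expect, abs=1e-12)


def test_backward_difference_invalid_step():
    with pytest.raises(ModelError):
        backward_difference(np.zeros(5), 0)
    with pytest.raises(ModelError):
        backward_difference(np.zeros(5), 5)


# --------------------------------------------------------------------------
# SE and residual blocks vs hand-rolled oracles
# --------------------------------------------------------------------------

def test_se_zero_weights_scale_half():
    F = rng.normal(size=(4, 8))
    out = se_forward(F, np.zeros((2, 4)), np.zeros((4, 2)))
    assert np.allclose(out, 0.5 * F)


def test_se_weights_strictly_in_unit_interval():
    from dmclibs._nn import SEBlock
    block = SEBlock(4, 2, np.random.default_rng(3))
    x = rng.normal(size=(5, 4, 8))
    y, cache = block.forward(x)
    z = cache[-1]
    assert (z > 0).all() and (z < 1).all()


def test_se_block_matches_functional_oracle():
    """Layer forward == independent evaluation of the squeeze-excite-scale
    chain on a random 4-channel x length-8 map."""
    from dmclibs._nn import SEBlock
    block = SEBlock(4, 2, np.random.default_rng(5))
    x = rng.normal(size=(1, 4, 8))
    y, _ = block.forward(x)
    oracle = se_forward(x[0], block.fc1.W.value.T, block.fc2.W.value.T,
                        block.fc1.b.value, block.fc2.b.value)
    assert np.abs(y[0] - oracle).max() < 1e-6


def _zero_main_path(block):
    for conv in (block.conv1, block.conv2):
        conv.W.value[...] = 0.0
        if conv.b is not None:
            conv.b.value[...] = 0.0
    for bn in (block.bn1, block.bn2):
        bn.beta.value[...] = 0.0


def test_residual_zero_F_is_identity():
    block = _ResBlock(4, 4, 1, 2, np.random.default_rng(1), use_se=False)
    _zero_main_path(block)
    x = np.abs(rng.normal(size=(4, 8)))      # nonnegative, as post-ReLU input
    out = residual_forward(x, block)
    assert np.abs(out - x).max() < 1e-5


def test_res_down_zero_main_is_shortcut_conv():
    block = _ResBlock(4, 6, 2, 2, np.random.default_rng(2), use_se=False)
    _zero_main_path(block)
    x = rng.normal(size=(1, 4, 8))
    out = residual_forward(x, block)
    shortcut, _ = block.downsample.forward(x)
    assert np.abs(out - np.maximum(shortcut, 0.0)).max() < 1e-5


def test_residual_matches_manual_recomputation():
    """y = relu(F(x) + shortcut(x)) recomputed layer by layer."""
    block = _ResBlock(4, 4, 1, 2, np.random.default_rng(9))
    x = rng.normal(size=(1, 4, 8))
    out = residual_forward(x, block)
    h, _ = block.conv1.forward(x)
    h, _ = block.bn1.forward(h)
    h = np.maximum(h, 0.0)
    h, _ = block.conv2.forward(h)
    h, _ = block.bn2.forward(h)
    h, _ = block.se.forward(h)
    manual = np.maximum(h + x, 0.0)
    assert np.abs(out - manual).max() < 1e-6


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------

def test_stream_weight_sharing_is_same_storage():
    model = build_model(DMCNNConfig(share_stream_weights=True))
    assert model.stream is model.stream_diff
    w = model.stream["msconv"].W.value
    w[0, 0, 0] = 123.0
    assert model.stream_diff["msconv"].W.value[0, 0, 0] == 123.0


def test_shared_parameter_count_equals_single_stream():
    shared = build_model(DMCNNConfig(share_stream_weights=True))
    unshared = build_model(DMCNNConfig(share_stream_weights=False))

    def stream_param_count(m, st):
        mods = st["scale_convs"] + [st["msconv"], st["res_basic"],
                                    st["res_down"]]
        return sum(p.value.size for mod in mods for p in mod.params())

    n_shared = sum(p.value.size for p in shared.params())
    n_unshared = sum(p.value.size for p in unshared.params())
    assert n_unshared - n_shared == stream_param_count(unshared,
                                                       unshared.stream_diff)


def test_forward_shape_contract():
    model = build_model(DMCNNConfig(n_classes=2))
    x = rng.normal(size=(6, 2048))
    logits, _ = model.forward(x)
    assert logits.shape == (6, 2)


@pytest.mark.parametrize("use_diff,use_ms", [(False, False), (True, False),
                                             (False, True), (True, True)])
def test_ablation_arms_build_and_run(use_diff, use_ms):
    cfg = DMCNNConfig(input_length=256, use_backward_difference=use_diff,
                      use_multiscale=use_ms)
    model = build_model(cfg)
    logits, _ = model.forward(rng.normal(size=(3, 256)))
    assert logits.shape == (3, 2)


def test_base_module_has_single_scale_single_stream():
    cfg = DMCNNConfig(use_backward_difference=False, use_multiscale=False)
    model = build_model(cfg)
    assert len(model.stream["scale_convs"]) == 1


def test_wrong_input_length_raises():
    model = build_model(DMCNNConfig(input_length=2048))
    with pytest.raises(ModelError, match="length"):
        model.forward(rng.normal(size=(2, 100)))


def test_invalid_configs_raise():
    with pytest.raises(ModelError):
        DMCNNConfig(dropout_rate=1.0)
    with pytest.raises(ModelError):
        DMCNNConfig(kernel_sizes=(2, 3))
    with pytest.raises(ModelError):
        DMCNNConfig(diff_step_h=0)


# --------------------------------------------------------------------------
# dataset splitting
# --------------------------------------------------------------------------

def test_split_sizes_622(preprocessed_default):
    tr, va, te = split_dataset(preprocessed_default, (0.6, 0.2, 0.2), seed=0)
    assert (len(tr), len(va), len(te)) == (1200, 400, 400)
    for part in (tr, va, te):                     # stratified
        assert int((part.labels == 0).sum()) == len(part) // 2


def test_split_sizes_73(preprocessed_default):
    tr, te = split_dataset(preprocessed_default, (0.7, 0.3), seed=0)
    assert (len(tr), len(te)) == (1400, 600)


def test_split_tiny_n10():
    from dmclibs import SpectralDataset
    ds = SpectralDataset(np.arange(4.0), rng.normal(size=(10, 4)),
                         [0, 1] * 5, ["a", "b"])
    tr, va, te = split_dataset(ds, (0.6, 0.2, 0.2), seed=1)
    assert (len(tr), len(va), len(te)) == (6, 2, 2)


def test_split_deterministic_and_disjoint(preprocessed_default):
    a = split_dataset(preprocessed_default, (0.6, 0.2, 0.2), seed=3)
    b = split_dataset(preprocessed_default, (0.6, 0.2, 0.2), seed=3)
    for pa, pb in zip(a, b):
        assert pa.sample_ids == pb.sample_ids
    ids = [set(p.sample_ids) for p in a]
    assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) \
        and not (ids[1] & ids[2])
    assert sum(map(len, a)) == len(preprocessed_default)


def test_group_aware_split_keeps_tablets_whole(preprocessed_default):
    tr, va, te = split_dataset(preprocessed_default, (0.6, 0.2, 0.2),
                               seed=0, group_aware=True)
    sets = [set(p.groups) for p in (tr, va, te)]
    assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
        and not (sets[1] & sets[2])


def test_split_too_few_spectra_raises():
    from dmclibs import SpectralDataset
    ds = SpectralDataset(np.arange(4.0), rng.normal(size=(3, 4)),
                         [0, 0, 1], ["a", "b"])
    with pytest.raises(ModelError, match="fewer"):
        split_dataset(ds, (0.6, 0.2, 0.2))


# --------------------------------------------------------------------------
# training and evaluation
# --------------------------------------------------------------------------

def test_zero_learning_rate_leaves_weights_unchanged(tiny_dataset):
    from dmclibs import preprocess_pipeline
    pp = preprocess_pipeline(tiny_dataset)
    tr, va, te = split_dataset(pp, (0.6, 0.2, 0.2), seed=0)
    model = build_model(DMCNNConfig(input_length=256), seed=0)
    before = [p.value.copy() for p in model.params()]
    model, _ = train(model, tr, va, TrainConfig(learning_rate=0.0, epochs=2,
                                                seed=0))
    for p, b in zip(model.params(), before):
        assert np.array_equal(p.value, b)


def test_divergence_raises_with_epoch(tiny_dataset):
    from dmclibs import preprocess_pipeline
    pp = preprocess_pipeline(tiny_dataset)
    tr, va, _ = split_dataset(pp, (0.6, 0.2, 0.2), seed=0)
    model = build_model(DMCNNConfig(input_length=256), seed=0)
    with pytest.raises(TrainingDivergence, match="epoch"):
        train(model, tr, va, TrainConfig(learning_rate=1e9, epochs=3, seed=0))


def test_training_learns_separable_tiny_task(tiny_dataset):
    """Clear class structure: training accuracy >= 0.99 in a short budget."""
    from dmclibs import preprocess_pipeline
    pp = preprocess_pipeline(tiny_dataset)
    tr, va, te = split_dataset(pp, (0.6, 0.2, 0.2), seed=0)
    model = build_model(DMCNNConfig(input_length=256), seed=0)
    model, hist = train(model, tr, va,
                        TrainConfig(learning_rate=0.01, epochs=25, seed=0))
    assert max(hist.train_accuracy_trace) >= 0.99
    result = evaluate(model, te, hist)
    assert result.n == len(te)
    assert result.train_accuracy_trace == hist.train_accuracy_trace


def test_evaluation_deterministic(tiny_dataset):
    from dmclibs import preprocess_pipeline
    pp = preprocess_pipeline(tiny_dataset)
    tr, va, te = split_dataset(pp, (0.6, 0.2, 0.2), seed=0)
    model = build_model(DMCNNConfig(input_length=256), seed=0)
    model, _ = train(model, tr, None, TrainConfig(learning_rate=0.01,
                                                  epochs=2, seed=0))
    a = evaluate(model, te)
    b = evaluate(model, te)
    assert (a.tp, a.tn, a.fp, a.fn, a.accuracy) == \
        (b.tp, b.tn, b.fp, b.fn, b.accuracy)


def test_evaluate_counts_sum_and_accuracy():
    class Fixed:
        def __init__(self, pred):
            self.pred = np.asarray(pred)

        def predict(self, X):
            return self.pred[:len(X)]

    from dmclibs import SpectralDataset
    ds = SpectralDataset(np.arange(4.0), np.zeros((8, 4)),
                         [0, 0, 0, 0, 1, 1, 1, 1], ["pos", "neg"])
    res = evaluate(Fixed([0, 0, 0, 1, 1, 1, 0, 0]), ds)
    assert (res.tp, res.fn, res.tn, res.fp) == (3, 1, 2, 2)
    assert res.n == 8
    assert res.accuracy == pytest.approx((res.tp + res.tn) / res.n)


def test_evaluate_empty_raises():
    from dmclibs import SpectralDataset
    ds = SpectralDataset(np.arange(4.0), np.empty((0, 4)), [], ["a"])
    with pytest.raises(ModelError, match="empty"):
        evaluate(None, ds)


def test_train_config_validation():
    with pytest.raises(ModelError):
        TrainConfig(split_ratios=(0.5, 0.2, 0.2))
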