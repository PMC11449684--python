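"""Layer gradients, the training loop contract, and prediction."""

import numpy as np
import pytest

from actsign import (ActivationSpec, PhantomSpec, SplitSpec, TrainConfig,
                     build_network, default_network, generate_phantoms,
                     predict, split_dataset, train)
from actsign._nn import (Activation, BatchNorm2D, Conv2D, Dense, Flatten,
                         MaxPool2D, Model, cross_entropy, softmax)
from actsign.training import TrainingError


def _numeric_grad(fn, x, eps=1e-3):
    """Central-difference gradient of scalar fn w.r.t. array x (float64)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = fn()
        x[i] = orig - eps
        fm = fn()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


@pytest.mark.parametrize("make_layer", [
    lambda rng: Conv2D(2, 3, (3, 3), (2, 2), 1, rng),
    lambda rng: Conv2D(2, 2, (3, 3), (3, 3), 1, rng),   # default-geometry stride
    lambda rng: BatchNorm2D(2),
    lambda rng: MaxPool2D((3, 3), (1, 1), 1),
    lambda rng: Activation(ActivationSpec("rectified_softsign")),
    lambda rng: Activation(ActivationSpec("gelu")),
], ids=["conv_s2", "conv_s3", "batchnorm", "maxpool_same", "act_rsoftsign", "act_gelu"])
def test_layer_backward_matches_numeric_gradient(make_layer):
    rng = np.random.default_rng(0)
    layer = make_layer(rng)
    # float64 inputs keep the finite-difference quotient well conditioned
    x = rng.normal(size=(2, 7, 7, 2))
    w_out = rng.normal(size=layer.forward(x, train=True).shape)

    def loss():
        return float((layer.forward(x, train=True) * w_out).sum())

    loss()
    dx = layer.backward(w_out)
    num_dx = _numeric_grad(loss, x)
    np.testing.assert_allclose(dx, num_dx, rtol=2e-2, atol=2e-3)
    for name in layer.params:
        num_dp = _numeric_grad(loss, layer.params[name])
        loss()
        layer.backward(w_out)
        np.testing.assert_allclose(layer.grads[name], num_dp, rtol=2e-2, atol=2e-3)


def test_dense_backward_matches_numeric_gradient():
    rng = np.random.default_rng(1)
    layer = Dense(6, 4, rng)
    x = rng.normal(size=(3, 6))
    w_out = rng.normal(size=(3, 4))

    def loss():
        return float((layer.forward(x, train=True) * w_out).sum())

    loss()
    dx = layer.backward(w_out)
    np.testing.assert_allclose(dx, _numeric_grad(loss, x), rtol=2e-2, atol=2e-3)
    num_dw = _numeric_grad(loss, layer.params["w"])
    loss()
    layer.backward(w_out)
    np.testing.assert_allclose(layer.grads["w"], num_dw, rtol=2e-2, atol=2e-3)


def test_softmax_rows_sum_to_one_and_uniform_on_equal_logits():
    rng = np.random.default_rng(2)
    p = softmax(rng.normal(size=(20, 4)) * 10)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_allclose(softmax(np.zeros((3, 4))), 0.25, atol=1e-12)


def test_predict_contract(trained_small_model):
    model = trained_small_model["model"]
    te = trained_small_model["test"]
    probs, labels = predict(model, te.images)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
    np.testing.assert_array_equal(labels, probs.argmax(axis=1))
    # batch of 1 equals the corresponding row of a larger batch (eval-mode BN)
    p1, _ = predict(model, te.images[3])
    np.testing.assert_allclose(p1[0], probs[3], atol=1e-6)


def test_predict_shape_mismatch():
    net = default_network(input_shape=(32, 32, 3))
    model = build_network(net, ActivationSpec("relu"), seed=0)
    with pytest.raises(TrainingError):
        predict(model, np.zeros((2, 16, 16, 3), np.float32))


def test_class_count_mismatch_is_error(small_phantoms):
    tr, va, _ = split_dataset(small_phantoms, SplitSpec(seed=0))
    net = default_network(input_shape=(64, 64, 3), num_classes=2)
    model = build_network(net, ActivationSpec("relu"), seed=0)
    with pytest.raises(TrainingError, match="classes"):
        train(model, tr, va, TrainConfig(max_epochs=1))


def test_zero_learning_rate_leaves_parameters(small_phantoms):
    tr, va, _ = split_dataset(small_phantoms, SplitSpec(seed=0))
    net = default_network(input_shape=(64, 64, 3))
    model = build_network(net, ActivationSpec("relu"), seed=1)
    for layer in model.layers:
        if isinstance(layer, BatchNorm2D):
            layer.frozen = True          # running stats would otherwise drift
    before = model.get_state()
    model, _ = train(model, tr, va, TrainConfig(learning_rate=0.0, max_epochs=1,
                                                batch_size=16, seed=1))
    after = model.get_state()
    for b, a in zip(before, after):
        for k in b:
            np.testing.assert_allclose(b[k], a[k], atol=1e-7)


def test_training_is_deterministic_under_fixed_seed(small_phantoms):
    tr, va, _ = split_dataset(small_phantoms, SplitSpec(seed=0))
    net = default_network(input_shape=(64, 64, 3))
    histories = []
    for _ in range(2):
        model = build_network(net, ActivationSpec("softsign"), seed=3)
        _, hist = train(model, tr, va, TrainConfig(max_epochs=3, batch_size=16,
                                                   seed=3))
        histories.append(hist)
    assert histories[0].train_loss == histories[1].train_loss
    assert histories[0].val_accuracy == histories[1].val_accuracy


def test_loss_decreases_on_separable_phantoms(trained_small_model):
    hist = trained_small_model["history"]
    assert min(hist.train_loss[1:10]) < hist.train_loss[0]
    assert hist.num_epochs() == len(hist.val_loss) == len(hist.train_accuracy)


def test_trained_model_learns_small_phantoms(trained_small_model):
    """Final training accuracy is well above the 25% chance level."""
    hist = trained_small_model["history"]
    te = trained_small_model["test"]
    assert hist.train_accuracy[-1] > 0.6
    _, pred = predict(trained_small_model["model"], te.images)
    assert (pred == te.labels).mean() > 0.5


def test_best_validation_checkpoint_returned(small_phantoms):
    tr, va, _ = split_dataset(small_phantoms, SplitSpec(seed=2))
    net = default_network(input_shape=(64, 64, 3))
    model = build_network(net, ActivationSpec("relu"), seed=2)
    model, hist = train(model, tr, va, TrainConfig(max_epochs=4, batch_size=16, seed=2))
    assert hist.best_epoch == int(np.argmax(hist.val_accuracy))
    # returned parameters reproduce the best epoch's validation accuracy
    _, pred = predict(model, va.images)
    assert (pred == va.labels).mean() == pytest.approx(
        hist.val_accuracy[hist.best_epoch], abs=1e-9)


def test_cross_entropy_of_one_hot_is_zero():
    probs = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert cross_entropy(probs, np.array([0, 1])) == pytest.approx(0.0, abs=1e-9)
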