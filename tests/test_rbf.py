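"""RBF-network regression: closed forms, training behaviour, serialization."""
import numpy as np
import pandas as pd
import pytest

from pearmedia.datasets import load_dataset, split_train_test
from pearmedia.factors import FACTOR_NAMES
from pearmedia.metrics import compute_metrics
from pearmedia.rbf import RBFNetwork, rbf_predict, select_hidden_units, train_rbf
from pearmedia.simulate import generate_replicates, spec_from_published


def _unit_net(w=2.0, b=0.5, sigma=1.0):
    return RBFNetwork(
        centers=np.array([[1.0, -1.0]]), widths=np.array([sigma]),
        weights=np.array([w]), bias=b,
        x_mean=np.zeros(2), x_std=np.ones(2), feature_names=("x1", "x2"),
    )


def test_prediction_closed_forms():
    net = _unit_net()
    assert rbf_predict(net, np.array([1.0, -1.0])) == pytest.approx(2.5)
    # at distance sigma from the center the activation is exp(-1/2)
    x = np.array([1.0, -1.0 + 1.0])
    assert rbf_predict(net, x) == pytest.approx(2.0 * np.exp(-0.5) + 0.5)
    zero_w = _unit_net(w=0.0, b=0.7)
    for x in ([0, 0], [3, 3], [-5, 2]):
        assert rbf_predict(zero_w, np.array(x, float)) == pytest.approx(0.7)


def test_dimension_mismatch_raises():
    with pytest.raises(ValueError, match="dimension"):
        rbf_predict(_unit_net(), np.array([1.0, 2.0, 3.0]))


def test_width_shrink_kills_off_center_activation():
    wide, narrow = _unit_net(sigma=1.0), _unit_net(sigma=1e-3)
    x = np.array([1.3, -1.0])
    assert abs(rbf_predict(narrow, x) - 0.5) < 1e-12   # -> bias only
    assert rbf_predict(wide, x) > 0.5


def test_invalid_network_parameters():
    with pytest.raises(ValueError):
        _unit_net(sigma=-1.0)
    with pytest.raises(ValueError):
        RBFNetwork(centers=np.zeros((2, 2)), widths=np.ones(1),
                   weights=np.ones(2), bias=0.0,
                   x_mean=np.zeros(2), x_std=np.ones(2))


@pytest.fixture(scope="module")
def bump_data():
    rng = np.random.default_rng(0)
    X = rng.uniform(-1, 1, size=(120, 2))
    cstar = np.array([0.1, -0.2])
    y = np.exp(-((X - cstar) ** 2).sum(1) / (2 * 0.5 ** 2))
    return pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1], "y": y})


def test_single_gaussian_bump_is_recovered(bump_data):
    """A realizable one-unit target trains to near-zero MSE."""
    net = train_rbf(bump_data, "y", n_hidden=1, learning_rate=0.1,
                    epochs=4000, seed=0, feature_names=("x1", "x2"))
    assert net.loss_history[-1] < 1e-4


def test_zero_epochs_returns_initialization(bump_data):
    net = train_rbf(bump_data, "y", n_hidden=3, epochs=0, seed=1,
                    feature_names=("x1", "x2"))
    assert net.loss_history == ()
    np.testing.assert_array_equal(net.weights, np.zeros(3))
    # zero weights => constant prediction at the target mean
    pred = net.predict(bump_data)
    np.testing.assert_allclose(pred, bump_data["y"].mean(), rtol=1e-12)


def test_loss_decreases_monotonically_at_small_step(bump_data):
    net = train_rbf(bump_data, "y", n_hidden=4, learning_rate=1e-4,
                    epochs=300, seed=0, feature_names=("x1", "x2"))
    loss = np.array(net.loss_history)
    assert (np.diff(loss) <= 1e-12).all()


def test_training_argument_validation(bump_data):
    with pytest.raises(ValueError):
        train_rbf(bump_data, "y", n_hidden=0, feature_names=("x1", "x2"))
    with pytest.raises(ValueError):
        train_rbf(bump_data, "y", learning_rate=-0.1, feature_names=("x1", "x2"))
    with pytest.raises(ValueError):
        train_rbf(bump_data.head(3), "y", n_hidden=5, feature_names=("x1", "x2"))


def test_seeded_training_is_deterministic(bump_data):
    a = train_rbf(bump_data, "y", n_hidden=3, epochs=50, seed=9,
                  feature_names=("x1", "x2"))
    b = train_rbf(bump_data, "y", n_hidden=3, epochs=50, seed=9,
                  feature_names=("x1", "x2"))
    np.testing.assert_array_equal(a.weights, b.weights)
    np.testing.assert_array_equal(a.centers, b.centers)


def test_json_round_trip(bump_data):
    net = train_rbf(bump_data, "y", n_hidden=3, epochs=100, seed=2,
                    feature_names=("x1", "x2"))
    clone = RBFNetwork.from_json(net.to_json())
    X = bump_data[["x1", "x2"]].to_numpy()
    np.testing.assert_allclose(clone.predict(X), net.predict(X), rtol=1e-12)


def test_holdout_fit_on_noiseless_media_surface():
    """Sanity bar: R^2 >= 0.9 on held-out design points of a smooth surface."""
    design = load_dataset("Pyrodwarf")[["medium_id", *FACTOR_NAMES]]
    spec = spec_from_published("Pyrodwarf", 0.0, replicates=1)
    df = generate_replicates(design, spec, seed=1)
    sp = split_train_test(df, 0.7, seed=2)
    net = train_rbf(sp.train, "STN", n_hidden=15, epochs=2000, seed=0)
    rep = compute_metrics(sp.test["STN"].to_numpy(float), net.predict(sp.test))
    assert rep.r_squared >= 0.9


def test_hidden_unit_selection_by_holdout_rmse(bump_data):
    best, scores = select_hidden_units(bump_data, "y", candidates=(1, 3),
                                       seed=0, epochs=300,
                                       feature_names=("x1", "x2"))
    assert best in scores and len(scores) == 2
    assert scores[best] == min(scores.values())
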