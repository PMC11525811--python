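"""scikit-learn estimator interface.

``RayBNNRegressor`` wraps the full pipeline — spherical cell placement, ray
traced connectivity, sparse recurrent forward pass, and gradient training —
behind fit/predict so the network composes with sklearn pipelines and model
selection.  Each sample is injected as one input vector and read back after
the propagation delay ``k``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .geometry import GeometryConfig, populate_sphere
from .network import build_model, forward
from .raytracing import RTConfig, trace
from .training import TrainConfig, train

__all__ = ["RayBNNRegressor"]


class RayBNNRegressor(RegressorMixin, BaseEstimator):
    """Ray-traced biological neural network for regression.

    Parameters
    ----------
    n_hidden, n_glial : int
        Hidden neurons and glial occluders placed uniformly in the network
        sphere.  Glial cells only block line-of-sight connections.
    rt_algorithm : {'rt1', 'rt2', 'rt3'}
        Connection-forming ray tracer; RT-3 limits connection lengths to
        ``2 * rt_radius``.
    rt_radius : float
        RT-3 cluster radius, in units of the cell radius.
    sphere_radius : float or None
        Network sphere radius; raised automatically to the minimum radius
        keeping the collision probability under ``collision_threshold``.
    k : int or None
        Propagation delay (update steps between input injection and output
        read-out); None uses the mean input-to-output path length.
    epochs, learning_rate, optimizer : training settings (full batch).
    prune_every, delete_fraction : probabilistic connection-deletion schedule
        (0 disables pruning during fit).
    random_state : int or None
        Seed controlling placement, tracing and initialization.

    Attributes
    ----------
    model_ : RayBNNModel
        The trained network (population, sparse weights, biases, per-neuron
        activation parameters).
    loss_history_ : list of float
        Training loss per epoch.
    n_features_in_ : int
    """

    def __init__(self, n_hidden=40, n_glial=40, rt_algorithm="rt3",
                 rt_radius=40.0, rays_per_neuron=10_000, sphere_radius=None,
                 collision_threshold=0.01, k=None, epochs=200,
                 learning_rate=0.02, optimizer="adam", prune_every=0,
                 delete_fraction=0.05, input_layout="helix", random_state=None):
        self.n_hidden = n_hidden
        self.n_glial = n_glial
        self.rt_algorithm = rt_algorithm
        self.rt_radius = rt_radius
        self.rays_per_neuron = rays_per_neuron
        self.sphere_radius = sphere_radius
        self.collision_threshold = collision_threshold
        self.k = k
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.prune_every = prune_every
        self.delete_fraction = delete_fraction
        self.input_layout = input_layout
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, multi_output=True, y_numeric=True)
        y2 = y if y.ndim == 2 else y[:, None]
        self.n_features_in_ = X.shape[1]
        self._n_outputs = y2.shape[1]
        seed = self.random_state
        rng = np.random.default_rng(seed)
        cfg = GeometryConfig(
            n_hidden=self.n_hidden, n_glial=self.n_glial,
            n_input=self.n_features_in_, n_output=self._n_outputs,
            r_s=self.sphere_radius, p_c_threshold=self.collision_threshold,
            input_layout=self.input_layout,
            seed=None,
        )
        population, self.placement_stats_ = populate_sphere(cfg, rng)
        rt_cfg = RTConfig(
            algorithm=self.rt_algorithm, rays_per_neuron=self.rays_per_neuron,
            r_rt=self.rt_radius if self.rt_algorithm == "rt3" else None,
        )
        connections = trace(population, rt_cfg, rng)
        self.model_ = build_model(population, connections, rng, k=self.k)
        train_cfg = TrainConfig(
            optimizer=self.optimizer, learning_rate=self.learning_rate,
            epochs=self.epochs, delete_fraction=self.delete_fraction,
            prune_every=self.prune_every,
        )
        inputs = X.T[None, :, :]   # (I_T=1, N_I, B)
        targets = y2.T[None, :, :]
        log = train(self.model_, inputs, targets, train_cfg, rng=rng)
        self.loss_history_ = [entry["loss"] for entry in log]
        self.n_iter_ = len(log)
        self._y_1d = y.ndim == 1
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; expected {self.n_features_in_}"
            )
        out = forward(self.model_, X.T[None, :, :])[0].T  # (B, N_O)
        return out[:, 0] if self._y_1d else out
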