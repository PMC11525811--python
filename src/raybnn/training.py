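"""Loss, sparse backpropagation through time, optimizer steps, and pruning.

The loss over a time series of I_T input/target pairs is

    J = (1/I_T) sum_t (Yhat^t - Y^t)^T (Yhat^t - Y^t)

and gradients are obtained by reverse-mode recursion through all U = I_T + k
update steps.  Gradients of the weight matrix are accumulated only at the
live sparse positions (row-major entry order); biases and the per-neuron UAF
parameters ride the same chain rule.  Input-slot overwrites cut gradient flow
into the overwritten coordinates.

Connection deletion follows the probabilistic rule: each live entry gets a
uniform random factor, and the requested fraction of entries with smallest
|random * weight| score is removed — zero-valued weights go first, large
weights survive with high probability.  Neurons left without outgoing
connections are redundant and are removed without changing the network
function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    RayBNNModel,
    enforce_structural_zeros,
    forward,
    uaf_gradients,
)

__all__ = [
    "Gradients",
    "TrainConfig",
    "AdamState",
    "loss_mse",
    "backprop",
    "optimizer_step",
    "train",
    "delete_connections_probabilistic",
    "delete_redundant_neurons",
    "count_trainable_params",
]


@dataclass
class Gradients:
    """dW aligned with the row-major flattened live entries of W; dH length N
    (zero on input slots); dC_eff N x 5."""

    dW: np.ndarray
    dH: np.ndarray
    dC: np.ndarray


@dataclass
class TrainConfig:
    loss: str = "mse"
    optimizer: str = "adam"
    learning_rate: float = 0.01
    epochs: int = 200
    delete_fraction: float = 0.05
    prune_every: int = 0  # epochs between probabilistic deletion sweeps; 0 = off
    train_uaf: bool = True
    train_bias: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.loss != "mse":
            raise ValueError("only the mse loss is implemented")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= self.delete_fraction < 1.0:
            raise ValueError("delete_fraction must be in [0, 1)")


def loss_mse(predicted, targets) -> float:
    """J = (1/I_T) sum_t ||Yhat^t - Y^t||^2, averaged over any batch axis."""
    predicted = np.asarray(predicted, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predicted.shape != targets.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {targets.shape}")
    i_t = predicted.shape[0]
    diff = predicted - targets
    per_step = np.sum(diff * diff, axis=1)  # sum over output coordinates
    return float(np.mean(np.sum(per_step, axis=0)) / i_t)


def backprop(model: RayBNNModel, inputs, targets) -> tuple[float, Gradients]:
    """Loss and gradients for one (batched) input/target sequence.

    ``inputs``: (I_T, N_I[, B]); ``targets``: (I_T, N_O[, B]).  Returns
    ``(J, Gradients)`` with dW per live entry in row-major entry order.
    """
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
        y = y[:, :, None]
    i_t, _, batch = x.shape
    if y.shape != (i_t, model.n_output, batch):
        raise ValueError("target shape mismatch")
    yhat, state = forward(model, x, return_state=True)
    j = loss_mse(yhat, y)

    n, k = model.n, model.k
    n_i = model.n_input
    w_csr = model.weights.tocsr()
    w_t = w_csr.T.tocsr()
    rows, cols = model.weights.rows, model.weights.cols
    c_eff = model.uaf.c_eff
    out_sl = model.output_slots

    n_steps = i_t + k - 1  # updates performed by the forward pass
    if len(state.z_history) != n_steps:
        raise RuntimeError("missing forward history")

    d_w = np.zeros(model.weights.nnz)
    d_h = np.zeros(n)
    d_c = np.zeros((n, 5))
    # adjoint of S^{t+1} while sweeping t backwards
    b_next = np.zeros((n, batch))
    scale = 2.0 / (i_t * batch)
    for t in range(n_steps - 1, -1, -1):
        # loss injection: S^{t+1} supplies Yhat^{t+1-k}
        t_out = t + 1 - k
        if 0 <= t_out < i_t:
            b_next[out_sl, :] += scale * (yhat[t_out] - y[t_out])
        z = state.z_history[t]
        q = state.q_history[t]
        a, b_p, c_p, d_p, _ = (c_eff[:, m][:, None] for m in range(5))
        dfdx, dfda, dfdb, dfdc, dfdd, dfde = uaf_gradients(z, a, b_p, c_p, d_p, 0.0)
        g = dfdx * b_next  # adjoint of Z^t
        d_h += g.sum(axis=1)
        d_w += np.einsum("eb,eb->e", g[rows, :], q[cols, :])
        d_c[:, 0] += (dfda * b_next).sum(axis=1)
        d_c[:, 1] += (dfdb * b_next).sum(axis=1)
        d_c[:, 2] += (dfdc * b_next).sum(axis=1)
        d_c[:, 3] += (dfdd * b_next).sum(axis=1)
        d_c[:, 4] += (dfde * b_next).sum(axis=1)
        # propagate to S^t through Q^t; input coordinates are overwritten by
        # the injected X and carry no dependence on the state
        b_next = w_t @ g
        b_next[:n_i, :] = 0.0
    d_h[:n_i] = 0.0  # input-slot biases are fixed at zero
    return j, Gradients(dW=d_w, dH=d_h, dC=d_c)


@dataclass
class AdamState:
    m_w: np.ndarray
    v_w: np.ndarray
    m_h: np.ndarray
    v_h: np.ndarray
    m_c: np.ndarray
    v_c: np.ndarray
    t: int = 0

    @classmethod
    def for_model(cls, model: RayBNNModel) -> "AdamState":
        return cls(
            m_w=np.zeros(model.weights.nnz), v_w=np.zeros(model.weights.nnz),
            m_h=np.zeros(model.n), v_h=np.zeros(model.n),
            m_c=np.zeros((model.n, 5)), v_c=np.zeros((model.n, 5)),
        )


def _adam_update(param, grad, m, v, t, lr, b1=0.9, b2=0.999, eps=1e-8):
    m *= b1
    m += (1 - b1) * grad
    v *= b2
    v += (1 - b2) * grad * grad
    m_hat = m / (1 - b1**t)
    v_hat = v / (1 - b2**t)
    param -= lr * m_hat / (np.sqrt(v_hat) + eps)


def optimizer_step(model: RayBNNModel, grads: Gradients, config: TrainConfig,
                   adam_state: AdamState | None = None) -> AdamState | None:
    """Apply one SGD or Adam update in place to the live weight values, the
    biases of non-input slots, and C_eff.  Structural zeros are untouched by
    construction (only live entries carry values)."""
    lr = config.learning_rate
    if config.optimizer == "sgd":
        model.weights.vals -= lr * grads.dW
        if config.train_bias:
            model.H -= lr * grads.dH
        if config.train_uaf:
            model.uaf.c_eff -= lr * grads.dC
        model.weights.invalidate()
        model.H[: model.n_input] = 0.0
        return adam_state
    if adam_state is None:
        adam_state = AdamState.for_model(model)
    adam_state.t += 1
    t = adam_state.t
    _adam_update(model.weights.vals, grads.dW, adam_state.m_w, adam_state.v_w, t, lr)
    if config.train_bias:
        _adam_update(model.H, grads.dH, adam_state.m_h, adam_state.v_h, t, lr)
    if config.train_uaf:
        _adam_update(model.uaf.c_eff, grads.dC, adam_state.m_c, adam_state.v_c, t, lr)
    model.weights.invalidate()
    model.H[: model.n_input] = 0.0
    return adam_state


def train(model: RayBNNModel, inputs, targets, config: TrainConfig,
          val_inputs=None, val_targets=None,
          stop_loss: float | None = None,
          rng: np.random.Generator | None = None):
    """Full-batch training loop.  Returns a per-epoch log (list of dicts with
    epoch, train/validation loss, nnz, active neuron and parameter counts).

    ``stop_loss`` stops early once the training loss falls at or below the
    threshold.  When ``prune_every`` is set, a probabilistic deletion sweep
    runs every that many epochs (fresh Adam moments afterwards, since the
    entry layout changed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    adam_state: AdamState | None = None
    log = []
    for epoch in range(1, config.epochs + 1):
        j, grads = backprop(model, inputs, targets)
        adam_state = optimizer_step(model, grads, config, adam_state)
        entry = {
            "epoch": epoch,
            "loss": j,
            "nnz": model.weights.nnz,
            "active_neurons": model.n_active,
            "params": count_trainable_params(model),
        }
        if val_inputs is not None:
            entry["val_loss"] = loss_mse(forward(model, val_inputs), np.asarray(val_targets, float))
        log.append(entry)
        if stop_loss is not None and j <= stop_loss:
            break
        if config.prune_every and epoch % config.prune_every == 0 and model.weights.nnz:
            delete_connections_probabilistic(model.weights, config.delete_fraction, rng)
            enforce_structural_zeros(model.weights, model.n_input, model.n_output,
                                     model.allow_self_loops)
            adam_state = None
    return log


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def delete_connections_probabilistic(weights, fraction: float,
                                     rng: np.random.Generator):
    """Probabilistic magnitude-biased deletion: draw R_e ~ U(0,1) per live
    entry, score by |R_e * w_e| and remove exactly ceil(fraction * nnz)
    entries with the smallest scores (stable order on ties).  Returns the
    removed (row, col, value) triples."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    nnz = weights.nnz
    n_del = int(np.ceil(fraction * nnz))
    if n_del == 0:
        return []
    score = np.abs(rng.random(nnz) * weights.vals)
    idx = np.argsort(score, kind="stable")[:n_del]
    removed = list(zip(weights.rows[idx].tolist(), weights.cols[idx].tolist(),
                       weights.vals[idx].tolist()))
    weights.drop(idx)
    return removed


def delete_redundant_neurons(model: RayBNNModel):
    """Remove every hidden neuron with out-degree zero, cascading to a fixed
    point.  A redundant neuron's incoming row is zeroed, its slot freed and
    its cell dropped from the population; because its outgoing column was
    already empty the network outputs are unchanged bit for bit.  Input and
    output neurons are exempt.  Returns the removed cell ids."""
    removed: list[int] = []
    n = model.n
    while True:
        out_deg = model.weights.out_degree()
        hidden_slots = np.flatnonzero(model.slot_cell >= 0)
        hidden_slots = hidden_slots[(hidden_slots >= model.n_input) & (hidden_slots < n - model.n_output)]
        dead = hidden_slots[out_deg[hidden_slots] == 0]
        # only neurons that still have incoming rows or an occupied slot matter
        if len(dead) == 0:
            break
        kill_entries = np.flatnonzero(np.isin(model.weights.rows, dead))
        if len(kill_entries):
            model.weights.drop(kill_entries)
        for slot in dead:
            removed.append(int(model.slot_cell[slot]))
            model.slot_cell[slot] = -1
    if removed:
        keep = ~np.isin(model.population.cell_id, removed)
        model.population.positions = model.population.positions[keep]
        model.population.cell_type = model.population.cell_type[keep]
        model.population.cell_id = model.population.cell_id[keep]
    return removed


def count_trainable_params(model: RayBNNModel) -> int:
    """nnz live weights + biases of active non-input slots + 5 UAF parameters
    per active non-input slot."""
    active = model.slot_cell >= 0
    active_non_input = int(active[model.n_input :].sum())
    return int(model.weights.nnz + active_non_input + 5 * active_non_input)
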