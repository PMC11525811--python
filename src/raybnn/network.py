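"""Sparse weighted adjacency matrix, universal activation functions, and the
time-stepped forward pass.

The network state is a length-N vector updated as

    Q^t <- S^t;  Q^t[0:N_I] <- X^t;  S^{t+1} <- f_UAF(W Q^t + H, C_eff)

where entry (i, j) of the sparse matrix W carries the signal from neuron j
into neuron i under the product W Q.  Input neurons occupy slots 0..N_I-1,
output neurons the last N_O slots; structural zeros keep rows of input slots,
columns of output slots, and (without self-loops) the diagonal empty.  After
``k`` update steps (the propagation delay) the output vector for input X^t is
read from the output slots of S^{t+k}.

Every neuron owns a five-parameter universal activation function (UAF)

    f(x) = ln(1 + exp(A(x+B) - |C| x^2)) - ln(1 + exp(D(x-B))) + E

whose parameters (rows of the N x 5 matrix C_eff) are trainable; with
(A, B, C, D, E) = (1, 0, 0, -1, 0) the UAF is exactly the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite
from scipy.sparse.csgraph import shortest_path

from .geometry import CellPopulation, write_positions, read_positions
from .raytracing import ConnectionSet

__all__ = [
    "SparseWeights",
    "UAFParams",
    "RayBNNModel",
    "NetworkState",
    "uaf",
    "uaf_vector",
    "uaf_gradients",
    "identity_uaf_params",
    "init_uaf_params",
    "init_weights_xavier",
    "enforce_structural_zeros",
    "forward",
    "default_delay",
    "build_model",
    "save_model",
    "load_model",
    "default_capacity",
]

IDENTITY_UAF = np.array([1.0, 0.0, 0.0, -1.0, 0.0])


# ---------------------------------------------------------------------------
# universal activation function
# ---------------------------------------------------------------------------

def _softplus(z):
    # overflow-safe: softplus(z) = max(z, 0) + log1p(exp(-|z|))
    z = np.asarray(z, dtype=float)
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def _sigmoid(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def uaf(x, a, b, c, d, e):
    """Scalar/array universal activation function (overflow-safe)."""
    x = np.asarray(x, dtype=float)
    arg1 = a * (x + b) - np.abs(c) * x * x
    arg2 = d * (x - b)
    out = _softplus(arg1) - _softplus(arg2) + e
    return out if out.ndim else float(out)


def uaf_vector(x, c_eff):
    """Apply the per-neuron UAF elementwise: row i of ``c_eff`` activates
    ``x[i]``.  ``x`` may be (N,) or (N, B) for a batch of B state columns."""
    x = np.asarray(x, dtype=float)
    c_eff = np.asarray(c_eff, dtype=float)
    if x.shape[0] != c_eff.shape[0]:
        raise ValueError(f"state length {x.shape[0]} != parameter rows {c_eff.shape[0]}")
    cols = (slice(None),) + (None,) * (x.ndim - 1)
    a, b, c, d, e = (c_eff[:, k][cols] for k in range(5))
    return uaf(x, a, b, c, d, e)


def uaf_gradients(x, a, b, c, d, e):
    """Partial derivatives of the UAF w.r.t. (x, A, B, C, D, E).

    Uses the logistic sigma of each softplus argument; the |C| kink at C = 0
    takes sign(0) := 0 (subgradient choice).  Broadcasts over arrays.
    """
    x = np.asarray(x, dtype=float)
    arg1 = a * (x + b) - np.abs(c) * x * x
    arg2 = d * (x - b)
    s1 = _sigmoid(arg1)
    s2 = _sigmoid(arg2)
    df_dx = s1 * (a - 2.0 * np.abs(c) * x) - s2 * d
    df_da = s1 * (x + b)
    df_db = s1 * a + s2 * d
    df_dc = s1 * (-np.sign(c)) * x * x
    df_dd = -s2 * (x - b)
    df_de = np.ones_like(s1 + s2)
    return df_dx, df_da, df_db, df_dc, df_dd, df_de


def identity_uaf_params(n: int) -> np.ndarray:
    return np.tile(IDENTITY_UAF, (n, 1))


def init_uaf_params(n: int, rng: np.random.Generator, jitter: float = 0.01) -> np.ndarray:
    """Near-identity initialization: (1, 0, 0, -1, 0) plus Gaussian jitter so
    an untrained network starts close to linear."""
    return identity_uaf_params(n) + jitter * rng.standard_normal((n, 5))


@dataclass
class UAFParams:
    """N x 5 matrix of per-neuron activation parameters (A, B, C, D, E);
    rows of inactive slots are ignored."""

    c_eff: np.ndarray

    def __post_init__(self):
        self.c_eff = np.asarray(self.c_eff, dtype=float).reshape(-1, 5)
        if not np.all(np.isfinite(self.c_eff)):
            raise ValueError("UAF parameters must be finite")

    def __call__(self, x):
        return uaf_vector(x, self.c_eff)


# ---------------------------------------------------------------------------
# sparse weights
# ---------------------------------------------------------------------------

@dataclass
class SparseWeights:
    """N x N weighted adjacency matrix with structural-zero constraints.

    Held in COO-like arrays (``rows``, ``cols``, ``vals``) kept sorted
    row-major — the flattening order of the gradient vector — and converted
    to CSR on demand for products.  Entry (i, j) carries the connection from
    neuron j into neuron i.
    """

    n: int
    rows: np.ndarray
    cols: np.ndarray
    vals: np.ndarray

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int).ravel()
        self.cols = np.asarray(self.cols, dtype=int).ravel()
        self.vals = np.asarray(self.vals, dtype=float).ravel()
        self._sort()
        self._csr = None

    def _sort(self):
        order = np.lexsort((self.cols, self.rows))  # row-major
        self.rows = self.rows[order]
        self.cols = self.cols[order]
        self.vals = self.vals[order]

    @property
    def nnz(self) -> int:
        return len(self.vals)

    def tocsr(self) -> sparse.csr_matrix:
        if self._csr is None:
            self._csr = sparse.csr_matrix(
                (self.vals, (self.rows, self.cols)), shape=(self.n, self.n)
            )
        return self._csr

    def invalidate(self):
        self._csr = None

    def set_values(self, vals: np.ndarray):
        if len(vals) != self.nnz:
            raise ValueError("value vector length mismatch")
        self.vals = np.asarray(vals, dtype=float).copy()
        self.invalidate()

    def matvec(self, q: np.ndarray) -> np.ndarray:
        return self.tocsr() @ q

    def out_degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        np.add.at(deg, self.cols, 1)
        return deg

    def in_degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        np.add.at(deg, self.rows, 1)
        return deg

    def drop(self, entry_indices: np.ndarray):
        keep = np.ones(self.nnz, dtype=bool)
        keep[np.asarray(entry_indices, int)] = False
        self.rows = self.rows[keep]
        self.cols = self.cols[keep]
        self.vals = self.vals[keep]
        self.invalidate()

    def copy(self) -> "SparseWeights":
        return SparseWeights(self.n, self.rows.copy(), self.cols.copy(), self.vals.copy())

    def triples(self) -> set:
        return set(zip(self.rows.tolist(), self.cols.tolist(), self.vals.tolist()))


def enforce_structural_zeros(weights: SparseWeights, n_input: int, n_output: int,
                             allow_self_loops: bool = False) -> SparseWeights:
    """Remove forbidden entries in place: rows 0..N_I-1 (nothing may write
    into an input slot), columns N-N_O..N-1 (output neurons have no outgoing
    connections), and the diagonal unless self-loops are allowed."""
    n = weights.n
    bad = (weights.rows < n_input) | (weights.cols >= n - n_output)
    if not allow_self_loops:
        bad |= weights.rows == weights.cols
    if bad.any():
        weights.drop(np.flatnonzero(bad))
    return weights


def init_weights_xavier(connections: ConnectionSet, n: int,
                        rng: np.random.Generator,
                        slot_of_cell: np.ndarray | None = None,
                        n_input: int = 0, n_output: int = 0,
                        allow_self_loops: bool = False) -> SparseWeights:
    """One matrix entry per connection (target slot row, source slot column),
    Xavier-uniform in +/- sqrt(6 / (fan_in + fan_out)) with fan_in the row
    count and fan_out the column count, then structural zeroing.

    ``slot_of_cell`` maps cell indices in the connection set to matrix slots
    (identity when omitted).  Duplicate (i, j) pairs are an error — the
    connection set contract is deduplicated input.
    """
    src = connections.source
    tgt = connections.target
    if slot_of_cell is not None:
        src = slot_of_cell[src]
        tgt = slot_of_cell[tgt]
    if np.any(src < 0) or np.any(tgt < 0) or np.any(src >= n) or np.any(tgt >= n):
        raise ValueError("connection indices outside matrix capacity")
    rows, cols = tgt, src  # entry (i, j): signal from j into i
    pair = rows * n + cols
    if len(np.unique(pair)) != len(pair):
        raise ValueError("duplicate connections; deduplicate upstream")
    fan_in = np.zeros(n, dtype=int)   # per-row incoming count
    fan_out = np.zeros(n, dtype=int)  # per-column outgoing count
    np.add.at(fan_in, rows, 1)
    np.add.at(fan_out, cols, 1)
    bound = np.sqrt(6.0 / (fan_in[rows] + fan_out[cols]))
    vals = rng.uniform(-1.0, 1.0, size=len(rows)) * bound
    weights = SparseWeights(n, rows, cols, vals)
    return enforce_structural_zeros(weights, n_input, n_output, allow_self_loops)


def default_capacity(n_active: int) -> int:
    """Next power of two above 1.2x the active neuron count (headroom so
    growth and pruning never force a matrix reallocation)."""
    need = max(int(np.ceil(1.2 * max(n_active, 1))), 2)
    return int(2 ** np.ceil(np.log2(need)))


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class RayBNNModel:
    """Population + sparse weights + biases + activation parameters, with the
    slot layout binding geometry to the learnable network.

    ``slot_cell`` maps matrix slot -> cell_id (-1 for unused capacity); input
    neurons occupy slots 0..N_I-1, output neurons the last N_O slots, hidden
    neurons in between.  ``H`` is forced to zero on input slots (their rows
    are structural zeros).
    """

    population: CellPopulation
    weights: SparseWeights
    H: np.ndarray
    uaf: UAFParams
    n_input: int
    n_output: int
    k: int
    slot_cell: np.ndarray
    evolution: int = 0  # transfer-learning step counter (lambda)
    allow_self_loops: bool = False

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float).ravel()
        self.slot_cell = np.asarray(self.slot_cell, dtype=int).ravel()
        n = self.weights.n
        if len(self.H) != n or len(self.uaf.c_eff) != n or len(self.slot_cell) != n:
            raise ValueError("H, C_eff and slot map must have capacity length")
        if self.k < 1:
            raise ValueError("propagation delay k must be >= 1")
        self.H[: self.n_input] = 0.0

    @property
    def n(self) -> int:
        return self.weights.n

    @property
    def active_slots(self) -> np.ndarray:
        return np.flatnonzero(self.slot_cell >= 0)

    @property
    def n_active(self) -> int:
        return int((self.slot_cell >= 0).sum())

    @property
    def output_slots(self) -> np.ndarray:
        return np.arange(self.n - self.n_output, self.n)

    @property
    def input_slots(self) -> np.ndarray:
        return np.arange(self.n_input)

    def slot_of_cell_array(self) -> np.ndarray:
        """Inverse map cell_id -> slot (-1 when absent)."""
        size = int(self.population.cell_id.max()) + 1 if self.population.n_cells else 1
        inv = np.full(max(size, int(self.slot_cell.max(initial=0)) + 1), -1, dtype=int)
        live = self.slot_cell >= 0
        inv[self.slot_cell[live]] = np.flatnonzero(live)
        return inv

    def copy(self) -> "RayBNNModel":
        return RayBNNModel(
            population=self.population.copy(),
            weights=self.weights.copy(),
            H=self.H.copy(),
            uaf=UAFParams(self.uaf.c_eff.copy()),
            n_input=self.n_input,
            n_output=self.n_output,
            k=self.k,
            slot_cell=self.slot_cell.copy(),
            evolution=self.evolution,
            allow_self_loops=self.allow_self_loops,
        )


@dataclass
class NetworkState:
    """Forward-pass history retained for backpropagation: the assembled
    temporary states Q^t and pre-activations Z^t = W Q^t + H for each step."""

    q_history: list = field(default_factory=list)
    z_history: list = field(default_factory=list)
    outputs: np.ndarray | None = None


def forward(model: RayBNNModel, inputs: np.ndarray, return_state: bool = False):
    """Run the time-stepped forward pass.

    ``inputs`` has shape (I_T, N_I) or (I_T, N_I, B) for a batch of B
    sequences.  Returns outputs of shape (I_T, N_O[, B]); with
    ``return_state`` also the retained history.  S^0 is the zero vector; after
    the last input step the input slots retain their final injected values
    while the remaining k flush steps run.
    """
    x = np.asarray(inputs, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    if x.ndim != 3 or x.shape[1] != model.n_input:
        raise ValueError(f"inputs must be (I_T, {model.n_input}[, B])")
    i_t, _, batch = x.shape
    n, k = model.n, model.k
    u = i_t + k
    w = model.weights.tocsr()
    h = model.H[:, None]
    c_eff = model.uaf.c_eff
    s = np.zeros((n, batch))
    state = NetworkState()
    outputs = np.empty((i_t, model.n_output, batch))
    out_sl = model.output_slots
    for t in range(u - 1):
        q = s.copy()
        q[: model.n_input, :] = x[min(t, i_t - 1)]
        z = w @ q + h
        s = uaf_vector(z, c_eff)
        if return_state:
            state.q_history.append(q)
            state.z_history.append(z)
        # S^{t+1} feeds Y^{t+1-k}
        t_out = t + 1 - k
        if 0 <= t_out < i_t:
            outputs[t_out] = s[out_sl, :]
    state.outputs = outputs
    result = outputs[:, :, 0] if squeeze else outputs
    if return_state:
        return result, state
    return result


def default_delay(model_or_weights, n_input: int | None = None, n_output: int | None = None) -> int:
    """Smallest integer >= the mean shortest-path length from input to output
    slots in the traced graph (propagation delay heuristic); at least 1."""
    if isinstance(model_or_weights, RayBNNModel):
        w = model_or_weights.weights
        n_input = model_or_weights.n_input
        n_output = model_or_weights.n_output
    else:
        w = model_or_weights
    n = w.n
    # graph edge j -> i for entry (i, j): distances measured along signal flow
    adj = sparse.csr_matrix((np.ones(w.nnz), (w.cols, w.rows)), shape=(n, n))
    if w.nnz == 0 or not n_input or not n_output:
        return 1
    dist = shortest_path(adj, method="D", directed=True, unweighted=True,
                         indices=np.arange(n_input))
    d = dist[:, n - n_output:]
    finite = d[np.isfinite(d)]
    if len(finite) == 0:
        return 1
    return max(1, int(np.ceil(finite.mean())))


# ---------------------------------------------------------------------------
# model assembly and bundle I/O
# ---------------------------------------------------------------------------

def build_slot_map(population: CellPopulation, capacity: int | None = None):
    """Assign matrix slots: inputs first, hidden next, outputs at the end of
    the capacity range.  Returns (slot_cell, slot_of_cell, capacity)."""
    n_i, n_h, n_o = population.n_input, population.n_hidden, population.n_output
    n_active = n_i + n_h + n_o
    if capacity is None:
        capacity = default_capacity(n_active)
    if capacity < n_active:
        raise ValueError("capacity below the active neuron count")
    slot_cell = np.full(capacity, -1, dtype=int)
    in_ids = population.cell_id[population.cell_type == "input"]
    hid_ids = population.cell_id[population.cell_type == "hidden"]
    out_ids = population.cell_id[population.cell_type == "output"]
    slot_cell[:n_i] = in_ids
    slot_cell[n_i : n_i + n_h] = hid_ids
    slot_cell[capacity - n_o :] = out_ids
    size = int(population.cell_id.max()) + 1 if population.n_cells else 1
    slot_of_cell = np.full(size, -1, dtype=int)
    live = slot_cell >= 0
    slot_of_cell[slot_cell[live]] = np.flatnonzero(live)
    return slot_cell, slot_of_cell, capacity


def build_model(population: CellPopulation, connections: ConnectionSet,
                rng: np.random.Generator, k: int | None = None,
                capacity: int | None = None, uaf_jitter: float = 0.01,
                bias_scale: float = 0.01,
                allow_self_loops: bool = False) -> RayBNNModel:
    """Wire a traced population into a trainable model: slot assignment,
    Xavier-initialized sparse weights with structural zeros, small random
    biases (zero on input slots), near-identity UAF rows, and the default
    propagation delay unless ``k`` is given."""
    slot_cell, slot_of_cell, n = build_slot_map(population, capacity)
    n_i, n_o = population.n_input, population.n_output
    weights = init_weights_xavier(
        connections, n, rng, slot_of_cell=slot_of_cell,
        n_input=n_i, n_output=n_o, allow_self_loops=allow_self_loops,
    )
    h = bias_scale * rng.standard_normal(n)
    h[:n_i] = 0.0
    c_eff = init_uaf_params(n, rng, jitter=uaf_jitter)
    model = RayBNNModel(
        population=population, weights=weights, H=h, uaf=UAFParams(c_eff),
        n_input=n_i, n_output=n_o, k=1, slot_cell=slot_cell,
        allow_self_loops=allow_self_loops,
    )
    model.k = k if k is not None else default_delay(model)
    return model


def save_model(model: RayBNNModel, path) -> None:
    """Model bundle directory: positions table (CSV), weights (Matrix Market
    coordinate, 1-based), per-slot UAF parameters and biases (CSV), and a JSON
    metadata file."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_positions(model.population, path / "positions.csv")
    mmwrite(path / "weights.mtx", model.weights.tocsr().tocoo(), precision=17)
    pd.DataFrame(
        {
            "slot": np.arange(model.n),
            "cell_id": model.slot_cell,
            "bias": model.H,
            "A": model.uaf.c_eff[:, 0],
            "B": model.uaf.c_eff[:, 1],
            "C": model.uaf.c_eff[:, 2],
            "D": model.uaf.c_eff[:, 3],
            "E": model.uaf.c_eff[:, 4],
        }
    ).to_csv(path / "neurons.csv", index=False, float_format="%.17g")
    meta = {
        "n": model.n,
        "n_input": model.n_input,
        "n_output": model.n_output,
        "k": model.k,
        "r_s": model.population.r_s,
        "r_n": model.population.r_n,
        "evolution": model.evolution,
        "allow_self_loops": model.allow_self_loops,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> RayBNNModel:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    population = read_positions(path / "positions.csv", r_s=meta["r_s"], r_n=meta["r_n"])
    coo = mmread(path / "weights.mtx").tocoo()
    weights = SparseWeights(meta["n"], coo.row, coo.col, coo.data)
    table = pd.read_csv(path / "neurons.csv", float_precision="round_trip")
    model = RayBNNModel(
        population=population,
        weights=weights,
        H=table["bias"].to_numpy(float),
        uaf=UAFParams(table[["A", "B", "C", "D", "E"]].to_numpy(float)),
        n_input=meta["n_input"],
        n_output=meta["n_output"],
        k=meta["k"],
        slot_cell=table["cell_id"].to_numpy(int),
        evolution=meta.get("evolution", 0),
        allow_self_loops=meta.get("allow_self_loops", False),
    )
    return model
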