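"""Structure-preserving transfer learning.

Growing a trained network onto a larger problem keeps every trained quantity
bit-exact: the sphere is rescaled radially (angles unchanged), input neurons
are re-laid out by densification or polar migration, new hidden/glial cells
are placed collision-free, and ray tracing runs only over cell pairs that
involve at least one new cell — old edges, weight values, biases and
activation-parameter rows all survive the move.  Shrinking applies repeated
probabilistic deletion sweeps followed by redundant-neuron removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import CellPopulation, min_sphere_radius, sample_hidden_positions
from .network import (
    RayBNNModel,
    SparseWeights,
    UAFParams,
    build_slot_map,
    default_capacity,
    enforce_structural_zeros,
    init_weights_xavier,
)
from .raytracing import ConnectionSet, RTConfig, rt1, rt2, rt3
from .training import delete_connections_probabilistic, delete_redundant_neurons

__all__ = ["GrowthPlan", "grow_network", "shrink_network", "transfer_report"]


@dataclass
class GrowthPlan:
    """Target sizes for one transfer-learning growth step.

    Counts are totals after growth and must not shrink.  ``input_mode``
    selects how new input neurons join the surface layout: ``densify``
    (higher-resolution grid, old neurons keep their positions), ``concat``
    (old neurons migrate north by the factor ``kappa``, new features fill the
    south), or ``none`` (no input change).
    """

    n_input: int
    n_hidden: int
    n_glial: int
    n_output: int
    r_s: float | None = None  # None: auto from the collision threshold
    p_c_threshold: float = 0.01
    input_mode: str = "concat"
    kappa: float | None = None
    rt: RTConfig = field(default_factory=lambda: RTConfig(algorithm="rt3", r_rt=40.0))
    seed: int | None = None

    def __post_init__(self):
        if self.input_mode not in ("densify", "concat", "none"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "concat" and self.kappa is not None and not 0 < self.kappa <= 1:
            raise ValueError("kappa must be in (0, 1]")


def _trace_new_pairs(population, rt_cfg: RTConfig, new_mask, rng):
    if rt_cfg.algorithm == "rt2":
        return rt2(population, rng=rng, new_mask=new_mask)
    if rt_cfg.algorithm == "rt1":
        edges = rt1(population, rt_cfg.rays_per_neuron, rng)
        keep = new_mask[edges.source] | new_mask[edges.target]
        return ConnectionSet(edges.source[keep], edges.target[keep], edges.length[keep])
    return rt3(population, rt_cfg.r_rt, rng, new_mask=new_mask)


def grow_network(model: RayBNNModel, plan: GrowthPlan,
                 rng: np.random.Generator | None = None) -> RayBNNModel:
    """Grow a trained model according to ``plan``; returns a new model.

    Old (source cell, target cell, weight) triples, biases and UAF rows are
    preserved exactly; only connections with at least one new endpoint are
    traced and Xavier-initialized.
    """
    pop = model.population
    d_in = plan.n_input - pop.n_input
    d_hid = plan.n_hidden - pop.n_hidden
    d_gli = plan.n_glial - pop.n_glial
    d_out = plan.n_output - pop.n_output
    if min(d_in, d_hid, d_gli, d_out) < 0:
        raise ValueError("grow_network cannot shrink counts; use shrink_network")
    if rng is None:
        rng = np.random.default_rng(plan.seed)

    if d_in == 0 and d_hid == 0 and d_gli == 0 and d_out == 0 and (
        plan.r_s is None or plan.r_s == pop.r_s
    ):
        return model.copy()

    # (1) sphere radius: requested or smallest radius meeting the collision
    # threshold for the grown population
    n_total_new = plan.n_input + plan.n_hidden + plan.n_glial + plan.n_output
    r_s_new = plan.r_s if plan.r_s is not None else 0.0
    r_s_new = max(r_s_new, min_sphere_radius(n_total_new, plan.p_c_threshold), pop.r_s)
    grown = geometry.grow_sphere(pop, r_s_new)

    # (2) input re-assignment and new input neurons
    next_id = int(grown.cell_id.max()) + 1 if grown.n_cells else 0
    new_input_pos = np.zeros((0, 3))
    new_input_v = None
    if d_in > 0:
        if plan.input_mode == "concat":
            kappa = plan.kappa if plan.kappa is not None else pop.n_input / plan.n_input
            grown = geometry.migrate_inputs_concat(grown, kappa)
            new_v_theta = kappa + (np.arange(d_in) + 1.0) * (1.0 - kappa) / (d_in + 1.0)
            new_v_phi = (np.arange(d_in) + 1.0) / (d_in + 1.0)
            new_input_v = np.column_stack([new_v_theta, new_v_phi])
        elif plan.input_mode == "densify":
            if grown.input_grid is None:
                raise ValueError("densify requires a gridded input layout")
            nx_old, ny_old = grown.input_grid
            nx_new = ny_new = int(np.ceil(np.sqrt(plan.n_input)))
            vt_new, vp_new, index_map = geometry.densify_inputs(nx_old, ny_old, nx_new, ny_new)
            claimed = set(index_map.values())
            free = [
                (i, j) for i in range(nx_new) for j in range(ny_new)
                if (i, j) not in claimed
            ][:d_in]
            new_input_v = np.array([[vt_new[i], vp_new[j]] for i, j in free])
            grown.input_grid = (nx_new, ny_new)
        else:
            raise ValueError("input count grew but input_mode is 'none'")
        theta = np.arccos(np.clip(2.0 * (new_input_v[:, 0] - 0.5), -1.0, 1.0))
        phi = 2.0 * np.pi * new_input_v[:, 1]
        new_input_pos = geometry.spherical_to_cartesian(
            np.full(d_in, grown.r_s), theta, phi
        )

    # (3) new hidden and glial cells, collision-free against all present cells
    n_new_interior = d_hid + d_gli
    new_interior = np.zeros((0, 3))
    if n_new_interior > 0:
        thr2 = 4.0
        grid = geometry._HashGrid(cell=2.0)
        interior_mask = (grown.cell_type == "hidden") | (grown.cell_type == "glial")
        for p in grown.positions[interior_mask]:
            grid.add(p)
        n_existing = len(grid.points)
        placed = []
        attempts = 0
        max_attempts = 50 * n_new_interior + 1000
        pending: list[np.ndarray] = []
        while len(placed) < n_new_interior:
            if attempts > max_attempts:
                raise RuntimeError("could not place grown cells without collisions")
            if not pending:
                pending = list(sample_hidden_positions(max(256, n_new_interior), grown.r_s, rng))
            p = pending.pop(0)
            attempts += 1
            if grid.conflicts(p, thr2):
                continue
            grid.add(p)
            placed.append(p)
        new_interior = np.asarray(placed)
        del n_existing

    new_types = np.concatenate([
        np.array(["input"] * d_in, dtype=object),
        np.array(["hidden"] * d_hid + ["glial"] * d_gli, dtype=object),
        np.array(["output"] * d_out, dtype=object),
    ])
    new_positions = np.vstack([
        new_input_pos,
        new_interior[:d_hid] if d_hid else np.zeros((0, 3)),
        new_interior[d_hid:] if d_gli else np.zeros((0, 3)),
        np.zeros((d_out, 3)),
    ])
    new_ids = np.arange(next_id, next_id + len(new_positions))

    merged = CellPopulation(
        positions=np.vstack([grown.positions, new_positions]),
        cell_type=np.concatenate([grown.cell_type, new_types]),
        r_s=grown.r_s,
        r_n=grown.r_n,
        cell_id=np.concatenate([grown.cell_id, new_ids]),
        input_grid=grown.input_grid,
        input_v=None if grown.input_v is None else (
            np.vstack([grown.input_v, new_input_v]) if new_input_v is not None else grown.input_v
        ),
    )
    new_mask = np.zeros(merged.n_cells, dtype=bool)
    new_mask[grown.n_cells :] = True

    # (4) ray tracing restricted to pairs involving >= 1 new cell
    new_edges = _trace_new_pairs(merged, plan.rt, new_mask, rng)

    # (5) rebuild the matrix under the new slot layout; old values bit-exact
    n_active_new = plan.n_input + plan.n_hidden + plan.n_output
    capacity = model.n
    if capacity < default_capacity(n_active_new):
        capacity = max(2 * capacity, default_capacity(n_active_new))  # doubling policy
    slot_cell, slot_of_cell, capacity = build_slot_map(merged, capacity)

    cell_of_old_slot = model.slot_cell
    # carry old entries (identified by cell ids) into the new layout
    old_rows_cells = cell_of_old_slot[model.weights.rows]
    old_cols_cells = cell_of_old_slot[model.weights.cols]
    new_rows = slot_of_cell[old_rows_cells]
    new_cols = slot_of_cell[old_cols_cells]
    old_weights = SparseWeights(capacity, new_rows, new_cols, model.weights.vals.copy())

    # drop traced edges duplicating surviving old connections
    existing = set(zip(old_weights.rows.tolist(), old_weights.cols.tolist()))
    add_rows = slot_of_cell[new_edges.target]
    add_cols = slot_of_cell[new_edges.source]
    fresh = np.array([
        (r, c) not in existing for r, c in zip(add_rows.tolist(), add_cols.tolist())
    ], dtype=bool) if len(add_rows) else np.zeros(0, bool)
    fresh_edges = ConnectionSet(
        new_edges.source[fresh], new_edges.target[fresh], new_edges.length[fresh]
    )
    new_weights = init_weights_xavier(
        fresh_edges, capacity, rng, slot_of_cell=slot_of_cell,
        n_input=plan.n_input, n_output=plan.n_output,
        allow_self_loops=model.allow_self_loops,
    )
    weights = SparseWeights(
        capacity,
        np.concatenate([old_weights.rows, new_weights.rows]),
        np.concatenate([old_weights.cols, new_weights.cols]),
        np.concatenate([old_weights.vals, new_weights.vals]),
    )
    enforce_structural_zeros(weights, plan.n_input, plan.n_output, model.allow_self_loops)

    # carry biases and UAF rows by cell identity; new slots get fresh values
    h = np.zeros(capacity)
    c_eff = np.tile(np.array([1.0, 0.0, 0.0, -1.0, 0.0]), (capacity, 1))
    c_eff += 0.01 * rng.standard_normal((capacity, 5))
    h += 0.01 * rng.standard_normal(capacity)
    live_old = model.slot_cell >= 0
    for old_slot in np.flatnonzero(live_old):
        cell = model.slot_cell[old_slot]
        new_slot = slot_of_cell[cell]
        if new_slot >= 0:
            h[new_slot] = model.H[old_slot]
            c_eff[new_slot] = model.uaf.c_eff[old_slot]
    h[: plan.n_input] = 0.0

    out = RayBNNModel(
        population=merged,
        weights=weights,
        H=h,
        uaf=UAFParams(c_eff),
        n_input=plan.n_input,
        n_output=plan.n_output,
        k=model.k,
        slot_cell=slot_cell,
        evolution=model.evolution + 1,
        allow_self_loops=model.allow_self_loops,
    )
    return out


def shrink_network(model: RayBNNModel, target_fraction: float,
                   rng: np.random.Generator | None = None,
                   sweep_fraction: float = 0.05) -> RayBNNModel:
    """Repeated probabilistic deletion sweeps until
    ``nnz <= target_fraction * nnz0``, then redundant-neuron removal.
    Surviving weights keep their values."""
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    out = model.copy()
    target = int(np.floor(target_fraction * out.weights.nnz))
    while out.weights.nnz > target and out.weights.nnz > 0:
        delete_connections_probabilistic(out.weights, sweep_fraction, rng)
    delete_redundant_neurons(out)
    return out


def transfer_report(old: RayBNNModel, new: RayBNNModel) -> dict:
    """Sparsity and preserved-weight statistics across a transfer step."""
    old_triples = set(
        zip(
            old.slot_cell[old.weights.rows].tolist(),
            old.slot_cell[old.weights.cols].tolist(),
            old.weights.vals.tolist(),
        )
    )
    new_triples = set(
        zip(
            new.slot_cell[new.weights.rows].tolist(),
            new.slot_cell[new.weights.cols].tolist(),
            new.weights.vals.tolist(),
        )
    )
    preserved = len(old_triples & new_triples)
    n_active_old = max(old.n_active, 1)
    n_active_new = max(new.n_active, 1)
    return {
        "old_nnz": old.weights.nnz,
        "new_nnz": new.weights.nnz,
        "preserved_weights": preserved,
        "preserved_fraction": preserved / max(len(old_triples), 1),
        "old_sparsity": old.weights.nnz / n_active_old**2,
        "new_sparsity": new.weights.nnz / n_active_new**2,
        "evolution": new.evolution,
    }
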