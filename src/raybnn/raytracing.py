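"""Line-of-sight connection formation between neurons.

A candidate connection from neuron i to neuron j is vetoed when any third
cell k (neuron or glial) lies within one cell radius of the segment i-j and
strictly between the endpoints:

    |d_perp(k, segment ij)| <= r_n
    (r_k - r_i) . (r_j - r_i) > 0   and   (r_k - r_j) . (r_i - r_j) > 0

Three tracing algorithms are provided:

* RT-1: every neuron emits K rays in uniformly random directions; each ray
  connects its source to the nearest intersected cell if that cell is a
  neuron (glial hits discard the ray).
* RT-2: all ordered neuron pairs, keeping pairs with unblocked line of sight.
* RT-3: distance-limited RT-2 inside pivot-centered clusters of radius r_RT,
  repeated until every neuron has been covered, with results deduplicated.

Connection lengths follow, at low density, the ball line-picking distribution
modulated by an occlusion survival factor (see ``connection_pdf_analytic``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order

from .geometry import CellPopulation

__all__ = [
    "ConnectionSet",
    "RTConfig",
    "segment_blocked",
    "rt1",
    "rt2",
    "rt3",
    "trace",
    "verify_io_connectivity",
    "connection_prob_unblocked",
    "connection_pdf_analytic",
    "connection_pdf_normalization",
    "connections_per_neuron",
    "resolve_colocated_hits",
]


@dataclass
class RTConfig:
    """Ray-tracing configuration: algorithm, rays per neuron (RT-1) and
    cluster radius (RT-3), in units of r_n."""

    algorithm: str = "rt3"
    rays_per_neuron: int = 10_000
    r_rt: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.algorithm not in ("rt1", "rt2", "rt3"):
            raise ValueError(f"unknown ray-tracing algorithm {self.algorithm!r}")
        if self.rays_per_neuron < 1:
            raise ValueError("rays_per_neuron must be >= 1")
        if self.algorithm == "rt3" and (self.r_rt is None or self.r_rt <= 0):
            raise ValueError("rt3 requires a positive cluster radius r_rt")


@dataclass
class ConnectionSet:
    """Deduplicated directed edges (source cell index, target cell index,
    Euclidean length in r_n)."""

    source: np.ndarray
    target: np.ndarray
    length: np.ndarray

    def __post_init__(self):
        self.source = np.asarray(self.source, dtype=int).ravel()
        self.target = np.asarray(self.target, dtype=int).ravel()
        self.length = np.asarray(self.length, dtype=float).ravel()
        if not len(self.source) == len(self.target) == len(self.length):
            raise ValueError("edge arrays must have equal length")

    def __len__(self) -> int:
        return len(self.source)

    @classmethod
    def empty(cls) -> "ConnectionSet":
        return cls(np.empty(0, int), np.empty(0, int), np.empty(0, float))

    @classmethod
    def from_edges(cls, source, target, positions) -> "ConnectionSet":
        source = np.asarray(source, dtype=int)
        target = np.asarray(target, dtype=int)
        length = np.linalg.norm(positions[target] - positions[source], axis=1) if len(source) else np.empty(0)
        return cls(source, target, length).deduplicate()

    def deduplicate(self) -> "ConnectionSet":
        """Remove duplicate (source, target) pairs; idempotent, sorts edges
        by (source, target) for a canonical order."""
        if len(self) == 0:
            return ConnectionSet.empty()
        key = np.stack([self.source, self.target], axis=1)
        uniq, idx = np.unique(key, axis=0, return_index=True)
        order = np.lexsort((uniq[:, 1], uniq[:, 0]))
        return ConnectionSet(uniq[order, 0], uniq[order, 1], self.length[idx][order])

    def union(self, other: "ConnectionSet") -> "ConnectionSet":
        return ConnectionSet(
            np.concatenate([self.source, other.source]),
            np.concatenate([self.target, other.target]),
            np.concatenate([self.length, other.length]),
        ).deduplicate()

    def as_pairs(self) -> set:
        return set(zip(self.source.tolist(), self.target.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"source_id": self.source, "target_id": self.target, "length_rn": self.length})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "ConnectionSet":
        df = pd.read_csv(path)
        return cls(df["source_id"].to_numpy(int), df["target_id"].to_numpy(int), df["length_rn"].to_numpy(float))


# ---------------------------------------------------------------------------
# occlusion predicate
# ---------------------------------------------------------------------------

def segment_blocked(p_i, p_j, obstacles, r_n: float = 1.0):
    """Whether the segment from ``p_i`` to ``p_j`` is occluded by any obstacle.

    Returns ``(blocked, first_blocker)`` where ``first_blocker`` is the index
    (into ``obstacles``) of the blocker closest to ``p_i``, or -1.  Endpoint
    cells must not be included in ``obstacles``.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    seg = p_j - p_i
    seg2 = float(seg @ seg)
    if seg2 == 0.0:
        raise ValueError("zero-length segment")
    obstacles = np.asarray(obstacles, dtype=float).reshape(-1, 3)
    if len(obstacles) == 0:
        return False, -1
    rel = obstacles - p_i
    proj = rel @ seg  # |seg| * component along the segment
    between = (proj > 0.0) & (proj < seg2)  # both strict dot-product conditions
    d_perp2 = np.einsum("ij,ij->i", rel, rel) - proj**2 / seg2
    hit = between & (d_perp2 <= r_n * r_n + 1e-12 * seg2)
    if not hit.any():
        return False, -1
    idx = np.flatnonzero(hit)
    return True, int(idx[np.argmin(proj[idx])])


# ---------------------------------------------------------------------------
# RT algorithms
# ---------------------------------------------------------------------------

def resolve_colocated_hits(targets, positions, neuron_indices, rng):
    """Map each hit target to a uniformly random member of its co-location
    group (stacked-channel input sites share one position)."""
    if len(targets) == 0:
        return targets
    pos = positions[neuron_indices]
    # group neurons by exact position
    _, group_id, counts = np.unique(pos, axis=0, return_inverse=True, return_counts=True)
    if counts.max() == 1:
        return targets
    out = targets.copy()
    local = {int(g): np.flatnonzero(group_id == g) for g in np.unique(group_id)}
    pos_of = {int(n): int(g) for n, g in zip(neuron_indices, group_id)}
    for e, t in enumerate(targets):
        g = pos_of[int(t)]
        members = local[g]
        if len(members) > 1:
            out[e] = neuron_indices[members[rng.integers(len(members))]]
    return out


def rt1(population: CellPopulation, rays_per_neuron: int = 10_000,
        rng: np.random.Generator | None = None) -> ConnectionSet:
    """Random-ray tracing: each neuron emits K rays with directions uniform on
    the unit sphere; a ray's nearest intersected cell decides the outcome
    (glial: discarded; neuron: directed edge source -> that neuron)."""
    if rays_per_neuron < 1:
        raise ValueError("rays_per_neuron must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    pos = population.positions
    r_n = population.r_n
    neuron_idx = np.flatnonzero(population.neuron_mask)
    sources, targets = [], []
    child_seeds = rng.integers(0, 2**31 - 1, size=len(neuron_idx))
    for s, i in zip(child_seeds, neuron_idx):
        sub = np.random.default_rng(int(s))  # per-neuron substream
        u = sub.random((rays_per_neuron, 2))
        theta = np.arccos(2.0 * (u[:, 0] - 0.5))
        phi = 2.0 * np.pi * u[:, 1]
        st = np.sin(theta)
        dirs = np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=1)
        rel = pos - pos[i]  # (m, 3)
        rel2 = np.einsum("ij,ij->i", rel, rel)
        proj = dirs @ rel.T  # (K, m): parametric distance of closest approach
        d_perp2 = rel2[None, :] - proj**2
        hit = (proj > 0.0) & (d_perp2 <= r_n * r_n)
        hit[:, i] = False
        t_hit = np.where(hit, proj, np.inf)
        nearest = np.argmin(t_hit, axis=1)  # ties -> lowest cell index (argmin rule)
        ok = np.isfinite(t_hit[np.arange(rays_per_neuron), nearest])
        nearest = nearest[ok]
        is_neuron = population.neuron_mask[nearest]
        tgt = np.unique(nearest[is_neuron])
        sources.append(np.full(len(tgt), i))
        targets.append(tgt)
    if not sources:
        return ConnectionSet.empty()
    src = np.concatenate(sources)
    tgt = np.concatenate(targets)
    tgt = resolve_colocated_hits(tgt, pos, neuron_idx, rng)
    return ConnectionSet.from_edges(src, tgt, pos)


def rt2(population: CellPopulation, subset: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
        new_mask: np.ndarray | None = None) -> ConnectionSet:
    """All-pairs tracing with occlusion: edge i -> j for every ordered neuron
    pair whose segment is not blocked by any other cell.

    ``subset`` restricts both candidate endpoints and obstacles to the given
    cell indices (the RT-3 cluster contract).  ``new_mask`` (over all cells)
    keeps only edges with at least one endpoint marked new (transfer growth).
    """
    pos = population.positions
    idx = np.arange(population.n_cells) if subset is None else np.asarray(subset, int)
    if len(idx) < 2:
        return ConnectionSet.empty()
    local_pos = pos[idx]
    local_neuron = population.neuron_mask[idx]
    neuron_rows = np.flatnonzero(local_neuron)
    if len(neuron_rows) < 2:
        return ConnectionSet.empty()
    if rng is None:
        rng = np.random.default_rng()
    sources, targets = [], []
    for row in neuron_rows:
        # visibility of every other local cell from this source; targets are
        # neurons only, but obstacles include glial cells and other neurons.
        visible = _visible_targets(row, local_pos, population.r_n)
        tgt_rows = np.flatnonzero(visible & local_neuron)
        tgt_rows = tgt_rows[tgt_rows != row]
        if new_mask is not None:
            keep = new_mask[idx[row]] | new_mask[idx[tgt_rows]]
            tgt_rows = tgt_rows[keep]
        sources.append(np.full(len(tgt_rows), idx[row]))
        targets.append(idx[tgt_rows])
    src = np.concatenate(sources) if sources else np.empty(0, int)
    tgt = np.concatenate(targets) if targets else np.empty(0, int)
    # all-pairs semantics: co-located targets each receive their own edge
    # (deterministic; the ray-based RT-1 resolves shared sites randomly)
    return ConnectionSet.from_edges(src, tgt, pos)


def _visible_targets(row: int, local_pos: np.ndarray, r_n: float) -> np.ndarray:
    """Visibility mask of all local cells from local cell ``row``; obstacles
    are all local cells except the endpoints.  Cells co-located with either
    endpoint are excluded by exact position comparison (the strict
    betweenness inequalities alone are not robust to rounding)."""
    p_i = local_pos[row]
    seg = local_pos - p_i  # (n, 3): target directions, index-aligned
    seg2 = np.einsum("ij,ij->i", seg, seg)
    rel2 = seg2  # obstacles are the same local cells
    proj = seg @ seg.T  # (obstacle k, target j)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_perp2 = rel2[:, None] - proj**2 / np.where(seg2 > 0, seg2, 1.0)[None, :]
    blocked = (proj > 0.0) & (proj < seg2[None, :]) & (d_perp2 <= r_n * r_n)
    blocked &= (rel2 > 0.0)[:, None]  # source (and co-located) never obstructs
    # an obstacle at exactly the target position never obstructs
    same_as_target = (local_pos[:, None, :] == local_pos[None, :, :]).all(axis=-1)
    blocked &= ~same_as_target
    visible = ~blocked.any(axis=0) & (seg2 > 0.0)
    return visible


def rt3(population: CellPopulation, r_rt: float,
        rng: np.random.Generator | None = None,
        new_mask: np.ndarray | None = None) -> ConnectionSet:
    """Distance-limited tracing: pick pivots, run RT-2 on the cluster of cells
    within ``r_rt`` of each pivot (obstacles restricted to cluster members),
    union and deduplicate.  Pivots are drawn uniformly from cells not yet
    covered until every neuron has appeared in at least one cluster, so no
    edge can be longer than ``2 r_rt``."""
    if r_rt <= 0:
        raise ValueError("r_rt must be positive")
    if rng is None:
        rng = np.random.default_rng()
    from scipy.spatial import cKDTree

    pos = population.positions
    m = population.n_cells
    if m == 0:
        return ConnectionSet.empty()
    tree = cKDTree(pos)
    covered = np.zeros(m, dtype=bool)
    covered[~population.neuron_mask] = True  # only neurons need covering
    edges = ConnectionSet.empty()
    while not covered.all():
        pending = np.flatnonzero(~covered)
        pivot = int(pending[rng.integers(len(pending))])
        cluster = np.asarray(tree.query_ball_point(pos[pivot], r_rt), dtype=int)
        cluster.sort()
        covered[cluster] = True
        covered[pivot] = True
        part = rt2(population, subset=cluster, rng=rng, new_mask=new_mask)
        edges = edges.union(part)
    return edges


def trace(population: CellPopulation, config: RTConfig,
          rng: np.random.Generator | None = None) -> ConnectionSet:
    """Dispatch on the configured algorithm."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.algorithm == "rt1":
        return rt1(population, config.rays_per_neuron, rng)
    if config.algorithm == "rt2":
        return rt2(population, rng=rng)
    return rt3(population, config.r_rt, rng)


# ---------------------------------------------------------------------------
# connectivity verification
# ---------------------------------------------------------------------------

def verify_io_connectivity(connections: ConnectionSet, input_indices, output_indices, n_cells: int):
    """Backward breadth-first traversal from each output neuron over reversed
    edges; reports per input neuron whether a directed path to every output
    exists.  Returns a dict with the per-input boolean table and an
    ``all_connected`` flag (a report, never an exception)."""
    input_indices = np.asarray(input_indices, int)
    output_indices = np.asarray(output_indices, int)
    n = int(n_cells)
    data = np.ones(len(connections), dtype=np.int8)
    adj = csr_matrix((data, (connections.source, connections.target)), shape=(n, n))
    adj_t = adj.T.tocsr()
    reaches = np.zeros((len(input_indices), len(output_indices)), dtype=bool)
    for col, out in enumerate(output_indices):
        order = breadth_first_order(adj_t, int(out), directed=True, return_predecessors=False)
        mask = np.zeros(n, dtype=bool)
        mask[order] = True
        reaches[:, col] = mask[input_indices]
    per_input = reaches.all(axis=1)
    return {
        "per_input": dict(zip(input_indices.tolist(), per_input.tolist())),
        "reaches": reaches,
        "all_connected": bool(per_input.all()) if len(per_input) else True,
    }


# ---------------------------------------------------------------------------
# analytic connection-length distribution
# ---------------------------------------------------------------------------

def connection_prob_unblocked(r, eta_T: float, r_n: float = 1.0):
    """Survival probability of a candidate connection of length ``r`` against
    occlusion at total cell density ``eta_T``:
    ``p(r) = max(0, 1 - pi r_n^2 eta_T r)`` (low-density cylinder count)."""
    r = np.asarray(r, dtype=float)
    out = np.clip(1.0 - np.pi * r_n**2 * eta_T * r, 0.0, None)
    return out if out.ndim else float(out)


def _pdf_unnormalized(r, r_m, eta_T, r_n=1.0):
    r = np.asarray(r, dtype=float)
    body = r**2 * np.clip(1.0 - np.pi * r_n**2 * eta_T * r, 0.0, None) * (r - 2 * r_m) ** 2 * (r + 4 * r_m)
    return np.where((r >= 0) & (r <= 2 * r_m), body, 0.0)


def connection_pdf_normalization(r_m: float, eta_T: float, r_n: float = 1.0) -> float:
    """Normalization constant K such that the length PDF integrates to 1 over
    [0, 2 r_m].  In the eta_T -> 0 limit K = 3 / (16 r_m^6) (ball line-picking
    distribution)."""
    val, _ = integrate.quad(lambda r: _pdf_unnormalized(r, r_m, eta_T, r_n), 0.0, 2.0 * r_m, limit=200)
    if val <= 0:
        raise ValueError("degenerate length distribution (density too high)")
    return 1.0 / val


def connection_pdf_analytic(r, r_m: float, eta_T: float, r_n: float = 1.0):
    """Probability density of RT-3 connection lengths:
    ``K r^2 (1 - pi r_n^2 eta_T r) (r - 2 r_m)^2 (r + 4 r_m)`` on [0, 2 r_m],
    zero outside."""
    k = connection_pdf_normalization(r_m, eta_T, r_n)
    out = k * _pdf_unnormalized(r, r_m, eta_T, r_n)
    return out if np.ndim(r) else float(out)


def connections_per_neuron(population: CellPopulation, connections: ConnectionSet):
    """Mean out-degree over neurons and the out-degree histogram."""
    neuron_idx = np.flatnonzero(population.neuron_mask)
    deg = np.zeros(population.n_cells, dtype=int)
    if len(connections):
        np.add.at(deg, connections.source, 1)
    degrees = deg[neuron_idx]
    values, counts = np.unique(degrees, return_counts=True) if len(degrees) else (np.empty(0, int), np.empty(0, int))
    mean = float(degrees.mean()) if len(degrees) else 0.0
    return mean, pd.DataFrame({"out_degree": values, "count": counts})
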