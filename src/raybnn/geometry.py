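"""Cell placement inside the network sphere.

Neurons and glial cells occupy positions in a ball of radius ``r_s`` (all
lengths are expressed in units of the cell radius ``r_n``).  Hidden neurons and
glial cells are distributed uniformly in the ball by inverse-CDF sampling of
spherical coordinates; input neurons sit on the sphere surface in an ordered
layout so that the spatial order of the data features is preserved; output
neurons are all fixed at the origin.  Cells are hard spheres: two cells whose
centers are within ``2 r_n`` of each other collide, and colliding placements
are rejected during population assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "CellPopulation",
    "GeometryConfig",
    "sample_hidden_positions",
    "radial_density",
    "collision_probability_analytic",
    "min_sphere_radius",
    "detect_collisions",
    "populate_sphere",
    "place_input_grid",
    "place_input_helix",
    "place_input_stacked",
    "grow_sphere",
    "densify_inputs",
    "migrate_inputs_concat",
    "read_positions",
    "write_positions",
]

CELL_TYPES = ("input", "hidden", "output", "glial")


def spherical_to_cartesian(r, theta, phi):
    """Right-handed convention: ``theta`` is the polar angle from +z, ``phi``
    the azimuth from +x."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    return np.stack([r * st * np.cos(phi), r * st * np.sin(phi), r * np.cos(theta)], axis=-1)


def cartesian_to_spherical(xyz):
    xyz = np.asarray(xyz, dtype=float)
    r = np.linalg.norm(xyz, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(r > 0, np.arccos(np.clip(xyz[..., 2] / np.where(r > 0, r, 1.0), -1, 1)), 0.0)
    phi = np.mod(np.arctan2(xyz[..., 1], xyz[..., 0]), 2 * np.pi)
    return r, theta, phi


@dataclass
class CellPopulation:
    """Positions and types of every cell in the network sphere.

    ``positions`` are Cartesian, in units of ``r_n``.  ``cell_type`` holds one
    of ``input``/``hidden``/``output``/``glial`` per cell, ``cell_id`` a stable
    integer identity that survives growth and pruning.  Row order is the cell
    index order used by the weight matrix builder.
    """

    positions: np.ndarray
    cell_type: np.ndarray
    r_s: float
    r_n: float = 1.0
    cell_id: np.ndarray = field(default=None)
    input_grid: tuple | None = None  # (N_x, N_y) of the surface layout, if gridded
    input_v: np.ndarray | None = None  # (n_inputs, 2) fractional grid coords (v_theta, v_phi)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        if self.cell_id is None:
            self.cell_id = np.arange(len(self.positions))
        self.cell_id = np.asarray(self.cell_id, dtype=int)
        if not (len(self.positions) == len(self.cell_type) == len(self.cell_id)):
            raise ValueError("positions, cell_type and cell_id must have equal length")
        bad = set(self.cell_type) - set(CELL_TYPES)
        if bad:
            raise ValueError(f"unknown cell types: {bad}")

    # -- derived counts -------------------------------------------------
    def count(self, kind: str) -> int:
        return int(np.sum(self.cell_type == kind))

    @property
    def n_input(self) -> int:
        return self.count("input")

    @property
    def n_hidden(self) -> int:
        return self.count("hidden")

    @property
    def n_output(self) -> int:
        return self.count("output")

    @property
    def n_glial(self) -> int:
        return self.count("glial")

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def n_neurons(self) -> int:
        return self.n_cells - self.n_glial

    def mask(self, kind: str) -> np.ndarray:
        return self.cell_type == kind

    @property
    def neuron_mask(self) -> np.ndarray:
        return self.cell_type != "glial"

    def density(self) -> float:
        """Total cell density eta_T = N_T / (4/3 pi r_s^3) in r_n^-3."""
        return self.n_cells / (4.0 / 3.0 * np.pi * self.r_s**3)

    def copy(self) -> "CellPopulation":
        return CellPopulation(
            positions=self.positions.copy(),
            cell_type=self.cell_type.copy(),
            r_s=self.r_s,
            r_n=self.r_n,
            cell_id=self.cell_id.copy(),
            input_grid=self.input_grid,
            input_v=None if self.input_v is None else self.input_v.copy(),
        )


@dataclass
class GeometryConfig:
    """Counts, collision threshold and input layout for building a population."""

    n_hidden: int = 0
    n_glial: int = 0
    n_input: int = 0
    n_output: int = 0
    r_s: float | None = None  # requested sphere radius; may be raised to the minimum
    p_c_threshold: float = 0.01
    input_layout: str = "helix"  # grid | helix | random | stacked_channels
    grid_shape: tuple | None = None  # (N_x, N_y) for grid, (N_x, N_y, C) for stacked
    strict_collisions: bool = False  # delete both members of a colliding pair
    enforce_min_radius: bool = True  # False: characterization sweeps above the collision regime
    seed: int | None = None

    def __post_init__(self):
        for name in ("n_hidden", "n_glial", "n_input", "n_output"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.p_c_threshold < 1.0:
            raise ValueError("p_c_threshold must be in (0, 1)")
        if self.input_layout not in ("grid", "helix", "random", "stacked_channels"):
            raise ValueError(f"unknown input layout {self.input_layout!r}")
        if self.input_layout == "grid":
            if self.grid_shape is None:
                raise ValueError("grid layout requires grid_shape=(N_x, N_y)")
            nx, ny = self.grid_shape[:2]
            if nx * ny < self.n_input:
                raise ValueError("grid layout requires N_x*N_y >= n_input")


# ---------------------------------------------------------------------------
# sampling and analytic relations
# ---------------------------------------------------------------------------

def sample_hidden_positions(n: int, r_s: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` points uniformly in the ball of radius ``r_s``.

    Inverse-CDF sampling in spherical coordinates: with uniform variates
    ``R_r, R_theta, R_phi`` in [0,1),

        r     = R_r**(1/3) * r_s
        theta = arccos(2 (R_theta - 1/2))
        phi   = 2 pi R_phi

    which gives constant density per volume element r^2 sin(theta) dr dtheta dphi.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if r_s <= 0:
        raise ValueError("r_s must be positive")
    u = rng.random((int(n), 3))
    r = u[:, 0] ** (1.0 / 3.0) * r_s
    theta = np.arccos(2.0 * (u[:, 1] - 0.5))
    phi = 2.0 * np.pi * u[:, 2]
    return spherical_to_cartesian(r, theta, phi)


def radial_density(population: CellPopulation, n_bins: int):
    """Histogram of radial distance for hidden + glial cells, with the
    least-squares quadratic fit ``count = a * r^2``.

    For a uniform ball the expected shell population is
    ``n_T(r) = 3 N_T r^2 / r_s^3``, so the fitted ``a`` should approach
    ``3 N_T / r_s^3`` (times the bin width).

    Returns a DataFrame with bin centers and counts, and the fitted
    coefficient ``a`` expressed per unit radius (bin-width normalized).
    ``a`` is NaN when the fit is degenerate (no cells).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if population.n_cells == 0:
        raise ValueError("population is empty")
    sel = (population.cell_type == "hidden") | (population.cell_type == "glial")
    radii = np.linalg.norm(population.positions[sel], axis=1)
    counts, edges = np.histogram(radii, bins=n_bins, range=(0.0, population.r_s))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    table = pd.DataFrame({"r": centers, "count": counts})
    if counts.sum() == 0:
        return table, float("nan")
    # least squares for count = a * width * r^2  ->  density coefficient a
    x = centers**2
    a_binned = float(np.dot(x, counts) / np.dot(x, x))
    return table, a_binned / width


def collision_probability_analytic(eta_T: float, r_n: float = 1.0) -> float:
    """Probability that a cell placed into a population of density ``eta_T``
    overlaps an existing cell: ``P_c = (32 pi / 3) eta_T r_n^3``.

    Valid in the sparse regime P_c << 1; not clamped, so callers can detect
    out-of-regime densities.
    """
    if eta_T < 0:
        raise ValueError("eta_T must be non-negative")
    return 32.0 * np.pi / 3.0 * eta_T * r_n**3


def min_sphere_radius(n_total: int, p_c_threshold: float, r_n: float = 1.0) -> float:
    """Smallest sphere radius keeping the collision probability below the
    threshold: ``r_s = (8 N_T / P_c_th)^(1/3) r_n``."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0.0 < p_c_threshold <= 1.0:
        raise ValueError("p_c_threshold must be in (0, 1]")
    return (8.0 * n_total / p_c_threshold) ** (1.0 / 3.0) * r_n


# ---------------------------------------------------------------------------
# collision detection
# ---------------------------------------------------------------------------

def detect_collisions(
    positions: np.ndarray,
    r_n: float = 1.0,
    method: str = "minibatch",
    chunk_size: int = 1024,
) -> np.ndarray:
    """Indices of all cells whose center lies within ``2 r_n`` (inclusive) of
    another cell's center.

    Methods, all returning the identical sorted index array:

    ``serial``
        one cell per pass against all others (O(M^2) time, O(M) memory);
    ``batch``
        the full pairwise distance matrix at once (O(M^2) memory);
    ``minibatch``
        fixed-size chunks of cells against all cells, never materializing the
        full M x M structure;
    ``kdtree``
        fixed-radius pair query on a k-d tree; the backend the Monte-Carlo
        sweeps use at large M.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    m = len(positions)
    thr = 2.0 * r_n
    if m < 2:
        return np.empty(0, dtype=int)
    if method == "serial":
        flagged = np.zeros(m, dtype=bool)
        for i in range(m):
            d2 = np.einsum("ij,ij->i", positions - positions[i], positions - positions[i])
            d2[i] = np.inf
            if d2.min() <= thr * thr:
                flagged[i] = True
        return np.flatnonzero(flagged)
    if method == "batch":
        diff = positions[:, None, :] - positions[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.fill_diagonal(d2, np.inf)
        return np.flatnonzero(d2.min(axis=1) <= thr * thr)
    if method == "minibatch":
        flagged = np.zeros(m, dtype=bool)
        for start in range(0, m, chunk_size):
            block = positions[start : start + chunk_size]
            diff = block[:, None, :] - positions[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            rows = np.arange(len(block))
            d2[rows, rows + start] = np.inf
            flagged[start : start + chunk_size] = d2.min(axis=1) <= thr * thr
        return np.flatnonzero(flagged)
    if method == "kdtree":
        tree = cKDTree(positions)
        pairs = tree.query_pairs(thr, output_type="ndarray")
        flagged = np.zeros(m, dtype=bool)
        flagged[pairs.ravel()] = True
        return np.flatnonzero(flagged)
    raise ValueError(f"unknown collision-detection method {method!r}")


class _HashGrid:
    """Spatial hash on a 2*r_n grid for sequential accept/reject placement."""

    def __init__(self, cell: float):
        self.cell = cell
        self.bins: dict[tuple, list] = {}
        self.points: list[np.ndarray] = []

    def _key(self, p):
        return (int(np.floor(p[0] / self.cell)), int(np.floor(p[1] / self.cell)), int(np.floor(p[2] / self.cell)))

    def conflicts(self, p, thr2: float) -> bool:
        kx, ky, kz = self._key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for idx in self.bins.get((kx + dx, ky + dy, kz + dz), ()):
                        q = self.points[idx]
                        d = p - q
                        if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] <= thr2:
                            return True
        return False

    def add(self, p):
        self.bins.setdefault(self._key(p), []).append(len(self.points))
        self.points.append(p)


def populate_sphere(config: GeometryConfig, rng: np.random.Generator | None = None):
    """Build a full cell population from a geometry configuration.

    Hidden neurons and glial cells are sampled uniformly into a sphere of
    radius ``max(config.r_s, min_sphere_radius)``, accepted sequentially with
    any candidate within ``2 r_n`` of a previously accepted cell rejected and
    redrawn.  Input neurons are then placed on the surface by the requested
    layout and output neurons at the origin (exempt from the separation rule).

    Returns ``(population, stats)`` where ``stats`` records attempts and
    rejections of the interior placement.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_interior = config.n_hidden + config.n_glial
    n_total = n_interior + config.n_input + config.n_output
    r_s = float(config.r_s) if config.r_s is not None else 0.0
    if n_total >= 1 and (config.enforce_min_radius or r_s <= 0):
        r_s = max(r_s, min_sphere_radius(max(n_total, 1), config.p_c_threshold))
    if r_s <= 0:
        raise ValueError("cannot determine a positive sphere radius")

    thr2 = (2.0) ** 2  # (2 r_n)^2 with r_n = 1 length unit
    grid = _HashGrid(cell=2.0)
    attempts = 0
    rejected = 0
    max_attempts = 50 * max(n_interior, 1) + 1000
    batch = max(1024, n_interior)
    pending: list[np.ndarray] = []

    if config.strict_collisions and n_interior:
        # strict mode: one placement pass, then delete BOTH members of every
        # colliding pair before topping up with accept/reject.
        candidates = sample_hidden_positions(n_interior, r_s, rng)
        attempts += n_interior
        bad = detect_collisions(candidates, method="kdtree")
        rejected += len(bad)
        for p in np.delete(candidates, bad, axis=0):
            grid.add(p)

    while len(grid.points) < n_interior:
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place cells without collisions; density too high "
                f"({len(grid.points)}/{n_interior} placed after {attempts} attempts)"
            )
        if not pending:
            pending = list(sample_hidden_positions(batch, r_s, rng))
        p = pending.pop(0)
        attempts += 1
        if grid.conflicts(p, thr2):
            rejected += 1
        else:
            grid.add(p)
    interior = np.asarray(grid.points, dtype=float).reshape(-1, 3) if n_interior else np.zeros((0, 3))

    # shuffle hidden/glial labels so neither type is biased by placement order
    types_interior = np.array(
        ["hidden"] * config.n_hidden + ["glial"] * (len(interior) - config.n_hidden), dtype=object
    )
    rng.shuffle(types_interior)

    input_pos, input_grid, input_v = _place_inputs(config, r_s, rng)
    output_pos = np.zeros((config.n_output, 3))

    positions = np.vstack([input_pos, interior, output_pos]) if n_total else np.zeros((0, 3))
    cell_type = np.concatenate(
        [
            np.array(["input"] * len(input_pos), dtype=object),
            types_interior,
            np.array(["output"] * config.n_output, dtype=object),
        ]
    )
    pop = CellPopulation(
        positions=positions,
        cell_type=cell_type,
        r_s=r_s,
        cell_id=np.arange(len(positions)),
        input_grid=input_grid,
        input_v=input_v,
    )
    stats = {"attempts": attempts, "rejected": rejected, "r_s": r_s,
             "rejection_fraction": rejected / attempts if attempts else 0.0}
    return pop, stats


def _place_inputs(config: GeometryConfig, r_s: float, rng: np.random.Generator):
    n = config.n_input
    if n == 0:
        return np.zeros((0, 3)), None, None
    if config.input_layout == "grid":
        nx, ny = config.grid_shape[:2]
        pos, v = place_input_grid(nx, ny, r_s, return_v=True)
        return pos[:n], (nx, ny), v[:n]
    if config.input_layout == "helix":
        pos, (nx, ny), v = place_input_helix(n, r_s, return_v=True)
        return pos, (nx, ny), v
    if config.input_layout == "stacked_channels":
        nx, ny, c = config.grid_shape
        pos, v = place_input_stacked(nx, ny, c, r_s, return_v=True)
        return pos[:n], (nx, ny), v[:n]
    # random surface placement: hidden-style angles at fixed radius r_s
    u = rng.random((n, 2))
    theta = np.arccos(2.0 * (u[:, 0] - 0.5))
    phi = 2.0 * np.pi * u[:, 1]
    return spherical_to_cartesian(np.full(n, r_s), theta, phi), None, None


# ---------------------------------------------------------------------------
# input-surface layouts
# ---------------------------------------------------------------------------

def grid_vectors(n_x: int, n_y: int):
    """Equally spaced fractional coordinates v in (0, 1):
    v_theta^i = (i+1)/(N_x+1), v_phi^j = (j+1)/(N_y+1)."""
    if n_x < 1 or n_y < 1:
        raise ValueError("grid dimensions must be >= 1")
    v_theta = (np.arange(n_x) + 1.0) / (n_x + 1.0)
    v_phi = (np.arange(n_y) + 1.0) / (n_y + 1.0)
    return v_theta, v_phi


def _v_to_position(v_theta, v_phi, r_s):
    theta = np.arccos(2.0 * (np.asarray(v_theta) - 0.5))
    phi = 2.0 * np.pi * np.asarray(v_phi)
    return spherical_to_cartesian(np.full(np.shape(theta), r_s), theta, phi)


def place_input_grid(n_x: int, n_y: int, r_s: float, return_v: bool = False):
    """Ordered surface positions for an N_x x N_y pixel grid, row-major.

    Pixel (i, j) maps to the surface point (r_s, arccos[2(v_theta^i - 1/2)],
    2 pi v_phi^j); equal cos(theta) spacing gives each input neuron the same
    solid angle."""
    v_theta, v_phi = grid_vectors(n_x, n_y)
    vt = np.repeat(v_theta, n_y)
    vp = np.tile(v_phi, n_x)
    pos = _v_to_position(vt, vp, r_s)
    if return_v:
        return pos, np.column_stack([vt, vp])
    return pos


def place_input_helix(n_1d: int, r_s: float, return_v: bool = False):
    """Surface positions for 1D data of length ``n_1d``: build the square grid
    with N_x = N_y = ceil(sqrt(n_1d)), flatten row-major (the helix pattern)
    and keep the first n_1d sites."""
    if n_1d < 1:
        raise ValueError("n_1d must be >= 1")
    n = int(np.ceil(np.sqrt(n_1d)))
    pos, v = place_input_grid(n, n, r_s, return_v=True)
    if return_v:
        return pos[:n_1d], (n, n), v[:n_1d]
    return pos[:n_1d]


def place_input_stacked(n_x: int, n_y: int, channels: int, r_s: float, return_v: bool = False):
    """Grid layout with ``channels`` co-located input neurons per site (RGB-style
    data).  Site order is row-major, channel-fastest.  Co-located neurons are
    exempt from the collision rule; a ray hitting a shared site is resolved to
    one of the co-located neurons uniformly at random by the ray tracer."""
    if channels < 1:
        raise ValueError("channels must be >= 1")
    base, v = place_input_grid(n_x, n_y, r_s, return_v=True)
    pos = np.repeat(base, channels, axis=0)
    if return_v:
        return pos, np.repeat(v, channels, axis=0)
    return pos


# ---------------------------------------------------------------------------
# growth / re-assignment
# ---------------------------------------------------------------------------

def grow_sphere(population: CellPopulation, r_s_new: float) -> CellPopulation:
    """Scale every cell's radial coordinate by ``r_s_new / r_s``, keeping polar
    and azimuthal angles (hence unit direction vectors) unchanged."""
    if r_s_new < population.r_s:
        raise ValueError("grow_sphere cannot shrink the network sphere")
    out = population.copy()
    out.positions = population.positions * (r_s_new / population.r_s)
    out.r_s = float(r_s_new)
    return out


def densify_inputs(n_x_old: int, n_y_old: int, n_x_new: int, n_y_new: int):
    """Densified grid vectors for a higher-resolution input layout.

    Returns ``(v_theta_new, v_phi_new, index_map)`` where the new vectors are
    the equally-spaced fractions at the new sizes and ``index_map[(i, j)]``
    gives, for each old grid site, the nearest new-grid site.  Old neurons keep
    their exact old surface positions; the map is bookkeeping that tells which
    new sites are claimed (new neurons occupy the rest)."""
    if n_x_new < n_x_old or n_y_new < n_y_old:
        raise ValueError("densify_inputs cannot shrink the grid")
    vt_old, vp_old = grid_vectors(n_x_old, n_y_old)
    vt_new, vp_new = grid_vectors(n_x_new, n_y_new)
    ix = np.abs(vt_old[:, None] - vt_new[None, :]).argmin(axis=1)
    iy = np.abs(vp_old[:, None] - vp_new[None, :]).argmin(axis=1)
    index_map = {(i, j): (int(ix[i]), int(iy[j])) for i in range(n_x_old) for j in range(n_y_old)}
    return vt_new, vp_new, index_map


def migrate_inputs_concat(population: CellPopulation, kappa: float) -> CellPopulation:
    """Compress the old input neurons toward the north pole:
    theta_i' = arccos[2 (kappa v_theta^i - 1/2)] with azimuth unchanged.

    The vacated southern polar band is then available for concatenated new
    input features.  Requires the population to carry its fractional grid
    coordinates (``input_v``)."""
    if not 0.0 < kappa <= 1.0:
        raise ValueError("kappa must be in (0, 1]")
    out = population.copy()
    sel = np.flatnonzero(population.cell_type == "input")
    v = population.input_v
    if v is None:
        # reconstruct fractional surface coordinates from the positions
        # (the theta map v -> arccos[2(v - 1/2)] is invertible)
        _, theta, phi = cartesian_to_spherical(population.positions[sel])
        v = np.column_stack([np.cos(theta) / 2.0 + 0.5, phi / (2.0 * np.pi)])
    theta_new = np.arccos(np.clip(2.0 * (kappa * v[:, 0] - 0.5), -1.0, 1.0))
    phi = 2.0 * np.pi * v[:, 1]
    out.positions[sel] = spherical_to_cartesian(np.full(len(sel), population.r_s), theta_new, phi)
    out.input_v = np.column_stack([kappa * v[:, 0], v[:, 1]])
    return out


# ---------------------------------------------------------------------------
# positions table I/O
# ---------------------------------------------------------------------------

def write_positions(population: CellPopulation, path) -> None:
    """Delimited text table (cell_id, type, x, y, z); row order is the cell
    index order used by the weight matrix."""
    df = pd.DataFrame(
        {
            "cell_id": population.cell_id,
            "type": population.cell_type,
            "x": population.positions[:, 0],
            "y": population.positions[:, 1],
            "z": population.positions[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_positions(path, r_s: float | None = None, r_n: float = 1.0) -> CellPopulation:
    df = pd.read_csv(path, float_precision="round_trip")
    positions = df[["x", "y", "z"]].to_numpy(float)
    if r_s is None:
        norms = np.linalg.norm(positions, axis=1)
        r_s = float(norms.max()) if len(norms) else 1.0
    return CellPopulation(
        positions=positions,
        cell_type=df["type"].to_numpy(object),
        r_s=r_s,
        r_n=r_n,
        cell_id=df["cell_id"].to_numpy(int),
    )
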