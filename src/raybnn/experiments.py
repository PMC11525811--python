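"""Monte-Carlo characterization sweeps and the synthetic localization task.

The sweeps reproduce the network-characterization measurements: collision
probability versus cell density (with its log-log least-squares fit and the
density meeting a target collision threshold), the radial cell-count
histogram and its quadratic fit, the RT-3 connection-length distribution
against the analytic form, and the connections-per-neuron trend.

The synthetic dataset emulates indoor Wi-Fi localization semantics: each
access point (AP) contributes one received-signal-strength (RSSI) feature,
detected values lie in [-99, -1] dBm, and a sentinel of +100 marks an AP that
is out of detection range; targets are the 2D device coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry, raytracing
from .geometry import GeometryConfig, populate_sphere, sample_hidden_positions
from .network import build_model, forward
from .raytracing import RTConfig, rt3, connection_pdf_normalization, _pdf_unnormalized
from .training import TrainConfig, loss_mse, train
from .transfer import GrowthPlan, grow_network

__all__ = [
    "SweepResult",
    "SyntheticLocalizationDataset",
    "mc_collision_curve",
    "mc_length_pdf",
    "length_ks_distance",
    "synth_localization",
    "prepare_features",
    "demo_transfer_pipeline",
]


@dataclass
class SweepResult:
    """Sweep table plus the log10-log10 least-squares fit (slope, intercept)
    where applicable."""

    table: pd.DataFrame
    slope: float | None = None
    intercept: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# collision-probability sweep
# ---------------------------------------------------------------------------

def mc_collision_curve(n_total: int, densities, seeds,
                       p_c_threshold: float = 0.01,
                       method: str = "kdtree") -> SweepResult:
    """Place ``n_total`` cells uniformly at each density, measure the colliding
    fraction, fit log10(P_c) against log10(eta) by ordinary least squares, and
    solve the fitted line for the density where P_c equals the threshold.

    Error bars are sample standard deviations across seeds.  The result
    carries the fitted slope, the threshold density ``eta_threshold`` and the
    implied minimum sphere radius ``r_s_min = (3 N_T / (4 pi eta))^(1/3)``.
    """
    densities = np.asarray(list(densities), dtype=float)
    rows = []
    for eta in densities:
        r_s = (3.0 * n_total / (4.0 * np.pi * eta)) ** (1.0 / 3.0)
        fractions = []
        for seed in seeds:
            rng = np.random.default_rng(int(seed))
            pos = sample_hidden_positions(n_total, r_s, rng)
            colliding = geometry.detect_collisions(pos, method=method)
            fractions.append(len(colliding) / n_total)
        rows.append(
            {
                "density": eta,
                "p_collision": float(np.mean(fractions)),
                "p_collision_std": float(np.std(fractions, ddof=1)) if len(fractions) > 1 else 0.0,
                "n_seeds": len(list(seeds)),
            }
        )
    table = pd.DataFrame(rows)
    x = np.log10(table["density"].to_numpy())
    y = np.log10(table["p_collision"].to_numpy())
    slope, intercept = np.polyfit(x, y, 1)
    eta_threshold = 10 ** ((np.log10(p_c_threshold) - intercept) / slope)
    r_s_min = (3.0 * n_total / (4.0 * np.pi * eta_threshold)) ** (1.0 / 3.0)
    return SweepResult(
        table=table, slope=float(slope), intercept=float(intercept),
        extras={"eta_threshold": float(eta_threshold), "r_s_min": float(r_s_min)},
    )


# ---------------------------------------------------------------------------
# connection-length distribution sweep
# ---------------------------------------------------------------------------

def _analytic_length_cdf(r_grid, r_m, eta_T):
    k = connection_pdf_normalization(r_m, eta_T)
    fine = np.linspace(0.0, 2.0 * r_m, 4001)
    pdf = k * _pdf_unnormalized(fine, r_m, eta_T)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(fine))])
    cdf /= cdf[-1]
    return np.interp(r_grid, fine, cdf)


def length_ks_distance(lengths: np.ndarray, r_m: float, eta_T: float) -> float:
    """Kolmogorov-Smirnov distance between empirical connection lengths and
    the analytic length distribution."""
    lengths = np.sort(np.asarray(lengths, float))
    n = len(lengths)
    if n == 0:
        raise ValueError("no connection lengths")
    cdf_model = _analytic_length_cdf(lengths, r_m, eta_T)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(emp_hi - cdf_model), np.abs(emp_lo - cdf_model))))


def mc_length_pdf(n_cells: int, densities, r_rt: float, seeds) -> SweepResult:
    """Build populations at each density (half neurons, half glia), trace with
    RT-3, and report the KS distance between the empirical connection-length
    histogram and the analytic distribution."""
    rows = []
    for eta in densities:
        for seed in seeds:
            r_s = (3.0 * n_cells / (4.0 * np.pi * eta)) ** (1.0 / 3.0)
            n_half = n_cells // 2
            # the sweep probes densities far above the 1% collision regime,
            # so the radius floor is disabled
            cfg = GeometryConfig(n_hidden=n_half, n_glial=n_cells - n_half,
                                 r_s=r_s, enforce_min_radius=False, seed=int(seed))
            pop, _ = populate_sphere(cfg)
            # realized density (post input/output bookkeeping, none here)
            eta_real = pop.density()
            edges = rt3(pop, r_rt, np.random.default_rng(int(seed) + 1))
            ks = length_ks_distance(edges.length, r_rt, eta_real)
            mean_deg, _ = raytracing.connections_per_neuron(pop, edges)
            rows.append({"density": eta, "seed": int(seed), "n_edges": len(edges),
                         "ks_distance": ks, "mean_out_degree": mean_deg})
    return SweepResult(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# synthetic localization data
# ---------------------------------------------------------------------------

RSSI_SENTINEL = 100.0


@dataclass
class SyntheticLocalizationDataset:
    """AP positions (P x 2), RSSI matrix (n x P) with +100 for undetected,
    device coordinates (n x 2), and the generating parameters."""

    ap_positions: np.ndarray
    rssi: np.ndarray
    targets: np.ndarray
    arena: float
    noise_sigma: float
    path_loss_exponent: float
    detection_range: float
    seed: int


def synth_localization(n_aps: int, n_samples: int, arena: float = 50.0,
                       noise_sigma: float = 2.0, path_loss_exponent: float = 2.5,
                       offset: float = -30.0, detection_range: float | None = None,
                       seed: int = 0) -> SyntheticLocalizationDataset:
    """Log-distance path-loss RSSI data.

    ``RSSI = clip(-10 gamma log10(d) + offset + N(0, sigma^2), -99, -1)`` for
    APs within the detection range, the +100 sentinel beyond it.  The default
    detection range is 60% of the arena diagonal, which leaves roughly a fifth
    of the entries undetected at the default geometry.
    """
    if n_aps < 1 or n_samples < 1:
        raise ValueError("n_aps and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    ap_pos = rng.uniform(0.0, arena, size=(n_aps, 2))
    targets = rng.uniform(0.0, arena, size=(n_samples, 2))
    if detection_range is None:
        detection_range = 0.6 * arena * np.sqrt(2.0)
    d = np.linalg.norm(targets[:, None, :] - ap_pos[None, :, :], axis=2)
    d = np.maximum(d, 1e-3)
    rssi = -10.0 * path_loss_exponent * np.log10(d) + offset
    rssi += noise_sigma * rng.standard_normal(rssi.shape)
    rssi = np.clip(rssi, -99.0, -1.0)
    rssi[d > detection_range] = RSSI_SENTINEL
    return SyntheticLocalizationDataset(
        ap_positions=ap_pos, rssi=rssi, targets=targets, arena=arena,
        noise_sigma=noise_sigma, path_loss_exponent=path_loss_exponent,
        detection_range=float(detection_range), seed=seed,
    )


def prepare_features(rssi: np.ndarray, center: float = -60.0, scale: float = 30.0):
    """Standardize RSSI features for training: detected values map to roughly
    unit scale, the +100 sentinel maps to the neutral value 0."""
    x = np.asarray(rssi, dtype=float)
    out = (x - center) / scale
    out[x == RSSI_SENTINEL] = 0.0
    return out


# ---------------------------------------------------------------------------
# transfer-learning demo pipeline
# ---------------------------------------------------------------------------

def _build_for(n_inputs: int, n_hidden: int, n_glial: int, r_rt: float,
               seed: int, k: int = 2):
    cfg = GeometryConfig(n_hidden=n_hidden, n_glial=n_glial, n_input=n_inputs,
                         n_output=2, input_layout="helix", seed=seed)
    pop, _ = populate_sphere(cfg)
    rng = np.random.default_rng(seed + 7)
    edges = rt3(pop, r_rt, rng)
    return build_model(pop, edges, rng, k=k)


def _epochs_to_threshold(log, threshold: float) -> int | None:
    for entry in log:
        if entry["loss"] <= threshold:
            return entry["epoch"]
    return None


def demo_transfer_pipeline(ap_schedule, seed: int = 0, n_samples: int = 200,
                           hidden_schedule=None, r_rt: float = 40.0,
                           epochs: int = 300, learning_rate: float = 0.02,
                           loss_threshold_fraction: float = 0.35) -> pd.DataFrame:
    """Grow a localization network along an increasing AP schedule and compare
    transfer-initialized training against scratch controls.

    For each segment the loss threshold is the given fraction of the
    predict-the-mean baseline loss of that segment's data.  Returns one row
    per segment with epochs-to-threshold for the transferred model and the
    scratch control, parameter counts and held-out MAE (arena units).
    """
    ap_schedule = list(ap_schedule)
    if any(b < a for a, b in zip(ap_schedule, ap_schedule[1:])):
        raise ValueError("ap_schedule must be non-decreasing")
    if hidden_schedule is None:
        hidden_schedule = [40 + 10 * i for i in range(len(ap_schedule))]
    data = synth_localization(ap_schedule[-1], n_samples + n_samples // 4, seed=seed)
    n_train = n_samples
    x_all = prepare_features(data.rssi)
    y_all = data.targets / data.arena  # normalized coordinates
    rows = []
    model = None
    for step, (n_ap, n_hid) in enumerate(zip(ap_schedule, hidden_schedule)):
        x_train = x_all[:n_train, :n_ap][None, :, :].transpose(0, 2, 1)  # (1, N_I, B)
        y_train = y_all[:n_train].T[None, :, :]
        x_test = x_all[n_train:, :n_ap][None, :, :].transpose(0, 2, 1)
        y_test = y_all[n_train:].T[None, :, :]
        base_loss = loss_mse(np.broadcast_to(y_train.mean(axis=2, keepdims=True), y_train.shape), y_train)
        threshold = loss_threshold_fraction * base_loss
        cfg = TrainConfig(epochs=epochs, learning_rate=learning_rate, seed=seed)

        if model is None:
            model = _build_for(n_ap, n_hid, n_hid, r_rt, seed)
            transferred = model
            transfer_epochs = None
            log_t = train(transferred, x_train, y_train, cfg, stop_loss=threshold)
            transfer_epochs = _epochs_to_threshold(log_t, threshold)
        else:
            plan = GrowthPlan(n_input=n_ap, n_hidden=n_hid, n_glial=n_hid,
                              n_output=2, input_mode="concat",
                              rt=RTConfig(algorithm="rt3", r_rt=r_rt),
                              seed=seed + 100 + step)
            transferred = grow_network(model, plan)
            log_t = train(transferred, x_train, y_train, cfg, stop_loss=threshold)
            transfer_epochs = _epochs_to_threshold(log_t, threshold)
        scratch = _build_for(n_ap, n_hid, n_hid, r_rt, seed + 999 + step)
        log_s = train(scratch, x_train, y_train, cfg, stop_loss=threshold)
        scratch_epochs = _epochs_to_threshold(log_s, threshold)

        pred = forward(transferred, x_test)[0].T  # (n_test, 2)
        mae = float(np.mean(np.abs(pred - y_test[0].T))) * data.arena
        rows.append(
            {
                "segment": step,
                "n_aps": n_ap,
                "transfer_epochs": transfer_epochs,
                "scratch_epochs": scratch_epochs,
                "threshold": threshold,
                "final_loss": log_t[-1]["loss"],
                "params": log_t[-1]["params"],
                "nnz": log_t[-1]["nnz"],
                "test_mae": mae,
            }
        )
        model = transferred
    return pd.DataFrame(rows)
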