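# Methods

## Model

The package implements a ray-traced biological neural network: a recurrent
network whose neurons and glial cells occupy physical positions inside a 3D
sphere, and whose connectivity is determined by geometric line of sight rather
than by layers.

**Geometry.** All lengths are measured in units of the cell radius `r_n`
(default 1). Hidden neurons and glial cells are placed uniformly in the ball
of radius `r_s` by inverse-CDF sampling of spherical coordinates
(`r = U^{1/3} r_s`, `cos θ = 2U − 1`, `φ = 2πU`), which yields constant
density per volume element. Input neurons sit on the sphere surface on an
equal-solid-angle grid (`cos θ` equally spaced) so ordered data keep their
spatial order and every input neuron sees the hidden volume without bias; 1D
feature vectors use the row-major flattening of the smallest enclosing square
grid. All output neurons sit at the exact origin — they pool information
symmetrically and are exempt from the separation rule, as are co-located
stacked input channels. Cells are hard spheres: any two (other) cells closer
than `2 r_n` collide. Placement is sequential accept/reject on a spatial hash
grid; the rejection rate of one additional placement against `N_T` resident
cells is `P_c = (32π/3) η_T r_n³` in the sparse regime, so the sphere radius
is floored at `r_s,min = (8 N_T / P_c,th)^{1/3}` for the configured collision
threshold `P_c,th` (default 1%). The floor makes infeasible packings
unreachable through the public configuration; characterization sweeps that
deliberately probe denser regimes disable it with
`GeometryConfig(enforce_min_radius=False)`. The run-level rejection fraction
of the sequential process integrates the one-more-cell rate over the growing
population and is therefore about half the final-density value — the tests
check both quantities separately.

**Connectivity.** A candidate connection i→j is vetoed when a third cell lies
within `r_n` of the segment and strictly between the endpoints (both
projection dot products positive). Cells exactly co-located with an endpoint
never occlude. Three tracing algorithms produce directed, deduplicated edges:

* **RT-1** — each neuron emits K random rays (default 10,000, per-neuron RNG
  substreams); the nearest intersected cell decides: glial → ray discarded,
  neuron → edge. Ties in parametric hit distance resolve to the lowest cell
  index. Rays extend to the sphere boundary; the nearest-hit rule makes longer
  extents irrelevant. When several input neurons share one surface site
  (stacked channels), a ray hit on the site is resolved uniformly at random
  among them.
* **RT-2** — all ordered neuron pairs, keeping unblocked lines of sight;
  deterministic, and co-located targets each receive their own edge.
* **RT-3** — RT-2 restricted to clusters of radius `r_RT` around pivots drawn
  from not-yet-covered cells until every neuron is covered; only cluster
  members occlude, and no edge exceeds `2 r_RT`. With a single cluster
  covering everything RT-3 reproduces RT-2 exactly.

At low density the RT-3 connection lengths follow the ball line-picking
density modulated by an occlusion survival factor,
`P(r) ∝ r² (1 − π r_n² η_T r)(r − 2 r_m)²(r + 4 r_m)` on `[0, 2 r_m]`, with
the normalization computed by quadrature (closed form `3/(16 r_m⁶)` as
`η_T → 0`, mode at `≈ 1.0494 r_m`). The linear survival term is a first-order
approximation: it clamps to zero at `r = 1/(π r_n² η_T)` whereas simulated
blocking follows the Poisson survival `exp(−π r_n² η_T r)`. Measured KS
distances against the analytic form are ≈0.02–0.05 for
`η_T ∈ [2×10⁻³, 5×10⁻³] r_n⁻³` (6,000 cells, `r_RT = 20 r_n`) and grow to
≈0.16 by `10⁻² r_n⁻³`, where the approximation no longer holds; the tests
assert agreement only in the moderate-density window and treat the
divergence as expected behavior.

**Network.** Connections map into an `N×N` sparse adjacency matrix (COO for
edits, CSR for products) with entry (i, j) carrying the signal from neuron j
into neuron i; capacity `N` defaults to the next power of two above 1.2× the
active neuron count so growth and pruning never reallocate. Input slots are
0..N_I−1, outputs the last N_O slots. Structural zeros — input rows, output
columns, and the diagonal unless self-loops are enabled — are re-enforced
after every edit. Weights initialize Xavier-uniform with per-entry fan-in =
row occupancy and fan-out = column occupancy.

Each neuron owns a five-parameter universal activation function
`f(x) = ln(1+e^{A(x+B)−|C|x²}) − ln(1+e^{D(x−B)}) + E`, evaluated with
shifted softplus so it stays finite for |x| up to 10⁶. Parameters initialize
at the identity point (1, 0, 0, −1, 0) plus Gaussian jitter σ = 0.01 so the
untrained network is near-linear; training moves each neuron's activation
independently. The subgradient of |C| at 0 is taken as 0.

**Forward pass.** `S⁰ = 0`; per step the temporary state copies `S^t`,
overwrites input slots with `X^t` (input slots retain the final injected
vector during the `k` flush steps), and
`S^{t+1} = f_UAF(W Q^t + H, C_eff)`. Outputs for `X^t` are read from the
output slots of `S^{t+k}`; `k` defaults to the ceiling of the mean shortest
input→output path length. Because the state assembled at `t+k` injects inputs
up to `X^{t+k−1}`, the strict "output t depends only on inputs ≤ t" property
holds at `k = 1`; at larger delays the update rule itself entails a k−1-step
input lookahead. Bias entries of input slots are fixed at zero (their rows
are structurally zero; a trainable bias there could never influence any
other neuron).

**Training.** The loss is `J = (1/I_T) Σ_t ‖Ŷ^t − Y^t‖²`, averaged over any
batch axis. Gradients come from reverse-mode recursion through all
`I_T + k − 1` updates with no truncation; `dW` is accumulated only at live
sparse positions in row-major entry order, and `dH`, `dC_eff` ride the same
chain through the activation partials. Input-slot overwrites cut the adjoint
into overwritten coordinates. All gradient coordinates are verified against
central finite differences (relative error < 10⁻⁴) on randomized small
models. Optimizers: Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸, default) and plain
SGD. Training is full batch: desk-scale problems (hundreds of samples,
thousands of weights) fit in one vectorized batch.

**Pruning.** Probabilistic connection deletion draws `R_e ~ U(0,1)` per live
entry and removes exactly `⌈fraction · nnz⌉` entries with smallest
`|R_e w_e|` (stable order on ties): zero weights go first, large weights
survive with high probability. Redundant-neuron removal deletes, to a fixed
point, every hidden neuron with out-degree zero — its incoming row is zeroed,
its slot freed, its cell dropped — leaving forward outputs bit-identical
because its outgoing column was already empty. Input neurons are exempt (they
encode the feature layout; dead inputs are reported by the connectivity
check instead), and output neurons are never removed.

**Transfer learning.** Growth rescales every radial coordinate by
`r_s'/r_s` (angles untouched), re-lays the input surface (densified grid
keeping old neurons in place, or polar migration
`θ' = cos⁻¹[2(κ v_θ − ½)]` that empties the low-θ band for concatenated
features), places new cells collision-free against the residents, ray traces
only pairs involving at least one new cell, and rebuilds the matrix under the
new slot layout carrying every old (source cell, target cell, weight) triple,
bias and activation row bit-exactly; capacity doubles when exceeded.
Shrinking applies deletion sweeps until the target live-entry fraction, then
removes redundant neurons.

## Synthetic localization data

The generator emulates indoor Wi-Fi localization semantics: P access points
uniform in a square arena (default 50 m), device positions uniform, and
`RSSI = clip(−10 γ log₁₀ d + offset + N(0, σ²), −99, −1)` dBm with γ = 2.5,
offset = −30 dBm, σ = 2 dBm; APs beyond the detection range (default 60% of
the arena diagonal, giving roughly a fifth of entries undetected) report the
sentinel +100. Targets are the 2D coordinates. For training, detected values
standardize to roughly unit scale and the sentinel maps to the neutral value
0. The generator reproduces the feature semantics (bounded dBm plus sentinel)
of real RSSI fingerprinting data but none of its hard parts — multipath,
wall attenuation, temporally correlated noise, heterogeneous hardware — so
passing tests demonstrate the mechanics of training and transfer on this
family of problems, not field-grade localization accuracy.

## Problem sizes and numerical choices

* Monte-Carlo collision sweep: 480,000 cells, six densities log-spaced in
  `[10⁻⁴, 10⁻³] r_n⁻³`, three seed replicates, k-d-tree fixed-radius pair
  detection; ordinary least squares on log₁₀–log₁₀. The analytic slope is 1;
  the measured slope is ≈0.99–1.00 and the implied minimum radius ≈722–725
  `r_n`.
* Length-distribution checks: 6,000 cells, `r_RT = 20 r_n`; degree-vs-density
  trend: 1,200 cells, `r_RT = 15 r_n`, densities 0.02–0.07 `r_n⁻³` where
  occlusion dominates.
* Transfer demo: AP schedule grown 4 → 6 → 8, 40–60 hidden neurons with equal
  glia, `r_RT = 40 r_n`, 200 training + 50 held-out samples, Adam at 0.02,
  epochs-to-threshold measured against 0.35× the predict-the-mean baseline
  loss; scratch controls use identical settings with independent seeds.
* Quadrature tolerance for the length-PDF normalization: `scipy.integrate.quad`
  at default tolerances (integral check at 10⁻⁸); KS distances computed
  against the trapezoid-integrated analytic CDF on a 4001-point grid.
* Determinism: every stochastic operation takes a `numpy.random.Generator` or
  seed; identical seeds give bit-identical populations, traces, and training
  trajectories. RT-1 derives one substream per neuron so adding neurons never
  perturbs earlier draws.

## Known limitations

* The linear occlusion survival (and hence the analytic length PDF) degrades
  above `η_T ≈ 10⁻² r_n⁻³`; the package reports the divergence rather than
  modeling the Poisson survival.
* RT-3 occlusion considers cluster members only; a blocker just outside the
  cluster ball can be missed relative to RT-2 (documented ε-discrepancy
  bounded by the cluster construction).
* Execution is CPU/numpy only, full-batch, double precision; no accelerator
  or minibatch-parallel semantics.
* Non-spherical network shapes and position optimization by training are out
  of scope.
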