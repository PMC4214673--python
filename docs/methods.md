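# Methods

## Model

The glomerular layer is modelled as G = 16 identical microcircuits, one
per glomerulus, each containing a single mitral (MC), external tufted
(ET), periglomerular (PG) and short-axon (SA) cell. All cells are
two-variable Izhikevich neurons,

    C dv/dt = k (v − v_r)(v − v_t) − u + I(t)
      du/dt = a [ b (v − v_r) − u ]
    v ≥ v_peak  →  v ← c,  u ← u + d

with per-type parameters

| type | C (pF) | k | v_r | v_t | a (1/ms) | b | v_peak | c | d |
|------|-------:|---:|----:|----:|---------:|---:|-------:|---:|---:|
| MC   | 40  | 1     | −55   | −50 | 0.4    | 2.6   | 35 | −50 | 200 |
| PG   | 5.9 | 0.049 | −53.1 | −20 | 0.0167 | −0.94 | 35 | −20 | 50  |
| ET   | 40  | 1     | −55   | −50 | 0.4    | 2.6   | 35 | −50 | 200 |
| SA   | 58  | 0.061 | −67   | −30 | 0.049  | −0.68 | 35 | −30 | 150 |

MC and ET are deliberately identical, so any difference between their
output codes is attributable to the wiring, not the membrane. The printed
unit of `d` is mV although it increments the recovery variable; it is
applied numerically as printed.

Wiring. Within glomerulus g, the receptor input drives MC_g, ET_g and
PG_g as a constant current; MC_g→PG_g (excitatory), PG_g→MC_g (the only
inhibitory synapse), ET_g→PG_g, ET_g→SA_g. Laterally, SA_g projects
excitation to PG_h and ET_h of every other glomerulus h ≠ g, all with the
single swept weight `sa_weight`. Consequences: (i) the ET/SA subnetwork
receives nothing from MC or PG — ET activity reflects the input plus
globally shared activity only; (ii) PG inhibition onto MC grows with
global (concentration-like) activity, which is what normalizes the MC
code.

Synapses are current-based with a single-exponential kernel: a spike at
t0 contributes `sign · w · exp(−(t − t0)/τ)` pA for t ≥ t0, τ = 10 ms for
all synapses, no transmission delay. Because every synapse shares τ, the
total synaptic current per neuron is integrated as one leaky accumulator
updated once per step; this is exactly equivalent to summing the
closed-form kernels at the step times.

Integration is classical fixed-step RK4 at dt = 0.1 ms with each
neuron's input current held constant over the step. The reset test
v ≥ v_peak runs once after each completed step (never mid-substage): the
discontinuity makes sub-stage resets ill-defined, and the convergence
test (halving dt changes a 0.5 s spike count by ≤ 1) guards accuracy.
Spike times are assigned to the end of the triggering step. Initial
conditions are v = v_r, u = 0 (the quiescent fixed point; only v is
prescribed by the source data, and u = 0 is the unique value that makes
rest stationary). State and synaptic currents are fully re-initialized
between exposures — exposures are independent by construction. Recorded
membrane traces clamp overshoot at v_peak for display; the integrated
state is never clamped (it is reset anyway).

## Stimuli

There is no receptor-transduction model: an odorant is its combinatorial
code, a row S of i.i.d. U(0, 40) pA sensitivities over the 16 glomeruli.
The response at dimensionless concentration c is `min(S·c, 40)` pA — a
hard saturation applied after the product, the simplest reading that
preserves linearity below the ceiling. The identity/concentration
experiment crosses 6 odors (A–F) with c ∈ {0.4, 0.6, 0.8, 1.0, 1.2, 1.4}
(36 exposures of 0.5 s each). The morph series interpolates odors C and
E at c = 1: step j is `(1−α_j)·R_C + α_j·R_E`, α on a 21-point uniform
grid, saturation applied after mixing (the endpoints rarely clip, so the
order matters little; it is fixed and documented here). A canonical
panel seed (1) defines the reference panel used by the CLI defaults and
tests; every entry point accepts `--seed`.

## Objective functions

Identity: Fisher's discriminant ratio, the trace ratio
`FDR = tr(S_B)/tr(S_W)` with `S_B = Σ_i n_i (μ_i−μ)(μ_i−μ)ᵀ` and
`S_W = Σ_i Σ_{x∈i} (x−μ_i)(x−μ_i)ᵀ`, classes = odors. In the experiment
pipelines the sample x is the population-mean firing rate (a scalar per
exposure). This scalarization is pinned by the input side of the
problem, which has no free parameters: the raw 36-stimulus input panel
scores ≈ 0.105 under it, matching the reported input-layer separability,
whereas the full 16-dimensional trace ratio scores ≈ 1.5 — an order of
magnitude away. The metric function itself accepts arbitrary-dimension
samples and is translation- and scale-invariant.

Concentration: per-odor Pearson correlation against the concentration
factors, summarized as mean ± sd across odors. The default pools every
(glomerulus, concentration) response of an odor as one sample pair.
Under pooling the raw input scores ≈ 0.547 — again matching the
input-layer reference with zero free parameters — because glomeruli with
different sensitivities contribute different slopes. A `mean`
scalarization (population mean first, then correlate; gives exactly 1.0
on unclipped linear inputs) is available via `method="mean"`.

Structure: mean-centred, unscaled PCA (all features share units;
fractions of explained variance are reported), and divisive hierarchical
clustering by bisecting 2-means — always splitting the cluster with the
largest within-cluster sum of squares, 10 seeded k-means restarts per
split (lowest inertia, ties to lowest restart index), down to singletons.
Node height is the mean distance of members to the node centroid, so
duplicated points merge at height 0. "Hierarchical clustering based on
k-means" admits several readings; the divisive form is used and all
conclusions drawn from dendrograms in the tests use partition-level facts
(which samples co-cluster at the two-cluster level), which are robust to
this choice. Dendrograms export to Newick.

## Calibration of the fixed weights

Only the cell parameters, the input statistics, τ and dt are fixed by the
source data; the non-lateral synaptic weights are free. They were
calibrated once so that the model's qualitative behavior holds
simultaneously on the default conditions (6×6 panel, 0.5 s, 10 panel
seeds) and then frozen as the shipped defaults:

| weight | value | role |
|---|---:|---|
| w_orn_mc | 2.5 | MC receptor gain — keeps MC (rheobase ≈ 14.4 pA) firing above the strong PG inhibition |
| w_orn_et | 0.65 | ET receptor gain — sets the private (odor-specific) share of ET variance |
| w_orn_pg | 1.0 | PG receptor gain |
| w_mc_pg  | 30  | local MC→PG feedback |
| w_pg_mc  | 250 | PG→MC inhibition — the normalization pathway |
| w_et_pg  | 30  | ET→PG feed-forward inhibition of MC |
| w_et_sa  | 120 | ET→SA drive — sets how the lateral weight axis maps onto inhibition strength |

Under these defaults (pA per spike): the MC-FDR curve over the integer
lateral-weight grid 0–30 rises from ≈ 0.15 at 0, peaks at **19**
(seed-averaged peak ≈ 0.4–0.5), and falls back to near the input level by
30; total MC spiking is non-increasing in the lateral weight; ET
concentration-PCC rises monotonically from ≈ 0.53 to a ≈ 0.93 plateau
beyond 19; ET FDR decays toward zero; at weight 19 the first ET principal
component carries > 95 % of the variance. `sa_weight` is expressed in the
same arbitrary units as the sweep axis — numerically it is the pA-per-
spike peak increment of every SA efferent.

## What the synthetic data do and do not show

The generator reproduces the study's stimulus statistics exactly
(uniform sensitivities, linear concentration scaling, hard saturation,
constant-current exposure). It omits temporal structure (sniffing,
onset transients), receptor nonlinearities other than the ceiling,
trial-to-trial noise, and cell multiplicity within a glomerulus
(configurable but defaulting to one of each type). Passing tests
therefore demonstrate properties of the network computation under
idealized drive, not predictions for noisy, temporally structured real
input.

## Numerical choices and degenerate inputs

- Rate readout: spike count / 0.5 s → a 2 Hz quantum. Smooth-trajectory
  checks (the morph projection onto the C→E axis) are therefore asserted
  up to the worst-case quantization noise (2 Hz × ‖u‖₁ for projection
  axis u) plus a rank-correlation bound, not to strict monotonicity,
  which is below the readout resolution at 0.5 s.
- FDR is signalled as degenerate when the within-class scatter is zero;
  per-odor PCC is undefined for constant responses — such odors are
  excluded and reported.
- Exact-zero lateral weights contribute exact 0.0 in the synaptic
  matrix-vector product, so a 16-glomerulus network at `sa_weight = 0`
  reproduces sixteen independent single-glomerulus simulations bit for
  bit (tested).
- Multi-panel runs are batched into a single vectorized simulation;
  exposures never interact, so batching is exact, and identical seeds
  give bit-identical results.
- At `sa_weight = 0` the MC FDR is close to, but not equal to, the input
  FDR (≈ 0.15 vs ≈ 0.105): the MC f–I nonlinearity reshapes the scalar
  distribution. Equality is not expected and not asserted.

## Problem sizes

Default analyses use the conditions above: 36 (or 57 with the morph
series) exposures of 0.5 s, 64 neurons, dt 0.1 ms. The shipped sweep
uses the integer grid 0–30 with 10 panel seeds; the acceptance script
uses the grid 10–30 with 16 panel seeds, the package's standard
replication for seed-averaged quantities.

## Known limitations

- One cell per type per glomerulus; population-level effects (e.g. PG
  heterogeneity) are out of scope.
- Current-based synapses without delays or short-term plasticity; no
  granule-cell layer, and no biphasic inhibitory/dopaminergic SA→ET
  transmission — the model keeps SA efferents purely excitatory.
- The lateral weight axis is calibrated, not derived: its absolute scale
  depends on the free fixed weights, so comparisons of `sa_weight`
  values are meaningful only within the shipped calibration.
- Headline metric values depend on the random panel; single-seed values
  scatter widely (MC FDR at the peak ranges roughly 0.1–0.9 across
  panels) and only multi-seed means are stable.
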