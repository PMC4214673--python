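"""The multi-glomerular network: wiring, synapses and stimulus runs.

Each glomerulus contains one mitral (MC), one external tufted (ET), one
periglomerular (PG) and one short-axon (SA) cell. Within a glomerulus the
receptor input drives MC, ET and PG as a constant current; MC excites PG,
PG inhibits MC (the negative feedback loop that normalizes MC output), ET
excites PG and its home SA. Across glomeruli, every SA cell projects
excitatory synapses onto the PG and ET cells of all *other* glomeruli —
the lateral pathway whose single swept weight (``sa_weight``) controls how
strongly global activity is shared. The ET/SA subnetwork receives nothing
from MC or PG, so ET activity reflects only the receptor input plus the
activity shared laterally.

Synapses are current-based with a single-exponential kernel: a presynaptic
spike at t0 adds ``sign * weight * exp(-(t - t0)/tau)`` pA to the
postsynaptic input current for t >= t0. All synapses share one decay
constant, so the per-neuron total synaptic current can be integrated as a
single leaky accumulator, which the simulator exploits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .neurons import (CELL_TYPES, NeuronState, ParamArrays, SpikeRecord,
                      _rk4_step, stack_params)

__all__ = [
    "SynapseSpec",
    "NetworkConfig",
    "Network",
    "build_glomerular_layer",
    "synaptic_current",
    "run_stimulus",
    "run_stimulus_batch",
    "mean_rate_readout",
]

POPULATIONS = ("MC", "ET", "PG", "SA")


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse: pre/post neuron indices, peak weight (pA per spike),
    sign (+1 excitatory, -1 inhibitory) and decay constant tau (ms)."""

    pre: int
    post: int
    weight: float
    sign: int
    tau: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("synaptic weight must be non-negative (sign is separate)")
        if self.tau <= 0:
            raise ValueError("synaptic tau must be positive")
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")


@dataclass
class NetworkConfig:
    """Structural and fixed-weight parameters of the glomerular layer.

    ``sa_weight`` is the swept lateral weight (pA per spike) applied
    identically to every SA efferent (SA->PG and SA->ET of all other
    glomeruli). The remaining synaptic weights are fixed; the shipped
    defaults are the package's calibration under which mitral-cell odor
    separability peaks at an interior lateral weight while tufted-cell
    output tracks concentration (see docs/methods.md).
    ``w_orn_*`` are dimensionless gains on the receptor current delivered
    to each cell type.
    """

    n_glomeruli: int = 16
    sa_weight: float = 19.0
    w_orn_mc: float = 2.5
    w_orn_et: float = 0.65
    w_orn_pg: float = 1.0
    w_mc_pg: float = 30.0
    w_pg_mc: float = 250.0
    w_et_pg: float = 30.0
    w_et_sa: float = 120.0
    tau_syn: float = 10.0
    dt: float = 0.1
    duration: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glomeruli < 1:
            raise ValueError("n_glomeruli must be at least 1")
        for name in ("sa_weight", "w_orn_mc", "w_orn_et", "w_orn_pg",
                     "w_mc_pg", "w_pg_mc", "w_et_pg", "w_et_sa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau_syn <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("tau_syn, dt and duration must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


class Network:
    """A built glomerular layer: populations, synapse list, weight matrix.

    Neuron indexing is population-major: MCs of glomeruli 0..G-1, then ETs,
    PGs and SAs. ``W[post, pre]`` holds the signed synaptic weight.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        G = config.n_glomeruli
        self.n_neurons = 4 * G
        self.params: ParamArrays = stack_params(
            [CELL_TYPES["MC"]] * G + [CELL_TYPES["ET"]] * G
            + [CELL_TYPES["PG"]] * G + [CELL_TYPES["SA"]] * G)
        self.neuron_labels = [f"{pop}{g}" for pop in POPULATIONS for g in range(G)]
        self._pop_slice = {pop: slice(i * G, (i + 1) * G)
                           for i, pop in enumerate(POPULATIONS)}

        mc = lambda g: g
        et = lambda g: G + g
        pg = lambda g: 2 * G + g
        sa = lambda g: 3 * G + g

        syn: list[SynapseSpec] = []
        tau = config.tau_syn
        for g in range(G):
            syn.append(SynapseSpec(mc(g), pg(g), config.w_mc_pg, +1, tau))
            syn.append(SynapseSpec(pg(g), mc(g), config.w_pg_mc, -1, tau))
            syn.append(SynapseSpec(et(g), pg(g), config.w_et_pg, +1, tau))
            syn.append(SynapseSpec(et(g), sa(g), config.w_et_sa, +1, tau))
        for g in range(G):
            for h in range(G):
                if h == g:
                    continue
                syn.append(SynapseSpec(sa(g), pg(h), config.sa_weight, +1, tau))
                syn.append(SynapseSpec(sa(g), et(h), config.sa_weight, +1, tau))
        self.synapses = syn

        W = np.zeros((self.n_neurons, self.n_neurons))
        for s in syn:
            W[s.post, s.pre] += s.sign * s.weight
        self.W = W

        # Receptor input map: stimulus component g -> constant current into
        # MC_g, ET_g, PG_g scaled by the per-type gain; SA gets none.
        M = np.zeros((self.n_neurons, G))
        M[self._pop_slice["MC"], :] = np.eye(G) * config.w_orn_mc
        M[self._pop_slice["ET"], :] = np.eye(G) * config.w_orn_et
        M[self._pop_slice["PG"], :] = np.eye(G) * config.w_orn_pg
        self.input_map = M

    def population_index(self, pop: str) -> slice:
        return self._pop_slice[pop]


def build_glomerular_layer(config: NetworkConfig) -> Network:
    """Construct the glomerular layer for the given configuration."""
    return Network(config)


def synaptic_current(spike_times, t, weight: float, sign: int = +1,
                     tau: float = 10.0) -> float:
    """Closed-form current of one exponential synapse at time t (ms).

    Each presynaptic spike at t0 contributes ``sign*weight*exp(-(t-t0)/tau)``
    for t >= t0; contributions sum linearly.
    """
    ts = np.asarray(spike_times, dtype=float)
    if ts.size == 0:
        return 0.0
    active = ts[ts <= t]
    return float(sign * weight * np.exp(-(t - active) / tau).sum())


def _simulate(network: Network, I_ext: np.ndarray, n_steps: int, dt: float,
              collect_times: bool = False, collect_vm: bool = False):
    """Core fixed-step engine over a batch of independent exposures.

    I_ext has shape (batch, n_neurons) and is held constant throughout.
    Every exposure starts from rest (v = v_r, u = 0) with zero synaptic
    current. Returns (spike counts (batch, n), spike times or None,
    membrane traces or None). Recorded traces clamp overshoot at v_peak;
    the integrated state is never clamped.
    """
    p = network.params
    B, n = I_ext.shape
    v = np.broadcast_to(p.v_r, (B, n)).copy()
    u = np.zeros((B, n))
    i_syn = np.zeros((B, n))
    decay = np.exp(-dt / network.config.tau_syn)
    Wt = network.W.T.copy()  # (pre, post) so that spikes @ Wt accumulates per post
    counts = np.zeros((B, n), dtype=int)
    events: list[tuple[int, np.ndarray, np.ndarray]] = []
    vm = np.empty((n_steps + 1, B, n)) if collect_vm else None
    if collect_vm:
        vm[0] = v
    for step in range(n_steps):
        I_tot = I_ext + i_syn
        v, u = _rk4_step(v, u, p, I_tot, dt)
        if not np.isfinite(v).all():
            raise FloatingPointError(f"non-finite membrane potential at step {step}")
        spk = v >= p.v_peak
        if collect_vm:
            vm[step + 1] = np.minimum(v, p.v_peak)
        if spk.any():
            v = np.where(spk, p.c, v)
            u = np.where(spk, u + p.d, u)
            counts += spk
            i_syn = i_syn * decay + spk.astype(float) @ Wt
            if collect_times:
                b_idx, n_idx = np.nonzero(spk)
                events.append((step + 1, b_idx, n_idx))
        else:
            i_syn = i_syn * decay
    times = None
    if collect_times:
        times = [[[] for _ in range(n)] for _ in range(B)]
        for step1, b_idx, n_idx in events:
            t_ms = step1 * dt
            for b, j in zip(b_idx, n_idx):
                times[b][j].append(t_ms)
        times = [[np.array(ts) for ts in per_b] for per_b in times]
    return counts, times, vm


def run_stimulus(network: Network, stimulus: np.ndarray,
                 duration: float | None = None,
                 collect_vm: bool = False):
    """Expose a freshly reset network to one constant stimulus vector.

    ``stimulus`` is the per-glomerulus receptor current (pA). Returns a
    SpikeRecord over all neurons (and the membrane traces if requested).
    """
    cfg = network.config
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.shape != (cfg.n_glomeruli,):
        raise ValueError(
            f"stimulus must have length n_glomeruli={cfg.n_glomeruli}, "
            f"got shape {stimulus.shape}")
    if not np.isfinite(stimulus).all():
        raise ValueError("non-finite stimulus")
    duration = cfg.duration if duration is None else duration
    n_steps = int(round(duration / cfg.dt))
    I_ext = (network.input_map @ stimulus)[None, :]
    _, times, vm = _simulate(network, I_ext, n_steps, cfg.dt,
                             collect_times=True, collect_vm=collect_vm)
    record = SpikeRecord(times=times[0], duration=duration,
                         neuron_labels=list(network.neuron_labels))
    if collect_vm:
        return record, vm[:, 0, :]
    return record


def run_stimulus_batch(network: Network, stimuli: np.ndarray,
                       duration: float | None = None) -> np.ndarray:
    """Run many independent exposures and return spike counts.

    ``stimuli`` has shape (n_stimuli, n_glomeruli); each row is simulated
    from rest exactly as in :func:`run_stimulus` (exposures never interact).
    Returns counts of shape (n_stimuli, n_neurons).
    """
    cfg = network.config
    stimuli = np.asarray(stimuli, dtype=float)
    if stimuli.ndim != 2 or stimuli.shape[1] != cfg.n_glomeruli:
        raise ValueError("stimuli must be (n_stimuli, n_glomeruli)")
    if not np.isfinite(stimuli).all():
        raise ValueError("non-finite stimuli")
    duration = cfg.duration if duration is None else duration
    n_steps = int(round(duration / cfg.dt))
    I_ext = stimuli @ network.input_map.T
    counts, _, _ = _simulate(network, I_ext, n_steps, cfg.dt)
    return counts


def mean_rate_readout(record: SpikeRecord, population: str = "MC",
                      duration: float | None = None) -> np.ndarray:
    """Per-glomerulus mean firing rate (Hz) of one population.

    The readout is the spike count over the exposure divided by its
    duration in seconds — the model's output code.
    """
    duration = record.duration if duration is None else duration
    if duration <= 0:
        raise ValueError("duration must be positive")
    idx = [i for i, lab in enumerate(record.neuron_labels)
           if lab.startswith(population)]
    if not idx:
        raise ValueError(f"no neurons of population {population!r} in record")
    counts = np.array([record.times[i].size for i in idx])
    return counts / (duration / 1000.0)


def rates_from_counts(counts: np.ndarray, network: Network, population: str,
                      duration: float) -> np.ndarray:
    """Convert batched spike counts to (n_stimuli, n_glomeruli) rates in Hz."""
    sl = network.population_index(population)
    return counts[:, sl] / (duration / 1000.0)
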