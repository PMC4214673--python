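"""Izhikevich point-neuron dynamics for the glomerular-layer cell types.

The membrane model is the two-variable quadratic integrate-and-fire system

    C dv/dt = k (v - v_r)(v - v_t) - u + I(t)
      du/dt = a [ b (v - v_r) - u ]

with the after-spike reset ``v >= v_peak  ->  v <- c, u <- u + d``. Four
parameter sets are shipped, one per glomerular cell type: mitral (MC),
external tufted (ET), periglomerular (PG) and short-axon (SA) cells. MC and
ET share identical membrane parameters; the interneurons have negative
recovery sensitivity ``b`` (amplifying sub-threshold dynamics).

Integration is a classical fixed-step fourth-order Runge-Kutta scheme with
the input current held constant over each step; the reset condition is
checked once at the end of every full step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "SpikeRecord",
    "MITRAL",
    "TUFTED",
    "PERIGLOMERULAR",
    "SHORT_AXON",
    "CELL_TYPES",
    "stack_params",
    "derivatives",
    "apply_reset",
    "integrate_step",
]


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich parameters of one cell type.

    Units: C pF, k 1/(GOhm mV), voltages mV, a 1/ms, b 1/GOhm, d mV
    (numerically it increments the recovery variable u).
    """

    C: float
    k: float
    v_r: float
    v_t: float
    a: float
    b: float
    v_peak: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.C, self.k, self.v_r, self.v_t, self.a,
                            self.b, self.v_peak, self.c, self.d]).all():
            raise ValueError("neuron parameters must be finite")
        if self.C <= 0:
            raise ValueError(f"membrane capacitance must be positive, got {self.C}")
        if not (self.v_r < self.v_t < self.v_peak):
            raise ValueError(
                f"require v_r < v_t < v_peak, got {self.v_r}, {self.v_t}, {self.v_peak}"
            )
        if self.c > self.v_peak:
            raise ValueError(f"after-spike reset c={self.c} above v_peak={self.v_peak}")


# Cell-type parameter sets (capacitance pF, gains, voltages mV).
MITRAL = NeuronParams(C=40.0, k=1.0, v_r=-55.0, v_t=-50.0, a=0.4, b=2.6,
                      v_peak=35.0, c=-50.0, d=200.0)
TUFTED = NeuronParams(C=40.0, k=1.0, v_r=-55.0, v_t=-50.0, a=0.4, b=2.6,
                      v_peak=35.0, c=-50.0, d=200.0)
PERIGLOMERULAR = NeuronParams(C=5.9, k=0.049, v_r=-53.1, v_t=-20.0, a=0.0167,
                              b=-0.94, v_peak=35.0, c=-20.0, d=50.0)
SHORT_AXON = NeuronParams(C=58.0, k=0.061, v_r=-67.0, v_t=-30.0, a=0.049,
                          b=-0.68, v_peak=35.0, c=-30.0, d=150.0)

CELL_TYPES: dict[str, NeuronParams] = {
    "MC": MITRAL,
    "ET": TUFTED,
    "PG": PERIGLOMERULAR,
    "SA": SHORT_AXON,
}


@dataclass
class ParamArrays:
    """Per-neuron parameter vectors for a heterogeneous population."""

    C: np.ndarray
    k: np.ndarray
    v_r: np.ndarray
    v_t: np.ndarray
    a: np.ndarray
    b: np.ndarray
    v_peak: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def __len__(self) -> int:
        return self.C.shape[0]


def stack_params(params: Sequence[NeuronParams] | NeuronParams,
                 n: int | None = None) -> ParamArrays:
    """Build per-neuron parameter arrays from one or many parameter sets."""
    if isinstance(params, NeuronParams):
        if n is None:
            n = 1
        params = [params] * n
    cols = {f.name: np.array([getattr(p, f.name) for p in params], dtype=float)
            for f in fields(NeuronParams)}
    return ParamArrays(**cols)


@dataclass
class NeuronState:
    """Phase variables of a population: membrane potential v (mV), recovery u."""

    v: np.ndarray
    u: np.ndarray

    @classmethod
    def at_rest(cls, params: ParamArrays | NeuronParams,
                n: int | None = None) -> "NeuronState":
        """All neurons at (v_r, 0) — the quiescent fixed point."""
        if isinstance(params, NeuronParams):
            params = stack_params(params, n or 1)
        return cls(v=params.v_r.copy(), u=np.zeros_like(params.v_r))

    def copy(self) -> "NeuronState":
        return NeuronState(self.v.copy(), self.u.copy())


def _as_param_arrays(params: ParamArrays | NeuronParams) -> ParamArrays:
    if isinstance(params, NeuronParams):
        return stack_params(params, 1)
    return params


def derivatives(state: NeuronState, params: ParamArrays | NeuronParams,
                I: np.ndarray | float):
    """Right-hand side (dv/dt in mV/ms, du/dt per ms) of the membrane model."""
    p = _as_param_arrays(params)
    v = np.asarray(state.v, dtype=float)
    u = np.asarray(state.u, dtype=float)
    I = np.asarray(I, dtype=float)
    if not (np.isfinite(v).all() and np.isfinite(u).all() and np.isfinite(I).all()):
        raise ValueError("non-finite membrane state or input current")
    dv = (p.k * (v - p.v_r) * (v - p.v_t) - u + I) / p.C
    du = p.a * (p.b * (v - p.v_r) - u)
    return dv, du


def apply_reset(state: NeuronState, params: ParamArrays | NeuronParams):
    """After-spike reset: where v >= v_peak, set v <- c and u <- u + d.

    Returns the (new state, spiked flags); the boundary v == v_peak fires.
    """
    p = _as_param_arrays(params)
    spiked = state.v >= p.v_peak
    v = np.where(spiked, p.c, state.v)
    u = np.where(spiked, state.u + p.d, state.u)
    return NeuronState(v=v, u=u), spiked


def _rk4_step(v, u, p: ParamArrays, I, dt: float):
    """One classical RK4 step of the membrane equations, current held fixed."""
    def f(v, u):
        dv = (p.k * (v - p.v_r) * (v - p.v_t) - u + I) / p.C
        du = p.a * (p.b * (v - p.v_r) - u)
        return dv, du

    k1v, k1u = f(v, u)
    k2v, k2u = f(v + 0.5 * dt * k1v, u + 0.5 * dt * k1u)
    k3v, k3u = f(v + 0.5 * dt * k2v, u + 0.5 * dt * k2u)
    k4v, k4u = f(v + dt * k3v, u + dt * k3u)
    v_new = v + (dt / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
    u_new = u + (dt / 6.0) * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
    return v_new, u_new


def integrate_step(state: NeuronState, params: ParamArrays | NeuronParams,
                   I: np.ndarray | float, dt: float = 0.1):
    """Advance a population one RK4 step and apply the after-spike reset.

    The input current per neuron is held constant over the step. Returns the
    new state and the boolean spike flags. Raises if the step produced
    non-finite values (numerical blow-up).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = _as_param_arrays(params)
    v = np.asarray(state.v, dtype=float)
    u = np.asarray(state.u, dtype=float)
    I = np.broadcast_to(np.asarray(I, dtype=float), v.shape)
    if v.shape != u.shape or v.shape[-1] != len(p):
        raise ValueError("state, params and currents must agree in length")
    if not np.isfinite(I).all():
        raise ValueError("non-finite input current")
    v_new, u_new = _rk4_step(v, u, p, I, dt)
    if not (np.isfinite(v_new).all() and np.isfinite(u_new).all()):
        raise FloatingPointError("integration produced non-finite values")
    new_state, spiked = apply_reset(NeuronState(v_new, u_new), p)
    return new_state, spiked


@dataclass
class SpikeRecord:
    """Spike times per neuron over one simulated exposure.

    ``times[i]`` is a strictly increasing array of spike times (ms) of neuron
    i; spike times are assigned to the end of the integration step on which
    the reset fired.
    """

    times: list[np.ndarray]
    duration: float
    neuron_labels: list[str] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return len(self.times)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.times])

    def rates(self) -> np.ndarray:
        """Mean firing rates in Hz over the record duration."""
        return self.counts() / (self.duration / 1000.0)

    def to_text(self, path) -> None:
        """Two-column export: time_ms <TAB> neuron_id."""
        rows = [(t, i) for i, ts in enumerate(self.times) for t in ts]
        rows.sort()
        with open(path, "w") as fh:
            fh.write("time_ms\tneuron_id\n")
            for t, i in rows:
                fh.write(f"{t:.4f}\t{i}\n")


def simulate_constant_current(params: NeuronParams, I: float,
                              duration: float = 500.0,
                              dt: float = 0.1) -> SpikeRecord:
    """Simulate a single isolated neuron under tonic current injection."""
    p = stack_params(params, 1)
    state = NeuronState.at_rest(p)
    n_steps = int(round(duration / dt))
    spikes = []
    for step in range(n_steps):
        state, fired = integrate_step(state, p, np.array([I]), dt)
        if fired[0]:
            spikes.append((step + 1) * dt)
    return SpikeRecord(times=[np.array(spikes)], duration=duration)
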