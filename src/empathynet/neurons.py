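"""Izhikevich point-neuron dynamics with current-based synaptic input.

Every population in the caregiving-circuit models is integrated on a fixed
1-ms grid with the two-variable Izhikevich model

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

with a spike emitted when ``v`` reaches 30 mV, followed by the reset
``v <- c``, ``u <- u + d``.  The membrane equation is advanced with two
0.5-ms half-steps per 1-ms iteration (the convention of the original
published integrator), while the recovery variable is updated once per
millisecond.  Synapses are current-based and act with a one-step delay: a
spike at iteration ``t`` contributes a rectangular 1-ms current pulse of
size ``sign * weight`` to its targets at iteration ``t + 1``.

A hard floor on the membrane potential (``V_FLOOR``) bounds hyperpolarisation;
without it, strong coincident inhibitory pulses can push ``v`` into the far
negative branch of the quadratic where the discrete integrator produces
non-physical rebound spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "V_PEAK",
    "V_FLOOR",
    "IzhikevichParams",
    "PRESETS",
    "PopulationState",
    "SpikeEvent",
    "SynapseBundle",
    "resting_state",
    "izhikevich_step",
    "step_population",
    "accumulate_synaptic_input",
]

#: Spike-detection threshold (mV).
V_PEAK = 30.0

#: Lower bound on the membrane potential (mV); numerical guard, see module docstring.
V_FLOOR = -90.0


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameter set of a single Izhikevich neuron class.

    Parameters
    ----------
    a : float
        Recovery time scale (1/ms); must be positive.
    b : float
        Sensitivity of the recovery variable to ``v`` (dimensionless).
    c : float
        After-spike reset potential (mV); must lie below the spike peak.
    d : float
        After-spike increment of the recovery variable.
    label : str
        ``"RS"``, ``"FS"``, ``"IB"`` or ``"custom"``.
    """

    a: float
    b: float
    c: float
    d: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"IzhikevichParams: a must be > 0, got {self.a}")
        if not self.c < V_PEAK:
            raise ValueError(
                f"IzhikevichParams: reset potential c={self.c} must be below the "
                f"spike threshold {V_PEAK}"
            )


#: Canonical published presets: regular-spiking, fast-spiking, intrinsically bursting.
PRESETS: Mapping[str, IzhikevichParams] = MappingProxyType(
    {
        "RS": IzhikevichParams(0.02, 0.2, -65.0, 8.0, "RS"),
        "FS": IzhikevichParams(0.1, 0.2, -65.0, 2.0, "FS"),
        "IB": IzhikevichParams(0.02, 0.2, -55.0, 4.0, "IB"),
    }
)


@dataclass
class PopulationState:
    """Per-neuron state of one population: membrane ``v``, recovery ``u``, input ``I``."""

    v: np.ndarray
    u: np.ndarray
    I: np.ndarray
    size: int

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.float64)
        self.u = np.asarray(self.u, dtype=np.float64)
        self.I = np.asarray(self.I, dtype=np.float64)
        if not (len(self.v) == len(self.u) == len(self.I) == self.size):
            raise ValueError("PopulationState arrays must all have length == size")

    def copy(self) -> "PopulationState":
        return PopulationState(self.v.copy(), self.u.copy(), self.I.copy(), self.size)


@dataclass(frozen=True)
class SpikeEvent:
    """A single recorded spike (1-based iteration time)."""

    neuron_index: int
    time_ms: int
    population_id: str


def resting_state(size: int, params: IzhikevichParams, v0: float = -70.0) -> PopulationState:
    """State with every neuron at ``v = v0`` and ``u = b * v0`` (near the resting fixed point)."""
    v = np.full(size, v0, dtype=np.float64)
    return PopulationState(v, params.b * v, np.zeros(size), size)


def izhikevich_step(
    v: np.ndarray,
    u: np.ndarray,
    I: np.ndarray,
    a: np.ndarray | float,
    b: np.ndarray | float,
    c: np.ndarray | float,
    d: np.ndarray | float,
) -> np.ndarray:
    """Advance ``(v, u)`` in place by one 1-ms iteration; return the spiked mask.

    Two 0.5-ms half-steps for ``v``, one full step for ``u``.  Spiking neurons
    are reset to ``c`` with ``u`` incremented by ``d``, so on return every
    entry of ``v`` is at most the spike threshold.
    """
    for _ in range(2):
        v += 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
        # Clamp after every half-step: a synchronized inhibitory volley can push
        # v far below the lower parabola branch, where the discrete map produces
        # a non-physical rebound spike (and can overflow).  The upper clip only
        # bounds the already-suprathreshold excursion before the reset.
        np.clip(v, V_FLOOR, 1e4, out=v)
    u += a * (b * v - u)
    fired = v >= V_PEAK
    if fired.any():
        v[fired] = np.broadcast_to(np.asarray(c, dtype=np.float64), v.shape)[fired]
        u[fired] += np.broadcast_to(np.asarray(d, dtype=np.float64), u.shape)[fired]
    np.maximum(v, V_FLOOR, out=v)
    return fired


def step_population(
    state: PopulationState,
    params: IzhikevichParams,
    dt: float = 1.0,
    population_id: str = "?",
    step: int | None = None,
) -> tuple[PopulationState, np.ndarray]:
    """Advance a homogeneous population one iteration.

    Returns the updated state (a copy; the input is left untouched) and the
    sorted indices of neurons that crossed threshold during this step.  The
    integration grid is fixed at 1 ms; ``dt`` is accepted only to make the
    contract explicit.

    Raises
    ------
    ValueError
        If ``dt != 1`` or the incoming state contains non-finite values (the
        diagnostic names the population and, when given, the step).
    """
    if dt != 1.0:
        raise ValueError("step_population integrates on a fixed 1-ms grid (dt must be 1)")
    if not (np.isfinite(state.v).all() and np.isfinite(state.u).all() and np.isfinite(state.I).all()):
        where = f" at step {step}" if step is not None else ""
        raise ValueError(f"non-finite state in population {population_id!r}{where}")
    out = state.copy()
    fired = izhikevich_step(out.v, out.u, out.I, params.a, params.b, params.c, params.d)
    return out, np.flatnonzero(fired)


@dataclass
class SynapseBundle:
    """Realised synapses of one projection, as parallel index/weight arrays.

    ``sign`` is +1 for excitatory and -1 for inhibitory projections; the
    current delivered per presynaptic spike is ``sign * weight``.
    """

    source_pop: str
    target_pop: str
    sources: np.ndarray
    targets: np.ndarray
    weights: np.ndarray
    sign: int = 1

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=np.int64)
        self.targets = np.asarray(self.targets, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if not (len(self.sources) == len(self.targets) == len(self.weights)):
            raise ValueError("synapse arrays must have equal length")


def accumulate_synaptic_input(
    spikes_prev: Mapping[str, np.ndarray | Sequence[int]],
    projections: Iterable[SynapseBundle],
    external: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Total input current per neuron for the current iteration.

    ``I[target] = external[target] + sum over incoming synapses of
    sign * weight * 1[source spiked at the previous step]``.

    ``external`` supplies one array per target population (already in model
    current units) and fixes each population's size.
    """
    currents = {pop: np.array(ext, dtype=np.float64, copy=True) for pop, ext in external.items()}
    for proj in projections:
        if proj.target_pop not in currents:
            raise KeyError(
                f"projection {proj.source_pop!r}->{proj.target_pop!r} targets an unknown population"
            )
        spiked = np.zeros(0, dtype=np.int64)
        if proj.source_pop in spikes_prev:
            spiked = np.asarray(spikes_prev[proj.source_pop], dtype=np.int64)
        if spiked.size == 0:
            continue
        mask = np.isin(proj.sources, spiked)
        if mask.any():
            np.add.at(
                currents[proj.target_pop],
                proj.targets[mask],
                proj.sign * proj.weights[mask],
            )
    return currents
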