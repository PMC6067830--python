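"""Seeded end-to-end simulation of a circuit under an injection schedule.

A run advances the whole network on a 1-ms grid for (by default) 30,000
iterations.  Each iteration: the injectable pools are perturbed, the
injected subsets c_t are drawn per the active phase's rules, the external
pulses and the synaptic currents from the previous step's spikes are
accumulated, and every population takes one Izhikevich step.  All
randomness flows from a single seed through four named sub-streams
(connectivity, designation, perturbation, selection), so resampling the
circuit never shifts the protocol draws.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit import CircuitModel, RealizedCircuit, realize_circuit, sample_mpfc_gradient_targets
from .neurons import izhikevich_step
from .protocol import InjectionSchedule, designate_targets, perturb_targets, ramp_count

__all__ = ["SimulationConfig", "SimulationResult", "run", "run_model"]


@dataclass
class SimulationConfig:
    circuit: CircuitModel
    schedule: InjectionSchedule
    seed: int
    total_iterations: int = 30000
    dt: float = 1.0
    record: str | Sequence[str] = "all"
    report_times_ms: tuple[int, ...] = (10000, 20000, 30000)

    def __post_init__(self) -> None:
        if self.total_iterations % len(self.schedule.phases) != 0:
            raise ValueError(
                "total_iterations must be divisible by the number of phases "
                f"({self.total_iterations} / {len(self.schedule.phases)})"
            )
        if self.dt != 1.0:
            raise ValueError("the simulation grid is fixed at 1 ms")


@dataclass
class SimulationResult:
    """Spike raster of one run plus the provenance needed to reproduce it."""

    times: np.ndarray  # spike times (ms, 1-based), int32
    gids: np.ndarray  # global neuron ids, int32
    region_slices: dict[str, slice]
    subpop_slices: dict[tuple[str, str], slice]
    subpop_labels: dict[tuple[str, str], str]  # (region, exc|inh) -> exc|inh|da
    injected_counts: dict[str, np.ndarray]
    seed: int
    config_hash: str
    total_iterations: int
    synapse_count: int
    wall_time_s: float = 0.0

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def population_size(self, region: str, which: str) -> int:
        sl = self.subpop_slices[(region, which)]
        return sl.stop - sl.start

    def spikes_of(self, region: str, which: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(times, gids) restricted to one region or sub-population."""
        sl = self.region_slices[region] if which is None else self.subpop_slices[(region, which)]
        mask = (self.gids >= sl.start) & (self.gids < sl.stop)
        return self.times[mask], self.gids[mask]

    def spike_frame(self) -> pd.DataFrame:
        """Flat spike table with columns neuron_id, region, subpop, time_ms."""
        region = np.empty(self.n_spikes, dtype=object)
        subpop = np.empty(self.n_spikes, dtype=object)
        for (name, which), sl in self.subpop_slices.items():
            mask = (self.gids >= sl.start) & (self.gids < sl.stop)
            region[mask] = name
            subpop[mask] = self.subpop_labels[(name, which)]
        return pd.DataFrame(
            {
                "neuron_id": self.gids,
                "region": region,
                "subpop": subpop,
                "time_ms": self.times,
            }
        )

    def manifest(self) -> dict[str, Any]:
        return {
            "seed": int(self.seed),
            "config_hash": self.config_hash,
            "total_iterations": int(self.total_iterations),
            "n_spikes": int(self.n_spikes),
            "synapse_count": int(self.synapse_count),
            "wall_time_s": round(float(self.wall_time_s), 3),
        }


class _UniformPool:
    """Injectable pool g_t(G) of one region, perturbed by uniform swaps."""

    def __init__(self, region: str, region_size: int, levels, rng: np.random.Generator):
        self.region = region
        self.region_size = region_size
        self.g = designate_targets(region_size, levels, rng)

    def perturb(self, fraction: float, rng: np.random.Generator) -> None:
        self.g = perturb_targets(self.g, self.region_size, fraction, rng)


class _BandPool:
    """Uniform injectable pool confined to one end of the ventral--dorsal axis.

    ``close`` maps to the ventral end and ``distant`` to the dorsal end
    (respecting the gradient's axis orientation); ``fraction`` sets how much
    of the axis the band covers.  Perturbation swaps stay within the band.
    """

    def __init__(self, spec, which: str, n_exc: int, pool_size: int,
                 rng: np.random.Generator, fraction: float = 0.5):
        width_band = max(1, int(round(n_exc * fraction)))
        ventral_high = spec.axis_orientation == "ventral_at_high_index"
        upper = (which == "close") == ventral_high
        self.lo, self.hi = (n_exc - width_band, n_exc) if upper else (0, width_band)
        width = self.hi - self.lo
        k = min(pool_size, width)
        self.g = self.lo + np.sort(rng.choice(width, size=k, replace=False)).astype(np.int64)

    def perturb(self, fraction: float, rng: np.random.Generator) -> None:
        local = perturb_targets(self.g - self.lo, self.hi - self.lo, fraction, rng)
        self.g = local + self.lo


class _GradientPool:
    """mPFC injectable pool drawn from (and replenished by) a gradient distribution."""

    def __init__(self, spec, which: str, n_exc: int, pool_size: int, rng: np.random.Generator):
        self.spec = spec
        self.which = which
        self.n_exc = n_exc
        self.g = sample_mpfc_gradient_targets(spec, which, n_exc, pool_size, rng, unique=True)
        self.member = np.zeros(n_exc, dtype=bool)
        self.member[self.g] = True

    def perturb(self, fraction: float, rng: np.random.Generator) -> None:
        n_swap = int(round(fraction * len(self.g)))
        if n_swap == 0:
            return
        leave = rng.choice(len(self.g), size=n_swap, replace=False)
        joiners: list[int] = []
        # rejection-sample fresh gradient draws that are in range and not members
        for _ in range(10000):
            if len(joiners) >= n_swap:
                break
            r, p = self.spec.params(self.which)
            draws = rng.negative_binomial(r, p, size=512)
            draws = draws[draws < self.n_exc]
            if self.spec.axis_orientation == "ventral_at_low_index":
                draws = self.n_exc - 1 - draws
            for x in draws:
                if not self.member[x]:
                    self.member[x] = True
                    joiners.append(int(x))
                    if len(joiners) >= n_swap:
                        break
        else:
            raise RuntimeError("gradient pool perturbation failed to find replacements")
        self.member[self.g[leave]] = False
        self.g = self.g.copy()
        self.g[leave] = np.asarray(joiners, dtype=np.int64)


def _build_pools(rc: RealizedCircuit, schedule: InjectionSchedule,
                 rng: np.random.Generator) -> dict[str, Any]:
    pools: dict[str, Any] = {}
    for region in schedule.stimulated_regions:
        spec = rc.model.region(region)
        if region == "mPFC":
            # one injectable pool per target mode, over excitatory (gradient-
            # indexed) cells; pool size is set by the whole-region count rule
            pool_size = math.floor(spec.size * schedule.levels.H)
            pools[region] = {}
            for mode, kind in schedule.mpfc_pool_sampling.items():
                if kind == "gradient":
                    pools[region][mode] = _GradientPool(
                        rc.model.mpfc_gradient, mode, spec.n_exc, pool_size, rng
                    )
                elif kind == "band_uniform":
                    pools[region][mode] = _BandPool(
                        rc.model.mpfc_gradient, mode, spec.n_exc, pool_size, rng,
                        schedule.mpfc_band_fraction[mode],
                    )
                else:
                    pool = _UniformPool.__new__(_UniformPool)
                    pool.region = region
                    pool.region_size = spec.n_exc
                    k = min(pool_size, spec.n_exc)
                    pool.g = np.sort(rng.choice(spec.n_exc, size=k, replace=False))
                    pools[region][mode] = pool
        else:
            pools[region] = _UniformPool(region, spec.size, schedule.levels, rng)
    return pools


def run(config: SimulationConfig) -> SimulationResult:
    """Execute one full seeded simulation and return the spike raster."""
    t0 = time.perf_counter()
    model = config.circuit
    schedule = config.schedule
    T = config.total_iterations
    p = T // len(schedule.phases)

    streams = np.random.SeedSequence(config.seed).spawn(4)
    conn_rng, des_rng, pert_rng, sel_rng = (np.random.default_rng(s) for s in streams)

    rc = realize_circuit(model, conn_rng)
    n = rc.n_neurons
    W = rc.weights
    indptr, indices, data = W.indptr, W.indices, W.data

    v = np.full(n, -70.0)
    u = rc.b * v
    amp = schedule.amplitude * model.current_gain

    pools = _build_pools(rc, schedule, des_rng)
    region_offsets = {name: sl.start for name, sl in rc.region_slices.items()}

    spike_times: list[np.ndarray] = []
    spike_gids: list[np.ndarray] = []
    injected_counts = {region: np.zeros(T, dtype=np.int32) for region in pools}

    ext = np.zeros(n)
    prev_spiked = np.zeros(0, dtype=np.int64)
    for t in range(1, T + 1):
        phase = schedule.phase_at(t, T)
        ext[:] = 0.0

        for region, pool in pools.items():
            if isinstance(pool, dict):
                for sub in pool.values():
                    sub.perturb(schedule.perturb_fraction, pert_rng)
            else:
                pool.perturb(schedule.perturb_fraction, pert_rng)

        for region, rule in phase.rules.items():
            if rule.kind == "off":
                continue
            pool = pools[region]
            if isinstance(pool, dict):
                pool = pool[phase.mpfc_target_mode]
            g_t = pool.g
            size = rc.model.region(region).size
            if rule.kind == "band":
                lo = schedule.levels.value(rule.lo)
                hi = schedule.levels.value(rule.hi)
                k = int(sel_rng.integers(math.floor(size * lo), math.floor(size * hi) + 1))
            else:  # ramp
                k = ramp_count(size, schedule.levels.value(rule.lo),
                               schedule.levels.value(rule.hi), t, p,
                               phase_index=phase.phase_index)
            k = min(k, len(g_t))
            if k > 0:
                c_t = sel_rng.choice(g_t, size=k, replace=False)
                ext[region_offsets[region] + c_t] = amp
            injected_counts[region][t - 1] = k

        I = ext.copy()
        if prev_spiked.size:
            tgt = np.concatenate([indices[indptr[j]:indptr[j + 1]] for j in prev_spiked])
            wts = np.concatenate([data[indptr[j]:indptr[j + 1]] for j in prev_spiked])
            np.add.at(I, tgt, wts)

        fired = izhikevich_step(v, u, I, rc.a, rc.b, rc.c, rc.d)
        prev_spiked = np.flatnonzero(fired)
        if prev_spiked.size:
            spike_times.append(np.full(prev_spiked.size, t, dtype=np.int32))
            spike_gids.append(prev_spiked.astype(np.int32))

        if t % 1000 == 0 and not np.isfinite(v).all():
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            region = next(r for r, sl in rc.region_slices.items() if sl.start <= bad < sl.stop)
            raise FloatingPointError(
                f"non-finite membrane state in region {region!r} at step {t}"
            )

    times = np.concatenate(spike_times) if spike_times else np.zeros(0, dtype=np.int32)
    gids = np.concatenate(spike_gids) if spike_gids else np.zeros(0, dtype=np.int32)

    if config.record != "all":
        keep = np.zeros(len(gids), dtype=bool)
        for region in config.record:
            sl = rc.region_slices[region]
            keep |= (gids >= sl.start) & (gids < sl.stop)
        times, gids = times[keep], gids[keep]

    labels = {
        (name, which): rc.model.region(name).subpop_label(which)
        for (name, which) in rc.subpop_slices
    }
    return SimulationResult(
        times=times,
        gids=gids,
        region_slices=rc.region_slices,
        subpop_slices=rc.subpop_slices,
        subpop_labels=labels,
        injected_counts=injected_counts,
        seed=config.seed,
        config_hash=f"{model.provenance}:{schedule.name}",
        total_iterations=T,
        synapse_count=rc.synapse_count,
        wall_time_s=time.perf_counter() - t0,
    )


def run_model(model: str, seed: int, total_iterations: int = 30000,
              overrides: Mapping[str, float] | None = None) -> SimulationResult:
    """Convenience wrapper: run a packaged model ('empathy' or 'self_attachment')."""
    from .circuit import build_empathy_circuit, build_self_attachment_circuit
    from .protocol import build_protocol_empathy, build_protocol_self_attachment

    if model == "empathy":
        circuit = build_empathy_circuit(overrides=overrides)
        schedule = build_protocol_empathy(circuit=circuit)
    elif model in ("self_attachment", "self-attachment"):
        circuit = build_self_attachment_circuit(overrides=overrides)
        schedule = build_protocol_self_attachment(circuit=circuit)
    else:
        raise ValueError(f"unknown model {model!r} (expected 'empathy' or 'self_attachment')")
    return run(SimulationConfig(circuit=circuit, schedule=schedule, seed=seed,
                                total_iterations=total_iterations))
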