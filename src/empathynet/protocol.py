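"""Phase-structured current-injection machinery.

Stimulation follows a three-phase schedule over a 30-s run.  For each
stimulated neural group G a designated injectable subset g(G) of size
``floor(|G| * H)`` is drawn once; at every 1-ms iteration that subset is
perturbed by swapping 10% of its members with non-members, giving g_t(G),
and a subset c_t(G) of g_t(G) actually receives a current pulse.  The size
of c_t(G) is either a uniform integer in a band ``[|G|*lo, |G|*hi]``
("fixed band") or a deterministic linear ramp between two levels across a
phase.  Stimulation levels are proportions of the group: L=0.05, M=0.1,
H=0.15.  The negatively valent BLMA population is stimulated in the
(M, H) band in every phase of both models, representing the sustained
distress stimulus.

mPFC stimulation is special: the injected pool encodes either a "close
other" or a "distant other" on the ventral--dorsal axis.  Pools can be
drawn from the corresponding negative-binomial gradient distribution,
uniformly within the matching end of the axis (the packaged default; see
the methods note for why), or uniformly over the whole region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import numpy as np
import yaml

from .circuit import CircuitModel

__all__ = [
    "StimLevels",
    "RegionRule",
    "PhaseSpec",
    "InjectionSchedule",
    "designate_targets",
    "perturb_targets",
    "select_fixed_band",
    "ramp_count",
    "build_protocol_empathy",
    "build_protocol_self_attachment",
    "load_packaged_protocol",
]


@dataclass(frozen=True)
class StimLevels:
    """Low / medium / high stimulation proportions."""

    L: float = 0.05
    M: float = 0.1
    H: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.L < self.M < self.H < 1.0:
            raise ValueError(f"stimulation levels must satisfy 0 < L < M < H < 1, got {self}")

    def value(self, name: str) -> float:
        if name not in ("L", "M", "H"):
            raise ValueError(f"unknown stimulation level {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class RegionRule:
    """Per-phase injection rule for one region.

    ``kind``: ``"off"``, ``"band"`` (uniform count in [lo, hi]) or ``"ramp"``
    (deterministic count interpolating from ``lo`` to ``hi`` across the phase).
    Levels are symbolic (``"L"|"M"|"H"``) and resolved against a StimLevels.
    """

    kind: str
    lo: str | None = None
    hi: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("off", "band", "ramp"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind != "off" and (self.lo is None or self.hi is None):
            raise ValueError(f"{self.kind} rule needs lo and hi levels")

    @classmethod
    def off(cls) -> "RegionRule":
        return cls("off")

    @classmethod
    def band(cls, lo: str, hi: str) -> "RegionRule":
        return cls("band", lo, hi)

    @classmethod
    def ramp(cls, frm: str, to: str) -> "RegionRule":
        return cls("ramp", frm, to)


@dataclass(frozen=True)
class PhaseSpec:
    phase_index: int
    t_range: tuple[int, int]  # (start_ms, end_ms], 1-based iteration times
    rules: Mapping[str, RegionRule]
    mpfc_target_mode: str = "close"

    def __post_init__(self) -> None:
        if self.phase_index not in (1, 2, 3):
            raise ValueError("phase_index must be 1, 2 or 3")
        if self.mpfc_target_mode not in ("close", "distant"):
            raise ValueError(f"bad mpfc_target_mode {self.mpfc_target_mode!r}")


@dataclass(frozen=True)
class InjectionSchedule:
    """Complete stimulation schedule: levels, amplitude and three phases."""

    name: str
    levels: StimLevels
    amplitude: float
    phases: tuple[PhaseSpec, ...]
    perturb_fraction: float = 0.10
    #: how each mPFC injectable pool is drawn: "gradient" (the matching
    #: negative-binomial distribution), "band_uniform" (uniform within the
    #: matching end of the ventral--dorsal axis) or "uniform" (whole mPFC)
    mpfc_pool_sampling: Mapping[str, str] = None  # type: ignore[assignment]
    #: axis fraction covered by a band_uniform pool (scalar or per mode)
    mpfc_band_fraction: Mapping[str, float] | float = 0.5

    def __post_init__(self) -> None:
        pools = self.mpfc_pool_sampling
        if pools is None:
            pools = "gradient"
        if isinstance(pools, str):
            pools = {"close": pools, "distant": pools}
        for mode, kind in pools.items():
            if mode not in ("close", "distant") or kind not in ("gradient", "uniform", "band_uniform"):
                raise ValueError(f"bad mpfc_pool_sampling entry {mode!r}: {kind!r}")
        object.__setattr__(self, "mpfc_pool_sampling", dict(pools))
        frac = self.mpfc_band_fraction
        if not isinstance(frac, Mapping):
            frac = {"close": float(frac), "distant": float(frac)}
        if not all(0.0 < f <= 1.0 for f in frac.values()):
            raise ValueError(f"mpfc_band_fraction must lie in (0, 1], got {frac}")
        object.__setattr__(self, "mpfc_band_fraction", dict(frac))
        if len(self.phases) != 3:
            raise ValueError("schedule must have exactly three phases")
        if not 0.0 <= self.perturb_fraction < 1.0:
            raise ValueError("perturb_fraction must lie in [0, 1)")
        blma = [ph.rules.get("BLMA_neg", RegionRule.off()).kind for ph in self.phases]
        if any(k == "off" for k in blma):
            raise ValueError("the BLMA_neg stimulus must be active in every phase")

    def phase_at(self, t: int, total_iterations: int) -> PhaseSpec:
        """Phase containing iteration ``t`` (phases partition (0, T] equally)."""
        p = total_iterations // len(self.phases)
        idx = min((t - 1) // p, len(self.phases) - 1)
        return self.phases[idx]

    @property
    def stimulated_regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ph in self.phases:
            for region in ph.rules:
                seen.setdefault(region, None)
        return tuple(seen)


# ---------------------------------------------------------------------------
# Target-set operations


def designate_targets(region_size: int, levels: StimLevels, rng: np.random.Generator) -> np.ndarray:
    """Draw the injectable subset g(G): ``floor(|G| * H)`` indices, uniform without replacement."""
    k = math.floor(region_size * levels.H)
    if k == 0:
        return np.zeros(0, dtype=np.int64)
    return np.sort(rng.choice(region_size, size=k, replace=False)).astype(np.int64)


def perturb_targets(
    g: np.ndarray,
    region_size: int,
    fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Swap ``round(fraction * |g|)`` members of g with uniformly chosen non-members.

    Cardinality is preserved.  Raises if the region has fewer non-members
    than the required number of swaps.
    """
    g = np.asarray(g, dtype=np.int64)
    n_swap = int(round(fraction * len(g)))
    if n_swap == 0:
        return g.copy()
    mask = np.ones(region_size, dtype=bool)
    mask[g] = False
    outside = np.flatnonzero(mask)
    if len(outside) < n_swap:
        raise ValueError(
            f"cannot swap {n_swap} targets: only {len(outside)} neurons outside the pool"
        )
    leave = rng.choice(len(g), size=n_swap, replace=False)
    join = rng.choice(len(outside), size=n_swap, replace=False)
    out = g.copy()
    out[leave] = outside[join]
    return out


def select_fixed_band(
    g_t: np.ndarray,
    region_size: int,
    low_level: float,
    high_level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw c_t(G): a uniform-count subset of g_t with count ~ U{floor(|G|*lo), floor(|G|*hi)}."""
    lo = math.floor(region_size * low_level)
    hi = math.floor(region_size * high_level)
    if hi > len(g_t):
        raise ValueError(
            f"band upper bound {hi} exceeds injectable pool size {len(g_t)}"
        )
    k = int(rng.integers(lo, hi + 1))
    if k == 0:
        return np.zeros(0, dtype=np.int64)
    return rng.choice(g_t, size=k, replace=False)


def ramp_count(
    region_size: int,
    from_level: float,
    to_level: float,
    t: int,
    p: int,
    phase_index: int | None = None,
) -> int:
    """Deterministic injected count of a linear ramp at absolute time ``t``.

    ``t`` is the absolute iteration (ms) and ``p`` the phase length; the ramp
    interpolates from ``region_size * from_level`` at the phase start to
    ``region_size * to_level`` at the phase end: for a phase spanning
    ``t/p`` in (k-1, k] the count is

        floor(region_size * (from + (to - from) * (t/p - (k-1)))).

    For a decreasing phase-2 ramp (from=H, to=L) this is exactly
    ``(|G|(L-H))(t/p) + |G|(2H-L)``; the increasing and third-phase forms
    follow the same identity.  ``phase_index`` anchors the formula when
    ``t/p`` falls exactly on a phase boundary (e.g. the phase-2 form at
    ``t/p = 1`` evaluates to the H endpoint); when omitted the phase is
    inferred as ``ceil(t/p)``.
    """
    x = t / p
    k = math.ceil(x) if phase_index is None else phase_index
    progress = min(max(x - (k - 1), 0.0), 1.0)
    raw = region_size * (from_level + (to_level - from_level) * progress)
    return max(0, math.floor(raw + 1e-9))


# ---------------------------------------------------------------------------
# Packaged schedules


def load_packaged_protocol(name: str) -> dict:
    text = resources.files("empathynet.data").joinpath(f"protocol_{name}.yaml").read_text()
    return yaml.safe_load(text)


def _schedule_from_config(config: Mapping[str, Any], circuit: CircuitModel | None) -> InjectionSchedule:
    levels_cfg = config.get("levels", {})
    levels = StimLevels(
        L=float(levels_cfg.get("L", 0.05)),
        M=float(levels_cfg.get("M", 0.1)),
        H=float(levels_cfg.get("H", 0.15)),
    )
    phases = []
    for ph in config["phases"]:
        rules = {}
        for region, rule in ph["rules"].items():
            if circuit is not None and region not in circuit.regions:
                raise ValueError(
                    f"schedule stimulates region {region!r} absent from circuit {circuit.name!r}"
                )
            kind = rule["kind"]
            if kind == "off":
                rules[region] = RegionRule.off()
            else:
                rules[region] = RegionRule(kind, rule["lo"], rule["hi"])
        phases.append(
            PhaseSpec(
                phase_index=int(ph["index"]),
                t_range=(int(ph["t_start"]), int(ph["t_end"])),
                rules=rules,
                mpfc_target_mode=ph.get("mpfc_target_mode", "close"),
            )
        )
    return InjectionSchedule(
        name=config.get("name", "custom"),
        levels=levels,
        amplitude=float(config.get("amplitude", 90.0)),
        phases=tuple(phases),
        perturb_fraction=float(config.get("perturb_fraction", 0.10)),
        mpfc_pool_sampling=config.get("mpfc_pool_sampling", "gradient"),
        mpfc_band_fraction=config.get("mpfc_band_fraction", 0.5),
    )


def build_protocol_empathy(levels: StimLevels | None = None,
                           circuit: CircuitModel | None = None) -> InjectionSchedule:
    """The empathy-model schedule: personal distress, weak EC, strong EC.

    Phase 1 stimulates the self-pain network (AI and PI in the (M, H) band)
    with the other-pain network low (aMCC at (L, M)); phases 2 and 3 reverse
    this, with the mPFC injected in the (M, H) band targeting distant-other
    (phase 2) then close-other (phase 3) representations.  The mPFC carries
    no direct injection in phase 1 — its phase-1 activity is inherited from
    the insula.  All phases keep the BLMA_neg stimulus in the (M, H) band.
    """
    schedule = _schedule_from_config(load_packaged_protocol("empathy"), circuit)
    if levels is not None:
        schedule = InjectionSchedule(
            schedule.name, levels, schedule.amplitude, schedule.phases,
            schedule.perturb_fraction, schedule.mpfc_pool_sampling,
        )
    return schedule


def build_protocol_self_attachment(levels: StimLevels | None = None,
                                   circuit: CircuitModel | None = None) -> InjectionSchedule:
    """The self-attachment schedule: distress, strengthening conceptualization, compassion.

    Phase 1 equals the empathy-model distress phase plus a low (L, M) mOFC
    stimulus.  Phase 2 ramps AI/PI linearly from H down to L and aMCC/mPFC
    from L up to H (close-other targets), modelling the strengthening
    self--other distinction.  Phase 3 holds AI/PI at (L, M) and aMCC/mPFC at
    (M, H) while the mOFC ramps from L to H, modelling progress in bonding.
    """
    schedule = _schedule_from_config(load_packaged_protocol("self_attachment"), circuit)
    if levels is not None:
        schedule = InjectionSchedule(
            schedule.name, levels, schedule.amplitude, schedule.phases,
            schedule.perturb_fraction, schedule.mpfc_pool_sampling,
        )
    return schedule
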