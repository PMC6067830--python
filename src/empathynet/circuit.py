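"""Construction of the caregiving-circuit graphs.

Two models are packaged:

* the *empathy* model — a basolateral/basomedial-amygdala (BLMA), insula
  (AI/PI), midcingulate (aMCC), medial-prefrontal (mPFC) network coupled to
  the mPOA-VTA-NAc-VP caregiving pathway, distinguishing personal distress
  from weak and strong empathic concern; and
* the *self-attachment* model — the same graph extended with a medial
  orbitofrontal (mOFC) region projecting to AI, the BLMA interneuron pool
  and the positively valent BLMA, which mediates the compassion state.

Self--other representations in the mPFC lie along a ventral--dorsal axis:
projections from the mPFC to the caregiving pathway, and the stimulation
targets that encode a "close other" versus a "distant other", are sampled
from negative-binomial distributions over the neuron index (close other:
r=7, p=0.0025; distant other: r=14, p=0.035), so that close-other
representations occupy the ventral (high-index) end of the axis.

All population sizes, connection probabilities and weights are a calibrated
parameter set shipped in :mod:`empathynet.data`; every value can be
overridden through the config mapping.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping

import numpy as np
import yaml

from .neurons import PRESETS, IzhikevichParams

__all__ = [
    "REGION_NAMES",
    "RegionSpec",
    "Projection",
    "GradientSpec",
    "CircuitModel",
    "RealizedCircuit",
    "CircuitConfigError",
    "load_packaged_config",
    "load_packaged_manifest",
    "build_empathy_circuit",
    "build_self_attachment_circuit",
    "sample_projection",
    "sample_mpfc_gradient_targets",
    "realize_circuit",
]

REGION_NAMES = (
    "BLMA_neg",
    "BLMA_pos",
    "BLMA_i",
    "AI",
    "PI",
    "aMCC",
    "mPFC",
    "mPOA",
    "VTA",
    "NAc",
    "VP",
    "mOFC",
)

_VALENCES = ("positive", "negative", "interneuron", "none")


class CircuitConfigError(ValueError):
    """Raised when a circuit config is inconsistent or incomplete."""


@dataclass(frozen=True)
class RegionSpec:
    """One brain region: excitatory/inhibitory sub-population sizes and neuron types."""

    name: str
    n_exc: int
    n_inh: int
    neuron_type_exc: str = "RS"
    neuron_type_inh: str = "FS"
    valence_tag: str = "none"
    dopaminergic: bool = False

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise CircuitConfigError(f"unknown region name {self.name!r}")
        if self.n_exc + self.n_inh <= 0:
            raise CircuitConfigError(f"region {self.name}: empty population")
        if self.valence_tag not in _VALENCES:
            raise CircuitConfigError(f"region {self.name}: bad valence {self.valence_tag!r}")
        if self.name == "BLMA_i" and self.n_exc != 0:
            raise CircuitConfigError("BLMA_i is a purely inhibitory interneuron pool")
        for t in (self.neuron_type_exc, self.neuron_type_inh):
            if t not in PRESETS:
                raise CircuitConfigError(f"region {self.name}: unknown neuron type {t!r}")

    @property
    def size(self) -> int:
        return self.n_exc + self.n_inh

    def subpop_label(self, which: str) -> str:
        """Reporting label: ``exc`` / ``inh``, with dopaminergic excitatory cells as ``da``."""
        if which == "exc" and self.dopaminergic:
            return "da"
        return which


@dataclass(frozen=True)
class Projection:
    """A signed, probabilistically sampled projection between (sub)populations.

    ``source`` is ``"<region>.exc"`` or ``"<region>.inh"``; ``target`` is a
    region name (all neurons) or a qualified sub-population.  ``sampling`` is
    ``"uniform"`` (independent Bernoulli per cell pair) or ``"mpfc_gradient"``
    (mPFC-side endpoints drawn from the close-other negative binomial).
    """

    source: str
    target: str
    sign: str
    connection_probability: float
    weight: float
    sampling: str = "uniform"
    intra: bool = False

    def __post_init__(self) -> None:
        if self.sign not in ("excitatory", "inhibitory"):
            raise CircuitConfigError(f"{self.key}: sign must be excitatory|inhibitory")
        if not 0.0 <= self.connection_probability <= 1.0:
            raise CircuitConfigError(
                f"{self.key}: connection probability {self.connection_probability} outside [0, 1]"
            )
        if self.weight < 0:
            raise CircuitConfigError(f"{self.key}: weight must be >= 0")
        if self.sampling not in (
            "uniform", "mpfc_gradient", "mpfc_gradient_close", "mpfc_gradient_distant",
        ):
            raise CircuitConfigError(f"{self.key}: unknown sampling {self.sampling!r}")
        if self.sampling != "uniform" and not (
            self.source.startswith("mPFC") or self.target.startswith("mPFC")
        ):
            raise CircuitConfigError(f"{self.key}: mpfc_gradient sampling requires an mPFC endpoint")

    @property
    def gradient_mode(self) -> str | None:
        """``close`` / ``distant`` for gradient-sampled projections, else ``None``."""
        if self.sampling == "uniform":
            return None
        return "distant" if self.sampling.endswith("distant") else "close"

    @property
    def key(self) -> str:
        return f"{self.source}->{self.target}"

    @property
    def source_region(self) -> str:
        return self.source.split(".")[0]

    @property
    def target_region(self) -> str:
        return self.target.split(".")[0]


@dataclass(frozen=True)
class GradientSpec:
    """Negative-binomial parameters of the mPFC ventral--dorsal self--other gradient.

    The distributions are in the failures-count parameterisation with mean
    ``r (1 - p) / p``.  ``axis_orientation`` fixes which end of the index
    axis is ventral; with ``ventral_at_high_index`` the close-other
    distribution (large mean) lands ventrally.
    """

    close_other: tuple[int, float] = (7, 0.0025)
    distant_other: tuple[int, float] = (14, 0.035)
    axis_orientation: str = "ventral_at_high_index"

    def __post_init__(self) -> None:
        for r, p in (self.close_other, self.distant_other):
            if not (r >= 1 and 0.0 < p < 1.0):
                raise CircuitConfigError(f"degenerate gradient parameters (r={r}, p={p})")
        if self.axis_orientation not in ("ventral_at_low_index", "ventral_at_high_index"):
            raise CircuitConfigError(f"bad axis_orientation {self.axis_orientation!r}")

    def params(self, which: str) -> tuple[int, float]:
        if which == "close":
            return self.close_other
        if which == "distant":
            return self.distant_other
        raise ValueError("which must be 'close' or 'distant'")


@dataclass
class CircuitModel:
    """A validated circuit: regions, projections, gradient spec and provenance."""

    name: str
    regions: dict[str, RegionSpec]
    projections: list[Projection]
    mpfc_gradient: GradientSpec
    current_gain: float
    provenance: str

    def region(self, name: str) -> RegionSpec:
        try:
            return self.regions[name]
        except KeyError:
            raise CircuitConfigError(f"missing region {name!r}") from None

    @property
    def inter_edges(self) -> set[tuple[str, str, str]]:
        """Region-level inter-region edge set ``(source_region, target_region, sign)``."""
        return {
            (p.source_region, p.target_region, p.sign)
            for p in self.projections
            if p.source_region != p.target_region
        }


# ---------------------------------------------------------------------------
# Config loading and validation


def _read_packaged_yaml(filename: str) -> dict:
    text = resources.files("empathynet.data").joinpath(filename).read_text()
    return yaml.safe_load(text)


def load_packaged_config(model: str) -> dict:
    """Return the packaged circuit config mapping for ``empathy`` or ``self_attachment``."""
    return _read_packaged_yaml(f"model_{model}.yaml")


def load_packaged_manifest(model: str) -> dict:
    return _read_packaged_yaml(f"manifest_{model}.yaml")


def _config_hash(config: Mapping[str, Any]) -> str:
    canon = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _build(config: Mapping[str, Any], manifest: Mapping[str, Any],
           overrides: Mapping[str, float] | None = None) -> CircuitModel:
    problems: list[str] = []
    regions: dict[str, RegionSpec] = {}
    for name, spec in config["regions"].items():
        regions[name] = RegionSpec(
            name=name,
            n_exc=int(spec.get("n_exc", 0)),
            n_inh=int(spec.get("n_inh", 0)),
            neuron_type_exc=spec.get("type_exc", "RS"),
            neuron_type_inh=spec.get("type_inh", "FS"),
            valence_tag=spec.get("valence", "none"),
            dopaminergic=bool(spec.get("dopaminergic", False)),
        )

    overrides = dict(overrides or {})
    projections: list[Projection] = []
    for entry in config["projections"]:
        proj = Projection(
            source=entry["source"],
            target=entry["target"],
            sign=entry["sign"],
            connection_probability=float(entry["p"]),
            weight=float(entry["w"]),
            sampling=entry.get("sampling", "uniform"),
            intra=bool(entry.get("intra", False)),
        )
        if proj.key in overrides:
            proj = Projection(
                proj.source, proj.target, proj.sign,
                proj.connection_probability, float(overrides.pop(proj.key)),
                proj.sampling, proj.intra,
            )
        projections.append(proj)
    if overrides:
        problems.append(f"weight overrides for unknown projections: {sorted(overrides)}")

    # referential and sign discipline checks
    for proj in projections:
        for endpoint, qualified in ((proj.source_region, proj.source), (proj.target_region, proj.target)):
            if endpoint not in regions:
                problems.append(f"{proj.key}: unknown region {endpoint!r}")
                continue
            if "." in qualified:
                which = qualified.split(".")[1]
                if which not in ("exc", "inh"):
                    problems.append(f"{proj.key}: bad subpopulation {which!r}")
                elif getattr(regions[endpoint], f"n_{which}") == 0:
                    problems.append(f"{proj.key}: {qualified} is empty")
        if proj.source.endswith(".inh") and proj.sign != "inhibitory":
            problems.append(f"{proj.key}: inhibitory source must form an inhibitory projection")
        if (
            proj.source.endswith(".exc")
            and proj.sign == "inhibitory"
            and not regions.get(proj.source_region, RegionSpec("AI", 1, 0)).dopaminergic
        ):
            problems.append(
                f"{proj.key}: excitatory source with inhibitory sign is only allowed "
                "for dopaminergic regions"
            )

    # manifest completeness: exact inter-region edge set
    required = {tuple(e) for e in manifest.get("required", [])}
    optional = {tuple(e) for e in manifest.get("optional", [])}
    built = {
        (p.source_region, p.target_region, p.sign)
        for p in projections
        if p.source_region != p.target_region and not p.intra
    }
    for missing in sorted(required - built):
        problems.append(f"manifest edge missing from config: {missing}")
    for extra in sorted(built - required - optional):
        problems.append(f"config edge absent from manifest: {extra}")

    gradient_cfg = config.get("gradient", {})
    gradient = GradientSpec(
        close_other=tuple(gradient_cfg.get("close_other", (7, 0.0025))),
        distant_other=tuple(gradient_cfg.get("distant_other", (14, 0.035))),
        axis_orientation=gradient_cfg.get("axis_orientation", "ventral_at_high_index"),
    )

    if problems:
        raise CircuitConfigError("invalid circuit config:\n  " + "\n  ".join(problems))

    return CircuitModel(
        name=config.get("name", "custom"),
        regions=regions,
        projections=projections,
        mpfc_gradient=gradient,
        current_gain=float(config.get("current_gain", 1.0)),
        provenance=_config_hash(dict(config)),
    )


def build_empathy_circuit(config: Mapping[str, Any] | None = None,
                          overrides: Mapping[str, float] | None = None) -> CircuitModel:
    """Build the 11-region personal-distress / empathic-concern circuit.

    With no arguments the packaged calibrated config is used; a custom config
    mapping (same schema as the packaged YAML) is validated against the
    packaged edge manifest.
    """
    if config is None:
        config = load_packaged_config("empathy")
    return _build(config, load_packaged_manifest("empathy"), overrides)


def build_self_attachment_circuit(config: Mapping[str, Any] | None = None,
                                  overrides: Mapping[str, float] | None = None) -> CircuitModel:
    """Build the 12-region self-attachment circuit (empathy circuit + mOFC edges)."""
    if config is None:
        config = load_packaged_config("self_attachment")
    return _build(config, load_packaged_manifest("self_attachment"), overrides)


# ---------------------------------------------------------------------------
# Sampling


def sample_projection(proj: Projection, source_size: int, target_size: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Realise one uniform projection: each cell pair connects independently.

    Returns local (source, target) index arrays of equal length.
    """
    if source_size <= 0 or target_size <= 0:
        raise ValueError("population sizes must be positive")
    p = proj.connection_probability
    if p == 0.0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    if p == 1.0:
        src, tgt = np.meshgrid(np.arange(source_size), np.arange(target_size), indexing="ij")
        return src.ravel().astype(np.int64), tgt.ravel().astype(np.int64)
    hits = rng.random(source_size * target_size) < p
    flat = np.flatnonzero(hits)
    return (flat // target_size).astype(np.int64), (flat % target_size).astype(np.int64)


def sample_mpfc_gradient_targets(
    spec: GradientSpec,
    which: str,
    mpfc_size: int,
    n_draws: int,
    rng: np.random.Generator,
    unique: bool = False,
    _batch: int = 4096,
    _max_batches: int = 20000,
) -> np.ndarray:
    """Draw mPFC indices from the close- or distant-other gradient distribution.

    Draws from the stated negative binomial, rejects (and resamples) values
    outside ``[0, mpfc_size)``, and maps them onto the ventral--dorsal axis
    according to the configured axis orientation.  With ``unique=True`` the result is
    a set of ``n_draws`` distinct indices (used to build stimulation pools);
    otherwise it is a multiset (used for synapse endpoints).
    """
    if mpfc_size <= 0:
        raise ValueError("mpfc_size must be positive")
    r, p = spec.params(which)
    out: list[np.ndarray] = []
    seen: set[int] | None = set() if unique else None
    count = 0
    for _ in range(_max_batches):
        if count >= n_draws:
            break
        draws = rng.negative_binomial(r, p, size=_batch)
        draws = draws[draws < mpfc_size]
        if spec.axis_orientation == "ventral_at_low_index":
            draws = mpfc_size - 1 - draws
        if unique:
            fresh = []
            for x in draws:
                if x not in seen:  # type: ignore[operator]
                    seen.add(int(x))  # type: ignore[union-attr]
                    fresh.append(x)
                    if count + len(fresh) >= n_draws:
                        break
            draws = np.asarray(fresh, dtype=np.int64)
        take = min(len(draws), n_draws - count)
        out.append(draws[:take].astype(np.int64))
        count += take
    else:
        raise RuntimeError(
            f"gradient sampling did not converge: {count}/{n_draws} draws "
            f"({which}, mpfc_size={mpfc_size}); the distribution has too little "
            "in-range support for the requested pool"
        )
    return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)


# ---------------------------------------------------------------------------
# Realisation into flat arrays


@dataclass
class RealizedCircuit:
    """A circuit with sampled synapses, flattened for simulation.

    Neurons are laid out region by region, excitatory sub-population first.
    ``weights`` is an (n, n) CSC matrix with ``weights[tgt, src]`` the signed
    current delivered to ``tgt`` per spike of ``src``.
    """

    model: CircuitModel
    n_neurons: int
    region_slices: dict[str, slice]
    subpop_slices: dict[tuple[str, str], slice]  # (region, exc|inh) -> global slice
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    weights: Any  # scipy.sparse.csc_matrix
    synapse_count: int

    def global_indices(self, region: str, which: str | None = None) -> np.ndarray:
        sl = self.region_slices[region] if which is None else self.subpop_slices[(region, which)]
        return np.arange(sl.start, sl.stop)


def realize_circuit(model: CircuitModel, rng: np.random.Generator) -> RealizedCircuit:
    """Sample every projection of ``model`` into a concrete synapse matrix."""
    from scipy import sparse

    region_slices: dict[str, slice] = {}
    subpop_slices: dict[tuple[str, str], slice] = {}
    a, b, c, d = [], [], [], []
    offset = 0
    for name, spec in model.regions.items():
        start = offset
        for which, n, type_name in (
            ("exc", spec.n_exc, spec.neuron_type_exc),
            ("inh", spec.n_inh, spec.neuron_type_inh),
        ):
            subpop_slices[(name, which)] = slice(offset, offset + n)
            params = PRESETS[type_name]
            a.append(np.full(n, params.a))
            b.append(np.full(n, params.b))
            c.append(np.full(n, params.c))
            d.append(np.full(n, params.d))
            offset += n
        region_slices[name] = slice(start, offset)
    n_total = offset

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    n_syn = 0
    for proj in model.projections:
        src_sl = _endpoint_slice(proj.source, subpop_slices, region_slices)
        tgt_sl = _endpoint_slice(proj.target, subpop_slices, region_slices)
        ns, nt = src_sl.stop - src_sl.start, tgt_sl.stop - tgt_sl.start
        if ns == 0 or nt == 0 or proj.connection_probability == 0.0:
            continue
        if proj.sampling != "uniform":
            # the mPFC-side endpoint is drawn from the gradient distribution,
            # the other endpoint uniformly
            count = rng.binomial(ns * nt, proj.connection_probability)
            mode = proj.gradient_mode or "close"
            if proj.source_region == "mPFC":
                src = sample_mpfc_gradient_targets(model.mpfc_gradient, mode, ns, count, rng)
                tgt = rng.integers(0, nt, size=count)
            else:
                src = rng.integers(0, ns, size=count)
                tgt = sample_mpfc_gradient_targets(model.mpfc_gradient, mode, nt, count, rng)
        else:
            src, tgt = sample_projection(proj, ns, nt, rng)
        sign = 1.0 if proj.sign == "excitatory" else -1.0
        rows.append(tgt + tgt_sl.start)
        cols.append(src + src_sl.start)
        vals.append(np.full(len(src), sign * proj.weight))
        n_syn += len(src)

    if rows:
        W = sparse.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_total, n_total),
        )
    else:
        W = sparse.csc_matrix((n_total, n_total))

    return RealizedCircuit(
        model=model,
        n_neurons=n_total,
        region_slices=region_slices,
        subpop_slices=subpop_slices,
        a=np.concatenate(a) if a else np.zeros(0),
        b=np.concatenate(b) if b else np.zeros(0),
        c=np.concatenate(c) if c else np.zeros(0),
        d=np.concatenate(d) if d else np.zeros(0),
        weights=W,
        synapse_count=n_syn,
    )


def _endpoint_slice(qualified: str, subpop_slices, region_slices) -> slice:
    if "." in qualified:
        region, which = qualified.split(".")
        return subpop_slices[(region, which)]
    return region_slices[qualified]
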