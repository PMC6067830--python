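"""Shared fixtures: small circuits, schedules, and a fake-result builder."""

import numpy as np
import pytest

from empathynet.circuit import _build
from empathynet.engine import SimulationResult
from empathynet.protocol import _schedule_from_config


def tiny_circuit_config(n_exc=40, n_inh=10, gain=0.036, extra_projections=()):
    """One-region (BLMA_neg) config; enough to exercise the whole pipeline."""
    return dict(
        name="tiny",
        current_gain=gain,
        regions={"BLMA_neg": dict(n_exc=n_exc, n_inh=n_inh)},
        projections=[
            dict(source="BLMA_neg.exc", target="BLMA_neg.inh", sign="excitatory",
                 p=0.2, w=10.0, intra=True),
            dict(source="BLMA_neg.inh", target="BLMA_neg.exc", sign="inhibitory",
                 p=0.5, w=2.0, intra=True),
            *extra_projections,
        ],
    )


def build_tiny_circuit(**kwargs):
    return _build(tiny_circuit_config(**kwargs), dict(required=[], optional=[]))


def tiny_schedule(rule=("band", "M", "H"), amplitude=90.0, total=3000):
    kind = rule[0]
    rule_cfg = {"kind": kind}
    if kind != "off":
        rule_cfg.update(lo=rule[1], hi=rule[2])
    phase_len = total // 3
    cfg = dict(
        name="tiny",
        amplitude=amplitude,
        perturb_fraction=0.1,
        levels=dict(L=0.05, M=0.1, H=0.15),
        phases=[
            dict(index=i, t_start=(i - 1) * phase_len, t_end=i * phase_len,
                 rules=dict(BLMA_neg=rule_cfg))
            for i in (1, 2, 3)
        ],
    )
    return _schedule_from_config(cfg, None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_circuit():
    return build_tiny_circuit()


def make_fake_result(spikes, sizes, total_iterations=30000):
    """Build a SimulationResult from {(region, subpop_label): [(t, local_idx), ...]}.

    ``sizes`` maps (region, subpop_label) -> population size; subpop label
    "exc" is stored as the excitatory slot, anything else as inhibitory.
    """
    region_slices, subpop_slices, labels = {}, {}, {}
    offset = 0
    offsets = {}
    for (region, label), size in sizes.items():
        which = "exc" if label == "exc" else "inh"
        subpop_slices[(region, which)] = slice(offset, offset + size)
        labels[(region, which)] = label
        offsets[(region, label)] = offset
        lo = min(s.start for (r, _), s in subpop_slices.items() if r == region)
        hi = max(s.stop for (r, _), s in subpop_slices.items() if r == region)
        region_slices[region] = slice(lo, hi)
        offset += size
    # missing counterpart subpops get empty slices so summarize() skips them
    for region in {r for r, _ in sizes}:
        for which in ("exc", "inh"):
            if (region, which) not in subpop_slices:
                subpop_slices[(region, which)] = slice(offset, offset)
                labels[(region, which)] = which
    times, gids = [], []
    for key, events in spikes.items():
        for t, idx in events:
            times.append(t)
            gids.append(offsets[key] + idx)
    order = np.argsort(times) if times else []
    return SimulationResult(
        times=np.asarray(times, dtype=np.int32)[order] if times else np.zeros(0, np.int32),
        gids=np.asarray(gids, dtype=np.int32)[order] if times else np.zeros(0, np.int32),
        region_slices=region_slices,
        subpop_slices=subpop_slices,
        subpop_labels=labels,
        injected_counts={},
        seed=0,
        config_hash="fake",
        total_iterations=total_iterations,
        synapse_count=0,
    )
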