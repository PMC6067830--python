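"""Windowed mean-firing-rate summaries and network-state classification.

The mean firing rate (MFR) of a sub-population at a report time is the
spike count in a trailing window (default 1000 ms) divided by the window
length in seconds and the sub-population size — spikes per neuron per
second.  Report times default to the three phase ends (10, 20, 30 s).

The per-phase network state is labelled from the rate summary with simple
relative-threshold rules: personal distress is a quiet ventral pallidum
(VP) with the self-pain network (AI/PI) at its peak; weak and strong
empathic concern are distinguished by the VP rate; compassion additionally
requires an active mOFC and a suppressed negatively valent BLMA.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult

__all__ = [
    "RateSummary",
    "StateLabel",
    "StateThresholds",
    "compute_mfr",
    "summarize",
    "classify_state",
    "compare_to_reference",
    "load_reference",
]

STATE_LABELS = (
    "personal_distress",
    "weak_empathic_concern",
    "strong_empathic_concern",
    "compassion",
)


@dataclass
class RateSummary:
    """Tidy MFR table with one row per (region, subpop, report time)."""

    table: pd.DataFrame  # columns: region, subpop, time_s, mfr_hz
    window_ms: int

    def mfr(self, region: str, subpop: str, time_s: float) -> float:
        rows = self.table[
            (self.table.region == region)
            & (self.table.subpop == subpop)
            & (self.table.time_s == time_s)
        ]
        if rows.empty:
            raise KeyError(f"no MFR entry for ({region}, {subpop}, {time_s} s)")
        return float(rows.mfr_hz.iloc[0])

    def has(self, region: str) -> bool:
        return bool((self.table.region == region).any())

    @property
    def report_times_s(self) -> list[float]:
        return sorted(self.table.time_s.unique())


@dataclass(frozen=True)
class StateLabel:
    phase_index: int
    label: str
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.label!r}")


@dataclass(frozen=True)
class StateThresholds:
    """Defaults are consistent with the reported rate trajectories."""

    vp_low_hz: float = 0.5
    vp_high_hz: float = 2.0
    blma_neg_suppression_ratio: float = 0.7
    mofc_active_inh_hz: float = 5.0


def compute_mfr(result: SimulationResult, region: str, subpop: str,
                at_ms: int, window_ms: int = 1000) -> float:
    """MFR (Hz) of one sub-population over the window ``(at_ms - window_ms, at_ms]``."""
    if at_ms - window_ms < 0 or at_ms > result.total_iterations:
        raise ValueError(
            f"window ({at_ms - window_ms}, {at_ms}] outside the run (0, {result.total_iterations}]"
        )
    which = _resolve_subpop(result, region, subpop)
    times, _ = result.spikes_of(region, which)
    count = int(((times > at_ms - window_ms) & (times <= at_ms)).sum())
    size = result.population_size(region, which)
    if size == 0:
        return 0.0
    return count / (window_ms / 1000.0) / size


def _resolve_subpop(result: SimulationResult, region: str, subpop: str) -> str:
    """Map a reporting label (exc|inh|da) to the stored sub-population key."""
    for (name, which), label in result.subpop_labels.items():
        if name == region and label == subpop and result.population_size(region, which) > 0:
            return which
    raise KeyError(f"region {region!r} has no sub-population labelled {subpop!r}")


def summarize(result: SimulationResult,
              report_times_ms: Sequence[int] = (10000, 20000, 30000),
              window_ms: int = 1000) -> RateSummary:
    """Full MFR table across regions, sub-populations and report times."""
    rows = []
    for (region, which), sl in result.subpop_slices.items():
        if sl.stop - sl.start == 0:
            continue
        label = result.subpop_labels[(region, which)]
        for at in report_times_ms:
            rows.append(
                {
                    "region": region,
                    "subpop": label,
                    "time_s": at / 1000.0,
                    "mfr_hz": compute_mfr(result, region, label, at, window_ms),
                }
            )
    return RateSummary(pd.DataFrame(rows), window_ms)


def mean_summary(summaries: Iterable[RateSummary]) -> RateSummary:
    """Entry-wise mean of several rate summaries (e.g. across seeds)."""
    summaries = list(summaries)
    table = (
        pd.concat([s.table for s in summaries])
        .groupby(["region", "subpop", "time_s"], as_index=False)
        .mfr_hz.mean()
    )
    return RateSummary(table, summaries[0].window_ms)


def classify_state(summary: RateSummary,
                   thresholds: StateThresholds = StateThresholds()) -> list[StateLabel]:
    """Label each phase of a run from its end-of-phase rates.

    Raises ``ValueError`` for an all-silent summary ("insufficient activity").
    """
    if float(summary.table.mfr_hz.sum()) == 0.0:
        raise ValueError("insufficient activity: every reported MFR is zero")

    times = summary.report_times_s
    vp = [summary.mfr("VP", "inh", t) for t in times]
    blma_neg = [summary.mfr("BLMA_neg", "exc", t) for t in times]
    has_mofc = summary.has("mOFC")

    labels: list[StateLabel] = []
    for i, t in enumerate(times):
        evidence: list[str] = []
        suppressed = blma_neg[0] > 0 and (
            blma_neg[i] < thresholds.blma_neg_suppression_ratio * blma_neg[0]
        )
        mofc_active = has_mofc and (
            summary.mfr("mOFC", "inh", t) >= thresholds.mofc_active_inh_hz
        )
        if vp[i] < thresholds.vp_low_hz:
            label = "personal_distress"
            evidence.append(f"VP {vp[i]:.2f} Hz < {thresholds.vp_low_hz} (caregiving output quiet)")
            for reg in ("AI", "PI"):
                series = [summary.mfr(reg, "exc", tt) for tt in times]
                if series[i] == max(series):
                    evidence.append(f"{reg}-exc at its maximum across phases (self-pain dominant)")
        elif vp[i] < thresholds.vp_high_hz:
            label = "weak_empathic_concern"
            evidence.append(
                f"VP {vp[i]:.2f} Hz in [{thresholds.vp_low_hz}, {thresholds.vp_high_hz})"
            )
        elif mofc_active and suppressed:
            label = "compassion"
            evidence.append(f"VP {vp[i]:.2f} Hz >= {thresholds.vp_high_hz}")
            evidence.append(
                f"BLMA_neg {blma_neg[i]:.2f} Hz < "
                f"{thresholds.blma_neg_suppression_ratio:.0%} of phase-1 ({blma_neg[0]:.2f} Hz)"
            )
            evidence.append("mOFC active (reward-association drive present)")
        else:
            label = "strong_empathic_concern"
            evidence.append(f"VP {vp[i]:.2f} Hz >= {thresholds.vp_high_hz}")
            if not suppressed:
                evidence.append("BLMA_neg not suppressed relative to phase 1")
        labels.append(StateLabel(phase_index=i + 1, label=label, evidence=tuple(evidence)))
    return labels


def load_reference(model: str) -> pd.DataFrame:
    """Packaged reference MFR table (the values quoted in the results narrative)."""
    text = resources.files("empathynet.data").joinpath("reference_mfr.csv").read_text()
    table = pd.read_csv(io.StringIO(text))
    out = table[table.model == model].drop(columns=["model"]).reset_index(drop=True)
    if out.empty:
        raise ValueError(f"no reference entries for model {model!r}")
    return out


def compare_to_reference(summary: RateSummary, reference: pd.DataFrame,
                         rel_tol: float = 0.25, abs_tol: float = 0.3) -> pd.DataFrame:
    """Per-entry comparison ``|sim - ref| <= max(abs_tol, rel_tol * ref)``.

    Returns the reference table with ``sim_hz``, ``tolerance`` and ``passed``
    columns; the aggregate pass fraction is ``report.passed.mean()``.
    """
    rows = []
    for entry in reference.itertuples():
        sim = summary.mfr(entry.region, entry.subpop, entry.time_s)
        tol = max(abs_tol, rel_tol * entry.mfr_hz)
        rows.append(
            {
                "region": entry.region,
                "subpop": entry.subpop,
                "time_s": entry.time_s,
                "ref_hz": entry.mfr_hz,
                "sim_hz": sim,
                "tolerance": tol,
                "passed": abs(sim - entry.mfr_hz) <= tol,
            }
        )
    return pd.DataFrame(rows)
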