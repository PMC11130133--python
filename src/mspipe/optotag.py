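"""Optogenetic-tag classification of striatal units.

In a ChR2-in-D2 tagging experiment, blue-light (473 nm) pulse trains identify
unit subtype by their effect on firing: a unit is a putative **D2-MSN**
(directly light-driven) when it responds within 5 ms of pulse onset and its
in-pulse firing rate exceeds baseline by at least 20%; a putative **D1-MSN**
when its in-pulse rate is suppressed at least 20% below baseline (suppressed
units emit no evoked spike, so no latency requirement applies); anything else
is unresponsive.  Boundary values (exactly 5 ms, exactly +/-20%) meet the
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import StimProtocol

__all__ = [
    "OptotagResult",
    "PopulationSummary",
    "pulse_aligned_rates",
    "first_spike_latency",
    "classify_unit",
    "tag_unit",
    "population_summary",
    "group_rate_table",
    "LABEL_ACTIVATED",
    "LABEL_INHIBITED",
    "LABEL_UNRESPONSIVE",
]

LABEL_ACTIVATED = "activated_D2"
LABEL_INHIBITED = "inhibited_D1"
LABEL_UNRESPONSIVE = "unresponsive"

VALID_GROUPS = ("C", "CE", "PD", "PE")

# absolute slack so that rates landing exactly on the 20% / 5 ms boundaries
# are not lost to floating-point round-off
_EPS = 1e-9


@dataclass
class OptotagResult:
    unit_id: str
    baseline_rate_hz: float
    stim_rate_hz: float
    modulation: float  # (stim - baseline) / baseline; nan if baseline == 0
    latency_ms: float | None  # median first-spike latency; None if undefined
    label: str


@dataclass
class PopulationSummary:
    n_total: int
    n_D1: int
    n_D2: int
    pct_D1: float
    pct_D2: float


def pulse_aligned_rates(
    spike_times: np.ndarray,
    protocol: StimProtocol,
    baseline_window: tuple[float, float] | None = None,
    baseline_s: float = 60.0,
    duration: float | None = None,
) -> dict[str, float]:
    """Firing rate inside light pulses versus a stimulation-free baseline.

    ``stim_rate_hz`` counts spikes within the pulse-on windows divided by the
    total pulse-on time.  The baseline defaults to the ``baseline_s`` seconds
    immediately preceding the first stimulation epoch (clipped at zero); an
    explicit ``baseline_window`` must not overlap any stimulation epoch.
    """
    t = np.asarray(spike_times, dtype=float)
    onsets = protocol.pulse_onsets(duration)
    if onsets.size == 0:
        raise ValueError("protocol delivers no pulses")
    if baseline_window is None:
        end = protocol.first_epoch_onset()
        baseline_window = (max(0.0, end - baseline_s), end)
    b0, b1 = baseline_window
    if b1 <= b0:
        raise ValueError("baseline window has zero or negative duration")
    for e0, d in zip(protocol.epoch_onsets, protocol.epoch_durations):
        if b0 < e0 + d and e0 < b1:
            raise ValueError("baseline window overlaps a stimulation epoch")
    width = protocol.pulse_width_s
    idx = np.searchsorted(onsets, t, side="right") - 1
    in_pulse = (idx >= 0) & (t < onsets[np.clip(idx, 0, None)] + width)
    stim_rate = float(np.sum(in_pulse) / (onsets.size * width))
    base_rate = float(np.sum((t >= b0) & (t < b1)) / (b1 - b0))
    return {"baseline_rate_hz": base_rate, "stim_rate_hz": stim_rate}


def first_spike_latency(
    spike_times: np.ndarray,
    pulse_onsets: np.ndarray,
    max_window_ms: float = 10.0,
    min_responsive_frac: float = 0.25,
) -> float | None:
    """Median latency (ms) of the first spike after pulse onset.

    Pulses with no spike inside ``max_window_ms`` are excluded; if fewer than
    ``min_responsive_frac`` of pulses contain a spike the latency is
    undefined (None).
    """
    if max_window_ms <= 0:
        raise ValueError("max_window_ms must be > 0")
    t = np.sort(np.asarray(spike_times, dtype=float))
    onsets = np.asarray(pulse_onsets, dtype=float)
    if onsets.size == 0:
        return None
    win = max_window_ms / 1000.0
    first_idx = np.searchsorted(t, onsets, side="right")
    has_spike = first_idx < t.size
    latencies = np.full(onsets.shape, np.nan)
    latencies[has_spike] = t[np.clip(first_idx, 0, t.size - 1)][has_spike] - onsets[has_spike]
    responsive = latencies <= win
    if np.sum(responsive) < min_responsive_frac * onsets.size:
        return None
    return float(np.median(latencies[responsive]) * 1000.0)


def classify_unit(
    baseline_rate_hz: float,
    stim_rate_hz: float,
    latency_ms: float | None,
    mod_threshold: float = 0.20,
    latency_max_ms: float = 5.0,
) -> str:
    """Apply the tagging rule to one unit's rates and latency.

    activated (putative D2) iff latency <= 5 ms and modulation >= +20%;
    inhibited (putative D1) iff modulation <= -20%; otherwise unresponsive.
    A unit with zero baseline rate is unclassifiable (unresponsive).
    """
    if baseline_rate_hz <= 0:
        return LABEL_UNRESPONSIVE
    modulation = (stim_rate_hz - baseline_rate_hz) / baseline_rate_hz
    if (
        modulation >= mod_threshold - _EPS
        and latency_ms is not None
        and latency_ms <= latency_max_ms + _EPS
    ):
        return LABEL_ACTIVATED
    if modulation <= -mod_threshold + _EPS:
        return LABEL_INHIBITED
    return LABEL_UNRESPONSIVE


def tag_unit(
    unit_id: str,
    spike_times: np.ndarray,
    protocol: StimProtocol,
    baseline_window: tuple[float, float] | None = None,
    baseline_s: float = 60.0,
    duration: float | None = None,
    mod_threshold: float = 0.20,
    latency_max_ms: float = 5.0,
    latency_window_ms: float = 10.0,
) -> OptotagResult:
    """Convenience wrapper: rates + latency + label for one spike train."""
    rates = pulse_aligned_rates(
        spike_times, protocol, baseline_window, baseline_s, duration
    )
    latency = first_spike_latency(
        spike_times, protocol.pulse_onsets(duration), latency_window_ms
    )
    label = classify_unit(
        rates["baseline_rate_hz"],
        rates["stim_rate_hz"],
        latency,
        mod_threshold,
        latency_max_ms,
    )
    base = rates["baseline_rate_hz"]
    modulation = (rates["stim_rate_hz"] - base) / base if base > 0 else np.nan
    return OptotagResult(
        unit_id=unit_id,
        baseline_rate_hz=base,
        stim_rate_hz=rates["stim_rate_hz"],
        modulation=modulation,
        latency_ms=latency,
        label=label,
    )


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def population_summary(labels: Sequence[str]) -> PopulationSummary:
    """Counts and percentages of putative D1/D2 units among all classified
    MSNs.  Percentages use the full MSN count as denominator and are rounded
    half-away-from-zero to one decimal."""
    labels = list(labels)
    if not labels:
        raise ValueError("no units to summarize")
    n_total = len(labels)
    n_d1 = sum(1 for l in labels if l == LABEL_INHIBITED)
    n_d2 = sum(1 for l in labels if l == LABEL_ACTIVATED)
    return PopulationSummary(
        n_total=n_total,
        n_D1=n_d1,
        n_D2=n_d2,
        pct_D1=_round_half_up(100.0 * n_d1 / n_total),
        pct_D2=_round_half_up(100.0 * n_d2 / n_total),
    )


def group_rate_table(records: Iterable[Mapping]) -> pd.DataFrame:
    """Long-format baseline-rate table (group x subtype x subject) feeding
    the group statistics stage.

    Each record needs ``unit_id``, ``group`` (C/CE/PD/PE), ``subtype`` (or a
    tagging ``label``), ``baseline_rate_hz`` and optionally ``subject``.
    """
    rows = []
    for rec in records:
        group = rec["group"]
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {VALID_GROUPS}")
        subtype = rec.get("subtype")
        if subtype is None:
            label = rec["label"]
            subtype = {LABEL_INHIBITED: "D1", LABEL_ACTIVATED: "D2"}.get(label, "other")
        rows.append(
            {
                "subject": rec.get("subject", rec["unit_id"]),
                "group": group,
                "subtype": subtype,
                "unit_id": rec["unit_id"],
                "measure": "baseline_rate_hz",
                "value": float(rec["baseline_rate_hz"]),
            }
        )
    if not rows:
        raise ValueError("no records provided")
    return pd.DataFrame(rows)
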