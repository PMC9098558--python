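"""MEP extraction, trial rejection and resting-motor-threshold estimation.

The motor evoked potential (MEP) is quantified as the peak-to-peak EMG
amplitude in a 10-60 ms window after the TMS pulse.  Trials contaminated by
muscle pre-activation — any sample exceeding ±20 µV in the 300 ms before the
pulse — are rejected.  Accepted trial amplitudes at one stimulation site are
reduced to their median.  The resting motor threshold (rMT) is the lowest
stimulator intensity (% of maximum stimulator output) at which at least 5 of
10 pulses exceed 100 µV.

Traces are assumed already hardware band-passed; no filtering is applied.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RejectReason",
    "MepRecord",
    "RmtResult",
    "extract_mep",
    "check_preactivation",
    "estimate_rmt",
    "aggregate_site",
]


class RejectReason(str, enum.Enum):
    none = "none"
    preactivation = "preactivation"


@dataclass(frozen=True)
class MepRecord:
    """Extracted response: peak-to-peak amplitude, latency, accept flag."""

    amplitude_uv: float
    latency_ms: float
    accepted: bool = True
    reject_reason: RejectReason = RejectReason.none


@dataclass(frozen=True)
class RmtResult:
    """Outcome of an rMT search over a tested intensity series."""

    found: bool
    rmt_pct_mso: float | None
    at_boundary: bool  # lowest tested intensity already met the criterion


def extract_mep(
    trace,
    trigger_index: int,
    sample_rate: float,
    window_ms: tuple[float, float] = (10.0, 60.0),
) -> MepRecord:
    """Peak-to-peak MEP amplitude in the post-pulse analysis window.

    Amplitude is max - min of the trace restricted to
    ``[trigger + window_ms[0], trigger + window_ms[1]]``; latency is the time
    of the window's absolute extremum relative to the trigger.

    Raises ``ValueError`` if the trace does not cover the window.
    """
    trace = np.asarray(trace, dtype=float)
    lo = trigger_index + int(round(window_ms[0] * sample_rate / 1000.0))
    hi = trigger_index + int(round(window_ms[1] * sample_rate / 1000.0))
    if lo < 0 or hi > len(trace):
        raise ValueError(
            f"analysis window [{window_ms[0]}, {window_ms[1]}] ms exceeds trace extent"
        )
    window = trace[lo : hi + 1] if hi < len(trace) else trace[lo:hi]
    amplitude = float(window.max() - window.min())
    i_ext = int(np.argmax(np.abs(window)))
    latency_ms = (lo + i_ext - trigger_index) * 1000.0 / sample_rate
    return MepRecord(amplitude_uv=amplitude, latency_ms=latency_ms)


def check_preactivation(
    trace,
    trigger_index: int,
    sample_rate: float,
    limit_uv: float = 20.0,
    lookback_ms: float = 300.0,
) -> bool:
    """True (accepted) unless baseline activity exceeds ±limit_uv pre-pulse.

    Only the ``lookback_ms`` immediately before the trigger are inspected;
    earlier excursions do not reject the trial.  Raises ``ValueError`` when
    the trace has fewer than ``lookback_ms`` of pre-trigger samples.
    """
    trace = np.asarray(trace, dtype=float)
    n_back = int(round(lookback_ms * sample_rate / 1000.0))
    if trigger_index < n_back:
        raise ValueError(
            f"trace provides only {trigger_index} pre-trigger samples; "
            f"{n_back} required for a {lookback_ms} ms lookback"
        )
    baseline = trace[trigger_index - n_back : trigger_index]
    return bool(np.all(np.abs(baseline) <= limit_uv))


def process_trial(
    trace,
    trigger_index: int,
    sample_rate: float,
    window_ms: tuple[float, float] = (10.0, 60.0),
    limit_uv: float = 20.0,
    lookback_ms: float = 300.0,
) -> MepRecord:
    """Extract an MEP and apply the pre-activation rejection rule."""
    rec = extract_mep(trace, trigger_index, sample_rate, window_ms)
    if not check_preactivation(trace, trigger_index, sample_rate, limit_uv, lookback_ms):
        return MepRecord(
            amplitude_uv=rec.amplitude_uv,
            latency_ms=rec.latency_ms,
            accepted=False,
            reject_reason=RejectReason.preactivation,
        )
    return rec


def estimate_rmt(
    series: dict[float, list[float]],
    criterion_uv: float = 100.0,
    k: int = 5,
    n: int = 10,
) -> RmtResult:
    """Resting motor threshold from a pre-collected intensity series.

    ``series`` maps tested stimulator intensity (% MSO) to the list of trial
    peak-to-peak amplitudes (µV) collected at that intensity.  The rMT is
    the minimum tested intensity at which at least ``k`` of ``n`` amplitudes
    exceed ``criterion_uv``.  When no intensity qualifies a not-found result
    is returned; when the lowest tested intensity already qualifies the
    boundary flag is set (the true threshold may lie below the tested range).
    """
    if not series:
        raise ValueError("empty intensity series")
    for intensity, amps in series.items():
        if len(amps) < n:
            raise ValueError(
                f"intensity {intensity} has {len(amps)} trials; {n} required"
            )
    qualifying = sorted(
        i
        for i, amps in series.items()
        if sum(a > criterion_uv for a in amps[:n]) >= k
    )
    if not qualifying:
        return RmtResult(found=False, rmt_pct_mso=None, at_boundary=False)
    rmt = qualifying[0]
    return RmtResult(found=True, rmt_pct_mso=float(rmt), at_boundary=rmt == min(series))


def aggregate_site(amplitudes) -> float:
    """Median of the accepted trial amplitudes at one stimulation site."""
    amplitudes = np.asarray(list(amplitudes), dtype=float)
    if amplitudes.size == 0:
        raise ValueError("no accepted amplitudes at site")
    return float(np.median(amplitudes))


def drop_empty_sites(site_amplitudes: dict[int, list[float]]) -> dict[int, float]:
    """Aggregate per-site amplitudes, dropping (with a warning) all-rejected sites."""
    out = {}
    for site_id, amps in site_amplitudes.items():
        if len(amps) == 0:
            warnings.warn(
                f"site {site_id}: all trials rejected; site dropped from map",
                stacklevel=2,
            )
            continue
        out[site_id] = aggregate_site(amps)
    return out
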