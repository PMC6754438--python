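"""Signal cleaning: the fixed chain turning raw traces into one averaged beat.

Order of operations (applied per recording):

1. ratiometric motion-artifact correction of AP and Ca using the MA trace,
2. inversion of the AP trace (the voltage dye dims on depolarization),
3. pseudo-ratio ΔF/F_min for AP and Ca,
4. a minimal trailing moving-average filter (2 frames by default),
5. pacing-aware event detection with an interpeak-distance check,
6. pointwise averaging of the first N complete events (5 by default).

Contraction traces skip steps 1–3: the frame-difference surrogate is already
baseline-anchored and motion *is* its signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    InputError,
    InsufficientEventsError,
    InterpeakMismatchError,
    NumericDomainError,
)
from .traces import Trace

__all__ = [
    "CleaningConfig",
    "EventSet",
    "ratiometric_correct",
    "invert",
    "delta_f_over_f",
    "moving_average",
    "detect_events",
    "average_events",
    "clean_trace",
    "clean_recording",
    "estimate_baseline",
]


@dataclass(frozen=True)
class CleaningConfig:
    """Tunable knobs of the cleaning chain.

    pacing_hz : field-stimulation frequency; all recordings are paced.
    filter_window : trailing moving-average width in frames.
    events_to_average : number of complete beats averaged per recording.
    interpeak_tolerance : admissible relative deviation of each inter-onset
        interval from the pacing period before a recording is rejected.
    onset_threshold : fraction of event amplitude whose rising crossing
        defines the event onset.
    """

    pacing_hz: float = 1.2
    filter_window: int = 2
    events_to_average: int = 5
    interpeak_tolerance: float = 0.1
    onset_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not self.pacing_hz > 0:
            raise InputError("pacing frequency must be positive")
        if self.filter_window < 1:
            raise InputError("filter window must be >= 1 frame")
        if self.events_to_average < 1:
            raise InputError("events_to_average must be >= 1")
        if not 0 < self.interpeak_tolerance < 0.5:
            raise InputError("interpeak tolerance must lie in (0, 0.5)")
        if not 0 < self.onset_threshold < 1:
            raise InputError("onset threshold must lie in (0, 1)")


@dataclass(frozen=True)
class EventSet:
    """Detected paced events of one trace.

    ``onsets`` are sample indices of complete events (those whose full
    pacing-period window fits inside the trace), strictly increasing.
    ``interpeak_ok`` is the pass flag of the pacing-period check over all
    detected onsets.
    """

    onsets: np.ndarray
    window: int
    period_samples: float
    interpeak_ok: bool

    def __len__(self) -> int:
        return int(np.asarray(self.onsets).size)


def estimate_baseline(values: np.ndarray) -> float:
    """Diastolic baseline: median of the lowest-decile sample values.

    For a paced cyclic beat the smallest samples are the late-diastolic
    (pre-upstroke) level, so this is a robust stand-in for a pre-upstroke
    median even when the window starts at the event onset.
    """
    values = np.asarray(values, dtype=float)
    k = max(3, values.size // 10)
    k = min(k, values.size)
    return float(np.median(np.sort(values)[:k]))


def ratiometric_correct(signal: Trace, ma: Trace) -> Trace:
    """Divide out the mean-normalized motion-artifact trace.

    ``out_i = signal_i / (ma_i / mean(ma))``: a constant MA leaves the
    signal untouched; a multiplicative contraction artifact shared by both
    channels cancels up to a constant factor (harmless after ΔF/F).
    """
    if len(signal) != len(ma):
        raise InputError("signal and MA traces differ in length")
    if abs(signal.rate - ma.rate) > 1e-9 * signal.rate:
        raise InputError("signal and MA traces differ in sampling rate")
    if np.any(ma.values <= 0):
        raise NumericDomainError(
            "MA trace has non-positive samples; offset-correct upstream"
        )
    factor = ma.values / ma.values.mean()
    return signal.with_values(signal.values / factor)


def invert(trace: Trace) -> Trace:
    """Reflect about mid-range: ``(max + min) - x``.

    Used for the AP channel, whose dye intensity decreases with
    depolarization.  Involution: applying twice returns the input.
    Reflection (rather than negation) keeps the trace positive, which the
    downstream ΔF/F_min step requires.
    """
    v = trace.values
    return trace.with_values((v.max() + v.min()) - v)


def delta_f_over_f(trace: Trace) -> Trace:
    """Pseudo-ratio ΔF/F_min: ``(F - F_min) / F_min``; minimum is exactly 0."""
    f_min = trace.values.min()
    if f_min <= 0:
        raise NumericDomainError(
            "trace minimum must be positive for dF/F_min; offset-correct upstream"
        )
    return trace.with_values((trace.values - f_min) / f_min)


def moving_average(trace: Trace, window: int) -> Trace:
    """Trailing mean over ``window`` frames; the first window-1 samples
    average over the available prefix so length and onset timing are kept."""
    n = len(trace)
    if window < 1:
        raise InputError("window must be >= 1")
    if window > n:
        raise InputError(f"window {window} exceeds trace length {n}")
    cs = np.concatenate([[0.0], np.cumsum(trace.values)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - window + 1)
    out = (cs[idx + 1] - cs[lo]) / (idx + 1 - lo)
    return trace.with_values(out)


def detect_events(trace: Trace, cfg: CleaningConfig) -> EventSet:
    """Locate paced event onsets and check the interpeak distance.

    Peaks are found at roughly the pacing period; each onset is the rising
    crossing of ``baseline + onset_threshold * (peak - baseline)`` before
    its peak.  The pass flag is true iff every inter-onset interval is
    within ``interpeak_tolerance`` of the pacing period.  Only events whose
    full window (one pacing period) fits in the trace are kept.
    """
    period = trace.rate / cfg.pacing_hz  # samples
    n = len(trace)
    if n < 2 * period:
        raise InputError("trace must span at least two pacing periods")
    v = trace.values
    vrange = float(v.max() - v.min())
    if vrange <= 0 or not np.isfinite(vrange):
        raise InsufficientEventsError("flat trace: no events detected")
    peaks, _ = find_peaks(
        v, distance=max(1, int(0.7 * period)), prominence=0.4 * vrange
    )
    if peaks.size == 0:
        raise InsufficientEventsError("no events detected")
    baseline = estimate_baseline(v)
    onsets = []
    for peak in peaks:
        level = baseline + cfg.onset_threshold * (v[peak] - baseline)
        below = np.nonzero(v[: peak + 1] < level)[0]
        onset = int(below[-1]) + 1 if below.size else 0
        if not onsets or onset > onsets[-1]:
            onsets.append(onset)
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size >= 2:
        gaps = np.diff(onsets)
        interpeak_ok = bool(np.all(np.abs(gaps - period) <= cfg.interpeak_tolerance * period))
    else:
        interpeak_ok = True
    window = int(np.floor(period))
    complete = onsets[onsets + window <= n]
    if complete.size < cfg.events_to_average:
        raise InsufficientEventsError(
            f"found {complete.size} complete events, need {cfg.events_to_average}"
        )
    return EventSet(
        onsets=complete, window=window, period_samples=period, interpeak_ok=interpeak_ok
    )


def average_events(trace: Trace, events: EventSet, cfg: CleaningConfig) -> Trace:
    """Pointwise mean of the first ``events_to_average`` onset-aligned windows."""
    if not events.interpeak_ok:
        raise InterpeakMismatchError(
            "inter-event intervals deviate from the pacing period; recording rejected"
        )
    if len(events) < cfg.events_to_average:
        raise InsufficientEventsError(
            f"{len(events)} events available, need {cfg.events_to_average}"
        )
    windows = [
        trace.values[onset : onset + events.window]
        for onset in events.onsets[: cfg.events_to_average]
    ]
    avg = np.mean(windows, axis=0)
    return Trace(avg, rate=trace.rate, channel=trace.channel, t0=0.0)


def clean_trace(trace: Trace, cfg: CleaningConfig, ma: Trace | None = None) -> Trace:
    """Run the full cleaning chain on one channel trace.

    AP: ratiometric correction (if MA given) → inversion → ΔF/F → filter →
    event detection → averaging.  Ca: same without inversion.  Co: filter
    and event averaging only.
    """
    out = trace
    if trace.channel in ("AP", "Ca"):
        if ma is not None:
            out = ratiometric_correct(out, ma)
        if trace.channel == "AP":
            out = invert(out)
        out = delta_f_over_f(out)
    out = moving_average(out, cfg.filter_window)
    events = detect_events(out, cfg)
    return average_events(out, events, cfg)


def clean_recording(traces: dict[str, Trace], cfg: CleaningConfig) -> dict[str, Trace]:
    """Clean the AP/Ca/Co traces of one recording; uses the MA trace if present."""
    ma = traces.get("MA")
    return {
        ch: clean_trace(traces[ch], cfg, ma=ma)
        for ch in ("AP", "Ca", "Co")
        if ch in traces
    }
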