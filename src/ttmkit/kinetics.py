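"""Per-beat kinetic quantification and baseline-normalized aggregation.

The averaged beat of each channel is summarized into the ten kinetic
parameters (4 AP + 3 Ca + 3 Co).  Conventions, all measured with linear
interpolation between samples:

* baseline: median of the lowest-decile samples (late-diastolic level),
* amplitude: peak − baseline,
* activation: rising crossing of 50% amplitude on the upstroke,
* APDx: activation → first post-peak crossing of (1 − x) · amplitude;
  ``t_APD`` reports APD90 and triangulation is APD90 − APD30,
* t_rise: 10% → 90% upstroke time,
* t_to_peak / t_contraction: 10% rising crossing → peak,
* t_decay / t_relaxation: peak → 50% decay crossing (level configurable).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .cleaning import estimate_baseline
from .errors import (
    DegenerateBaselineError,
    EmptyAggregateError,
    IncompleteTransientError,
    InputError,
)
from .hypotheses import KineticParameter
from .traces import Trace

__all__ = [
    "KineticsConfig",
    "KineticParameters",
    "apd_at",
    "ap_kinetics",
    "ca_kinetics",
    "co_kinetics",
    "measure_recording",
    "normalize_to_baseline",
    "aggregate",
]


@dataclass(frozen=True)
class KineticsConfig:
    """Measurement levels (fractions of amplitude)."""

    apd_fraction: float = 0.9          # repolarization fraction defining t_APD
    triangulation_low: float = 0.3     # APD90 - APD30 by default
    decay_fraction: float = 0.5        # Ca decay / Co relaxation level
    rise_low: float = 0.1
    rise_high: float = 0.9
    activation_fraction: float = 0.5

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not 0 < v < 1:
                raise InputError(f"{f.name} must lie in (0, 1)")
        if self.rise_low >= self.rise_high:
            raise InputError("rise_low must be below rise_high")
        if self.triangulation_low >= self.apd_fraction:
            raise InputError("triangulation_low must be below apd_fraction")


@dataclass(frozen=True)
class KineticParameters:
    """The 10-parameter summary of one averaged recording.

    Unusable values are NaN; a record with any NaN is flagged unusable and
    excluded from aggregation.
    """

    AP_amplitude: float = math.nan
    AP_t_rise: float = math.nan
    AP_t_APD: float = math.nan
    AP_triangulation: float = math.nan
    Ca_amplitude: float = math.nan
    Ca_t_to_peak: float = math.nan
    Ca_t_decay: float = math.nan
    Co_amplitude: float = math.nan
    Co_t_contraction: float = math.nan
    Co_t_relaxation: float = math.nan

    def as_dict(self) -> dict[KineticParameter, float]:
        return {p: float(getattr(self, p.name)) for p in KineticParameter}

    @classmethod
    def from_dict(cls, values: dict[KineticParameter, float]) -> "KineticParameters":
        return cls(**{p.name: float(v) for p, v in values.items()})

    @property
    def is_usable(self) -> bool:
        return all(np.isfinite(v) for v in self.as_dict().values())


# ---- crossing helpers -----------------------------------------------------


def _cross_before(v: np.ndarray, level: float, peak: int) -> float:
    """Interpolated index of the rising crossing of ``level`` closest before
    ``peak``.

    When the window starts above the level (the averaged window begins at
    the detected onset, which may sit just past a low crossing level) the
    crossing is back-extrapolated along the initial upstroke slope, capped
    at one sample before the window.
    """
    below = np.nonzero(v[: peak + 1] < level)[0]
    if below.size == 0:
        if peak >= 1 and v[1] > v[0]:
            return max(-1.0, (level - v[0]) / (v[1] - v[0]))
        return 0.0
    i = int(below[-1])
    if i == peak:
        return float(peak)
    return i + (level - v[i]) / (v[i + 1] - v[i])


def _cross_after(v: np.ndarray, level: float, peak: int) -> float | None:
    """Interpolated index of the first falling crossing of ``level`` after
    ``peak``; None when the level is never reached."""
    after = np.nonzero(v[peak:] <= level)[0]
    if after.size == 0:
        return None
    j = peak + int(after[0])
    if j == peak:
        return float(peak)
    return j - 1 + (v[j - 1] - level) / (v[j - 1] - v[j])


def _beat_geometry(trace: Trace) -> tuple[np.ndarray, float, int, float]:
    v = trace.values
    baseline = estimate_baseline(v)
    peak = int(np.argmax(v))
    amplitude = float(v[peak] - baseline)
    return v, baseline, peak, amplitude


def _is_flat(v: np.ndarray, amplitude: float) -> bool:
    scale = max(abs(float(np.max(np.abs(v)))), 1.0)
    return amplitude <= 1e-9 * scale


def apd_at(avg_ap: Trace, repol_fraction: float,
           cfg: KineticsConfig | None = None) -> float:
    """Duration (ms) from activation to ``repol_fraction`` repolarization.

    Activation is the 50%-amplitude rising crossing on the upstroke; the
    repolarization time is the first post-peak crossing of
    ``amplitude * (1 - repol_fraction)`` above baseline.
    """
    if not 0 < repol_fraction < 1:
        raise InputError("repolarization fraction must lie in (0, 1)")
    cfg = cfg or KineticsConfig()
    v, baseline, peak, amplitude = _beat_geometry(avg_ap)
    if _is_flat(v, amplitude):
        raise IncompleteTransientError("flat trace: no action potential present")
    act = _cross_before(v, baseline + cfg.activation_fraction * amplitude, peak)
    level = baseline + (1.0 - repol_fraction) * amplitude
    cross = _cross_after(v, level, peak)
    if cross is None:
        raise IncompleteTransientError(
            f"repolarization never reached {repol_fraction:.0%} inside the window"
        )
    return (cross - act) * avg_ap.dt_ms


def ap_kinetics(avg_ap: Trace, cfg: KineticsConfig | None = None
                ) -> dict[KineticParameter, float]:
    """Amplitude, 10–90% rise time, APD (APD90) and triangulation of one beat."""
    cfg = cfg or KineticsConfig()
    v, baseline, peak, amplitude = _beat_geometry(avg_ap)
    if _is_flat(v, amplitude):
        return {
            KineticParameter.AP_amplitude: 0.0,
            KineticParameter.AP_t_rise: math.nan,
            KineticParameter.AP_t_APD: math.nan,
            KineticParameter.AP_triangulation: math.nan,
        }
    t_lo = _cross_before(v, baseline + cfg.rise_low * amplitude, peak)
    t_hi = _cross_before(v, baseline + cfg.rise_high * amplitude, peak)
    apd_main = apd_at(avg_ap, cfg.apd_fraction, cfg)
    apd_low = apd_at(avg_ap, cfg.triangulation_low, cfg)
    return {
        KineticParameter.AP_amplitude: amplitude,
        KineticParameter.AP_t_rise: (t_hi - t_lo) * avg_ap.dt_ms,
        KineticParameter.AP_t_APD: apd_main,
        KineticParameter.AP_triangulation: apd_main - apd_low,
    }


def _refine_peak(v: np.ndarray, peak: int) -> float:
    """Sub-sample peak position by parabolic interpolation (argmax is
    ill-conditioned on flat-topped transients)."""
    if not 0 < peak < v.size - 1:
        return float(peak)
    y0, y1, y2 = v[peak - 1], v[peak], v[peak + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(peak)
    offset = 0.5 * (y0 - y2) / denom
    return peak + float(np.clip(offset, -1.0, 1.0))


def _transient_kinetics(trace: Trace, cfg: KineticsConfig) -> tuple[float, float, float]:
    """Shared geometry of Ca and Co beats: amplitude, onset→peak, peak→decay."""
    v, baseline, peak, amplitude = _beat_geometry(trace)
    if _is_flat(v, amplitude):
        return 0.0, math.nan, math.nan
    onset = _cross_before(v, baseline + cfg.rise_low * amplitude, peak)
    peak_t = _refine_peak(v, peak)
    t_to_peak = (peak_t - onset) * trace.dt_ms
    level = baseline + (1.0 - cfg.decay_fraction) * amplitude
    cross = _cross_after(v, level, peak)
    if cross is None:
        raise IncompleteTransientError(
            f"decay never reached {cfg.decay_fraction:.0%} inside the window"
        )
    t_decay = (cross - peak_t) * trace.dt_ms
    return amplitude, t_to_peak, t_decay


def ca_kinetics(avg_ca: Trace, cfg: KineticsConfig | None = None
                ) -> dict[KineticParameter, float]:
    """Amplitude, time-to-peak and 50% decay time of the calcium beat."""
    amplitude, t_to_peak, t_decay = _transient_kinetics(avg_ca, cfg or KineticsConfig())
    return {
        KineticParameter.Ca_amplitude: amplitude,
        KineticParameter.Ca_t_to_peak: t_to_peak,
        KineticParameter.Ca_t_decay: t_decay,
    }


def co_kinetics(avg_co: Trace, cfg: KineticsConfig | None = None
                ) -> dict[KineticParameter, float]:
    """Amplitude, contraction time and 50% relaxation time of the motion beat."""
    amplitude, t_con, t_rel = _transient_kinetics(avg_co, cfg or KineticsConfig())
    return {
        KineticParameter.Co_amplitude: amplitude,
        KineticParameter.Co_t_contraction: t_con,
        KineticParameter.Co_t_relaxation: t_rel,
    }


def measure_recording(avg: dict[str, Trace], cfg: KineticsConfig | None = None
                      ) -> KineticParameters:
    """Quantify the averaged AP/Ca/Co beats of one recording."""
    cfg = cfg or KineticsConfig()
    values: dict[KineticParameter, float] = {}
    values.update(ap_kinetics(avg["AP"], cfg))
    values.update(ca_kinetics(avg["Ca"], cfg))
    values.update(co_kinetics(avg["Co"], cfg))
    return KineticParameters.from_dict(values)


def normalize_to_baseline(post: KineticParameters, baseline: KineticParameters
                          ) -> KineticParameters:
    """Fieldwise ratio post/baseline (1 = no change)."""
    base = baseline.as_dict()
    bad = [p.name for p, v in base.items() if not (np.isfinite(v) and v > 0)]
    if bad:
        raise DegenerateBaselineError(
            f"non-positive baseline parameter(s): {', '.join(bad)}"
        )
    post_d = post.as_dict()
    return KineticParameters.from_dict({p: post_d[p] / base[p] for p in base})


def aggregate(records: list[KineticParameters]) -> tuple[KineticParameters, int]:
    """Fieldwise mean over usable records (area → well, or well → condition).

    Returns the mean record and the number of contributing records.
    """
    if not records:
        raise EmptyAggregateError("no records to aggregate")
    usable = [r for r in records if r.is_usable]
    if not usable:
        raise EmptyAggregateError("all records unusable")
    mean = {
        p: float(np.mean([r.as_dict()[p] for r in usable]))
        for p in KineticParameter
    }
    return KineticParameters.from_dict(mean), len(usable)
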