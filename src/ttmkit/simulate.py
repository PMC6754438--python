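"""Synthetic paced triple-transient experiments with known ground truth.

The generator emulates the study conditions end to end: 7 s recordings of
1.2 Hz-paced action-potential, calcium and contraction transients sampled at
1000/3 samples/s per channel, a plate layout of vehicle plus drug
concentrations with 5 wells × 3 areas, each area measured at baseline and
after treatment, per-MOA parameter perturbations following the hypotheses
table, multiplicative well-to-well and recording-to-recording biological
variability, additive photometric noise and an optional multiplicative
motion-artifact shared by the AP/Ca channels and the membrane-label (MA)
reference.

Waveform templates are phenomenological, not biophysical: the AP is a
half-cosine upstroke followed by a stretched-exponential repolarization
whose two shape constants are solved in closed form from the APD30/APD90
targets; Ca and Co events are a half-cosine rise followed by a single
exponential decay.  The half-cosine makes the slope vanish at the peak, so
the sampled maximum stays within a fraction of a percent of the true
amplitude at 333 fps.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import InputError, ShapeInfeasibleError
from .hypotheses import (
    Effect,
    HypothesisTable,
    KineticParameter,
    MOA,
    builtin_table,
)
from .ingest import FrameStack
from .kinetics import KineticParameters
from .traces import Trace

__all__ = [
    "APWaveform",
    "TransientWaveform",
    "ExperimentDesign",
    "Recording",
    "SimulatedDataset",
    "default_waveforms",
    "simulate_event",
    "simulate_recording",
    "apply_moa",
    "realize_directions",
    "apply_directions",
    "simulate_experiment",
    "expected_kinetics",
    "render_interleaved_frames",
]

# 10%/90% crossing geometry of the half-cosine rise (fractions of rise time)
_RISE_T10 = math.acos(0.8) / math.pi            # ≈ 0.2048
_RISE_T90 = math.acos(-0.8) / math.pi           # ≈ 0.7952
_LN_07 = math.log(1 / 0.7)
_LN_10 = math.log(10.0)


@dataclass(frozen=True)
class APWaveform:
    """Action-potential template: baseline intensity, amplitude, onset delay,
    half-cosine rise time and the APD30/APD90 targets (all times ms)."""

    baseline: float = 100.0
    amplitude: float = 50.0
    delay_ms: float = 10.0
    rise_ms: float = 20.0
    apd30_ms: float = 200.0
    apd90_ms: float = 350.0

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.amplitude < 0:
            raise InputError("baseline must be > 0 and amplitude >= 0")
        if self.amplitude >= self.baseline:
            raise InputError("AP amplitude must stay below baseline intensity")
        if not 0 < self.apd30_ms < self.apd90_ms:
            raise ShapeInfeasibleError("need 0 < APD30 < APD90")
        self.shape_constants()  # validate feasibility eagerly

    def shape_constants(self) -> tuple[float, float]:
        """Stretched-exponential constants (tau_ms, power) hitting the APD
        targets, measured from the 50%-upstroke activation time."""
        d30 = self.apd30_ms - self.rise_ms / 2.0
        d90 = self.apd90_ms - self.rise_ms / 2.0
        if d30 <= 0:
            raise ShapeInfeasibleError("APD30 must exceed half the rise time")
        power = math.log(_LN_10 / _LN_07) / math.log(d90 / d30)
        if power < 0.5:
            raise ShapeInfeasibleError(
                "APD90/APD30 ratio too large for the stretched-exponential template"
            )
        tau = d30 / _LN_07 ** (1.0 / power)
        return tau, power


@dataclass(frozen=True)
class TransientWaveform:
    """Calcium / contraction template: half-cosine rise, exponential decay."""

    baseline: float = 100.0
    amplitude: float = 80.0
    delay_ms: float = 30.0
    rise_ms: float = 80.0
    tau_ms: float = 130.0

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.amplitude < 0:
            raise InputError("baseline must be > 0 and amplitude >= 0")
        if self.rise_ms <= 0 or self.tau_ms <= 0:
            raise InputError("rise and decay times must be positive")


def default_waveforms() -> dict[str, APWaveform | TransientWaveform]:
    """Template triple transient of a healthy paced hiPSC-CM culture."""
    return {
        "AP": APWaveform(),
        "Ca": TransientWaveform(baseline=100.0, amplitude=80.0, delay_ms=30.0,
                                rise_ms=80.0, tau_ms=130.0),
        "Co": TransientWaveform(baseline=5.0, amplitude=30.0, delay_ms=50.0,
                                rise_ms=120.0, tau_ms=140.0),
    }


# ---- event shapes ---------------------------------------------------------


def _ap_pulse(t_ms: np.ndarray, wp: APWaveform) -> np.ndarray:
    """Upright AP deflection (0 at baseline) at times ``t_ms`` after stimulus."""
    tau, power = wp.shape_constants()
    t = t_ms - wp.delay_ms
    out = np.zeros_like(t, dtype=float)
    rising = (t >= 0) & (t < wp.rise_ms)
    out[rising] = 0.5 * (1.0 - np.cos(math.pi * t[rising] / wp.rise_ms))
    falling = t >= wp.rise_ms
    out[falling] = np.exp(-(((t[falling] - wp.rise_ms) / tau) ** power))
    return wp.amplitude * out


def _transient_pulse(t_ms: np.ndarray, wp: TransientWaveform) -> np.ndarray:
    """Upright Ca/Co deflection at times ``t_ms`` after stimulus."""
    t = t_ms - wp.delay_ms
    out = np.zeros_like(t, dtype=float)
    rising = (t >= 0) & (t < wp.rise_ms)
    out[rising] = 0.5 * (1.0 - np.cos(math.pi * t[rising] / wp.rise_ms))
    falling = t >= wp.rise_ms
    out[falling] = np.exp(-(t[falling] - wp.rise_ms) / wp.tau_ms)
    return wp.amplitude * out


def _pulse(t_ms: np.ndarray, wp: APWaveform | TransientWaveform) -> np.ndarray:
    if isinstance(wp, APWaveform):
        return _ap_pulse(t_ms, wp)
    return _transient_pulse(t_ms, wp)


def _pulse_train(t_ms: np.ndarray, wp, pacing_hz: float) -> np.ndarray:
    period_ms = 1000.0 / pacing_hz
    n_stim = int(np.ceil(t_ms[-1] / period_ms)) + 1
    out = np.zeros_like(t_ms, dtype=float)
    for k in range(n_stim):
        out += _pulse(t_ms - k * period_ms, wp)
    return out


def simulate_event(channel: str, wp: APWaveform | TransientWaveform,
                   rate: float, duration_s: float | None = None) -> Trace:
    """One upright, baseline-anchored event sampled at ``rate``.

    The trace is ``baseline + pulse`` for every channel (already in the
    orientation the kinetics stage expects); ``simulate_recording`` emits
    the physical camera orientation instead (AP dims on depolarization).
    """
    if duration_s is None:
        duration_s = 1.0 / 1.2
    n = int(round(duration_s * rate))
    if n < 2:
        raise InputError("event duration too short for the sampling rate")
    t_ms = np.arange(n) * 1000.0 / rate
    return Trace(wp.baseline + _pulse(t_ms, wp), rate=rate, channel=channel)


def expected_kinetics(wps: Mapping[str, APWaveform | TransientWaveform]
                      ) -> KineticParameters:
    """Closed-form kinetic parameters the pipeline should recover.

    AP/Ca amplitudes are the ΔF/F values after cleaning (A/(B−A) for the
    inverted AP channel, A/B for Ca); the Co amplitude is in raw motion
    units.  Rise/peak times follow the half-cosine crossing geometry and the
    decay times equal τ·ln 2.
    """
    ap: APWaveform = wps["AP"]
    ca: TransientWaveform = wps["Ca"]
    co: TransientWaveform = wps["Co"]
    rise_frac = _RISE_T90 - _RISE_T10
    return KineticParameters(
        AP_amplitude=ap.amplitude / (ap.baseline - ap.amplitude),
        AP_t_rise=ap.rise_ms * rise_frac,
        AP_t_APD=ap.apd90_ms,
        AP_triangulation=ap.apd90_ms - ap.apd30_ms,
        Ca_amplitude=ca.amplitude / ca.baseline,
        Ca_t_to_peak=ca.rise_ms * (1.0 - _RISE_T10),
        Ca_t_decay=ca.tau_ms * math.log(2.0),
        Co_amplitude=co.amplitude,
        Co_t_contraction=co.rise_ms * (1.0 - _RISE_T10),
        Co_t_relaxation=co.tau_ms * math.log(2.0),
    )


# ---- MOA perturbations ----------------------------------------------------


def realize_directions(moa: MOA, rng: np.random.Generator,
                       table: HypothesisTable | None = None
                       ) -> dict[KineticParameter, Effect]:
    """Draw one concrete effect direction per parameter for a drug of ``moa``.

    Plain cells keep their direction; negated cells ("not up" etc.) draw
    uniformly among the admissible alternatives, honouring the table's
    "might be expected" semantics.
    """
    table = table or builtin_table()
    directions = {}
    for param in KineticParameter:
        cell = table.expected_effect(moa, param)
        if cell.is_negated:
            options = cell.admissible
            directions[param] = options[int(rng.integers(len(options)))]
        else:
            directions[param] = cell
    return directions


def _factor(direction: Effect, magnitude: float) -> float:
    if direction is Effect.UP:
        return 1.0 + magnitude
    if direction is Effect.DOWN:
        return 1.0 - magnitude
    return 1.0


def apply_directions(wps: Mapping[str, APWaveform | TransientWaveform],
                     directions: Mapping[KineticParameter, Effect],
                     magnitude: float
                     ) -> tuple[dict[str, APWaveform | TransientWaveform],
                                dict[KineticParameter, float]]:
    """Scale waveform parameters by the per-parameter direction factors."""
    if not 0 <= magnitude <= 0.5:
        raise InputError("effect magnitude must lie in [0, 0.5]")
    f = {p: _factor(directions[p], magnitude) for p in KineticParameter}
    ap: APWaveform = wps["AP"]
    ca: TransientWaveform = wps["Ca"]
    co: TransientWaveform = wps["Co"]
    new_apd90 = ap.apd90_ms * f[KineticParameter.AP_t_APD]
    new_tri = (ap.apd90_ms - ap.apd30_ms) * f[KineticParameter.AP_triangulation]
    new_ap = replace(
        ap,
        amplitude=ap.amplitude * f[KineticParameter.AP_amplitude],
        rise_ms=ap.rise_ms * f[KineticParameter.AP_t_rise],
        apd90_ms=new_apd90,
        apd30_ms=new_apd90 - new_tri,
    )
    new_ca = replace(
        ca,
        amplitude=ca.amplitude * f[KineticParameter.Ca_amplitude],
        rise_ms=ca.rise_ms * f[KineticParameter.Ca_t_to_peak],
        tau_ms=ca.tau_ms * f[KineticParameter.Ca_t_decay],
    )
    new_co = replace(
        co,
        amplitude=co.amplitude * f[KineticParameter.Co_amplitude],
        rise_ms=co.rise_ms * f[KineticParameter.Co_t_contraction],
        tau_ms=co.tau_ms * f[KineticParameter.Co_t_relaxation],
    )
    return {"AP": new_ap, "Ca": new_ca, "Co": new_co}, f


def apply_moa(wps: Mapping[str, APWaveform | TransientWaveform], moa: MOA,
              magnitude: float, rng: np.random.Generator,
              table: HypothesisTable | None = None
              ) -> tuple[dict[str, APWaveform | TransientWaveform],
                         dict[KineticParameter, float]]:
    """Perturb a waveform set per the hypotheses-table column of ``moa``.

    Returns the perturbed waveforms and the realized per-parameter factors
    (the exported ground truth).
    """
    directions = realize_directions(moa, rng, table)
    return apply_directions(wps, directions, magnitude)


# ---- full experiments -----------------------------------------------------


@dataclass(frozen=True)
class ExperimentDesign:
    """Plate design: drug, true MOA, dosing, replication and noise levels.

    ``magnitude`` is the effect size at the top concentration; intermediate
    doses follow a saturating (Hill-type, EC50 at the median concentration)
    scaling unless explicit ``magnitudes`` are given.  ``noise_sd`` is the
    additive photometric noise as a fraction of each channel's amplitude;
    ``well_variability`` and ``recording_jitter`` are lognormal sigmas of
    multiplicative biological variability at well and recording level.
    """

    drug: str = "drugA"
    moa: MOA | None = None
    concentrations: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0)
    magnitude: float = 0.3
    magnitudes: tuple[float, ...] | None = None
    wells_per_condition: int = 5
    areas_per_well: int = 3
    vehicle_wells: int = 5
    duration_s: float = 7.0
    pacing_hz: float = 1.2
    rate: float = 1000.0 / 3.0
    noise_sd: float = 0.05
    crosstalk_gain: float = 0.1
    well_variability: float = 0.05
    recording_jitter: float = 0.01
    events_to_average: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wells_per_condition < 1 or self.vehicle_wells < 1:
            raise InputError("need at least one well per condition")
        if self.areas_per_well < 1:
            raise InputError("need at least one area per well")
        if self.duration_s * self.pacing_hz < self.events_to_average + 1:
            raise InputError(
                "recording too short for the requested number of averaged events"
            )
        if self.magnitudes is not None and len(self.magnitudes) != len(self.concentrations):
            raise InputError("magnitudes must match concentrations one-to-one")
        if any(c <= 0 for c in self.concentrations):
            raise InputError("drug concentrations must be positive (vehicle is implicit)")

    def magnitudes_per_concentration(self) -> dict[float, float]:
        if self.magnitudes is not None:
            return dict(zip(self.concentrations, self.magnitudes))
        conc = np.asarray(sorted(self.concentrations), dtype=float)
        ec50 = float(np.median(conc))
        occupancy = conc / (conc + ec50)
        scaled = self.magnitude * occupancy / occupancy[-1]
        return dict(zip(conc.tolist(), scaled.tolist()))

    # -- flat-file round trip (used by the CLI) --

    def to_yaml_dict(self) -> dict:
        d = asdict(self)
        d["moa"] = self.moa.name if self.moa is not None else None
        d["concentrations"] = list(self.concentrations)
        d["magnitudes"] = list(self.magnitudes) if self.magnitudes else None
        return d

    @classmethod
    def from_yaml_dict(cls, d: Mapping) -> "ExperimentDesign":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown design key(s): {sorted(unknown)}")
        d = dict(d)
        if d.get("moa") is not None:
            try:
                d["moa"] = MOA[d["moa"]]
            except KeyError as exc:
                raise InputError(f"unknown MOA {d['moa']!r}") from exc
        if "concentrations" in d:
            d["concentrations"] = tuple(d["concentrations"])
        if d.get("magnitudes") is not None:
            d["magnitudes"] = tuple(d["magnitudes"])
        return cls(**d)


@dataclass(frozen=True)
class Recording:
    """One area measurement: the four raw channel traces plus its labels."""

    drug: str
    concentration_uM: float
    well: str
    area: int
    phase: str  # "baseline" | "post"
    traces: dict[str, Trace]


@dataclass(frozen=True)
class SimulatedDataset:
    design: ExperimentDesign
    recordings: list[Recording]
    ground_truth: dict

    def to_dir(self, path: str | Path) -> Path:
        """Materialize manifest.tsv, per-channel trace CSVs and ground truth."""
        root = Path(path)
        (root / "traces").mkdir(parents=True, exist_ok=True)
        rows = ["drug\tconcentration_uM\twell\tarea\tphase\tchannel\tfile"]
        for rec in self.recordings:
            for channel, trace in rec.traces.items():
                fname = (
                    f"traces/{rec.drug}_{rec.concentration_uM:g}_{rec.well}"
                    f"_a{rec.area}_{rec.phase}_{channel}.csv"
                )
                trace.to_csv(root / fname)
                rows.append(
                    f"{rec.drug}\t{rec.concentration_uM:g}\t{rec.well}"
                    f"\t{rec.area}\t{rec.phase}\t{channel}\t{fname}"
                )
        (root / "manifest.tsv").write_text("\n".join(rows) + "\n")
        (root / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True) + "\n"
        )
        return root


def _jitter_wps(wps: Mapping[str, APWaveform | TransientWaveform], sigma: float,
                rng: np.random.Generator) -> dict[str, APWaveform | TransientWaveform]:
    """Multiplicative lognormal jitter on amplitudes and time constants."""
    if sigma <= 0:
        return dict(wps)
    def g() -> float:
        return float(np.exp(rng.normal(0.0, sigma)))
    ap: APWaveform = wps["AP"]
    apd90 = ap.apd90_ms * g()
    tri = (ap.apd90_ms - ap.apd30_ms) * g()
    out: dict[str, APWaveform | TransientWaveform] = {
        "AP": replace(ap, amplitude=ap.amplitude * g(), rise_ms=ap.rise_ms * g(),
                      apd90_ms=apd90, apd30_ms=apd90 - tri)
    }
    for ch in ("Ca", "Co"):
        wp: TransientWaveform = wps[ch]
        out[ch] = replace(wp, amplitude=wp.amplitude * g(),
                          rise_ms=wp.rise_ms * g(), tau_ms=wp.tau_ms * g())
    return out


def simulate_recording(wps: Mapping[str, APWaveform | TransientWaveform],
                       design: ExperimentDesign,
                       rng: np.random.Generator,
                       ma_baseline: float = 100.0) -> dict[str, Trace]:
    """Render the four raw traces of one 7 s recording.

    The AP channel is emitted in camera orientation (intensity dips on
    depolarization); AP, Ca and MA share a multiplicative motion artifact
    proportional to the normalized contraction waveform.
    """
    n = int(round(design.duration_s * design.rate))
    t_ms = np.arange(n) * 1000.0 / design.rate
    ap, ca, co = wps["AP"], wps["Ca"], wps["Co"]
    ap_train = _pulse_train(t_ms, ap, design.pacing_hz)
    ca_train = _pulse_train(t_ms, ca, design.pacing_hz)
    co_train = _pulse_train(t_ms, co, design.pacing_hz)
    motion = co_train / co.amplitude if co.amplitude > 0 else np.zeros(n)
    artifact = 1.0 - design.crosstalk_gain * motion

    def noise(scale: float) -> np.ndarray:
        if design.noise_sd <= 0 or scale <= 0:
            return np.zeros(n)
        return rng.normal(0.0, design.noise_sd * scale, n)

    ap_raw = (ap.baseline - ap_train) * artifact + noise(ap.amplitude)
    ca_raw = (ca.baseline + ca_train) * artifact + noise(ca.amplitude)
    ma_raw = ma_baseline * artifact + noise(design.crosstalk_gain * ma_baseline)
    co_raw = co.baseline + co_train + noise(co.amplitude)
    return {
        "AP": Trace(ap_raw, rate=design.rate, channel="AP"),
        "Ca": Trace(ca_raw, rate=design.rate, channel="Ca"),
        "Co": Trace(co_raw, rate=design.rate, channel="Co"),
        "MA": Trace(ma_raw, rate=design.rate, channel="MA"),
    }


def simulate_experiment(design: ExperimentDesign,
                        table: HypothesisTable | None = None) -> SimulatedDataset:
    """Generate the full plate: vehicle wells plus every drug concentration.

    Every well gets a baseline and a post recording per area; vehicle wells
    differ between phases only by noise and recording jitter, drug wells are
    additionally perturbed along the realized hypotheses-table directions,
    scaled per concentration.  Fully deterministic under ``design.seed``.
    """
    table = table or builtin_table()
    rng = np.random.default_rng(design.seed)
    base = default_waveforms()
    if design.moa is not None:
        directions = realize_directions(design.moa, rng, table)
    else:
        directions = {p: Effect.SAME for p in KineticParameter}
    magnitudes = design.magnitudes_per_concentration()

    recordings: list[Recording] = []

    def record_pair(drug: str, conc: float, well: str, area: int,
                    well_wps, post_wps) -> None:
        for phase, wps in (("baseline", well_wps), ("post", post_wps)):
            rec_wps = _jitter_wps(wps, design.recording_jitter, rng)
            traces = simulate_recording(rec_wps, design, rng)
            recordings.append(Recording(drug, conc, well, area, phase, traces))

    for w in range(design.vehicle_wells):
        well_wps = _jitter_wps(base, design.well_variability, rng)
        for area in range(1, design.areas_per_well + 1):
            record_pair("vehicle", 0.0, f"V{w + 1}", area, well_wps, well_wps)

    factors_per_conc: dict[str, dict[str, float]] = {}
    for ci, conc in enumerate(sorted(design.concentrations)):
        mag = magnitudes[conc]
        for w in range(design.wells_per_condition):
            well_wps = _jitter_wps(base, design.well_variability, rng)
            post_wps, factors = apply_directions(well_wps, directions, mag)
            for area in range(1, design.areas_per_well + 1):
                record_pair(design.drug, conc, f"c{ci + 1}w{w + 1}", area,
                            well_wps, post_wps)
        factors_per_conc[f"{conc:g}"] = {p.name: f for p, f in factors.items()}

    ground_truth = {
        "drug": design.drug,
        "moa": design.moa.name if design.moa is not None else None,
        "seed": design.seed,
        "directions": {p.name: directions[p].value for p in KineticParameter},
        "factors_per_concentration": factors_per_conc,
    }
    return SimulatedDataset(design=design, recordings=recordings,
                            ground_truth=ground_truth)


# ---- frame rendering (exercises the ingest stage) -------------------------


def render_interleaved_frames(ap: Trace, ca: Trace, ma: Trace,
                              motion: np.ndarray | None = None,
                              shape: tuple[int, int] = (64, 64),
                              max_shift: int = 6) -> FrameStack:
    """Render traces as an interleaved AP/Ca/Co frame stack.

    AP and Ca become uniform frames whose mean equals the trace value; the
    Co channel is a periodic Gaussian blob whose mean intensity follows the
    MA trace and whose horizontal position translates with ``motion``
    (values in [0, 1], scaled to ``max_shift`` pixels), so the
    frame-difference contraction quantifier responds to it.
    """
    n = len(ap)
    if not (len(ca) == n == len(ma)):
        raise InputError("traces must have equal length")
    if motion is None:
        motion = np.zeros(n)
    motion = np.asarray(motion, dtype=float)
    if motion.size != n:
        raise InputError("motion profile must match trace length")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    blob = np.exp(-(((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / (2 * (h / 8.0) ** 2)))
    blob /= blob.mean()  # ROI mean 1; np.roll keeps the mean exact
    frames = np.empty((3 * n, h, w), dtype=float)
    shifts = np.round(motion * max_shift).astype(int)
    for i in range(n):
        frames[3 * i] = ap.values[i]
        frames[3 * i + 1] = ca.values[i]
        frames[3 * i + 2] = np.roll(blob, shifts[i], axis=1) * ma.values[i]
    return FrameStack(frames, rate=3.0 * ap.rate, layout=("AP", "Ca", "Co"))
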