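"""The cleaning chain: artifact correction, ΔF/F, filtering, event averaging."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttmkit.cleaning import (
    CleaningConfig,
    average_events,
    clean_recording,
    delta_f_over_f,
    detect_events,
    invert,
    moving_average,
    ratiometric_correct,
)
from ttmkit.errors import (
    InputError,
    InsufficientEventsError,
    InterpeakMismatchError,
    NumericDomainError,
)
from ttmkit.traces import Trace

RATE = 1000.0 / 3.0


def _trace(values, rate=RATE, channel="Ca"):
    return Trace(np.asarray(values, dtype=float), rate=rate, channel=channel)


finite_arrays = st.lists(
    st.floats(min_value=1.0, max_value=1e4, allow_nan=False), min_size=2, max_size=50
)


# ---- ratiometric correction ----------------------------------------------


def test_constant_ma_leaves_signal_untouched():
    sig = _trace([10, 12, 14, 12])
    ma = _trace([7, 7, 7, 7], channel="MA")
    assert np.allclose(ratiometric_correct(sig, ma).values, sig.values)


def test_pure_artifact_corrects_to_constant():
    ma = _trace([4, 5, 6, 5], channel="MA")
    out = ratiometric_correct(_trace(ma.values), ma)
    assert np.allclose(out.values, ma.values.mean())


def test_multiplicative_artifact_is_removed():
    rng = np.random.default_rng(1)
    clean = 100 + 10 * np.sin(np.linspace(0, 6 * np.pi, 300))
    artifact = 1 - 0.15 * (np.cos(np.linspace(0, 6 * np.pi, 300)) + 1) / 2
    sig = _trace(clean * artifact)
    ma = _trace(60.0 * artifact, channel="MA")
    corrected = ratiometric_correct(sig, ma)
    # equal up to the constant factor mean(artifact)
    ratio = corrected.values / clean
    assert np.ptp(ratio) < 1e-9


def test_nonpositive_ma_rejected():
    with pytest.raises(NumericDomainError):
        ratiometric_correct(_trace([1, 2, 3]), _trace([1, 0, 1], channel="MA"))


# ---- inversion and ΔF/F ---------------------------------------------------


def test_invert_reflects_about_mid_range():
    assert np.allclose(invert(_trace([5, 3, 5])).values, [3, 5, 3])
    assert np.allclose(invert(_trace([2, 2, 2])).values, [2, 2, 2])


@settings(derandomize=True, max_examples=50)
@given(values=finite_arrays)
def test_invert_is_an_involution(values):
    tr = _trace(values)
    assert np.allclose(invert(invert(tr)).values, tr.values)


def test_delta_f_over_f_definition():
    assert np.allclose(delta_f_over_f(_trace([100, 150, 100])).values, [0, 0.5, 0])
    assert np.allclose(delta_f_over_f(_trace([7, 7, 7])).values, 0.0)


@settings(derandomize=True, max_examples=50)
@given(values=finite_arrays, k=st.floats(min_value=0.1, max_value=100))
def test_delta_f_over_f_scale_invariant_with_zero_minimum(values, k):
    base = delta_f_over_f(_trace(values)).values
    scaled = delta_f_over_f(_trace(np.asarray(values) * k)).values
    assert base.min() == 0.0
    assert np.allclose(base, scaled, atol=1e-9)


def test_delta_f_over_f_requires_positive_minimum():
    with pytest.raises(NumericDomainError):
        delta_f_over_f(_trace([0.0, 1.0, 2.0]))


# ---- moving average -------------------------------------------------------


def test_moving_average_trailing_with_prefix_rule():
    assert np.allclose(moving_average(_trace([1, 3]), 2).values, [1, 2])
    assert np.allclose(moving_average(_trace([1, 3, 5, 7]), 1).values, [1, 3, 5, 7])
    assert np.allclose(moving_average(_trace([4, 4, 4]), 3).values, 4.0)


@settings(derandomize=True, max_examples=50)
@given(values=finite_arrays, window=st.integers(min_value=1, max_value=10))
def test_moving_average_never_increases_range(values, window):
    tr = _trace(values)
    if window > len(tr):
        return
    out = moving_average(tr, window).values
    tol = 1e-9 * max(abs(v) for v in values)
    assert out.max() - out.min() <= (tr.values.max() - tr.values.min()) + tol
    assert len(out) == len(tr)


def test_moving_average_window_exceeding_length_rejected():
    with pytest.raises(InputError):
        moving_average(_trace([1, 2, 3]), 4)


# ---- event detection and averaging ---------------------------------------


def _paced_trace(n=2333, period=278, onsets_shift=None, rate=RATE, amp=5.0):
    """Paced train of identical triangular events with known integer onsets.

    278-sample spacing is within 0.1% of the true 1.2 Hz period at 333.33
    samples/s, so the interpeak check passes while every event is an exact
    sample-aligned copy.
    """
    v = np.zeros(n)
    onsets = [20 + k * period for k in range(9)]
    if onsets_shift:
        for idx, delta in onsets_shift.items():
            onsets[idx] += delta
    for onset in onsets:
        i0 = int(round(onset))
        rise, fall = 20, 60
        for j in range(rise):
            if i0 + j < n:
                v[i0 + j] += amp * j / rise
        for j in range(fall):
            if i0 + rise + j < n:
                v[i0 + rise + j] += amp * (1 - j / fall)
    return _trace(v + 1.0, rate=rate)


def test_paced_recording_yields_eight_complete_events(ccfg):
    # 7 s at 1.2 Hz: 8.4 cycles, 8 of them complete
    events = detect_events(_paced_trace(), ccfg)
    assert len(events) == 8
    assert events.interpeak_ok
    gaps = np.diff(events.onsets)
    assert np.all(np.abs(gaps - events.period_samples) <= 1.0)


def test_displaced_event_fails_interpeak_check(ccfg):
    events = detect_events(_paced_trace(onsets_shift={4: 0.3 * RATE / 1.2}), ccfg)
    assert not events.interpeak_ok
    with pytest.raises(InterpeakMismatchError):
        average_events(_paced_trace(), events, ccfg)


def test_flat_trace_has_no_events(ccfg):
    with pytest.raises(InsufficientEventsError):
        detect_events(_trace(np.ones(2000)), ccfg)


def test_too_few_events_rejected(ccfg):
    # only ~3.4 pacing periods -> fewer than the 5 events to average
    with pytest.raises(InsufficientEventsError):
        detect_events(_paced_trace(n=800), ccfg)


def test_averaging_identical_events_returns_the_event(ccfg):
    tr = _paced_trace()
    events = detect_events(tr, ccfg)
    avg = average_events(tr, events, ccfg)
    first = tr.values[events.onsets[0]: events.onsets[0] + events.window]
    assert np.allclose(avg.values, first, atol=1e-9)
    assert len(avg) == events.window


def test_event_averaging_reduces_noise_like_sqrt_n(ccfg):
    """Averaging 5 noisy copies shrinks the residual sd by ~sqrt(5).

    Onsets are supplied exactly (sample-aligned copies) so the check
    isolates the averaging operator from detection jitter.
    """
    from ttmkit.cleaning import EventSet

    rng = np.random.default_rng(42)
    template = _paced_trace().values
    events = EventSet(onsets=np.array([22 + 278 * k for k in range(8)]),
                      window=277, period_samples=RATE / 1.2, interpeak_ok=True)
    clean = template[events.onsets[0]: events.onsets[0] + events.window]
    sigma = 0.05
    ratios = []
    for _ in range(100):
        noisy = _trace(template + rng.normal(0, sigma, template.size))
        avg = average_events(noisy, events, ccfg)
        ratios.append(np.std(avg.values - clean) / sigma)
    assert np.mean(ratios) == pytest.approx(1 / np.sqrt(5), rel=0.1)


def test_full_chain_produces_one_period_beats(noise_free_recording, ccfg):
    _, traces = noise_free_recording
    avg = clean_recording(traces, ccfg)
    period_samples = int(RATE / 1.2)
    for ch in ("AP", "Ca", "Co"):
        assert len(avg[ch]) == period_samples
        assert avg[ch].rate == pytest.approx(RATE)
    # AP and Ca are ΔF/F: dimensionless with zero-anchored baseline region
    assert avg["AP"].values.min() >= 0.0
    assert avg["Ca"].values.min() >= 0.0
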