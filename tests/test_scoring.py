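"""Probability-score algebra, hypothesis totals and MOA assignment."""
import math

import numpy as np
import pandas as pd
import pytest

from ttmkit.errors import (
    DegenerateVehicleError,
    InputError,
    MissingVehicleError,
    SchemaError,
)
from ttmkit.hypotheses import Effect, KineticParameter, MOA, builtin_table
from ttmkit.scoring import (
    SUBSETS,
    assign_moa,
    concentration_response,
    fit_vehicle,
    ps_down,
    ps_effect,
    ps_same,
    ps_up,
    score_hypotheses,
)

P = KineticParameter.Ca_amplitude


@pytest.fixture(scope="module")
def stats():
    # mean 1, sd 0.1 for every parameter
    rng = np.random.default_rng(0)
    return fit_vehicle({
        p: 1.0 + 0.1 * np.array([-1.3490, -0.2857, 0.3859, 0.9406, 0.3082])
        for p in KineticParameter
    })


@pytest.fixture(scope="module")
def unit_stats():
    """Exact mean 1, sd 1 (values -1, 0, 1, 2, 3 around 1)."""
    return fit_vehicle({p: [0.0, 1.0, 2.0] for p in KineticParameter})


def test_fit_vehicle_mean_and_sample_sd():
    s = fit_vehicle({p: [1.0, 2.0, 3.0] for p in KineticParameter})
    assert s.mean[P] == pytest.approx(2.0)
    assert s.sd[P] == pytest.approx(1.0)  # ddof = 1
    assert s.n == 3


def test_fit_vehicle_sem_mode():
    s = fit_vehicle({p: [1.0, 2.0, 3.0] for p in KineticParameter}, sd_mode="sem")
    assert s.sd[P] == pytest.approx(1.0 / math.sqrt(3))


def test_identical_vehicle_values_are_degenerate():
    with pytest.raises(DegenerateVehicleError):
        fit_vehicle({p: [1.0, 1.0, 1.0] for p in KineticParameter})


def test_fit_vehicle_recovers_known_population():
    rng = np.random.default_rng(11)
    mu, sigma, n = 1.0, 0.08, 25
    errs_mean, errs_sd = [], []
    for _ in range(50):
        sample = rng.normal(mu, sigma, n)
        s = fit_vehicle({p: sample for p in KineticParameter})
        errs_mean.append(abs(s.mean[P] - mu) / (sigma / math.sqrt(n)))
        errs_sd.append(abs(s.sd[P] - sigma) / (sigma / math.sqrt(2 * (n - 1))))
    # estimates land within 3 standard errors in essentially every draw
    assert np.quantile(errs_mean, 0.95) < 3
    assert np.quantile(errs_sd, 0.95) < 3


@pytest.mark.parametrize("offset_sd, expected", [
    (0.0, 10.0),
    (1.0, 10 * math.exp(-0.5)),    # ≈ 6.0653
    (2.0, 10 * math.exp(-2.0)),    # ≈ 1.3534
    (-1.0, 10 * math.exp(-0.5)),
])
def test_ps_same_is_scaled_gaussian(unit_stats, offset_sd, expected):
    x = unit_stats.mean[P] + offset_sd * unit_stats.sd[P]
    assert ps_same(x, unit_stats, P) == pytest.approx(expected, abs=1e-12)


def test_ps_up_piecewise(unit_stats):
    mu, sd = unit_stats.mean[P], unit_stats.sd[P]
    assert ps_up(mu, unit_stats, P) == 0.0
    assert ps_up(mu - sd, unit_stats, P) == 0.0
    assert ps_up(mu + sd, unit_stats, P) == pytest.approx(10 - 10 * math.exp(-0.5))


def test_ps_down_mirrors_ps_up(unit_stats):
    mu, sd = unit_stats.mean[P], unit_stats.sd[P]
    assert ps_down(mu, unit_stats, P) == 0.0
    assert ps_down(mu + sd, unit_stats, P) == 0.0
    assert ps_down(mu - 2 * sd, unit_stats, P) == pytest.approx(10 - 10 * math.exp(-2))


@pytest.mark.parametrize("effect, offset_sd, expected", [
    (Effect.NOT_DOWN, 0.0, 10.0),
    (Effect.NOT_SAME, 0.0, 0.0),
    (Effect.NOT_UP, 1.0, 10 * math.exp(-0.5)),
])
def test_negated_effects_score_the_complement(unit_stats, effect, offset_sd, expected):
    x = unit_stats.mean[P] + offset_sd * unit_stats.sd[P]
    assert ps_effect(x, unit_stats, P, effect) == pytest.approx(expected, abs=1e-9)


def test_plain_scores_partition_ten_pointwise(stats):
    rng = np.random.default_rng(5)
    for x in rng.normal(1.0, 0.5, 200):
        total = (ps_same(x, stats, P) + ps_up(x, stats, P) + ps_down(x, stats, P))
        assert total == pytest.approx(10.0, abs=1e-12)


def test_all_parameters_at_vehicle_means_scores_no_effect_100(stats):
    at_mean = {p: stats.mean[p] for p in KineticParameter}
    totals = score_hypotheses(at_mean, stats)
    assert totals[MOA.Co_same] == pytest.approx(100.0, abs=1e-9)
    assert assign_moa(totals).moa is MOA.Co_same
    # hand summation of the cAMP column at the mean: only AP_amplitude is "="
    assert totals[MOA.Co_plus_cAMP] == pytest.approx(10.0, abs=1e-9)
    ap_totals = score_hypotheses(at_mean, stats, subset="AP")
    assert ap_totals[MOA.Co_same] == pytest.approx(40.0, abs=1e-9)


def test_totals_respect_subset_bounds(stats):
    rng = np.random.default_rng(9)
    for _ in range(50):
        x = {p: float(rng.normal(1.0, 0.3)) for p in KineticParameter}
        for subset, members in SUBSETS.items():
            totals = score_hypotheses(x, stats, subset=subset)
            for t in totals.values():
                assert -1e-9 <= t <= 10.0 * len(members) + 1e-9


def test_ap_subset_cannot_separate_no_effect_from_myosin(stats):
    rng = np.random.default_rng(13)
    for _ in range(50):
        x = {p: float(rng.normal(1.0, 0.3)) for p in KineticParameter}
        totals = score_hypotheses(x, stats, subset="AP")
        assert totals[MOA.Co_same] == totals[MOA.Co_plus_Myosin]


def _bruteforce_totals(x, stats, subset="ALL"):
    """Independent re-evaluation: Gaussian density formula per cell, NOT
    cells as the sum of the two admissible plain scores."""
    table = builtin_table()

    def plain(effect, v, mu, sd):
        pdf = math.exp(-((v - mu) ** 2) / (2 * sd * sd))  # /PDF(mean)
        if effect is Effect.SAME:
            return 10 * pdf
        if effect is Effect.UP:
            return 0.0 if v < mu else 10 - 10 * pdf
        return 10 - 10 * pdf if v <= mu else 0.0

    totals = {}
    for moa in MOA:
        total = 0.0
        for p in SUBSETS[subset]:
            cell = table.expected_effect(moa, p)
            mu, sd = stats.mean[p], stats.sd[p]
            if cell.is_negated:
                total += sum(plain(e, x[p], mu, sd) for e in cell.admissible)
            else:
                total += plain(cell, x[p], mu, sd)
        totals[moa] = total
    return totals


def test_totals_match_bruteforce_oracle(stats):
    rng = np.random.default_rng(21)
    for _ in range(100):
        x = {p: float(rng.normal(1.0, 0.4)) for p in KineticParameter}
        mine = score_hypotheses(x, stats)
        ref = _bruteforce_totals(x, stats)
        for moa in MOA:
            assert mine[moa] == pytest.approx(ref[moa], abs=1e-9)


def test_assign_moa_argmax_and_ties():
    totals = {m: 50.0 for m in MOA}
    totals[MOA.Co_plus_Ca] = 95.0
    totals[MOA.Co_same] = 80.0
    a = assign_moa(totals)
    assert a.moa is MOA.Co_plus_Ca and not a.tie

    totals[MOA.Co_same] = 95.0 + 1e-9
    a = assign_moa(totals, tie_epsilon=1e-6)
    assert a.tie and set(a.tied) == {MOA.Co_plus_Ca, MOA.Co_same}


def test_missing_subset_parameter_rejected(stats):
    with pytest.raises(InputError):
        score_hypotheses({P: 1.0}, stats, subset="ALL")


# ---- concentration-response scoring ---------------------------------------


def _params_frame(rng, drug_shift=None, n_wells=5):
    rows = []
    for w in range(n_wells):
        row = {"drug": "vehicle", "concentration_uM": 0.0, "well": f"V{w}"}
        row.update({p.name: 1.0 + 0.02 * rng.standard_normal() for p in KineticParameter})
        rows.append(row)
    if drug_shift is not None:
        for conc in (1.0, 10.0):
            for w in range(n_wells):
                row = {"drug": "drugX", "concentration_uM": conc, "well": f"D{conc}-{w}"}
                for p in KineticParameter:
                    shift = drug_shift.get(p, 0.0) * (1.0 if conc == 10.0 else 0.5)
                    row[p.name] = 1.0 + shift + 0.02 * rng.standard_normal()
                rows.append(row)
    return pd.DataFrame(rows)


def test_concentration_response_recovers_calcium_mediated_increase():
    rng = np.random.default_rng(2)
    up = {KineticParameter.Ca_amplitude: 0.3, KineticParameter.Co_amplitude: 0.3,
          KineticParameter.AP_t_rise: -0.25, KineticParameter.AP_triangulation: -0.25,
          KineticParameter.AP_t_APD: -0.2, KineticParameter.Co_t_contraction: 0.1,
          KineticParameter.Ca_t_decay: 0.1}
    scores = concentration_response(_params_frame(rng, drug_shift=up))
    top = scores[(scores.drug == "drugX") & (scores.concentration_uM == 10.0)
                 & (scores.subset == "ALL")].iloc[0]
    assert top["assigned"] == "Co_plus_Ca"
    assert top[MOA.Co_plus_Ca.name] > top[MOA.Co_same.name]


def test_vehicle_scores_itself_as_no_effect():
    rng = np.random.default_rng(4)
    scores = concentration_response(_params_frame(rng))
    veh = scores[(scores.concentration_uM == 0.0) & (scores.subset == "ALL")].iloc[0]
    assert veh["assigned"] == "Co_same"
    # leave-one-out self-scoring: high total, clearly above all competitors
    assert veh[MOA.Co_same.name] > 50
    others = [veh[m.name] for m in MOA if m is not MOA.Co_same]
    assert veh[MOA.Co_same.name] > max(others)


def test_score_rows_cover_all_subsets():
    rng = np.random.default_rng(6)
    scores = concentration_response(_params_frame(rng))
    assert set(scores["subset"]) == set(SUBSETS)


def test_missing_vehicle_rows_rejected():
    rng = np.random.default_rng(8)
    df = _params_frame(rng, drug_shift={})
    with pytest.raises(MissingVehicleError):
        concentration_response(df[df.concentration_uM > 0])


def test_missing_parameter_column_rejected():
    rng = np.random.default_rng(10)
    df = _params_frame(rng).drop(columns=[KineticParameter.Ca_t_decay.name])
    with pytest.raises(SchemaError):
        concentration_response(df)
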