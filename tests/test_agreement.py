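import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actidiary.agreement import (
    GroupProfile,
    OptimizerConfig,
    ScalingResult,
    SubjectAgreement,
    TremorLabel,
    alpha_closed_form,
    apply_minmax,
    fit_alpha,
    fit_minmax,
    group_profile,
    normalize_panels,
    subject_rmse,
    summarize_rmse,
    tremor_split,
)
from actidiary.cohort_qc import CohortDay, CohortPanel
from actidiary.errors import DataError

DATE = dt.date(2020, 3, 2)


def profile(values):
    v = np.asarray(values, dtype=float)
    return GroupProfile(mean=v, sd=np.zeros_like(v), n_participants=np.ones(v.size, dtype=int))


def panel_from_arrays(per_participant, level="avg", sensor="ankle"):
    """per_participant: dict pid -> list of (enmo, met) day arrays."""
    participants = {}
    for pid, days in per_participant.items():
        recs = []
        for i, (e, m) in enumerate(days):
            e = np.asarray(e, float)
            m = np.asarray(m, float)
            mask = np.isfinite(e) & np.isfinite(m)
            recs.append(CohortDay(date=DATE + dt.timedelta(days=i), enmo=e, met=m, mask=mask))
        participants[pid] = recs
    n_slots = len(next(iter(per_participant.values()))[0][0])
    return CohortPanel(sensor_position=sensor, met_level=level, participants=participants, n_slots=n_slots)


class TestMinMax:
    def test_identity_scope(self):
        p = fit_minmax(np.array([0.0, 0.5, 1.0]))
        assert (p.observed_min, p.observed_max) == (0.0, 1.0)
        np.testing.assert_allclose(apply_minmax(np.array([0.0, 0.5, 1.0]), p), [0, 0.5, 1])

    def test_affine_scope(self):
        p = fit_minmax(np.array([2.0, 4.0]))
        np.testing.assert_allclose(apply_minmax(np.array([2.0, 3.0, 4.0]), p), [0, 0.5, 1])

    def test_degenerate_scope(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p = fit_minmax(np.array([0.3, 0.3]))
        assert p.degenerate
        np.testing.assert_array_equal(apply_minmax(np.array([0.3, 0.3]), p), [0.0, 0.0])

    def test_no_finite_values(self):
        with pytest.raises(DataError):
            fit_minmax(np.array([np.nan]))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=50))
    def test_normalized_values_in_unit_interval(self, values):
        import warnings

        arr = np.asarray(values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fit_minmax(arr)
        out = apply_minmax(arr, p)
        assert np.all(out >= -1e-12) and np.all(out <= 1 + 1e-12)


class TestGroupProfile:
    def test_two_participant_mean_sd(self):
        panel = panel_from_arrays({"P1": [([0.2, 0.2], [0, 0])], "P2": [([0.4, 0.4], [0, 0])]})
        prof = group_profile(panel, "enmo")
        assert prof.mean[0] == pytest.approx(0.3)
        assert prof.sd[0] == pytest.approx(np.std([0.2, 0.4], ddof=1))
        assert prof.sd[0] == pytest.approx(0.1414213562, abs=1e-9)

    def test_single_participant_sd_zero(self):
        panel = panel_from_arrays({"P1": [([0.2, 0.3], [0, 0])]})
        prof = group_profile(panel, "enmo")
        assert prof.sd[0] == 0.0

    def test_days_averaged_within_participant_first(self):
        panel = panel_from_arrays({"P1": [([0.1], [0]), ([0.3], [0])], "P2": [([0.4], [0])]})
        prof = group_profile(panel, "enmo")
        # P1 day-mean 0.2, then group mean of {0.2, 0.4}
        assert prof.mean[0] == pytest.approx(0.3)

    def test_single_stage_pooling_differs(self):
        panel = panel_from_arrays({"P1": [([0.1], [0]), ([0.3], [0])], "P2": [([0.4], [0])]})
        pooled = group_profile(panel, "enmo", two_stage=False)
        assert pooled.mean[0] == pytest.approx((0.1 + 0.3 + 0.4) / 3)

    def test_missing_slot_marked(self):
        panel = panel_from_arrays({"P1": [([0.1, np.nan], [0.2, np.nan])]})
        prof = group_profile(panel, "enmo")
        assert np.isnan(prof.mean[1])
        assert prof.n_participants[1] == 0


class TestAlphaFit:
    def test_closed_form_identity(self):
        e = profile([0.1, 0.5, 0.9])
        assert alpha_closed_form(e, e) == pytest.approx(1.0)

    def test_closed_form_half(self):
        e = profile([0.2, 0.6])
        m = profile([0.1, 0.3])
        assert alpha_closed_form(e, m) == pytest.approx(0.5)

    def test_closed_form_hand_example(self):
        # E=(1,2), M=(2,2): (2 + 4) / (1 + 4) = 1.2
        assert alpha_closed_form(profile([1.0, 2.0]), profile([2.0, 2.0])) == pytest.approx(1.2)

    def test_all_zero_enmo_errors(self):
        with pytest.raises(DataError):
            alpha_closed_form(profile([0.0, 0.0]), profile([1.0, 1.0]))

    def test_fit_identity_profiles(self):
        e = profile([0.1, 0.4, 0.8])
        res = fit_alpha(e, e)
        assert res.alpha == pytest.approx(1.0, abs=1e-6)
        assert res.fit_rmse == pytest.approx(0.0, abs=1e-8)
        assert res.converged

    def test_fit_matches_hand_example(self):
        res = fit_alpha(profile([1.0, 2.0]), profile([2.0, 2.0]))
        assert res.alpha == pytest.approx(1.2, abs=1e-6)
        assert res.init_alpha == pytest.approx(2.0 / 1.5)

    def test_fit_agrees_with_closed_form_sweep(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            e = profile(rng.uniform(0.01, 1.0, 36))
            m = profile(rng.uniform(0.0, 1.0, 36))
            assert abs(fit_alpha(e, m).alpha - alpha_closed_form(e, m)) < 1e-6

    def test_too_few_slots(self):
        with pytest.raises(DataError, match="at least 2"):
            fit_alpha(profile([1.0]), profile([1.0]))

    def test_slot_reordering_invariance(self):
        rng = np.random.default_rng(3)
        e = rng.uniform(0.1, 1, 36)
        m = rng.uniform(0, 1, 36)
        perm = rng.permutation(36)
        r1 = fit_alpha(profile(e), profile(m))
        r2 = fit_alpha(profile(e[perm]), profile(m[perm]))
        assert r1.alpha == pytest.approx(r2.alpha, abs=1e-6)
        assert r1.fit_rmse == pytest.approx(r2.fit_rmse, abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 20.0, allow_nan=False))
    def test_scaling_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        e = rng.uniform(0.05, 1.0, 12)
        m = rng.uniform(0.0, 1.0, 12)
        r1 = fit_alpha(profile(e), profile(m))
        r2 = fit_alpha(profile(c * e), profile(m))
        assert r2.alpha == pytest.approx(r1.alpha / c, rel=1e-4)
        assert r2.fit_rmse == pytest.approx(r1.fit_rmse, abs=1e-6)

    def test_custom_tolerances_respected(self):
        res = fit_alpha(profile([1.0, 2.0]), profile([2.0, 2.0]), OptimizerConfig(xatol=1e-10, fatol=1e-10))
        assert res.alpha == pytest.approx(1.2, abs=1e-8)


class TestSubjectRmse:
    def scaling(self, alpha, sensor="ankle", level="avg"):
        return ScalingResult(sensor, level, alpha, 0.0, alpha, True, 36)

    def test_exact_match_zero_rmse(self):
        e = np.linspace(0.1, 0.9, 10)
        panel = panel_from_arrays({"P1": [(e, 0.5 * e)]})
        out = subject_rmse(panel, self.scaling(0.5))
        assert out[0].rmse == pytest.approx(0.0, abs=1e-15)

    def test_constant_residual(self):
        e = np.zeros(8)
        m = np.full(8, 0.25)
        panel = panel_from_arrays({"P1": [(e, m)]})
        out = subject_rmse(panel, self.scaling(1.0))
        assert out[0].rmse == pytest.approx(0.25)
        assert out[0].n_epochs == 8

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        e = rng.uniform(0, 1, 20)
        m = rng.uniform(0, 1, 20)
        alpha = 0.7
        panel = panel_from_arrays({"P1": [(e, m)]})
        out = subject_rmse(panel, self.scaling(alpha))
        oracle = np.sqrt(np.mean((alpha * e - m) ** 2))
        assert abs(out[0].rmse - oracle) < 1e-12

    def test_pooled_vs_per_day(self):
        e1, m1 = np.array([0.5] * 4), np.array([0.1] * 4)
        e2, m2 = np.array([0.5] * 8), np.array([0.5] * 8)
        panel = panel_from_arrays({"P1": [(e1, m1), (e2, m2)]})
        pooled = subject_rmse(panel, self.scaling(1.0))[0].rmse
        per_day = subject_rmse(panel, self.scaling(1.0), per_day_average=True)[0].rmse
        assert pooled == pytest.approx(np.sqrt((4 * 0.16) / 12))
        assert per_day == pytest.approx(0.2)

    def test_wrong_scaling_rejected(self):
        panel = panel_from_arrays({"P1": [([0.1], [0.1])]})
        with pytest.raises(DataError, match="fitted for"):
            subject_rmse(panel, self.scaling(1.0, sensor="wrist"))


class TestSummaries:
    def agreements(self, values, sensor="ankle", level="avg"):
        return [SubjectAgreement(f"P{i}", sensor, level, v, 10) for i, v in enumerate(values)]

    def test_basic_median_min_max(self):
        out = summarize_rmse(self.agreements([0.1, 0.2, 0.3]))
        row = out.iloc[0]
        assert (row["median"], row["min"], row["max"]) == (0.2, 0.1, 0.3)

    def test_single_value(self):
        row = summarize_rmse(self.agreements([0.42])).iloc[0]
        assert row["median"] == row["min"] == row["max"] == 0.42

    def test_even_count_midpoint_median(self):
        row = summarize_rmse(self.agreements([0.1, 0.2, 0.3, 0.4])).iloc[0]
        assert row["median"] == pytest.approx(0.25)

    def test_tremor_boundaries(self):
        assert TremorLabel("P1", 0).group == "no_minimal"
        assert TremorLabel("P2", 1).group == "no_minimal"
        assert TremorLabel("P3", 2).group == "stronger"

    def test_tremor_split_layout(self):
        ag = []
        for sensor in ("wrist", "lower_back", "ankle"):
            for lvl in ("low", "avg", "high"):
                ag += [SubjectAgreement(f"P{i}", sensor, lvl, 0.1 * (i + 1), 5) for i in range(4)]
        labels = [TremorLabel(f"P{i}", 0 if i < 2 else 3) for i in range(4)]
        out = tremor_split(labels, ag)
        assert set(out["tremor_group"]) == {"no_minimal", "stronger"}
        assert set(out["sensor"]) == {"wrist", "lower_back"}
        assert len(out) == 12  # 2 strata x 2 positions x 3 levels

    def test_unlabeled_participant_errors(self):
        ag = [SubjectAgreement("P1", "wrist", "avg", 0.1, 5)]
        with pytest.raises(DataError, match="unlabeled"):
            tremor_split([], ag)


class TestNormalizePanels:
    def test_shared_met_transform_and_per_sensor_enmo(self):
        panels = {}
        for sensor, scale in (("ankle", 0.1), ("wrist", 0.2)):
            for lvl, ratio in (("low", 0.5), ("avg", 0.75), ("high", 1.0)):
                e = np.linspace(0, scale, 10)
                m = np.linspace(1.0, 1.0 + ratio * 7, 10)
                panels[(sensor, lvl)] = panel_from_arrays({"P1": [(e, m)]}, level=lvl, sensor=sensor)
        norm, params = normalize_panels(panels)
        assert params["enmo/ankle"].observed_max == pytest.approx(0.1)
        assert params["enmo/wrist"].observed_max == pytest.approx(0.2)
        assert params["met"].observed_max == pytest.approx(8.0)
        for panel in norm.values():
            assert panel.enmo_values().max() <= 1 + 1e-12
            assert panel.met_values().min() >= -1e-12
        # high level attains 1 under the shared transform, low does not
        assert norm[("ankle", "high")].met_values().max() == pytest.approx(1.0)
        assert norm[("ankle", "low")].met_values().max() < 0.6
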