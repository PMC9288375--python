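"""Stabilised IP weights: closed-form hand cases, guards, truncation, balance."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ipwmsm as m
from ipwmsm.weights import combine_weights


def _two_stratum_treatment():
    """P(L=1)=0.5, P(A=1|L=1)=0.8, P(A=1|L=0)=0.2, counts exact."""
    L = np.repeat([1, 0], 500)
    a0 = np.concatenate([np.repeat([1, 0], [400, 100]), np.repeat([1, 0], [100, 400])])
    X0 = pd.DataFrame({"L": L.astype(float)})
    X0.index.name = "patient_id"
    return X0, pd.Series(a0, index=X0.index)


class TestTreatmentWeights:
    def test_saturated_two_stratum_closed_form(self):
        X0, a0 = _two_stratum_treatment()
        sw = m.fit_baseline_treatment_weights(X0, a0)
        treated_l1 = sw[(a0 == 1) & (X0["L"] == 1)]
        assert treated_l1.iloc[0] == pytest.approx(0.5 / 0.8, rel=1e-6)
        untreated_l0 = sw[(a0 == 0) & (X0["L"] == 0)]
        assert untreated_l0.iloc[0] == pytest.approx(0.5 / 0.8, rel=1e-6)
        assert sw.mean() == pytest.approx(1.0, abs=1e-6)

    def test_randomised_treatment_gives_unit_weights(self):
        cfg = m.SimulationConfig(n_patients=4000, seed=31)
        cfg.treatment.coef = {}
        cohort = m.generate_cohort(cfg)
        eligible, _ = m.apply_eligibility(cohort)
        from ipwmsm.design import baseline_design

        pat = eligible.patients_frame().set_index("patient_id")
        a0 = pd.Series([1 if m.classify_exposure(r) == "initiator" else 0
                        for r in eligible.records], index=pat.index)
        sw = m.fit_baseline_treatment_weights(baseline_design(pat), a0)
        assert abs(sw.mean() - 1.0) < 0.02

    def test_single_group_raises(self):
        X0, a0 = _two_stratum_treatment()
        with pytest.raises(m.EstimationError):
            m.fit_baseline_treatment_weights(X0, pd.Series(1, index=a0.index))

    def test_perfect_separation_names_covariate(self):
        rng = np.random.default_rng(0)
        a0 = pd.Series(rng.integers(0, 2, 200))
        X0 = pd.DataFrame({"sep": a0.astype(float), "noise": rng.normal(size=200)})
        with pytest.raises(m.EstimationError, match="sep"):
            m.fit_baseline_treatment_weights(X0, a0)


class TestSelectionWeights:
    def _additive_case(self):
        # cells (A,L): survival 0.9, 0.75, 0.75, 0.5 - exactly additive in log-odds
        rows = []
        for a, l, surv in ((1, 0, 90), (1, 1, 75), (0, 0, 75), (0, 1, 50)):
            rows += [(a, l, 1)] * surv + [(a, l, 0)] * (100 - surv)
        df = pd.DataFrame(rows, columns=["a0", "L", "s"])
        X0 = df[["L"]].astype(float)
        X0.index.name = "patient_id"
        return X0, df["a0"], df["s"]

    def test_hand_computed_stratum_ratios(self):
        X0, a0, s = self._additive_case()
        sw = m.fit_baseline_selection_weights(X0, a0, s)
        surv = s == 1
        w_a1_l0 = sw[surv & (a0 == 1) & (X0["L"] == 0)].iloc[0]
        w_a0_l1 = sw[surv & (a0 == 0) & (X0["L"] == 1)].iloc[0]
        assert w_a1_l0 == pytest.approx(0.825 / 0.9, rel=1e-5)
        assert w_a0_l1 == pytest.approx(0.625 / 0.5, rel=1e-5)

    def test_no_losses_returns_unit_weights_with_warning(self):
        X0, a0, s = self._additive_case()
        with pytest.warns(UserWarning):
            sw = m.fit_baseline_selection_weights(X0, a0, pd.Series(1, index=a0.index))
        assert (sw == 1.0).all()

    def test_weighted_survivors_recover_cohort_prevalence(self):
        """Selection weighting undoes covariate-dependent 90-day loss."""
        cfg = m.SimulationConfig(n_patients=6000, seed=32)
        cohort = m.generate_cohort(cfg)
        eligible, _ = m.apply_eligibility(cohort)
        intervals = m.build_person_intervals(eligible, "ITT")
        ws = m.estimate_weights(eligible, intervals, "ITT")
        pat = eligible.patients_frame().set_index("patient_id")
        survivors = intervals.groupby("patient_id").first()
        w = ws.frame.groupby(intervals["patient_id"])["sw_select"].first() * \
            ws.frame.groupby(intervals["patient_id"])["sw_treat"].first()
        full_age = pat["age"].mean()
        naive_age = pat.loc[survivors.index, "age"].mean()
        weighted_age = np.average(pat.loc[survivors.index, "age"], weights=w)
        assert abs(weighted_age - full_age) < abs(naive_age - full_age)


def _censoring_hand_rows():
    """Two intervals, uncensored prob 0.9 (L=0) / 0.7 (L=1), symmetric in a0."""
    rows = []
    pid = 0
    for a in (0, 1):
        for l, n, c1, c2 in ((0, 100, 10, 9), (1, 100, 30, 21)):
            for i in range(n):
                cens1 = i < c1
                rows.append((pid, 1, a, int(cens1), l))
                if not cens1:
                    rows.append((pid, 2, a, int(i - c1 < c2), l))
                pid += 1
    df = pd.DataFrame(rows, columns=["patient_id", "t", "a0", "c_dt", "l_deter"])
    df["y"] = 0
    df["ac"] = 0
    return df.sort_values(["patient_id", "t"]).reset_index(drop=True)


class TestCensoringWeights:
    def test_hand_computed_lagged_cumulative_product(self):
        df = _censoring_hand_rows()
        X0 = pd.DataFrame(index=pd.RangeIndex(df["patient_id"].max() + 1))
        X0.index.name = "patient_id"
        sw = m.fit_followup_censoring_weights(df, X0, time_kind="none")
        p_num = 290 / 360
        first = sw[df["t"] == 1]
        assert np.allclose(first, 1.0)
        t2_l0 = sw[(df["t"] == 2) & (df["l_deter"] == 0)]
        t2_l1 = sw[(df["t"] == 2) & (df["l_deter"] == 1)]
        assert np.allclose(t2_l0, p_num / 0.9, rtol=1e-5)
        assert np.allclose(t2_l1, p_num / 0.7, rtol=1e-5)

    def test_no_censoring_returns_unit_weights(self):
        df = _censoring_hand_rows()
        df["c_dt"] = 0
        X0 = pd.DataFrame(index=pd.RangeIndex(df["patient_id"].max() + 1))
        X0.index.name = "patient_id"
        with pytest.warns(UserWarning):
            sw = m.fit_followup_censoring_weights(df, X0)
        assert (sw == 1.0).all()


class TestPersistenceWeights:
    def test_zero_deviation_group_gets_unit_weights(self):
        df = _censoring_hand_rows()
        df["ac"] = 0
        X0 = pd.DataFrame(index=pd.RangeIndex(df["patient_id"].max() + 1))
        X0.index.name = "patient_id"
        with pytest.warns(UserWarning):
            sw = m.fit_persistence_weights(df, X0)
        assert (sw == 1.0).all()

    def test_full_persistence_simulation_all_unit(self):
        cfg = m.recovery_config(n_patients=800, seed=33)
        cohort = m.generate_cohort(cfg)
        eligible, _ = m.apply_eligibility(cohort)
        pp = m.build_person_intervals(eligible, "PP")
        assert pp["ac"].sum() == 0
        with pytest.warns(UserWarning):
            ws = m.estimate_weights(eligible, pp, "PP")
        assert (ws.frame["sw_pers"] == 1.0).all()


class TestCombineWeights:
    IDX = pd.RangeIndex(1)

    def _series(self, v):
        return pd.Series([v], index=self.IDX)

    def test_level1_is_treatment_weight_exactly(self):
        out = combine_weights(1, "ITT", self._series(1.2))
        assert out.iloc[0] == 1.2

    def test_pp_level3_hand_product(self):
        out = combine_weights(3, "PP", self._series(1.2), self._series(0.9),
                              self._series(1.1), self._series(0.8))
        assert out.iloc[0] == pytest.approx(1.2 * 0.9 * 1.1 * 0.8)

    def test_unit_components_give_unit_product(self):
        one = self._series(1.0)
        assert combine_weights(3, "PP", one, one, one, one).iloc[0] == 1.0

    def test_persistence_in_itt_mode_raises(self):
        with pytest.raises(m.ConfigurationError):
            combine_weights(3, "ITT", self._series(1.0), self._series(1.0),
                            self._series(1.0), self._series(1.0))

    def test_missing_component_raises(self):
        with pytest.raises(m.ConfigurationError):
            combine_weights(2, "ITT", self._series(1.0))


class TestTruncation:
    def test_interior_weights_unchanged(self):
        w = np.linspace(0.5, 2.0, 1000)
        out, meta = m.truncate_weights(w, "fixed_0.1_10")
        assert np.array_equal(out, w)
        assert meta["n_truncated"] == 0

    def test_fixed_bounds_cap_extreme_value(self):
        w = np.concatenate([np.ones(99), [50.0]])
        out, _ = m.truncate_weights(w, "fixed_0.1_10")
        assert out.max() == 10.0

    def test_percentile_bounds_lie_between_order_statistics(self):
        rng = np.random.default_rng(8)
        w = rng.lognormal(0, 0.6, 1000)
        _, meta = m.truncate_weights(w, "pct_1_99")
        s = np.sort(w)
        assert s[9] <= meta["lower"] <= s[10]
        assert s[989] <= meta["upper"] <= s[990]

    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=50),
           st.sampled_from(["pct_1_99", "pct_05_995", "fixed_0.1_10", "none"]))
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_order_preserving(self, w, method):
        w = np.asarray(w)
        once, _ = m.truncate_weights(w, method)
        twice, _ = m.truncate_weights(once, method)
        # weakly order-preserving
        order = np.argsort(w, kind="stable")
        assert (np.diff(once[order]) >= -1e-12).all()
        if method == "none" or method.startswith("fixed"):
            assert np.allclose(once, twice)

    def test_empty_vector_raises(self):
        with pytest.raises(m.ConfigurationError):
            m.truncate_weights([], "none")


def test_treatment_weighting_improves_baseline_balance(small_eligible, small_intervals):
    """Weighting by sw_treat shrinks the SMD of configured confounders."""
    from ipwmsm.balance import weighted_smd_continuous, weighted_smd_binary

    ws = m.estimate_weights(small_eligible, small_intervals, "ITT")
    pat = small_eligible.patients_frame().set_index("patient_id")
    a0 = pd.Series([1 if m.classify_exposure(r) == "initiator" else 0
                    for r in small_eligible.records], index=pat.index)
    sw = ws.frame.groupby(small_intervals["patient_id"])["sw_treat"].first()
    pat = pat.loc[sw.index]
    a = a0.loc[sw.index].to_numpy()
    haem = (pat["subtype"] == "haemorrhagic").to_numpy(dtype=float)
    for x, fn in ((pat["age"].to_numpy(), weighted_smd_continuous),
                  (haem, weighted_smd_binary)):
        raw = fn(x, a)
        adj = fn(x, a, sw.to_numpy())
        assert adj < raw


def test_weight_diagnostics_report_components_and_products(small_eligible, small_intervals):
    ws = m.estimate_weights(small_eligible, small_intervals, "ITT")
    diag = ws.diagnostics().set_index("weight")
    for comp in ("sw_treat", "sw_select", "sw_cens", "w_model1", "w_model3"):
        assert comp in diag.index
    assert (diag["min"] > 0).all()
    assert abs(diag.loc["sw_treat", "mean"] - 1) < 0.05
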