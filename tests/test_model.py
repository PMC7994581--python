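"""Strategy-mixture trial model: selection, drifts, likelihood, preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from mathstrat.model import (
    IndividualParams,
    ItemParams,
    counting_drift_rate,
    memory_drift_rate,
    p_memory_retrieval,
    preprocess_trials,
    retrieval_use_summary,
    strategy_responsibility,
    trial_likelihood,
    TRIAL_COLUMNS,
)
from mathstrat.wiener import WienerParams, wiener_pdf

IP = IndividualParams(rho_i=0.5, delta_M=1.5, delta_C=2.0, alpha=1.5,
                      tau=0.3, tau_switch=0.4)
ITEM = ItemParams("3+4", n_k=3, rho_k=0.2)


class TestStrategySelection:
    @pytest.mark.parametrize("rho_i,rho_k,expected", [
        (0.0, 0.0, 0.5),
        (1.0, 0.0, 0.7310586),
        (0.0, 1.0, 0.2689414),
    ])
    def test_logistic_values(self, rho_i, rho_k, expected):
        assert p_memory_retrieval(rho_i, rho_k) == pytest.approx(expected, abs=1e-6)

    @given(st.floats(-500, 500), st.floats(-500, 500))
    @settings(max_examples=100, deadline=None)
    def test_memory_and_counting_probabilities_are_complementary(self, ri, rk):
        p = p_memory_retrieval(ri, rk)
        assert 0.0 <= p <= 1.0
        assert p + (1.0 - p) == pytest.approx(1.0)

    def test_overflow_safe(self):
        assert p_memory_retrieval(1e4, -1e4) == 1.0
        assert p_memory_retrieval(-1e4, 1e4) == 0.0


class TestDriftRates:
    def test_memory_drift_values(self):
        assert memory_drift_rate(1.0, 0.0) == pytest.approx(0.5)
        assert memory_drift_rate(2.0, 1.0) == pytest.approx(0.537883, abs=1e-6)
        assert memory_drift_rate(1.0, 800.0) == pytest.approx(0.0)

    def test_memory_drift_monotone_decreasing_in_difficulty(self):
        rks = np.linspace(-4, 4, 30)
        v = memory_drift_rate(1.7, rks)
        assert np.all(np.diff(v) < 0)
        assert np.all(v < 1.7)

    def test_counting_drift_values_and_monotonicity(self):
        assert counting_drift_rate(3.0, 3) == pytest.approx(1.0)
        assert counting_drift_rate(2.0, 1) == pytest.approx(2.0)
        v = counting_drift_rate(2.5, np.arange(2, 10))
        assert np.all(np.diff(v) < 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            memory_drift_rate(-1.0, 0.0)
        with pytest.raises(ValueError):
            counting_drift_rate(1.0, 0)


class TestTrialLikelihood:
    def test_pure_memory_limit_reduces_to_memory_density(self):
        ip = IndividualParams(rho_i=50.0, delta_M=1.5, delta_C=2.0, alpha=1.5,
                              tau=0.3, tau_switch=0.4)
        lik = trial_likelihood(0.9, True, ip, ITEM)
        wp = WienerParams(1.5, memory_drift_rate(1.5, ITEM.rho_k), 0.3)
        assert lik == pytest.approx(float(wiener_pdf(0.9, "correct", wp)), rel=1e-10)

    def test_counting_component_vanishes_before_switch_floor(self):
        # tau < rt <= tau + tau_switch: only memory can have finished
        rt = 0.5
        lik = trial_likelihood(rt, True, IP, ITEM)
        p_m = p_memory_retrieval(IP.rho_i, ITEM.rho_k)
        wp = WienerParams(IP.alpha, memory_drift_rate(IP.delta_M, ITEM.rho_k), IP.tau)
        assert lik == pytest.approx(p_m * float(wiener_pdf(rt, "correct", wp)), rel=1e-10)
        assert strategy_responsibility(rt, True, IP, ITEM) == pytest.approx(1.0)

    def test_missing_rt_returns_nan(self):
        assert np.isnan(trial_likelihood(float("nan"), True, IP, ITEM))
        assert np.isnan(strategy_responsibility(None, True, IP, ITEM))

    def test_joint_density_integrates_to_one(self):
        total = 0.0
        for correct in (True, False):
            mass, _ = quad(lambda t: trial_likelihood(t, correct, IP, ITEM),
                           IP.tau, 40.0, limit=300)
            total += mass
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_responsibilities_normalize(self):
        for rt in (0.8, 1.5, 3.0):
            r_mem = strategy_responsibility(rt, True, IP, ITEM)
            # complementary responsibility computed from the same mixture
            p_m = p_memory_retrieval(IP.rho_i, ITEM.rho_k)
            lik = trial_likelihood(rt, True, IP, ITEM)
            wp_c = WienerParams(IP.alpha, counting_drift_rate(IP.delta_C, ITEM.n_k),
                                IP.tau + IP.tau_switch)
            r_cnt = (1 - p_m) * float(wiener_pdf(rt, "correct", wp_c)) / lik
            assert r_mem + r_cnt == pytest.approx(1.0, rel=1e-9)

    def test_undefined_responsibility_when_both_components_zero(self):
        # rt below the non-decision floor of both strategies
        assert np.isnan(strategy_responsibility(0.2, True, IP, ITEM))


class TestLabeledSimulation:
    def test_responsibility_separates_true_strategies(self, small_cohort):
        trials = small_cohort["trials"]
        truth = small_cohort["truth"]
        pop = small_cohort["pop"]
        items = {r.item_id: ItemParams(r.item_id, int(r.n_k), float(r.rho_k))
                 for r in small_cohort["items"].itertuples()}
        resp, labels = [], []
        # generator emits observed and truth rows in lockstep
        merged = trials.join(truth[["true_memory"]])
        merged = merged.dropna(subset=["rt_seconds"])
        for row in merged.itertuples():
            p = pop.loc[row.participant_id]
            s = 1 if row.session == "post" else 0
            ip = IndividualParams(
                rho_i=p.rho_pre + s * p.d_rho,
                delta_M=p.delta_M_pre + s * p.d_delta_M,
                delta_C=p.delta_C_pre + s * p.d_delta_C,
                alpha=p.alpha_pre + s * p.d_alpha,
                tau=p.tau,
                tau_switch=max(p.tau_switch_pre + s * p.d_tau_switch, 0.0),
            )
            r = strategy_responsibility(row.rt_seconds, row.response_correct,
                                        ip, items[row.item_id])
            if np.isfinite(r):
                resp.append(r)
                labels.append(bool(row.true_memory))
        resp = np.asarray(resp)
        labels = np.asarray(labels)
        assert resp[labels].mean() > resp[~labels].mean()
        acc = ((resp > 0.5) == labels).mean()
        assert acc > 0.5


class TestRetrievalUseSummary:
    def _mk(self, rts, rho_i):
        trials = pd.DataFrame({
            "participant_id": "p0", "session": "pre", "item_id": "3+4",
            "addend_a": 3, "addend_b": 4, "equation_valid": True,
            "response_correct": True, "rt_seconds": rts,
        })
        params = {("p0", "pre"): IndividualParams(
            rho_i=rho_i, delta_M=1.5, delta_C=2.0, alpha=1.5, tau=0.3,
            tau_switch=0.4)}
        items = {"3+4": ITEM}
        return trials, params, items

    def test_all_memory_gives_one(self):
        trials, params, items = self._mk([0.8, 1.2, 0.9], rho_i=60.0)
        for method in ("mean", "classify"):
            s = retrieval_use_summary(trials, params, items, method=method)
            assert s.iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_all_counting_gives_zero(self):
        trials, params, items = self._mk([1.5, 2.0, 1.8], rho_i=-60.0)
        s = retrieval_use_summary(trials, params, items)
        assert s.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_no_valid_trials_gives_missing(self):
        trials, params, items = self._mk([np.nan, np.nan], rho_i=0.0)
        s = retrieval_use_summary(trials, params, items)
        assert np.isnan(s.iloc[0])


class TestPreprocessing:
    def _raw(self, rows):
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)

    def test_fast_rts_marked_missing_and_boundary_retained(self):
        raw = self._raw([
            ("p0", "pre", "3+4", 3, 4, True, True, 0.25),
            ("p0", "pre", "3+4", 3, 4, True, True, 0.300),
        ])
        out = preprocess_trials(raw)
        assert np.isnan(out.loc[0, "rt_seconds"])
        assert out.loc[1, "rt_seconds"] == 0.300
        assert out.attrs["exclusions"]["rt_marked_missing"] == 1

    def test_overlong_and_malformed_rows_dropped(self):
        raw = self._raw([
            ("p0", "pre", "3+4", 3, 4, True, True, 10.0),   # over deadline
            ("p0", "pre", "1+4", 1, 4, True, True, 1.0),    # operand 1 excluded
            ("p0", "pre", "3+4", 3, 4, True, True, -0.5),   # nonpositive RT
            ("p0", "pre", "5+6", 5, 6, True, False, 2.0),
        ])
        out = preprocess_trials(raw)
        assert len(out) == 1
        assert out.attrs["exclusions"]["rt_over_max"] == 1
        assert out.attrs["exclusions"]["malformed"] == 2

    def test_empty_table(self):
        out = preprocess_trials(self._raw([]))
        assert len(out) == 0
        assert out.attrs["exclusions"] == {
            "malformed": 0, "rt_over_max": 0, "rt_marked_missing": 0}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            preprocess_trials(pd.DataFrame({"participant_id": []}))
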