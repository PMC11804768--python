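import numpy as np
import pytest

from posturekit.clinimetrics import (
    MDC_FACTOR,
    MeasurementMatrix,
    agreement,
    anova_mean_squares,
    icc,
    icc_discrepancy_gate,
    reliability_report,
    sem_mdc,
)
from posturekit.errors import DataError, DegenerateDataError, ParameterError
from posturekit.reference import DEVICE_MEAN_ROWS, SEM_MDC_ROWS

from _oracles import anova_mean_squares_oracle, icc_oracle


class TestAnovaMeanSquares:
    def test_perfectly_repeated_columns(self):
        ms = anova_mean_squares(MeasurementMatrix([[1, 1], [2, 2], [3, 3]]))
        assert ms["MSE"] == 0.0 and ms["MSW"] == 0.0
        assert ms["MSR"] > 0

    def test_matches_statsmodels_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, (6, 2)) + rng.normal(0, 1, (6, 1))
            ms = anova_mean_squares(MeasurementMatrix(x))
            oracle = anova_mean_squares_oracle(x)
            for key in ("MSR", "MSC", "MSE", "MSW"):
                assert ms[key] == pytest.approx(oracle[key], abs=1e-10)

    def test_column_offset_changes_only_column_terms(self, rng):
        x = rng.normal(0, 1, (8, 2))
        y = x.copy()
        y[:, 1] += 5.0
        ms_x = anova_mean_squares(MeasurementMatrix(x))
        ms_y = anova_mean_squares(MeasurementMatrix(y))
        assert ms_y["MSR"] == pytest.approx(ms_x["MSR"], abs=1e-10)
        assert ms_y["MSE"] == pytest.approx(ms_x["MSE"], abs=1e-10)
        assert ms_y["MSC"] > ms_x["MSC"]
        assert ms_y["MSW"] > ms_x["MSW"]


class TestIcc:
    def test_perfect_repeats_give_unity(self):
        m = MeasurementMatrix([[1, 1], [2, 2], [3, 3], [4, 4]])
        for kind in ("oneway", "agreement", "consistency"):
            assert icc(m, kind).estimate == pytest.approx(1.0)

    def test_constant_bias_splits_consistency_and_agreement(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = MeasurementMatrix(np.column_stack([base, base + 1.0]))
        assert icc(m, "consistency").estimate == pytest.approx(1.0)
        r = icc(m, "agreement")
        assert r.estimate < 1.0
        # closed form with MSE = 0: MSR/(MSR + (k/n) MSC)
        ms = anova_mean_squares(m)
        expected = ms["MSR"] / (ms["MSR"] + (2 / 5) * ms["MSC"])
        assert r.estimate == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_oracle(self, rng):
        for _ in range(20):
            n, k = int(rng.integers(3, 30)), int(rng.integers(2, 5))
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, 1.5, (n, 1))
            m = MeasurementMatrix(x)
            oracle = icc_oracle(x)
            for kind in ("oneway", "agreement", "consistency"):
                assert icc(m, kind).estimate == pytest.approx(oracle[kind], abs=1e-10)

    def test_ci_brackets_estimate(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, (12, 2)) + rng.normal(0, 1, (12, 1))
            m = MeasurementMatrix(x)
            for kind in ("oneway", "agreement", "consistency"):
                r = icc(m, kind)
                assert r.ci95_low <= r.estimate <= r.ci95_high
                assert r.estimate <= 1.0

    def test_parameter_recovery_two_way_model(self):
        # true ICC(A,1) = 0.8 (variances 0.8 / 0.05 / 0.15); a quick
        # 200-replicate version of the full simulation check
        from posturekit.synthetic_data import simulate_two_way_matrix
        rng = np.random.default_rng(99)
        ests, cover = [], 0
        for _ in range(200):
            x = simulate_two_way_matrix(30, 2, 0.8, 0.05, 0.15, rng)
            r = icc(MeasurementMatrix(x), "agreement")
            ests.append(r.estimate)
            cover += r.ci95_low <= 0.8 <= r.ci95_high
        assert np.mean(ests) == pytest.approx(0.8, abs=0.03)
        assert 0.90 <= cover / 200 <= 0.99

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc(MeasurementMatrix(np.full((5, 2), 3.0)), "oneway")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            icc(MeasurementMatrix([[1, 2], [3, 4]]), "icc2k")


class TestSemMdc:
    def test_arithmetic(self):
        sem, mdc = sem_mdc(1.0, 0.75)
        assert sem == pytest.approx(0.5)
        assert mdc == pytest.approx(0.5 * MDC_FACTOR)
        assert mdc == pytest.approx(1.38593, abs=1e-5)

    def test_published_pathlength_value(self):
        # published SEM 3.303 cm for pathlength maps to the published MDC 9.155
        sem, mdc = sem_mdc(3.303 / np.sqrt(1 - 0.564), 0.564)
        assert mdc == pytest.approx(9.155, rel=2e-4)

    def test_perfect_reliability(self):
        assert sem_mdc(2.0, 1.0) == (0.0, 0.0)

    def test_out_of_range_icc_rejected(self):
        with pytest.raises(ParameterError):
            sem_mdc(1.0, 1.5)

    def test_negative_icc_warns(self):
        with pytest.warns(UserWarning, match="negative ICC"):
            sem, _ = sem_mdc(1.0, -0.2)
        assert sem > 1.0

    def test_all_published_sem_mdc_pairs_consistent(self):
        # printed SEM and MDC are independently rounded to 3 decimals, so
        # recomputing MDC from the printed SEM can differ by at most half
        # an ULP through the factor plus half an ULP of the printed MDC
        bound = 0.0005 * (1 + MDC_FACTOR) + 1e-12
        for *_, sem, mdc in SEM_MDC_ROWS:
            assert abs(sem * MDC_FACTOR - mdc) <= bound


class TestAgreement:
    def test_simple_difference(self):
        rep = agreement([10.0, 10.0], [8.0, 8.0])
        assert rep.absolute_mean == pytest.approx(2.0)
        assert rep.relative_mean_pct == pytest.approx(20.0)

    def test_self_agreement_is_zero(self, rng):
        ref = rng.uniform(1, 10, 20)
        rep = agreement(ref, ref)
        assert rep.absolute_mean == 0.0 and rep.absolute_sd == 0.0
        assert rep.relative_mean_pct == 0.0 and rep.relative_sd_pct == 0.0

    def test_published_group_means_reproduce_absolute_agreement(self):
        # mean-preserving two-subject vectors around the published device
        # means reproduce the published absolute agreement exactly
        for *_, idx_mean, ref_mean, published in DEVICE_MEAN_ROWS:
            rep = agreement([ref_mean - 0.1, ref_mean + 0.1],
                            [idx_mean - 0.1, idx_mean + 0.1])
            assert rep.absolute_mean == pytest.approx(published, abs=1.0001e-3)

    def test_near_zero_reference_excluded_from_relative(self):
        with pytest.warns(UserWarning, match="excluded"):
            rep = agreement([10.0, 0.0], [8.0, 1.0])
        assert rep.n_relative_excluded == 1
        assert rep.relative_mean_pct == pytest.approx(20.0)


class TestGateAndReport:
    def test_marginal_differences_gate_to_oneway(self):
        from posturekit.clinimetrics import IccResult
        res = [IccResult(k, e, e - 0.1, e + 0.1, 1, 1, 1, 0.5)
               for k, e in zip(("oneway", "agreement", "consistency"),
                               (0.731, 0.733, 0.734))]
        gate = icc_discrepancy_gate(res)
        assert gate.report_oneway_only

    def test_large_differences_flag_bias(self):
        from posturekit.clinimetrics import IccResult
        res = [IccResult(k, e, e - 0.1, e + 0.1, 1, 1, 1, 0.5)
               for k, e in zip(("oneway", "agreement", "consistency"),
                               (0.60, 0.75, 0.76))]
        gate = icc_discrepancy_gate(res)
        assert not gate.report_oneway_only
        assert "bias" in gate.flag

    def test_report_mdc_sem_ratio_exact(self, rng):
        s1 = rng.normal(10, 2, 25)
        s2 = s1 + rng.normal(0, 1, 25)
        rep = reliability_report(s1, s2)["metric"]
        assert rep.mdc / rep.sem == pytest.approx(MDC_FACTOR, rel=1e-12)
        assert rep.sem >= 0

    def test_listwise_drop_counts_subjects(self):
        s1 = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        s2 = np.array([1.1, 2.1, 3.0, 4.2, 5.1])
        m = MeasurementMatrix.from_sessions(s1, s2)
        assert m.n == 4 and m.n_dropped == 1

    def test_sd_source_session1(self, rng):
        s1 = rng.normal(10, 2, 25)
        s2 = s1 + rng.normal(0, 1, 25)
        rep_all = reliability_report(s1, s2, sd_source="all")["metric"]
        rep_s1 = reliability_report(s1, s2, sd_source="session1")["metric"]
        assert rep_s1.pooled_sd == pytest.approx(np.std(s1, ddof=1))
        assert rep_all.pooled_sd != rep_s1.pooled_sd

    def test_tiny_matrix_rejected(self):
        with pytest.raises(DataError):
            MeasurementMatrix([[1.0, 2.0]])
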