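import numpy as np
import pytest

from sersdx.correlation import (
    ImputationError,
    correlation_matrix,
    fit_linear,
    impute_tau,
    records_to_frame,
)
from sersdx.spectra_io import ClinicalRecord


def _rec(sid, t_tau=None, p_tau=None, **kw):
    defaults = dict(label="dementia", sex="F", age=75.0)
    defaults.update(kw)
    return ClinicalRecord(sid, t_tau=t_tau, p_tau=p_tau, **defaults)


TAU_LINE = (0.1134, 35.28)


class TestFitLinear:
    def test_identity_line(self):
        x = np.arange(10.0)
        fit = fit_linear(x, x)
        assert fit.slope == pytest.approx(1.0) and fit.intercept == pytest.approx(0.0)
        assert fit.r == pytest.approx(1.0)

    def test_tau_line_recovered_exactly(self):
        t = np.arange(100.0, 1000.0, 100.0)
        p = TAU_LINE[0] * t + TAU_LINE[1]
        fit = fit_linear(t, p)
        assert fit.slope == pytest.approx(TAU_LINE[0], abs=1e-9)
        assert fit.intercept == pytest.approx(TAU_LINE[1], abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.n == 9

    def test_noisy_line_recovery_within_3se(self):
        # OLS estimates should land within 3 standard errors of the truth
        # for the vast majority of repetitions
        slope, intercept, sd, n = 2.0, -1.0, 0.5, 50
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 10, n)
            y = slope * x + intercept + rng.normal(0, sd, n)
            fit = fit_linear(x, y)
            se = sd / (np.std(x) * np.sqrt(n))
            hits += abs(fit.slope - slope) < 3 * se
        assert hits >= 95

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1.0, 2.0], [1.0, 2.0])


class TestImputeTau:
    def _complete(self):
        t = np.arange(100.0, 1000.0, 100.0)
        return [
            _rec(f"C{i}", t_tau=float(ti), p_tau=TAU_LINE[0] * ti + TAU_LINE[1])
            for i, ti in enumerate(t)
        ]

    def test_missing_p_filled_from_line(self):
        records = self._complete() + [_rec("M", t_tau=500.0)]
        out, flags, excluded, fit = impute_tau(records)
        filled = next(r for r in out if r.sample_id == "M")
        assert filled.p_tau == pytest.approx(0.1134 * 500 + 35.28)  # 91.98
        assert flags == {"M": "p_tau"} and excluded == []

    def test_missing_t_filled_by_inversion(self):
        records = self._complete() + [_rec("M", p_tau=91.98)]
        out, flags, _, _ = impute_tau(records)
        filled = next(r for r in out if r.sample_id == "M")
        assert filled.t_tau == pytest.approx(500.0, abs=1e-6)
        assert flags == {"M": "t_tau"}

    def test_complete_records_unchanged(self):
        records = self._complete()
        out, flags, excluded, _ = impute_tau(records)
        assert out == records and flags == {} and excluded == []

    def test_both_missing_excluded(self):
        records = self._complete() + [_rec("R")]
        out, _, excluded, _ = impute_tau(records)
        assert excluded == ["R"]
        assert all(r.sample_id != "R" for r in out)

    def test_exclusion_list_is_exactly_both_missing_set(self):
        records = (
            self._complete()
            + [_rec("R"), _rec("Z"), _rec("M", t_tau=200.0), _rec("N", p_tau=60.0)]
        )
        _, flags, excluded, _ = impute_tau(records)
        assert sorted(excluded) == ["R", "Z"]
        assert sorted(flags) == ["M", "N"]

    def test_too_few_complete_cases_rejected(self):
        with pytest.raises(ImputationError):
            impute_tau([_rec("A", t_tau=1.0, p_tau=1.0), _rec("B")])


class TestCorrelationMatrix:
    def _frame(self, n=200, planted_r=-0.9, seed=0):
        # scores uniform; CDRSUM constructed for the planted correlation
        rng = np.random.default_rng(seed)
        score = rng.uniform(0, 100, n)
        noise_sd = np.std(score) * np.sqrt(1 / planted_r**2 - 1)
        cdr = -score + rng.normal(0, noise_sd, n)
        cdr = 18 * (cdr - cdr.min()) / np.ptp(cdr)
        records = [
            _rec(f"S{i}", t_tau=400.0 + i, p_tau=80.0 + i, cdr_sum=round(c * 2) / 2)
            for i, c in enumerate(cdr)
        ]
        return records_to_frame(records, {f"S{i}": s for i, s in enumerate(score)})

    def test_self_correlation_is_one(self):
        m = correlation_matrix(self._frame(), variables=("score", "cdr_sum"))
        assert m.lookup("score", "score") == 1.0

    def test_negated_variable_gives_minus_one(self):
        frame = self._frame()
        frame["neg"] = -frame["score"]
        m = correlation_matrix(frame, variables=("score", "neg"))
        assert m.lookup("score", "neg") == pytest.approx(-1.0)

    def test_planted_negative_correlation_recovered(self):
        m = correlation_matrix(self._frame(n=200, planted_r=-0.9))
        assert m.lookup("score", "cdr_sum") == pytest.approx(-0.9, abs=0.1)

    def test_symmetry_and_pairwise_counts(self):
        m = correlation_matrix(self._frame(n=50))
        np.testing.assert_allclose(m.r, m.r.T)
        i = m.variables.index("score")
        j = m.variables.index("cdr_sum")
        assert m.n_pairwise[i, j] == 50

    def test_zero_variance_flagged_not_dropped(self):
        frame = self._frame(n=30)
        frame["flat"] = 1.0
        m = correlation_matrix(frame, variables=("score", "cdr_sum", "flat"))
        k = m.variables.index("flat")
        assert np.all(np.isnan(m.r[k, :]))
        assert np.isfinite(m.lookup("score", "cdr_sum"))

    def test_fit_linear_r_matches_matrix_r(self):
        frame = self._frame(n=80)
        fit = fit_linear(frame["score"], frame["cdr_sum"])
        m = correlation_matrix(frame, variables=("score", "cdr_sum"))
        assert fit.r == pytest.approx(m.lookup("score", "cdr_sum"), abs=1e-12)

    def test_mcar_deletion_barely_shifts_correlations(self):
        # delete 15% of the tau values completely at random at n = 200:
        # pairwise-complete correlations move by < 0.05
        rng = np.random.default_rng(42)
        full = self._frame(n=200, seed=3)
        m_full = correlation_matrix(full, variables=("score", "cdr_sum", "t_tau"))
        holey = full.copy()
        mask = rng.random(len(holey)) < 0.15
        holey.loc[mask, "t_tau"] = np.nan
        m_holey = correlation_matrix(holey, variables=("score", "cdr_sum", "t_tau"))
        diff = np.abs(m_full.r - m_holey.r)
        assert np.nanmax(diff) < 0.05
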