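"""Histogram fitting, oligomer-state selection, and Monte Carlo envelopes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from stepstoich import (
    BinomialFDEEstimator,
    OligomerModel,
    OligomerModelSelector,
    StepHistogram,
    binomial_step_pmf,
    correct_contaminants,
    detected_step_distribution,
    fit_fde_binomial,
    fit_lambda_p,
    histogram_from_step_calls,
    monte_carlo_envelope,
    poisson_mean_scan,
    rmsd,
    select_oligomer,
)


def exact_histogram(m, lam, p, n=1000.0):
    frac = detected_step_distribution(OligomerModel(m=m, lam=lam, p=p))
    return StepHistogram(counts=frac * n)


class TestRmsd:
    def test_identical_vectors_zero(self):
        assert rmsd([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_arithmetic(self):
        assert rmsd([0.5, 0.5], [0.4, 0.6]) == pytest.approx(0.1)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st_h.permutations(list(range(5))))
    def test_permutation_invariance_within_bin_set(self, perm):
        obs = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        exp = np.array([0.15, 0.18, 0.27, 0.28, 0.12])
        base = rmsd(obs, exp)
        assert rmsd(obs[perm], exp[perm]) == pytest.approx(base)

    def test_empty_bin_set_rejected(self):
        with pytest.raises(ValueError):
            rmsd([0.5, 0.5], [0.4, 0.6], bins=[])


class TestContaminantCorrection:
    def test_subtraction(self):
        hist = StepHistogram(counts=np.array([10.0, 5, 3, 0, 0, 0, 0, 0]))
        out = correct_contaminants(hist, 4.0)
        assert out.counts[0] == 6.0 and out.corrected

    def test_floor_at_zero(self):
        hist = StepHistogram(counts=np.array([2.0, 5, 0, 0, 0, 0, 0, 0]))
        assert correct_contaminants(hist, 5.0).counts[0] == 0.0

    def test_rate_based_estimate(self):
        # 2.7% of 300 membrane-positive spots
        hist = StepHistogram(counts=np.array([20.0, 5, 3, 0, 0, 0, 0, 0]))
        out = correct_contaminants(hist, 0.027 * 300)
        assert out.counts[0] == pytest.approx(20 - 8.1)

    def test_double_correction_rejected(self):
        hist = StepHistogram(counts=np.array([10.0, 5, 0, 0, 0, 0, 0, 0]))
        once = correct_contaminants(hist, 1.0)
        with pytest.raises(ValueError):
            correct_contaminants(once, 1.0)


class TestFitLambdaP:
    def test_self_consistency_tetramer(self):
        fit = fit_lambda_p(exact_histogram(4, 1.0, 0.7), m=4)
        assert fit.lam == pytest.approx(1.0, abs=0.005)
        assert fit.p == pytest.approx(0.7, abs=0.001)
        assert fit.rmsd < 1e-6

    @pytest.mark.parametrize("m,lam,p", [(2, 3.2, 0.55), (4, 2.0, 0.4), (6, 0.8, 0.85)])
    def test_oracle_equivalence_grid(self, m, lam, p):
        fit = fit_lambda_p(exact_histogram(m, lam, p), m=m)
        assert fit.lam == pytest.approx(lam, abs=0.005)
        assert fit.p == pytest.approx(p, abs=0.001)
        assert fit.rmsd < 1e-6

    def test_monomer_family_identified_up_to_product(self):
        # for m=1 the step distribution depends on lam and p only through
        # lam*p (Poisson thinning), so only the product is recoverable
        fit = fit_lambda_p(exact_histogram(1, 0.5, 0.9), m=1)
        assert fit.lam * fit.p == pytest.approx(0.45, abs=0.005)
        assert fit.rmsd < 1e-6

    def test_pinned_fde_recovers_poisson_mean(self):
        fit = fit_lambda_p(exact_histogram(1, 3.0, 1.0), m=1, pin_p=1.0)
        assert fit.lam == pytest.approx(3.0, abs=0.05)
        assert fit.p == 1.0

    def test_degenerate_histogram_rejected(self):
        hist = StepHistogram(counts=np.zeros(8), n_censored=50)
        with pytest.raises(ValueError):
            fit_lambda_p(hist, m=4)

    def test_degenerate_extreme_bin_hits_boundary(self):
        # all mass in the top bin pushes the Poisson mean to the grid edge
        hist = StepHistogram(counts=np.array([0.0, 0, 0, 0, 0, 0, 0, 100]))
        fit = fit_lambda_p(hist, m=1)
        assert fit.at_boundary

    def test_poisson_mean_scan_minimum(self):
        scan = poisson_mean_scan(exact_histogram(1, 3.2, 1.0), m=1, p=1.0)
        best = scan.loc[scan["rmsd"].idxmin(), "lam"]
        assert best == pytest.approx(3.2, abs=0.05)


class TestBinomialFDE:
    def test_tetramer_standard_recovery(self):
        frac = binomial_step_pmf(4, 0.76)[1:]
        frac = frac / frac.sum()
        hist = StepHistogram(counts=np.concatenate([frac, np.zeros(4)]) * 1000)
        p_hat, r = fit_fde_binomial(hist, n_total=4)
        assert p_hat == pytest.approx(0.76, abs=0.01)
        assert r < 1e-6

    def test_dimer_standard_recovery(self):
        frac = binomial_step_pmf(2, 0.82)[1:]
        frac = frac / frac.sum()
        hist = StepHistogram(counts=np.concatenate([frac, np.zeros(6)]) * 1000)
        p_hat, _ = fit_fde_binomial(hist, n_total=2)
        assert p_hat == pytest.approx(0.82, abs=0.01)

    def test_all_mass_at_full_count_gives_unity(self):
        hist = StepHistogram(counts=np.array([0.0, 0, 0, 500, 0, 0, 0, 0]))
        p_hat, _ = fit_fde_binomial(hist, n_total=4)
        assert p_hat == pytest.approx(1.0, abs=1e-9)

    def test_estimator_wrapper(self):
        frac = binomial_step_pmf(4, 0.76)[1:]
        counts = np.concatenate([frac / frac.sum(), np.zeros(4)]) * 1000
        est = BinomialFDEEstimator(n_total=4).fit(counts)
        assert est.fde_ == pytest.approx(0.76, abs=0.01)


class TestSelectOligomer:
    def test_exact_tetramer_fractions_select_four(self):
        result = select_oligomer(exact_histogram(4, 1.0, 0.7))
        assert result.selected_m == 4
        assert result.rmsd < 1e-6

    def test_truncated_poisson_selects_monomer(self):
        result = select_oligomer(exact_histogram(1, 3.0, 1.0))
        assert result.selected_m == 1

    def test_rmsd_curve_has_minimum_at_truth(self):
        table = select_oligomer(exact_histogram(4, 1.0, 0.7)).per_m_table
        rmsds = table.set_index("m")["rmsd"]
        assert rmsds.idxmin() == 4
        # deviation grows away from the truth on both sides
        assert rmsds[3] > rmsds[4] and rmsds[5] > rmsds[4]

    def test_table_carries_empty_and_dark_fractions(self):
        table = select_oligomer(exact_histogram(4, 1.0, 0.7)).per_m_table
        row = table.set_index("m").loc[4]
        assert row["empty_fraction"] == pytest.approx(np.exp(-1), abs=0.01)
        assert row["dark_fraction"] > row["empty_fraction"]


class TestMonteCarloEnvelope:
    def test_binomial_sd_at_5000_trials(self):
        env = monte_carlo_envelope(np.array([0.5, 0.5]), n_spots=100, n_trials=5000, seed=1)
        expected = np.sqrt(0.25 / 100)
        np.testing.assert_allclose(env.per_bin_sd, expected, rtol=0.10)

    def test_zero_bin_has_zero_sd(self):
        env = monte_carlo_envelope(np.array([0.7, 0.0, 0.3]), n_spots=50, n_trials=2000, seed=2)
        assert env.per_bin_sd[1] == 0.0

    def test_fixed_seed_bit_identical(self):
        q = np.array([0.3, 0.5, 0.2])
        a = monte_carlo_envelope(q, 200, 1000, seed=7)
        b = monte_carlo_envelope(q, 200, 1000, seed=7)
        np.testing.assert_array_equal(a.per_bin_sd, b.per_bin_sd)


class TestHistogramFromCalls:
    def test_censored_and_uncallable_excluded(self):
        calls = pd.DataFrame(
            {
                "spot_id": list("abcdef"),
                "n_steps": pd.array([1, 4, 9, None, 4, 8], dtype="Int64"),
                "censored": [False, False, True, False, False, False],
                "quality": [1.0] * 6,
                "flag": ["", "", "", "uncallable", "", ""],
            }
        )
        hist = histogram_from_step_calls(calls, s_max=8)
        assert hist.counts[0] == 1 and hist.counts[3] == 2 and hist.counts[7] == 1
        assert hist.n_censored == 1
        assert hist.n_total_analyzed == 4


class TestSelectorEstimator:
    def test_sklearn_protocol_and_attributes(self):
        from sklearn.base import clone

        sel = OligomerModelSelector(m_values=(1, 2, 3, 4, 5))
        cloned = clone(sel)
        assert cloned.get_params()["m_values"] == (1, 2, 3, 4, 5)
        frac = detected_step_distribution(OligomerModel(m=4, lam=1.0, p=0.7))
        sel.fit(frac * 500)
        assert sel.selected_m_ == 4
        assert sel.predict() == 4
        assert sel.lambda_ == pytest.approx(1.0, abs=0.01)
        assert sel.fde_ == pytest.approx(0.7, abs=0.01)
        assert sel.predicted_fractions_.shape == (8,)

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            OligomerModelSelector().predict()
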