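"""Fixation-index estimators and the bias-corrected membership Z-test."""

import math

import numpy as np
import pytest

from sbcc import (
    CohortDesign,
    PanelSpec,
    PopulationStructure,
    compute_raf,
    estimate_fst,
    estimate_fst_pairing,
    evaluate_error_rates,
    expected_z,
    run_membership_test,
    sbcc_statistic,
    simulate_cohort,
    simulate_panel,
)
from sbcc.sbcc_test import fst_from_counts, pairing_fst_from_obs


class TestAnovaFst:
    def test_recovers_moderate_f(self):
        structure = PopulationStructure.uniform(4, 0.006)
        panel = simulate_panel(structure, PanelSpec.balanced(2000, 4), seed=21, o=5000)
        fst, se = estimate_fst(panel, return_se=True)
        assert abs(fst - 0.006) < 4 * se

    def test_null_panel_near_zero(self):
        structure = PopulationStructure.uniform(4, 0.0)
        panel = simulate_panel(structure, PanelSpec.balanced(2000, 4), seed=22, o=5000)
        fst, se = estimate_fst(panel, return_se=True)
        assert fst < 4 * se  # floored at zero, so one-sided

    def test_single_subpopulation_is_zero_by_convention(self):
        panel = simulate_panel(
            PopulationStructure.uniform(1, 0.0), PanelSpec(np.array([100])), seed=1, o=200
        )
        assert estimate_fst(panel) == 0.0

    def test_undersized_stratum_rejected(self):
        with pytest.raises(ValueError):
            fst_from_counts(np.zeros((2, 50)), np.array([1, 10]))

    def test_matrix_path_equals_count_path(self):
        """estimate_fst on a matrix is exactly fst_from_counts on its reduction."""
        structure = PopulationStructure.uniform(3, 0.01)
        panel = simulate_panel(structure, PanelSpec.balanced(300, 3), seed=4, o=500)
        ca, cn, co, un = panel.stratum_counts()
        direct, _ = fst_from_counts(ca + co, cn + un)
        assert estimate_fst(panel) == direct


class TestPairingFst:
    def test_unbiased_with_stated_variance(self, rng):
        """Mean recovers F; replicate variance is ~ 1/panel_size by design."""
        structure = PopulationStructure.uniform(2, 0.01)
        n_panel, reps = 500, 400
        vals = []
        for _ in range(reps):
            cohort_f = rng.uniform(0.05, 0.5, size=600)
            pf = np.empty((2, 600))
            for i in range(2):
                a = cohort_f * 0.99 / 0.01
                b = (1 - cohort_f) * 0.99 / 0.01
                pf[i] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
            idx = np.arange(n_panel) % 600
            sub = np.repeat([0, 1], n_panel // 2)
            g = rng.binomial(2, pf[sub, idx])
            vals.append(pairing_fst_from_obs(g, cohort_f[idx]))
        vals = np.asarray(vals)
        assert abs(vals.mean() - 0.01) < 4 * vals.std(ddof=1) / np.sqrt(reps)
        assert 0.6 < vals.var(ddof=1) * n_panel < 1.6

    def test_dosage_identity(self):
        """1[G=2] - p G + p^2 equals the centered allele product for each G."""
        p = 0.3
        for g, (x1, x2) in [(0, (0, 0)), (1, (0, 1)), (2, (1, 1))]:
            direct = (x1 - p) * (x2 - p) / (p * (1 - p))
            assert pairing_fst_from_obs(np.array([g]), np.array([p])) == pytest.approx(direct)

    def test_alignment_required(self):
        panel = simulate_panel(
            PopulationStructure.uniform(1, 0.0), PanelSpec(np.array([10])), 1, o=50
        )
        with pytest.raises(ValueError):
            estimate_fst_pairing(panel, np.full(40, 0.3))


class TestStatistic:
    def test_perfect_bias_cancellation(self):
        res = sbcc_statistic(rho_hat=math.sqrt(200) / 2 * 0.01, n=200, m=2,
                             f_tilde=0.01, o=5000, k=0.1)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5)
        assert not res.reject

    def test_perfect_panel_regime(self):
        """With k = 0 the Z of a member at rho = 1/sqrt(n) is sqrt(o/n)."""
        n, o = 1500, 50_000
        res = sbcc_statistic(1 / math.sqrt(n), n=n, m=1, f_tilde=0.0, o=o, k=0.0)
        assert res.z == pytest.approx(math.sqrt(o / n), rel=1e-12)
        assert res.z == pytest.approx(5.77, abs=0.01)
        assert res.reject

    def test_rejection_boundary(self):
        from scipy.stats import norm

        o, alpha = 50_000, 0.05
        rho = norm.ppf(1 - alpha) / math.sqrt(o)
        res = sbcc_statistic(rho, n=100, m=1, f_tilde=0.0, o=o, k=0.0, alpha=alpha)
        assert res.p_value == pytest.approx(alpha, abs=1e-12)
        assert not res.reject  # boundary is not strict exceedance

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            sbcc_statistic(0.1, 100, 2, 0.0, o=math.inf, k=0.0)


class TestMembershipTest:
    def _simulated_case(self, seed=31):
        design = CohortDesign.balanced(100, 2)
        structure = PopulationStructure.uniform(2, 0.005)
        cohort = simulate_cohort(design, structure, 2000, seed=seed)
        raf = compute_raf(cohort, 1.0)
        panel = simulate_panel(
            structure, PanelSpec.balanced(1000, 2), seed + 1,
            subpop_freqs=cohort.subpop_freqs, ancestral_freqs=cohort.ancestral_freqs,
        )
        return cohort, raf, panel, design

    def test_deterministic(self):
        cohort, raf, panel, design = self._simulated_case()
        a = run_membership_test(cohort.dosages[0], raf, panel, design)
        b = run_membership_test(cohort.dosages[0], raf, panel, design)
        assert a == b

    def test_member_detected_with_perfect_panel(self):
        """Unstratified n = 100 with o >> n and k -> 0: Z ~ sqrt(o/n) ~ 22."""
        from sbcc import empirical_cgr

        design = CohortDesign.balanced(100, 1)
        structure = PopulationStructure.uniform(1, 0.0)
        cohort = simulate_cohort(design, structure, 50_000, seed=41)
        raf = compute_raf(cohort, 1.0)
        rho = empirical_cgr(cohort.dosages[0], raf)
        res = sbcc_statistic(rho, n=100, m=1, f_tilde=0.0, o=50_000, k=0.0)
        mu = expected_z(100, 50_000, 0.0, 1)
        assert res.reject and abs(res.z - mu) < 4

    def test_snp_misalignment_reported(self):
        cohort, raf, panel, design = self._simulated_case()
        panel.snp_ids = np.array([f"other{j}" for j in range(panel.n_snps)])
        with pytest.raises(ValueError, match="not aligned"):
            run_membership_test(cohort.dosages[0], raf, panel, design)

    def test_unknown_modes_rejected(self):
        cohort, raf, panel, design = self._simulated_case()
        with pytest.raises(ValueError):
            run_membership_test(cohort.dosages[0], raf, panel, design, fst_method="x")
        with pytest.raises(ValueError):
            run_membership_test(cohort.dosages[0], raf, panel, design, ref_source="x")


class TestErrorRates:
    def test_null_calibration_without_drift(self):
        """F = 0: empirical type-I stays inside the binomial CI of alpha."""
        design = CohortDesign.balanced(200, 2)
        structure = PopulationStructure.uniform(2, 0.0)
        tab = evaluate_error_rates(
            design, structure, PanelSpec.balanced(2000, 2), o=2000,
            replicates=500, seed=5,
        )
        assert tab["type1_ci_low"][0] <= 0.05 <= tab["type1_ci_high"][0]

    def test_mean_z_matches_analytic_mu(self):
        """Replicate-mean Z of members agrees with mu = (1/sqrt(n)) / se."""
        design = CohortDesign.balanced(100, 2)
        structure = PopulationStructure.uniform(2, 0.002)
        tab = evaluate_error_rates(
            design, structure, PanelSpec.balanced(1000, 2), o=2000,
            replicates=400, seed=6,
        )
        mu = expected_z(100, 2000, 100 / 1000, 2)
        assert abs(tab["mean_z_in"][0] - mu) < 3 / np.sqrt(400)

    def test_out_of_cohort_mean_matches_closed_form(self):
        """Out-of-cohort same-subpopulation subjects carry only the drift signal.

        Their replicate-mean correlation equals the exact out-of-cohort
        moments (for which sqrt(n) F / m is the first-order description),
        so the oracle-corrected statistic is centered on the second-order
        remainder, not on a residual membership signal.
        """
        from sbcc import CgrQuery, cgr_exact

        design = CohortDesign.balanced(100, 2)
        structure = PopulationStructure.uniform(2, 0.002)
        tab, per = evaluate_error_rates(
            design, structure, PanelSpec.balanced(1000, 2), o=2000,
            replicates=300, seed=7, fst_method="oracle", details=True,
        )
        expected = cgr_exact(CgrQuery(design, structure, in_cohort=False))
        se = per["rho_out"].std(ddof=1) / np.sqrt(len(per))
        assert abs(per["rho_out"].mean() - expected) < 3 * se
        # oracle-corrected null statistic deviates from 0 only by the
        # exact-minus-Taylor remainder of the printed bias correction
        remainder = expected - math.sqrt(100) / 2 * 0.002
        rho0 = per["rho_out"] - math.sqrt(100) / 2 * 0.002
        assert abs(rho0.mean() - remainder) < 3 * se

    def test_power_monotone_in_panel_size(self):
        design = CohortDesign.balanced(200, 2)
        structure = PopulationStructure.uniform(2, 0.005)
        small = evaluate_error_rates(design, structure, PanelSpec.balanced(500, 2),
                                     o=2000, replicates=300, seed=8)
        large = evaluate_error_rates(design, structure, PanelSpec.balanced(5000, 2),
                                     o=2000, replicates=300, seed=8)
        se = np.sqrt(2 * 0.25 / 300)
        assert large["power"][0] >= small["power"][0] - 2 * se

    def test_seed_prefix_contract(self):
        """Extending the replicate count preserves the earlier replicates."""
        design = CohortDesign.balanced(50, 2)
        structure = PopulationStructure.uniform(2, 0.005)
        panel = PanelSpec.balanced(200, 2)
        _, a = evaluate_error_rates(design, structure, panel, o=200,
                                    replicates=20, seed=9, details=True)
        _, b = evaluate_error_rates(design, structure, panel, o=200,
                                    replicates=21, seed=9, details=True)
        assert np.array_equal(a["z_in"], b["z_in"][:20])
        assert np.array_equal(a["z_out"], b["z_out"][:20])

    def test_validation_errors(self):
        design = CohortDesign.balanced(50, 2)
        structure = PopulationStructure.uniform(2, 0.005)
        with pytest.raises(ValueError):
            evaluate_error_rates(design, structure, PanelSpec.balanced(200, 4),
                                 o=100, replicates=10)
        with pytest.raises(ValueError):
            evaluate_error_rates(design, structure, PanelSpec.balanced(200, 2),
                                 o=100, replicates=0)
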