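"""Core estimator: deltas, hybrid frequency, likelihood, grid search,
information matrix and its inverse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aimix
from aimix.errors import DegenerateInformationError, NoDataError, ValidationError
from aimix.mle import (
    InformationMatrix,
    compute_deltas,
    estimate_admixture,
    estimate_cohort,
    genotype_loglik,
    hybrid_freq,
    information_matrix,
    invert_information,
    simplex_grid,
    total_loglik,
)
from aimix.panel_io import ParentalPanel
from aimix.simulate import CohortTruth, PanelSimConfig, simulate_cohort, simulate_panel


def _random_panel(rng, n=8):
    f = rng.uniform(0.05, 0.95, size=(n, 3))
    return ParentalPanel(
        pd.DataFrame(
            {
                "snp_id": [f"r{i}" for i in range(n)],
                "chrom": ["1"] * n,
                "pos": np.arange(1, n + 1) * 10_000,
                "allele1": ["A"] * n,
                "allele2": ["G"] * n,
                "p_eu": f[:, 0],
                "p_ai": f[:, 1],
                "p_af": f[:, 2],
            }
        )
    )


class TestDeltas:
    def test_direct_subtraction(self, tiny_panel):
        d = compute_deltas(tiny_panel)
        # panel is sorted by (chrom, pos): rs1, rs2, rs3
        assert d.d1 == pytest.approx([0.8, 0.6, 0.0])
        assert d.d2 == pytest.approx([0.5, 0.4, 0.0])

    def test_allele2_deltas_are_negated(self, rng):
        panel = _random_panel(rng, 20)
        d = compute_deltas(panel)
        # allele-2 frequency differences computed from 1-p arithmetic
        q_delta1 = (1 - panel.p_eu) - (1 - panel.p_af)
        assert np.allclose(d.d3, q_delta1)
        assert np.allclose(d.d4, -d.d2)


class TestHybridFreq:
    def test_vertex_limits(self, tiny_panel):
        assert hybrid_freq(0, 0, 0.9, 0.6, 0.1) == pytest.approx(0.1)
        assert hybrid_freq(1, 0, 0.9, 0.6, 0.1) == pytest.approx(0.9)
        assert hybrid_freq(0, 1, 0.9, 0.6, 0.1) == pytest.approx(0.6)

    def test_direct_substitution(self):
        assert hybrid_freq(0.5, 0.25, 0.8, 0.6, 0.2) == pytest.approx(0.6)

    def test_equals_convex_combination(self, rng):
        panel = _random_panel(rng)
        m1, m2 = 0.3, 0.45
        p = hybrid_freq(m1, m2, panel.p_eu, panel.p_ai, panel.p_af, clamp=0.0)
        direct = m1 * panel.p_eu + m2 * panel.p_ai + (1 - m1 - m2) * panel.p_af
        assert np.allclose(p, direct)

    def test_outside_simplex_rejected(self):
        with pytest.raises(ValidationError):
            hybrid_freq(0.7, 0.5, 0.5, 0.5, 0.5)

    def test_clamping_keeps_logs_finite(self):
        p = hybrid_freq(1.0, 0.0, 1.0, 0.5, 0.0, clamp=1e-3)
        assert p == pytest.approx(1 - 1e-3)


class TestGenotypeLoglik:
    @pytest.mark.parametrize(
        "dosage, p_h, expected",
        [
            (1, 0.5, np.log(0.5)),
            (0, 0.3, np.log(0.49)),
            (2, 0.7, np.log(0.49)),
        ],
    )
    def test_hwe_values(self, dosage, p_h, expected):
        assert genotype_loglik(dosage, p_h) == pytest.approx(expected)

    def test_certain_genotype_near_zero(self):
        assert genotype_loglik(2, 1 - 1e-6) == pytest.approx(0.0, abs=1e-5)


class TestTotalLoglik:
    def test_additivity_and_missing(self, tiny_panel):
        d = np.array([1.0, np.nan, 0.0])
        p = hybrid_freq(0.2, 0.3, tiny_panel.p_eu, tiny_panel.p_ai, tiny_panel.p_af)
        expected = genotype_loglik(1, p[0]) + genotype_loglik(0, p[2])
        assert total_loglik(d, tiny_panel, 0.2, 0.3) == pytest.approx(expected)
        # dropping the missing SNP's value does not change anything
        d2 = np.array([1.0, 2.0, 0.0])
        assert total_loglik(d2, tiny_panel, 0.2, 0.3) == pytest.approx(
            expected + genotype_loglik(2, p[1])
        )

    def test_all_missing_errors(self, tiny_panel):
        with pytest.raises(NoDataError):
            total_loglik(np.array([np.nan] * 3), tiny_panel, 0.5, 0.2)


class TestEstimateAdmixture:
    def test_vertex_recovery_with_extreme_frequencies(self):
        n = 50
        panel = ParentalPanel(
            pd.DataFrame(
                {
                    "snp_id": [f"v{i}" for i in range(n)],
                    "chrom": ["1"] * n,
                    "pos": np.arange(1, n + 1) * 1000,
                    "allele1": ["A"] * n,
                    "allele2": ["G"] * n,
                    # two SNP types so the information matrix has full rank
                    "p_eu": [0.999, 0.001] * (n // 2),
                    "p_ai": [0.001, 0.999] * (n // 2),
                    "p_af": [0.3, 0.3] * (n // 2),
                }
            )
        )
        # genotypes of a pure-EU individual: allele 1 everywhere p_eu is high
        dosages = np.array([2.0, 0.0] * (n // 2))
        est = estimate_admixture(dosages, panel)
        assert (est.m1, est.m2, est.m3) == (1.0, 0.0, 0.0)

    def test_stochastic_recovery_within_3se(self, balanced_panel):
        truth = CohortTruth(np.array([[0.5, 0.3, 0.2]]))
        geno = simulate_cohort(balanced_panel, truth, seed=55)
        est = estimate_admixture(geno.dosages[0], balanced_panel)
        for m, mu, se in zip(est.proportions, (0.5, 0.3, 0.2), est.standard_errors):
            assert abs(m - mu) < 3 * se

    def test_simplex_closure_and_variance_identities(self, small_panel, rng):
        truth = CohortTruth(rng.dirichlet((1, 1, 1), size=5))
        geno = simulate_cohort(small_panel, truth, seed=9)
        for est in estimate_cohort(geno, grid_step=0.001):
            assert est.m1 + est.m2 + est.m3 == pytest.approx(1.0, abs=1e-12)
            assert 0 <= min(est.m1, est.m2, est.m3)
            assert est.v_m3 == pytest.approx(
                est.v_m1 + est.v_m2 + 2 * est.cov_m1m2, rel=1e-9, abs=1e-12
            )
            assert est.se_m1 == pytest.approx(np.sqrt(est.v_m1))

    def test_permutation_invariance(self, small_panel, rng):
        truth = CohortTruth(np.array([[0.4, 0.4, 0.2]]))
        geno = simulate_cohort(small_panel, truth, seed=10)
        est = estimate_admixture(geno.dosages[0], small_panel)
        perm = rng.permutation(small_panel.G)
        shuffled = ParentalPanel(small_panel.df.iloc[perm].reset_index(drop=True))
        # align dosages to the shuffled panel's (re-sorted) row order
        pos = pd.Index(small_panel.snp_ids).get_indexer(shuffled.snp_ids)
        est2 = estimate_admixture(geno.dosages[0][pos], shuffled)
        assert (est.m1, est.m2) == (est2.m1, est2.m2)
        assert est.se_m1 == pytest.approx(est2.se_m1)

    def test_tie_break_smallest_m1_then_m2(self):
        # one completely uninformative SNP: every grid point ties
        panel = ParentalPanel(
            pd.DataFrame(
                {
                    "snp_id": ["u"], "chrom": ["1"], "pos": [100],
                    "allele1": ["A"], "allele2": ["G"],
                    "p_eu": [0.5], "p_ai": [0.5], "p_af": [0.5],
                }
            )
        )
        est = estimate_admixture(
            np.array([1.0]), panel, grid_step=0.01, mode="exact-grid",
            on_degenerate="nan",
        )
        assert (est.m1, est.m2) == (0.0, 0.0)

    def test_no_data_errors(self, tiny_panel):
        with pytest.raises(NoDataError):
            estimate_admixture(np.array([np.nan] * 3), tiny_panel)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_coarse_to_fine_equals_exact_grid(self, seed):
        rng = np.random.default_rng(seed)
        panel = _random_panel(rng, n=6)
        truth = CohortTruth(rng.dirichlet((1, 1, 1))[None, :])
        geno = simulate_cohort(panel, truth, seed=seed + 1)
        fast = estimate_admixture(geno.dosages[0], panel, mode="coarse-to-fine",
                                  on_degenerate="nan")
        exact = estimate_admixture(geno.dosages[0], panel, mode="exact-grid",
                                   on_degenerate="nan")
        assert (fast.m1, fast.m2) == (exact.m1, exact.m2)


class TestInformationMatrix:
    def test_uninformative_snp_contributes_zero(self):
        panel = ParentalPanel(
            pd.DataFrame(
                {
                    "snp_id": ["u", "v"], "chrom": ["1", "1"], "pos": [1, 1_000_000],
                    "allele1": ["A", "A"], "allele2": ["G", "G"],
                    "p_eu": [0.4, 0.9], "p_ai": [0.4, 0.2], "p_af": [0.4, 0.5],
                }
            )
        )
        both = information_matrix(np.array([1.0, 1.0]), panel, 0.3, 0.3)
        only_v = information_matrix(np.array([np.nan, 1.0]), panel, 0.3, 0.3)
        assert both.i_m1 == pytest.approx(only_v.i_m1)
        assert both.i_m1m2 == pytest.approx(only_v.i_m1m2)

    def test_single_snp_closed_form(self):
        # delta1 = 0.5, delta2 = 0, P = 0.5 -> I_m1 = 2*0.25/0.25 = 2
        panel = ParentalPanel(
            pd.DataFrame(
                {
                    "snp_id": ["s"], "chrom": ["1"], "pos": [1],
                    "allele1": ["A"], "allele2": ["G"],
                    "p_eu": [0.75], "p_ai": [0.25], "p_af": [0.25],
                }
            )
        )
        info = information_matrix(np.array([1.0]), panel, 0.5, 0.25)
        assert info.i_m1 == pytest.approx(2.0)
        assert info.i_m2 == pytest.approx(0.0)
        assert info.i_m1m2 == pytest.approx(0.0)

    def test_matches_numerical_hessian_of_expected_loglik(self, rng):
        panel = _random_panel(rng, n=10)
        for _ in range(5):
            m = rng.dirichlet((2, 2, 2))
            m1, m2 = float(m[0]), float(m[1])
            info = information_matrix(np.ones(panel.G), panel, m1, m2, clamp=0.0)
            num = _numerical_expected_hessian(panel, m1, m2)
            assert info.i_m1 == pytest.approx(num[0, 0], rel=1e-4)
            assert info.i_m2 == pytest.approx(num[1, 1], rel=1e-4)
            assert info.i_m1m2 == pytest.approx(num[0, 1], rel=1e-4)

    def test_observed_information_matches_fisher_in_expectation(self, small_panel):
        # E[dosage] = 2P, so observed info at the truth averages to expected info
        truth = CohortTruth(np.array([[0.4, 0.35, 0.25]] * 2000))
        geno = simulate_cohort(small_panel, truth, seed=42)
        exp = information_matrix(geno.dosages[0], small_panel, 0.4, 0.35)
        obs = [
            information_matrix(geno.dosages[i], small_panel, 0.4, 0.35, kind="observed").i_m1
            for i in range(2000)
        ]
        assert np.mean(obs) == pytest.approx(exp.i_m1, rel=0.05)

    def test_monotone_information(self, rng):
        panel = _random_panel(rng, n=12)
        d = np.ones(panel.G)
        full = information_matrix(d, panel, 0.3, 0.3)
        d_less = d.copy()
        d_less[0] = np.nan
        less = information_matrix(d_less, panel, 0.3, 0.3)
        assert full.i_m1 >= less.i_m1
        assert full.i_m2 >= less.i_m2


def _numerical_expected_hessian(panel, m1, m2, h=1e-4):
    """Central finite differences of the expected log-likelihood, negated.

    Independent oracle: E[l(a, b)] = sum_g 2P(m) ln P(a,b) + (2-2P(m)) ln(1-P(a,b)),
    evaluated with plain Python floats per SNP.
    """
    pe, pa, pf = panel.p_eu, panel.p_ai, panel.p_af

    def expected_ll(a, b):
        total = 0.0
        for g in range(panel.G):
            P0 = pf[g] + m1 * (pe[g] - pf[g]) + m2 * (pa[g] - pf[g])
            P = pf[g] + a * (pe[g] - pf[g]) + b * (pa[g] - pf[g])
            total += 2 * P0 * np.log(P) + (2 - 2 * P0) * np.log(1 - P)
        return total

    f = expected_ll
    d11 = (f(m1 + h, m2) - 2 * f(m1, m2) + f(m1 - h, m2)) / h**2
    d22 = (f(m1, m2 + h) - 2 * f(m1, m2) + f(m1, m2 - h)) / h**2
    d12 = (
        f(m1 + h, m2 + h) - f(m1 + h, m2 - h) - f(m1 - h, m2 + h) + f(m1 - h, m2 - h)
    ) / (4 * h**2)
    return -np.array([[d11, d12], [d12, d22]])


class TestInvertInformation:
    @pytest.mark.parametrize(
        "i1, i2, i12, v1, v2, cov",
        [
            (100.0, 100.0, 0.0, 0.01, 0.01, 0.0),
            (4.0, 1.0, 0.0, 0.25, 1.0, 0.0),
        ],
    )
    def test_diagonal_inverse(self, i1, i2, i12, v1, v2, cov):
        out = invert_information(InformationMatrix(i1, i2, i12))
        assert out["v_m1"] == pytest.approx(v1)
        assert out["v_m2"] == pytest.approx(v2)
        assert out["cov_m1m2"] == pytest.approx(cov)
        assert out["v_m3"] == pytest.approx(v1 + v2 + 2 * cov)
        assert out["se_m1"] == pytest.approx(np.sqrt(v1))

    def test_third_component_variance_identity(self):
        out = invert_information(InformationMatrix(100.0, 100.0, 0.0))
        assert out["se_m3"] == pytest.approx(np.sqrt(0.02))

    def test_singular_matrix_raises(self):
        with pytest.raises(DegenerateInformationError):
            invert_information(InformationMatrix(1.0, 1.0, 1.0))

    def test_grid_is_restricted_to_simplex(self):
        m1s, m2s = simplex_grid(0.1)
        assert len(m1s) == 66  # 11 + 10 + ... + 1
        assert (m1s + m2s <= 1.0 + 1e-12).all()
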