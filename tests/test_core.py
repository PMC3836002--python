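"""Unit and property tests for the component and combined statistics."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportions_ztest

from popfam import (
    MendelianError,
    MixedDataset,
    TrioRecord,
    compute_tau,
    compute_weight,
    count_transmissions,
    popfam_stat,
    popfam_test,
    popfam_test_batch,
    sigma2_hwe,
    sigma2_mom,
    trend_stat,
    wald_stat,
)
from popfam.simulate import simulate_null_batch

from .oracles import phase_enumeration


class TestCountTransmissions:
    @pytest.mark.parametrize(
        "trio,expected",
        [((1, 0, 1), (1, 1)), ((2, 2, 2), (0, 0)), ((1, 1, 1), (2, 1)),
         ((0, 1, 0), (1, 0)), ((2, 1, 2), (1, 1))],
    )
    def test_examples(self, trio, expected):
        assert count_transmissions(*trio) == expected

    @pytest.mark.parametrize("trio", [(0, 0, 1), (2, 2, 1), (0, 2, 0), (0, 2, 2)])
    def test_mendelian_errors(self, trio):
        with pytest.raises(MendelianError):
            count_transmissions(*trio)

    def test_exhaustive_against_phase_enumeration(self):
        """All 27 genotype triples agree with brute-force phase counting."""
        for f, m, c in product(range(3), repeat=3):
            phases = phase_enumeration(f, m, c)
            if not phases:
                with pytest.raises(MendelianError):
                    count_transmissions(f, m, c)
                continue
            assert len(set(phases)) == 1, "t must be phase-invariant"
            assert count_transmissions(f, m, c) == phases[0]
            assert TrioRecord(f, m, c).t == phases[0][1]

    def test_bad_genotype_rejected(self):
        with pytest.raises(ValueError):
            count_transmissions(3, 0, 0)


class TestVarianceEstimators:
    def test_sigma2_hwe_values(self):
        assert sigma2_hwe(0.5) == 0.5
        assert sigma2_hwe(0.2) == pytest.approx(0.32)
        assert sigma2_hwe(0.0) == 0.0

    def test_sigma2_mom_matches_sample_variance(self):
        # {2, 1, 1, 0}: sum g^2 / n - gbar^2 = 6/4 - 1
        assert sigma2_mom(g1=2, g2=1, n_total=4) == pytest.approx(0.5)
        assert sigma2_mom(g1=5, g2=0, n_total=5) == 0.0

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=40))
    @settings(derandomize=True)
    def test_sigma2_mom_is_biased_sample_variance(self, gs):
        g = np.array(gs)
        got = sigma2_mom(int((g == 1).sum()), int((g == 2).sum()), g.size)
        assert got == pytest.approx(g.var())

    def test_sigma2_mom_recovers_hwe_variance_under_hwe(self, rng):
        """E[MOM estimate] = 2p(1-p) when genotypes really are HWE."""
        p = 0.3
        g = rng.binomial(2, p, size=(400, 500))
        est = [
            sigma2_mom(int((row == 1).sum()), int((row == 2).sum()), row.size)
            for row in g
        ]
        se = np.std(est) / math.sqrt(len(est))
        assert abs(np.mean(est) - sigma2_hwe(p)) < 4 * se + 1e-3

    def test_sigma2_mom_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            sigma2_mom(3, 3, 4)
        with pytest.raises(ValueError):
            sigma2_mom(0, 0, 0)


class TestTrendStat:
    def test_zero_for_identical_samples(self):
        P, _, _ = trend_stat([0, 1, 2, 1], [1, 2, 0, 1])
        assert P == pytest.approx(0.0)

    def test_hand_example_pooled(self):
        P, sigma2, maf = trend_stat([2, 1], [0, 1], "hwe", maf_source="pooled")
        assert maf == pytest.approx(0.5)
        assert sigma2 == pytest.approx(0.5)
        assert P == pytest.approx(1 / math.sqrt(0.5))

    def test_matches_two_sample_proportions_ztest(self, rng):
        """With HWE variance the trend test is the classic pooled z-test
        on allele proportions."""
        for _ in range(25):
            N, M = rng.integers(5, 60, size=2)
            case = rng.integers(0, 3, N)
            ctrl = rng.integers(0, 3, M)
            if len(set(case) | set(ctrl)) == 1:
                continue
            P, _, _ = trend_stat(case, ctrl, "hwe", maf_source="pooled")
            z, _ = proportions_ztest(
                [case.sum(), ctrl.sum()], [2 * N, 2 * M], prop_var=False
            )
            assert P == pytest.approx(z, rel=1e-10)

    def test_allele_swap_antisymmetry(self, rng):
        case = rng.integers(0, 3, 30)
        ctrl = rng.integers(0, 3, 25)
        for source in ("pooled", "controls"):
            P, *_ = trend_stat(case, ctrl, maf_source=source)
            Pswap, *_ = trend_stat(2 - case, 2 - ctrl, maf_source=source)
            assert Pswap == pytest.approx(-P)

    def test_monomorphic_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            trend_stat([0, 0], [0, 0])


class TestWaldStat:
    @pytest.mark.parametrize(
        "H,T,expected", [(4, 2, 0.0), (4, 3, 1.0), (9, 9, 3.0)]
    )
    def test_examples(self, H, T, expected):
        assert wald_stat(H, T) == pytest.approx(expected)

    def test_tdt_equivalence_exhaustive(self):
        """F^2 equals the TDT chi-square (b-c)^2/(b+c) for all H <= 50."""
        for H in range(1, 51):
            for T in range(H + 1):
                b, c = T, H - T
                assert wald_stat(H, T) ** 2 == pytest.approx((b - c) ** 2 / (b + c))

    def test_general_p0_reduces_to_half(self):
        assert wald_stat(10, 7, 0.5) == pytest.approx(2 * math.sqrt(10) * 0.2)
        assert wald_stat(10, 7, 0.7) == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            wald_stat(0, 0)
        with pytest.raises(ValueError):
            wald_stat(4, 5)


class TestWeightAndTau:
    @pytest.mark.parametrize(
        "N,M,H,expected", [(200, 200, 100, 0.5), (50, 70, 0, 1.0), (100, 100, 50, 0.5)]
    )
    def test_weight(self, N, M, H, expected):
        assert compute_weight(N, M, H) == pytest.approx(expected)

    def test_weight_monotone_in_H(self):
        ws = [compute_weight(200, 200, H) for H in range(0, 400, 10)]
        assert all(a >= b for a, b in zip(ws, ws[1:]))

    def test_tau_analytic_half(self):
        """At N = M with H at its null expectation 2N*sigma2, tau = 1/2."""
        for N, maf in ((200, 0.2), (100, 0.4), (500, 0.09)):
            sigma2 = sigma2_hwe(maf)
            H = 2 * N * sigma2
            tau = compute_tau(N, N, round(H), sigma2)
            assert tau == pytest.approx(0.5, abs=0.01)

    def test_tau_large_M_limit(self):
        N, H, sigma2 = 200, 64, 0.32
        tau = compute_tau(N, 10**6, H, sigma2)
        assert tau == pytest.approx(math.sqrt(H) / (2 * math.sqrt(N * sigma2)),
                                    rel=1e-3)

    def test_tau_clipped_at_one(self):
        # plug-in estimate would exceed 1; a covariance of two
        # unit-variance statistics cannot
        assert compute_tau(2, 2, 400, 0.005) == 1.0


class TestCombination:
    def test_null_point(self):
        assert popfam_stat(0.0, 0.0, 0.3, 0.7) == 0.0

    def test_weight_collapse(self):
        assert popfam_stat(2.3, -5.0, 1.0, 0.9) == pytest.approx(2.3)
        assert popfam_stat(2.3, -5.0, 0.0, 0.9) == pytest.approx(-5.0)

    def test_direct_arithmetic(self):
        assert popfam_stat(1.0, 1.0, 0.5, 0.5) == pytest.approx(2 / math.sqrt(3))

    @given(
        st.floats(-4, 4), st.floats(-4, 4),
        st.floats(0.05, 0.95), st.floats(0.0, 1.0),
    )
    @settings(derandomize=True)
    def test_monotone_in_components(self, P, F, w, tau):
        z = popfam_stat(P, F, w, tau)
        assert popfam_stat(P + 0.5, F, w, tau) > z
        assert popfam_stat(P, F + 0.5, w, tau) > z


def _random_valid_dataset(rng, N=40, M=40, maf=0.3):
    father = rng.binomial(2, maf, N)
    mother = rng.binomial(2, maf, N)
    child = rng.binomial(1, father / 2) + rng.binomial(1, mother / 2)
    controls = rng.binomial(2, maf, M)
    return MixedDataset(father, mother, child, controls)


class TestPopfamTest:
    def test_allele_swap_negates_z_fixes_pvalue(self, rng):
        for _ in range(20):
            ds = _random_valid_dataset(rng)
            swapped = MixedDataset(
                2 - ds.father_g, 2 - ds.mother_g, 2 - ds.child_g, 2 - ds.control_g
            )
            a = popfam_test(ds)
            b = popfam_test(swapped)
            assert b.z == pytest.approx(-a.z)
            assert b.P_stat == pytest.approx(-a.P_stat)
            assert b.F_stat == pytest.approx(-a.F_stat)
            assert b.p_value == pytest.approx(a.p_value)

    def test_h_zero_falls_back_to_trend(self):
        ds = MixedDataset([0, 2], [0, 2], [0, 2], [0, 1, 2, 1])
        res = popfam_test(ds)
        assert res.H == 0 and res.w == 1.0 and res.tau == 0.0
        P, _, _ = trend_stat(ds.case_g, ds.control_g)
        assert res.z == pytest.approx(P)

    def test_pvalue_is_two_sided_normal_tail(self, rng):
        from scipy.stats import norm

        ds = _random_valid_dataset(rng)
        res = popfam_test(ds)
        assert res.p_value == pytest.approx(2 * norm.sf(abs(res.z)))

    def test_counts_reported(self, rng):
        ds = _random_valid_dataset(rng)
        res = popfam_test(ds)
        assert res.N == 40 and res.M == 40
        assert res.H == int(ds.h.sum())
        assert res.X == int((ds.h >= 1).sum())

    def test_extra_cases_enter_population_component_only(self, rng):
        ds = _random_valid_dataset(rng)
        extra = MixedDataset(
            ds.father_g, ds.mother_g, ds.child_g, ds.control_g, [1, 2, 0, 1]
        )
        a, b = popfam_test(ds), popfam_test(extra)
        assert b.N == a.N + 4
        assert b.H == a.H  # family component unchanged
        assert b.F_stat == pytest.approx(a.F_stat)
        assert b.P_stat != pytest.approx(a.P_stat)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            popfam_test(MixedDataset([], [], [], [0, 1]))

    def test_weight_modes(self, rng):
        ds = _random_valid_dataset(rng)
        half = popfam_test(ds, weight_mode="half")
        ss = popfam_test(ds, weight_mode="sample_size")
        assert half.w == 0.5
        assert ss.w == pytest.approx(compute_weight(ds.n_cases, ds.n_controls, ds.H))

    def test_batch_matches_scalar_path(self, rng):
        """The vectorized batch evaluator reproduces popfam_test exactly."""
        f, m, c, s = simulate_null_batch(0.25, 50, 60, 40, rng)
        for variance_mode, maf_source in product(
            ("hwe", "mom"), ("controls", "pooled")
        ):
            batch = popfam_test_batch(
                f, m, c, s, variance_mode=variance_mode, maf_source=maf_source
            )
            for i in range(40):
                res = popfam_test(
                    MixedDataset(f[i], m[i], c[i], s[i]),
                    variance_mode=variance_mode,
                    maf_source=maf_source,
                )
                assert batch["z"][i] == pytest.approx(res.z)
                assert batch["P"][i] == pytest.approx(res.P_stat)
                assert batch["tau"][i] == pytest.approx(res.tau)
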