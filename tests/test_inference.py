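"""Mixture likelihood, MLE, and the boundary-corrected LRT."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

from mosaicstr import (
    LocusReadData,
    StutterParams,
    estimate_mosaicism,
    log_likelihood,
    log_likelihood_case,
    mixture_null_pvalue,
)
from mosaicstr.simulate import SimulationSpec, simulate_read_vector

THETA = StutterParams(u=0.01, d=0.01, rho=0.9)


def hand_stutter(r, g, u, d, rho):
    """Independent scalar evaluation of the stutter PMF."""
    if r == g:
        return 1 - u - d
    if r > g:
        return u * rho * (1 - rho) ** (r - g - 1)
    return d * rho * (1 - rho) ** (g - r - 1)


def hand_loglik(reads, a, b, c, f, u, d, rho):
    """Term-by-term mixture log-likelihood (mosaic on B's haplotype)."""
    total = 0.0
    for r in reads:
        total += math.log(
            0.5 * hand_stutter(r, a, u, d, rho)
            + (0.5 - f) * hand_stutter(r, b, u, d, rho)
            + f * hand_stutter(r, c, u, d, rho)
        )
    return total


class TestLogLikelihoodCase:
    def test_matches_hand_evaluation(self):
        reads = [10, 10, 12]
        data = LocusReadData(A=10, B=10, reads=reads, theta=THETA)
        got = log_likelihood_case(data, C=12, f=0.3, mutated_allele="B")
        assert got == pytest.approx(hand_loglik(reads, 10, 10, 12, 0.3, 0.01, 0.01, 0.9))

    def test_het_case_matches_hand_evaluation(self):
        reads = [10, 11, 12, 12, 14]
        data = LocusReadData(A=10, B=12, reads=reads, theta=THETA)
        got = log_likelihood_case(data, C=14, f=0.2, mutated_allele="B")
        assert got == pytest.approx(hand_loglik(reads, 10, 12, 14, 0.2, 0.01, 0.01, 0.9))
        swapped = log_likelihood_case(data, C=14, f=0.2, mutated_allele="A")
        assert swapped == pytest.approx(hand_loglik(reads, 12, 10, 14, 0.2, 0.01, 0.01, 0.9))

    def test_f_zero_independent_of_C_and_case(self):
        data = LocusReadData(A=10, B=12, reads=[10, 10, 12, 13], theta=THETA)
        vals = {
            log_likelihood_case(data, C, 0.0, case)
            for C in (8, 11, 14, 20)
            for case in ("A", "B")
        }
        assert len({round(v, 10) for v in vals}) == 1

    def test_increasing_in_f_when_reads_support_C(self):
        reads = [10] * 10 + [12] * 10 + [14] * 6
        data = LocusReadData(A=10, B=12, reads=reads, theta=THETA)
        lls = [log_likelihood_case(data, 14, f, "B") for f in (0.0, 0.01, 0.05, 0.1)]
        assert all(x < y for x, y in zip(lls, lls[1:]))

    def test_invalid_inputs(self):
        data = LocusReadData(A=10, B=12, reads=[10, 12], theta=THETA)
        with pytest.raises(ValueError):
            log_likelihood_case(data, 14, 0.7)
        with pytest.raises(ValueError):
            log_likelihood_case(data, 14, 0.1, mutated_allele="X")
        with pytest.raises(ValueError):
            LocusReadData(A=10, B=12, reads=[], theta=THETA)


class TestLogLikelihood:
    def test_homozygous_cases_coincide(self):
        data = LocusReadData(A=11, B=11, reads=[11, 11, 13], theta=THETA)
        ll, case = log_likelihood(data, 13, 0.2)
        assert ll == pytest.approx(log_likelihood_case(data, 13, 0.2, "A"))
        assert case == "B"  # tie goes to B

    def test_max_of_both_branches(self):
        data = LocusReadData(A=9, B=11, reads=[11, 11, 13, 13, 9], theta=THETA)
        ll, case = log_likelihood(data, 13, 0.2)
        la = log_likelihood_case(data, 13, 0.2, "A")
        lb = log_likelihood_case(data, 13, 0.2, "B")
        assert ll == pytest.approx(max(la, lb))
        assert case == ("A" if la > lb else "B")

    def test_label_swap_symmetry(self):
        reads = [9, 11, 11, 13]
        d1 = LocusReadData(A=9, B=11, reads=reads, theta=THETA)
        d2 = LocusReadData(A=11, B=9, reads=reads, theta=THETA)
        assert log_likelihood(d1, 13, 0.15)[0] == pytest.approx(log_likelihood(d2, 13, 0.15)[0])


class TestMixtureNullPvalue:
    def test_point_mass_at_zero(self):
        assert mixture_null_pvalue(0.0) == 1.0

    def test_half_chi2_tail(self):
        lam = chi2.isf(0.05, df=2)  # 5.991
        assert mixture_null_pvalue(lam) == pytest.approx(0.025, rel=1e-3)

    def test_monotone_non_increasing(self):
        lams = np.linspace(0, 30, 100)
        ps = [mixture_null_pvalue(l) for l in lams]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_negative_input(self):
        assert mixture_null_pvalue(-1e-12) == 1.0
        with pytest.raises(ValueError):
            mixture_null_pvalue(-0.5)


class TestEstimateMosaicism:
    def test_null_reads_give_f_zero_p_one(self):
        data = LocusReadData(A=12, B=12, reads=[12] * 50, theta=THETA)
        est = estimate_mosaicism(data)
        assert est.f_hat == pytest.approx(0.0, abs=1e-4)
        assert est.pvalue == pytest.approx(1.0)
        assert est.lambda_lr == pytest.approx(0.0, abs=1e-8)

    def test_recovers_planted_mosaic(self):
        spec = SimulationSpec(A=10, B=12, coverage=100, theta=THETA,
                              mosaic_alleles=[(14, 0.2)], seed=21)
        reads = simulate_read_vector(spec, np.random.default_rng(21))
        est = estimate_mosaicism(LocusReadData(A=10, B=12, reads=reads, theta=THETA))
        assert est.C_hat == 14
        assert est.f_hat == pytest.approx(0.2, abs=0.08)
        assert est.pvalue < 1e-6
        assert est.converged

    def test_mean_f_recovery_over_replicates(self):
        root = np.random.SeedSequence(99)
        f_hats = []
        for child in root.spawn(60):
            rng = np.random.default_rng(child)
            spec = SimulationSpec(A=10, B=12, coverage=100, theta=THETA,
                                  mosaic_alleles=[(14, 0.2)], seed=0)
            reads = simulate_read_vector(spec, rng)
            est = estimate_mosaicism(LocusReadData(A=10, B=12, reads=reads, theta=THETA))
            f_hats.append(est.f_hat)
        assert np.mean(f_hats) == pytest.approx(0.2, abs=0.03)

    def test_C_hat_never_equals_germline_allele(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            spec = SimulationSpec(A=10, B=12, coverage=40, theta=THETA, seed=0)
            reads = simulate_read_vector(spec, rng)
            est = estimate_mosaicism(LocusReadData(A=10, B=12, reads=reads, theta=THETA))
            assert est.C_hat not in (10, 12)
            assert est.lambda_lr >= 0
            assert 0 < est.pvalue <= 1

    def test_lambda_invariant_to_read_permutation(self, rng):
        reads = rng.permutation([10] * 20 + [12] * 15 + [14] * 8 + [11] * 2)
        d1 = LocusReadData(A=10, B=12, reads=reads, theta=THETA)
        d2 = LocusReadData(A=10, B=12, reads=reads[::-1].copy(), theta=THETA)
        assert estimate_mosaicism(d1).lambda_lr == pytest.approx(
            estimate_mosaicism(d2).lambda_lr)

    def test_beats_bruteforce_grid(self):
        """Iterative MLE within 1e-4 of an exhaustive (C, f)-grid maximum."""
        rng = np.random.default_rng(5)
        for i in range(10):
            A = float(rng.integers(6, 15))
            B = A + float(rng.integers(0, 4))
            spec = SimulationSpec(
                A=A, B=B, coverage=int(rng.integers(20, 80)), theta=THETA,
                mosaic_alleles=[(A + 5.0, 0.25)] if i % 2 else [], seed=0)
            reads = simulate_read_vector(spec, rng)
            data = LocusReadData(A=A, B=B, reads=reads, theta=THETA)
            est = estimate_mosaicism(data)
            lo = int(np.floor(reads.min())) - 3
            hi = int(np.ceil(reads.max())) + 3
            best = -np.inf
            for C in range(lo, hi + 1):
                if C in (A, B):
                    continue
                for f in np.arange(0.0, 0.5001, 0.005):
                    best = max(best, log_likelihood(data, float(C), float(f))[0])
            assert est.loglik >= best - 1e-4

    def test_mosaic_support_counts_reads_at_C(self):
        reads = [10] * 20 + [12] * 14 + [14] * 6
        est = estimate_mosaicism(LocusReadData(A=10, B=12, reads=reads, theta=THETA))
        assert est.C_hat == 14
        assert est.mosaic_support == 6
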