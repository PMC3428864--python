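import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonehistory.core import PhasedSNP
from clonehistory.battenberg import (
    clonal_hf,
    subclonal_hf,
    allele_specific_cn,
    total_cn_from_logr,
    logr_from_total_cn,
    pcf,
    phase_switch_segment,
    test_clonality as clonality_call,
    estimate_tau,
    fine_tune_purity,
    balanced_loss_suspected,
    call_segments,
    HaplotypeSegment,
)
from clonehistory.simulate import simulate_phased_chromosome


class TestClonalHf:
    def test_pure_tumor_balanced(self):
        assert clonal_hf(1.0, 1, 1) == 0.5

    def test_loh_at_70_percent_purity(self):
        # hand arithmetic: (1-0.7)/(2*0.3+0.7) = 0.3/1.3
        assert clonal_hf(0.7, 1, 0) == pytest.approx(0.3 / 1.3)
        assert clonal_hf(0.7, 1, 0) == pytest.approx(0.2308, abs=1e-4)

    def test_pure_normal_always_half(self):
        for nA, nB in [(1, 0), (3, 1), (2, 2)]:
            assert clonal_hf(0.0, nA, nB) == pytest.approx(0.5)


class TestAlleleSpecificCn:
    @given(
        rho=st.floats(0.1, 1.0),
        nA=st.integers(0, 4),
        nB=st.integers(0, 4),
        psi=st.floats(1.0, 4.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_exact_inverse_of_forward_model(self, rho, nA, nB, psi):
        """clonal_hf + logR forward then allele_specific_cn back recovers
        the integer state to near machine precision."""
        if nA + nB == 0:
            return
        hf = clonal_hf(rho, nA, nB)
        lr = logr_from_total_cn(nA + nB, rho, psi)
        nA_hat, nB_hat = allele_specific_cn(hf, lr, rho, psi)
        assert nA_hat == pytest.approx(nA, abs=1e-9)
        assert nB_hat == pytest.approx(nB, abs=1e-9)

    def test_trivial_diploid(self):
        assert allele_specific_cn(0.5, 0.0, 1.0, 2.0) == pytest.approx((1.0, 1.0))

    def test_extreme_logr_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            nA, nB = allele_specific_cn(0.5, -10.0, 0.9, 2.0)
        assert nA == 0.0 and nB == 0.0


class TestPcf:
    def _exhaustive(self, x, penalty, var):
        """Oracle: brute-force search over all breakpoint subsets."""
        x = np.asarray(x, dtype=float)
        n = len(x)
        best_cost, best_bps = np.inf, []
        for k in range(n):
            for bps in itertools.combinations(range(1, n), k):
                bounds = [0, *bps, n]
                cost = penalty * var * k
                for i, j in zip(bounds[:-1], bounds[1:]):
                    seg = x[i:j]
                    cost += ((seg - seg.mean()) ** 2).sum()
                if cost < best_cost - 1e-12:
                    best_cost, best_bps = cost, list(bps)
        return best_bps

    def test_matches_exhaustive_search_on_small_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = np.concatenate(
                [rng.normal(0.0, 0.1, 4), rng.normal(rng.uniform(0, 1), 0.1, 4)]
            )
            var = 0.01
            assert pcf(x, penalty=3.0, var=var) == self._exhaustive(x, 3.0, var)

    def test_constant_input_single_segment(self):
        assert pcf([0.5] * 20, penalty=3.0) == []

    def test_clear_step_detected_at_right_place(self):
        x = [0.5] * 10 + [0.34] * 10
        assert pcf(x, penalty=3.0, var=1e-4) == [10]


class TestPhaseSwitchSegment:
    def test_constant_fraction_one_segment(self):
        snps = [
            PhasedSNP("chr3", 1000 * (i + 1), 50, 50, block_id=i // 10)
            for i in range(100)
        ]
        segs = phase_switch_segment(snps)
        assert len(segs) == 1
        assert segs[0].hf == pytest.approx(0.5, abs=1e-6)

    def test_flipped_blocks_rephased_into_one_band(self):
        """Two imputation blocks at fractions 0.34 and 0.66 (labels
        flipped) re-phase to a single segment at 0.34."""
        snps = [PhasedSNP("chr13", 100 + i, 34, 66, block_id=0) for i in range(20)]
        snps += [PhasedSNP("chr13", 200 + i, 66, 34, block_id=1) for i in range(20)]
        segs = phase_switch_segment(snps)
        assert len(segs) == 1
        assert segs[0].hf == pytest.approx(0.34, abs=1e-6)

    def test_mid_chromosome_step_gives_two_segments(self):
        rng = np.random.default_rng(5)
        snps = []
        for i in range(400):
            p = 0.5 if i < 200 else 0.34
            n = 120
            h1 = rng.binomial(n, p)
            snps.append(
                PhasedSNP("chr8", 10_000 * (i + 1), int(h1), n - int(h1), block_id=i // 10)
            )
        segs = phase_switch_segment(snps)
        assert len(segs) == 2
        assert segs[0].hf == pytest.approx(0.5, abs=0.02)
        assert segs[1].hf == pytest.approx(0.34, abs=0.02)
        assert segs[0].n_snps == 200


def _segment_from_fracs(fracs, depth=200):
    fracs = np.asarray(fracs, dtype=float)
    return HaplotypeSegment(
        chrom="chrT",
        start=0,
        end=1000,
        hf=float(fracs.mean()),
        n_snps=len(fracs),
        snp_fractions=fracs,
        snp_depths=np.full(len(fracs), depth),
        snp_blocks=np.arange(len(fracs)) // 10,
    )


class TestClonality:
    def test_exact_clonal_state_is_clonal(self):
        hf = clonal_hf(0.7, 1, 0)
        seg = _segment_from_fracs(np.full(100, hf))
        verdict, state = clonality_call(seg, 0.7, 1.02, 0.01)
        assert verdict == "clonal" and state == (1, 0)

    def test_far_from_every_state_with_tight_snps_is_subclonal(self):
        rng = np.random.default_rng(2)
        hf = clonal_hf(0.7, 1, 1) - 0.05
        fracs = rng.normal(hf, 0.01, 500)
        seg = _segment_from_fracs(fracs)
        # oracle: t statistic against the nearest state is enormous
        t_stat = abs(fracs.mean() - 0.5) / (fracs.std(ddof=1) / math.sqrt(500))
        assert t_stat > 10
        nA, nB = allele_specific_cn(seg.hf, logr_from_total_cn(2.0, 0.7, 2.0), 0.7, 2.0)
        assert clonality_call(seg, 0.7, nA, nB)[0] == "subclonal"

    def test_below_min_dev_is_clonal_regardless_of_p(self):
        rng = np.random.default_rng(3)
        hf = clonal_hf(0.7, 1, 1) - 0.005  # below the 0.01 minimum deviation
        fracs = rng.normal(hf, 0.005, 2000)
        seg = _segment_from_fracs(fracs)
        assert clonality_call(seg, 0.7, 1.0, 0.97)[0] == "clonal"


class TestEstimateTau:
    def test_noise_free_forward_inversion(self):
        """Forward-simulated hf and logR at rho=0.8, tau=0.3 with states
        (2,1)/(1,1) invert back to tau to near machine precision."""
        rho, tau, s1, s2 = 0.8, 0.3, (2, 1), (1, 1)
        hf = subclonal_hf(rho, tau, s1, s2)
        total = tau * sum(s1) + (1 - tau) * sum(s2)
        lr = logr_from_total_cn(total, rho, 2.0)
        seg = _segment_from_fracs(np.full(50, hf))
        s1_hat, s2_hat, tau_hat, ci = estimate_tau(seg, lr, rho, 2.0, n_boot=10, seed=0)
        assert {s1_hat, s2_hat} == {s1, s2}
        recovered = tau_hat if s1_hat == s1 else 1 - tau_hat
        assert recovered == pytest.approx(tau, abs=1e-9)

    def test_hf_at_clonal_state_gives_tau_zero(self):
        rho = 0.7
        hf = clonal_hf(rho, 1, 1)
        lr = logr_from_total_cn(2.0, rho, 2.0)
        seg = _segment_from_fracs(np.full(50, hf))
        _, _, tau_hat, _ = estimate_tau(seg, lr, rho, 2.0, n_boot=10, seed=0)
        assert min(tau_hat, 1 - tau_hat) == pytest.approx(0.0, abs=1e-9)

    def test_chr13_scenario_recovered_with_narrow_ci(self):
        """rho=0.70, truth tau=0.68 (1+0 vs 1+1), depth 188, 5000 SNPs:
        the estimate lands within 2 points of truth with a tight CI."""
        snps = simulate_phased_chromosome(
            rho=0.70, tau=0.68, state1=(1, 0), state2=(1, 1),
            n_snps=5000, depth=188, seed=13,
        )
        segs = phase_switch_segment(snps)
        seg = max(segs, key=lambda s: s.n_snps)
        lr = logr_from_total_cn(0.68 * 1 + 0.32 * 2, 0.70, 2.0)
        s1, s2, tau_hat, ci = estimate_tau(seg, lr, 0.70, 2.0, n_boot=1000, seed=13)
        assert (s1, s2) == ((1, 0), (1, 1))
        assert tau_hat == pytest.approx(0.68, abs=0.02)
        assert ci[1] - ci[0] < 0.05

    def test_bootstrap_ci_covers_truth_across_seeds(self):
        hits = 0
        for seed in range(10):
            snps = simulate_phased_chromosome(
                rho=0.70, tau=0.68, state1=(1, 0), state2=(1, 1),
                n_snps=1500, depth=120, seed=100 + seed,
            )
            seg = max(phase_switch_segment(snps), key=lambda s: s.n_snps)
            lr = logr_from_total_cn(1.32, 0.70, 2.0)
            _, _, _, ci = estimate_tau(seg, lr, 0.70, 2.0, n_boot=400, seed=seed)
            hits += ci[0] - 0.005 <= 0.68 <= ci[1] + 0.005
        assert hits >= 8  # nominal 95% coverage, Monte Carlo slack


def test_fine_tune_purity_recovers_true_rho():
    rho_true = 0.712
    hf = clonal_hf(rho_true, 1, 0)
    seg = _segment_from_fracs(np.full(200, hf))
    assert fine_tune_purity(seg, 0.71, (1, 0)) == pytest.approx(rho_true, abs=2e-3)


def test_balanced_subclonal_loss_flagged():
    """Both parental copies lost in equal subclones: hf stays at 0.5 but
    logR drops below the diploid baseline."""
    rng = np.random.default_rng(7)
    seg = _segment_from_fracs(rng.normal(0.5, 0.02, 300))
    low_logr = logr_from_total_cn(1.6, 0.7, 2.0)
    assert balanced_loss_suspected(seg, low_logr, 0.7, 2.0)
    assert not balanced_loss_suspected(seg, 0.0, 0.7, 2.0)


def test_call_segments_end_to_end_chr13():
    snps = simulate_phased_chromosome(
        rho=0.70, tau=0.68, state1=(1, 0), state2=(1, 1),
        n_snps=3000, depth=188, seed=21,
    )
    lr = logr_from_total_cn(1.32, 0.70, 2.0)
    out = call_segments(snps, {"chr13": lr}, rho=0.70, psi=2.0, n_boot=300, seed=21)
    main = max(out, key=lambda s: s.end - s.start)
    assert main.subclonal
    assert main.state1 == (1, 0) and main.state2 == (1, 1)
    assert main.tau == pytest.approx(0.68, abs=0.02)
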