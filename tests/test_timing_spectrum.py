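import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clonehistory.core import MutationCall, CNSegment, SampleMeta
from clonehistory.timing_spectrum import (
    GainTiming,
    assign_multiplicity,
    time_gain,
    bootstrap_timing,
    heterogeneity_test,
    compare_spectra,
    time_segment,
    SUBCLONAL,
)
from clonehistory.simulate import SimConfig, SimSegment, simulate_tumor


TRISOMY_SEG = CNSegment("chr1", 0, 10**8, nA=2, nB=1)


class TestTimeGain:
    def test_printed_worked_example(self):
        """100 ploidy-1 and 20 ploidy-2 mutations on a trisomic chromosome
        date the gain at 43% of molecular time."""
        t = time_gain(100, 20, "trisomy_2+1")
        assert t == pytest.approx(20 / (20 + (100 - 20) / 3))
        assert round(100 * t) == 43

    def test_no_ploidy2_mutations_means_gain_at_time_zero(self):
        assert time_gain(100, 0, "trisomy_2+1") == 0.0

    def test_equal_counts_trisomy_gain_at_end(self):
        # formula limit: all mutations pre-gain
        assert time_gain(50, 50, "trisomy_2+1") == 1.0

    def test_upd_and_tetraploid_formulas(self):
        assert time_gain(100, 50, "UPD_2+0") == pytest.approx(50 / (50 + 50))
        assert time_gain(0, 30, "tetraploid_2+2") == 1.0

    def test_no_mutations_is_error(self):
        with pytest.raises(ValueError, match="no mutations"):
            time_gain(0, 0, "trisomy_2+1")

    @given(
        n1=st.integers(0, 500),
        n2=st.integers(0, 500),
        k=st.integers(2, 20),
        cls=st.sampled_from(["trisomy_2+1", "UPD_2+0", "tetraploid_2+2"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, n1, n2, k, cls):
        if n1 + n2 == 0:
            return
        assert time_gain(n1, n2, cls) == pytest.approx(time_gain(k * n1, k * n2, cls))


class TestBootstrapTiming:
    def test_interval_contains_point_estimate(self):
        labels = [1] * 100 + [2] * 20
        lo, hi = bootstrap_timing(labels, "trisomy_2+1", n_boot=2000, seed=1)
        assert lo <= 0.43 <= hi
        assert hi - lo < 0.35

    def test_all_ploidy2_degenerate_interval(self):
        lo, hi = bootstrap_timing([2] * 30, "trisomy_2+1", n_boot=100, seed=2)
        assert (lo, hi) == (1.0, 1.0)

    def test_single_resample_interval_collapses(self):
        labels = [1] * 10 + [2] * 5
        lo, hi = bootstrap_timing(labels, "trisomy_2+1", n_boot=1, seed=3)
        assert lo == hi


class TestAssignMultiplicity:
    def test_clonal_single_copy_vaf_is_ploidy_one(self, meta70):
        m = MutationCall("chr1", 10, "C", "T", 200, 52, tumor_cn=3.0)  # VAF = zeta
        assert assign_multiplicity(m, TRISOMY_SEG, meta70) == 1

    def test_trisomy_high_vaf_is_ploidy_two(self, meta70):
        """VAF 0.52 in a 2+1 region at purity 0.7: the Binomial likelihood
        at multiplicity 2 (expected VAF 0.519) dwarfs multiplicity 1."""
        zeta = 0.7 / (0.7 * 3 + 0.3 * 2)
        m = MutationCall("chr1", 10, "C", "T", 200, 104, tumor_cn=3.0)
        ll1 = stats.binom.logpmf(104, 200, zeta)
        ll2 = stats.binom.logpmf(104, 200, 2 * zeta)
        assert ll2 > ll1  # oracle comparison
        assert assign_multiplicity(m, TRISOMY_SEG, meta70) == 2

    def test_half_expected_vaf_is_subclonal(self, meta70):
        zeta = 0.7 / (0.7 * 3 + 0.3 * 2)
        m = MutationCall(
            "chr1", 10, "C", "T", 400, int(round(0.5 * zeta * 400)), tumor_cn=3.0
        )
        assert assign_multiplicity(m, TRISOMY_SEG, meta70) == SUBCLONAL


class TestHeterogeneity:
    def test_identical_segments_show_none(self):
        a = GainTiming(None, "trisomy_2+1", 100, 20, 0.43, (0.3, 0.6))
        b = GainTiming(None, "trisomy_2+1", 100, 20, 0.43, (0.3, 0.6))
        assert heterogeneity_test([a, b]) > 0.9

    def test_opposite_segments_highly_significant(self):
        a = GainTiming(None, "trisomy_2+1", 100, 20, 0.43, (0.3, 0.6))
        b = GainTiming(None, "trisomy_2+1", 20, 100, 1.0, (0.9, 1.0))
        # oracle: chi-square on the 2x2 table by hand
        chi2, p_hand, _, _ = stats.chi2_contingency([[20, 100], [100, 20]])
        assert p_hand < 1e-3
        assert heterogeneity_test([a, b]) < 1e-3

    def test_single_segment_undefined(self):
        a = GainTiming(None, "trisomy_2+1", 100, 20, 0.43, (0.3, 0.6))
        with pytest.raises(ValueError, match="two"):
            heterogeneity_test([a])


class TestCompareSpectra:
    def _muts(self, classes):
        table = {"C>A": ("C", "A"), "C>T": ("C", "T"), "T>C": ("T", "C")}
        return [
            MutationCall("chr1", i + 1, *table[c], depth=100, alt_reads=50)
            for i, c in enumerate(classes)
        ]

    def test_identical_proportions_no_signal(self):
        muts = self._muts(["C>T"] * 40 + ["T>C"] * 60 + ["C>T"] * 40 + ["T>C"] * 60)
        labels = [2] * 100 + [1] * 100
        comp = compare_spectra(muts, labels)
        assert comp.chi2 == pytest.approx(0.0, abs=1e-9)
        assert comp.p == pytest.approx(1.0)

    def test_empty_early_vector_is_error(self):
        muts = self._muts(["C>T"] * 10)
        with pytest.raises(ValueError, match="early and late"):
            compare_spectra(muts, [1] * 10)

    def test_simulated_spectrum_shift_detected(self):
        """Early 40% C>T vs late 15% C>T at ~500 mutations per epoch is
        detected at p < 0.01 in nearly all seeds."""
        early = (0.15, 0.15, 0.40, 0.10, 0.10, 0.10)
        late = (0.20, 0.20, 0.15, 0.15, 0.15, 0.15)
        hits = 0
        for seed in range(6):
            cfg = SimConfig(
                purity=0.7,
                coverage=150.0,
                clone_fractions=(1.0,),
                parents=(-1,),
                mutations_per_clone=(2300,),
                segments=(SimSegment("chr1", 0, 10**8, nA=2, nB=1, gain_time=0.6),),
                early_spectrum=early,
                late_spectrum=late,
                seed=seed,
            )
            bundle = simulate_tumor(cfg)
            meta = bundle.meta
            seg = CNSegment("chr1", 0, 10**8, nA=2, nB=1)
            labels = [assign_multiplicity(m, seg, meta) for m in bundle.mutations]
            comp = compare_spectra(bundle.mutations, labels)
            hits += comp.p < 0.01
        assert hits >= 5


def test_timing_recovers_configured_gain_time():
    """Point estimate recovers the configured molecular time with small
    bias on a 2+1 trisomy with plenty of informative mutations."""
    t_true = 0.43
    ests = []
    for seed in range(4):
        cfg = SimConfig(
            purity=0.7,
            coverage=150.0,
            clone_fractions=(1.0,),
            parents=(-1,),
            mutations_per_clone=(1000,),
            segments=(SimSegment("chr1", 0, 10**8, nA=2, nB=1, gain_time=t_true),),
            seed=seed + 20,
        )
        bundle = simulate_tumor(cfg)
        g = time_segment(
            bundle.mutations, bundle.segments[0], bundle.meta, n_boot=500, seed=seed
        )
        ests.append(g.t)
    assert abs(np.mean(ests) - t_true) < 0.05
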