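import numpy as np
import pytest
from scipy import stats

from clonehistory.core import MutationCall, SampleMeta
from clonehistory.ccf_dp import (
    cell_fraction,
    expected_vaf,
    fit_dirichlet,
    classify_mutations,
    density_peaks,
    subclonal_mode,
    _stick_weights,
)
from clonehistory.simulate import SimConfig, simulate_tumor


def _mut(r, R, cn=2.0):
    return MutationCall("chr1", 100, "C", "T", depth=R, alt_reads=r, tumor_cn=cn)


class TestCellFraction:
    def test_major_cluster_is_fully_clonal(self, meta70):
        """VAF 35% at purity 0.70 on a diploid locus means 100% of tumor
        cells carry the mutation."""
        ccf = cell_fraction(_mut(70, 200), meta70)
        assert ccf.f == pytest.approx(1.0)
        assert ccf.zeta == pytest.approx(0.35)

    def test_zero_alt_reads_zero_fraction(self, meta70):
        assert cell_fraction(_mut(0, 200), meta70).f == 0.0

    def test_subclonal_arithmetic(self, meta70):
        # VAF 0.19 / zeta 0.35 = 2 * 0.19 / 0.7 (hand arithmetic)
        ccf = cell_fraction(_mut(19, 100), meta70)
        assert ccf.f == pytest.approx(2 * 0.19 / 0.7, abs=1e-9)

    def test_zero_depth_is_error(self, meta70):
        with pytest.raises(ValueError, match="depth"):
            cell_fraction(_mut(0, 0), meta70)

    def test_capped_at_one(self, meta70):
        assert cell_fraction(_mut(90, 100), meta70).f == 1.0

    def test_expected_vaf_deleted_copy_scenario(self, meta70):
        """Mutations on the parental copy deleted in 68% of tumor cells at
        purity 0.70 are expected at ~15% VAF."""
        tau = 0.68
        vaf = expected_vaf(
            meta70, cell_frac=1.0 - tau, multiplicity=1.0, tumor_cn=2.0 - tau
        )
        assert round(100 * vaf) == 15


class TestStickBreaking:
    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            V = rng.beta(1.0, rng.gamma(1.0) + 0.1, size=30)
            V[-1] = 1.0
            assert _stick_weights(V).sum() == pytest.approx(1.0, abs=1e-12)

    def test_weights_match_recursive_definition(self):
        V = np.array([0.5, 0.25, 1.0])
        np.testing.assert_allclose(_stick_weights(V), [0.5, 0.125, 0.375])


def _em_two_binomial(y, N, zeta, locs=(0.9, 0.5), iters=500):
    """Independent oracle: two-component binomial EM on cell fractions."""
    pi = np.array(locs, dtype=float)
    w = np.array([0.5, 0.5])
    for _ in range(iters):
        ll = np.stack(
            [stats.binom.logpmf(y, N, np.clip(zeta * p, 1e-9, 1 - 1e-9)) for p in pi]
        )
        ll += np.log(w)[:, None]
        ll -= ll.max(axis=0)
        resp = np.exp(ll)
        resp /= resp.sum(axis=0)
        w = resp.mean(axis=1)
        pi = np.clip((resp * (y / N / zeta)).sum(axis=1) / resp.sum(axis=1), 1e-6, 1.0)
    return np.sort(pi)


class TestFitDirichlet:
    def test_requires_minimum_mutations(self, meta70):
        with pytest.raises(ValueError, match="at least 20"):
            fit_dirichlet([_mut(10, 30)] * 5, meta70)

    def test_identical_deep_mutations_single_clonal_cluster(self, meta70):
        muts = [_mut(3500, 10000) for _ in range(40)]
        model = fit_dirichlet(muts, meta70, iters=1500, burn=500, seed=1)
        peaks = density_peaks(model)
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(1.0, abs=0.02)
        bands = classify_mutations(model)["bands"]
        assert bands["clonal"][0] == pytest.approx(40, abs=1)

    def test_two_component_recovery_matches_em_oracle(self, meta70):
        """Locations of a clonal + 50%-cell mixture recovered within 0.02
        of an independent two-component binomial EM fit."""
        rng = np.random.default_rng(42)
        N = rng.poisson(500, size=400)
        pi_true = np.repeat([1.0, 0.5], 200)
        y = rng.binomial(N, 0.35 * pi_true)
        muts = [_mut(int(yi), int(Ni)) for yi, Ni in zip(y, N)]
        em_locs = _em_two_binomial(y, N, 0.35)
        model = fit_dirichlet(muts, meta70, iters=2500, burn=1000, seed=7)
        peaks = sorted(p for p, _ in density_peaks(model, min_mass=0.1))
        assert len(peaks) == 2
        assert abs(peaks[0] - em_locs[0]) < 0.02
        assert abs(peaks[1] - min(em_locs[1], 1.0)) < 0.02

    def test_flat_sensitivity_leaves_weights_uncorrected(self, meta70):
        muts = [_mut(int(r), 200) for r in np.random.default_rng(3).binomial(200, 0.35, 50)]
        model = fit_dirichlet(
            muts,
            meta70,
            sensitivity_curve=lambda t: np.ones_like(np.asarray(t)),
            iters=800,
            burn=300,
            seed=2,
        )
        np.testing.assert_allclose(model.omega_draws, model.kappa_draws, atol=1e-12)

    def test_posterior_density_integrates_to_one(self, meta70):
        muts = [_mut(int(r), 150) for r in np.random.default_rng(4).binomial(150, 0.2, 60)]
        model = fit_dirichlet(muts, meta70, iters=800, burn=300, seed=3)
        area = np.trapezoid(model.density_median, model.density_grid)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_kappa_sums_to_one_every_kept_iteration(self, meta70):
        muts = [_mut(int(r), 150) for r in np.random.default_rng(5).binomial(150, 0.3, 40)]
        model = fit_dirichlet(muts, meta70, iters=600, burn=200, seed=4)
        np.testing.assert_allclose(model.kappa_draws.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.omega_draws.sum(axis=1), 1.0, atol=1e-9)


def test_band_classification_sim_recovery(meta70):
    """A 60%-cell subclone holding ~44% of mutations dominates the 50-95%
    band after sensitivity correction."""
    cfg = SimConfig(
        purity=0.7,
        coverage=150.0,
        clone_fractions=(1.0, 0.6),
        parents=(-1, 0),
        mutations_per_clone=(200, 200),
        seed=6,
    )
    bundle = simulate_tumor(cfg)
    model = fit_dirichlet(bundle.mutations, bundle.meta, iters=2000, burn=800, seed=8)
    bands = model.band_counts
    assert bands["50_95"][0] == pytest.approx(200, rel=0.2)
    assert bands["clonal"][0] == pytest.approx(200, rel=0.2)
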