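import numpy as np
import pytest

import neiqtl as nq
from neiqtl.genotypes import AA, BB
from neiqtl.scan import Phenotype
from neiqtl.varcomp import _reml_parts, aireml, build_covariance, fit_varcomp

from test_neighbors import deterministic, make_gp


@pytest.fixture(scope="module")
def f2_cov(f2_gp, f2_smap):
    return build_covariance(f2_gp, f2_smap, s=30.0)


def reml_loglik(y, X, V):
    return _reml_parts(y, X, V)[2]


def mvn_trait(rng, sig1, sig2, sige, K):
    n = K.K1.shape[0]
    V = sig1 * K.K1 + sig2 * K.K2 + sige * np.eye(n)
    L = np.linalg.cholesky(V + 1e-10 * np.eye(n))
    return L @ rng.normal(size=n)


class TestCovariance:
    def test_identical_individuals_have_offdiagonal_equal_diagonal(self):
        codes = [AA, AA, BB]
        gp = make_gp(
            np.repeat(deterministic(codes), 3, axis=1), "riself"
        )  # 3 identical positions
        smap = nq.SpatialMap(["a", "b", "c"], [[0, 0], [1, 0], [0, 1]])
        cov = build_covariance(gp, smap, s=2.0, standardize=False)
        assert cov.K1[0, 1] == pytest.approx(cov.K1[0, 0], abs=1e-12)

    def test_k1_matches_hand_computed_cross_product(self):
        """2 individuals x 3 positions with explicit probabilities: K1 equals
        the raw additive-score cross-product over (q - 1) computed by hand."""
        probs = np.array(
            [
                [[0.9, 0.1, 0.0], [0.2, 0.5, 0.3], [0.1, 0.2, 0.7]],
                [[0.3, 0.4, 0.3], [0.6, 0.3, 0.1], [0.2, 0.6, 0.2]],
            ]
        )
        gp = make_gp(probs)
        smap = nq.SpatialMap(["a", "b"], [[0, 0], [1, 0]])
        cov = build_covariance(gp, smap, s=2.0, center=False, standardize=False)
        P1 = probs[:, :, 2] - probs[:, :, 0]  # expected -1/0/1 code
        assert np.allclose(cov.K1, P1 @ P1.T / 2, atol=1e-12)

    def test_kernels_are_psd(self, f2_cov):
        for K in (f2_cov.K1, f2_cov.K2):
            w = np.linalg.eigvalsh((K + K.T) / 2)
            assert w.min() >= -1e-8

    def test_k2_invariant_under_allele_swap(self, f2_gp, f2_smap):
        gp_sw = nq.GenoProbs(
            f2_gp.probs[:, :, ::-1].copy(),
            f2_gp.cross_type,
            f2_gp.grid,
            f2_gp.error_prob,
            ids=f2_gp.ids,
        )
        K2 = build_covariance(f2_gp, f2_smap, 30.0).K2
        K2_sw = build_covariance(gp_sw, f2_smap, 30.0).K2
        assert np.allclose(K2, K2_sw, atol=1e-10)


class TestREML:
    def test_optimum_matches_grid_search(self, f2_smap):
        """The AI-REML restricted likelihood at the optimum is within 0.05
        log-units of a dense grid search over variance proportions (total
        variance profiled out in closed form), n = 50."""
        gmap = nq.default_map(3, 4, 15.0)
        cross = nq.sim_cross("f2", gmap, 50, seed=61)
        smap = nq.sim_spatial(50, seed=62)
        gp = nq.calc_genoprob(cross)
        cov = build_covariance(gp, smap, s=40.0)
        rng = np.random.default_rng(63)
        y = mvn_trait(rng, 0.8, 0.6, 1.0, cov)
        X = np.ones((50, 1))
        sig, _, _, converged, _ = aireml(y, X, [cov.K1, cov.K2, np.eye(50)])
        assert converged
        ll_fit = reml_loglik(y, X, sig[0] * cov.K1 + sig[1] * cov.K2 + sig[2] * np.eye(50))

        best = -np.inf
        n, p = 50, 1
        for v1 in np.arange(0, 1.0001, 0.02):
            for v2 in np.arange(0, 1.0001 - v1, 0.02):
                V0 = v1 * cov.K1 + v2 * cov.K2 + (1 - v1 - v2) * np.eye(n)
                if 1 - v1 - v2 < 1e-9 and np.linalg.eigvalsh(V0).min() < 1e-9:
                    continue
                P, Py, _, _ = _reml_parts(y, X, V0 + 1e-10 * np.eye(n))
                st2 = float(y @ Py) / (n - p)
                ll = reml_loglik(y, X, st2 * (V0 + 1e-10 * np.eye(n)))
                best = max(best, ll)
        assert ll_fit >= best - 0.05

    def test_rescaling_invariance(self, f2_cov, f2_gp):
        rng = np.random.default_rng(64)
        y = mvn_trait(rng, 0.5, 0.5, 1.0, f2_cov)
        vc = fit_varcomp(Phenotype(y), f2_cov)
        vc_scaled = fit_varcomp(Phenotype(3.0 * y), f2_cov)
        assert vc_scaled.sigma1 == pytest.approx(9 * vc.sigma1, abs=1e-5 * max(vc.sigma1, 1))
        assert vc_scaled.pve_nei == pytest.approx(vc.pve_nei, abs=1e-6)
        assert vc_scaled.pve_self == pytest.approx(vc.pve_self, abs=1e-6)

    def test_pve_components_normalized(self, f2_cov):
        rng = np.random.default_rng(65)
        y = mvn_trait(rng, 1.0, 0.5, 1.0, f2_cov)
        vc = fit_varcomp(Phenotype(y), f2_cov)
        tot = vc.sigma1 + vc.sigma2 + vc.sigma_e
        assert vc.pve_self == pytest.approx(vc.sigma1 / tot)
        assert vc.pve_nei == pytest.approx(vc.sigma2 / tot)
        assert 0 <= vc.pve_self <= 1 and 0 <= vc.pve_nei <= 1
        assert vc.pve_self + vc.pve_nei <= 1

    def test_null_trait_shrinks_both_pves(self):
        gmap = nq.default_map()
        cross = nq.sim_cross("f2", gmap, 200, seed=66)
        smap = nq.sim_spatial(200, seed=67)
        gp = nq.calc_genoprob(cross)
        cov = build_covariance(gp, smap, s=30.0)
        rng = np.random.default_rng(68)
        small = 0
        for _ in range(20):
            vc = fit_varcomp(Phenotype(rng.normal(size=200)), cov)
            if vc.pve_self < 0.1 and vc.pve_nei < 0.1:
                small += 1
        assert small >= 18

    def test_equal_component_recovery(self):
        """sigma1 = sigma2 = sigma_e at n = 400: the median PVE over repeat
        simulations lands in a band around the true 1/3 (repetition bounds the
        sampling error of the single-replicate split between the two
        correlated kernels)."""
        gmap = nq.default_map()
        cross = nq.sim_cross("f2", gmap, 400, seed=69)
        smap = nq.sim_spatial(400, seed=70)
        gp = nq.calc_genoprob(cross)
        cov = build_covariance(gp, smap, s=30.0)
        rng = np.random.default_rng(71)
        fits = [fit_varcomp(Phenotype(mvn_trait(rng, 1.0, 1.0, 1.0, cov)), cov) for _ in range(5)]
        assert 0.20 <= np.median([v.pve_self for v in fits]) <= 0.46
        assert 0.20 <= np.median([v.pve_nei for v in fits]) <= 0.46

    def test_h2_equals_single_kernel_fit(self, f2_gp, f2_smap, f2_cov):
        rng = np.random.default_rng(72)
        y = mvn_trait(rng, 1.0, 0.3, 1.0, f2_cov)
        ph = Phenotype(y)
        h2 = nq.heritability(ph, f2_gp)
        sig, *_ = aireml(y, ph.design_null(), [f2_cov.K1, np.eye(len(y))])
        assert h2 == pytest.approx(sig[0] / (sig[0] + sig[1]), abs=1e-6)


class TestBinomialPQL:
    def test_rve_nonnegative_and_fit_runs(self, f2_cov):
        rng = np.random.default_rng(80)
        n = f2_cov.K1.shape[0]
        eta = mvn_trait(rng, 1.5, 1.0, 0.3, f2_cov)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        vc = fit_varcomp(Phenotype(y, family="binomial"), f2_cov)
        assert vc.family == "binomial" and vc.sigma_e is None
        assert vc.sigma1 >= 0 and vc.sigma2 >= 0
        assert vc.rve_nei >= 0


class TestDeltaPVE:
    def test_single_usable_scale_returned_with_warning(self, f2_gp, f2_smap):
        rng = np.random.default_rng(90)
        ph = Phenotype(rng.normal(size=f2_gp.n_individuals))
        scales = nq.DistanceScales([25.0], [20.0])
        with pytest.warns(UserWarning, match="only one usable"):
            prof = nq.delta_pve(ph, f2_gp, f2_smap, scales)
        assert prof.s_hat == 25.0

    def test_short_range_scale_recovered(self):
        """Traits generated at the 10th-percentile distance: the selected
        scale is at or adjacent to the 10th-percentile scale in most
        replicates."""
        hits = 0
        for seed in range(5):
            sim = nq.simulate_dataset(nq.SimScenario(seed=seed, true_percentile=10, n=150))
            gp = nq.calc_genoprob(sim.cross)
            scales = nq.distance_scales(sim.smap, 10)
            prof = nq.delta_pve(Phenotype(sim.trait), gp, sim.smap, scales)
            if prof.s_hat_percentile <= 20:
                hits += 1
        assert hits >= 4

    def test_phenotype_kernel_does_not_beat_genotype_kernel(self):
        """On traits generated from genotypic identity, replacing the neighbor
        genotype kernel by the neighbor-phenotype kernel does not increase
        PVE_nei."""
        for seed in (0, 1):
            sim = nq.simulate_dataset(nq.SimScenario(seed=seed, true_percentile=10, n=150))
            gp = nq.calc_genoprob(sim.cross)
            ph = Phenotype(sim.trait)
            cov_g = build_covariance(gp, sim.smap, sim.s_true)
            cov_p = build_covariance(gp, sim.smap, sim.s_true, source="phenotype", ph=ph)
            pve_g = fit_varcomp(ph, cov_g).pve_nei
            pve_p = fit_varcomp(ph, cov_p).pve_nei
            assert pve_p <= pve_g + 0.02
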