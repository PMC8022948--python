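import numpy as np
import pytest

import neiqtl as nq
from neiqtl.exceptions import DegenerateTraitError, ParameterError
from neiqtl.genotypes import AA, BB
from neiqtl.scan import LOG10, Phenotype, perm_threshold, scan_epistasis

from conftest import ols_rss


@pytest.fixture(scope="module")
def f2_pipeline(f2_gp, f2_smap):
    rng = np.random.default_rng(21)
    cov = rng.normal(size=(f2_gp.n_individuals, 1))
    y = rng.normal(size=f2_gp.n_individuals) + 0.3 * cov[:, 0]
    ph = Phenotype(y, covariates=cov, covariate_names=["c1"])
    ni = nq.neighbor_identity(f2_gp, f2_smap, s=30.0)
    sf = nq.scan_self(f2_gp, ph)
    nf = nq.scan_neighbor(f2_gp, ni, ph, sf)
    return ph, ni, sf, nf


class TestGaussianLodOracle:
    def test_self_lod_matches_rss_oracle(self, f2_gp, f2_pipeline):
        """LOD_self equals (n/2) log10(RSS_null / RSS_full) with RSS computed
        independently through explicit hat matrices (this is also the standard
        single-QTL Haley-Knott scan, so parity with it comes for free)."""
        ph, _, sf, _ = f2_pipeline
        X0 = ph.design_null()
        rss0 = ols_rss(X0, ph.values)
        n = ph.n
        xa, xd = f2_gp.additive_score(), f2_gp.dominance_score()
        for p in range(f2_gp.n_positions):
            X1 = np.column_stack([X0, xa[:, p], xd[:, p]])
            expected = (n / 2) * np.log10(rss0 / ols_rss(X1, ph.values))
            assert sf.table["lod_self"].iloc[p] == pytest.approx(expected, abs=1e-8)

    def test_neighbor_lod_matches_rss_oracle(self, f2_gp, f2_pipeline):
        ph, ni, sf, nf = f2_pipeline
        X0 = ph.design_null()
        n = ph.n
        for p in range(f2_gp.n_positions):
            Xs = np.column_stack([X0, sf.self_effect[:, p]])
            z = ni.values[:, p]
            Xn = np.column_stack([Xs, z, z * z])
            expected = (n / 2) * np.log10(ols_rss(Xs, ph.values) / ols_rss(Xn, ph.values))
            assert nf.table["lod_nei"].iloc[p] == pytest.approx(expected, abs=1e-8)

    def test_stepwise_nesting_keeps_lods_nonnegative(self, f2_pipeline):
        _, _, sf, nf = f2_pipeline
        assert (sf.table["lod_self"] >= 0).all()
        assert (nf.table["lod_nei"] >= 0).all()


class TestEffectRecovery:
    def test_noiseless_f2_recovers_homozygote_difference(self):
        """y built from genotype values (a1, d1, -a1) = (0.5, 0, -0.5) at one
        marker: reported 2a1 = mean(AA) - mean(BB) = 1.0, and the LOD at the
        causal marker dwarfs machine noise."""
        gmap = nq.GeneticMap(["1"], {"1": ["m0", "m1"]}, {"1": np.array([0.0, 40.0])})
        cross = nq.sim_cross("f2", gmap, 150, seed=5)
        gp = nq.calc_genoprob(cross, error_prob=0.0)
        g = cross.genotypes[:, 0]
        y = np.array([0.5, 0.0, -0.5])[g]
        sf = nq.scan_self(gp, Phenotype(y))
        assert sf.table["lod_self"].iloc[0] > 1e3
        assert sf.table["eff_2a1"].iloc[0] == pytest.approx(1.0, abs=1e-8)
        assert sf.table["eff_d1"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_ril_neighbor_identity_recovers_2a2sq(self, small_map):
        """Selfed RIL with y equal to the neighbor identity itself: the
        reported signed effect 2a2^2 is +2 (identical homozygote neighbors
        raise the trait by 2 relative to opposite ones)."""
        cross = nq.sim_cross("riself", small_map, 80, seed=6)
        smap = nq.sim_spatial(80, seed=7)
        gp = nq.calc_genoprob(cross, error_prob=0.0)
        ni = nq.neighbor_identity(gp, smap, s=40.0)
        y = ni.values[:, 0].copy()
        ph = Phenotype(y)
        sf = nq.scan_self(gp, ph)
        nf = nq.scan_neighbor(gp, ni, ph, sf)
        assert nf.table["eff_2a2sq"].iloc[0] == pytest.approx(2.0, abs=1e-6)
        assert nf.table["lod_nei"].iloc[0] > 1e3

    def test_positive_sign_means_sharing_alleles_increases_trait(self, small_map):
        cross = nq.sim_cross("riself", small_map, 80, seed=8)
        smap = nq.sim_spatial(80, seed=9)
        gp = nq.calc_genoprob(cross)
        ni = nq.neighbor_identity(gp, smap, s=40.0)
        rng = np.random.default_rng(10)
        y = 0.8 * ni.values[:, 2] + 0.2 * rng.normal(size=80)
        ph = Phenotype(y)
        nf = nq.scan_neighbor(gp, ni, ph, nq.scan_self(gp, ph))
        assert nf.table["eff_2a2sq"].iloc[2] > 0

    def test_two_genotype_codings_give_identical_lod(self, small_map):
        """Backcross-linear and inbred-linear codings on relabeled two-class
        data produce the same neighbor LOD curve."""
        ril = nq.sim_cross("riself", small_map, 100, seed=13)
        bc_geno = np.where(ril.genotypes == BB, 1, ril.genotypes).astype(np.int8)
        bc = nq.CrossPopulation("backcross", bc_geno, ril.ids, small_map)
        smap = nq.sim_spatial(100, seed=14)
        rng = np.random.default_rng(15)
        y = rng.normal(size=100)
        gp_ril = nq.calc_genoprob(ril, error_prob=0.0)
        gp_bc = nq.calc_genoprob(bc, error_prob=0.0)
        ph = Phenotype(y)
        lods = []
        for gp in (gp_ril, gp_bc):
            ni = nq.neighbor_identity(gp, smap, s=40.0)
            nf = nq.scan_neighbor(gp, ni, ph, nq.scan_self(gp, ph))
            lods.append(nf.table["lod_nei"].to_numpy())
        assert np.allclose(lods[0], lods[1], atol=1e-8)


class TestNullBehavior:
    def test_pure_noise_mean_self_lod_small(self, small_map):
        cross = nq.sim_cross("f2", small_map, 200, seed=20)
        gp = nq.calc_genoprob(cross)
        rng = np.random.default_rng(21)
        lods = []
        for _ in range(20):
            sf = nq.scan_self(gp, Phenotype(rng.normal(size=200)))
            lods.append(sf.table["lod_self"].mean())
        assert np.mean(lods) < 0.5

    def test_no_neighbor_effect_mean_nei_lod_small(self):
        """Traits simulated with a2 = d2 = 0: the neighbor scan at the major
        self-QTL stays near zero."""
        lods = []
        for seed in range(20):
            sc = nq.SimScenario(seed=seed, n=150, major_marker=7)
            sim = nq.simulate_dataset(sc)
            ph = Phenotype(sim.self_component)  # self-only trait
            gp = nq.calc_genoprob(sim.cross)
            ni = nq.neighbor_identity(gp, sim.smap, s=30.0)
            nf = nq.scan_neighbor(gp, ni, ph, nq.scan_self(gp, ph))
            mi = gp.grid.marker_grid_indices(sim.cross.map)[7]
            lods.append(nf.table["lod_nei"].iloc[mi])
        assert np.mean(lods) < 0.5

    def test_constant_trait_rejected(self, f2_gp):
        with pytest.raises(DegenerateTraitError):
            nq.scan_self(f2_gp, Phenotype(np.ones(f2_gp.n_individuals)))


class TestBinomial:
    def test_lod_matches_statsmodels_deviance(self, f2_gp, f2_smap):
        """Binomial LODs agree with statsmodels GLM log-likelihood differences."""
        import statsmodels.api as sm

        rng = np.random.default_rng(30)
        n = f2_gp.n_individuals
        y = (rng.random(n) < 0.4).astype(float)
        ph = Phenotype(y, family="binomial")
        sf = nq.scan_self(f2_gp, ph)
        ni = nq.neighbor_identity(f2_gp, f2_smap, 30.0)
        nf = nq.scan_neighbor(f2_gp, ni, ph, sf)
        X0 = ph.design_null()
        ll0 = sm.GLM(y, X0, family=sm.families.Binomial()).fit().llf
        xa, xd = f2_gp.additive_score(), f2_gp.dominance_score()
        for p in range(0, f2_gp.n_positions, 3):
            X1 = np.column_stack([X0, xa[:, p], xd[:, p]])
            ll1 = sm.GLM(y, X1, family=sm.families.Binomial()).fit().llf
            assert sf.table["lod_self"].iloc[p] == pytest.approx(
                (ll1 - ll0) / LOG10, abs=1e-6
            )
            Xs = np.column_stack([X0, sf.self_effect[:, p]])
            z = ni.values[:, p]
            Xn = np.column_stack([Xs, z, z * z])
            lls = sm.GLM(y, Xs, family=sm.families.Binomial()).fit().llf
            lln = sm.GLM(y, Xn, family=sm.families.Binomial()).fit().llf
            assert nf.table["lod_nei"].iloc[p] == pytest.approx(
                (lln - lls) / LOG10, abs=1e-6
            )

    def test_non_binary_trait_rejected(self):
        with pytest.raises(ParameterError):
            Phenotype(np.array([0.0, 0.5, 1.0]), family="binomial")


class TestPermutations:
    def test_threshold_monotone_in_alpha(self, f2_gp, f2_smap):
        rng = np.random.default_rng(40)
        ph = Phenotype(rng.normal(size=f2_gp.n_individuals))
        ni = nq.neighbor_identity(f2_gp, f2_smap, 30.0)
        thr = perm_threshold(f2_gp, ni, ph, n_perm=120, alphas=(0.05, 0.10), seed=1)
        assert thr.thresholds_nei[0.05] >= thr.thresholds_nei[0.10]
        assert thr.thresholds_self[0.05] >= thr.thresholds_self[0.10]
        assert thr.seed == 1 and thr.n_perm == 120

    def test_too_few_permutations_rejected(self, f2_gp, f2_smap):
        ph = Phenotype(np.random.default_rng(0).normal(size=f2_gp.n_individuals))
        ni = nq.neighbor_identity(f2_gp, f2_smap, 30.0)
        with pytest.raises(ParameterError):
            perm_threshold(f2_gp, ni, ph, n_perm=50, alphas=(0.05,))


class TestEpistasis:
    def test_product_interaction_found_at_true_pair(self, f2_gp, f2_smap):
        """A trait built from the product of two positions' identities puts the
        top interaction LOD at (or adjacent to) the true partner in most
        replicates."""
        ni = nq.neighbor_identity(f2_gp, f2_smap, 30.0)
        focal, partner = 2, 11
        hits = 0
        rng = np.random.default_rng(50)
        for _ in range(10):
            zf, zm = ni.values[:, focal], ni.values[:, partner]
            prod = zf * zm
            y = prod / prod.std() + 0.3 * rng.normal(size=len(zf))
            res = scan_epistasis(f2_gp, ni, Phenotype(y), focal)
            top = res.loc[res["lod_int"].idxmax(), "grid_index"]
            if abs(int(top) - partner) <= 1:
                hits += 1
        assert hits >= 8

    def test_null_interaction_lod_small(self, f2_gp, f2_smap):
        ni = nq.neighbor_identity(f2_gp, f2_smap, 30.0)
        rng = np.random.default_rng(51)
        means = [
            scan_epistasis(f2_gp, ni, Phenotype(rng.normal(size=f2_gp.n_individuals)), 2)[
                "lod_int"
            ].mean()
            for _ in range(5)
        ]
        assert np.mean(means) < 0.5

    def test_focal_excluded_and_linked_flagged(self, f2_gp, f2_smap):
        ni = nq.neighbor_identity(f2_gp, f2_smap, 30.0)
        ph = Phenotype(np.random.default_rng(52).normal(size=f2_gp.n_individuals))
        res = scan_epistasis(f2_gp, ni, ph, 2, linked_cm=1.0)
        assert 2 not in res["grid_index"].to_numpy()
        grid = f2_gp.grid.to_frame().reset_index()
        near = res[
            (res["chromosome"] == grid.loc[2, "chromosome"])
            & ((res["position"] - grid.loc[2, "position"]).abs() <= 1.0)
        ]
        assert near["linked"].all()
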