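import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from stepblup.mme import build_design
from stepblup.pedigree import build_A, build_A_inverse, extract_A22
from stepblup.recovery import recovery_config
from stepblup.reml import (
    ai_reml,
    ai_reml_bivariate,
    ai_reml_from_design,
    reml_loglik,
)
from stepblup.simulate import simulate_dataset


def small_sim(seed=5, **overrides):
    """~60-boar, 4-generation simulation used across the REML tests."""
    from stepblup.simulate import SimulationConfig

    params = dict(
        n_generations=4,
        n_founders=30,
        n_sires_per_gen=5,
        n_dams_per_gen=14,
        offspring_per_mating=2,
        n_snps=10,
        traits=["T"],
        variance_components_per_trait={"T": (4.0, 2.0, 6.0)},
        trait_means={"T": 10.0},
        pheno_generations=[1, 2, 3],
        records_per_boar_mean=5.0,
        n_year_seasons=4,
        genotyping_proportion_by_generation=[0] * 4,
        seed=seed,
    )
    params.update(overrides)
    cfg = SimulationConfig(**params)
    sim = simulate_dataset(cfg, with_genotypes=False)
    design = build_design(sim.phenotypes, sim.pedigree.ids, trait=params["traits"][0])
    return sim, design


class TestLoglik:
    def test_dense_and_mme_paths_agree(self):
        sim, d = small_sim()
        A = build_A(sim.pedigree).toarray()
        Ainv = build_A_inverse(sim.pedigree)
        for theta in [(4.0, 2.0, 6.0), (1.0, 0.5, 9.0), (8.0, 3.0, 2.0)]:
            dense = reml_loglik(d.y, d.X, d.Z, d.W, theta, K=A, method="dense")
            mme = reml_loglik(d.y, d.X, d.Z, d.W, theta, K_inv=Ainv, method="mme")
            assert mme == pytest.approx(dense, abs=1e-8)

    def test_scale_equivariance(self):
        sim, d = small_sim()
        A = build_A(sim.pedigree).toarray()
        c = 3.0
        theta = (4.0, 2.0, 6.0)
        scaled = tuple(c**2 * t for t in theta)
        base = reml_loglik(d.y, d.X, d.Z, d.W, theta, K=A, method="dense")
        up = reml_loglik(c * d.y, d.X, d.Z, d.W, scaled, K=A, method="dense")
        n_star = d.n - d.X.shape[1]
        assert up == pytest.approx(base - 0.5 * n_star * np.log(c**2), abs=1e-8)

    def test_redundant_fixed_column_leaves_likelihood_unchanged(self):
        sim, d = small_sim()
        A = build_A(sim.pedigree).toarray()
        theta = (4.0, 2.0, 6.0)
        base = reml_loglik(d.y, d.X, d.Z, d.W, theta, K=A, method="dense")
        X2 = np.column_stack([d.X, d.X[:, 0] + d.X[:, 1]])
        dup = reml_loglik(d.y, X2, d.Z, d.W, theta, K=A, method="dense")
        assert dup == pytest.approx(base, abs=1e-9)


class TestAIReml:
    def test_matches_direct_likelihood_maximiser_on_toy(self):
        sim, d = small_sim(seed=11)
        # ~30-record toy: restrict to the first boars' records
        keep = d.record_index < d.record_index[0] + 1e18  # all; then slice frame
        rec = sim.phenotypes.records.iloc[:30].copy()
        from stepblup.mme import TraitDataset

        toy = TraitDataset(rec, ["T"])
        design = build_design(toy, sim.pedigree.ids, trait="T")
        A = build_A(sim.pedigree).toarray()
        Ainv = build_A_inverse(sim.pedigree)
        vc = ai_reml(design.y, design.X, design.Z, design.W, Ainv)

        def neg(logth):
            th = np.exp(logth)
            return -reml_loglik(
                design.y, design.X, design.Z, design.W, th, K=A, method="dense"
            )

        opt = scipy.optimize.minimize(
            neg,
            np.log([np.var(design.y) / 3] * 3),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        # likelihoods at the two optima agree to numerical precision
        assert vc.loglik == pytest.approx(-opt.fun, abs=1e-6)
        scale = np.var(design.y)
        for got, want in zip([vc.sigma_a2, vc.sigma_p2, vc.sigma_e2], np.exp(opt.x)):
            # components at the zero boundary agree in absolute terms only
            assert got == pytest.approx(want, rel=2e-3, abs=1e-5 * scale)

    def test_record_order_invariance(self):
        sim, d = small_sim(seed=7)
        Ainv = build_A_inverse(sim.pedigree)
        vc1 = ai_reml_from_design(d, Ainv)
        rng = np.random.default_rng(0)
        perm = rng.permutation(sim.phenotypes.n_records)
        from stepblup.mme import TraitDataset

        shuffled = TraitDataset(
            sim.phenotypes.records.iloc[perm].reset_index(drop=True), ["T"]
        )
        d2 = build_design(shuffled, sim.pedigree.ids, trait="T")
        vc2 = ai_reml_from_design(d2, Ainv)
        assert vc1.sigma_a2 == pytest.approx(vc2.sigma_a2, rel=1e-6)
        assert vc1.sigma_e2 == pytest.approx(vc2.sigma_e2, rel=1e-6)

    def test_em_fallback_steps_never_decrease_likelihood(self):
        # a low-variance trait exercises the EM fallback path
        sim, d = small_sim(
            seed=21, variance_components_per_trait={"T": (0.05, 0.1, 3.0)}
        )
        Ainv = build_A_inverse(sim.pedigree)
        vc = ai_reml_from_design(d, Ainv)
        traj = vc.trajectory
        for prev, cur in zip(traj, traj[1:]):
            if cur["step"] == "EM":
                assert cur["neg2"] <= prev["neg2"] + 1e-6

    def test_boundary_component_is_flagged_not_fatal(self):
        sim, d = small_sim(
            seed=32, variance_components_per_trait={"T": (4.0, 0.0, 6.0)}
        )
        Ainv = build_A_inverse(sim.pedigree)
        with pytest.warns(UserWarning, match="boundary"):
            vc = ai_reml_from_design(d, Ainv)
        assert vc.boundary
        assert vc.sigma_p2 < 0.05 * vc.total
        # heritability remains estimable: truth 0.4, loose 2-SE-style band
        assert abs(vc.h2 - 0.4) < 0.25

    def test_collapsed_boar_model_equals_full_pedigree_model(self):
        """The boar-collapsed K = A_bb parameterisation must reproduce the
        full-pedigree animal-model REML estimates exactly."""
        sim, d = small_sim(seed=41)
        Ainv = build_A_inverse(sim.pedigree)
        full = ai_reml_from_design(d, Ainv)
        boars = sim.phenotypes.boars
        A_bb = extract_A22(sim.pedigree, boars).toarray()
        K_inv = np.linalg.inv(A_bb)
        d2 = build_design(sim.phenotypes, boars, trait="T")
        collapsed = ai_reml(d2.y, d2.X, d2.Z, d2.W, K_inv)
        assert collapsed.sigma_a2 == pytest.approx(full.sigma_a2, rel=1e-4)
        assert collapsed.sigma_p2 == pytest.approx(full.sigma_p2, rel=1e-4)
        assert collapsed.sigma_e2 == pytest.approx(full.sigma_e2, rel=1e-4)
        assert collapsed.loglik == pytest.approx(
            full.loglik + 0.5 * np.linalg.slogdet(A_bb)[1] * 0, abs=5e-3
        )


class TestBivariate:
    def _bivariate_sim(self, rg, seed, vc1=(4.0, 2.0, 6.0), vc2=(3.0, 1.5, 5.0),
                       n_founders=60, records=5.0):
        from stepblup.simulate import SimulationConfig

        cfg = SimulationConfig(
            n_generations=4,
            n_founders=n_founders,
            n_sires_per_gen=8,
            n_dams_per_gen=n_founders // 2 - 2,
            offspring_per_mating=2,
            n_snps=10,
            traits=["T1", "T2"],
            variance_components_per_trait={"T1": vc1, "T2": vc2},
            trait_means={"T1": 0.0, "T2": 0.0},
            genetic_correlation_matrix=np.array([[1.0, rg], [rg, 1.0]]),
            pheno_generations=[1, 2, 3],
            records_per_boar_mean=records,
            n_year_seasons=4,
            genotyping_proportion_by_generation=[0] * 4,
            seed=seed,
        )
        sim = simulate_dataset(cfg, with_genotypes=False)
        d = build_design(sim.phenotypes, sim.pedigree.ids, trait="T1")
        Y = sim.phenotypes.records[["T1", "T2"]].to_numpy(float)
        Ainv = build_A_inverse(sim.pedigree)
        return sim, d, Y, Ainv

    def test_duplicated_trait_with_fresh_residuals_has_unit_correlation(self):
        sim, d, _, Ainv = self._bivariate_sim(0.0, seed=3)
        rec = sim.phenotypes.records
        truth = sim.truth
        rng = np.random.default_rng(17)
        a = truth.breeding_values.loc[rec["id"], "T1"].to_numpy()
        p = truth.permanent_env.loc[rec["id"], "T1"].to_numpy()
        fixed = truth.record_fixed["T1"].to_numpy()
        y2 = fixed + a + p + rng.normal(0, np.sqrt(6.0), size=len(rec))
        Y = np.column_stack([rec["T1"].to_numpy(float), y2])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            est = ai_reml_bivariate(Y, d.X, d.Z, d.W, Ainv)
        se = est.genetic_correlation_se or 0.1
        assert est.genetic_correlation > 1.0 - 2 * max(se, 0.05)

    def test_zero_genetic_covariance_recovered_near_zero(self):
        sim, d, Y, Ainv = self._bivariate_sim(
            0.0, seed=9, vc1=(5.0, 2.0, 3.0), vc2=(5.0, 2.0, 3.0),
            n_founders=120, records=6.0
        )
        est = ai_reml_bivariate(Y, d.X, d.Z, d.W, Ainv)
        assert abs(est.genetic_correlation) < 0.1 + 2 * (est.genetic_correlation_se or 0)

    def test_marginal_equals_single_trait_when_covariances_fixed_at_zero(self):
        sim, d, Y, Ainv = self._bivariate_sim(0.4, seed=13)
        est = ai_reml_bivariate(Y, d.X, d.Z, d.W, Ainv, fix_covariances=True)
        single = ai_reml(Y[:, 0], d.X, d.Z, d.W, Ainv)
        assert est.sigma_a[0, 0] == pytest.approx(single.sigma_a2, rel=1e-3)
        assert est.sigma_p[0, 0] == pytest.approx(single.sigma_p2, rel=1e-3)
        assert est.sigma_e[0, 0] == pytest.approx(single.sigma_e2, rel=1e-3)
        assert est.sigma_a[0, 1] == 0.0


def test_parameter_recovery_structure_smoke():
    """recovery_config builds the reduced study-shaped population."""
    cfg = recovery_config({"T1": (7.27, 4.25, 13.12)}, seed=2)
    sim = simulate_dataset(cfg, with_genotypes=False)
    assert sim.pedigree.generations.max() == 11
    n_boars = sim.phenotypes.records["id"].nunique()
    assert 850 <= n_boars <= 1100
    mean_records = sim.phenotypes.n_records / n_boars
    assert 18 <= mean_records <= 22
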