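import numpy as np
import pandas as pd
import pytest

from stepblup.genomic import MISSING
from stepblup.pedigree import build_A
from stepblup.simulate import (
    ConfigurationError,
    SimulationConfig,
    simulate_breeding_values,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


def small_cfg(**kw):
    base = dict(
        n_generations=4,
        n_founders=20,
        n_sires_per_gen=4,
        n_dams_per_gen=8,
        offspring_per_mating=2,
        n_snps=50,
        traits=["T"],
        variance_components_per_trait={"T": (4.0, 2.0, 6.0)},
        trait_means={"T": 10.0},
        pheno_generations=[2, 3],
        records_per_boar_mean=5.0,
        n_year_seasons=4,
        genotyping_proportion_by_generation=[0, 0, 0.5, 0.5],
        seed=77,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            small_cfg(n_generations=0)

    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ConfigurationError, match="PSD"):
            small_cfg(
                traits=["A", "B"],
                variance_components_per_trait={"A": (1, 1, 1), "B": (1, 1, 1)},
                trait_means={"A": 0, "B": 0},
                genetic_correlation_matrix=bad,
            )

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigurationError, match="negative"):
            small_cfg(variance_components_per_trait={"T": (-1.0, 1.0, 1.0)})


class TestPedigreeSim:
    def test_generation_labels_and_founders(self):
        ped = simulate_pedigree(SimulationConfig.demo(seed=3))
        assert ped.generations.max() == 7  # demo profile: 8 generations
        founders = ped.frame[ped.frame["generation"] == 0]
        assert founders["sire"].isna().all() and founders["dam"].isna().all()

    def test_twelve_generation_default_labels(self):
        cfg = small_cfg(n_generations=12, n_founders=30, n_dams_per_gen=10)
        ped = simulate_pedigree(cfg)
        assert ped.generations.max() == 11

    def test_monogamous_matings_give_full_sib_pairs(self):
        cfg = small_cfg(monogamous=True)
        ped = simulate_pedigree(cfg)
        A = build_A(ped).to_frame()
        offspring = ped.frame[ped.frame["generation"] == 1]
        sibs = offspring.groupby(["sire", "dam"])["id"].apply(list)
        checked = 0
        for ids in sibs:
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    assert A.loc[ids[i], ids[j]] == pytest.approx(0.5)
                    checked += 1
        assert checked > 0

    def test_same_seed_is_byte_identical(self):
        p1 = simulate_pedigree(small_cfg())
        p2 = simulate_pedigree(small_cfg())
        pd.testing.assert_frame_equal(p1.frame, p2.frame)


class TestGenotypeSim:
    def test_codes_and_mendelian_consistency(self):
        cfg = small_cfg(missing_rate=0.0)
        ped = simulate_pedigree(cfg)
        gm = simulate_genotypes(ped, cfg)
        codes = gm.codes
        assert set(np.unique(codes)) <= {0, 1, 2}
        pos = {a: i for i, a in enumerate(gm.ids)}
        for i in range(ped.n):
            s, d = ped.sire_idx[i], ped.dam_idx[i]
            if s < 0 or d < 0:
                continue
            off, cs, cd = codes[i], codes[s], codes[d]
            # homozygous parent pairs fully determine the offspring
            both0 = (cs == 0) & (cd == 0)
            both2 = (cs == 2) & (cd == 2)
            opposite = ((cs == 0) & (cd == 2)) | ((cs == 2) & (cd == 0))
            assert (off[both0] == 0).all()
            assert (off[both2] == 2).all()
            assert (off[opposite] == 1).all()

    def test_pooled_allele_frequency_tracks_founder_maf(self):
        cfg = small_cfg(
            founder_maf_range=(0.3, 0.3), n_snps=400, missing_rate=0.0
        )
        ped = simulate_pedigree(cfg)
        gm = simulate_genotypes(ped, cfg)
        # founder allele count is binomial(2 * n_founders, 0.3) per locus
        founder_codes = gm.codes[: cfg.n_founders]
        p_hat = founder_codes.mean() / 2.0
        se = np.sqrt(0.3 * 0.7 / (2 * cfg.n_founders * cfg.n_snps))
        assert abs(p_hat - 0.3) < 3 * se

    def test_missing_rate_injection(self):
        cfg = small_cfg(missing_rate=0.1, n_snps=300)
        ped = simulate_pedigree(cfg)
        gm = simulate_genotypes(ped, cfg)
        frac = (gm.codes == MISSING).mean()
        assert abs(frac - 0.1) < 0.01


class TestBreedingValues:
    def test_founder_covariance_matches_truth(self):
        cfg = SimulationConfig(
            n_generations=1,
            n_founders=4000,
            n_snps=1,
            traits=["A", "B"],
            variance_components_per_trait={"A": (4.0, 0, 1.0), "B": (9.0, 0, 1.0)},
            trait_means={"A": 0, "B": 0},
            genetic_correlation_matrix=np.array([[1.0, 0.5], [0.5, 1.0]]),
            pheno_generations=[0],
            seed=5,
        )
        ped = simulate_pedigree(cfg)
        truth = simulate_breeding_values(ped, cfg)
        emp = np.cov(truth.breeding_values.to_numpy().T)
        expect = np.array([[4.0, 3.0], [3.0, 9.0]])
        np.testing.assert_allclose(emp, expect, rtol=0.12)

    def test_uncorrelated_traits_have_near_zero_bv_correlation(self):
        cfg = SimulationConfig(
            n_generations=1,
            n_founders=5000,
            n_snps=1,
            traits=["A", "B"],
            variance_components_per_trait={"A": (1.0, 0, 1.0), "B": (1.0, 0, 1.0)},
            trait_means={"A": 0, "B": 0},
            genetic_correlation_matrix=np.eye(2),
            pheno_generations=[0],
            seed=6,
        )
        ped = simulate_pedigree(cfg)
        truth = simulate_breeding_values(ped, cfg)
        r = np.corrcoef(truth.breeding_values.to_numpy().T)[0, 1]
        assert abs(r) < 0.05

    def test_mendelian_sampling_variance_for_noninbred_parents(self):
        # one sire x one dam, many full sibs: var(a_off - parent mean) = sa/2
        rows = [(1, 0, 0, 0), (2, 0, 0, 0)] + [
            (i, 1, 2, 1) for i in range(3, 4003)
        ]
        frame = pd.DataFrame(rows, columns=["id", "sire", "dam", "generation"])
        from stepblup.pedigree import read_and_validate_pedigree

        ped = read_and_validate_pedigree(frame)
        cfg = small_cfg(variance_components_per_trait={"T": (8.0, 2.0, 6.0)})
        truth = simulate_breeding_values(ped, cfg, rng=np.random.default_rng(8))
        bv = truth.breeding_values["T"]
        dev = bv.loc[3:] - 0.5 * (bv.loc[1] + bv.loc[2])
        assert np.var(dev) == pytest.approx(4.0, rel=0.1)


class TestPhenotypes:
    def test_degenerate_variances_reduce_to_intercept_plus_bv(self):
        cfg = small_cfg(
            variance_components_per_trait={"T": (4.0, 0.0, 0.0)},
            n_year_seasons=1,
            year_season_effect_sd=0.0,
            age_slope=0.0,
            interval_slope=0.0,
        )
        ped = simulate_pedigree(cfg)
        truth = simulate_breeding_values(ped, cfg)
        data = simulate_phenotypes(ped, truth, cfg)
        rec = data.records
        a = truth.breeding_values.loc[rec["id"], "T"].to_numpy()
        np.testing.assert_allclose(rec["T"].to_numpy(), 10.0 + a, atol=1e-10)

    def test_reconstruction_identity(self, demo_sim):
        rec = demo_sim.phenotypes.records
        truth = demo_sim.truth
        for trait in demo_sim.config.traits:
            a = truth.breeding_values.loc[rec["id"], trait].to_numpy()
            p = truth.permanent_env.loc[rec["id"], trait].to_numpy()
            e = truth.record_residual[trait].to_numpy()
            fixed = truth.record_fixed[trait].to_numpy()
            np.testing.assert_allclose(
                rec[trait].to_numpy(), fixed + a + p + e, atol=1e-10
            )

    def test_intraclass_correlation_matches_repeatability(self):
        # distal-droplet-like components: r = (sa+sp)/(sa+sp+se)
        vc = (7.2729, 4.2530, 13.1157)
        cfg = small_cfg(
            n_founders=200,
            n_dams_per_gen=90,
            n_sires_per_gen=12,
            pheno_generations=[1, 2, 3],
            records_per_boar_mean=10.0,
            variance_components_per_trait={"T": vc},
            year_season_effect_sd=0.0,
            age_slope=0.0,
            interval_slope=0.0,
            n_year_seasons=1,
        )
        ped = simulate_pedigree(cfg)
        truth = simulate_breeding_values(ped, cfg)
        data = simulate_phenotypes(ped, truth, cfg)
        rec = data.records
        grand = rec["T"].mean()
        groups = rec.groupby("id")["T"]
        n_bar = groups.size().mean()
        between = groups.mean().var(ddof=1) * n_bar
        within = (rec["T"] - groups.transform("mean")).pow(2).sum() / (
            len(rec) - groups.ngroups
        )
        icc = (between - within) / (between + (n_bar - 1) * within)
        truth_icc = (vc[0] + vc[1]) / sum(vc)
        # the between-boar variance also carries genetic covariance among
        # relatives, so allow a generous band around the target
        assert abs(icc - truth_icc) < 0.1

    def test_mean_records_per_boar(self):
        cfg = small_cfg(records_per_boar_mean=22.6, pheno_generations=[1, 2, 3])
        ped = simulate_pedigree(cfg)
        truth = simulate_breeding_values(ped, cfg)
        data = simulate_phenotypes(ped, truth, cfg)
        n_boars = data.records["id"].nunique()
        mean_records = len(data.records) / n_boars
        # zero-truncated Poisson around 22.6: SE ~ sqrt(22.6/n_boars)
        assert abs(mean_records - 22.6) < 4 * np.sqrt(22.6 / n_boars)


def test_dataset_determinism():
    s1 = simulate_dataset(small_cfg())
    s2 = simulate_dataset(small_cfg())
    pd.testing.assert_frame_equal(s1.pedigree.frame, s2.pedigree.frame)
    pd.testing.assert_frame_equal(s1.phenotypes.records, s2.phenotypes.records)
    np.testing.assert_array_equal(s1.genotypes.codes, s2.genotypes.codes)
    assert list(s1.genotyped_ids) == list(s2.genotyped_ids)
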