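import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepblup.genomic import (
    MISSING,
    GenotypeMatrix,
    HBlendConfig,
    allele_frequencies,
    blend_G,
    build_G,
    build_H_inverse,
    fill_missing_as_heterozygote,
    hwe_exact_test,
    qc_filter,
)
from stepblup.mme import ModelSpec, TraitDataset, build_design, solve_mme
from stepblup.pedigree import (
    RelationshipMatrix,
    build_A,
    build_A_inverse,
    extract_A22,
    read_and_validate_pedigree,
)
from tests.oracles import dense_H, hwe_exact_enumeration, random_pedigree


def gm(codes, ids=None):
    codes = np.asarray(codes, dtype=np.int8)
    ids = ids if ids is not None else [f"i{k}" for k in range(codes.shape[0])]
    snps = [f"s{k}" for k in range(codes.shape[1])]
    return GenotypeMatrix(codes, pd.Index(ids), pd.Index(snps))


class TestHWE:
    def test_perfect_proportions_give_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_total_heterozygote_deficit_is_extreme(self):
        assert hwe_exact_test(50, 0, 50) < 1e-5

    def test_monomorphic_is_uninformative(self):
        assert hwe_exact_test(0, 0, 10) == 1.0

    def test_zero_counts_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert hwe_exact_test(0, 0, 0) == 1.0

    @given(
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_full_enumeration_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        p = hwe_exact_test(a, h, b)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(hwe_exact_enumeration(a, h, b), rel=1e-9)

    def test_chi2_variant_available(self):
        p = hwe_exact_test(50, 0, 50, method="chi2")
        assert p < 1e-5


class TestQC:
    def test_fixed_allele_removed_others_kept(self):
        m = gm([[0, 2, 1], [0, 1, 1], [0, 2, 0], [0, 1, 2]])
        out, rep = qc_filter(m, hwe_p=0.0)
        assert list(out.snp_ids) == ["s1", "s2"]
        assert rep.removed("snps") == 1

    def test_low_call_rate_individual_removed(self):
        codes = np.ones((3, 10), dtype=np.int8)
        codes[0, :2] = MISSING  # call rate 0.8 < 0.9
        out, rep = qc_filter(gm(codes), maf=0.0, hwe_p=0.0)
        assert out.n_individuals == 2
        assert rep.steps[0] == ("individual_call_rate", "individuals", 1)

    def test_planted_violations_match_hand_count(self, rng):
        # 40 individuals x 12 SNPs in HWE, then plant failures
        n = 40
        codes = rng.binomial(2, 0.4, size=(n, 12)).astype(np.int8)
        codes[:, 0] = 0  # monomorphic -> MAF filter
        codes[:, 1] = np.where(np.arange(n) % 2 == 0, 0, 2)  # no hets -> HWE
        codes[0, 2:8] = MISSING  # individual call rate 0.5
        codes[1:, 2] = MISSING  # SNP call rate ~0 (after ind removal)
        out, rep = qc_filter(gm(codes))
        steps = dict((f, nrem) for f, _, nrem in rep.steps)
        assert steps["individual_call_rate"] == 1
        assert steps["snp_call_rate"] == 1
        assert steps["maf"] == 1
        assert steps["hwe"] >= 1
        assert rep.n_individuals_out == 39
        assert rep.n_individuals_in == 40 and rep.n_snps_in == 12

    def test_idempotent(self, rng):
        codes = rng.binomial(2, 0.3, size=(60, 30)).astype(np.int8)
        codes[rng.random(codes.shape) < 0.02] = MISSING
        once, _ = qc_filter(gm(codes))
        twice, rep2 = qc_filter(once)
        assert rep2.removed("snps") == 0 and rep2.removed("individuals") == 0
        np.testing.assert_array_equal(once.codes, twice.codes)

    def test_all_snps_removed_is_an_error(self):
        m = gm([[0, 0], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="all SNPs"):
            qc_filter(m)


class TestMissingFill:
    def test_no_missing_is_noop(self):
        m = gm([[0, 1], [2, 1]])
        out = fill_missing_as_heterozygote(m)
        np.testing.assert_array_equal(out.codes, m.codes)

    def test_single_cell_fill(self):
        m = gm([[0, MISSING], [2, 1]])
        out = fill_missing_as_heterozygote(m)
        assert out.codes[0, 1] == 1
        assert out.codes[0, 0] == 0 and out.codes[1, 0] == 2

    def test_low_rate_fixture_changes_expected_fraction(self, rng):
        codes = rng.binomial(2, 0.4, size=(700, 1500)).astype(np.int8)
        mask = rng.random(codes.shape) < 0.0014
        codes[mask] = MISSING
        out = fill_missing_as_heterozygote(gm(codes))
        changed = (out.codes == 1) & mask
        assert changed.sum() == mask.sum()
        assert mask.mean() == pytest.approx(0.0014, rel=0.12)


class TestG:
    def test_hand_example_two_individuals_one_snp(self):
        m = gm([[2], [0]])
        G = build_G(m, freqs=np.array([0.5]))
        np.testing.assert_allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicated_individual_rows_match(self, rng):
        codes = rng.binomial(2, 0.3, size=(10, 200)).astype(np.int8)
        codes[9] = codes[0]
        G = build_G(gm(codes)).values
        np.testing.assert_allclose(G[0], G[9])
        assert G[0, 0] == pytest.approx(G[9, 9])

    def test_unrelated_sample_moments(self, rng):
        n, m = 400, 4000
        p = rng.uniform(0.1, 0.5, size=m)
        codes = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        G = build_G(gm(codes)).values
        off = G[np.triu_indices(n, 1)]
        assert np.abs(np.diag(G).mean() - 1.0) < 0.05
        assert np.abs(off.mean()) < 0.05

    def test_allele_swap_invariance(self, rng):
        codes = rng.binomial(2, 0.3, size=(15, 300)).astype(np.int8)
        G1 = build_G(gm(codes)).values
        G2 = build_G(gm(2 - codes)).values
        np.testing.assert_allclose(G1, G2, atol=1e-10)

    def test_missing_codes_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_G(gm([[MISSING, 1], [0, 2]]))

    def test_frequencies_before_or_after_fill(self):
        m = gm([[0, MISSING], [2, 1], [1, 1]])
        after = allele_frequencies(m, fill_first=True)
        before = allele_frequencies(m, fill_first=False)
        assert after[1] == pytest.approx(0.5)  # (1+1+1)/6
        assert before[1] == pytest.approx(0.5)  # (1+1)/4
        assert after[0] == before[0] == pytest.approx(0.5)


class TestBlend:
    def test_weight_one_returns_G(self, rng):
        codes = rng.binomial(2, 0.3, size=(8, 100)).astype(np.int8)
        G = build_G(gm(codes))
        A22 = RelationshipMatrix(np.eye(8), G.ids, role="A22")
        Gw = blend_G(G, A22, HBlendConfig(weight=1.0))
        np.testing.assert_allclose(Gw.values, G.values)

    def test_arithmetic(self):
        ids = pd.Index(["a", "b"])
        G = RelationshipMatrix(np.array([[1.0, 0.8], [0.8, 1.0]]), ids, "G")
        A22 = RelationshipMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ids, "A22")
        Gw = blend_G(G, A22, 0.9)
        assert Gw.values[0, 1] == pytest.approx(0.77)

    def test_eigenvalue_floor_from_A22(self, rng):
        # blending with PSD A22 keeps Gw comfortably invertible
        codes = rng.binomial(2, 0.4, size=(30, 20)).astype(np.int8)  # n > m: G singular
        G = build_G(gm(codes))
        A22 = RelationshipMatrix(np.eye(30), G.ids, role="A22")
        Gw = blend_G(G, A22, 0.9)
        lo = np.linalg.eigvalsh(Gw.toarray()).min()
        assert lo >= 0.1 * 1.0 - 1e-8

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            HBlendConfig(weight=0.0)

    def test_order_mismatch_rejected(self):
        G = RelationshipMatrix(np.eye(2), pd.Index(["a", "b"]), "G")
        A22 = RelationshipMatrix(np.eye(2), pd.Index(["b", "a"]), "A22")
        with pytest.raises(ValueError, match="order"):
            blend_G(G, A22)


class TestHInverse:
    def _pedigree_with_genotypes(self, seed=31, n_geno=15):
        ped = read_and_validate_pedigree(
            random_pedigree(10, 30, seed=seed, generations=4)
        )
        rng = np.random.default_rng(seed)
        gids = pd.Index(
            sorted(rng.choice(ped.ids.to_numpy(), size=n_geno, replace=False))
        )
        codes = rng.binomial(2, 0.4, size=(n_geno, 500)).astype(np.int8)
        G = build_G(gm(codes, ids=gids))
        return ped, gids, G

    def test_no_genotyped_animals_returns_A_inverse(self, trio_pedigree):
        A_inv = build_A_inverse(trio_pedigree)
        empty = RelationshipMatrix(np.zeros((0, 0)), pd.Index([]), "G_blended")
        a22 = RelationshipMatrix(np.zeros((0, 0)), pd.Index([]), "A22")
        H_inv = build_H_inverse(A_inv, a22, empty)
        np.testing.assert_allclose(H_inv.toarray(), A_inv.toarray())
        assert H_inv.role == "H_inverse"

    def test_Gw_equal_A22_cancels_to_A_inverse(self):
        ped, gids, _ = self._pedigree_with_genotypes()
        A_inv = build_A_inverse(ped)
        A22 = extract_A22(ped, gids)
        Gw_eq = RelationshipMatrix(A22.toarray().copy(), gids, "G_blended")
        H_inv = build_H_inverse(A_inv, A22, Gw_eq)
        np.testing.assert_allclose(H_inv.toarray(), A_inv.toarray(), atol=1e-8)

    def test_correction_zero_outside_genotyped_block(self):
        ped, gids, G = self._pedigree_with_genotypes()
        A_inv = build_A_inverse(ped)
        A22 = extract_A22(ped, gids)
        Gw = blend_G(G, A22, 0.9)
        H_inv = build_H_inverse(A_inv, A22, Gw)
        diff = H_inv.toarray() - A_inv.toarray()
        pos = A_inv.ids.get_indexer(gids)
        mask = np.zeros_like(diff, dtype=bool)
        mask[np.ix_(pos, pos)] = True
        assert np.abs(diff[~mask]).max() == 0.0

    def test_mme_with_H_inverse_matches_dense_H_oracle(self):
        ped, gids, G = self._pedigree_with_genotypes(seed=77, n_geno=12)
        A = build_A(ped)
        A_inv = build_A_inverse(ped)
        A22 = extract_A22(ped, gids)
        Gw = blend_G(G, A22, 0.9)
        H_inv = build_H_inverse(A_inv, A22, Gw)

        H = dense_H(A.toarray(), ped.positions(gids), Gw.toarray())
        np.testing.assert_allclose(
            np.linalg.inv(H_inv.toarray()), H, atol=1e-7
        )

        # phenotypes on a subset of animals; EBVs via both K parameterisations
        rng = np.random.default_rng(4)
        rec_ids = rng.choice(ped.ids.to_numpy(), size=20, replace=False)
        rec = pd.DataFrame(
            {
                "id": np.repeat(rec_ids, 2),
                "year_season": "all",
                "age_months": 12.0,
                "interval_days": 5.0,
                "T": rng.normal(size=40),
            }
        )
        data = TraitDataset(rec, ["T"])
        design = build_design(data, ped.ids, ModelSpec(fixed_classes=(), covariates=()))
        sol_sparse = solve_mme(design, H_inv, sigma_a2=1.0, sigma_e2=2.0, sigma_p2=0.5)
        sol_dense = solve_mme(
            design, np.linalg.inv(H), sigma_a2=1.0, sigma_e2=2.0, sigma_p2=0.5
        )
        assert np.abs(sol_sparse.ebv - sol_dense.ebv).max() < 1e-6
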