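"""Polygenic scoring: LD r^2, clumping, weighting, PCA, adjustment."""

import numpy as np
import pandas as pd
import pytest

from gxetwin.prs import (AlleleMismatchError, ClumpConfig, MonomorphicSnpError,
                         adjust_score, clump, genotype_pca, ld_r2, score,
                         score_set)


class TestLdR2:
    def test_identical_vectors(self):
        assert ld_r2([0, 1, 2, 0, 1], [0, 1, 2, 0, 1]) == pytest.approx(1.0)

    def test_perfect_negative_ld(self):
        assert ld_r2([0, 1, 2, 0], [2, 1, 0, 2]) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.3, 10_000)
        b = rng.binomial(2, 0.4, 10_000)
        assert ld_r2(a, b) < 0.01

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicSnpError):
            ld_r2([1, 1, 1, 1], [0, 1, 2, 0])

    def test_complete_pairs_only(self):
        a = [0.0, 1, 2, 0, np.nan]
        b = [0.0, 1, 2, 0, 2]
        assert ld_r2(a, b) == pytest.approx(1.0)


def _block_cohort(seed=0, n=4000):
    """3 SNPs in tight LD (pairwise r^2 ~ 0.5) plus one unlinked SNP."""
    rng = np.random.default_rng(seed)
    base = rng.binomial(1, 0.5, (n, 2)).sum(axis=1)

    def tag(r2):
        # per-haplotype copy-with-flip at sqrt(r2)
        keep = rng.random((n, 2)) < np.sqrt(r2)
        h = np.column_stack([np.clip(base, 0, 1), (base > 1).astype(int)])
        fresh = rng.binomial(1, 0.5, (n, 2))
        return np.where(keep, h, fresh).sum(axis=1)

    dos = pd.DataFrame({
        "b1": base, "b2": tag(0.5), "b3": tag(0.5),
        "u1": rng.binomial(2, 0.5, n),
    }, index=[f"i{k}" for k in range(n)])
    ss = pd.DataFrame({
        "SNP": ["b1", "b2", "b3", "u1"],
        "CHR": [1, 1, 1, 1],
        "BP": [1000, 2000, 3000, 900_000],
        "A1": ["A"] * 4, "A2": ["G"] * 4,
        "FREQ": [0.5] * 4,
        "BETA": [0.1, 0.1, 0.1, 0.1],
        "SE": [0.01] * 4,
        "P": [1e-8, 1e-6, 1e-4, 0.3],
    })
    return ss, dos


class TestClump:
    def test_independent_snps_all_retained(self, toy_sumstats, toy_dosages):
        rng = np.random.default_rng(1)
        dos = pd.DataFrame(rng.binomial(2, 0.5, (500, 5)),
                           columns=toy_sumstats["SNP"])
        out = clump(toy_sumstats, dos, ClumpConfig())
        assert set(out["SNP"]) == set(toy_sumstats["SNP"])

    def test_block_keeps_lead_snp_only(self):
        ss, dos = _block_cohort()
        out = clump(ss, dos, ClumpConfig(r2_threshold=0.1, window_kb=250))
        assert set(out["SNP"]) == {"b1", "u1"}

    def test_posthoc_greedy_oracle(self):
        """No retained pair in-window exceeds the threshold, and every
        removed SNP has a retained, more significant in-window neighbour
        above the threshold (exhaustive replay of the greedy definition)."""
        ss, dos = _block_cohort(seed=3)
        cfg = ClumpConfig(r2_threshold=0.1, window_kb=250)
        out = clump(ss, dos, cfg)
        retained = set(out["SNP"])
        info = ss.set_index("SNP")
        for a in retained:
            for b in retained:
                if a < b and info.loc[a, "CHR"] == info.loc[b, "CHR"] \
                        and abs(info.loc[a, "BP"] - info.loc[b, "BP"]) <= 250_000:
                    assert ld_r2(dos[a], dos[b]) <= cfg.r2_threshold
        for snp in set(ss["SNP"]) - retained:
            partners = [
                r for r in retained
                if info.loc[r, "CHR"] == info.loc[snp, "CHR"]
                and abs(info.loc[r, "BP"] - info.loc[snp, "BP"]) <= 250_000
                and info.loc[r, "P"] <= info.loc[snp, "P"]
                and ld_r2(dos[r], dos[snp]) > cfg.r2_threshold]
            assert partners, f"removed SNP {snp} has no retained cause"

    def test_invariant_to_row_permutation(self):
        ss, dos = _block_cohort(seed=5)
        out1 = clump(ss, dos)
        out2 = clump(ss.sample(frac=1.0, random_state=2), dos)
        assert list(out1["SNP"]) == list(out2["SNP"])

    def test_missing_snps_reported_and_skipped(self, toy_sumstats, toy_dosages):
        with pytest.warns(UserWarning, match="missing from dosages"):
            out = clump(toy_sumstats, toy_dosages.drop(columns=["s5"]))
        assert out.attrs["skipped"] == ["s5"]
        assert "s5" not in set(out["SNP"])


class TestScore:
    def test_two_term_hand_sum(self):
        dos = pd.DataFrame({"a": [2], "b": [1]})
        ss = pd.DataFrame({"SNP": ["a", "b"], "CHR": [1, 1], "BP": [1, 2],
                           "A1": ["A", "A"], "A2": ["G", "G"],
                           "FREQ": [0.5, 0.5], "BETA": [0.1, -0.2],
                           "SE": [0.01, 0.01], "P": [0.001, 0.001]})
        s, k = score(dos, ss, ["a", "b"], p_threshold=0.05)
        assert s.iloc[0] == pytest.approx(0.0)
        assert k == 2

    def test_threshold_below_all_p_gives_empty_score(self, toy_sumstats,
                                                     toy_dosages):
        s, k = score(toy_dosages, toy_sumstats, toy_sumstats["SNP"], 1e-12)
        assert k == 0
        assert np.allclose(s, 0.0)

    def test_matches_matrix_vector_oracle(self, toy_sumstats, toy_dosages):
        retained = ["s1", "s2", "s3", "s4", "s5"]
        s, k = score(toy_dosages, toy_sumstats, retained, p_threshold=1.0)
        beta = toy_sumstats.set_index("SNP")["BETA"]
        expected = toy_dosages.to_numpy(float) @ beta[retained].to_numpy()
        assert np.allclose(s.to_numpy(), expected)
        assert k == 5

    def test_allele_flip(self, toy_sumstats, toy_dosages):
        counted = {s: a for s, a in zip(toy_sumstats["SNP"], toy_sumstats["A1"])}
        counted["s2"] = toy_sumstats.set_index("SNP").loc["s2", "A2"]
        s_flip, _ = score(toy_dosages, toy_sumstats, ["s2"], 1.0,
                          counted_alleles=counted)
        s_raw, _ = score(toy_dosages, toy_sumstats, ["s2"], 1.0)
        beta = toy_sumstats.set_index("SNP").loc["s2", "BETA"]
        assert np.allclose(s_flip.to_numpy(),
                           beta * (2.0 - toy_dosages["s2"].to_numpy()))
        assert not np.allclose(s_flip, s_raw)

    def test_unresolvable_allele_raises(self, toy_sumstats, toy_dosages):
        with pytest.raises(AlleleMismatchError, match="s1"):
            score(toy_dosages, toy_sumstats, ["s1"], 1.0,
                  counted_alleles={"s1": "T"})

    def test_missing_dosage_mean_imputed(self, toy_sumstats, toy_dosages):
        dos = toy_dosages.astype(float).copy()
        dos.iloc[0, 0] = np.nan
        s, _ = score(dos, toy_sumstats, ["s1"], 1.0)
        freq = toy_sumstats.set_index("SNP").loc["s1", "FREQ"]
        beta = toy_sumstats.set_index("SNP").loc["s1", "BETA"]
        assert s.iloc[0] == pytest.approx(beta * 2 * freq)

    def test_retained_count_nondecreasing_in_threshold(self, toy_sumstats,
                                                       toy_dosages):
        ps = score_set(toy_dosages, toy_sumstats, toy_sumstats["SNP"],
                       ClumpConfig())
        counts = [ps.n_snps[pt] for pt in ClumpConfig().p_thresholds]
        assert counts == sorted(counts)


class TestPcaAndAdjust:
    def test_duplicate_snp_pruned(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.5, 200)
        dos = pd.DataFrame({"a": a, "dup": a,
                            "b": rng.binomial(2, 0.4, 200),
                            "c": rng.binomial(2, 0.3, 200)})
        pcs = genotype_pca(dos, n_components=2)
        # 4 SNPs, one perfect duplicate pruned -> PCA ran on 3 columns
        assert pcs.shape == (200, 2)

    def test_planted_group_structure_recovered(self):
        rng = np.random.default_rng(6)
        n, m = 400, 300
        groups = np.repeat([0, 1], n // 2)
        f = np.where(groups[:, None] == 0, 0.3, 0.7)
        dos = pd.DataFrame(rng.binomial(2, f, (n, m)).astype(np.int8))
        pcs = genotype_pca(dos, n_components=3)
        r = np.corrcoef(pcs["PC1"], groups)[0, 1]
        assert abs(r) > 0.9

    def test_components_orthogonal_unit_variance(self):
        rng = np.random.default_rng(8)
        dos = pd.DataFrame(rng.binomial(2, 0.4, (300, 200)).astype(np.int8))
        pcs = genotype_pca(dos, n_components=5).to_numpy()
        gram = pcs.T @ pcs / len(pcs)
        assert np.allclose(gram, np.eye(5), atol=1e-6)

    def test_rank_error(self):
        rng = np.random.default_rng(9)
        dos = pd.DataFrame(rng.binomial(2, 0.4, (50, 4)))
        with pytest.raises(ValueError, match="components"):
            genotype_pca(dos, n_components=10)

    def test_adjust_no_covariates_is_zscore(self):
        rng = np.random.default_rng(10)
        s = pd.Series(rng.standard_normal(100) * 3 + 5)
        adj = adjust_score(s)
        assert np.allclose(adj, (s - s.mean()) / s.std(ddof=0))

    def test_adjust_removes_planted_pc_loading(self):
        rng = np.random.default_rng(11)
        pc1 = rng.standard_normal(500)
        s = 0.5 * pc1 + rng.standard_normal(500)
        adj = adjust_score(pd.Series(s), components=pc1[:, None])
        assert abs(np.corrcoef(adj, pc1)[0, 1]) < 1e-10
        assert adj.mean() == pytest.approx(0.0, abs=1e-12)
        assert adj.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_batch_warns(self):
        rng = np.random.default_rng(12)
        s = pd.Series(rng.standard_normal(50))
        x = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="collinear"):
            adjust_score(s, components=np.column_stack([x, x]))
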