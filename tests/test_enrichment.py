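import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meqtlkit.enrichment import (
    EXCLUDED_BIOTYPES,
    compute_opportunity,
    enrichment_test,
    expand_locus,
    find_proxies,
    ld_r2,
    maf_bin_index,
    opportunity_bin_label,
    sample_null_sets,
    stratify_snps,
    supervised_ld_prune,
)
from meqtlkit.simulate import ScenarioSpec, simulate_genotypes
from meqtlkit.types import MeqtlMap


@pytest.fixture(scope="module")
def ld_panel():
    spec = ScenarioSpec(
        n_samples=300, n_snps=50, n_chroms=1, block_size=10, rho=0.9,
        maf_range=(0.1, 0.5), seed=31,
    )
    return simulate_genotypes(spec)


class TestLdR2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 2, 1, 0, 2])
        assert ld_r2(v, v) == pytest.approx(1.0)

    def test_orthogonal_contrast(self):
        assert ld_r2([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            ld_r2([1, 1, 1], [0, 1, 2])

    def test_matches_corrcoef_oracle(self, rng):
        for _ in range(20):
            a = rng.integers(0, 3, 50).astype(float)
            b = rng.integers(0, 3, 50).astype(float)
            if a.var() == 0 or b.var() == 0:
                continue
            expect = np.corrcoef(a, b)[0, 1] ** 2
            assert ld_r2(a, b) == pytest.approx(expect, abs=1e-12)


class TestFindProxies:
    def test_no_neighbors(self, ld_panel):
        snp = ld_panel.snps["snp_id"].iloc[0]
        out = find_proxies([snp], ld_panel, r2_min=1.1)  # nothing can pass
        assert out == {snp}

    def test_perfect_copy_included(self, ld_panel):
        gm = ld_panel
        dup = gm.subset_snps(np.arange(gm.n_snps))
        dup.dosages = np.column_stack([gm.dosages, gm.dosages[:, [0]]])
        snps = pd.concat(
            [gm.snps, pd.DataFrame([{"snp_id": "copy", "chrom": gm.snps.loc[0, "chrom"],
                                     "pos": gm.snps.loc[0, "pos"] + 1000,
                                     "maf": gm.snps.loc[0, "maf"]}])],
            ignore_index=True,
        )
        from meqtlkit.types import GenotypeMatrix

        panel = GenotypeMatrix(samples=gm.samples, dosages=dup.dosages, snps=snps)
        out = find_proxies([gm.snps["snp_id"].iloc[0]], panel)
        assert "copy" in out

    def test_matches_brute_force(self, ld_panel):
        idx = list(ld_panel.snps["snp_id"].iloc[[3, 20]])
        out = find_proxies(idx, ld_panel, r2_min=0.5, window=30_000)
        expect = set(idx)
        meta = ld_panel.snps
        for s in idx:
            i = list(meta["snp_id"]).index(s)
            for j in range(ld_panel.n_snps):
                same = meta.loc[j, "chrom"] == meta.loc[i, "chrom"]
                near = abs(meta.loc[j, "pos"] - meta.loc[i, "pos"]) <= 30_000
                if same and near and ld_r2(
                    ld_panel.dosages[:, i], ld_panel.dosages[:, j]
                ) >= 0.5:
                    expect.add(meta.loc[j, "snp_id"])
        assert out == expect


def brute_force_prune(priority, panel, r2_prune, window):
    meta = panel.snps.set_index("snp_id")
    unresolved = set(priority)
    kept = []
    while unresolved:
        best = min(
            unresolved,
            key=lambda s: (priority[s], meta.loc[s, "pos"], s),
        )
        kept.append(best)
        unresolved.discard(best)
        bi = list(panel.snps["snp_id"]).index(best)
        for s in list(unresolved):
            si = list(panel.snps["snp_id"]).index(s)
            if meta.loc[s, "chrom"] != meta.loc[best, "chrom"]:
                continue
            if abs(meta.loc[s, "pos"] - meta.loc[best, "pos"]) > window:
                continue
            if ld_r2(panel.dosages[:, si], panel.dosages[:, bi]) > r2_prune:
                unresolved.discard(s)
    return kept


class TestSupervisedLdPrune:
    def test_nothing_pruned_when_uncorrelated(self, rng):
        spec = ScenarioSpec(n_samples=400, n_snps=20, rho=0.0, seed=33)
        panel = simulate_genotypes(spec)
        priority = {s: 0.5 for s in panel.snps["snp_id"]}
        kept = supervised_ld_prune(priority, panel, r2_prune=0.7)
        assert set(kept) == set(priority)

    def test_priority_rule(self):
        spec = ScenarioSpec(n_samples=200, n_snps=2, block_size=2, rho=0.999,
                            maf_range=(0.3, 0.3000001), n_chroms=1, seed=34)
        panel = simulate_genotypes(spec)
        a, b = panel.snps["snp_id"]
        if ld_r2(panel.dosages[:, 0], panel.dosages[:, 1]) > 0.7:
            kept = supervised_ld_prune({a: 1e-3, b: 1e-6}, panel)
            assert kept == [b]

    def test_matches_brute_force(self, ld_panel, rng):
        priority = {
            s: float(p)
            for s, p in zip(ld_panel.snps["snp_id"], rng.uniform(0, 1, ld_panel.n_snps))
        }
        kept = supervised_ld_prune(priority, ld_panel, r2_prune=0.5, window=40_000)
        assert kept == brute_force_prune(priority, ld_panel, 0.5, 40_000)

    def test_no_kept_pair_exceeds_r2(self, ld_panel, rng):
        priority = {
            s: float(p)
            for s, p in zip(ld_panel.snps["snp_id"], rng.uniform(0, 1, ld_panel.n_snps))
        }
        kept = supervised_ld_prune(priority, ld_panel, r2_prune=0.5, window=40_000)
        meta = ld_panel.snps.set_index("snp_id")
        cols = {s: i for i, s in enumerate(ld_panel.snps["snp_id"])}
        for i, s1 in enumerate(kept):
            for s2 in kept[i + 1:]:
                if meta.loc[s1, "chrom"] != meta.loc[s2, "chrom"]:
                    continue
                if abs(meta.loc[s1, "pos"] - meta.loc[s2, "pos"]) > 40_000:
                    continue
                assert ld_r2(
                    ld_panel.dosages[:, cols[s1]], ld_panel.dosages[:, cols[s2]]
                ) <= 0.5

    def test_missing_snp_errors(self, ld_panel):
        with pytest.raises(ValueError, match="missing from panel"):
            supervised_ld_prune({"nope": 0.1}, ld_panel)


class TestStratify:
    def test_opportunity_binning(self):
        assert opportunity_bin_label(73 // 50) == "50-99"
        assert opportunity_bin_label(0) == "0-49"

    def test_maf_binning(self):
        assert maf_bin_index(0.07) == 1  # [0.05, 0.10)
        assert maf_bin_index(0.03) == 0
        assert maf_bin_index(0.5) == 9  # top bin closed at 0.5

    def test_opportunity_zero(self):
        snps = pd.DataFrame(
            {"snp_id": ["s"], "chrom": ["9"], "pos": [100], "maf": [0.2]}
        )
        cpgs = pd.DataFrame({"cpg_id": ["c"], "chrom": ["1"], "pos": [100]})
        out = stratify_snps(snps, cpgs, window=1000)
        assert out.loc[0, "opp_label"] == "0-49"

    def test_opportunity_matches_brute_force(self, rng):
        snps = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(50)],
                "chrom": rng.choice(["1", "2"], 50),
                "pos": rng.integers(1, 10**5, 50),
                "maf": rng.uniform(0.01, 0.5, 50),
            }
        )
        cpgs = pd.DataFrame(
            {
                "cpg_id": [f"c{i}" for i in range(200)],
                "chrom": rng.choice(["1", "2"], 200),
                "pos": rng.integers(1, 10**5, 200),
            }
        )
        opp = compute_opportunity(snps, cpgs, 5000)
        for i in range(50):
            expect = sum(
                1
                for _, c in cpgs.iterrows()
                if c["chrom"] == snps.loc[i, "chrom"]
                and abs(c["pos"] - snps.loc[i, "pos"]) <= 5000
            )
            assert opp[i] == expect


@pytest.fixture(scope="module")
def stratified_world():
    rng = np.random.default_rng(35)
    n = 2000
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "maf": rng.uniform(0.05, 0.5, n),
        }
    )
    cpgs = pd.DataFrame(
        {
            "cpg_id": [f"c{i}" for i in range(500)],
            "chrom": "1",
            "pos": rng.integers(1, n * 1000, 500),
        }
    )
    strata = stratify_snps(snps, cpgs, window=100_000)
    disease = list(rng.choice(snps["snp_id"], 100, replace=False))
    pool = [s for s in snps["snp_id"] if s not in set(disease)]
    return snps, strata, disease, pool


class TestSampleNullSets:
    def test_sizes_and_stratum_histograms(self, stratified_world):
        snps, strata, disease, pool = stratified_world
        sets = sample_null_sets(disease, pool, strata, n_sets=50, seed=1)
        key = (strata.set_index("snp_id")["maf_bin"].astype(str)
               + "|" + strata.set_index("snp_id")["opp_bin"].astype(str))
        want = key.loc[disease].value_counts().sort_index()
        for ns in sets:
            assert len(ns) == len(disease)
            got = key.loc[list(ns)].value_counts().sort_index()
            pd.testing.assert_series_equal(got, want, check_names=False)

    def test_empty_stratum_errors(self, stratified_world):
        snps, strata, disease, _ = stratified_world
        with pytest.raises(ValueError, match="stratum"):
            sample_null_sets(disease, [], strata, n_sets=2, seed=0)

    def test_within_stratum_uniformity(self):
        # one stratum, small pool: chi-square on selection frequencies
        strata = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(21)], "maf_bin": 0, "opp_bin": 0}
        )
        disease = ["s0"]
        pool = [f"s{i}" for i in range(1, 21)]
        sets = sample_null_sets(disease, pool, strata, n_sets=10_000, seed=3)
        counts = pd.Series([s for ns in sets for s in ns]).value_counts()
        chi2 = (((counts - 500) ** 2) / 500).sum()
        p = stats.chi2.sf(chi2, df=19)
        assert p > 0.01

    def test_determinism(self, stratified_world):
        snps, strata, disease, pool = stratified_world
        a = sample_null_sets(disease, pool, strata, n_sets=5, seed=9)
        b = sample_null_sets(disease, pool, strata, n_sets=5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestEnrichmentTest:
    def test_fold_arithmetic(self):
        disease = ["a", "b", "c", "d", "e"]  # observed prop 0.2
        nulls = [np.array(["x", "q1", "q2", "q3", "q4"])] * 10  # prop 0.2 each
        res = enrichment_test(disease, nulls, {"a", "x"})
        assert res.observed_prop == pytest.approx(0.2)
        assert res.fold == pytest.approx(1.0)

    def test_fold_two(self):
        disease = ["a", "b", "c", "d", "e"]  # 1/5 = 0.2 meQTL
        nulls = [np.array(["x", "n1", "n2", "n3", "n4", "n5", "n6", "n7", "n8",
                           "n9"])] * 4  # 1/10 = 0.1
        res = enrichment_test(disease, nulls, {"a", "x"})
        assert res.fold == pytest.approx(2.0)
        assert res.perm_p == 0.0
        assert res.perm_p_conservative == pytest.approx(1 / 5)
        assert res.perm_p_display == "<0.25"

    def test_zero_null_mean_errors(self):
        with pytest.raises(ValueError, match="fold undefined"):
            enrichment_test(["a"], [np.array(["x"])], {"a"})

    def test_type_one_calibration(self, stratified_world, rng):
        # disease sets drawn by the same matching procedure: fold ~ 1
        snps, strata, _, _ = stratified_world
        meqtl = set(rng.choice(snps["snp_id"], 400, replace=False))
        folds = []
        for rep in range(15):
            r = np.random.default_rng(500 + rep)
            disease = list(r.choice(snps["snp_id"], 80, replace=False))
            pool = [s for s in snps["snp_id"] if s not in set(disease)]
            sets = sample_null_sets(disease, pool, strata, n_sets=200,
                                    seed=600 + rep)
            folds.append(enrichment_test(disease, sets, meqtl).fold)
        assert 0.9 < np.mean(folds) < 1.1


class TestExpandLocus:
    @staticmethod
    def world():
        genes = pd.DataFrame(
            {
                "gene_id": ["A", "B", "L1"],
                "chrom": ["1", "1", "1"],
                "start": [100, 5000, 200],
                "end": [1000, 6000, 900],
                "biotype": ["protein_coding", "protein_coding", "lincRNA"],
            }
        )
        rec = pd.DataFrame(
            {"snp_id": ["s1", "s2"], "cpg_id": ["c1", "c2"], "p": [1e-9, 1e-9]}
        )
        m = MeqtlMap(records=rec)
        snp_meta = pd.DataFrame(
            {"snp_id": ["s1", "s2"], "chrom": ["1", "1"], "pos": [500, 100_000]}
        )
        cpg_meta = pd.DataFrame(
            {"cpg_id": ["c1", "c2"], "chrom": ["1", "1"], "pos": [5500, 100_500]}
        )
        blocks = [("1", 0, 10_000)]
        return genes, m, snp_meta, cpg_meta, blocks

    def test_snp_and_target_genes_in_block(self):
        genes, m, snp_meta, cpg_meta, blocks = self.world()
        out = expand_locus(["s1"], m, genes, blocks, snp_meta, cpg_meta)
        row = out.iloc[0]
        assert set(row["genes"].split(",")) == {"A", "B"}  # SNP in A, target in B

    def test_noncoding_biotype_dropped(self):
        genes, m, snp_meta, cpg_meta, blocks = self.world()
        out = expand_locus(["s1"], m, genes, blocks, snp_meta, cpg_meta)
        assert "L1" not in out.iloc[0]["genes"]
        assert "lincRNA" in EXCLUDED_BIOTYPES

    def test_snp_without_targets(self):
        genes, m, snp_meta, cpg_meta, blocks = self.world()
        m2 = MeqtlMap(records=m.records[m.records["snp_id"] != "s1"])
        out = expand_locus(["s1"], m2, genes, blocks, snp_meta, cpg_meta)
        assert set(out.iloc[0]["genes"].split(",")) == {"A"}

    def test_snp_outside_blocks_gets_singleton(self):
        genes, m, snp_meta, cpg_meta, blocks = self.world()
        out = expand_locus(["s1", "s2"], m, genes, blocks, snp_meta, cpg_meta)
        assert len(out) == 2  # s2 at 100 kb is outside the only block
        single = out[out["block_start"] == 100_000 - 1]
        assert len(single) == 1
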