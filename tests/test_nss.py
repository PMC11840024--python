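"""Sweep-score joins, enrichment curves, gene averaging and window scans."""
import numpy as np
import pandas as pd
import pytest

import pleiosweep as ps
from pleiosweep.loci import Locus
from pleiosweep.nss import (NssTrack, ScoredSet, compare_sets, enrichment_qq,
                            extreme_windows, gene_mean_scores, join_scores,
                            region_overlap)
from pleiosweep.regions import GenomicRegion
from pleiosweep.simulate import simulate_nss_track
from .oracles import oracle_interval_overlap


def _track(positions, scores, chrom="1"):
    return NssTrack(df=pd.DataFrame({
        "chrom": [chrom] * len(positions), "pos": positions, "score": scores}))


def _snps(positions, chrom="1"):
    return pd.DataFrame({"snp": [f"rs{i}" for i in range(len(positions))],
                         "chrom": [chrom] * len(positions), "pos": positions})


class TestJoinScores:
    def test_partial_coverage_counted(self):
        snps = _snps(range(10))
        track = _track([0, 2, 4, 6], [1.0, -1.0, 0.5, 0.5])
        s = join_scores(snps, track)
        assert (s.n_input, s.n_scored) == (10, 4)
        assert s.coverage == pytest.approx(0.4)

    def test_empty_track_is_hard_error(self):
        with pytest.raises(ValueError, match="empty"):
            join_scores(_snps([1]), _track([], []))

    def test_idempotent_and_masked_coverage_regime(self):
        """A 60%-masked synthetic track leaves ~40% of SNPs scored, the
        coverage regime of joining real candidate SNPs to the public track."""
        rng = np.random.default_rng(0)
        covs = []
        for seed in range(10):
            pos = np.arange(1, 3001) * 10
            chrom = np.array(["1"] * 3000, dtype=object)
            tdf, _ = simulate_nss_track(chrom, pos, seed=seed, mask_fraction=0.6)
            track = NssTrack(df=tdf)
            s = join_scores(_snps(pos), track)
            covs.append(s.coverage)
            again = join_scores(s.df[["snp", "chrom", "pos"]], track)
            assert again.coverage == 1.0  # joining scored SNPs is idempotent
            np.testing.assert_array_equal(again.scores, s.scores)
        se = np.sqrt(0.4 * 0.6 / 3000)
        assert abs(np.mean(covs) - 0.4) < 3 * se


class TestEnrichmentQq:
    def test_identity_subsample_is_diagonal(self):
        rng = np.random.default_rng(1)
        bg = rng.standard_normal(5000)
        curve, p = enrichment_qq(bg, bg)
        np.testing.assert_array_equal(curve["candidate"], curve["background"])

    def test_constant_shift_moves_curve(self):
        rng = np.random.default_rng(2)
        bg = rng.standard_normal(20000)
        curve, p = enrichment_qq(bg - 1.5, bg)
        np.testing.assert_allclose(curve["candidate"],
                                   curve["background"] - 1.5, atol=0.08)
        assert p < 1e-10

    def test_small_candidate_set_suppresses_test(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="suppressed"):
            curve, p = enrichment_qq(rng.standard_normal(5),
                                     rng.standard_normal(100))
        assert p is None and len(curve) == 99

    def test_sweep_drawn_candidates_detected(self):
        """Candidates drawn from delta = -2 sweep regions reject the null
        at alpha = 0.001 in nearly all seeds."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            pos = np.arange(1, 20_001) * 50
            chrom = np.array(["1"] * 20_000, dtype=object)
            region = GenomicRegion("1", 1, 100_000)
            tdf, _ = simulate_nss_track(chrom, pos, [(region, -2.0)], seed=seed)
            inside = tdf["pos"] <= 100_000
            cand = tdf.loc[inside, "score"].to_numpy()[:111]
            _, p = enrichment_qq(cand, tdf["score"].to_numpy())
            if p < 0.001:
                wins += 1
        assert wins >= int(0.95 * n_seeds)


def _scored(label, scores):
    m = len(scores)
    return ScoredSet(label=label, df=pd.DataFrame({
        "snp": [f"{label}{i}" for i in range(m)], "chrom": "1",
        "pos": range(m), "score": scores}), n_input=m)


class TestCompareSets:
    def test_identical_sets_null(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        summary, tests = compare_sets([_scored("a", x), _scored("b", x.copy())])
        assert tests["p"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert summary["mean"].iloc[0] == summary["mean"].iloc[1]

    def test_printed_moment_sets_ordered_in_between(self):
        """Sets at the published moments: the shared set's mean falls
        between the disorder set and the anthropometric set."""
        rng = np.random.default_rng(5)
        an = _scored("an", rng.normal(-1.91, 1.61, 111))
        bmi = _scored("bmi", rng.normal(-0.10, 2.00, 111))
        shared = _scored("shared", rng.normal(-0.62, 1.73, 111))
        summary, tests = compare_sets([an, bmi, shared])
        assert list(summary["label"]) == ["an", "shared", "bmi"]
        for label, mu, sd in (("an", -1.91, 1.61), ("bmi", -0.10, 2.00),
                              ("shared", -0.62, 1.73)):
            got = summary.set_index("label").loc[label, "mean"]
            assert abs(got - mu) < 3 * sd / np.sqrt(111)
        assert set(tests.columns) >= {"p", "p_bh"}

    def test_tiny_set_excluded(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="excluded"):
            summary, _ = compare_sets([
                _scored("a", rng.standard_normal(50)),
                _scored("b", rng.standard_normal(50)),
                _scored("tiny", np.array([0.5])),
            ])
        assert set(summary["label"]) == {"a", "b"}


class TestGeneScores:
    def test_arithmetic_mean_per_gene(self):
        gmap = pd.DataFrame({"gene": ["G1", "G1", "G2"],
                             "snp": ["rs0", "rs1", "rs2"]})
        scored = _scored("s", np.array([-1.0, -3.0, 0.5]))
        scored.df["snp"] = ["rs0", "rs1", "rs2"]
        out = gene_mean_scores(gmap, scored)
        assert out.set_index("gene").loc["G1", "mean_nss"] == -2.0
        assert out.set_index("gene").loc["G2", "n_snps"] == 1
        assert list(out["gene"]) == ["G1", "G2"]  # ascending mean

    def test_unscored_genes_omitted_and_matches_loop(self):
        rng = np.random.default_rng(7)
        gmap = pd.DataFrame({
            "gene": rng.choice(["A", "B", "C", "D"], 40),
            "snp": [f"rs{i}" for i in rng.integers(0, 30, 40)],
        }).drop_duplicates()
        scored = _scored("s", rng.standard_normal(20))
        scored.df["snp"] = [f"rs{i}" for i in range(20)]
        out = gene_mean_scores(gmap, scored).set_index("gene")
        lookup = dict(zip(scored.df["snp"], scored.df["score"]))
        for g in ["A", "B", "C", "D"]:
            vals = [lookup[s] for s in gmap.loc[gmap["gene"] == g, "snp"]
                    if s in lookup]
            if vals:
                assert out.loc[g, "mean_nss"] == pytest.approx(np.mean(vals))
            else:
                assert g not in out.index


class TestExtremeWindows:
    def test_tie_semantics_all_equal_scores(self):
        """All-equal window means: every eligible window ties with the
        threshold and all are flagged (documented tie policy)."""
        pos = np.arange(1, 5001) * 100
        track = _track(pos, np.zeros(5000))
        regions, windows = extreme_windows(track, 100_000, 50_000, 0.05)
        eligible = windows[windows["n_snps"] >= 5]
        assert eligible["flagged"].all()

    def test_flagged_fraction_matches_tail_definition(self):
        """With continuous scores the flagged fraction is exactly
        ceil(q * n) / n of eligible windows."""
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(10**7, 50_000, replace=False)) + 1
        track = _track(pos, rng.standard_normal(50_000))
        regions, windows = extreme_windows(track, 100_000, 50_000, 0.05)
        eligible = windows[windows["n_snps"] >= 5]
        n = len(eligible)
        assert eligible["flagged"].sum() == int(np.ceil(0.05 * n))

    def test_planted_deep_sweep_always_flagged(self):
        for seed in range(10):
            pos = np.arange(1, 40_001) * 250  # 10 Mb, 4 SNPs/kb
            chrom = np.array(["1"] * 40_000, dtype=object)
            region = GenomicRegion("1", 4_000_001, 4_200_000)
            tdf, _ = simulate_nss_track(chrom, pos, [(region, -3.0)], seed=seed)
            track = NssTrack(df=tdf)
            regions, _ = extreme_windows(track, 100_000, 50_000, 0.05)
            assert any(r.intersects(region) for r in regions)

    def test_empty_track_is_hard_error(self):
        with pytest.raises(ValueError, match="empty"):
            extreme_windows(_track([], []), 1000, 500)


class TestRegionOverlap:
    def test_empty_set_and_identity(self):
        loci = [Locus("1", 10, 20, "a", ["a"], 0.01)]
        df, counts = region_overlap(loci, {
            "empty": [], "self": [GenomicRegion("1", 10, 20)]})
        assert counts == {"empty": 0, "self": 1}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            loci = [Locus("1", int(s), int(s + l), f"a{i}", [f"a{i}"], 0.01)
                    for i, (s, l) in enumerate(zip(
                        rng.integers(0, 10**5, 8), rng.integers(1, 10**4, 8)))]
            regions = [GenomicRegion("1", int(s), int(s + l))
                       for s, l in zip(rng.integers(0, 10**5, 5),
                                       rng.integers(1, 10**4, 5))]
            df, counts = region_overlap(loci, {"set": regions})
            want = oracle_interval_overlap(
                [(L.chrom, L.start, L.end) for L in loci],
                [(r.chrom, r.start, r.end) for r in regions])
            assert list(df["set"]) == want
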