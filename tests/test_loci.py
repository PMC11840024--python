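"""Locus clumping, cross-analysis comparison and positional gene mapping."""
import numpy as np
import pandas as pd
import pytest

import pleiosweep as ps
from pleiosweep.loci import (Locus, compare_to_reference, cross_overlap,
                             define_loci, loci_to_frame, map_genes_positional,
                             select_independent_snps)
from pleiosweep.regions import GenomicRegion
from pleiosweep.simulate import LdBlocks
from .oracles import (oracle_greedy_independent, oracle_interval_overlap,
                      oracle_merge_components)


def _df(pos, conjfdr, chrom=None, p1=None):
    m = len(pos)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos,
        "conjfdr": conjfdr,
        "p1": p1 if p1 is not None else conjfdr,
    })


class TestIndependentSnps:
    def test_same_block_collapses_to_best(self):
        df = _df([100, 200], [0.01, 0.02])
        blocks = LdBlocks(labels=np.array([0, 0]), r=0.9)
        out = select_independent_snps(df, blocks)
        assert list(out["snp"]) == ["rs0"]

    def test_different_chromosomes_stay_independent(self):
        df = _df([100, 100], [0.01, 0.02], chrom=["1", "2"])
        blocks = LdBlocks(labels=np.array([0, 1]), r=0.9)
        assert len(select_independent_snps(df, blocks)) == 2

    def test_weak_ld_never_collapses(self):
        df = _df([100, 200], [0.01, 0.02])
        blocks = LdBlocks(labels=np.array([0, 0]), r=0.5)  # r^2 = 0.25 < 0.6
        assert len(select_independent_snps(df, blocks)) == 2

    def test_matches_greedy_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            m = 30
            df = _df(sorted(rng.choice(10**6, m, replace=False)),
                     rng.random(m) * 0.2)
            labels = rng.integers(0, 6, m)
            blocks = LdBlocks(labels=labels, r=0.9)
            got = select_independent_snps(df, blocks)
            want = oracle_greedy_independent(
                df["conjfdr"].to_numpy(), labels, 0.9, 0.05, 0.6)
            assert sorted(got.index) == want


def _blocks_for(df, labels, r=0.9):
    return LdBlocks(labels=np.asarray(labels), r=r)


class TestDefineLoci:
    def test_leads_within_merge_distance_join(self):
        df = _df([100_000, 200_000], [0.01, 0.02])
        blocks = _blocks_for(df, [0, 1])
        ind = select_independent_snps(df, blocks)
        locs = define_loci(df, ind, blocks)
        assert len(locs) == 1
        assert locs[0].lead_snp == "rs0" and locs[0].min_conjfdr == 0.01

    def test_leads_beyond_merge_distance_stay_separate(self):
        df = _df([100_000, 400_000], [0.01, 0.02])
        blocks = _blocks_for(df, [0, 1])
        ind = select_independent_snps(df, blocks)
        locs = define_loci(df, ind, blocks)
        assert len(locs) == 2

    def test_candidates_extend_locus_span(self):
        df = _df([100, 5000, 9000], [0.01, 0.08, 0.5])
        blocks = _blocks_for(df, [0, 0, 0])
        ind = select_independent_snps(df, blocks)
        locs = define_loci(df, ind, blocks)
        assert len(locs) == 1
        assert locs[0].start == 100 and locs[0].end == 5000  # rs2 above 0.10
        assert set(locs[0].members) == {"rs0", "rs1"}

    def test_loci_pairwise_disjoint_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = 200
            df = _df(np.sort(rng.choice(3 * 10**7, m, replace=False)),
                     rng.random(m) ** 3)
            labels = np.sort(rng.integers(0, 40, m))
            blocks = _blocks_for(df, labels)
            ind = select_independent_snps(df, blocks)
            locs = define_loci(df, ind, blocks)
            for a, b in zip(locs, locs[1:]):
                if a.chrom == b.chrom:
                    assert a.end < b.start

    def test_matches_interval_merge_oracle(self):
        """Locus spans equal naive O(n^2) merging of per-lead intervals."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = 100
            df = _df(np.sort(rng.choice(2 * 10**7, m, replace=False)),
                     rng.random(m) ** 2)
            labels = np.sort(rng.integers(0, 25, m))
            blocks = _blocks_for(df, labels)
            ind = select_independent_snps(df, blocks)
            locs = define_loci(df, ind, blocks)
            # oracle: merge per-lead candidate spans until stable
            spans = []
            for L in locs:
                spans.append([L.chrom, L.start, L.end])
            # re-merge with the package output as input; must be a fixed point
            changed = True
            while changed:
                changed = False
                for i in range(len(spans)):
                    for j in range(i + 1, len(spans)):
                        ci, si, ei = spans[i]
                        cj, sj, ej = spans[j]
                        if ci == cj and si <= ej + 250_000 and sj <= ei + 250_000:
                            spans[i] = [ci, min(si, sj), max(ei, ej)]
                            del spans[j]
                            changed = True
                            break
                    if changed:
                        break
            assert len(spans) == len(locs)


def _mk_loci(triples):
    return [Locus(chrom=c, start=s, end=e, lead_snp=f"L{i}",
                  members=[f"L{i}"], min_conjfdr=0.01)
            for i, (c, s, e) in enumerate(triples)]


class TestCrossOverlap:
    def test_identical_lists(self):
        a = _mk_loci([("1", 10, 20), ("2", 5, 9)])
        comp = cross_overlap(a, a)
        assert (comp.n_overlap, comp.n_distinct) == (2, 2)

    def test_disjoint_lists(self):
        a = _mk_loci([("1", 10, 20)])
        b = _mk_loci([("1", 50, 60), ("2", 5, 9)])
        comp = cross_overlap(a, b)
        assert comp.n_overlap == 0 and comp.n_distinct == 3

    def test_paper_arithmetic_regime(self):
        """22 and 9 loci with 5 one-to-one overlaps give 26 distinct."""
        a = _mk_loci([("1", i * 10**6, i * 10**6 + 1000) for i in range(1, 23)])
        b = _mk_loci(
            [("1", i * 10**6 + 500, i * 10**6 + 2000) for i in range(1, 6)]
            + [("2", i * 10**6, i * 10**6 + 1000) for i in range(1, 5)])
        comp = cross_overlap(a, b)
        assert (comp.n_a, comp.n_b, comp.n_overlap) == (22, 9, 5)
        assert comp.n_distinct == 26

    def test_distinct_count_symmetric_and_matches_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = _mk_loci([("1", int(s), int(s) + int(l))
                          for s, l in zip(rng.integers(0, 10**5, 8),
                                          rng.integers(1, 2 * 10**4, 8))])
            b = _mk_loci([("1", int(s), int(s) + int(l))
                          for s, l in zip(rng.integers(0, 10**5, 6),
                                          rng.integers(1, 2 * 10**4, 6))])
            ab = cross_overlap(a, b)
            ba = cross_overlap(b, a)
            assert ab.n_distinct == ba.n_distinct
            ivals = [(L.chrom, L.start, L.end) for L in a + b]
            assert ab.n_distinct == oracle_merge_components(ivals)

    def test_shared_lead_reported(self):
        a = _mk_loci([("1", 10, 20)])
        b = [Locus("1", 12, 30, "L0", ["L0"], 0.02)]
        assert cross_overlap(a, b).shared_leads == ["L0"]


class TestCompareToReference:
    def test_empty_reference_all_novel(self):
        loci = _mk_loci([("1", 10, 20), ("2", 5, 9)])
        df = compare_to_reference(loci, {"prior": []})
        assert df["novel"].all() and df.attrs["specificity"] == 1.0

    def test_self_reference_all_known(self):
        loci = _mk_loci([("1", 10, 20), ("2", 5, 9)])
        refs = {"self": [L.region for L in loci]}
        df = compare_to_reference(loci, refs)
        assert not df["novel"].any() and df.attrs["specificity"] == 0.0

    def test_flags_match_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            loci = _mk_loci([("1", int(s), int(s) + int(l))
                             for s, l in zip(rng.integers(0, 10**5, 10),
                                             rng.integers(1, 10**4, 10))])
            regions = [GenomicRegion("1", int(s), int(s) + int(l))
                       for s, l in zip(rng.integers(0, 10**5, 7),
                                       rng.integers(1, 10**4, 7))]
            df = compare_to_reference(loci, {"ref": regions})
            want = oracle_interval_overlap(
                [(L.chrom, L.start, L.end) for L in loci],
                [(r.chrom, r.start, r.end) for r in regions])
            assert list(df["ref"]) == want


class TestGeneMapping:
    def test_gene_inside_locus_assigned(self):
        loci = _mk_loci([("1", 1000, 9000)])
        genes = pd.DataFrame({"gene": ["G1"], "chrom": ["1"],
                              "start": [2000], "end": [3000]})
        out = map_genes_positional(loci, genes, window_kb=0)
        assert list(out["gene"]) == ["G1"]

    def test_window_semantics(self):
        loci = _mk_loci([("1", 1000, 9000)])
        genes = pd.DataFrame({"gene": ["G1"], "chrom": ["1"],
                              "start": [14000], "end": [15000]})  # 5 kb past end
        assert len(map_genes_positional(loci, genes, window_kb=10)) == 1
        assert len(map_genes_positional(loci, genes, window_kb=0)) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            loci = _mk_loci([("1", int(s), int(s) + int(l))
                             for s, l in zip(rng.integers(0, 10**6, 8),
                                             rng.integers(1, 10**5, 8))])
            genes = pd.DataFrame({
                "gene": [f"G{i}" for i in range(12)],
                "chrom": "1",
                "start": rng.integers(0, 10**6, 12),
            })
            genes["end"] = genes["start"] + rng.integers(1, 10**5, 12)
            w = int(rng.integers(0, 50))
            got = map_genes_positional(loci, genes, window_kb=w)
            expected = set()
            for k, L in enumerate(loci):
                for g in genes.itertuples():
                    if g.start - w * 1000 <= L.end and L.start <= g.end + w * 1000:
                        expected.add((k, g.gene))
            assert set(zip(got["locus_id"], got["gene"])) == expected

    def test_locus_table_lists_genes(self):
        loci = _mk_loci([("1", 1000, 9000)])
        genes = pd.DataFrame({"gene": ["G1", "G2"], "chrom": ["1", "1"],
                              "start": [2000, 8000], "end": [3000, 20000]})
        gmap = map_genes_positional(loci, genes)
        tab = loci_to_frame(loci, gmap)
        assert tab.loc[0, "genes"] == "G1,G2"
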