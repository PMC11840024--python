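"""From per-SNP conjunctional FDR to genomic risk loci.

Follows the FUMA-style clumping conventions: significant SNPs
(conjFDR < 0.05) are greedily thinned to *independent significant SNPs*
at r^2 < 0.6; independent SNPs mutually at r^2 < 0.1 become *lead SNPs*;
*candidate SNPs* are every SNP below a looser conjFDR threshold (0.10)
in LD (r^2 >= 0.6) with an independent significant SNP; each locus spans
the positions of its candidate SNPs, and loci closer than 250 kb on one
chromosome are merged.  All constants are arguments.

In the exchangeable-block LD model, two SNPs are correlated at the block
r if and only if they share a block, so "r^2 >= threshold with X" reduces
to same-block membership whenever block_r^2 clears the threshold.

The comparison helpers (locus-set overlap, novelty against reference
lists, positional gene mapping) are plain interval intersections on
1-based inclusive coordinates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .regions import GenomicRegion
from .simulate import LdBlocks

log = logging.getLogger(__name__)

SIG_THRESHOLD = 0.05
CANDIDATE_THRESHOLD = 0.10
R2_INDEPENDENT = 0.6
R2_LEAD = 0.1
MERGE_KB = 250


@dataclass
class Locus:
    """A merged genomic risk interval with its member SNPs."""

    chrom: str
    start: int
    end: int
    lead_snp: str
    members: list[str]
    min_conjfdr: float

    def __post_init__(self):
        assert self.start <= self.end
        assert self.lead_snp in self.members

    @property
    def region(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, self.start, self.end, self.lead_snp)

    def intersects(self, other: "Locus") -> bool:
        return self.region.intersects(other.region)


def _order_by_significance(df: pd.DataFrame) -> np.ndarray:
    """Ascending conjFDR; ties by primary-trait p, then position."""
    p1 = df["p1"].to_numpy() if "p1" in df.columns else np.zeros(len(df))
    return np.lexsort((df["pos"].to_numpy(), p1, df["conjfdr"].to_numpy()))


def select_independent_snps(
    df: pd.DataFrame,
    blocks: LdBlocks,
    sig_threshold: float = SIG_THRESHOLD,
    r2_independent: float = R2_INDEPENDENT,
) -> pd.DataFrame:
    """Greedy selection of independent significant SNPs.

    ``df`` needs columns snp, chrom, pos, conjfdr (optionally p1 for
    tie-breaks) aligned with ``blocks.labels``.  SNPs are taken in
    ascending conjFDR; a significant SNP joins the independent set only
    if its r^2 with every already-selected SNP is below
    ``r2_independent`` (same-block membership counts as dependent when
    block_r^2 >= r2_independent).
    """
    df = df.reset_index(drop=True)
    labels = np.asarray(blocks.labels)
    sig = df["conjfdr"].to_numpy() < sig_threshold
    if not sig.any():
        return df.iloc[[]].copy()
    block_dependent = blocks.r ** 2 >= r2_independent
    chosen: list[int] = []
    used_blocks: set[int] = set()
    for i in _order_by_significance(df):
        if not sig[i]:
            continue
        if block_dependent and labels[i] in used_blocks:
            continue
        chosen.append(i)
        used_blocks.add(int(labels[i]))
    out = df.iloc[sorted(chosen)].copy()
    out["block"] = labels[sorted(chosen)]
    return out


def define_loci(
    df: pd.DataFrame,
    independent: pd.DataFrame,
    blocks: LdBlocks,
    candidate_threshold: float = CANDIDATE_THRESHOLD,
    r2_independent: float = R2_INDEPENDENT,
    lead_r2: float = R2_LEAD,
    merge_kb: float = MERGE_KB,
) -> list[Locus]:
    """Build merged risk loci from independent significant SNPs.

    Lead SNPs are independent SNPs mutually at r^2 < ``lead_r2``
    (greedy, ascending conjFDR).  Candidate SNPs are SNPs with conjFDR
    below ``candidate_threshold`` in LD (r^2 >= ``r2_independent``) with
    an independent significant SNP, plus the independent SNPs themselves.
    Each lead's locus spans its candidates; loci closer than
    ``merge_kb`` kb on the same chromosome are merged, members unioned,
    the lead re-chosen as the most significant member lead.
    """
    if len(independent) == 0:
        return []
    df = df.reset_index(drop=True)
    labels = np.asarray(blocks.labels)

    # leads: greedy thinning of the independent set at lead_r2
    block_linked_lead = blocks.r ** 2 >= lead_r2
    ind_sorted = independent.iloc[_order_by_significance(independent)]
    lead_blocks: dict[int, int] = {}  # block label -> positional index of lead
    leads: list[int] = []
    for row in ind_sorted.itertuples():
        b = int(labels[row.Index])
        if block_linked_lead and b in lead_blocks:
            continue
        leads.append(row.Index)
        lead_blocks[b] = row.Index

    # candidate SNPs: below the loose threshold and in LD with an
    # independent significant SNP
    ind_block_set = set(int(labels[i]) for i in independent.index)
    conjfdr = df["conjfdr"].to_numpy()
    block_candidate = blocks.r ** 2 >= r2_independent
    cand_mask = np.zeros(len(df), dtype=bool)
    cand_mask[list(independent.index)] = True
    if block_candidate:
        in_ind_block = np.isin(labels, list(ind_block_set))
        cand_mask |= in_ind_block & (conjfdr < candidate_threshold)

    # attach members to leads: a member joins the lead of its own block
    # when the block is lead-linked, otherwise (weak LD) only the
    # independent SNPs stand alone as their own loci
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy(object)
    snp = df["snp"].to_numpy(object)
    proto: dict[int, list[int]] = {i: [i] for i in leads}
    for i in np.flatnonzero(cand_mask):
        if i in proto:
            continue
        b = int(labels[i])
        if block_linked_lead and b in lead_blocks:
            proto[lead_blocks[b]].append(i)
    # unattached independent SNPs (weak-LD regime): they are leads already

    raw: list[Locus] = []
    for li, members in proto.items():
        members = sorted(members, key=lambda k: pos[k])
        raw.append(Locus(
            chrom=str(chrom[li]),
            start=int(pos[members[0]]),
            end=int(pos[members[-1]]),
            lead_snp=str(snp[li]),
            members=[str(snp[k]) for k in members],
            min_conjfdr=float(conjfdr[members].min()
                              if isinstance(members, np.ndarray)
                              else min(conjfdr[k] for k in members)),
        ))

    # distance merge
    raw.sort(key=lambda L: (L.chrom, L.start, L.end))
    gap = int(merge_kb * 1000)
    merged: list[Locus] = []
    snp_meta = {str(s): (float(c), float(p), int(q)) for s, c, p, q in zip(
        snp, conjfdr,
        df["p1"].to_numpy() if "p1" in df.columns else np.zeros(len(df)),
        pos)}
    lead_set = {str(snp[i]) for i in leads}
    for L in raw:
        if merged and merged[-1].chrom == L.chrom \
                and L.start - merged[-1].end - 1 < gap:
            prev = merged.pop()
            members = sorted(set(prev.members) | set(L.members),
                             key=lambda s: snp_meta[s][2])
            member_leads = [s for s in members if s in lead_set]
            lead = min(member_leads, key=lambda s: snp_meta[s])
            merged.append(Locus(
                chrom=prev.chrom,
                start=min(prev.start, L.start),
                end=max(prev.end, L.end),
                lead_snp=lead,
                members=members,
                min_conjfdr=min(snp_meta[s][0] for s in members),
            ))
        else:
            merged.append(L)
    log.info("defined %d loci from %d independent significant SNPs",
             len(merged), len(independent))
    return merged


@dataclass
class LocusComparison:
    """Overlap bookkeeping between two locus sets."""

    n_a: int
    n_b: int
    n_overlap: int          # loci of A intersecting any locus of B
    n_overlap_b: int        # loci of B intersecting any locus of A
    n_distinct: int         # components of the merged union
    a_overlaps_b: list[bool] = field(default_factory=list)
    b_overlaps_a: list[bool] = field(default_factory=list)
    shared_leads: list[str] = field(default_factory=list)


def cross_overlap(loci_a: Sequence[Locus], loci_b: Sequence[Locus]) -> LocusComparison:
    """Pair loci across two analyses by interval intersection.

    ``n_distinct`` counts the connected components of the union of both
    interval sets under overlap (strict intersection, not distance);
    identical lead SNPs across the analyses are reported.
    """
    a_hits = [any(la.intersects(lb) for lb in loci_b) for la in loci_a]
    b_hits = [any(lb.intersects(la) for la in loci_a) for lb in loci_b]
    allr = sorted(
        [(L.chrom, L.start, L.end) for L in loci_a]
        + [(L.chrom, L.start, L.end) for L in loci_b]
    )
    n_distinct = 0
    cur = None
    for c, s, e in allr:
        if cur is None or c != cur[0] or s > cur[2]:
            n_distinct += 1
            cur = (c, s, e)
        else:
            cur = (c, s, max(cur[2], e))
    leads_a = {L.lead_snp for L in loci_a}
    shared_leads = sorted(leads_a & {L.lead_snp for L in loci_b})
    return LocusComparison(
        n_a=len(loci_a), n_b=len(loci_b),
        n_overlap=int(sum(a_hits)), n_overlap_b=int(sum(b_hits)),
        n_distinct=n_distinct,
        a_overlaps_b=a_hits, b_overlaps_a=b_hits,
        shared_leads=shared_leads,
    )


def compare_to_reference(
    loci: Sequence[Locus],
    reference_sets: Mapping[str, Sequence[GenomicRegion]],
    specificity_sets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flag each locus known/novel per reference list; specificity fraction.

    A locus is *known* for a list if it intersects any of its intervals.
    The returned frame carries one boolean column per list plus a
    ``novel`` column (intersects none of the lists).  The specificity
    fraction — the proportion of loci intersecting none of the designated
    comparison lists (default: all lists) — is stored in
    ``df.attrs['specificity']``.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, regions in reference_sets.items():
        per_chrom: dict[str, IntervalTree] = {}
        for r in regions:
            per_chrom.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1)
        trees[name] = per_chrom
    rows = []
    for L in loci:
        row = {"chrom": L.chrom, "start": L.start, "end": L.end,
               "lead_snp": L.lead_snp}
        for name in reference_sets:
            tree = trees[name].get(L.chrom)
            row[name] = bool(tree is not None and tree.overlap(L.start, L.end + 1))
        row["novel"] = not any(row[name] for name in reference_sets)
        rows.append(row)
    df = pd.DataFrame(rows)
    spec_cols = list(specificity_sets) if specificity_sets else list(reference_sets)
    if len(df) and spec_cols:
        hit_any = df[spec_cols].any(axis=1)
        df.attrs["specificity"] = float(1.0 - hit_any.mean())
    else:
        df.attrs["specificity"] = 1.0
    return df


def map_genes_positional(
    loci: Sequence[Locus],
    genes: pd.DataFrame,
    window_kb: float = 0.0,
) -> pd.DataFrame:
    """Assign genes to loci by positional intersection with a window.

    A gene (columns gene, chrom, start, end) maps to a locus when the
    gene interval extended by ``window_kb`` kb on both sides intersects
    the locus.  Multi-gene loci are expected and allowed.  Returns a
    long-format frame (locus_id, lead_snp, gene).
    """
    w = int(window_kb * 1000)
    per_chrom: dict[str, IntervalTree] = {}
    for g in genes.itertuples():
        lo = max(1, int(g.start) - w)
        per_chrom.setdefault(str(g.chrom), IntervalTree()).addi(
            lo, int(g.end) + w + 1, g.gene)
    rows = []
    for k, L in enumerate(loci):
        tree = per_chrom.get(L.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(L.start, L.end + 1)):
            rows.append({"locus_id": k, "lead_snp": L.lead_snp, "gene": iv.data})
    return pd.DataFrame(rows, columns=["locus_id", "lead_snp", "gene"])


def loci_to_frame(loci: Sequence[Locus],
                  gene_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabular locus summary mirroring a supplementary locus table."""
    rows = []
    for k, L in enumerate(loci):
        genes = ""
        if gene_map is not None and len(gene_map):
            genes = ",".join(gene_map.loc[gene_map["locus_id"] == k, "gene"])
        rows.append({
            "locus_id": k + 1, "chrom": L.chrom, "start": L.start, "end": L.end,
            "lead_snp": L.lead_snp, "min_conjfdr": L.min_conjfdr,
            "n_members": len(L.members), "members": ",".join(L.members),
            "genes": genes,
        })
    return pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end",
                                       "lead_snp", "min_conjfdr", "n_members",
                                       "members", "genes"])
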