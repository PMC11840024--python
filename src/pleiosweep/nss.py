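"""Evolutionary layer: selective-sweep score enrichment of candidate SNPs.

The sweep score (an NSS-style statistic) is a per-position, z-standardized
contrast of ancestral vs. non-ancestral allele abundance between archaic
and modern human genomes; strongly negative values mark candidate
positive selection in modern humans.  The track is an *input* (the
package never computes scores from alignments): a chrom/pos/score TSV
covering a subset of the genome, so a candidate SNP set typically joins
with partial coverage.

Provided here: the exact positional join with coverage accounting, a
quantile-quantile enrichment comparison of candidate vs. background
scores with a one-sided Mann-Whitney U test, multi-set distribution
comparisons with Benjamini-Hochberg-corrected pairwise tests, per-gene
mean scores, a sliding-window scan for the lowest-tail genome regions,
and locus-vs-region-set intersection counts.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .loci import Locus
from .regions import GenomicRegion, normalize_chrom

log = logging.getLogger(__name__)


@dataclass
class NssTrack:
    """Per-position sweep scores keyed by (chrom, pos)."""

    df: pd.DataFrame  # columns: chrom, pos, score

    def __post_init__(self):
        d = self.df
        if not np.all(np.isfinite(d["score"].to_numpy(float))):
            raise ValueError("track scores must be finite")
        if d.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate positions in score track")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "NssTrack":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        df["chrom"] = df["chrom"].map(normalize_chrom)
        return cls(df=df[["chrom", "pos", "score"]])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class ScoredSet:
    """A labeled SNP set joined to the track, with coverage accounting."""

    label: str
    df: pd.DataFrame  # columns: snp, chrom, pos, score (scored SNPs only)
    n_input: int

    @property
    def n_scored(self) -> int:
        return len(self.df)

    @property
    def coverage(self) -> float:
        return self.n_scored / self.n_input if self.n_input else 0.0

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(float)

    @property
    def mean(self) -> float:
        return float(self.scores.mean()) if self.n_scored else float("nan")

    @property
    def sd(self) -> float:
        return float(self.scores.std(ddof=1)) if self.n_scored > 1 else float("nan")


def join_scores(snps: pd.DataFrame, track: NssTrack, label: str = "set") -> ScoredSet:
    """Exact (chrom, pos) join of candidate SNPs onto the score track."""
    if len(track) == 0:
        raise ValueError("empty score track")
    merged = snps[["snp", "chrom", "pos"]].merge(
        track.df, on=["chrom", "pos"], how="inner")
    out = ScoredSet(label=label, df=merged.reset_index(drop=True),
                    n_input=len(snps))
    if out.coverage < 0.2:
        log.warning("%s: only %.0f%% of %d SNPs carry a score",
                    label, 100 * out.coverage, out.n_input)
    else:
        log.info("%s: scores for %d of %d SNPs (%.0f%%)",
                 label, out.n_scored, out.n_input, 100 * out.coverage)
    return out


DEFAULT_PROBS = np.arange(0.01, 1.0, 0.01)


def enrichment_qq(
    candidate_scores: np.ndarray,
    background_scores: np.ndarray,
    probs: np.ndarray = DEFAULT_PROBS,
) -> tuple[pd.DataFrame, float | None]:
    """Quantile curve of candidate vs. background scores + location test.

    For each probability q the x-coordinate is the background quantile
    and y the candidate quantile (both ascending).  A curve below the
    diagonal in the left tail means the candidates carry an excess of
    negative scores.  The second return value is the one-sided
    Mann-Whitney U p-value (alternative: candidate scores smaller),
    suppressed (None, with a warning) when the candidate set has fewer
    than 10 scores.
    """
    cand = np.asarray(candidate_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if len(cand) == 0 or len(bg) == 0:
        raise ValueError("both score sets must be non-empty")
    curve = pd.DataFrame({
        "prob": probs,
        "background": np.quantile(bg, probs),
        "candidate": np.quantile(cand, probs),
    })
    if len(cand) < 10:
        warnings.warn("candidate set < 10 scored SNPs; location test suppressed")
        return curve, None
    p = float(stats.mannwhitneyu(cand, bg, alternative="less").pvalue)
    return curve, p


def compare_sets(sets: Sequence[ScoredSet]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary statistics and pairwise location tests across SNP sets.

    Sets with fewer than 2 scored SNPs are excluded with a warning.
    Pairwise two-sided Mann-Whitney U p-values are Benjamini-Hochberg
    corrected across the pairs.  The summary frame carries the
    "in-between" ordering: sets sorted by mean, most negative first.
    """
    usable = []
    for s in sets:
        if s.n_scored < 2:
            warnings.warn(f"set {s.label!r} has n < 2 scored SNPs; excluded")
        else:
            usable.append(s)
    if len(usable) < 2:
        raise ValueError("need at least two usable sets")
    summary = pd.DataFrame({
        "label": [s.label for s in usable],
        "n_input": [s.n_input for s in usable],
        "n_scored": [s.n_scored for s in usable],
        "coverage": [s.coverage for s in usable],
        "mean": [s.mean for s in usable],
        "sd": [s.sd for s in usable],
    }).sort_values("mean", kind="stable").reset_index(drop=True)
    summary["rank_most_negative"] = np.arange(1, len(summary) + 1)

    rows = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            p = float(stats.mannwhitneyu(a.scores, b.scores,
                                         alternative="two-sided").pvalue)
            rows.append({"set_a": a.label, "set_b": b.label,
                         "mean_a": a.mean, "mean_b": b.mean, "p": p})
    tests = pd.DataFrame(rows)
    tests["p_bh"] = multipletests(tests["p"], method="fdr_bh")[1]
    return summary, tests


@dataclass
class GeneScore:
    gene: str
    n_snps: int
    mean_nss: float


def gene_mean_scores(
    gene_map: pd.DataFrame, scored: ScoredSet
) -> pd.DataFrame:
    """Mean sweep score per gene over the SNPs the gene was mapped from.

    ``gene_map`` is the (locus_id, lead_snp, gene) frame from positional
    mapping extended with a ``snp`` column, or any frame with columns
    (gene, snp).  Genes with zero scored SNPs are omitted; output is
    ranked ascending (most negative first).
    """
    scores = scored.df.set_index("snp")["score"]
    merged = gene_map.merge(scores.rename("score"), left_on="snp",
                            right_index=True, how="inner")
    if len(merged) == 0:
        return pd.DataFrame(columns=["gene", "n_snps", "mean_nss"])
    out = merged.groupby("gene")["score"].agg(["count", "mean"]).reset_index()
    out.columns = ["gene", "n_snps", "mean_nss"]
    return out.sort_values(["mean_nss", "gene"], kind="stable").reset_index(drop=True)


def extreme_windows(
    track: NssTrack,
    window_bp: int = 100_000,
    step_bp: int = 50_000,
    tail_quantile: float = 0.05,
    min_snps: int = 5,
) -> tuple[list[GenomicRegion], pd.DataFrame]:
    """Sliding-window scan for the lowest-mean tail of the score track.

    Windows of ``window_bp`` advanced by ``step_bp`` per chromosome;
    windows with fewer than ``min_snps`` scored positions are skipped.
    The threshold is the ``tail_quantile`` empirical quantile of eligible
    window means (the ceil(q*n)-th order statistic); windows with mean
    <= threshold are flagged — ties at the threshold are all included —
    and overlapping/adjacent flagged windows merge into regions.
    """
    if len(track) == 0:
        raise ValueError("empty score track")
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    rows = []
    for chrom, sub in track.df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        sc = sub["score"].to_numpy(float)[order]
        csum = np.concatenate([[0.0], np.cumsum(sc)])
        last = int(pos.max())
        starts = np.arange(1, max(last - window_bp + 2, 2), step_bp)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_bp - 1, side="right")
        n_in = hi - lo
        means = np.where(n_in > 0, (csum[hi] - csum[lo]) / np.maximum(n_in, 1),
                         np.nan)
        for s, k, mu in zip(starts, n_in, means):
            rows.append({"chrom": chrom, "start": int(s),
                         "end": int(s + window_bp - 1), "n_snps": int(k),
                         "mean": float(mu) if k else np.nan})
    windows = pd.DataFrame(rows)
    eligible = windows[windows["n_snps"] >= min_snps].copy()
    if len(eligible) == 0:
        return [], windows.assign(flagged=False)
    means = np.sort(eligible["mean"].to_numpy())
    k = max(1, int(np.ceil(tail_quantile * len(means))))
    threshold = means[k - 1]
    windows["flagged"] = (windows["n_snps"] >= min_snps) & (
        windows["mean"] <= threshold)
    flagged = [GenomicRegion(r.chrom, r.start, r.end)
               for r in windows[windows["flagged"]].itertuples()]
    # merge overlapping or adjacent flagged windows
    merged: list[GenomicRegion] = []
    for r in sorted(flagged, key=lambda r: (r.chrom, r.start)):
        if merged and merged[-1].chrom == r.chrom \
                and r.start <= merged[-1].end + 1:
            prev = merged[-1]
            merged[-1] = GenomicRegion(prev.chrom, prev.start,
                                       max(prev.end, r.end), "extreme")
        else:
            merged.append(GenomicRegion(r.chrom, r.start, r.end, "extreme"))
    log.info("extreme-window scan: %d/%d eligible windows flagged, %d regions",
             int(windows["flagged"].sum()), len(eligible), len(merged))
    return merged, windows


def region_overlap(
    loci: Sequence[Locus],
    region_sets: Mapping[str, Sequence[GenomicRegion]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-locus intersection flags against labeled region sets.

    Returns a frame with one boolean column per set and a per-set count
    of loci intersecting at least one of its regions.
    """
    rows = []
    for L in loci:
        row = {"chrom": L.chrom, "start": L.start, "end": L.end,
               "lead_snp": L.lead_snp}
        for name, regions in region_sets.items():
            row[name] = any(L.region.intersects(r) for r in regions)
        rows.append(row)
    df = pd.DataFrame(rows)
    counts = {name: int(df[name].sum()) if len(df) else 0
              for name in region_sets}
    return df, counts
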