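"""Conditional and conjunctional FDR for cross-trait polygenic overlap.

The conditional FDR of a SNP for a primary trait given a secondary trait
is the empirical-Bayes upper bound

    condFDR(p1 | p2) = p1 / F_hat(p1 | P2 <= p2),

where F_hat is the empirical conditional cdf of the primary p-values
among SNPs whose secondary p-value is at most p2.  Conditioning on
"everything" (p2 = 1) collapses it to the unconditional p1 / ecdf(p1),
the Benjamini-Hochberg-style empirical FDR; stronger secondary
association shrinks the denominator's stratum and, under cross-trait
enrichment, lowers the bound.  No pi0 estimate is applied, so the value
is a conservative upper bound throughout.

The conjunctional FDR — evidence of association with *both* traits — is
the per-SNP maximum of the two conditional FDRs taken in either
direction, thresholded at 0.05 by convention.

Estimation is on a fixed grid over (-log10 p1, -log10 p2): counts come
from a cumulative 2-D histogram, cells backed by too few SNPs inherit
the nearest reliable (less extreme) cell, and monotonicity along the
primary axis is enforced by a running minimum.  Per-SNP values are read
off the grid by bilinear interpolation in -log10 space.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import LdBlocks
from .sumstats import HarmonizedPanel

log = logging.getLogger(__name__)

#: grid edges over -log10 p: 101 nodes from 0 to 10 (p clipped below
#: 1e-10 for binning only; reported p-values are untouched)
N_EDGES = 101
LOG10_MAX = 10.0
#: cells estimated from fewer SNPs than this inherit their neighbor
MIN_CELL_COUNT = 30
DEFAULT_THRESHOLD = 0.05


def default_edges() -> np.ndarray:
    return np.linspace(0.0, LOG10_MAX, N_EDGES)


@dataclass
class CondFdrGrid:
    """Conditional-FDR lookup surface.

    ``values[i, j]`` is condFDR at primary p1 = 10**-edges[i] given the
    secondary stratum P2 <= 10**-edges[j]; ``counts[i, j]`` is the number
    of SNPs in the joint tail that produced the estimate.
    """

    edges: np.ndarray
    values: np.ndarray  # (n_edges, n_edges), primary axis first
    counts: np.ndarray
    n_secondary: np.ndarray  # stratum sizes per secondary edge

    def __post_init__(self):
        k = len(self.edges)
        assert self.values.shape == (k, k) == self.counts.shape


def _neglog10(p: np.ndarray) -> np.ndarray:
    return np.clip(-np.log10(np.asarray(p, dtype=float)), 0.0, LOG10_MAX)


def _tail_counts(lx: np.ndarray, ly: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """count[i, j] = #{k : lx_k >= edges[i] and ly_k >= edges[j]}."""
    bins = np.append(edges, np.inf)
    hist, _, _ = np.histogram2d(lx, ly, bins=[bins, bins])
    return np.cumsum(np.cumsum(hist[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]


def conditional_cdf_grid(
    p_primary: np.ndarray,
    p_secondary: np.ndarray,
    edges: np.ndarray | None = None,
    min_cell_count: int = MIN_CELL_COUNT,
) -> CondFdrGrid:
    """Estimate the conditional-FDR grid from two aligned p-value vectors.

    For every secondary edge t the stratum is {i : p2_i <= t}; within it
    the empirical conditional cdf of p1 gives

        cell[i, j] = p1_i * |stratum_j| / #{p1 <= p1_i, p2 <= t_j},

    clipped to [0, 1].  Cells whose joint-tail count falls below
    ``min_cell_count`` are unreliable and inherit the nearest reliable
    cell toward looser p1; empty strata inherit the nearest looser
    stratum.  A cumulative minimum along the primary axis enforces that
    condFDR never increases as p1 becomes more significant.
    """
    p1 = np.asarray(p_primary, dtype=float)
    p2 = np.asarray(p_secondary, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError("p vectors must be 1-D and aligned")
    if len(p1) < 100:
        raise ValueError("need at least 100 SNPs to estimate the grid")
    if np.any(~np.isfinite(p1)) or np.any(~np.isfinite(p2)):
        raise ValueError("p-values must be finite")
    if p1.min() <= 0 or p1.max() > 1 or p2.min() <= 0 or p2.max() > 1:
        raise ValueError("p-values must lie in (0, 1]")
    edges = default_edges() if edges is None else np.asarray(edges, dtype=float)

    counts = _tail_counts(_neglog10(p1), _neglog10(p2), edges)
    n_secondary = counts[0, :].copy()
    if n_secondary[0] == 0:
        raise ValueError("empty secondary stratum at the loosest threshold")

    p1_nodes = 10.0 ** (-edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = p1_nodes[:, None] * n_secondary[None, :] / counts
    raw = np.clip(raw, 0.0, 1.0)

    values = np.empty_like(raw)
    k = len(edges)
    for j in range(k):
        if n_secondary[j] == 0:
            values[:, j] = values[:, j - 1]  # inherit looser stratum
            continue
        col = raw[:, j]
        reliable = counts[:, j] >= min_cell_count
        reliable[0] = True  # cell at p1 = 1 is exactly 1 by construction
        # forward-fill unreliable cells with the last reliable value
        idx = np.where(reliable, np.arange(k), 0)
        np.maximum.accumulate(idx, out=idx)
        values[:, j] = col[idx]
    values = np.minimum.accumulate(values, axis=0)
    return CondFdrGrid(edges=edges, values=values, counts=counts,
                       n_secondary=n_secondary)


def lookup_cond_fdr(
    grid: CondFdrGrid, p1: np.ndarray | float, p2: np.ndarray | float
) -> np.ndarray:
    """Bilinear interpolation of the grid in -log10 space.

    Queries beyond the last edge clamp to the boundary cell; output is
    clipped to [0, 1].  NaN input is a hard error.
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    if np.any(np.isnan(p1)) or np.any(np.isnan(p2)):
        raise ValueError("NaN p-value passed to lookup")
    x = _neglog10(p1)
    y = _neglog10(p2)
    e = grid.edges
    k = len(e)
    i0 = np.clip(np.searchsorted(e, x, side="right") - 1, 0, k - 2)
    j0 = np.clip(np.searchsorted(e, y, side="right") - 1, 0, k - 2)
    dx = (x - e[i0]) / (e[i0 + 1] - e[i0])
    dy = (y - e[j0]) / (e[j0 + 1] - e[j0])
    dx = np.clip(dx, 0.0, 1.0)
    dy = np.clip(dy, 0.0, 1.0)
    v = grid.values
    out = (
        v[i0, j0] * (1 - dx) * (1 - dy)
        + v[i0 + 1, j0] * dx * (1 - dy)
        + v[i0, j0 + 1] * (1 - dx) * dy
        + v[i0 + 1, j0 + 1] * dx * dy
    )
    return np.clip(out, 0.0, 1.0)


def conj_fdr(condfdr_12: np.ndarray, condfdr_21: np.ndarray) -> np.ndarray:
    """Conjunctional FDR: the per-SNP maximum of the two conditional FDRs."""
    a = np.asarray(condfdr_12, dtype=float)
    b = np.asarray(condfdr_21, dtype=float)
    if a.shape != b.shape:
        raise ValueError("misaligned SNP sets in conj_fdr")
    return np.maximum(a, b)


@dataclass
class CondFdrResult:
    """Per-SNP conditional/conjunctional FDR plus the grids behind them."""

    snps: pd.DataFrame
    condfdr_12: np.ndarray
    condfdr_21: np.ndarray
    conjfdr: np.ndarray
    grid_12: CondFdrGrid
    grid_21: CondFdrGrid
    threshold: float = DEFAULT_THRESHOLD
    trait_primary: str = "trait1"
    trait_secondary: str = "trait2"

    @property
    def shared_mask(self) -> np.ndarray:
        return self.conjfdr < self.threshold

    def to_frame(self, p1: np.ndarray, p2: np.ndarray) -> pd.DataFrame:
        df = self.snps.rename(columns={"snp": "SNP", "chrom": "CHR",
                                       "pos": "BP"}).copy()
        df["P1"] = p1
        df["P2"] = p2
        df["condFDR12"] = self.condfdr_12
        df["condFDR21"] = self.condfdr_21
        df["conjFDR"] = self.conjfdr
        df["shared_flag"] = self.shared_mask.astype(int)
        return df


def analyze_pair(
    panel: HarmonizedPanel,
    primary: int | str = 0,
    secondary: int | str = 1,
    threshold: float = DEFAULT_THRESHOLD,
    blocks: LdBlocks | None = None,
    n_prune: int = 0,
    seed: int = 0,
    edges: np.ndarray | None = None,
) -> CondFdrResult:
    """Both-direction conditional FDR and the conjunctional FDR for a pair.

    ``n_prune > 0`` averages each grid over LD-pruned subsamples (one SNP
    per block per iteration) before the per-SNP lookup.
    """
    i = panel.traits.index(primary) if isinstance(primary, str) else primary
    j = panel.traits.index(secondary) if isinstance(secondary, str) else secondary
    p1 = panel.p[:, i]
    p2 = panel.p[:, j]
    if n_prune > 0:
        if blocks is None:
            raise ValueError("pruned estimation requires LD blocks")
        g12 = random_prune_average(p1, p2, blocks, n_iter=n_prune, seed=seed,
                                   edges=edges)
        g21 = random_prune_average(p2, p1, blocks, n_iter=n_prune, seed=seed + 1,
                                   edges=edges)
    else:
        g12 = conditional_cdf_grid(p1, p2, edges=edges)
        g21 = conditional_cdf_grid(p2, p1, edges=edges)
    c12 = lookup_cond_fdr(g12, p1, p2)
    c21 = lookup_cond_fdr(g21, p2, p1)
    cj = conj_fdr(c12, c21)
    res = CondFdrResult(
        snps=panel.snps, condfdr_12=c12, condfdr_21=c21, conjfdr=cj,
        grid_12=g12, grid_21=g21, threshold=threshold,
        trait_primary=panel.traits[i], trait_secondary=panel.traits[j],
    )
    log.info(
        "conjFDR %s|%s: %d / %d SNPs below %.3g",
        res.trait_primary, res.trait_secondary,
        int(res.shared_mask.sum()), len(cj), threshold,
    )
    return res


DEFAULT_STRATA = (1.0, 0.1, 0.01, 0.001)


def stratified_qq(
    p_primary: np.ndarray,
    p_secondary: np.ndarray,
    strata: tuple[float, ...] = DEFAULT_STRATA,
) -> pd.DataFrame:
    """Stratified Q-Q curves: observed vs expected -log10 p1 by p2 stratum.

    Within each stratum {p2 <= t} the primary p-values are ranked
    ascending; the i-th observed -log10 p1 is paired with the expected
    quantile -log10((i - 0.5) / n).  Upward deviation that grows as t
    tightens is the cross-trait enrichment signature.  Empty strata are
    omitted with a warning.  Returned long-format: (stratum, expected,
    observed).
    """
    p1 = np.asarray(p_primary, dtype=float)
    p2 = np.asarray(p_secondary, dtype=float)
    frames = []
    for t in strata:
        sel = p2 <= t
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"stratum p2 <= {t} is empty; omitted")
            continue
        obs = np.sort(_neglog10(p1[sel]))[::-1]
        exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        frames.append(pd.DataFrame({"stratum": t, "expected": exp,
                                    "observed": obs}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["stratum", "expected", "observed"])


def random_prune_average(
    p_primary: np.ndarray,
    p_secondary: np.ndarray,
    blocks: LdBlocks,
    n_iter: int = 100,
    seed: int = 0,
    edges: np.ndarray | None = None,
    min_cell_count: int = MIN_CELL_COUNT,
) -> CondFdrGrid:
    """LD-aware grid: average over random one-SNP-per-block prunings.

    Each iteration samples one SNP uniformly from every LD block,
    estimates the grid on that pruned set, and the final surface is the
    elementwise mean.  Deterministic under ``seed``.
    """
    if blocks is None or blocks.labels is None:
        raise ValueError("block labels missing: run without pruning instead")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    p1 = np.asarray(p_primary, dtype=float)
    p2 = np.asarray(p_secondary, dtype=float)
    labels = blocks.labels
    rng = np.random.default_rng(seed)
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    starts = np.searchsorted(sorted_labels, np.arange(blocks.n_blocks))
    ends = np.searchsorted(sorted_labels, np.arange(blocks.n_blocks), side="right")
    acc_values = None
    acc_counts = None
    acc_nsec = None
    grid = None
    for _ in range(n_iter):
        offs = rng.integers(0, ends - starts)
        pick = order[starts + offs]
        grid = conditional_cdf_grid(p1[pick], p2[pick], edges=edges,
                                    min_cell_count=min_cell_count)
        if acc_values is None:
            acc_values = grid.values.copy()
            acc_counts = grid.counts.astype(float)
            acc_nsec = grid.n_secondary.astype(float)
        else:
            acc_values += grid.values
            acc_counts += grid.counts
            acc_nsec += grid.n_secondary
    return CondFdrGrid(edges=grid.edges, values=acc_values / n_iter,
                       counts=acc_counts / n_iter, n_secondary=acc_nsec / n_iter)
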