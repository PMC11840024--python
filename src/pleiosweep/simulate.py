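"""Synthetic GWAS summary statistics with controlled polygenic overlap.

The generator emulates the statistical structure a cross-trait pleiotropy
analysis sees: two (optionally three) polygenic traits whose per-SNP
effects follow a spike-and-slab architecture, with a configurable
proportion of causal variants shared between traits and a configurable
correlation of effect sizes among the shared causals.  Linkage
disequilibrium is modeled as exchangeable within contiguous blocks: a
single correlation ``block_r`` both spreads causal effects across a block
and correlates the sampling noise of z-scores within it.

Under this model the expected per-SNP chi-square is exactly the LD-score
regression identity  E[z_j^2] = 1 + n * h2 * l_j / m  with
l_j = 1 + (block size - 1) * block_r**2, which is what makes the
generated panels a valid test bed for both the conditional-FDR estimator
and the heritability/genetic-correlation fits.

Effect-size vectors are rescaled so the realized sum of squared effects
equals the configured heritability exactly; the rescaling is a per-trait
scalar, so the effect correlation among shared causals is untouched.

A separate routine lays a selective-sweep score track over the panel:
standard-normal background with planted negative-mean regions (negative
scores imitate candidate positive selection in modern humans) and a
configurable missing fraction emulating incomplete track coverage.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import GenomicRegion
from .sumstats import HarmonizedPanel, P_FLOOR

#: two synthetic chromosomes by default so cross-chromosome logic is exercised
DEFAULT_CHROM_LENGTHS = {"1": 120_000_000, "2": 100_000_000}


@dataclass
class SimConfig:
    """Parameters of the two-trait generator (optional third trait).

    ``pi1``/``pi2`` are per-trait causal proportions, ``pi_shared`` the
    proportion causal in both traits, ``rho_beta`` the effect correlation
    among shared causals.  ``block_r`` is the single within-block
    correlation used both for effect spreading and for z-score noise.
    """

    m_snps: int = 20_000
    n_blocks: int = 1_000
    block_r: float = 0.9
    pi1: float = 0.01
    pi2: float = 0.01
    pi_shared: float = 0.005
    rho_beta: float = 0.8
    h2_1: float = 0.3
    h2_2: float = 0.3
    n1: int = 50_000
    n2: int = 50_000
    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    # optional third trait (paired with trait 1 only)
    pi3: float | None = None
    pi_shared_13: float = 0.0
    rho_beta_13: float = 0.0
    h2_3: float = 0.3
    n3: int = 50_000

    def validate(self) -> None:
        if not (0 <= self.block_r < 1):
            raise ValueError("block_r must be in [0, 1)")
        if self.pi_shared > min(self.pi1, self.pi2) + 1e-12:
            raise ValueError("pi_shared exceeds min(pi1, pi2): infeasible config")
        if self.pi3 is not None and self.pi_shared_13 > min(self.pi1, self.pi3) + 1e-12:
            raise ValueError("pi_shared_13 exceeds min(pi1, pi3): infeasible config")
        for h2 in (self.h2_1, self.h2_2) + ((self.h2_3,) if self.pi3 is not None else ()):
            if not (0 <= h2 <= 1):
                raise ValueError("heritabilities must lie in [0, 1]")
        if min(self.m_snps, self.n_blocks, self.n1, self.n2) <= 0:
            raise ValueError("counts must be positive")
        if abs(self.rho_beta) > 1 or abs(self.rho_beta_13) > 1:
            raise ValueError("effect correlations must lie in [-1, 1]")


@dataclass
class LdBlocks:
    """Exchangeable-block LD: same-block pairs correlate at ``r``, others at 0."""

    labels: np.ndarray  # (m,) integer block label per SNP
    r: float

    @property
    def n_blocks(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_blocks)

    def r2(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        return self.r ** 2 if self.labels[i] == self.labels[j] else 0.0


@dataclass
class TruthTable:
    """Planted-signal record: per-SNP causal flags and planted regions."""

    flags: pd.DataFrame  # columns: causal_t1, causal_t2, causal_shared [, causal_t3 ...]
    shared_regions: list[GenomicRegion] = field(default_factory=list)
    sweep_regions: list[GenomicRegion] = field(default_factory=list)


def _layout_positions(cfg: SimConfig, rng: np.random.Generator):
    """Uniform positions on the synthetic chromosomes, m split by length."""
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    m_per = np.floor(cfg.m_snps * lengths / lengths.sum()).astype(int)
    m_per[0] += cfg.m_snps - m_per.sum()
    chrom_col, pos_col = [], []
    for c, L, m in zip(chroms, lengths, m_per):
        # rejection-sample distinct positions; collisions are vanishingly
        # rare at the default density (~1e-4 per draw)
        pos = np.unique(rng.integers(1, np.int64(L) + 1, size=m))
        while len(pos) < m:
            extra = rng.integers(1, np.int64(L) + 1, size=m - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chrom_col.append(np.full(m, c, dtype=object))
        pos_col.append(pos)
    return np.concatenate(chrom_col), np.concatenate(pos_col), m_per


def _block_labels(
    m_per_chrom: np.ndarray, n_blocks: int, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous blocks with random (Dirichlet-uniform) sizes.

    Cut points are drawn uniformly without replacement, giving block
    sizes with coefficient of variation near 1 — a crude stand-in for
    the wide LD-block size spectrum of real genomes, and the size
    variation LD-score regression needs for a well-posed slope.
    Blocks never span a chromosome boundary.
    """
    total = int(m_per_chrom.sum())
    b_per = np.maximum(1, np.floor(n_blocks * m_per_chrom / total)).astype(int)
    b_per[0] += max(0, n_blocks - b_per.sum())
    labels = np.empty(total, dtype=np.int64)
    offset_snp = 0
    offset_block = 0
    for m, b in zip(m_per_chrom, b_per):
        b = min(b, m)
        cuts = np.concatenate([
            [0], np.sort(rng.choice(m - 1, size=b - 1, replace=False)) + 1, [m],
        ]) if b > 1 else np.array([0, m])
        lab = np.repeat(np.arange(b), np.diff(cuts))
        labels[offset_snp:offset_snp + m] = lab + offset_block
        offset_snp += m
        offset_block += b
    return labels


def _draw_effects(rng, m, causal1, causal2, shared, rho, h2_1, h2_2):
    """Spike-and-slab effects; realized sum of squares rescaled to h2."""
    b1 = np.zeros(m)
    b2 = np.zeros(m)
    k = shared.sum()
    if k:
        # manual bivariate construction stays exact at |rho| = 1
        x = rng.standard_normal(k)
        w = rng.standard_normal(k)
        b1[shared] = x
        b2[shared] = rho * x + np.sqrt(max(0.0, 1.0 - rho ** 2)) * w
    only1 = causal1 & ~shared
    only2 = causal2 & ~shared
    b1[only1] = rng.standard_normal(only1.sum())
    b2[only2] = rng.standard_normal(only2.sum())
    for b, h2 in ((b1, h2_1), (b2, h2_2)):
        ss = (b ** 2).sum()
        if ss > 0 and h2 > 0:
            b *= np.sqrt(h2 / ss)
        else:
            b[:] = 0.0
    return b1, b2


def _block_noise(rng, labels, n_blocks, r, size):
    """Exchangeable within-block noise: corr r inside a block, 0 across."""
    g = rng.standard_normal(n_blocks)[labels]
    e = rng.standard_normal(size)
    return np.sqrt(r) * g + np.sqrt(1.0 - r) * e


def _smooth(beta: np.ndarray, labels: np.ndarray, n_blocks: int, r: float) -> np.ndarray:
    """Apply the exchangeable LD operator R: (R b)_j = b_j + r * sum_{k!=j} b_k."""
    block_sum = np.bincount(labels, weights=beta, minlength=n_blocks)[labels]
    return (1.0 - r) * beta + r * block_sum


def _z_to_p(z: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR)


def simulate_panel(cfg: SimConfig) -> tuple[HarmonizedPanel, TruthTable, LdBlocks]:
    """Generate a harmonized 2- or 3-trait panel with planted truth.

    Returns the panel (alleles arbitrarily A/G, already aligned), the
    truth table (per-SNP causal flags plus the positional extent of every
    LD block containing a shared causal, as "planted shared regions"),
    and the LD-block structure.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_snps
    chrom, pos, m_per = _layout_positions(cfg, rng)
    labels = _block_labels(m_per, cfg.n_blocks, rng)
    n_blocks = int(labels.max()) + 1

    def pick(k, exclude=None):
        pool = np.arange(m) if exclude is None else np.setdiff1d(np.arange(m), exclude)
        return rng.choice(pool, size=k, replace=False)

    n_sh = int(round(m * cfg.pi_shared))
    n_c1 = int(round(m * cfg.pi1))
    n_c2 = int(round(m * cfg.pi2))
    idx_sh = pick(n_sh)
    idx_1only = pick(n_c1 - n_sh, exclude=idx_sh)
    idx_2only = pick(n_c2 - n_sh, exclude=np.concatenate([idx_sh, idx_1only]))
    causal1 = np.zeros(m, bool); causal1[idx_sh] = True; causal1[idx_1only] = True
    causal2 = np.zeros(m, bool); causal2[idx_sh] = True; causal2[idx_2only] = True
    shared = np.zeros(m, bool); shared[idx_sh] = True

    b1, b2 = _draw_effects(rng, m, causal1, causal2, shared,
                           cfg.rho_beta, cfg.h2_1, cfg.h2_2)

    r = cfg.block_r
    traits = ["trait1", "trait2"]
    betas = [b1, b2]
    ns = [cfg.n1, cfg.n2]
    causal_cols = {"causal_t1": causal1, "causal_t2": causal2,
                   "causal_shared": shared}

    if cfg.pi3 is not None:
        n_sh13 = int(round(m * cfg.pi_shared_13))
        n_c3 = int(round(m * cfg.pi3))
        idx_sh13 = rng.choice(idx_sh if n_sh13 <= n_sh and n_sh > 0 else np.arange(m),
                              size=min(n_sh13, max(n_sh, 1)), replace=False) \
            if n_sh13 and n_sh else pick(n_sh13)
        # trait-3 shared causals reuse trait-1 causal positions where possible
        idx_sh13 = np.asarray(idx_sh13, dtype=int)
        remaining = n_c3 - len(idx_sh13)
        idx_3only = pick(max(remaining, 0), exclude=idx_sh13)
        causal3 = np.zeros(m, bool); causal3[idx_sh13] = True; causal3[idx_3only] = True
        shared13 = np.zeros(m, bool); shared13[idx_sh13] = True
        b3 = np.zeros(m)
        k13 = shared13.sum()
        if k13:
            # conditional draw with correlation rho_beta_13 to trait 1's effect
            b1_std = np.where(np.abs(b1) > 0, b1, 0.0)
            s1 = b1_std[shared13]
            s1 = s1 / (s1.std() if s1.std() > 0 else 1.0)
            b3[shared13] = cfg.rho_beta_13 * s1 + np.sqrt(
                max(0.0, 1 - cfg.rho_beta_13 ** 2)) * rng.standard_normal(k13)
        b3[idx_3only] = rng.standard_normal(len(idx_3only))
        ss = (b3 ** 2).sum()
        b3 = b3 * np.sqrt(cfg.h2_3 / ss) if ss > 0 and cfg.h2_3 > 0 else b3 * 0.0
        traits.append("trait3")
        betas.append(b3)
        ns.append(cfg.n3)
        causal_cols["causal_t3"] = causal3
        causal_cols["causal_shared_13"] = shared13

    z_cols, p_cols, n_cols = [], [], []
    for beta, n in zip(betas, ns):
        signal = _smooth(beta, labels, n_blocks, r)
        eps = _block_noise(rng, labels, n_blocks, r, m)
        z = np.sqrt(n) * signal + eps
        z_cols.append(z)
        p_cols.append(_z_to_p(z))
        n_cols.append(np.full(m, float(n)))

    snps = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(m)],
        "chrom": chrom,
        "pos": pos,
        "a1": "A",
        "a2": "G",
    })
    panel = HarmonizedPanel(
        traits=traits,
        snps=snps,
        z=np.column_stack(z_cols),
        p=np.column_stack(p_cols),
        n=np.column_stack(n_cols),
        ld_block=labels,
    )

    shared_regions = []
    for b in np.unique(labels[shared]):
        in_b = labels == b
        shared_regions.append(GenomicRegion(
            chrom[in_b][0], int(pos[in_b].min()), int(pos[in_b].max()),
            f"shared_block_{b}",
        ))
    truth = TruthTable(flags=pd.DataFrame(causal_cols), shared_regions=shared_regions)
    return panel, truth, LdBlocks(labels=labels, r=r)


def simulate_nss_track(
    chrom: np.ndarray,
    pos: np.ndarray,
    sweep_regions: Sequence[tuple[GenomicRegion, float]] = (),
    seed: int = 0,
    mask_fraction: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Selective-sweep score track over the given positions.

    Background scores are i.i.d. standard normal; positions inside a sweep
    region get mean ``delta`` (negative delta imitates positive selection
    in modern humans).  ``mask_fraction`` of positions are dropped from
    the returned track to emulate incomplete coverage; the boolean
    coverage mask (True = score available) is returned alongside.
    """
    rng = np.random.default_rng(seed)
    m = len(pos)
    scores = rng.standard_normal(m)
    for region, delta in sweep_regions:
        if not np.isfinite(delta):
            raise ValueError("sweep mean shift must be finite")
        inside = (np.asarray(chrom, dtype=object) == region.chrom) \
            & (pos >= region.start) & (pos <= region.end)
        scores[inside] += delta
    covered = rng.random(m) >= mask_fraction
    track = pd.DataFrame({"chrom": np.asarray(chrom, dtype=object)[covered],
                          "pos": np.asarray(pos)[covered],
                          "score": scores[covered]})
    return track, covered


def simulate_gene_annotation(
    chrom_lengths: dict[str, int],
    n_genes: int,
    mean_length: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene intervals (overlaps allowed) on the synthetic chromosomes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    which = rng.choice(len(chroms), size=n_genes, p=lengths / lengths.sum())
    glen = np.maximum(1, rng.exponential(mean_length, size=n_genes).astype(np.int64))
    rows = []
    for i in range(n_genes):
        c = chroms[which[i]]
        L = chrom_lengths[c]
        length = min(int(glen[i]), L)
        start = int(rng.integers(1, L - length + 2))
        rows.append((f"GENE{i + 1}", c, start, start + length - 1))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_region_set(
    chrom_lengths: dict[str, int],
    n_regions: int,
    mean_length: int = 100_000,
    seed: int = 0,
    label: str = "region",
) -> list[GenomicRegion]:
    """Random labeled regions (disjointness not enforced)."""
    if n_regions == 0:
        return []
    df = simulate_gene_annotation(chrom_lengths, n_regions, mean_length, seed)
    return [
        GenomicRegion(r.chrom, int(r.start), int(r.end), f"{label}_{i + 1}")
        for i, r in enumerate(df.itertuples())
    ]
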