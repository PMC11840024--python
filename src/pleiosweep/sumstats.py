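"""Reading, validation and cross-trait harmonization of GWAS summary statistics.

A single trait's summary statistics are held as a :class:`SumStats` (a
validated DataFrame with standardized columns).  Two or more traits are
merged into a :class:`HarmonizedPanel`: the rsID intersection with effect
alleles aligned to the first trait, ordered by genomic position, with
per-trait z/p/n matrices.

Input files are headered, whitespace- or tab-delimited tables (optionally
gzipped); a column map translates the file's header names into the
standard fields.  All positions are 1-based on a single reference build;
the package asserts positional agreement across traits but performs no
liftover.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicRegion, normalize_chrom

log = logging.getLogger(__name__)

STANDARD_FIELDS = ("snp", "chrom", "pos", "a1", "a2", "z", "beta", "se", "p", "n")
MANDATORY = ("snp", "chrom", "pos", "a1", "a2", "p")

#: minimum p-value retained; p = 0 inputs are clipped here (needed in
#: -log10 space downstream) with a logged warning.
P_FLOOR = 1e-300

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    """Strand-ambiguous pair (A/T or C/G): indistinguishable after a flip."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class SumStats:
    """One trait's validated per-variant association summary."""

    trait: str
    df: pd.DataFrame  # columns: snp, chrom, pos, a1, a2, z, p, n
    n_read: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str],
    trait: str | None = None,
    z_beta_rtol: float = 1e-6,
) -> SumStats:
    """Read one trait's summary statistics with validation.

    Parameters
    ----------
    path
        Delimited text file with a header row (``.gz`` accepted).
    column_map
        Mapping from file column names to standard fields. Must resolve
        ``snp, chrom, pos, a1, a2, p`` and either ``z`` or ``beta`` + ``se``.
        If ``n`` is absent a hard error is raised unless a constant is
        supplied via the pseudo-entry ``{"__n__": <int>}``.
    trait
        Label for the trait; defaults to the file stem.

    Records failing validation (p out of range, non-finite z, n <= 0,
    inconsistent beta/se vs z) are dropped and counted by reason.
    Duplicate rsIDs keep the record with the largest n.
    """
    path = Path(path)
    trait = trait or path.stem
    rename = {src: dst for src, dst in column_map.items() if not src.startswith("__")}
    unknown = set(rename.values()) - set(STANDARD_FIELDS)
    if unknown:
        raise ValueError(f"column_map targets unknown fields: {sorted(unknown)}")

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep=None, engine="python")
    df = df.rename(columns=rename)

    have = set(df.columns)
    missing = [c for c in MANDATORY if c not in have]
    if missing:
        raise ValueError(f"{path}: cannot resolve mandatory column(s) {missing}")
    if "z" not in have and not {"beta", "se"} <= have:
        raise ValueError(f"{path}: need either a z column or beta + se columns")

    n_read = len(df)
    drops: dict[str, int] = {}

    def drop(mask: np.ndarray, reason: str) -> None:
        nonlocal df
        k = int(mask.sum())
        if k:
            drops[reason] = drops.get(reason, 0) + k
            df = df.loc[~mask]

    df = df.copy()
    df["snp"] = df["snp"].astype(str)
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["p"] = pd.to_numeric(df["p"], errors="coerce")
    for col in ("z", "beta", "se"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "n" in df.columns:
        df["n"] = pd.to_numeric(df["n"], errors="coerce")
    elif "__n__" in column_map:
        df["n"] = float(column_map["__n__"])
    else:
        raise ValueError(f"{path}: no sample-size column; map 'n' or pass '__n__'")

    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()

    drop(df["pos"].isna().to_numpy() | (df["pos"] <= 0).to_numpy(), "bad position")
    df["pos"] = df["pos"].astype(np.int64)

    n_zero_p = int((df["p"] == 0).sum())
    if n_zero_p:
        log.warning("%s: clipping %d p = 0 values to %.0e", trait, n_zero_p, P_FLOOR)
        df.loc[df["p"] == 0, "p"] = P_FLOOR
    drop(df["p"].isna().to_numpy() | (df["p"] <= 0).to_numpy() | (df["p"] > 1).to_numpy(),
         "p out of range")
    drop(df["n"].isna().to_numpy() | (df["n"] <= 0).to_numpy(), "n not positive")

    if "z" in df.columns:
        drop(~np.isfinite(df["z"].to_numpy(float)), "z not finite")
        if {"beta", "se"} <= set(df.columns):
            with np.errstate(divide="ignore", invalid="ignore"):
                z_from_beta = df["beta"].to_numpy(float) / df["se"].to_numpy(float)
            z = df["z"].to_numpy(float)
            bad = np.isfinite(z_from_beta) & (
                np.abs(z - z_from_beta) > z_beta_rtol * np.maximum(1.0, np.abs(z))
            )
            drop(bad, "z inconsistent with beta/se")
    else:
        drop(
            ~np.isfinite(df["beta"].to_numpy(float))
            | ~np.isfinite(df["se"].to_numpy(float))
            | (df["se"].to_numpy(float) <= 0),
            "bad beta/se",
        )
        df["z"] = df["beta"] / df["se"]

    # duplicate rsIDs: keep the largest-n record
    before = len(df)
    df = df.sort_values("n", ascending=False, kind="stable").drop_duplicates("snp")
    if before - len(df):
        drops["duplicate rsID"] = drops.get("duplicate rsID", 0) + (before - len(df))
    before = len(df)
    df = df.drop_duplicates(["chrom", "pos", "a1", "a2"])
    if before - len(df):
        drops["duplicate variant"] = drops.get("duplicate variant", 0) + (before - len(df))

    df = df[["snp", "chrom", "pos", "a1", "a2", "z", "p", "n"]].sort_values(
        ["chrom", "pos"], kind="stable"
    ).reset_index(drop=True)

    n_dropped = n_read - len(df)
    log.info(
        "%s: read %d records, kept %d, dropped %d (%s)",
        trait, n_read, len(df), n_dropped,
        "; ".join(f"{k}: {v}" for k, v in drops.items()) or "none",
    )
    if len(df) == 0:
        raise ValueError(f"{path}: zero valid records after validation")
    return SumStats(trait=trait, df=df, n_read=n_read, n_dropped=n_dropped,
                    drop_reasons=drops)


def write_sumstats(ss: SumStats, path: str | Path) -> None:
    """Write a trait's records as a tab-delimited table (round-trippable)."""
    out = ss.df.rename(columns={
        "snp": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2",
        "z": "Z", "p": "P", "n": "N",
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


DEFAULT_COLUMN_MAP = {"SNP": "snp", "CHR": "chrom", "BP": "pos", "A1": "a1",
                      "A2": "a2", "Z": "z", "P": "p", "N": "n",
                      "BETA": "beta", "SE": "se"}


@dataclass
class HarmonizedPanel:
    """Variants shared across traits with alleles aligned to trait 1.

    ``snps`` holds the variant identity (snp, chrom, pos, a1, a2) sorted by
    (chrom, pos); ``z`` and ``p`` are (m, k) arrays, one column per trait;
    ``n`` is (m, k); ``ld_block`` is an optional (m,) integer label array.
    """

    traits: list[str]
    snps: pd.DataFrame
    z: np.ndarray
    p: np.ndarray
    n: np.ndarray
    ld_block: np.ndarray | None = None

    def __post_init__(self):
        m, k = self.z.shape
        assert len(self.snps) == m and self.p.shape == (m, k) == self.n.shape
        assert len(self.traits) == k

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def subset(self, mask: np.ndarray) -> "HarmonizedPanel":
        idx = np.asarray(mask)
        return HarmonizedPanel(
            traits=list(self.traits),
            snps=self.snps.loc[idx].reset_index(drop=True),
            z=self.z[idx],
            p=self.p[idx],
            n=self.n[idx],
            ld_block=None if self.ld_block is None else self.ld_block[idx],
        )

    def to_sumstats(self) -> list[SumStats]:
        """Decompose back into one SumStats per trait (alignment preserved)."""
        out = []
        for j, t in enumerate(self.traits):
            df = self.snps.copy()
            df["z"] = self.z[:, j]
            df["p"] = self.p[:, j]
            df["n"] = self.n[:, j]
            out.append(SumStats(trait=t, df=df.reset_index(drop=True)))
        return out

    def to_frame(self) -> pd.DataFrame:
        df = self.snps.rename(columns={"snp": "SNP", "chrom": "CHR", "pos": "BP",
                                       "a1": "A1", "a2": "A2"}).copy()
        for j, t in enumerate(self.traits):
            df[f"Z_{t}"] = self.z[:, j]
        for j, t in enumerate(self.traits):
            df[f"P_{t}"] = self.p[:, j]
        for j, t in enumerate(self.traits):
            df[f"N_{t}"] = self.n[:, j]
        if self.ld_block is not None:
            df["BLOCK"] = self.ld_block
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HarmonizedPanel":
        df = pd.read_csv(path, sep="\t")
        traits = [c[2:] for c in df.columns if c.startswith("Z_")]
        snps = df[["SNP", "CHR", "BP", "A1", "A2"]].rename(columns={
            "SNP": "snp", "CHR": "chrom", "BP": "pos", "A1": "a1", "A2": "a2"})
        snps["chrom"] = snps["chrom"].map(normalize_chrom)
        return cls(
            traits=traits,
            snps=snps.reset_index(drop=True),
            z=df[[f"Z_{t}" for t in traits]].to_numpy(float),
            p=df[[f"P_{t}" for t in traits]].to_numpy(float),
            n=df[[f"N_{t}" for t in traits]].to_numpy(float),
            ld_block=df["BLOCK"].to_numpy(int) if "BLOCK" in df.columns else None,
        )


def harmonize_panel(
    traits: Sequence[SumStats], ambiguity_policy: str = "drop"
) -> HarmonizedPanel:
    """Intersect >= 2 traits on rsID and align effect alleles to trait 1.

    For each shared SNP the other traits' alleles are matched to trait 1
    directly, as a swap (z negated), as a strand flip, or as a flipped
    swap (z negated); incompatible allele pairs are dropped.  Under
    ``ambiguity_policy='drop'`` strand-ambiguous SNPs (A/T, C/G) are
    removed.  SNPs whose positions disagree across traits are dropped with
    a logged reason.  The panel is ordered by (chrom, pos).
    """
    if len(traits) < 2:
        raise ValueError("harmonization requires at least two traits")
    if ambiguity_policy not in ("drop", "keep"):
        raise ValueError(f"unknown ambiguity_policy {ambiguity_policy!r}")

    base = traits[0].df.set_index("snp")
    shared = base.index
    for t in traits[1:]:
        shared = shared.intersection(t.df["snp"])
    if len(shared) == 0:
        raise ValueError("empty SNP intersection across traits")

    frames = [t.df.set_index("snp").loc[shared] for t in traits]
    ref = frames[0]
    keep = np.ones(len(shared), dtype=bool)
    z_cols = [ref["z"].to_numpy(float)]
    p_cols = [ref["p"].to_numpy(float)]
    n_cols = [ref["n"].to_numpy(float)]
    dropped: dict[str, int] = {}

    a1_ref = ref["a1"].to_numpy(object)
    a2_ref = ref["a2"].to_numpy(object)

    if ambiguity_policy == "drop":
        amb = np.array([_is_ambiguous(x, y) for x, y in zip(a1_ref, a2_ref)])
        if amb.any():
            dropped["strand-ambiguous"] = int(amb.sum())
            keep &= ~amb

    for t, fr in zip(traits[1:], frames[1:]):
        pos_ok = (fr["pos"].to_numpy() == ref["pos"].to_numpy()) & (
            fr["chrom"].to_numpy(object) == ref["chrom"].to_numpy(object)
        )
        if (~pos_ok).any():
            dropped["position conflict"] = dropped.get("position conflict", 0) + int(
                (~pos_ok & keep).sum()
            )
            keep &= pos_ok

        a1 = fr["a1"].to_numpy(object)
        a2 = fr["a2"].to_numpy(object)
        comp1 = np.array([_COMPLEMENT.get(a, "?") for a in a1], dtype=object)
        comp2 = np.array([_COMPLEMENT.get(a, "?") for a in a2], dtype=object)
        direct = (a1 == a1_ref) & (a2 == a2_ref)
        swapped = (a1 == a2_ref) & (a2 == a1_ref) & ~direct
        flipped = (comp1 == a1_ref) & (comp2 == a2_ref) & ~direct & ~swapped
        flipswap = (comp1 == a2_ref) & (comp2 == a1_ref) & ~(direct | swapped | flipped)
        compatible = direct | swapped | flipped | flipswap
        if (~compatible & keep).any():
            n_bad = int((~compatible & keep).sum())
            dropped["allele mismatch"] = dropped.get("allele mismatch", 0) + n_bad
            log.info("trait %s: %d SNPs dropped, allele mismatch", t.trait, n_bad)
        keep &= compatible

        sign = np.where(swapped | flipswap, -1.0, 1.0)
        z_cols.append(fr["z"].to_numpy(float) * sign)
        p_cols.append(fr["p"].to_numpy(float))
        n_cols.append(fr["n"].to_numpy(float))

    snps = pd.DataFrame({
        "snp": np.asarray(shared, dtype=object)[keep],
        "chrom": ref["chrom"].to_numpy(object)[keep],
        "pos": ref["pos"].to_numpy()[keep],
        "a1": a1_ref[keep],
        "a2": a2_ref[keep],
    })
    z = np.column_stack([c[keep] for c in z_cols])
    p = np.column_stack([c[keep] for c in p_cols])
    n = np.column_stack([c[keep] for c in n_cols])

    order = np.lexsort((snps["pos"].to_numpy(), snps["chrom"].to_numpy(object)))
    panel = HarmonizedPanel(
        traits=[t.trait for t in traits],
        snps=snps.iloc[order].reset_index(drop=True),
        z=z[order], p=p[order], n=n[order],
    )
    log.info(
        "harmonized %d traits: %d shared SNPs kept (%s)",
        len(traits), len(panel),
        "; ".join(f"{k}: {v}" for k, v in dropped.items()) or "no drops",
    )
    return panel


def exclude_region(
    panel: HarmonizedPanel, regions: Sequence[GenomicRegion]
) -> HarmonizedPanel:
    """Remove every SNP falling inside any of ``regions`` (inclusive bounds)."""
    if not regions:
        return panel
    chrom = panel.snps["chrom"].to_numpy(object)
    pos = panel.snps["pos"].to_numpy()
    inside = np.zeros(len(panel), dtype=bool)
    for r in regions:
        inside |= (chrom == r.chrom) & (pos >= r.start) & (pos <= r.end)
    log.info("excluded %d SNPs inside %d region(s)", int(inside.sum()), len(regions))
    return panel.subset(~inside)
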