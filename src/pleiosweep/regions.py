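"""Genomic intervals: the shared coordinate convention and BED round-trip.

Every interval in this package is 1-based and inclusive on both ends, the
convention used by most GWAS locus tables.  BED files are 0-based,
half-open; the conversion happens only inside :func:`read_bed` and
:func:`write_bed`, never in analysis code.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so 'chr6' and '6' compare equal."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class GenomicRegion:
    """A labeled interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValueError(
                f"region start > end: {self.chrom}:{self.start}-{self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == self.chrom and self.start <= pos <= self.end

    def intersects(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: The extended MHC interval conventionally excluded from pleiotropy
#: analyses because its extreme LD distorts empirical-cdf estimators.
MHC_REGION = GenomicRegion("6", 25_119_106, 33_854_733, "MHC")

_REGION_RE = re.compile(
    r"^(?P<chrom>\w+):(?P<start>[\d,]+)\s*[-–—]\s*(?P<end>[\d,]+)$"
)


def parse_region(text: str, label: str = "") -> GenomicRegion:
    """Parse ``chr6:25,119,106-33,854,733`` (hyphen or en-dash, commas ok)."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region string: {text!r}")
    return GenomicRegion(
        m.group("chrom"),
        int(m.group("start").replace(",", "")),
        int(m.group("end").replace(",", "")),
        label,
    )


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read a BED file into 1-based inclusive regions."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            regions.append(GenomicRegion(chrom, start + 1, end, label))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.label if r.label else "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def merge_intervals(regions: Sequence[GenomicRegion], gap: int = 0) -> list[GenomicRegion]:
    """Merge intervals closer than ``gap`` bp (0 = merge only on overlap/abutment)."""
    out: list[GenomicRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if out and out[-1].chrom == r.chrom and r.start <= out[-1].end + gap + 1:
            prev = out[-1]
            out[-1] = GenomicRegion(
                prev.chrom, prev.start, max(prev.end, r.end), prev.label
            )
        else:
            out.append(r)
    return out
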