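"""Readers and writers for the on-disk formats the toolkit touches.

Everything is normalized at the boundary to a single internal convention:
0-based, half-open coordinates. SAM/BAM (1-based) and 4DN-style pairs text
(1-based) are converted on read and converted back on write, so downstream
modules never see a mixed convention.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import SeqIO

__all__ = [
    "GenomeLayout",
    "AlignmentRecord",
    "PairRecord",
    "FormatError",
    "BARCODE_SCHEMES",
    "read_alignments",
    "read_pairs",
    "write_pairs",
    "read_length_list",
    "read_histogram",
    "write_histogram",
    "write_report",
    "read_report",
]

HAPLOTAG_RE = re.compile(r"A\d+C\d+B\d+D\d+")
BARCODE_SCHEMES = ("bx_tag", "readname_suffix", "haplotag_acbd", "none")

#: chromosome placeholders meaning "unmapped end" in pairs text
_UNMAPPED_CHROMS = {"!", ".", "*"}


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


def _natural_key(name: str):
    """Sort chr2 before chr10: split digit runs and compare numerically."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", name)
    )


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered set of reference sequences; the order is the canonical rank
    used for pair canonicalization and contact-matrix bin numbering."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes.items()))

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        """Two-column chrom-sizes TSV (name, length)."""
        chroms = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 columns")
                chroms.append((parts[0], int(parts[1])))
        return cls(tuple(chroms))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def rank(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"chromosome {name!r} not in layout") from None

    def __len__(self) -> int:
        return len(self.chromosomes)


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned (or unaligned) read, 0-based half-open."""

    read_id: str
    chrom: str | None
    start: int
    end: int
    strand: str = "+"
    mapq: int = 0
    mate_chrom: str | None = None
    mate_start: int | None = None
    mate_strand: str | None = None
    duplicate: bool = False
    barcode: str | None = None

    def __post_init__(self):
        if self.chrom is not None and self.end <= self.start:
            raise ValueError("mapped record requires end > start")

    @property
    def mapped(self) -> bool:
        return self.chrom is not None


@dataclass(frozen=True)
class PairRecord:
    """One Hi-C read pair, canonicalized to upper-triangle order.

    ``pos1``/``pos2`` are the 0-based leftmost mapped positions of the two
    ends (the *i* and *j* whose separation ``|i - j|`` is the link-separation
    distance). ``mapq_min`` is the smaller of the two ends' mapping
    qualities.
    """

    chrom1: str | None
    pos1: int
    strand1: str
    chrom2: str | None
    pos2: int
    strand2: str
    duplicate: bool = False
    unmapped: bool = False
    mapq_min: int = 255

    @property
    def intra(self) -> bool:
        return self.chrom1 is not None and self.chrom1 == self.chrom2

    @property
    def distance(self) -> int | None:
        """Link-separation distance |i - j|; None for inter/unmapped pairs."""
        if not self.intra:
            return None
        return abs(self.pos2 - self.pos1)

    def canonical(self, layout: GenomeLayout | None = None) -> "PairRecord":
        """Return the pair in upper-triangle order: (chrom rank, pos) of end 1
        not after end 2. Rank comes from ``layout`` when given, else from
        natural name order."""
        if self.chrom1 is None or self.chrom2 is None:
            return self
        if layout is not None:
            key1 = (layout.rank(self.chrom1), self.pos1)
            key2 = (layout.rank(self.chrom2), self.pos2)
        else:
            key1 = (_natural_key(self.chrom1), self.pos1)
            key2 = (_natural_key(self.chrom2), self.pos2)
        if key1 <= key2:
            return self
        return replace(
            self,
            chrom1=self.chrom2, pos1=self.pos2, strand1=self.strand2,
            chrom2=self.chrom1, pos2=self.pos1, strand2=self.strand1,
        )


# ---------------------------------------------------------------------------
# barcode extraction

def _extract_barcode(aln: pysam.AlignedSegment, scheme: str) -> str | None:
    if scheme == "none":
        return None
    if scheme == "bx_tag":
        return aln.get_tag("BX") if aln.has_tag("BX") else None
    if scheme == "readname_suffix":
        name = aln.query_name or ""
        if "#" in name:
            return name.rsplit("#", 1)[1] or None
        return None
    if scheme == "haplotag_acbd":
        name = aln.query_name or ""
        m = HAPLOTAG_RE.search(name)
        if m:
            return m.group(0)
        if aln.has_tag("BX"):
            m = HAPLOTAG_RE.search(str(aln.get_tag("BX")))
            if m:
                return m.group(0)
        return None
    raise ValueError(f"unknown barcode scheme {scheme!r}; expected one of {BARCODE_SCHEMES}")


def read_alignments(path, barcode_scheme: str = "none") -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file in file order.

    Secondary and supplementary alignments are skipped so each sequenced
    fragment is counted once; 1-based SAM POS becomes a 0-based half-open
    [start, end) span.
    """
    if barcode_scheme not in BARCODE_SCHEMES:
        raise ValueError(f"unknown barcode scheme {barcode_scheme!r}; expected one of {BARCODE_SCHEMES}")
    try:
        fh = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot open alignment file: {exc}") from exc
    with fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped:
                chrom, start, end = None, 0, 0
            else:
                chrom = aln.reference_name
                start = aln.reference_start
                end = aln.reference_end if aln.reference_end is not None else start + (aln.query_length or 1)
            mate_mapped = aln.is_paired and not aln.is_unmapped and not aln.mate_is_unmapped and aln.next_reference_id >= 0
            yield AlignmentRecord(
                read_id=aln.query_name or "",
                chrom=chrom,
                start=start,
                end=end,
                strand="-" if aln.is_reverse else "+",
                mapq=aln.mapping_quality,
                mate_chrom=aln.next_reference_name if mate_mapped else None,
                mate_start=aln.next_reference_start if mate_mapped else None,
                mate_strand=("-" if aln.mate_is_reverse else "+") if mate_mapped else None,
                duplicate=aln.is_duplicate,
                barcode=_extract_barcode(aln, barcode_scheme),
            )


# ---------------------------------------------------------------------------
# pairs text (4DN-style)

def read_pairs(path, layout: GenomeLayout | None = None) -> Iterator[PairRecord]:
    """Stream PairRecords from a 4DN-style pairs text file.

    Columns: readID chr1 pos1 chr2 pos2 strand1 strand2 [pair_type], tab or
    whitespace delimited, ``#`` header lines skipped. Positions are 1-based
    in the file and converted to 0-based; records are canonicalized to
    upper-triangle order on read.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split()
            if len(cols) < 7:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 7 columns, got {len(cols)}"
                )
            _, c1, p1, c2, p2, s1, s2 = cols[:7]
            pair_type = cols[7] if len(cols) > 7 else "UU"
            un1 = c1 in _UNMAPPED_CHROMS
            un2 = c2 in _UNMAPPED_CHROMS
            unmapped = un1 or un2 or "N" in pair_type
            try:
                pos1 = int(p1) - 1 if not un1 else 0
                pos2 = int(p2) - 1 if not un2 else 0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position") from exc
            rec = PairRecord(
                chrom1=None if un1 else c1,
                pos1=pos1,
                strand1=s1,
                chrom2=None if un2 else c2,
                pos2=pos2,
                strand2=s2,
                duplicate=pair_type == "DD",
                unmapped=unmapped,
            )
            yield rec.canonical(layout)


def write_pairs(pairs: Iterable[PairRecord], path, layout: GenomeLayout | None = None) -> None:
    """Write pairs back to 4DN-style text (positions re-exported 1-based)."""
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chr1 pos1 chr2 pos2 strand1 strand2 pair_type\n")
        for i, p in enumerate(pairs):
            c1 = p.chrom1 if p.chrom1 is not None else "!"
            c2 = p.chrom2 if p.chrom2 is not None else "!"
            if p.unmapped:
                ptype = "NN"
            elif p.duplicate:
                ptype = "DD"
            else:
                ptype = "UU"
            fh.write(
                f"r{i}\t{c1}\t{p.pos1 + 1}\t{c2}\t{p.pos2 + 1}\t"
                f"{p.strand1}\t{p.strand2}\t{ptype}\n"
            )


# ---------------------------------------------------------------------------
# sequence-length lists

def read_length_list(path) -> list[int]:
    """Sequence lengths from a FASTA file or a one-integer-per-line text file.

    Order-preserving; empty FASTA records and non-positive integers are
    rejected.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        lengths = []
        for rec in SeqIO.parse(str(path), "fasta"):
            n = len(rec.seq)
            if n == 0:
                raise FormatError(f"{path}: empty sequence record {rec.id!r}")
            lengths.append(n)
        return lengths
    lengths = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                n = int(line.strip())
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: not an integer") from exc
            if n <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length {n}")
            lengths.append(n)
    return lengths


# ---------------------------------------------------------------------------
# histograms and reports

def write_histogram(hist: Mapping[int, int], path, header: tuple[str, str] = ("value", "count")) -> None:
    """Two-column TSV (value, count); counts must be non-negative."""
    for value, count in hist.items():
        if count < 0:
            raise ValueError(f"negative count {count} for value {value}")
    with open(path, "w") as fh:
        fh.write(f"#{header[0]}\t{header[1]}\n")
        for value in sorted(hist):
            fh.write(f"{value}\t{hist[value]}\n")


def read_histogram(path) -> dict[int, int]:
    hist: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            value, count = int(parts[0]), int(parts[1])
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            hist[value] = count
    return hist


def write_report(report, path) -> None:
    """Serialize a MetricsReport (or any mapping) to JSON, atomically."""
    data = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    try:
        with open(tmp, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        tmp.replace(path)
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_report(path) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read report from {path}: {exc}") from exc
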