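"""Linked-Read metrics: molecule reconstruction, length and read-density
N50s, clustered-read percentage, barcode collisions and accessibility.

Barcoded short reads are grouped back into the high-molecular-weight DNA
molecules they came from: reads sharing a barcode on one chromosome form a
molecule, split wherever the gap between consecutive reads exceeds
``max_gap``. A barcode attached to two or more reconstructed molecules is a
collision — its reads are spuriously "linked" across loci. Accessibility
for Linked Reads is A = 1 - D - U: there is no inter-chromosomal term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AlignmentRecord
from .hic_qc import InsufficientDataError, total_accessibility

__all__ = [
    "Molecule",
    "MoleculeSet",
    "LinkedMetrics",
    "reconstruct_molecules",
    "molecule_length_n50",
    "molecule_length_curve",
    "reads_per_molecule_n50",
    "clustered_read_percentage",
    "collision_rate",
    "mark_linked_duplicates",
    "linked_metrics",
]

DEFAULT_MAX_GAP = 50_000
DEFAULT_MIN_READS = 2


@dataclass(frozen=True)
class Molecule:
    """A reconstructed HMW-DNA fragment: the span covered by same-barcode
    reads on one chromosome."""

    barcode: str
    chrom: str
    start: int
    end: int
    n_reads: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("molecule span must be non-empty")
        if self.n_reads < 1:
            raise ValueError("molecule needs at least one read")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MoleculeSet:
    """Reconstruction output: molecules passing the ``min_reads`` filter
    plus the discarded ones, kept for collision and clustering bookkeeping."""

    retained: list[Molecule]
    discarded: list[Molecule]
    max_gap: int
    min_reads: int

    @property
    def all_molecules(self) -> list[Molecule]:
        return self.retained + self.discarded

    @property
    def n_reads_total(self) -> int:
        return sum(m.n_reads for m in self.all_molecules)

    @property
    def n_reads_retained(self) -> int:
        return sum(m.n_reads for m in self.retained)


def reconstruct_molecules(
    reads: Iterable[AlignmentRecord],
    max_gap: int = DEFAULT_MAX_GAP,
    min_reads: int = DEFAULT_MIN_READS,
) -> MoleculeSet:
    """Group mapped, non-duplicate, barcoded reads into molecules.

    Within each (barcode, chromosome) group, reads are sorted by start and
    split wherever the gap between consecutive read intervals exceeds
    ``max_gap``; a barcode seen on two chromosomes always yields separate
    molecules. Molecules with fewer than ``min_reads`` reads are moved to
    the discarded list (still counted for collisions and clustering).
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    groups: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for r in reads:
        if not r.mapped or r.duplicate or r.barcode is None:
            continue
        groups.setdefault((r.barcode, r.chrom), []).append(r)
    retained: list[Molecule] = []
    discarded: list[Molecule] = []
    for (barcode, chrom), members in groups.items():
        members.sort(key=lambda r: (r.start, r.end))
        run: list[AlignmentRecord] = []
        for r in members:
            if run and r.start - max(m.end for m in run) > max_gap:
                _emit(run, barcode, chrom, min_reads, retained, discarded)
                run = []
            run.append(r)
        if run:
            _emit(run, barcode, chrom, min_reads, retained, discarded)
    return MoleculeSet(retained, discarded, max_gap=max_gap, min_reads=min_reads)


def _emit(run, barcode, chrom, min_reads, retained, discarded):
    mol = Molecule(
        barcode=barcode,
        chrom=chrom,
        start=min(r.start for r in run),
        end=max(r.end for r in run),
        n_reads=len(run),
    )
    (retained if mol.n_reads >= min_reads else discarded).append(mol)


def _weighted_n50(values: Sequence[int], x: float = 50.0) -> int:
    """Smallest value v such that entries >= v account for >= x% of the
    total; the same rule as assembly Nx, applied to any size multiset."""
    vals = sorted(values, reverse=True)
    target = sum(vals) * x / 100.0
    acc = 0
    for v in vals:
        acc += v
        if acc >= target:
            return v
    return vals[-1]


def molecule_length_n50(molecules: Sequence[Molecule] | MoleculeSet) -> int:
    """Length-weighted molecule N50 over retained molecules."""
    mols = molecules.retained if isinstance(molecules, MoleculeSet) else list(molecules)
    if not mols:
        raise InsufficientDataError("no molecules")
    return _weighted_n50([m.length for m in mols])


def molecule_length_curve(molecules: Sequence[Molecule] | MoleculeSet) -> np.ndarray:
    """Cumulative length-weighted fraction by molecule length, descending.

    Returns an (n, 2) array of (length, cumulative_fraction) rows: the
    fraction of total molecule length contained in molecules at least that
    long — the accumulated-percentage view of the length distribution.
    """
    mols = molecules.retained if isinstance(molecules, MoleculeSet) else list(molecules)
    if not mols:
        raise InsufficientDataError("no molecules")
    lengths = np.sort(np.array([m.length for m in mols]))[::-1]
    cum = np.cumsum(lengths) / lengths.sum()
    return np.column_stack([lengths, cum])


def reads_per_molecule_n50(
    molecules: Sequence[Molecule] | MoleculeSet, min_reads: int = 5
) -> int | None:
    """N50 of per-molecule read counts over molecules with >= min_reads
    reads (the read-density indicator); None when nothing qualifies."""
    mols = molecules.retained if isinstance(molecules, MoleculeSet) else list(molecules)
    counts = [m.n_reads for m in mols if m.n_reads >= min_reads]
    if not counts:
        warnings.warn(f"no molecules with >= {min_reads} reads", stacklevel=2)
        return None
    return _weighted_n50(counts)


def clustered_read_percentage(molecule_set: MoleculeSet) -> float:
    """Percentage of usable barcoded reads that ended up in retained
    molecules: 100 × retained reads / (mapped, non-duplicate, barcoded
    reads). The denominator is exactly the reads that entered
    reconstruction, so retained + discarded reads partition it."""
    total = molecule_set.n_reads_total
    if total == 0:
        raise InsufficientDataError("no barcoded mapped reads; percentage undefined")
    return 100.0 * molecule_set.n_reads_retained / total


def collision_rate(molecule_set: MoleculeSet) -> float:
    """Fraction of barcodes attached to two or more distinct molecules
    (retained or discarded)."""
    per_barcode: dict[str, int] = {}
    for m in molecule_set.all_molecules:
        per_barcode[m.barcode] = per_barcode.get(m.barcode, 0) + 1
    if not per_barcode:
        raise InsufficientDataError("no barcodes observed")
    n_collided = sum(1 for n in per_barcode.values() if n >= 2)
    return n_collided / len(per_barcode)


def mark_linked_duplicates(reads: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Flag duplicate barcoded reads keyed on (barcode, chrom, start,
    strand) — barcoded libraries deduplicate per tagged fragment, not per
    pair. First occurrence kept; unmapped reads never flagged."""
    from dataclasses import replace

    seen: set[tuple] = set()
    out = []
    for r in reads:
        if not r.mapped:
            out.append(r)
            continue
        key = (r.barcode, r.chrom, r.start, r.strand)
        if key in seen:
            out.append(replace(r, duplicate=True))
        else:
            seen.add(key)
            out.append(r)
    return out


@dataclass
class LinkedMetrics:
    """Dataset-level Linked-Read summary.

    Rates share the single total-reads denominator so that
    A = 1 - D - U holds exactly.
    """

    n_reads: int
    n_read_pairs: int
    unmapped_rate: float
    duplication_rate: float
    total_accessibility: float
    molecule_n50: int | None
    reads_per_molecule_n50_ge3: int | None
    reads_per_molecule_n50_ge5: int | None
    clustered_read_pct: float | None
    collision_rate: float | None
    max_gap: int = DEFAULT_MAX_GAP
    min_reads: int = DEFAULT_MIN_READS


def linked_metrics(
    reads: Sequence[AlignmentRecord],
    max_gap: int = DEFAULT_MAX_GAP,
    min_reads: int = DEFAULT_MIN_READS,
    dedup: bool = True,
) -> LinkedMetrics:
    """Compute the full Linked-Read metrics bundle from a read stream."""
    reads = list(reads)
    if not reads:
        raise InsufficientDataError("no reads")
    if dedup:
        reads = mark_linked_duplicates(reads)
    n = len(reads)
    n_unmapped = sum(1 for r in reads if not r.mapped)
    n_dup = sum(1 for r in reads if r.mapped and r.duplicate)
    u = n_unmapped / n
    d = n_dup / n
    mols = reconstruct_molecules(reads, max_gap=max_gap, min_reads=min_reads)
    have_mols = bool(mols.all_molecules)
    return LinkedMetrics(
        n_reads=n,
        n_read_pairs=n // 2,
        unmapped_rate=u,
        duplication_rate=d,
        total_accessibility=total_accessibility(d, 0.0, u),
        molecule_n50=molecule_length_n50(mols) if mols.retained else None,
        reads_per_molecule_n50_ge3=reads_per_molecule_n50(mols, 3) if have_mols else None,
        reads_per_molecule_n50_ge5=reads_per_molecule_n50(mols, 5) if have_mols else None,
        clustered_read_pct=clustered_read_percentage(mols) if have_mols else None,
        collision_rate=collision_rate(mols) if have_mols else None,
        max_gap=max_gap,
        min_reads=min_reads,
    )
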