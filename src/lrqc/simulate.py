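"""Truth-tagged simulators for Hi-C pairs, barcoded Linked Reads and
coverage tracks.

Each generator embodies the statistical structure its metric assumes — a
truncated power-law for link-separation distances, barcodes drawing one or
more molecules (collisions), Poisson or Gamma-mixed-Poisson depth — and
writes a truth sidecar with every configured parameter, so downstream
metrics can be validated by parameter recovery. All randomness flows from
one integer seed; reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .io_formats import AlignmentRecord, GenomeLayout, PairRecord, write_pairs

__all__ = [
    "SimTruth",
    "simulate_hic",
    "simulate_linked",
    "simulate_coverage",
    "sample_truncated_power_law",
    "write_linked_sam",
    "write_depth_tsv",
]


@dataclass
class SimTruth:
    """Configured parameters of a simulation run, serialized beside every
    output so recovery tests can compare estimate against truth."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "params": self.params,
            "derived": self.derived,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def sample_truncated_power_law(
    rng: np.random.Generator, n: int, b: float, d_min: float, d_max: float
) -> np.ndarray:
    """Draw n separations from density ∝ d^-b truncated to [d_min, d_max]
    by inverse-CDF (closed form; exact, no rejection)."""
    if d_min <= 0 or d_max <= d_min:
        raise ValueError("need 0 < d_min < d_max")
    u = rng.random(n)
    if abs(b - 1.0) < 1e-12:
        return d_min * (d_max / d_min) ** u
    a = 1.0 - b
    return (d_min**a + u * (d_max**a - d_min**a)) ** (1.0 / a)


def _choose_chroms(rng: np.random.Generator, layout: GenomeLayout, n: int) -> np.ndarray:
    lengths = np.array([length for _, length in layout.chromosomes], dtype=float)
    return rng.choice(len(lengths), size=n, p=lengths / lengths.sum())


def simulate_hic(
    layout: GenomeLayout,
    n_pairs: int,
    b: float = 1.2,
    ici_frac: float = 0.0,
    dup_frac: float = 0.0,
    unmapped_frac: float = 0.0,
    d_min: float = 1e4,
    d_max: float = 1e7,
    seed: int = 0,
    out_prefix: str | Path | None = None,
) -> tuple[list[PairRecord], SimTruth]:
    """Generate a Hi-C pair set with known class fractions and exponent.

    Each pair is unmapped, a duplicate (a re-emitted copy of an existing
    mapped pair), inter-chromosomal (two chromosomes length-weighted,
    positions uniform) or intra-chromosomal with separation drawn from the
    truncated power law d^-b on [d_min, d_max].
    """
    if ici_frac + dup_frac + unmapped_frac > 1.0:
        raise ValueError("class fractions must sum to <= 1")
    names = layout.names
    lengths = layout.lengths
    if d_max > min(lengths.values()):
        raise ValueError(
            f"d_max={d_max:g} exceeds the shortest chromosome "
            f"({min(lengths.values())}); infeasible geometry"
        )
    rng = np.random.default_rng(seed)
    n_un, n_dup, n_inter = rng.multinomial(
        n_pairs, [unmapped_frac, dup_frac, ici_frac, 0.0]
    )[:3]
    n_intra = n_pairs - n_un - n_dup - n_inter
    pairs: list[PairRecord] = []

    strands = "+-"
    # intra: power-law separations
    chrom_idx = _choose_chroms(rng, layout, n_intra)
    dists = np.floor(sample_truncated_power_law(rng, n_intra, b, d_min, d_max)).astype(np.int64)
    len_arr = np.array([lengths[names[i]] for i in chrom_idx], dtype=np.int64)
    starts = np.floor(rng.random(n_intra) * (len_arr - dists)).astype(np.int64)
    s1 = rng.integers(0, 2, size=n_intra)
    s2 = rng.integers(0, 2, size=n_intra)
    for ci, d, lo, a, c in zip(chrom_idx, dists, starts, s1, s2):
        name = names[ci]
        pairs.append(
            PairRecord(name, int(lo), strands[a], name, int(lo) + int(d), strands[c], mapq_min=60)
        )

    # inter: two distinct chromosomes (requires >= 2 in the layout)
    if n_inter and len(names) < 2:
        raise ValueError("ici_frac > 0 requires at least two chromosomes")
    for _ in range(n_inter):
        i, j = rng.choice(len(names), size=2, replace=False)
        p = PairRecord(
            names[i], int(rng.integers(0, lengths[names[i]])), strands[rng.integers(0, 2)],
            names[j], int(rng.integers(0, lengths[names[j]])), strands[rng.integers(0, 2)],
            mapq_min=60,
        )
        pairs.append(p.canonical(layout))

    # duplicates: re-emit existing mapped pairs
    if n_dup:
        if not pairs:
            raise ValueError("dup_frac > 0 requires some mapped pairs")
        src = rng.integers(0, len(pairs), size=n_dup)
        pairs.extend(pairs[i] for i in src)

    pairs.extend(
        PairRecord(None, 0, "+", None, 0, "+", unmapped=True, mapq_min=0)
        for _ in range(n_un)
    )
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]

    truth = SimTruth(
        kind="hic",
        seed=seed,
        params={
            "n_pairs": n_pairs,
            "b": b,
            "ici_frac": ici_frac,
            "dup_frac": dup_frac,
            "unmapped_frac": unmapped_frac,
            "d_min": d_min,
            "d_max": d_max,
        },
        derived={
            "n_unmapped": int(n_un),
            "n_duplicate": int(n_dup),
            "n_inter": int(n_inter),
            "n_intra": int(n_intra),
        },
    )
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        write_pairs(pairs, out_prefix.with_suffix(".pairs"), layout)
        truth.write(out_prefix.with_suffix(".truth.json"))
    return pairs, truth


def simulate_linked(
    layout: GenomeLayout,
    n_barcodes: int,
    molecules_per_barcode: int | Sequence[float] = 1,
    length_mean: float = 50_000.0,
    reads_per_kb: float = 0.8,
    dup_frac: float = 0.0,
    unmapped_frac: float = 0.0,
    read_length: int = 150,
    insert_size: int = 350,
    seed: int = 0,
    out_prefix: str | Path | None = None,
    max_retries: int = 100,
) -> tuple[list[AlignmentRecord], SimTruth]:
    """Generate a barcoded Linked-Read set with known molecule structure.

    Each barcode draws a molecule count — a fixed integer, or an index
    sampled from a probability vector over counts 1, 2, ... (so
    ``(0.99, 0.01)`` gives a 1 % collision rate). Molecule lengths are
    exponential with the given mean (floored at one insert), placed
    uniformly on length-weighted chromosomes; read pairs fall uniformly
    within each molecule at ``reads_per_kb`` expected reads per kilobase.
    Duplicate reads are re-emitted copies; unmapped reads carry a barcode
    but no coordinates. The truth sidecar lists every placed molecule.
    """
    if reads_per_kb <= 0:
        raise ValueError("reads_per_kb must be positive")
    rng = np.random.default_rng(seed)
    names = layout.names
    lengths = layout.lengths

    if isinstance(molecules_per_barcode, int):
        mol_counts = np.full(n_barcodes, molecules_per_barcode, dtype=np.int64)
    else:
        probs = np.asarray(molecules_per_barcode, dtype=float)
        if probs.sum() <= 0:
            raise ValueError("molecules-per-barcode law must have positive mass")
        probs = probs / probs.sum()
        mol_counts = rng.choice(len(probs), size=n_barcodes, p=probs) + 1

    min_len = max(insert_size, 1)
    truth_molecules: list[dict] = []
    reads: list[AlignmentRecord] = []
    rid = 0
    for bi, n_mols in enumerate(mol_counts):
        barcode = f"BC{bi:07d}"
        for _ in range(int(n_mols)):
            for attempt in range(max_retries):
                length = int(max(rng.exponential(length_mean), min_len))
                ci = int(_choose_chroms(rng, layout, 1)[0])
                if length < lengths[names[ci]]:
                    break
            else:
                raise RuntimeError(
                    f"could not place a molecule of ~{length_mean:g} bp after "
                    f"{max_retries} retries; chromosomes too short"
                )
            chrom = names[ci]
            start = int(rng.integers(0, lengths[chrom] - length))
            n_frags = int(rng.poisson(length * reads_per_kb / 1000.0 / 2.0))
            truth_molecules.append(
                {"barcode": barcode, "chrom": chrom, "start": start,
                 "end": start + length, "n_reads": 2 * n_frags}
            )
            span = length - insert_size
            for _ in range(n_frags):
                fs = start + int(rng.integers(0, max(span, 1)))
                reads.append(AlignmentRecord(
                    read_id=f"sim{rid}", chrom=chrom, start=fs,
                    end=fs + read_length, strand="+", mapq=60, barcode=barcode,
                ))
                reads.append(AlignmentRecord(
                    read_id=f"sim{rid}", chrom=chrom,
                    start=fs + insert_size - read_length, end=fs + insert_size,
                    strand="-", mapq=60, barcode=barcode,
                ))
                rid += 1

    n_base = len(reads)
    if n_base == 0:
        raise RuntimeError("simulation produced no reads; raise reads_per_kb or length_mean")
    if dup_frac + unmapped_frac >= 1.0:
        raise ValueError("dup_frac + unmapped_frac must be < 1")
    # both fractions are over the final total read count
    n_total = n_base / (1.0 - dup_frac - unmapped_frac)
    if dup_frac > 0:
        n_dup = int(round(n_total * dup_frac))
        src = rng.integers(0, n_base, size=n_dup)
        reads.extend(reads[i] for i in src)
    if unmapped_frac > 0:
        n_un = int(round(n_total * unmapped_frac))
        reads.extend(
            AlignmentRecord(
                read_id=f"un{k}", chrom=None, start=0, end=0, strand="+",
                mapq=0, barcode=f"BC{int(rng.integers(0, n_barcodes)):07d}",
            )
            for k in range(n_un)
        )
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    per_barcode: dict[str, int] = {}
    for m in truth_molecules:
        per_barcode[m["barcode"]] = per_barcode.get(m["barcode"], 0) + 1
    true_collision = (
        sum(1 for v in per_barcode.values() if v >= 2) / len(per_barcode)
        if per_barcode else 0.0
    )
    truth = SimTruth(
        kind="linked",
        seed=seed,
        params={
            "n_barcodes": n_barcodes,
            "molecules_per_barcode": (
                molecules_per_barcode if isinstance(molecules_per_barcode, int)
                else list(molecules_per_barcode)
            ),
            "length_mean": length_mean,
            "reads_per_kb": reads_per_kb,
            "dup_frac": dup_frac,
            "unmapped_frac": unmapped_frac,
            "read_length": read_length,
            "insert_size": insert_size,
        },
        derived={
            "n_molecules": len(truth_molecules),
            "n_reads": len(reads),
            "true_collision_rate": true_collision,
            "molecules": truth_molecules,
        },
    )
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        write_linked_sam(reads, layout, out_prefix.with_suffix(".sam"))
        truth.write(out_prefix.with_suffix(".truth.json"))
    return reads, truth


def simulate_coverage(
    n_sites: int,
    mean: float = 30.0,
    dispersion: float | None = None,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Generate a per-site depth track.

    Poisson mode (``dispersion=None``): depth ~ Poisson(mean) — the even,
    uniform-rate ideal. Gamma–Poisson mode: each site's rate is drawn from
    Gamma(shape=dispersion, mean=mean) and the depth from Poisson(rate),
    giving a negative-binomial track whose unevenness converges to
    mean/dispersion.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if dispersion is not None and dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    if dispersion is None:
        depths = rng.poisson(mean, size=n_sites)
    else:
        rates = rng.gamma(shape=dispersion, scale=mean / dispersion, size=n_sites)
        depths = rng.poisson(rates)
    truth = SimTruth(
        kind="coverage",
        seed=seed,
        params={"n_sites": n_sites, "mean": mean, "dispersion": dispersion},
        derived={"expected_unevenness": 0.0 if dispersion is None else mean / dispersion},
    )
    if out_path is not None:
        out_path = Path(out_path)
        write_depth_tsv(depths, out_path)
        truth.write(out_path.with_suffix(".truth.json"))
    return depths, truth


def write_linked_sam(reads: Sequence[AlignmentRecord], layout: GenomeLayout, path) -> None:
    """Write AlignmentRecords as a plain-text SAM with BX barcode tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in layout.chromosomes],
    }
    ranks = {name: i for i, (name, _) in enumerate(layout.chromosomes)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            if r.mapped:
                a.reference_id = ranks[r.chrom]
                a.reference_start = r.start
                a.mapping_quality = r.mapq
                a.cigarstring = f"{r.end - r.start}M"
                a.flag = 16 if r.strand == "-" else 0
            else:
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
            seq_len = (r.end - r.start) if r.mapped else 150
            a.query_sequence = "N" * seq_len
            a.query_qualities = pysam.qualitystring_to_array("I" * seq_len)
            if r.barcode is not None:
                a.set_tag("BX", r.barcode)
            fh.write(a)


def write_depth_tsv(depths: np.ndarray, path, chrom: str = "sim") -> None:
    """Per-base depth TSV: chrom, pos (0-based), depth."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tdepth\n")
        for i, d in enumerate(depths):
            fh.write(f"{chrom}\t{i}\t{int(d)}\n")
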