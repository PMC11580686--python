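"""Hi-C association and accessibility metrics.

A Hi-C library is informative when (a) the frequency of intra-chromosomal
contacts decays as a power law of the genomic separation between the two
ends of a pair — long-range structure survives in the long tail — and
(b) most pairs are usable: mapped, non-duplicate and intra-chromosomal.
This module classifies pairs, bins the link-separation distances, fits the
power-law tail on a log–log scale, computes inter-chromosomal interaction
(ICI) rates with the 30 % pass/fail rule, and combines the unmapped (U),
PCR-duplication (D) and ICI (C) rates into a total accessibility
A = 1 - D - C - U. A binned contact matrix can be exported for plotting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse

from .io_formats import GenomeLayout, PairRecord

__all__ = [
    "PairClass",
    "LsdHistogram",
    "PowerLawFit",
    "IciResult",
    "HicMetrics",
    "classify_pair",
    "mark_duplicates",
    "lsd_histogram",
    "fit_power_law",
    "ici_rates",
    "total_accessibility",
    "hic_metrics",
    "contact_matrix",
    "write_contact_matrix",
]

DEFAULT_MAPQ_MIN = 10
DEFAULT_ICI_THRESHOLD = 0.30
MIN_FIT_BINS = 10


class PairClass(enum.Enum):
    """Mutually exclusive pair classes, in precedence order."""

    UNMAPPED = "unmapped"
    DUPLICATE = "duplicate"
    INTER = "inter"
    INTRA = "intra"


class InsufficientDataError(ValueError):
    """Not enough usable observations for the requested statistic."""


def classify_pair(pair: PairRecord, mapq_min: int = DEFAULT_MAPQ_MIN) -> PairClass:
    """Classify one pair with precedence unmapped > duplicate > inter > intra.

    A pair counts as unmapped when either end is unmapped or when the
    smaller of its two mapping qualities falls below ``mapq_min``.
    """
    if pair.unmapped or pair.chrom1 is None or pair.chrom2 is None or pair.mapq_min < mapq_min:
        return PairClass.UNMAPPED
    if pair.duplicate:
        return PairClass.DUPLICATE
    if pair.chrom1 != pair.chrom2:
        return PairClass.INTER
    return PairClass.INTRA


def mark_duplicates(pairs: Iterable[PairRecord]) -> list[PairRecord]:
    """Flag positional duplicates: pairs sharing both ends' (chrom, pos,
    strand) exactly. The first occurrence is kept unflagged; later copies
    are flagged. Idempotent, and order-insensitive after canonicalization.
    Unmapped pairs carry no usable coordinates and are never flagged.
    """
    seen: set[tuple] = set()
    out = []
    for p in pairs:
        if p.unmapped or p.chrom1 is None or p.chrom2 is None:
            out.append(p)
            continue
        key = (p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2)
        if key in seen:
            out.append(replace(p, duplicate=True))
        else:
            seen.add(key)
            out.append(p)
    return out


@dataclass
class LsdHistogram:
    """Link-separation distances binned at fixed width (default 100 bp).

    ``counts`` maps bin index -> count, where bin index is
    floor(distance / bin_width). The percentage view mirrors how these
    distributions are usually plotted: each non-empty bin as a percentage
    of all contributing pairs.
    """

    bin_width: int = 100
    counts: dict[int, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def add(self, distance: int) -> None:
        if distance < 0:
            raise ValueError("distance must be >= 0")
        idx = distance // self.bin_width
        self.counts[idx] = self.counts.get(idx, 0) + 1

    def percentages(self) -> dict[int, float]:
        """Bin index -> percentage of contributing pairs; sums to 100."""
        total = self.total
        if total == 0:
            raise InsufficientDataError("empty histogram")
        return {idx: 100.0 * c / total for idx, c in self.counts.items() if c > 0}

    def bin_center(self, idx: int) -> float:
        return (idx + 0.5) * self.bin_width


def lsd_histogram(
    pairs: Iterable[PairRecord],
    bin_width: int = 100,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> LsdHistogram:
    """Histogram of |i - j| over intra-chromosomal pairs only."""
    hist = LsdHistogram(bin_width=bin_width)
    for p in pairs:
        if classify_pair(p, mapq_min) is PairClass.INTRA:
            hist.add(abs(p.pos2 - p.pos1))
    if hist.total == 0:
        raise InsufficientDataError("no intra-chromosomal pairs to bin")
    return hist


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of log10 frequency against log10 distance.

    ``exponent`` is b in f(d) ∝ d^-b (the negated slope); ``r_squared``
    measures how well the tail follows a straight line on the log–log
    scale — a low value flags deviation from power-law structure.
    """

    exponent: float
    d_min: float
    d_max: float
    r_squared: float
    n_bins: int
    intercept: float = 0.0

    def ok(self, min_r_squared: float = 0.8) -> bool:
        return self.r_squared >= min_r_squared


def _log_rebin(
    hist: LsdHistogram,
    d_min: float,
    d_max: float,
    bins_per_decade: int,
    exclusion_window: tuple[float, float] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate fixed-width bins into log-spaced bins.

    For each log bin the representative frequency is the mean count per
    raw bin (preserving the per-100-bp frequency scale) and the abscissa
    is the geometric mean of the raw-bin centers it covers.
    """
    idx = np.array(sorted(hist.counts), dtype=float)
    centers = (idx + 0.5) * hist.bin_width
    counts = np.array([hist.counts[int(i)] for i in idx], dtype=float)
    keep = (centers >= d_min) & (centers <= d_max)
    if exclusion_window is not None:
        lo, hi = exclusion_window
        keep &= ~((centers >= lo) & (centers <= hi))
    centers, counts = centers[keep], counts[keep]
    if centers.size == 0:
        return np.array([]), np.array([])
    n_edges = int(math.ceil(bins_per_decade * math.log10(d_max / d_min))) + 1
    edges = np.logspace(math.log10(d_min), math.log10(d_max), max(n_edges, 2))
    which = np.clip(np.searchsorted(edges, centers, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for j in np.unique(which):
        sel = which == j
        # raw bins inside this log bin, occupied or not
        lo_idx = math.floor(edges[j] / hist.bin_width)
        hi_idx = math.floor(edges[j + 1] / hist.bin_width)
        n_raw = max(hi_idx - lo_idx, 1)
        total = counts[sel].sum()
        if total <= 0:
            continue
        xs.append(float(np.exp(np.log(centers[sel]).mean())))
        ys.append(total / n_raw)
    return np.array(xs), np.array(ys)


def fit_power_law(
    hist: LsdHistogram,
    d_min: float = 1e4,
    d_max: float = 1e7,
    bins_per_decade: int = 32,
    exclusion_window: tuple[float, float] | None = None,
) -> PowerLawFit:
    """Fit the power-law tail of a link-separation histogram.

    The raw 100-bp bins are re-binned onto ``bins_per_decade`` log-spaced
    bins to stabilize the sparse far tail, then a straight line is fitted
    through (log10 distance, log10 frequency) by least squares. The
    exponent b is the negated slope. ``exclusion_window`` optionally masks
    a (lo, hi) distance range containing a known alignment artefact peak.

    Raises :class:`InsufficientDataError` with fewer than 10 usable bins.
    """
    xs, ys = _log_rebin(hist, d_min, d_max, bins_per_decade, exclusion_window)
    if xs.size < MIN_FIT_BINS:
        raise InsufficientDataError(
            f"power-law fit needs >= {MIN_FIT_BINS} non-empty bins in "
            f"[{d_min:g}, {d_max:g}], got {xs.size}"
        )
    lx, ly = np.log10(xs), np.log10(ys)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PowerLawFit(
        exponent=float(-slope),
        d_min=d_min,
        d_max=d_max,
        r_squared=r2,
        n_bins=int(xs.size),
        intercept=float(intercept),
    )


@dataclass(frozen=True)
class IciResult:
    """Inter-chromosomal interaction rate with the pass/fail QC rule.

    ``rate`` is inter / (inter + intra) over mapped, non-duplicate pairs;
    a dataset fails QC only when the rate strictly exceeds the threshold
    (default 30 %).
    """

    rate: float
    per_chromosome: pd.DataFrame
    qc_pass: bool
    threshold: float = DEFAULT_ICI_THRESHOLD


def ici_rates(
    pairs: Iterable[PairRecord],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    threshold: float = DEFAULT_ICI_THRESHOLD,
) -> IciResult:
    """ICI rate over mapped non-duplicate pairs, overall and per chromosome.

    The per-chromosome rate for chromosome c is the fraction of usable
    pairs touching c that are inter-chromosomal.
    """
    inter = intra = 0
    touch_inter: dict[str, int] = {}
    touch_all: dict[str, int] = {}
    for p in pairs:
        cls = classify_pair(p, mapq_min)
        if cls is PairClass.INTER:
            inter += 1
            for c in {p.chrom1, p.chrom2}:
                touch_inter[c] = touch_inter.get(c, 0) + 1
                touch_all[c] = touch_all.get(c, 0) + 1
        elif cls is PairClass.INTRA:
            intra += 1
            touch_all[p.chrom1] = touch_all.get(p.chrom1, 0) + 1
    usable = inter + intra
    if usable == 0:
        raise InsufficientDataError("no mapped non-duplicate pairs; ICI rate undefined")
    rate = inter / usable
    table = pd.DataFrame(
        {
            "chromosome": sorted(touch_all),
            "n_pairs": [touch_all[c] for c in sorted(touch_all)],
            "n_inter": [touch_inter.get(c, 0) for c in sorted(touch_all)],
        }
    )
    table["ici_rate"] = table["n_inter"] / table["n_pairs"]
    return IciResult(
        rate=rate,
        per_chromosome=table,
        qc_pass=rate <= threshold,
        threshold=threshold,
    )


def total_accessibility(dup_rate: float, ici_rate: float, unmapped_rate: float) -> float:
    """Total accessibility A = 1 - D - C - U.

    All three rates must be fractions in [0, 1]; pass C = 0 for Linked
    Reads, which have no inter-chromosomal term.
    """
    for name, value in (("D", dup_rate), ("C", ici_rate), ("U", unmapped_rate)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"rate {name}={value} outside [0, 1]")
    return 1.0 - dup_rate - ici_rate - unmapped_rate


@dataclass
class HicMetrics:
    """Dataset-level Hi-C accessibility and association summary.

    The four class counts partition the pairs, and the four rates — all
    over the same total-pairs denominator — satisfy A + D + C + U = 1
    exactly. ``ici`` additionally carries the conditional rate
    inter / (inter + intra) used by the 30 % QC rule.
    """

    n_pairs: int
    n_unmapped: int
    n_duplicate: int
    n_inter: int
    n_intra: int
    unmapped_rate: float
    duplication_rate: float
    ici_rate: float
    total_accessibility: float
    ici: IciResult | None = None
    association: PowerLawFit | None = None
    mapq_min: int = DEFAULT_MAPQ_MIN

    @property
    def qc_ici_pass(self) -> bool | None:
        return None if self.ici is None else self.ici.qc_pass

    @property
    def qc_powerlaw_ok(self) -> bool | None:
        return None if self.association is None else self.association.ok()


def hic_metrics(
    pairs: Sequence[PairRecord],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    ici_threshold: float = DEFAULT_ICI_THRESHOLD,
    bin_width: int = 100,
    fit_d_min: float = 1e4,
    fit_d_max: float = 1e7,
    dedup: bool = True,
) -> HicMetrics:
    """Compute the full Hi-C metrics bundle from a pair stream.

    Pairs are duplicate-marked first (unless ``dedup`` is False, e.g. for
    pre-deduplicated input), classified, and summarized. The power-law
    fit is attempted and left as None when the tail is too sparse.
    """
    pairs = list(pairs)
    if dedup:
        pairs = mark_duplicates(pairs)
    if not pairs:
        raise InsufficientDataError("no pairs")
    n = len(pairs)
    counts = {cls: 0 for cls in PairClass}
    for p in pairs:
        counts[classify_pair(p, mapq_min)] += 1
    u = counts[PairClass.UNMAPPED] / n
    d = counts[PairClass.DUPLICATE] / n
    c = counts[PairClass.INTER] / n
    try:
        ici = ici_rates(pairs, mapq_min, ici_threshold)
    except InsufficientDataError:
        ici = None
    try:
        fit = fit_power_law(
            lsd_histogram(pairs, bin_width, mapq_min), fit_d_min, fit_d_max
        )
    except InsufficientDataError:
        fit = None
    return HicMetrics(
        n_pairs=n,
        n_unmapped=counts[PairClass.UNMAPPED],
        n_duplicate=counts[PairClass.DUPLICATE],
        n_inter=counts[PairClass.INTER],
        n_intra=counts[PairClass.INTRA],
        unmapped_rate=u,
        duplication_rate=d,
        ici_rate=c,
        total_accessibility=total_accessibility(d, c, u),
        ici=ici,
        association=fit,
        mapq_min=mapq_min,
    )


def contact_matrix(
    pairs: Iterable[PairRecord],
    layout: GenomeLayout,
    bin_size: int,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> tuple[scipy.sparse.coo_matrix, pd.DataFrame]:
    """Genome-wide binned contact matrix from mapped non-duplicate pairs.

    Returns an upper-triangle sparse COO matrix over global bins plus the
    bin table (chromosome, start, end, global id). The sum of all entries
    equals the number of contributing pairs.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    offsets: dict[str, int] = {}
    rows = []
    total_bins = 0
    for name, length in layout.chromosomes:
        offsets[name] = total_bins
        n_bins = math.ceil(length / bin_size)
        for k in range(n_bins):
            rows.append(
                (name, k * bin_size, min((k + 1) * bin_size, length), total_bins + k)
            )
        total_bins += n_bins
    bins = pd.DataFrame(rows, columns=["chromosome", "start", "end", "bin_id"])
    counts: dict[tuple[int, int], int] = {}
    for p in pairs:
        cls = classify_pair(p, mapq_min)
        if cls not in (PairClass.INTER, PairClass.INTRA):
            continue
        for chrom in (p.chrom1, p.chrom2):
            if chrom not in offsets:
                raise ValueError(f"pair references chromosome {chrom!r} absent from layout")
        b1 = offsets[p.chrom1] + p.pos1 // bin_size
        b2 = offsets[p.chrom2] + p.pos2 // bin_size
        if b1 > b2:
            b1, b2 = b2, b1
        counts[(b1, b2)] = counts.get((b1, b2), 0) + 1
    if counts:
        ij = np.array(list(counts), dtype=np.int64)
        data = np.array([counts[tuple(k)] for k in ij], dtype=np.int64)
        mat = scipy.sparse.coo_matrix(
            (data, (ij[:, 0], ij[:, 1])), shape=(total_bins, total_bins)
        )
    else:
        mat = scipy.sparse.coo_matrix((total_bins, total_bins), dtype=np.int64)
    return mat, bins


def write_contact_matrix(mat: scipy.sparse.coo_matrix, bins: pd.DataFrame, path, bins_path=None) -> None:
    """Export a contact matrix as COO TSV (bin1_id, bin2_id, count) with an
    optional sidecar bin table."""
    with open(path, "w") as fh:
        fh.write("#bin1_id\tbin2_id\tcount\n")
        order = np.lexsort((mat.col, mat.row))
        for i in order:
            fh.write(f"{mat.row[i]}\t{mat.col[i]}\t{mat.data[i]}\n")
    if bins_path is not None:
        bins.to_csv(bins_path, sep="\t", index=False)
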