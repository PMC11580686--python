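"""Coverage evenness: depth histograms, the unevenness statistic, and
seeded downsampling.

Uniform sampling of a genome gives Poisson-distributed per-base depth, so
the variance of the non-zero depth distribution should match its mean.
Real libraries are overdispersed — the sampling rate varies along the
genome — and the unevenness statistic

    U = (Var(coverage) - mean(coverage)) / mean(coverage)

measures that excess: U = 0 for a perfect Poisson, and grows with the
heterogeneity of the underlying rate (for a Gamma-mixed Poisson with mean
m and shape k, U -> m/k). Zero-depth sites are excluded throughout, since
unsequenced or unmappable bases say nothing about the sampling noise of
the covered genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .io_formats import AlignmentRecord, GenomeLayout
from .hic_qc import InsufficientDataError

__all__ = [
    "CoverageHistogram",
    "EvennessResult",
    "coverage_histogram",
    "depth_histogram_from_tsv",
    "unevenness",
    "unevenness_from_moments",
    "downsample",
    "thin_depths",
]


@dataclass
class CoverageHistogram:
    """Depth -> number of sites at that depth.

    ``zero_excluded`` must be True for the evenness statistic; including
    depth-0 sites is allowed only for diagnostic output.
    """

    counts: dict[int, int]
    zero_excluded: bool = True

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("site counts must be non-negative")
        if self.zero_excluded and 0 in self.counts:
            raise ValueError("zero-depth bin present in a zero-excluded histogram")

    @property
    def n_sites(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_depths(cls, depths: np.ndarray, exclude_zero: bool = True) -> "CoverageHistogram":
        depths = np.asarray(depths)
        if depths.size == 0:
            raise InsufficientDataError("empty depth track")
        values, counts = np.unique(depths, return_counts=True)
        mapping = {int(v): int(c) for v, c in zip(values, counts)}
        if exclude_zero:
            mapping.pop(0, None)
        if not mapping:
            raise InsufficientDataError("no covered sites")
        return cls(mapping, zero_excluded=exclude_zero)


def coverage_histogram(
    reads: Iterable[AlignmentRecord],
    layout: GenomeLayout,
    exclude_zero: bool = True,
) -> CoverageHistogram:
    """Per-base depth histogram from mapped non-duplicate reads.

    Depth is tallied with a difference array per chromosome (+1 at read
    start, -1 at read end, cumulative sum), which handles arbitrary
    overlap in O(genome + reads).
    """
    lengths = layout.lengths
    diffs = {name: np.zeros(length + 1, dtype=np.int64) for name, length in layout.chromosomes}
    n_used = 0
    for r in reads:
        if not r.mapped or r.duplicate:
            continue
        if r.chrom not in diffs:
            raise ValueError(f"read maps to chromosome {r.chrom!r} absent from layout")
        end = min(r.end, lengths[r.chrom])
        diffs[r.chrom][r.start] += 1
        diffs[r.chrom][end] -= 1
        n_used += 1
    if n_used == 0:
        raise InsufficientDataError("no mapped non-duplicate reads; empty coverage")
    depths = np.concatenate([np.cumsum(d[:-1]) for d in diffs.values()])
    return CoverageHistogram.from_depths(depths, exclude_zero=exclude_zero)


def depth_histogram_from_tsv(path, exclude_zero: bool = True) -> CoverageHistogram:
    """Histogram from a per-base depth TSV: chrom, pos (0-based), depth."""
    depths = np.loadtxt(path, usecols=2, dtype=np.int64, ndmin=1)
    return CoverageHistogram.from_depths(depths, exclude_zero=exclude_zero)


@dataclass(frozen=True)
class EvennessResult:
    """Mean, population variance and unevenness of non-zero coverage.

    ``poisson_rate`` is the rate of the Poisson reference distribution the
    track is compared against (its mean). ``degenerate`` flags a
    single-depth histogram, where the variance is zero by construction.
    """

    mean: float
    variance: float
    unevenness: float
    poisson_rate: float
    n_sites: int
    degenerate: bool = False


def unevenness_from_moments(mean: float, variance: float) -> float:
    """U = (variance - mean) / mean, the dispersion index minus one."""
    if mean <= 0:
        raise ValueError("mean coverage must be positive")
    if variance < 0:
        raise ValueError("variance must be non-negative")
    return (variance - mean) / mean


def unevenness(hist: CoverageHistogram) -> EvennessResult:
    """Unevenness of a zero-excluded coverage histogram.

    Uses the weighted mean and population variance of the depths. Reports
    U rounded only at presentation time; the stored value is exact.
    """
    if not hist.zero_excluded:
        raise ValueError("unevenness requires a zero-excluded histogram")
    if not hist.counts:
        raise InsufficientDataError("empty coverage histogram")
    depths = np.array(sorted(hist.counts), dtype=float)
    weights = np.array([hist.counts[int(d)] for d in depths], dtype=float)
    n = weights.sum()
    m = float((depths * weights).sum() / n)
    v = float((weights * (depths - m) ** 2).sum() / n)
    return EvennessResult(
        mean=m,
        variance=v,
        unevenness=unevenness_from_moments(m, v),
        poisson_rate=m,
        n_sites=int(n),
        degenerate=len(hist.counts) == 1,
    )


def downsample(
    records: Iterable,
    current_mean: float,
    target_mean: float = 30.0,
    seed: int | None = None,
) -> Iterator:
    """Keep each record independently with p = target_mean / current_mean.

    Binomial thinning: applied to reads it scales expected depth from
    ``current_mean`` to ``target_mean`` while preserving the Poisson
    character of an even track. Deterministic for a given seed.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible downsampling")
    if target_mean > current_mean:
        raise ValueError(f"target mean {target_mean} exceeds current mean {current_mean}")
    p = target_mean / current_mean
    rng = np.random.default_rng(seed)
    for rec in records:
        if p >= 1.0 or rng.random() < p:
            yield rec


def thin_depths(
    depths: np.ndarray,
    current_mean: float,
    target_mean: float = 30.0,
    seed: int | None = None,
) -> np.ndarray:
    """Binomially thin a per-base depth track: depth_i -> Binomial(depth_i, p)
    with p = target_mean / current_mean. The thinned track of a Poisson
    track is again Poisson."""
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible downsampling")
    if target_mean > current_mean:
        raise ValueError(f"target mean {target_mean} exceeds current mean {current_mean}")
    p = target_mean / current_mean
    rng = np.random.default_rng(seed)
    depths = np.asarray(depths, dtype=np.int64)
    return rng.binomial(depths, p)
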