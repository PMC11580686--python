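"""Assembly capability statistics: Nx values and before/after comparisons.

Nx is the length of the shortest sequence such that all sequences at least
that long cumulatively cover x% of the total assembly length (ties resolved
by >=). Comparing N50/N90 with and without long-range scaffolding measures
how much contiguity the long-range data buys; a scaffold longer than the
longest expected chromosome is a mis-assembly signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["NxStats", "AssemblyComparison", "nx", "compare_assemblies"]

NX_LEVELS = (10, 20, 50, 90)


def nx(lengths: Sequence[int], x: float) -> int:
    """Nx of a set of sequence lengths.

    Sort descending and return the first length at which the cumulative
    sum reaches >= x% of the total.
    """
    if not lengths:
        raise ValueError("empty length list")
    if any(v <= 0 for v in lengths):
        raise ValueError("lengths must be positive")
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    ordered = sorted(lengths, reverse=True)
    target = sum(ordered) * x / 100.0
    acc = 0
    for v in ordered:
        acc += v
        if acc >= target:
            return v
    return ordered[-1]


@dataclass(frozen=True)
class NxStats:
    """Summary of one sequence-length set."""

    total: int
    count: int
    mean: float
    maximum: int
    nx_values: dict[int, int]

    @classmethod
    def from_lengths(cls, lengths: Sequence[int], levels: Sequence[int] = NX_LEVELS) -> "NxStats":
        if not lengths:
            raise ValueError("empty length list")
        return cls(
            total=sum(lengths),
            count=len(lengths),
            mean=sum(lengths) / len(lengths),
            maximum=max(lengths),
            nx_values={x: nx(lengths, x) for x in levels},
        )

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "count": self.count,
            "mean": self.mean,
            "maximum": self.maximum,
            **{f"N{x}": v for x, v in sorted(self.nx_values.items())},
        }


@dataclass(frozen=True)
class AssemblyComparison:
    """Before/after Nx table with deltas and mis-assembly warnings."""

    before: NxStats
    after: NxStats
    deltas: dict[int, int]
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "before": self.before.to_dict(),
            "after": self.after.to_dict(),
            "deltas": {f"N{x}": v for x, v in sorted(self.deltas.items())},
            "warnings": list(self.warnings),
        }


def compare_assemblies(
    before: Sequence[int],
    after: Sequence[int],
    expected_max: int | None = None,
    levels: Sequence[int] = NX_LEVELS,
) -> AssemblyComparison:
    """Nx statistics before and after scaffolding, with deltas.

    When ``expected_max`` (the longest plausible chromosome) is supplied
    and the scaffolded assembly exceeds it, a warning is emitted: a
    scaffold longer than any chromosome indicates joined sequences that do
    not belong together.
    """
    stats_before = NxStats.from_lengths(before, levels)
    stats_after = NxStats.from_lengths(after, levels)
    deltas = {
        x: stats_after.nx_values[x] - stats_before.nx_values[x] for x in levels
    }
    warn: list[str] = []
    if expected_max is not None and stats_after.maximum > expected_max:
        warn.append(
            f"maximum scaffold length {stats_after.maximum} exceeds expected "
            f"maximum chromosome length {expected_max}: possible mis-assembly"
        )
    return AssemblyComparison(stats_before, stats_after, deltas, tuple(warn))
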