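"""Overlap statistics between compound hit lists (two-sided Fisher, Venn)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

from scipy import stats

__all__ = ["OverlapResult", "fisher_overlap", "venn_counts"]


@dataclass(frozen=True)
class OverlapResult:
    """2x2 overlap of two gene sets within a universe of N genes."""

    both: int
    a_only: int
    b_only: int
    neither: int
    p_value: float

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.both, self.a_only), (self.b_only, self.neither))


def fisher_overlap(
    set_a: Collection[str],
    set_b: Collection[str],
    universe_size: int,
) -> OverlapResult:
    """Two-sided Fisher's exact test on the overlap of two gene sets.

    The 2x2 table is (both, A-only, B-only, neither) over a universe of
    ``universe_size`` genes; the two-sided p-value sums, with the margins
    fixed, the probabilities of all tables whose point probability does not
    exceed the observed one (the conventional definition, which
    scipy.stats.fisher_exact computes in a numerically safe way).
    """
    a, b = set(set_a), set(set_b)
    both = len(a & b)
    a_only = len(a) - both
    b_only = len(b) - both
    neither = universe_size - len(a | b)
    if neither < 0:
        raise ValueError(
            f"universe size {universe_size} smaller than |A union B| = {len(a | b)}"
        )
    p = stats.fisher_exact([[both, a_only], [b_only, neither]], alternative="two-sided")[1]
    return OverlapResult(both, a_only, b_only, neither, float(p))


def venn_counts(set_a: Collection[str], set_b: Collection[str]) -> tuple[int, int, int]:
    """(both, A-only, B-only) partition counts of two gene sets."""
    a, b = set(set_a), set(set_b)
    both = len(a & b)
    return both, len(a) - both, len(b) - both
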