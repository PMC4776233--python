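"""Overlap arithmetic between substrate sets and reference degradome lists.

In vitro substrate calls are validated by intersecting them with
independently published lists: curated known-substrate databases and
in vivo apoptosis degradome sets.  Two percentages matter: the fraction of
one set recovered in the other (``pct_of_a``) and the Jaccard overlap
ratio, intersection over union (``jaccard_pct``).  Matching is exact
string identity after whitespace stripping; identifier mapping between
namespaces is a curation step upstream of this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .calling import SubstrateCall

logger = logging.getLogger(__name__)

__all__ = ["OverlapResult", "overlap", "overlap_from_counts", "stratified_overlap"]


@dataclass(frozen=True)
class OverlapResult:
    """Set sizes and overlap percentages; raw doubles, round only to print."""

    size_a: int
    size_b: int
    intersection: int

    def __post_init__(self) -> None:
        if min(self.size_a, self.size_b, self.intersection) < 0:
            raise ValueError("counts must be non-negative")
        if self.intersection > min(self.size_a, self.size_b):
            raise ValueError(
                f"intersection {self.intersection} exceeds a set size "
                f"({self.size_a}, {self.size_b})"
            )

    @property
    def union(self) -> int:
        return self.size_a + self.size_b - self.intersection

    @property
    def pct_of_a(self) -> float:
        """Percentage of A recovered in B; NaN when A is empty."""
        return 100.0 * self.intersection / self.size_a if self.size_a else float("nan")

    @property
    def jaccard_pct(self) -> float:
        """Overlap ratio: intersection over union, as a percentage."""
        return 100.0 * self.intersection / self.union if self.union else float("nan")


def _clean(accessions: Iterable[str]) -> set[str]:
    return {a.strip() for a in accessions if a.strip()}


def overlap(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapResult:
    """Exact set overlap between two accession collections."""
    a, b = _clean(set_a), _clean(set_b)
    return OverlapResult(len(a), len(b), len(a & b))


def overlap_from_counts(size_a: int, size_b: int, union_size: int) -> OverlapResult:
    """Overlap reconstructed from published set sizes and their union."""
    if union_size > size_a + size_b:
        raise ValueError(f"union {union_size} exceeds {size_a} + {size_b}")
    if union_size < max(size_a, size_b):
        raise ValueError(f"union {union_size} smaller than a set ({size_a}, {size_b})")
    return OverlapResult(size_a, size_b, size_a + size_b - union_size)


def stratified_overlap(
    calls: Iterable[SubstrateCall], invivo: Iterable[str]
) -> dict[str, OverlapResult]:
    """Overlap with an in vivo set, per tier and combined.

    Returns ``{"hot": ..., "warm": ..., "combined": ...}``; a tier with no
    members yields a result whose ``pct_of_a`` is NaN (logged), never 0.
    """
    invivo_set = _clean(invivo)
    tiers: dict[str, set[str]] = {"hot": set(), "warm": set()}
    for call in calls:
        tiers[call.tier].add(call.accession)
    results: dict[str, OverlapResult] = {}
    for name, accs in {**tiers, "combined": tiers["hot"] | tiers["warm"]}.items():
        if not accs:
            logger.warning("tier %r is empty; its percentage is undefined", name)
        results[name] = overlap(accs, invivo_set)
    return results
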