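"""Substrate calling from quantified peptide ratios.

A protein is called a substrate when at least ``min_peptides`` distinct
peptide sequences from it pass the log2 ratio cutoff (default log2 >= 1.8
with >= 2 peptides, the screen's optimized dual-threshold criteria).
Calls are tiered: "hot" substrates are supported by >= 5 up-regulated
peptides, "warm" substrates by 2-4.  The cutoff-optimization curves
(percentage of known substrates versus ratio cutoff or peptide-count
minimum) are what justified those thresholds in the first place and are
reproduced here for any table plus reference set.

Comparison conventions, chosen deliberately and used verbatim everywhere:
the substrate-calling ratio cutoff is inclusive (log2 >= cutoff), while the
"up-regulated peptide" fraction uses a strict inequality (log2 > cutoff).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .quantio import QuantTable, QuantifiedPeptide

logger = logging.getLogger(__name__)

__all__ = [
    "SubstrateCall",
    "CutoffCurve",
    "DEFAULT_LOG2_CUTOFF",
    "DEFAULT_MIN_PEPTIDES",
    "HOT_MIN_PEPTIDES",
    "fold_to_log2",
    "upregulated_fraction",
    "call_substrates",
    "known_percentage_by_ratio_cutoff",
    "known_percentage_by_count",
]

DEFAULT_LOG2_CUTOFF = 1.8
DEFAULT_MIN_PEPTIDES = 2
HOT_MIN_PEPTIDES = 5


@dataclass
class SubstrateCall:
    """A protein passing the dual-threshold criteria."""

    accession: str
    n_up_peptides: int
    tier: str  # "hot" | "warm"
    peptides: list[QuantifiedPeptide] = field(default_factory=list, repr=False)
    is_known: bool | None = None

    def __post_init__(self) -> None:
        if self.n_up_peptides < 2:
            raise ValueError("a substrate call needs >= 2 supporting peptides")
        expected = "hot" if self.n_up_peptides >= HOT_MIN_PEPTIDES else "warm"
        if self.tier != expected:
            raise ValueError(
                f"tier {self.tier!r} inconsistent with {self.n_up_peptides} peptides"
            )


@dataclass
class CutoffCurve:
    """Percentage of known substrates as a function of a threshold.

    ``percent_known`` entries are NaN (the undefined marker, never 0) where
    the denominator was empty.
    """

    thresholds: list[float]
    percent_known: list[float]
    denominator_kind: str  # "peptides" | "proteins"
    n_numerator: list[int] = field(default_factory=list)
    n_denominator: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.percent_known):
            raise ValueError("thresholds and percent_known differ in length")
        for pct in self.percent_known:
            if not math.isnan(pct) and not 0.0 <= pct <= 100.0:
                raise ValueError(f"percentage {pct} outside [0, 100]")
        if self.denominator_kind not in ("peptides", "proteins"):
            raise ValueError(f"bad denominator_kind {self.denominator_kind!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "percent_known": self.percent_known,
                "n_numerator": self.n_numerator,
                "n_denominator": self.n_denominator,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fold_to_log2(fold: float) -> float:
    """Convert an x-fold change to the log2 scale used by the cutoffs."""
    if fold <= 0:
        raise ValueError(f"fold change must be positive, got {fold}")
    return math.log2(fold)


def upregulated_fraction(table: QuantTable, log2_cutoff: float = 1.0) -> float:
    """Fraction of peptide rows with log2 ratio strictly above the cutoff."""
    if len(table) == 0:
        raise ValueError("empty table")
    n_up = sum(1 for r in table if r.log2_ratio > log2_cutoff)
    return n_up / len(table)


def _passing_by_accession(
    table: QuantTable, log2_cutoff: float
) -> dict[str, list[QuantifiedPeptide]]:
    by_acc: dict[str, list[QuantifiedPeptide]] = {}
    for row in table:
        if row.log2_ratio >= log2_cutoff:
            by_acc.setdefault(row.accession, []).append(row)
    return by_acc


def call_substrates(
    table: QuantTable,
    log2_cutoff: float = DEFAULT_LOG2_CUTOFF,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
    known: set[str] | None = None,
) -> list[SubstrateCall]:
    """Apply the dual-threshold criteria and tier the calls.

    Peptides are counted as distinct sequences (charge and modification
    variants of one sequence collapse to a single peptide).  Output is
    sorted by accession.
    """
    if min_peptides < 2:
        raise ValueError("min_peptides must be >= 2")
    calls = []
    passing = _passing_by_accession(table, log2_cutoff)
    for accession in sorted(passing):
        rows = passing[accession]
        n_distinct = len({r.sequence for r in rows})
        if n_distinct < min_peptides:
            continue
        calls.append(
            SubstrateCall(
                accession=accession,
                n_up_peptides=n_distinct,
                tier="hot" if n_distinct >= HOT_MIN_PEPTIDES else "warm",
                peptides=sorted(rows, key=lambda r: (r.start, r.sequence)),
                is_known=None if known is None else accession in known,
            )
        )
    return calls


def known_percentage_by_ratio_cutoff(
    table: QuantTable, known: set[str], cutoffs: list[float]
) -> CutoffCurve:
    """Of the peptides at or above each ratio cutoff, the % from known substrates."""
    if not cutoffs:
        raise ValueError("no cutoffs supplied")
    pct, n_num, n_den = [], [], []
    for cutoff in cutoffs:
        passing = [r for r in table if r.log2_ratio >= cutoff]
        hits = sum(1 for r in passing if r.accession in known)
        n_num.append(hits)
        n_den.append(len(passing))
        if not passing:
            logger.warning("no peptides at log2 cutoff %.3g; percentage undefined", cutoff)
            pct.append(float("nan"))
        else:
            pct.append(100.0 * hits / len(passing))
    return CutoffCurve(list(cutoffs), pct, "peptides", n_num, n_den)


def known_percentage_by_count(
    table: QuantTable,
    known: set[str],
    log2_cutoff: float = DEFAULT_LOG2_CUTOFF,
    count_minima: list[int] | None = None,
) -> CutoffCurve:
    """Of the proteins with >= m distinct passing peptides, the % known."""
    if count_minima is None:
        count_minima = [1, 2, 3, 4, 5]
    if not count_minima:
        raise ValueError("no count minima supplied")
    distinct_counts = {
        acc: len({r.sequence for r in rows})
        for acc, rows in _passing_by_accession(table, log2_cutoff).items()
    }
    pct, n_num, n_den = [], [], []
    for minimum in count_minima:
        qualifying = [acc for acc, n in distinct_counts.items() if n >= minimum]
        hits = sum(1 for acc in qualifying if acc in known)
        n_num.append(hits)
        n_den.append(len(qualifying))
        if not qualifying:
            logger.warning("no proteins with >= %d passing peptides; percentage undefined", minimum)
            pct.append(float("nan"))
        else:
            pct.append(100.0 * hits / len(qualifying))
    return CutoffCurve([float(m) for m in count_minima], pct, "proteins", n_num, n_den)
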