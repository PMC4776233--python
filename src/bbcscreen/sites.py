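"""Cleavage-site derivation, enzyme classification and motif analysis.

Every non-terminal peptide terminus reads out one cleavage site: the bond
before its first residue (N-side) and the bond after its last residue
(C-side).  Because released fragments are digested with trypsin before MS,
most sites are tryptic (P1 = K/R, not before P); the remainder carry the
upstream protease's signature — for a caspase-3 screen, aspartate at P1
and a DXXD P4-P1 preference with DEXD / DLXD / DDXD sub-families.

Sites are unique per (protein, P1 position).  Context strings use the
field's dot notation — five residues ending at P1, a dot for the scissile
bond, five residues after — e.g. ``PPEKD.GFPSG``-style windows, padded
with ``'-'`` where the window runs off the protein.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .quantio import AMINO_ACIDS, ProteinRecord, QuantifiedPeptide, TERMINUS

logger = logging.getLogger(__name__)

__all__ = [
    "CleavageSite",
    "PositionFrequencyMatrix",
    "SiteSummary",
    "FLANK",
    "classify_p1",
    "classify_site",
    "site_context",
    "motif_class",
    "extract_sites",
    "build_pfm",
    "summarize_sites",
    "write_sites_tsv",
]

#: residues on each side of the scissile bond in a context window
FLANK = 5

TRYPTIC = "tryptic"
ASPARTATE = "aspartate"
OTHER = "other"

_DXXD_FAMILIES = {"E": "DEXD", "L": "DLXD", "D": "DDXD"}


@dataclass(frozen=True)
class CleavageSite:
    """A unique cleavage event: the bond after ``position`` (the P1 residue)."""

    accession: str
    position: int
    p1: str
    enzyme_class: str
    context: str
    source_terminus: str  # "n_side" | "c_side"
    motif_family: str | None = None

    def __post_init__(self) -> None:
        if len(self.context) != 2 * FLANK + 1 or self.context[FLANK] != ".":
            raise ValueError(f"malformed context {self.context!r}")
        if self.context[FLANK - 1] != self.p1:
            raise ValueError("context disagrees with P1 residue")
        if self.enzyme_class not in (TRYPTIC, ASPARTATE, OTHER):
            raise ValueError(f"bad enzyme class {self.enzyme_class!r}")


def classify_p1(p1: str, following: str) -> str:
    """Enzyme class of a cut from its P1 and P1' residues.

    Tryptic iff P1 is K/R and P1' is not proline; otherwise aspartate iff
    P1 is D (the caspase signature); otherwise other.
    """
    if p1 in "KR" and following != "P":
        return TRYPTIC
    if p1 == "D":
        return ASPARTATE
    return OTHER


def classify_site(site: CleavageSite) -> str:
    """Re-derive a site's enzyme class from its context window."""
    return classify_p1(site.p1, site.context[FLANK + 1])


def site_context(protein: ProteinRecord, position: int) -> str:
    """Dot-notation window: 5 residues ending at P1, '.', 5 residues after."""
    if not 1 <= position <= len(protein) - 1:
        raise ValueError(
            f"position {position} outside [1, {len(protein) - 1}] for {protein.accession}"
        )
    seq = protein.sequence
    left = seq[max(0, position - FLANK) : position]
    right = seq[position : position + FLANK]
    return left.rjust(FLANK, TERMINUS) + "." + right.ljust(FLANK, TERMINUS)


def motif_class(site: CleavageSite, protein: ProteinRecord) -> str | None:
    """Caspase motif family of an aspartate site, from its P4-P1 residues.

    Returns ``None`` for non-DXXD sites (including sites whose P4 falls
    outside the protein), the sub-family name when P3 is E/L/D, otherwise
    the generic ``"DXXD"``.
    """
    if site.enzyme_class != ASPARTATE:
        return None
    if site.position < 4:
        logger.warning(
            "%s position %d: P4 outside protein; motif classified none",
            site.accession, site.position,
        )
        return None
    window = protein.sequence[site.position - 4 : site.position]
    if window[0] != "D" or window[3] != "D":
        return None
    return _DXXD_FAMILIES.get(window[1], "DXXD")


def extract_sites(
    peptides: Iterable[QuantifiedPeptide],
    proteome: Mapping[str, ProteinRecord],
) -> list[CleavageSite]:
    """Read cleavage sites off peptide termini, deduplicated per (protein, position).

    The caller supplies peptides already filtered to the ratio cutoff.
    Terminal peptides contribute only their non-flush side: a peptide
    starting at residue 1 has no N-side site, one ending at the protein's
    last residue has no C-side site.  When duplicates arise the N-side
    reading is preferred as ``source_terminus``, then first-seen order;
    output is sorted by (accession, position).
    """
    chosen: dict[tuple[str, int], CleavageSite] = {}
    for pep in peptides:
        protein = proteome.get(pep.accession)
        if protein is None:
            raise ValueError(f"peptide accession {pep.accession} not in proteome")
        if protein.sequence[pep.start - 1 : pep.end] != pep.sequence:
            raise ValueError(
                f"{pep.accession}:{pep.start}-{pep.end} does not match {pep.sequence}"
            )
        readings = []
        if pep.start > 1:
            readings.append((pep.start - 1, "n_side"))
        if pep.end < len(protein):
            readings.append((pep.end, "c_side"))
        for position, terminus in readings:
            key = (pep.accession, position)
            if key in chosen and not (
                terminus == "n_side" and chosen[key].source_terminus == "c_side"
            ):
                continue
            p1 = protein.sequence[position - 1]
            following = protein.sequence[position] if position < len(protein) else TERMINUS
            site = CleavageSite(
                accession=pep.accession,
                position=position,
                p1=p1,
                enzyme_class=classify_p1(p1, following),
                context=site_context(protein, position),
                source_terminus=terminus,
            )
            site = CleavageSite(
                **{**vars(site), "motif_family": motif_class(site, protein)}
            )
            chosen[key] = site
    return [chosen[k] for k in sorted(chosen)]


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue frequencies around the scissile bond.

    Rows are the 20 residues plus the ``'-'`` gap sentinel; columns are
    P5..P1 then P1'..P5'.  Every column sums to 1 (gap mass included).
    """

    frequencies: pd.DataFrame
    n_sites: int

    POSITIONS = ["P5", "P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'", "P5'"]

    def __post_init__(self) -> None:
        sums = self.frequencies.sum(axis=0)
        if not ((sums - 1.0).abs() < 1e-9).all():
            raise ValueError("PFM columns must each sum to 1")

    def write_tsv(self, path: str | Path) -> None:
        """Logo-tool-compatible matrix: residues as rows, positions as columns."""
        self.frequencies.to_csv(path, sep="\t", index_label="residue")


def build_pfm(sites: Iterable[CleavageSite]) -> PositionFrequencyMatrix:
    """Count residue frequencies over all site context windows."""
    sites = list(sites)
    if not sites:
        raise ValueError("cannot build a PFM from zero sites")
    residues = list(AMINO_ACIDS) + [TERMINUS]
    counts = {pos: Counter() for pos in PositionFrequencyMatrix.POSITIONS}
    for site in sites:
        window = site.context.replace(".", "")
        for pos, residue in zip(PositionFrequencyMatrix.POSITIONS, window):
            counts[pos][residue] += 1
    freq = pd.DataFrame(
        {pos: [counts[pos][r] / len(sites) for r in residues]
         for pos in PositionFrequencyMatrix.POSITIONS},
        index=residues,
    )
    return PositionFrequencyMatrix(freq, n_sites=len(sites))


@dataclass
class SiteSummary:
    """Headline numbers of a cleavage-site analysis."""

    n_sites: int
    n_tryptic: int
    n_aspartate: int
    n_other: int
    tryptic_fraction: float
    aspartate_fraction: float
    other_fraction: float
    n_dxxd: int
    dxxd_pct_of_aspartate: float
    n_dexd: int
    n_dlxd: int
    n_ddxd: int
    n_substrates_with_d_site: int | None = None
    substrates_with_d_site_fraction: float | None = None


def summarize_sites(
    sites: Iterable[CleavageSite],
    called_accessions: set[str] | None = None,
) -> SiteSummary:
    """Counts and fractions per enzyme class and caspase motif family.

    With ``called_accessions`` supplied, also reports how many of those
    substrates carry at least one aspartate (D) cleavage site.
    """
    sites = list(sites)
    by_class = Counter(s.enzyme_class for s in sites)
    n = len(sites)
    n_aspartate = by_class[ASPARTATE]
    families = Counter(s.motif_family for s in sites if s.motif_family)
    n_dxxd = sum(families.values())

    with_d: int | None = None
    d_fraction: float | None = None
    if called_accessions is not None:
        d_accs = {s.accession for s in sites if s.enzyme_class == ASPARTATE}
        with_d = len(d_accs & called_accessions)
        d_fraction = with_d / len(called_accessions) if called_accessions else float("nan")

    return SiteSummary(
        n_sites=n,
        n_tryptic=by_class[TRYPTIC],
        n_aspartate=n_aspartate,
        n_other=by_class[OTHER],
        tryptic_fraction=by_class[TRYPTIC] / n if n else float("nan"),
        aspartate_fraction=n_aspartate / n if n else float("nan"),
        other_fraction=by_class[OTHER] / n if n else float("nan"),
        n_dxxd=n_dxxd,
        dxxd_pct_of_aspartate=100.0 * n_dxxd / n_aspartate if n_aspartate else float("nan"),
        n_dexd=families["DEXD"],
        n_dlxd=families["DLXD"],
        n_ddxd=families["DDXD"],
        n_substrates_with_d_site=with_d,
        substrates_with_d_site_fraction=d_fraction,
    )


def write_sites_tsv(sites: Iterable[CleavageSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "accession": s.accession,
                "position": s.position,
                "p1": s.p1,
                "enzyme_class": s.enzyme_class,
                "context": s.context,
                "motif_family": s.motif_family or "",
            }
            for s in sites
        ],
        columns=["accession", "position", "p1", "enzyme_class", "context", "motif_family"],
    ).to_csv(path, sep="\t", index=False)
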