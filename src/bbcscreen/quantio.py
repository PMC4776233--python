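"""Readers, writers and peptide-to-protein mapping.

Everything downstream of the mass spectrometer is driven by two text
formats: a FASTA file holding the screening library (the proteome that was
immobilized on beads) and a tab-separated quantified-peptide table, one row
per peptide with its heavy/light (treated/untreated) abundance ratio.  This
module turns those files into validated in-memory records and keeps all
coordinate conventions in one place: positions are 1-based inclusive, and a
peptide's flanking residues use ``'-'`` as the protein-terminus sentinel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 canonical residues; sequences are validated against this alphabet
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: sentinel for a flanking position that falls outside the protein
TERMINUS = "-"


class FormatError(ValueError):
    """A file does not conform to its documented schema."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein of the screening library: accession plus sequence."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession or any(c.isspace() for c in self.accession):
            raise ValueError(f"invalid accession {self.accession!r}")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"{self.accession}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QuantifiedPeptide:
    """A quantified peptide located on its protein.

    ``ratio_hl`` is oriented treated (H) over untreated control (L):
    values above 1 mean the peptide was released more strongly when the
    protease was present.  ``caspase_released`` is simulator provenance
    (``None`` for real data): True when the peptide's source fragment was
    created by a planted protease cut.
    """

    sequence: str
    accession: str
    start: int
    end: int
    ratio_hl: float
    log2_ratio: float
    preceding: str
    following: str
    caspase_released: bool | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates [{self.start}, {self.end}]")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.sequence}: span [{self.start}, {self.end}] does not "
                f"match sequence length {len(self.sequence)}"
            )
        if self.ratio_hl <= 0:
            raise ValueError(f"non-positive ratio {self.ratio_hl}")
        if abs(self.log2_ratio - math.log2(self.ratio_hl)) >= 1e-9:
            raise ValueError("log2_ratio inconsistent with ratio_hl")
        for flank in (self.preceding, self.following):
            if len(flank) != 1 or (flank != TERMINUS and flank not in _AA_SET):
                raise ValueError(f"bad flanking residue {flank!r}")


@dataclass
class QuantTable:
    """Ordered collection of quantified peptides plus provenance text."""

    rows: list[QuantifiedPeptide]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [(r.sequence, r.accession, r.start) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (sequence, accession, start) rows")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[QuantifiedPeptide]:
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view of the rows (one column per field)."""
        return pd.DataFrame([vars(r) for r in self.rows])


def proteome_index(proteins: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Accession -> record mapping, rejecting duplicate accessions."""
    index: dict[str, ProteinRecord] = {}
    for rec in proteins:
        if rec.accession in index:
            raise FormatError(f"duplicate accession {rec.accession}")
        index[rec.accession] = rec
    return index


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load a protein FASTA file.

    The accession is the first whitespace-delimited token of the header;
    sequences are uppercased and validated against the canonical alphabet.
    Duplicate accessions or illegal residues raise :class:`FormatError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        accession = rec.id
        if not accession:
            raise FormatError(f"{path}: record {i} has an empty header")
        if accession in seen:
            raise FormatError(f"{path}: duplicate accession {accession} (record {i})")
        seen.add(accession)
        try:
            records.append(ProteinRecord(accession, str(rec.seq).upper()))
        except ValueError as exc:
            raise FormatError(f"{path}: record {i} ({accession}): {exc}") from exc
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as standard FASTA, 60-column wrapped."""
    seqs = [
        SeqRecord(Seq(p.sequence), id=p.accession, description="")
        for p in proteins
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Quantified-peptide table

#: columns of the on-disk TSV schema, in order
QUANT_COLUMNS = ["sequence", "accession", "start", "ratio_hl"]


def map_peptide(sequence: str, protein: ProteinRecord) -> list[int]:
    """All 1-based start positions of exact matches, overlaps allowed."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    positions = []
    pos = protein.sequence.find(sequence)
    while pos != -1:
        positions.append(pos + 1)
        pos = protein.sequence.find(sequence, pos + 1)
    return positions


def locate_peptide(
    sequence: str, protein: ProteinRecord, start: int | None = None
) -> QuantifiedPeptide | None:
    """Place a peptide on its protein and annotate flanking residues.

    Returns ``None`` when the peptide cannot be located (no exact match, or
    an explicit ``start`` whose substring does not match).  With several
    matches the smallest start wins and a warning is logged.
    """
    if start is None:
        hits = map_peptide(sequence, protein)
        if not hits:
            return None
        if len(hits) > 1:
            logger.warning(
                "%s matches %s at %d positions; using smallest start %d",
                sequence, protein.accession, len(hits), hits[0],
            )
        start = hits[0]
    end = start + len(sequence) - 1
    if end > len(protein) or protein.sequence[start - 1 : end] != sequence:
        return None
    preceding = protein.sequence[start - 2] if start > 1 else TERMINUS
    following = protein.sequence[end] if end < len(protein) else TERMINUS
    # ratio filled by the caller; placeholder 1.0 keeps the invariant
    return QuantifiedPeptide(
        sequence, protein.accession, start, end, 1.0, 0.0, preceding, following
    )


def read_quant_table(
    path: str | Path, proteome: Iterable[ProteinRecord] | Mapping[str, ProteinRecord]
) -> QuantTable:
    """Read the quantified-peptide TSV and annotate it against the proteome.

    Mandatory columns: ``sequence``, ``accession``, ``ratio_hl``; ``start``
    is optional (peptides are located by exact match when absent).  Rows
    with unknown accessions, failed location or non-positive ratios are
    dropped with a logged count.
    """
    index = proteome if isinstance(proteome, Mapping) else proteome_index(proteome)
    df = pd.read_csv(
        path, sep="\t", dtype={"sequence": str, "accession": str},
        float_precision="round_trip",
    )
    missing = [c for c in ("sequence", "accession", "ratio_hl") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    has_start = "start" in df.columns
    has_flag = "caspase_released" in df.columns

    rows: list[QuantifiedPeptide] = []
    n_dropped = 0
    for tup in df.itertuples(index=False):
        ratio = float(getattr(tup, "ratio_hl"))
        accession = getattr(tup, "accession")
        sequence = str(getattr(tup, "sequence")).upper()
        if ratio <= 0 or not math.isfinite(ratio):
            logger.warning("dropping %s/%s: non-positive ratio %r", accession, sequence, ratio)
            n_dropped += 1
            continue
        protein = index.get(accession)
        if protein is None:
            logger.warning("dropping %s: accession not in proteome", accession)
            n_dropped += 1
            continue
        start = None
        if has_start and not pd.isna(getattr(tup, "start")):
            start = int(getattr(tup, "start"))
        located = locate_peptide(sequence, protein, start)
        if located is None:
            logger.warning("dropping %s/%s: cannot locate on protein", accession, sequence)
            n_dropped += 1
            continue
        flag = None
        if has_flag and not pd.isna(getattr(tup, "caspase_released")):
            flag = bool(getattr(tup, "caspase_released"))
        rows.append(
            QuantifiedPeptide(
                located.sequence, located.accession, located.start, located.end,
                ratio, math.log2(ratio), located.preceding, located.following, flag,
            )
        )
    if n_dropped:
        logger.info("read_quant_table: dropped %d rows", n_dropped)
    return QuantTable(rows, provenance=f"loaded from {path}")


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Write the table in the documented TSV schema.

    Only the schema columns (plus the simulator provenance flag when
    present) are persisted; derived fields are recomputed on read.
    """
    records = []
    with_flag = any(r.caspase_released is not None for r in table)
    for r in table:
        rec = {
            "sequence": r.sequence,
            "accession": r.accession,
            "start": r.start,
            "ratio_hl": repr(r.ratio_hl),
        }
        if with_flag:
            rec["caspase_released"] = bool(r.caspase_released)
        records.append(rec)
    cols = QUANT_COLUMNS + (["caspase_released"] if with_flag else [])
    pd.DataFrame(records, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Accession lists


def read_accession_list(path: str | Path) -> set[str]:
    """Plain-text accession list: one per line, ``#`` comments, deduplicated."""
    accessions: set[str] = set()
    with open(path) as handle:
        for line in handle:
            entry = line.split("#", 1)[0].strip()
            if entry:
                accessions.add(entry)
    return accessions


def write_accession_list(accessions: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for acc in sorted(set(accessions)):
            handle.write(acc + "\n")
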