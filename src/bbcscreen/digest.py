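"""In-silico tryptic digestion of protein fragments.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) unless the next
residue is proline — the classic "KR/P" rule.  Because the fragments fed to
trypsin here were themselves produced by another protease, the first and
last peptide of each fragment carry fragment-edge flags: a flagged terminus
was NOT made by trypsin, which is what lets semi-tryptic peptides report
the upstream protease's cleavage sites.
"""

from __future__ import annotations

from typing import NamedTuple


class DigestPeptide(NamedTuple):
    """One peptide from a digest, located within its source fragment."""

    sequence: str
    start_offset: int  # 0-based offset within the fragment
    n_term_is_fragment_edge: bool
    c_term_is_fragment_edge: bool


def tryptic_cut_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1.

    Cuts after K/R except before P; the fragment's last residue is never a
    cut site (there is no bond after it).
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest_tryptic(fragment_sequence: str, max_missed: int = 2) -> list[DigestPeptide]:
    """All tryptic peptides of a fragment with up to ``max_missed`` missed cleavages.

    Peptides are emitted in order of start offset, then length.  Edge flags
    mark termini that coincide with the fragment boundary rather than a
    tryptic cut.
    """
    if not fragment_sequence:
        raise ValueError("empty fragment")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    n = len(fragment_sequence)
    boundaries = [0] + [i + 1 for i in tryptic_cut_sites(fragment_sequence)] + [n]
    peptides: list[DigestPeptide] = []
    for bi in range(len(boundaries) - 1):
        for bj in range(bi + 1, min(bi + 2 + max_missed, len(boundaries))):
            start, end = boundaries[bi], boundaries[bj]
            peptides.append(
                DigestPeptide(
                    fragment_sequence[start:end],
                    start,
                    n_term_is_fragment_edge=(start == 0),
                    c_term_is_fragment_edge=(end == n),
                )
            )
    return peptides
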