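"""Synthetic bead-based cleavage (BBC) degradome experiments.

The wet-lab screen immobilizes a whole proteome on beads through its
primary amines, incubates one aliquot with an active protease (here a
caspase-3-like enzyme with DXXD preference) and one without, collects the
fragments that are released into solution, trypsin-digests them, and
quantifies each peptide as a heavy/light (treated/control) ratio.  This
module generates a synthetic proteome with planted caspase substrates and
plays the whole experiment forward — attachment, specific and background
cleavage, release, tryptic digestion, ratio quantification with noise —
emitting a quantified-peptide table together with the ground truth needed
for parameter-recovery testing.

The simulation is fully deterministic under ``SimulationParams.seed``: all
randomness flows from one :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .digest import digest_tryptic
from .quantio import AMINO_ACIDS, ProteinRecord, QuantTable, QuantifiedPeptide, TERMINUS

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_proteome",
    "plant_substrates",
    "sample_attachments",
    "simulate_release",
    "simulate_experiment",
]

# Background residue composition: Swiss-Prot average amino-acid frequencies,
# renormalized over the 20 canonical residues.
BACKGROUND_AA_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

_AA = np.array(list(AMINO_ACIDS))
_AA_P = np.array([BACKGROUND_AA_FREQS[a] for a in AMINO_ACIDS])
_AA_P = _AA_P / _AA_P.sum()

#: shortest protein the generator will emit
MIN_PROTEIN_LENGTH = 50

#: log2-ratio cap for peptides seen in only one channel
LOG2_RATIO_CAP = 10.0


def _default_motif_weights() -> dict[str, float]:
    # canonical caspase-3 P4-P1 preferences; X = background-drawn residue
    return {"DEVD": 0.4, "DELD": 0.2, "DDXD": 0.2, "DQXD": 0.2}


@dataclass
class SimulationParams:
    """All knobs of the synthetic experiment.

    Probabilities are per event: ``coupling_prob`` per primary amine
    (protein N-terminus and every lysine side chain), ``background_rate``
    per peptide bond per arm (shared between arms, see
    :func:`simulate_experiment`), ``cleavage_efficiency`` per planted site
    in the treated arm.
    """

    n_proteins: int = 300
    length_mean: float = 350.0
    length_sd: float = 100.0
    substrate_fraction: float = 0.15
    sites_per_substrate_mean: float = 4.0
    motif_weights: dict[str, float] = field(default_factory=_default_motif_weights)
    coupling_prob: float = 0.2
    background_rate: float = 0.001
    cleavage_efficiency: float = 0.9
    log2_bg_sd: float = 0.4
    log2_sub_mean: float = 3.0
    log2_sub_sd: float = 0.8
    max_missed_cleavages: int = 2
    min_pep_len: int = 7
    max_pep_len: int = 35
    seed: int = 42

    def validate(self) -> None:
        for name in ("substrate_fraction", "coupling_prob", "background_rate",
                     "cleavage_efficiency"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        if self.length_mean <= 0 or self.length_sd < 0:
            raise ValueError("length distribution parameters must be positive")
        if self.sites_per_substrate_mean < 1:
            raise ValueError("sites_per_substrate_mean must be >= 1")
        if self.log2_bg_sd < 0 or self.log2_sub_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not 1 <= self.min_pep_len <= self.max_pep_len:
            raise ValueError("need 1 <= min_pep_len <= max_pep_len")
        if not self.motif_weights:
            raise ValueError("motif_weights must be non-empty")
        for motif, w in self.motif_weights.items():
            if len(motif) != 4 or motif[0] != "D" or motif[3] != "D":
                raise ValueError(f"motif {motif!r} is not a P4-P1 DXXD-style motif")
            if w < 0:
                raise ValueError("motif weights must be >= 0")
        if sum(self.motif_weights.values()) <= 0:
            raise ValueError("motif weights must not all be zero")


@dataclass
class GroundTruth:
    """What the simulator planted, for parameter-recovery tests."""

    substrate_accessions: set[str] = field(default_factory=set)
    true_sites: set[tuple[str, int]] = field(default_factory=set)
    background_degraded: set[str] = field(default_factory=set)

    def sites_of(self, accession: str) -> list[int]:
        return sorted(p for acc, p in self.true_sites if acc == accession)


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_proteome(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> list[ProteinRecord]:
    """Random protein library with realistic residue composition.

    Lengths are normal(length_mean, length_sd) rounded and truncated below
    at 50 residues; residues are i.i.d. draws from the Swiss-Prot background
    frequency table.
    """
    params.validate()
    if rng is None:
        rng = _rng_streams(params.seed, 4)[0]
    records = []
    lengths = rng.normal(params.length_mean, params.length_sd, size=params.n_proteins)
    width = max(4, len(str(params.n_proteins)))
    for i, raw in enumerate(lengths, start=1):
        length = max(MIN_PROTEIN_LENGTH, int(round(raw)))
        seq = "".join(rng.choice(_AA, size=length, p=_AA_P))
        records.append(ProteinRecord(f"SYN{i:0{width}d}", seq))
    return records


_PLACEMENT_RETRIES = 50


def plant_substrates(
    proteins: list[ProteinRecord],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Turn a Bernoulli(substrate_fraction) subset into caspase substrates.

    Each substrate receives >=1 planted cleavage sites (count 1 + Poisson
    with the configured mean); at each site the four residues ending at P1
    are overwritten with a motif drawn from ``motif_weights`` ('X' positions
    drawn from the background composition), so every planted P1 is D.
    Planted windows never overlap; a protein where no site can be placed
    after bounded retries is skipped (left out of the substrate set).
    """
    params.validate()
    if rng is None:
        rng = _rng_streams(params.seed, 4)[1]
    motifs = sorted(params.motif_weights)
    weights = np.array([params.motif_weights[m] for m in motifs], dtype=float)
    weights /= weights.sum()

    truth = GroundTruth()
    out: list[ProteinRecord] = []
    for protein in proteins:
        if rng.random() >= params.substrate_fraction:
            out.append(protein)
            continue
        length = len(protein)
        # valid P1 positions: the P4..P1 window [p-3, p] must fit and the
        # cut must be internal (p <= length - 1)
        lo, hi = 4, length - 1
        if hi < lo:
            out.append(protein)
            continue
        n_sites = 1 + rng.poisson(params.sites_per_substrate_mean - 1.0)
        seq = list(protein.sequence)
        placed: list[int] = []
        for _ in range(n_sites):
            for _attempt in range(_PLACEMENT_RETRIES):
                p1 = int(rng.integers(lo, hi + 1))
                if all(abs(p1 - q) >= 4 for q in placed):
                    placed.append(p1)
                    break
        if not placed:
            out.append(protein)
            continue
        for p1 in placed:
            motif = motifs[int(rng.choice(len(motifs), p=weights))]
            filled = [
                c if c != "X" else str(rng.choice(_AA, p=_AA_P)) for c in motif
            ]
            seq[p1 - 4 : p1] = filled
        out.append(ProteinRecord(protein.accession, "".join(seq)))
        truth.substrate_accessions.add(protein.accession)
        truth.true_sites.update((protein.accession, p) for p in placed)
    return out, truth


def sample_attachments(
    protein: ProteinRecord, coupling_prob: float, rng: np.random.Generator
) -> set[int]:
    """Bead-coupled residue positions (1-based).

    CNBr-style coupling acts on primary amines: the protein N-terminus and
    every lysine side chain, each independently with ``coupling_prob``.
    """
    amines = sorted({1} | {i + 1 for i, aa in enumerate(protein.sequence) if aa == "K"})
    return {pos for pos in amines if rng.random() < coupling_prob}


def simulate_release(
    protein: ProteinRecord,
    cut_positions: set[int],
    attachment_positions: set[int],
) -> list[tuple[int, int]]:
    """Fragments that leave the beads after cleavage.

    The chain is partitioned at every cut (cleavage after the P1 residue);
    a fragment is released iff it contains no bead attachment.  Fragments
    are 1-based inclusive ``(start, end)`` intervals in protein coordinates.
    """
    length = len(protein)
    for p in cut_positions:
        if not 1 <= p <= length - 1:
            raise ValueError(f"cut position {p} outside [1, {length - 1}]")
    for a in attachment_positions:
        if not 1 <= a <= length:
            raise ValueError(f"attachment position {a} outside [1, {length}]")
    bounds = [0] + sorted(cut_positions) + [length]
    released = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        start, end = lo + 1, hi
        if not any(start <= a <= end for a in attachment_positions):
            released.append((start, end))
    return released


def _collect_peptides(
    protein: ProteinRecord,
    fragments: list[tuple[int, int]],
    caspase_fragment: list[bool],
    params: SimulationParams,
) -> tuple[Counter, set]:
    """Detectable peptide occurrences of one arm.

    Returns a counter over (sequence, start, end) occurrence keys and the
    subset of keys whose source fragment was produced by a planted cut.
    """
    counts: Counter = Counter()
    from_caspase: set = set()
    for (fs, fe), is_caspase in zip(fragments, caspase_fragment):
        for pep in digest_tryptic(
            protein.sequence[fs - 1 : fe], params.max_missed_cleavages
        ):
            if not params.min_pep_len <= len(pep.sequence) <= params.max_pep_len:
                continue
            start = fs + pep.start_offset
            key = (pep.sequence, start, start + len(pep.sequence) - 1)
            counts[key] += 1
            if is_caspase:
                from_caspase.add(key)
    return counts, from_caspase


def simulate_experiment(params: SimulationParams) -> tuple[QuantTable, GroundTruth]:
    """Run the full synthetic BBC experiment.

    Treated and control arms share the same bead attachments and the same
    background cuts (a paired design: identical beads split into two
    aliquots), so background peptides have a log2 ratio centred at 0 and
    only protease-released material is up-regulated.  Peptide H/L ratios:

    * detected in both arms — occurrence-count ratio times multiplicative
      log-normal noise with sd ``log2_bg_sd`` (in log2 units);
    * detected only in the treated arm (caspase-released) — log2 ratio
      drawn from Normal(log2_sub_mean, log2_sub_sd), capped at +10; the
      control channel of a real experiment bottoms out at a noise floor,
      so "infinite" ratios are finite, large and stochastic;
    * detected only in the control arm (peptides spanning an executed cut)
      — the mirrored treatment, capped at -10.
    """
    params.validate()
    rng_gen, rng_plant, rng_exp, rng_noise = _rng_streams(params.seed, 4)
    proteins = generate_proteome(params, rng_gen)
    proteins, truth = plant_substrates(proteins, params, rng_plant)

    rows: list[QuantifiedPeptide] = []
    for protein in proteins:
        length = len(protein)
        attachments = sample_attachments(protein, params.coupling_prob, rng_exp)
        bond_hits = rng_exp.random(length - 1) < params.background_rate
        bg_cuts = {i + 1 for i in np.flatnonzero(bond_hits)}
        planted = truth.sites_of(protein.accession)
        executed = {p for p in planted if rng_exp.random() < params.cleavage_efficiency}

        control_frags = simulate_release(protein, bg_cuts, attachments)
        treated_frags = simulate_release(protein, bg_cuts | executed, attachments)
        if control_frags:
            truth.background_degraded.add(protein.accession)

        treated_is_caspase = [
            (s - 1 in executed) or (e in executed) for s, e in treated_frags
        ]
        control_counts, _ = _collect_peptides(
            protein, control_frags, [False] * len(control_frags), params
        )
        treated_counts, caspase_keys = _collect_peptides(
            protein, treated_frags, treated_is_caspase, params
        )

        for key in sorted(set(control_counts) | set(treated_counts)):
            seq, start, end = key
            t, c = treated_counts.get(key, 0), control_counts.get(key, 0)
            if t and c:
                log2 = math.log2(t / c) + rng_noise.normal(0.0, params.log2_bg_sd)
            elif t:
                log2 = rng_noise.normal(params.log2_sub_mean, params.log2_sub_sd)
            else:
                log2 = -rng_noise.normal(params.log2_sub_mean, params.log2_sub_sd)
            log2 = float(np.clip(log2, -LOG2_RATIO_CAP, LOG2_RATIO_CAP))
            rows.append(
                QuantifiedPeptide(
                    sequence=seq,
                    accession=protein.accession,
                    start=start,
                    end=end,
                    ratio_hl=2.0 ** log2,
                    log2_ratio=log2,
                    preceding=protein.sequence[start - 2] if start > 1 else TERMINUS,
                    following=protein.sequence[end] if end < length else TERMINUS,
                    caspase_released=key in caspase_keys,
                )
            )

    table = QuantTable(
        rows,
        provenance=(
            f"simulate_experiment(seed={params.seed}, n_proteins={params.n_proteins}, "
            f"substrate_fraction={params.substrate_fraction})"
        ),
    )
    return table, truth
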