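import math

import pytest

from bbcscreen import ProteinRecord, QuantTable, QuantifiedPeptide, SimulationParams, simulate_experiment


def make_row(
    sequence: str,
    accession: str = "P1",
    start: int = 1,
    ratio: float = 4.0,
    preceding: str = "-",
    following: str = "-",
) -> QuantifiedPeptide:
    """Build a valid peptide row without needing a real protein behind it."""
    return QuantifiedPeptide(
        sequence=sequence,
        accession=accession,
        start=start,
        end=start + len(sequence) - 1,
        ratio_hl=ratio,
        log2_ratio=math.log2(ratio),
        preceding=preceding,
        following=following,
    )


def embed(segments: list[str], n_before: int, filler: str = "GASTG") -> str:
    """Concatenate segments after n_before filler residues, plus a short tail."""
    pad = (filler * (n_before // len(filler) + 1))[:n_before]
    return pad + "".join(segments) + "GASTGASTG"


@pytest.fixture(scope="session")
def pak2_like() -> ProteinRecord:
    """Synthetic protein embedding two published caspase-site contexts.

    The window PPEKD.GFPSGTPALNAK.GTEAP is placed so its scissile D is at
    position 148 and SIYTR.SVIDPVPAPVGDSHVD.GAAKS so its C-side D is at
    position 212 — the coordinates under which these PAK2 sites are known.
    """
    pad = ("GASTG" * 29)[:143]                       # positions 1..143
    seq = pad + "PPEKD" + "GFPSGTPALNAK" + "GTEAP"   # D at 148, window to 165
    seq += ("GASTG" * 6)[: 191 - len(seq)]           # filler 166..191
    seq += "SIYTR" + "SVIDPVPAPVGDSHVD" + "GAAKS"    # D at 212, window to 217
    seq += "GASTGASTG"
    assert seq[147] == "D" and seq[211] == "D" and len(seq) == 226
    return ProteinRecord("PAK2_SYN", seq)


@pytest.fixture(scope="session")
def bcas2_like() -> ProteinRecord:
    """Synthetic protein embedding the EVVVD.ALPYFDQGYEAPGVR.EAAAA context at D14."""
    seq = embed(["EVVVD", "ALPYFDQGYEAPGVR", "EAAAA"], n_before=9)
    return ProteinRecord("BCAS2_SYN", seq)


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated experiment, shared across tests."""
    params = SimulationParams()
    table, truth = simulate_experiment(params)
    return params, table, truth


@pytest.fixture()
def tiny_table() -> QuantTable:
    """Hand-countable table: 3 rows, log2 ratios 0.5 / 1.5 / 2.5."""
    return QuantTable(
        [
            make_row("AAAAAAA", "P1", 1, 2 ** 0.5),
            make_row("CCCCCCC", "P2", 1, 2 ** 1.5),
            make_row("DDDDDDD", "P3", 1, 2 ** 2.5),
        ]
    )
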