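"""Cleavage-site extraction, enzyme classes, motif families and PFMs."""

import random
import re

import pytest

from bbcscreen import (
    ProteinRecord,
    SimulationParams,
    build_pfm,
    classify_p1,
    classify_site,
    extract_sites,
    generate_proteome,
    motif_class,
    plant_substrates,
    site_context,
    summarize_sites,
)
from bbcscreen.sites import ASPARTATE, OTHER, TRYPTIC, CleavageSite
from conftest import make_row


class TestClassify:
    @pytest.mark.parametrize(
        "p1,following,expected",
        [
            ("R", "S", TRYPTIC),   # ...SIYTR | SVID... reading
            ("K", "G", TRYPTIC),   # ...ALNAK | GTEAP reading
            ("D", "A", ASPARTATE),  # ...EVVVD | ALPYF reading
            ("D", "G", ASPARTATE),
            ("K", "P", OTHER),     # proline blocks trypsin
            ("R", "P", OTHER),
            ("A", "G", OTHER),
        ],
    )
    def test_enzyme_rules(self, p1, following, expected):
        assert classify_p1(p1, following) == expected

    def test_classify_site_reads_the_context(self, bcas2_like):
        (site,) = extract_sites(
            [make_row("ALPYFDQGYEAPGVR", "BCAS2_SYN", 15, 8.0, "D", "E")],
            {"BCAS2_SYN": bcas2_like},
        )[:1]
        assert classify_site(site) == site.enzyme_class


class TestSiteContext:
    def test_published_context_prefix(self, bcas2_like):
        assert site_context(bcas2_like, 14) == "EVVVD.ALPYF"

    def test_boundary_padding(self):
        protein = ProteinRecord("P1", "MKADGGG")
        assert site_context(protein, 2) == "---MK.ADGGG"
        assert site_context(protein, 6) == "KADGG.G----"

    def test_round_trip_substring_identity(self):
        rng = random.Random(31)
        proteins = generate_proteome(SimulationParams(n_proteins=5, seed=31))
        for protein in proteins:
            pos = rng.randint(1, len(protein) - 1)
            ctx = site_context(protein, pos).replace(".", "").replace("-", "")
            assert ctx in protein.sequence

    def test_out_of_range_rejected(self):
        protein = ProteinRecord("P1", "MKADGGG")
        for pos in (0, 7, 99):
            with pytest.raises(ValueError):
                site_context(protein, pos)


class TestExtractSites:
    def test_terminal_peptide_yields_only_internal_side(self):
        protein = ProteinRecord("P1", "MKADGGGWWK")
        sites = extract_sites([make_row("MKAD", "P1", 1, 8.0, "-", "G")], {"P1": protein})
        assert [(s.position, s.source_terminus) for s in sites] == [(4, "c_side")]
        sites = extract_sites([make_row("GGGWWK", "P1", 5, 8.0, "D", "-")], {"P1": protein})
        assert [(s.position, s.source_terminus) for s in sites] == [(4, "n_side")]

    def test_published_peptide_reads_one_aspartate_and_one_tryptic_site(self, pak2_like):
        sites = extract_sites(
            [make_row("GFPSGTPALNAK", "PAK2_SYN", 149, 5.85, "D", "G")],
            {"PAK2_SYN": pak2_like},
        )
        assert [(s.position, s.p1, s.enzyme_class) for s in sites] == [
            (148, "D", ASPARTATE),
            (160, "K", TRYPTIC),
        ]

    def test_shared_boundary_counted_once(self):
        protein = ProteinRecord("P1", "AAAKCCCKDDDKEEEK")
        peptides = [
            make_row("CCCK", "P1", 5, 8.0, "K", "D"),
            make_row("CCCKDDDK", "P1", 5, 8.0, "K", "E"),
            make_row("AAAKCCCK", "P1", 1, 8.0, "-", "D"),
        ]
        sites = extract_sites(peptides, {"P1": protein})
        positions = [s.position for s in sites]
        assert positions == sorted(set(positions)) == [4, 8, 12]

    def test_shuffled_input_gives_identical_set(self, default_sim):
        params, table, _ = default_sim
        proteome = {
            p.accession: p
            for p in plant_substrates(generate_proteome(params), params)[0]
        }
        passing = [r for r in table if r.log2_ratio >= 1.8]
        forward = extract_sites(passing, proteome)
        shuffled = list(passing)
        random.Random(37).shuffle(shuffled)
        backward = extract_sites(shuffled, proteome)
        assert [(s.accession, s.position, s.enzyme_class) for s in forward] == [
            (s.accession, s.position, s.enzyme_class) for s in backward
        ]

    def test_substring_violation_rejected(self):
        protein = ProteinRecord("P1", "MKADGGG")
        with pytest.raises(ValueError):
            extract_sites([make_row("WWW", "P1", 2, 8.0, "M", "G")], {"P1": protein})


def _aspartate_site(protein, position):
    return extract_sites(
        [
            make_row(
                protein.sequence[position : position + 8],
                protein.accession,
                position + 1,
                8.0,
                protein.sequence[position - 1],
                protein.sequence[position + 8]
                if position + 8 < len(protein)
                else "-",
            )
        ],
        {protein.accession: protein},
    )[0]


class TestMotifClass:
    @pytest.mark.parametrize(
        "p4_p1,family",
        [
            ("DEVD", "DEXD"),
            ("DELD", "DEXD"),
            ("DLND", "DLXD"),
            ("DDAD", "DDXD"),
            ("DQTD", "DXXD"),  # DXXD but no named sub-family
            ("AEVD", None),
            ("DEVA", None),
        ],
    )
    def test_families(self, p4_p1, family):
        seq = "GGGGG" + p4_p1 + "AAAAKGGGGG"
        protein = ProteinRecord("P1", seq)
        site = _aspartate_site(protein, 9)
        if p4_p1.endswith("D"):
            assert site.enzyme_class == ASPARTATE
            assert motif_class(site, protein) == family
            assert site.motif_family == family
        else:
            assert site.enzyme_class != ASPARTATE

    def test_random_4mers_match_regex_oracle(self):
        rng = random.Random(41)
        for _ in range(200):
            p4_p1 = "".join(rng.choice("ADELQVG") for _ in range(3)) + "D"
            protein = ProteinRecord("P1", "GGGGG" + p4_p1 + "AAAAKGGGGG")
            site = _aspartate_site(protein, 9)
            got = motif_class(site, protein)
            assert (got is not None) == bool(re.fullmatch(r"D..D", p4_p1))

    def test_p4_outside_protein_is_none(self):
        protein = ProteinRecord("P1", "GADAAAKGG")
        site = _aspartate_site(protein, 3)
        assert site.position == 3
        assert motif_class(site, protein) is None


class TestPFM:
    def test_single_site_is_a_point_mass(self, bcas2_like):
        site = _aspartate_site(bcas2_like, 14)
        pfm = build_pfm([site])
        for pos, residue in zip(pfm.POSITIONS, site.context.replace(".", "")):
            col = pfm.frequencies[pos]
            assert col[residue] == 1.0
            assert col.sum() == pytest.approx(1.0)

    def test_forced_p1_column(self):
        proteins = [
            ProteinRecord(f"P{i}", "GGGGG" + "DEVD" + "AAAAKGGGGG") for i in range(5)
        ]
        sites = [_aspartate_site(p, 9) for p in proteins]
        pfm = build_pfm(sites)
        assert pfm.frequencies.loc["D", "P1"] == 1.0

    def test_planted_devd_sites_recover_the_motif(self):
        params = SimulationParams(
            n_proteins=120, substrate_fraction=1.0, motif_weights={"DEVD": 1.0}, seed=43
        )
        planted, truth = plant_substrates(generate_proteome(params), params)
        index = {p.accession: p for p in planted}
        sites = []
        for acc, pos in sorted(truth.true_sites):
            if pos >= 8 and pos + 8 < len(index[acc]):
                sites.append(_aspartate_site(index[acc], pos))
        assert len(sites) >= 100
        pfm = build_pfm(sites)
        for pos, residue in zip(["P4", "P3", "P2", "P1"], "DEVD"):
            assert pfm.frequencies[pos].idxmax() == residue

    def test_columns_normalized_and_empty_rejected(self, default_sim):
        params, table, _ = default_sim
        proteome = {
            p.accession: p
            for p in plant_substrates(generate_proteome(params), params)[0]
        }
        sites = extract_sites([r for r in table if r.log2_ratio >= 1.8], proteome)
        pfm = build_pfm(sites)
        assert (abs(pfm.frequencies.sum(axis=0) - 1.0) < 1e-9).all()
        with pytest.raises(ValueError):
            build_pfm([])


class TestSummarize:
    def _site(self, accession, position, p1, following, motif=None):
        left = ("G" * 4 + p1).rjust(5, "-")
        return CleavageSite(
            accession, position, p1,
            classify_p1(p1, following),
            left + "." + (following + "G" * 4).ljust(5, "-"),
            "n_side", motif,
        )

    def test_all_tryptic(self):
        sites = [self._site(f"P{i}", 10 + i, "K", "A") for i in range(4)]
        summary = summarize_sites(sites)
        assert summary.tryptic_fraction == 1.0
        assert summary.n_aspartate == summary.n_other == 0

    def test_mixed_hand_count(self):
        sites = [self._site(f"P{i}", 10 + i, "K", "A") for i in range(8)]
        sites.append(self._site("P8", 20, "D", "A", "DEXD"))
        sites.append(self._site("P9", 21, "K", "P"))
        summary = summarize_sites(sites, called_accessions={f"P{i}" for i in range(10)})
        assert summary.n_sites == 10
        assert (summary.tryptic_fraction, summary.aspartate_fraction, summary.other_fraction) == (
            0.8, 0.1, 0.1,
        )
        assert summary.n_dxxd == summary.n_dexd == 1
        assert summary.n_substrates_with_d_site == 1
        assert summary.substrates_with_d_site_fraction == pytest.approx(0.1)

    def test_class_fractions_partition(self, default_sim):
        params, table, _ = default_sim
        proteome = {
            p.accession: p
            for p in plant_substrates(generate_proteome(params), params)[0]
        }
        sites = extract_sites([r for r in table if r.log2_ratio >= 1.8], proteome)
        summary = summarize_sites(sites)
        assert summary.tryptic_fraction + summary.aspartate_fraction + summary.other_fraction == pytest.approx(1.0)
        assert summary.n_tryptic + summary.n_aspartate + summary.n_other == summary.n_sites
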