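import numpy as np
import pytest

from lucdesign import (
    CodonTable,
    DissectionSite,
    RestrictionSite,
    SequenceRecord,
    ValidationError,
    assemble_expression_insert,
    assemble_pca_probe,
    assemble_strain_probe,
    enzyme,
    find_restriction_sites,
    propose_dissection_sites,
    reverse_translate,
    translate,
)
from lucdesign.seq import RegionAnnotation

from conftest import random_peptide


class TestCodonTable:
    def test_top_codons_are_highest_usage(self, codon_table):
        for aa, entries in codon_table.codons.items():
            fracs = [f for _, f in entries]
            assert fracs == sorted(fracs, reverse=True)
            assert codon_table.top_codon(aa) == entries[0][0]

    def test_every_codon_translates_to_its_residue(self, codon_table):
        for aa, entries in codon_table.codons.items():
            for codon, _ in entries:
                assert translate(codon) == aa
        for stop in codon_table.stops:
            assert translate(stop) == "*"

    def test_unknown_residue_rejected(self, codon_table):
        with pytest.raises(ValidationError):
            codon_table.top_codon("B")


class TestRestrictionSites:
    def test_known_recognition_sequences(self):
        assert enzyme("HindIII").recognition == "AAGCTT"
        assert enzyme("XhoI").recognition == "CTCGAG"
        assert enzyme("KpnI").recognition == "GGTACC"
        assert enzyme("BamHI").recognition == "GGATCC"

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ValidationError, match="unknown enzyme"):
            enzyme("NopeI")

    def test_find_overlapping_occurrences(self):
        site = RestrictionSite("pal", "AAAA")
        hits = find_restriction_sites("CAAAAAG", [site])
        assert hits == [("pal", 2), ("pal", 3)]

    def test_find_on_bad_dna_rejected(self):
        with pytest.raises(ValidationError):
            find_restriction_sites("ACGU", [enzyme("KpnI")])


class TestReverseTranslate:
    def test_round_trip_translation(self, codon_table):
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = random_peptide(rng, 40)
            assert translate(reverse_translate(p, codon_table)) == p

    def test_no_forbidden_is_pure_top_codons(self, codon_table):
        p = "MAGT"
        dna = reverse_translate(p, codon_table)
        assert dna == "".join(codon_table.top_codon(c) for c in p)

    def test_internal_kpni_from_top_codons_is_removed(self, codon_table):
        # top mouse codons for W-Y-Q are TGG TAC CAG: "GGTACC" spans the
        # W/Y junction, so naive reverse translation creates a KpnI site
        naive = "".join(codon_table.top_codon(c) for c in "WYQ")
        assert find_restriction_sites(naive, [enzyme("KpnI")])
        dna = reverse_translate("WYQ", codon_table, forbidden=[enzyme("KpnI")])
        assert not find_restriction_sites(dna, [enzyme("KpnI")])
        assert translate(dna) == "WYQ"

    def test_single_codon_swap_is_minimal(self, codon_table):
        # custom forbidden site GCCGCC == top codons of "AA"; one swap fixes it
        site = RestrictionSite("cust", "GCCGCC")
        dna = reverse_translate("AA", codon_table, forbidden=[site])
        assert not find_restriction_sites(dna, [site])
        codons = [dna[0:3], dna[3:6]]
        assert codons.count("GCC") == 1  # exactly one codon swapped

    def test_unavoidable_site_raises(self, codon_table):
        # tryptophan has a single codon TGG; forbidding it cannot succeed
        site = RestrictionSite("w", "TGGTGG")
        with pytest.raises(ValidationError, match="unavoidable"):
            reverse_translate("WW", codon_table, forbidden=[site])

    def test_fixed_codons_used_verbatim(self, codon_table):
        dna = reverse_translate("GT", codon_table, fixed_codons={0: "GGT", 1: "ACC"})
        assert dna == "GGTACC"

    def test_allowed_occurrence_is_skipped(self, codon_table):
        kpn = enzyme("KpnI")
        dna = reverse_translate(
            "GT",
            codon_table,
            forbidden=[kpn],
            fixed_codons={0: "GGT", 1: "ACC"},
            allowed_occurrences={(0, "GGTACC")},
        )
        assert dna == "GGTACC"

    def test_empty_protein_rejected(self, codon_table):
        with pytest.raises(ValidationError):
            reverse_translate("", codon_table)


class TestExpressionInsert:
    def test_layout_and_round_trip(self, template_194, codon_table):
        c = assemble_expression_insert(template_194, codon_table)
        assert c.dna.startswith("AAGCTT") and c.dna.endswith("CTCGAG")
        # non-Met template gains an initiator methionine
        assert c.protein == "M" + template_194.seq
        assert len(c.dna) == 6 + 3 * (195 + 1) + 6

    def test_flanking_sites_unique(self, template_194, codon_table):
        c = assemble_expression_insert(template_194, codon_table)
        for name in ("HindIII", "XhoI"):
            assert len(find_restriction_sites(c.dna, [enzyme(name)])) == 1

    def test_met_start_not_duplicated(self, codon_table):
        c = assemble_expression_insert(SequenceRecord("m", "MKWLP"), codon_table)
        assert c.protein == "MKWLP"


class TestStrainProbe:
    def test_assembly_bookkeeping(self, template_194, codon_table):
        rng = np.random.default_rng(93)
        pn = SequenceRecord("pn", "M" + random_peptide(rng, 92))
        pc = SequenceRecord("pc", random_peptide(rng, 107))
        layout, c = assemble_strain_probe(pn, template_194, pc, codon_table)
        assert layout.kind == "strain_probe"
        # 93 + GT + 194 + GS + 107 = 398 residues
        assert len(c.protein) == 398
        assert c.protein == pn.seq + "GT" + template_194.seq + "GS" + pc.seq

    def test_internal_junctions_exactly_once(self, template_194, codon_table):
        rng = np.random.default_rng(94)
        pn = SequenceRecord("pn", "M" + random_peptide(rng, 40))
        pc = SequenceRecord("pc", random_peptide(rng, 40))
        _, c = assemble_strain_probe(pn, template_194, pc, codon_table)
        for name in ("KpnI", "BamHI", "HindIII", "XhoI"):
            assert len(find_restriction_sites(c.dna, [enzyme(name)])) == 1

    def test_reporter_with_sp_rejected(self, codon_table):
        rng = np.random.default_rng(95)
        reporter = SequenceRecord(
            "rep", random_peptide(rng, 60), annotations=(RegionAnnotation("SP", 1, 17),)
        )
        pn = SequenceRecord("pn", "MGG")
        pc = SequenceRecord("pc", "GG")
        with pytest.raises(ValidationError, match="secretion peptide"):
            assemble_strain_probe(pn, reporter, pc, codon_table)


class TestDissection:
    def test_coil_between_helices_lower_median(self):
        #          123456789012345
        ss =      "HHHHCCCHHHHHHHH"
        protein = SequenceRecord("p", "A" * 15)
        sites = propose_dissection_sites(protein, ss)
        assert [s.after_residue for s in sites] == [6]  # lower median of 5..7

    def test_terminal_and_strand_flanked_coils_excluded(self):
        ss = "CCHHHCCEEECCHHHCC"
        protein = SequenceRecord("p", "A" * len(ss))
        sites = propose_dissection_sites(protein, ss)
        assert sites == []  # no coil has helices on both sides

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            propose_dissection_sites(SequenceRecord("p", "AAA"), "HHHH")

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValidationError, match="H, E, C"):
            propose_dissection_sites(SequenceRecord("p", "AAA"), "HXH")

    def test_fragment_lengths(self):
        site = DissectionSite(157, 201)
        assert site.n_frag_len == 157 and site.c_frag_len == 44

    def test_invalid_split_rejected(self):
        with pytest.raises(ValidationError):
            DissectionSite(201, 201)
        with pytest.raises(ValidationError):
            DissectionSite(0, 201)


class TestPcaProbe:
    def test_empty_insert_is_reconstitution_identity(self, template_194, codon_table):
        site = DissectionSite(100, 194)
        _, c = assemble_pca_probe(template_194, site, None, codon_table)
        assert c.protein == template_194.seq

    def test_insert_sandwiched_between_fragments(self, template_194, codon_table):
        rng = np.random.default_rng(44)
        insert = SequenceRecord("ins", random_peptide(rng, 30))
        site = DissectionSite(100, 194)
        layout, c = assemble_pca_probe(template_194, site, insert, codon_table)
        expected = (
            template_194.seq[:100] + "GT" + insert.seq + "GS" + template_194.seq[100:]
        )
        assert c.protein == expected
        assert [role for role, _ in layout.parts] == ["n_frag", "insert", "c_frag"]

    def test_wrong_protein_length_rejected(self, template_194, codon_table):
        site = DissectionSite(100, 200)
        with pytest.raises(ValidationError, match="different protein length"):
            assemble_pca_probe(template_194, site, None, codon_table)


class TestNucleotideConstruct:
    def test_orf_properties(self, codon_table):
        c = assemble_expression_insert(SequenceRecord("m", "MAG"), codon_table)
        assert c.orf == c.dna[6:-6]
        assert translate(c.orf).endswith("*")

    def test_manifest_fields(self, codon_table):
        import json

        from lucdesign.constructs import construct_manifest

        c = assemble_expression_insert(SequenceRecord("m", "MAG"), codon_table)
        data = json.loads(construct_manifest(c))
        assert data["protein_length"] == 3
        assert data["orf"] == [7, 7 + 12 - 1]
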