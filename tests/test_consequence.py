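"""Consequence derivation: codon arithmetic, splice outcomes, HGVS naming."""

import pytest

from recgene import consequence as cq
from recgene import simulate
from recgene.model import CdnaPosition, SpliceOutcome, TranscriptModel


class TestCodonIndex:
    @pytest.mark.parametrize("cdna, residue", [
        (1, 1), (3, 1), (4, 2),
        (421, 141), (547, 183), (664, 222), (1372, 458), (1807, 603),
    ])
    def test_codon_arithmetic(self, cdna, residue):
        assert cq.cdna_codon_index(cdna) == residue

    def test_intronic_position_rejected(self):
        with pytest.raises(ValueError, match="intronic"):
            cq.cdna_codon_index(CdnaPosition.parse("940+1"))

    @pytest.mark.parametrize("text, base, offset", [
        ("940+1", 940, 1), ("1461+1", 1461, 1), ("665-2", 665, -2), ("664", 664, 0),
    ])
    def test_cdna_position_parsing(self, text, base, offset):
        pos = CdnaPosition.parse(text)
        assert (pos.base, pos.offset) == (base, offset)


def _toy_model():
    # 3 exons fully coding apart from short UTRs; exon 2 has length 7 (not a
    # multiple of 3) so skipping it shifts the frame
    exon_seqs = ["AAATGGCTGCT", "GCTGCTG", "CTGCTTAAGGG"]
    return TranscriptModel(gene="TOY", strand="+",
                           exons=[(10, 20), (30, 36), (50, 60)],
                           exon_seqs=exon_seqs, cds_start=3, cds_end=26)


class TestApplySpliceOutcome:
    def test_exon_skip_shortens_cds_by_exon_overlap(self):
        m = _toy_model()
        mut = cq.apply_splice_outcome(m, SpliceOutcome(kind="exon_skip", exon_index=2))
        # mutant CDS runs from the original start codon to transcript end
        assert mut == "ATGGCTGCT" + "CTGCTTAAGGG"

    def test_insertion_lengthens_by_inserted_bases(self):
        m = _toy_model()
        ins = "T" * 23
        mut = cq.apply_splice_outcome(
            m, SpliceOutcome(kind="insertion", insert_after=11, inserted_seq=ins))
        ref_tail = m.spliced()[m.cds_start - 1 :]
        assert len(mut) == len(ref_tail) + 23

    def test_skip_of_start_codon_exon_unsupported(self):
        m = _toy_model()
        with pytest.raises(cq.UnsupportedConsequenceError, match="start codon"):
            cq.apply_splice_outcome(m, SpliceOutcome(kind="exon_skip", exon_index=1))

    def test_generated_cases_match_generator_truth_cds(self):
        for seed in range(25):
            model, outcome, _ = simulate.generate_transcript_case(
                seed, exon_count=5, skip_exon=3)
            mut = cq.apply_splice_outcome(model, outcome)
            pc = cq.name_consequence(
                model.cds(), mut, ref_downstream=model.spliced()[model.cds_end:])
            assert pc.category in {"frameshift", "inframe_deletion", "nonsense",
                                   "no_stop_found", "missense"}


def _cds_of(codons):
    return "".join(codons)


class TestNameConsequence:
    def test_identical_sequences_no_change(self):
        cds = _cds_of(["ATG", "GAA", "TGG", "TAA"])
        pc = cq.name_consequence(cds, cds)
        assert pc.category == "no_change" and pc.hgvs_p == "p.="

    def test_single_base_deletion_frameshifts_at_codon_five(self):
        # 12-codon CDS; deleting one base of codon 5 shifts the frame there.
        # Expected values frozen from hand translation:
        #   ref: ATG AAA TTT CTG GAA ATA ACC CAT ATT CCA CGT TAA
        #         M   K   F   L   E   I   T   H   I   P   R   *
        #   mut (drop G of GAA): ...CTG AAA TAA -> M K F L K *  (fs*2)
        ref = _cds_of(["ATG", "AAA", "TTT", "CTG", "GAA", "ATA", "ACC", "CAT",
                       "ATT", "CCA", "CGT", "TAA"])
        mut = ref[:12] + ref[13:]
        pc = cq.name_consequence(ref, mut)
        assert pc.category == "frameshift"
        assert (pc.position, pc.ref_aa, pc.new_aa, pc.stop_offset) == (5, "E", "K", 2)
        assert pc.hgvs_p == "p.E5Kfs*2"

    def test_substitution_to_stop_named_as_nonsense(self):
        # codon 141 GAA -> TAA via a c.421G>T substitution: p.E141X
        codons = ["ATG"] + ["GCT"] * 139 + ["GAA"] + ["TGG"] * 10 + ["TGA"]
        ref = _cds_of(codons)
        mut = cq.apply_cdna_substitution(ref, 421, "G", "T")
        pc = cq.name_consequence(ref, mut)
        assert (pc.category, pc.position, pc.hgvs_p) == ("nonsense", 141, "p.E141X")

    def test_missense_single_and_three_letter_names(self):
        codons = ["ATG"] + ["GCT"] * 220 + ["GGA"] + ["TGG"] * 10 + ["TGA"]
        ref = _cds_of(codons)
        mut = cq.apply_cdna_substitution(ref, 222 * 3 - 2, "G", "A")  # GGA -> AGA
        pc1 = cq.name_consequence(ref, mut)
        pc3 = cq.name_consequence(ref, mut, three_letter=True)
        assert (pc1.category, pc1.hgvs_p) == ("missense", "p.G222R")
        assert pc3.hgvs_p == "p.Gly222Arg"

    def test_inframe_exon_loss_named_as_block_deletion(self):
        # removing codons 3-4 (an in-frame block) keeps the downstream protein
        ref = _cds_of(["ATG", "GCA", "CCG", "AAA", "GCA", "TGG", "TAA"])
        mut = _cds_of(["ATG", "GCA", "GCA", "TGG", "TAA"])
        pc = cq.name_consequence(ref, mut)
        assert pc.category == "inframe_deletion"
        assert pc.position == 3 and pc.hgvs_p == "p.P3_K4del"

    def test_fs_numbering_matches_published_convention(self):
        # frameshift at residue 4 with the stop as the 3rd residue of the new
        # frame: p.K4Rfs*3
        ref = _cds_of(["ATG", "GCA", "CCG", "AAA", "GCA", "CCG", "TGG", "TAA"])
        mut = _cds_of(["ATG", "GCA", "CCG", "AGA", "GCA", "TGA"])
        pc = cq.name_consequence(ref, mut)
        assert pc.category == "frameshift"
        assert pc.position == 4 and pc.stop_offset == 3
        assert pc.hgvs_p == "p.K4Rfs*3"

    def test_no_stop_reported_as_category_not_error(self):
        ref = _cds_of(["ATG", "AAA", "TAA"])
        mut = _cds_of(["ATG", "AGG", "AAG", "AAG"])  # runs off without stop
        pc = cq.name_consequence(ref, mut)
        assert pc.category == "no_stop_found"

    def test_internal_stop_in_reference_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            cq.name_consequence("ATGTAAAAATAA", "ATGTAAAAATAA"[:9])


class TestFrameArithmetic:
    """Skipped-length mod 3 decides frameshift vs in-frame deletion."""

    @pytest.mark.parametrize("seed", range(40))
    def test_dichotomy_on_generated_skips(self, seed):
        model, outcome, truth = simulate.generate_transcript_case(
            seed, exon_count=6, skip_exon=3)
        lens = model.exon_lengths_tx_order()
        skipped = lens[outcome.exon_index - 1]
        if skipped % 3 == 0:
            assert truth.category in {"inframe_deletion", "nonsense", "no_change"}
        else:
            # a shifted frame; when the very first shifted codon is a stop the
            # change is named as a nonsense substitution at that residue
            assert truth.category in {"frameshift", "nonsense", "no_stop_found"}
        mut = cq.apply_splice_outcome(model, outcome)
        pc = cq.name_consequence(
            model.cds(), mut, ref_downstream=model.spliced()[model.cds_end:])
        assert (pc.category, pc.position, pc.stop_offset) == (
            truth.category, truth.position, truth.stop_offset)


class TestHgvsRoundTrip:
    @pytest.mark.parametrize("hgvs, expected", [
        ("p.=", ("no_change", None, None)),
        ("p.G222R", ("missense", 222, None)),
        ("p.E141X", ("nonsense", 141, None)),
        ("p.R603X", ("nonsense", 603, None)),
        ("p.R288Gfs*7", ("frameshift", 288, 7)),
        ("p.I488Lfs*11", ("frameshift", 488, 11)),
        ("p.A5del", ("inframe_deletion", 5, None)),
        ("p.A5_G7del", ("inframe_deletion", 5, None)),
        ("p.K4fs*?", ("no_stop_found", 4, None)),
    ])
    def test_parse_known_forms(self, hgvs, expected):
        assert cq.parse_hgvs_p(hgvs) == expected

    @pytest.mark.parametrize("seed", range(60))
    def test_emitted_names_parse_back(self, seed):
        if seed % 2:
            model, outcome, _ = simulate.generate_transcript_case(
                seed, exon_count=5, skip_exon=3)
        else:
            model, outcome, _ = simulate.generate_transcript_case(
                seed, exon_count=5, insert_len=(seed % 30) + 1)
        mut = cq.apply_splice_outcome(model, outcome)
        pc = cq.name_consequence(
            model.cds(), mut, ref_downstream=model.spliced()[model.cds_end:])
        if pc.category == "no_change":
            return
        category, position, stop_offset = cq.parse_hgvs_p(pc.hgvs_p)
        assert category == pc.category
        assert position == pc.position
        assert stop_offset == pc.stop_offset
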