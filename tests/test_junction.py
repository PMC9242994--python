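import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circtrans.circorf import CircRNA
from circtrans.junction import (
    FilterReport,
    JunctionProtein,
    PSMRecord,
    build_junction_db,
    check_modifications,
    cleavage_sites,
    digest_trypsin,
    filter_psms,
    junction_residue_stats,
    junction_translations,
    linear_control_peptides,
    min_mismatch_ungapped,
    parse_modifications,
    read_junction_fasta,
    read_psm_tsv,
    spectra_summaries,
    write_junction_fasta,
    write_psm_tsv,
)


# AAAK AAAA AA repeated around the junction: one tryptic peptide spans the
# junction with 6 residues left and 4 right of it (frame 0 of this circle).
TOY_CIRCLE = "GCTGCTGCTAAAGCTGCTGCTGCTGCTGCT"  # codes AAAKAAAAAA, L=30


class TestJunctionTranslations:
    def test_three_records(self):
        assert len(junction_translations(TOY_CIRCLE, "toy")) == 3

    def test_stop_bounded_frame(self):
        # stops two codons either side of the junction in frame 0
        seq = "GCT" * 2 + "TAA" + "GCT" * 4 + "TAA" + "GCT" * 2
        jp = junction_translations(seq, "c")[0]
        assert len(jp.sequence) <= 7
        assert 0 <= jp.junction_pos <= len(jp.sequence)

    def test_stop_free_circle_capped_at_one_circle_per_side(self):
        seq = "GCT" * 12  # 36 nt, no stops anywhere in frame 0
        jp = junction_translations(seq, "c")[0]
        assert len(jp.sequence) == 24  # 12 codons per side
        assert jp.junction_pos == 12

    def test_junction_position_marks_spanning_codon(self):
        jp0 = junction_translations(TOY_CIRCLE, "toy")[0]
        # frame 0, L % 3 == 0: junction falls between codons
        assert jp0.sequence[jp0.junction_pos - 1 : jp0.junction_pos + 1] == "AA"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            junction_translations("ACGTA", "c")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            junction_translations("ACGTN" * 6, "c")


class TestDigest:
    def test_fully_cleaved_and_one_missed(self):
        peps = digest_trypsin("AAAAKCCCCR", max_missed=1, min_len=1)
        seqs = {(p.sequence, p.missed_cleavages) for p in peps}
        assert seqs == {("AAAAK", 0), ("CCCCR", 0), ("AAAAKCCCCR", 1)}

    def test_no_cut_sites(self):
        peps = digest_trypsin("AAAAAAAA", min_len=1)
        assert [(p.sequence, p.missed_cleavages) for p in peps] == [("AAAAAAAA", 0)]

    def test_proline_suppression(self):
        peps = digest_trypsin("AAKPAAR", max_missed=0, min_len=1)
        assert [p.sequence for p in peps] == ["AAKPAAR"]

    def test_min_len_filter(self):
        peps = digest_trypsin("AAAAKCCCCR", max_missed=0, min_len=8)
        assert peps == []

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            digest_trypsin("")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_reconstruction_identity(self, protein):
        """0-missed fragments concatenate to the protein; every k-missed
        peptide is the concatenation of k+1 consecutive 0-missed fragments."""
        full = digest_trypsin(protein, max_missed=4, min_len=1)
        zero = [p for p in full if p.missed_cleavages == 0]
        assert "".join(p.sequence for p in sorted(zero, key=lambda p: p.start)) == protein
        frags = sorted(zero, key=lambda p: p.start)
        for pep in full:
            k = pep.missed_cleavages
            run = [f for f in frags if pep.start <= f.start and f.end <= pep.end]
            assert len(run) == k + 1
            assert "".join(f.sequence for f in run) == pep.sequence


class TestBuildJunctionDb:
    def test_toy_spanning_peptide(self):
        db = build_junction_db([CircRNA("toy", TOY_CIRCLE)])
        rec = db.by_sequence.get("AAAAAAAAAK")
        assert rec is not None
        assert rec.junction_offset == 6
        assert rec.left_flank_aa == 6 and rec.right_flank_aa == 4
        assert ("toy", 0) in rec.sources

    def test_flank_and_length_rules_enforced(self):
        db = build_junction_db([CircRNA("toy", TOY_CIRCLE)])
        for rec in db.records:
            assert rec.left_flank_aa >= 2
            assert rec.right_flank_aa >= 2
            assert len(rec.sequence) >= 8
            assert rec.missed_cleavages <= 3
            # independent recheck: internal K/R sites of the peptide
            assert len(cleavage_sites(rec.sequence)) == rec.missed_cleavages
            assert rec.left_flank_aa + rec.right_flank_aa == len(rec.sequence)

    def test_thin_flank_excluded(self):
        # K right before the junction; the fully cleaved spanning peptide
        # would carry a 1-residue left flank and must not be in the db
        circle = "GCT" * 8 + "AAA"  # protein ...AAAK|AAA..., junction after K
        db = build_junction_db([CircRNA("c", circle)])
        for rec in db.records:
            assert rec.left_flank_aa >= 2 and rec.right_flank_aa >= 2

    def test_empty_input(self):
        assert len(build_junction_db([])) == 0

    def test_fasta_round_trip(self, tmp_path):
        db = build_junction_db([CircRNA("toy", TOY_CIRCLE)])
        path = tmp_path / "db.fa"
        write_junction_fasta(db, path)
        back = read_junction_fasta(path)
        assert len(back) == len(db)
        for rec in db.records:
            got = back.by_sequence[rec.sequence]
            assert got.junction_offset == rec.junction_offset
            assert got.sources[0] == rec.sources[0]
            assert got.missed_cleavages == rec.missed_cleavages


class TestModifications:
    def test_whitelisted(self):
        assert check_modifications("MCDEFSTY", [(0, "Acetyl"), (1, "Carbamidomethyl")]) is None
        assert check_modifications("MCDEFSTY", [(0, "Oxidation"), (5, "Phospho")]) is None

    def test_rejections(self):
        assert check_modifications("MCDEF", [(1, "TMT")]) is not None
        assert check_modifications("MCDEF", [(3, "Oxidation")]) is not None  # not on M
        assert check_modifications("QCDEF", [(2, "Pyro-Glu")]) is not None  # not N-term
        assert check_modifications("MCDEF", [(9, "Oxidation")]) is not None  # out of range
        assert check_modifications("MCDEF", None) is not None  # malformed upstream

    def test_parse_malformed(self):
        with pytest.raises(ValueError):
            parse_modifications("badtoken")
        assert parse_modifications("-") == []
        assert parse_modifications("3:Oxidation;0:Acetyl") == [(3, "Oxidation"), (0, "Acetyl")]


def _psm(sid, pep, q=0.001, mods=(), sample="s1", frags=(("b", 2), ("y", 2))):
    return PSMRecord(
        spectrum_id=sid,
        peptide=pep,
        q_value=q,
        modifications=list(mods),
        sample_id=sample,
        fragments=list(frags),
    )


class TestFilterPsms:
    REF = {"ref1": "MMMMWWWWAAAACCCCDDDDEEEE", "ref2": "GGGGHHHHFFFFSSSS"}
    INDEX = {
        "NQDEFGHW": 4,
        "WAAAACCC": 4,  # exact substring of ref1
        "WAAGACCC": 4,  # 2 substitutions from ref1 window
        "NQDEFGHT": 4,
    }

    def test_q_threshold(self):
        psms = [_psm("a", "NQDEFGHW", q=0.02)]
        surviving, rep = filter_psms(psms, self.REF, self.INDEX)
        assert surviving == []
        assert rep.steps[0] == ("thresholds", 1, 0)

    def test_exact_reference_match_removed_at_step_1(self):
        psms = [_psm("a", "WAAAACCC")]
        _, rep = filter_psms(psms, self.REF, self.INDEX)
        assert rep.steps[0][2] == 1  # passed thresholds
        assert rep.steps[1] == ("known_protein", 1, 0)

    def test_two_mismatch_removed_at_step_2(self):
        psms = [_psm("a", "WAAGACCC")]
        _, rep = filter_psms(psms, self.REF, self.INDEX)
        assert rep.steps[1][2] == 1
        assert rep.steps[2] == ("homology", 1, 0)

    def test_one_sided_ions_removed_retained_with_both(self):
        one_sided = _psm("a", "NQDEFGHW", frags=[("b", 1), ("b", 2)])
        both = _psm("b", "NQDEFGHT", frags=[("b", 2), ("y", 2)])
        surviving, rep = filter_psms([one_sided, both], self.REF, self.INDEX)
        assert [p.spectrum_id for p in surviving] == ["b"]
        assert rep.steps[3] == ("fragment_ions", 2, 1)

    def test_peptide_not_in_index_removed(self):
        psms = [_psm("a", "ZZZZZZZZ")]
        surviving, _ = filter_psms(psms, self.REF, self.INDEX)
        assert surviving == []

    def test_short_peptide_and_thin_flank(self):
        index = dict(self.INDEX, SHORTPE=3, NQDEFGHX=1)
        short = _psm("a", "SHORTPE", frags=[("b", 1), ("y", 1)])
        thin = _psm("b", "NQDEFGHX", frags=[("y", 2)])
        surviving, rep = filter_psms([short, thin], self.REF, index)
        assert surviving == []
        assert rep.steps[0] == ("thresholds", 2, 0)

    def test_missed_cleavage_limit(self):
        index = dict(self.INDEX, AKAKAKAKDW=5)
        psms = [_psm("a", "AKAKAKAKDW", frags=[("b", 4), ("y", 4)])]
        surviving, _ = filter_psms(psms, self.REF, index)
        assert surviving == []

    def test_il_equivalence(self):
        # reference has LLLL; peptide with IIII folds onto it
        ref = {"r": "WWWWLLLLGGGG"}
        index = {"WWIIIIGG": 4}
        psms = [_psm("a", "WWIIIIGG")]
        surviving, rep = filter_psms(psms, ref, index)
        assert surviving == []
        surviving, _ = filter_psms(psms, ref, index, il_equivalent=False, max_mismatch=2)
        # 4 mismatches without folding -> survives homology, dies nowhere
        assert len(surviving) == 1

    def test_report_monotone_validation(self):
        with pytest.raises(ValueError):
            FilterReport([("a", 5, 6)])
        with pytest.raises(ValueError):
            FilterReport([("a", 5, 3), ("b", 4, 2)])


class TestMinMismatch:
    def test_exact(self):
        assert min_mismatch_ungapped("AAA", "GGAAAGG") == 0

    def test_two(self):
        assert min_mismatch_ungapped("ACA", "GGAAAGG") == 1
        assert min_mismatch_ungapped("CCC", "GGAAAGG") == 3

    def test_peptide_longer_than_protein(self):
        assert min_mismatch_ungapped("AAAA", "AA") == 4


class TestPsmTsv:
    def test_round_trip(self, tmp_path):
        psms = [
            _psm("s1", "NQDEFGHW", mods=[(0, "Acetyl")]),
            _psm("s2", "NQDEFGHT", frags=[("y", 3)]),
        ]
        path = tmp_path / "psms.tsv"
        write_psm_tsv(psms, path)
        back = read_psm_tsv(path)
        assert [p.spectrum_id for p in back] == ["s1", "s2"]
        assert back[0].modifications == [(0, "Acetyl")]
        assert back[1].fragments == [("y", 3)]

    def test_malformed_modifications_marked(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text(
            "spectrum_id\tpeptide\tq_value\tmodifications\tsample_id\tmatched_ions\n"
            "s1\tNQDEFGHW\t0.001\tgarbage\ts\tb2;y2\n"
        )
        back = read_psm_tsv(path)
        assert back[0].modifications is None
        assert back[0].mod_error
        surviving, _ = filter_psms(back, {"r": "WWWW"}, {"NQDEFGHW": 4})
        assert surviving == []

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text("spectrum_id\tpeptide\n")
        with pytest.raises(ValueError):
            read_psm_tsv(path)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            _psm("s", "NQDEFGHW", q=1.5)

    def test_invalid_fragment_rejected(self):
        with pytest.raises(ValueError):
            _psm("s", "NQDEFGHW", frags=[("b", 8)])


class TestLinearControls:
    EXONS = ["GCTGCTGCTAAA", "GCTGCTGCTGCTGCTAAA", "GCTGCTGCTGCT"]

    def test_three_exon_toy_has_both_junctions(self):
        peps = linear_control_peptides(self.EXONS, 2, 2)
        assert peps  # both adjacent junctions contribute
        for rec in peps:
            assert rec.left_flank_aa >= 2 and rec.right_flank_aa >= 2
            assert len(rec.sequence) >= 8
            assert rec.missed_cleavages <= 3
        sides = {rec.sources[0][0] for rec in peps}
        assert sides <= {"linear_5prime", "linear_3prime"}
        assert len(sides) == 2

    def test_single_exon_host_empty(self):
        assert linear_control_peptides(["GCT" * 10], 1, 1) == []

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            linear_control_peptides(self.EXONS, 3, 2)


class TestSummaries:
    def test_residue_stats(self):
        jps = [
            JunctionProtein("a", 0, "AAKAAA", 3),   # K at -1
            JunctionProtein("b", 0, "AAAAAA", 3),   # no K/R anywhere
            JunctionProtein("c", 0, "RAAAAA", 1),   # R at -1
            JunctionProtein("d", 0, "AARAAA", 4),   # R present, not at -1
        ]
        frac_minus1, frac_any = junction_residue_stats(jps)
        assert frac_minus1 == pytest.approx(2 / 4)
        assert frac_any == pytest.approx(3 / 4)

    def test_boundary_junction_skipped(self):
        jps = [JunctionProtein("a", 0, "AAAA", 0), JunctionProtein("b", 0, "AAKA", 2)]
        frac_minus1, frac_any = junction_residue_stats(jps)
        assert frac_minus1 == 0.0
        assert frac_any == 1.0

    def test_spectra_summaries(self):
        db = build_junction_db([CircRNA("toy", TOY_CIRCLE)])
        pep = db.records[0].sequence
        j = db.records[0].junction_offset
        n = len(pep)
        frags = [("b", max(1, j - 1)), ("y", max(1, n - j - 1))]
        psms = [
            _psm("s1", pep, sample="x", frags=frags),
            _psm("s2", pep, sample="x", frags=frags),
            _psm("s3", pep, sample="y", frags=frags),
        ]
        table = spectra_summaries(psms, db)
        assert len(table) == 1
        assert table.loc[0, "spectra"] == 3
        assert table.loc[0, "samples"] == 2

    def test_spectra_summaries_empty(self):
        db = build_junction_db([CircRNA("toy", TOY_CIRCLE)])
        table = spectra_summaries([], db)
        assert table.empty
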