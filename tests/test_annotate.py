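"""Frame classification, translation, segment assignment, decomposition."""

import numpy as np
import pytest

from tcrrep.annotate import (
    AlignParams,
    UnassignableError,
    annotate_sample,
    assign_segments,
    classify_frame,
    decompose_junction,
    translate_junction,
)
from tcrrep.simulate import preset_config, simulate_repertoire
from tcrrep.types import GermlineSegment


class TestClassifyFrame:
    @pytest.mark.parametrize(
        "nt,expected",
        [
            ("TGTGCCAGCAGTGGGACAGGGAGTACTGAAGCTTTTTCC", "in_frame"),  # 39 nt, no stop
            ("TGTGCCAGCAGTGGGACAGGGAGTACTGAAGCTTTTTCCA", "oof_frameshift"),  # 40 nt
            ("TGTGCCAGCAGTTAAACAGGGAGTACTGAAGCTTTTTCC", "oof_stop"),  # TAA codon 5
            ("TGT", "in_frame"),
            ("TGTTAA", "oof_stop"),
            ("TGTTA", "oof_frameshift"),  # frameshift takes precedence
        ],
    )
    def test_frame_rule(self, nt, expected):
        assert classify_frame(nt) == expected

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_frame("TGTNCC")
        with pytest.raises(ValueError):
            classify_frame("")


class TestTranslateJunction:
    def test_standard_code(self):
        assert translate_junction("TGTGCCAGCTTT") == "CASF"

    def test_stop_rendered_as_star(self):
        assert translate_junction("TGTTAAGCC") == "C*A"

    def test_frameshift_untranslatable(self):
        assert translate_junction("TGTGCCAGCT") is None

    def test_in_frame_never_contains_stop(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            nt = "".join(rng.choice(list("ACGT"), size=3 * rng.integers(2, 15)))
            if classify_frame(nt) == "in_frame":
                assert "*" not in translate_junction(nt)


def _toy_germline():
    return [
        GermlineSegment("TRBV_A", "V", "TGTGCCAGCAGTTAC", anchor_offset=0),
        GermlineSegment("TRBV_B", "V", "TGTGCCAGCAGTTAC", anchor_offset=0),
        GermlineSegment("TRBD_1", "D", "GGGACAGGGGGC"),
        GermlineSegment("TRBJ_1", "J", "AACACTGAAGCTTTCGGA", anchor_offset=12),
    ]


class TestAssignSegments:
    def test_identical_v_sequences_tie_break_lexicographic(self):
        g = _toy_germline()
        read = "TGTGCCAGCAGTTACGGAACACTGAAGCTTTC"
        asn = assign_segments(read, g)
        assert asn.v_call == "TRBV_A"

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            assign_segments("", _toy_germline())

    def test_too_short_terminal_match_unassignable(self):
        g = _toy_germline()
        with pytest.raises(UnassignableError):
            assign_segments("AAAAAAAAAAAAAAAAAAAAAA", g)

    def test_simulator_truth_recovered_when_d_retained(self, germline, germline_by_name):
        cfg = preset_config("control", germline, seed=8, n_clones=300, n_reads=3000)
        sample, truth = simulate_repertoire(cfg, "s", "control")
        by_nt = {}
        for r in truth.itertuples():
            by_nt.setdefault(r.cdr3_nt, r)
        checked = 0
        for rec in sample.clonotypes:
            t = by_nt[rec.cdr3_nt]
            d_retained = len(germline_by_name[t.d_call].sequence) - t.del_d5 - t.del_d3
            v_ret = len(germline_by_name[t.v_call].junction_region) - t.del_v3
            j_ret = len(germline_by_name[t.j_call].junction_region) - t.del_j5
            if v_ret < 8 or j_ret < 8 or d_retained < 5:
                continue  # only comfortably identifiable clones for this check
            asn = assign_segments(rec.cdr3_nt, germline)
            assert asn.v_call == t.v_call
            assert asn.j_call == t.j_call
            checked += 1
        assert checked > 100


class TestDecomposeJunction:
    def test_full_segments_with_known_insertions(self):
        g = _toy_germline()
        by_name = {s.name: s for s in g}
        v = by_name["TRBV_A"].junction_region
        d = by_name["TRBD_1"].sequence
        j = by_name["TRBJ_1"].junction_region
        read = v + "TT" + d + "A" + j  # GC-poor insertions cannot extend blocks
        asn = assign_segments(read, g)
        dec = decompose_junction(read, asn, by_name)
        assert (dec.del_v3, dec.del_d5, dec.del_d3, dec.del_j5) == (0, 0, 0, 0)
        assert (dec.ins_vd_seq, dec.ins_dj_seq) == ("TT", "A")

    def test_trimmed_d_below_threshold_reports_merged(self):
        g = _toy_germline()
        by_name = {s.name: s for s in g}
        v = by_name["TRBV_A"].junction_region
        j = by_name["TRBJ_1"].junction_region
        read = v + "TT" + "AC" + "TA" + j  # middle has no >=3 nt D match
        asn = assign_segments(read, g, AlignParams(min_d_match=3))
        dec = decompose_junction(read, asn, by_name)
        assert not dec.d_identified
        assert dec.merged_ins_seq == "TTACTA"

    def test_pure_deletion_no_insertion(self):
        g = _toy_germline()
        by_name = {s.name: s for s in g}
        v = by_name["TRBV_A"].junction_region
        j = by_name["TRBJ_1"].junction_region
        # trim so the bases flanking the join differ from the trimmed
        # germline continuation (the boundary is then unambiguous)
        read = v[:-3] + j[2:]
        asn = assign_segments(read, g)
        dec = decompose_junction(read, asn, by_name)
        assert (dec.del_v3, dec.del_j5) == (3, 2)
        assert not dec.d_identified
        assert dec.merged_ins_seq == ""


def _conserved(rec, by_name):
    j = rec.junction
    v_ret = len(by_name[rec.v_call].junction_region) - j.del_v3
    j_ret = len(by_name[rec.j_call].junction_region) - j.del_j5
    if j.d_identified:
        d_ret = len(by_name[rec.d_call].sequence) - j.del_d5 - j.del_d3
        total = v_ret + len(j.ins_vd_seq) + d_ret + len(j.ins_dj_seq) + j_ret
    else:
        total = v_ret + len(j.merged_ins_seq) + j_ret
    return total == len(rec.cdr3_nt)


class TestAnnotateSample:
    @pytest.mark.parametrize("mode", ["greedy", "posterior"])
    def test_length_conservation_holds_for_every_clonotype(self, germline, germline_by_name, mode):
        cfg = preset_config("control", germline, seed=4, n_clones=800, n_reads=8000)
        sample, _ = simulate_repertoire(cfg, "s", "control")
        ann, summary = annotate_sample(sample, germline, boundary_mode=mode, seed=2)
        checked = 0
        for rec in ann.clonotypes:
            if rec.junction is None:
                continue
            assert _conserved(rec, germline_by_name)
            checked += 1
        assert checked > 700

    def test_annotation_deterministic(self, germline):
        cfg = preset_config("AT", germline, seed=6, n_clones=300, n_reads=3000)
        sample, _ = simulate_repertoire(cfg, "s", "AT")
        a1, _ = annotate_sample(sample, germline, boundary_mode="posterior", seed=5)
        a2, _ = annotate_sample(sample, germline, boundary_mode="posterior", seed=5)
        assert [(c.key, c.junction) for c in a1.clonotypes] == [
            (c.key, c.junction) for c in a2.clonotypes
        ]

    def test_unassignable_counted_not_fatal(self, germline):
        from conftest import make_sample

        sample = make_sample([("AAATTTAAATTTAAATTTAAA", "x", "y", 1)])
        ann, summary = annotate_sample(sample, germline, seed=0)
        assert summary.n_unassignable == 1
        assert ann.clonotypes[0].junction is None
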