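"""Length spectra, amino-acid composition, and insertion nucleotide content."""

import numpy as np
import pytest

from conftest import make_clonotype, make_sample
from tcrrep.composition import (
    cdr3_length_distribution,
    indel_length_distributions,
    insertion_gc_content,
    position_aa_composition,
    y_index,
)
from tcrrep.types import JunctionDecomposition, RepertoireSample

NT36 = "TGTGCCAGCAGTGGGACAGGGGGCAGTACTGAAGCT"
NT42 = "TGTGCCAGCAGTGGGACAGGGGGCAGTACTGAAGCTACTGCT"


class TestCdr3LengthDistribution:
    def test_unique_weighting_counts_each_clone_once(self):
        s = make_sample([(NT36, "V1", "J1", 9), (NT42, "V1", "J2", 1)])
        d = cdr3_length_distribution(s, "all", "unique")
        assert d.histogram == {36: 0.5, 42: 0.5}
        assert d.mean == pytest.approx(39.0)

    def test_total_weighting_uses_read_counts(self):
        s = make_sample([(NT36, "V1", "J1", 9), (NT42, "V1", "J2", 1)])
        d = cdr3_length_distribution(s, "all", "total")
        assert d.mean == pytest.approx(36.6)

    def test_empty_frame_subset_errors(self):
        s = make_sample([(NT36 + "A", "V1", "J1", 1)])  # frameshift only
        with pytest.raises(ValueError):
            cdr3_length_distribution(s, "in_frame", "unique")

    def test_masses_sum_to_one_and_mean_consistent(self, germline):
        from tcrrep.simulate import preset_config, simulate_repertoire

        s, _ = simulate_repertoire(
            preset_config("ICF1", germline, seed=3, n_clones=400, n_reads=4000), "x", "ICF1"
        )
        for subset in ("all", "in_frame", "out_of_frame"):
            for weighting in ("unique", "total"):
                d = cdr3_length_distribution(s, subset, weighting)
                assert sum(d.histogram.values()) == pytest.approx(1.0, abs=1e-9)
                assert d.mean == pytest.approx(
                    sum(k * v for k, v in d.histogram.items()), abs=1e-9
                )


def _with_junction(nt, v, j, reads, junction):
    rec = make_clonotype(nt, v, j, reads=reads)
    rec.junction = junction
    return rec


class TestIndelDistributions:
    def test_decomposition_bookkeeping(self):
        j1 = JunctionDecomposition(
            del_v3=0, del_j5=0, del_d5=0, del_d3=0,
            ins_vd_seq="GG", ins_dj_seq="T", d_identified=True,
        )
        j2 = JunctionDecomposition(del_v3=2, del_j5=1, d_identified=False, merged_ins_seq="ACGT")
        recs = [
            _with_junction(NT36, "V1", "J1", 1, j1),
            _with_junction(NT42, "V1", "J2", 1, j2),
        ]
        s = RepertoireSample("s", "g", recs)
        out = indel_length_distributions(s)
        assert out["ins_vd"].histogram == {2: 1.0}
        assert out["ins_dj"].histogram == {1: 1.0}
        # total N length includes the merged insertion of the D-ambiguous clone
        assert out["total_n_length"].histogram == {3: 0.5, 4: 0.5}

    def test_all_d_ambiguous_emits_only_total(self):
        j = JunctionDecomposition(del_v3=1, del_j5=1, d_identified=False, merged_ins_seq="AC")
        s = RepertoireSample("s", "g", [_with_junction(NT36, "V1", "J1", 1, j)])
        out = indel_length_distributions(s)
        assert out["ins_vd"] is None and out["del_d5"] is None
        assert out["total_n_length"].mean == pytest.approx(2.0)

    def test_recovers_generator_insertion_mean(self, germline):
        # averaged over three independent repertoires to tame generator noise
        from tcrrep.annotate import annotate_sample
        from tcrrep.simulate import preset_config, simulate_repertoire

        means_vd, means_dj = [], []
        for seed in (0, 1, 2):
            s, _ = simulate_repertoire(
                preset_config("control", germline, seed=seed, n_clones=5000, n_reads=50000),
                "x", "control",
            )
            ann, _ = annotate_sample(s, germline, boundary_mode="posterior", seed=7)
            out = indel_length_distributions(ann)
            means_vd.append(out["ins_vd"].mean)
            means_dj.append(out["ins_dj"].mean)
        assert np.mean(means_vd) == pytest.approx(4.5, abs=0.2)
        assert np.mean(means_dj) == pytest.approx(4.5, abs=0.2)


class TestYIndex:
    def test_single_clone(self):
        s = make_sample([("TGTGCCAGCAGTTAC", "V1", "J1", 1)])  # CASSY
        assert s.clonotypes[0].cdr3_aa == "CASSY"
        assert y_index(s) == pytest.approx(0.2)

    def test_no_tyrosine(self):
        s = make_sample([("TGTGCCAGCAGTTTT", "V1", "J1", 1), ("TGTGCCAGCAGTCTG", "V1", "J2", 1)])
        assert y_index(s) == 0.0

    def test_total_weighting(self):
        # CAYYA (3 reads) and CAAAA (1 read): (3*2 + 0) / (4*5) = 0.3
        s = make_sample([("TGTGCCTACTACGCC", "V1", "J1", 3), ("TGTGCCGCCGCCGCA", "V1", "J2", 1)])
        assert s.clonotypes[0].cdr3_aa == "CAYYA"
        assert y_index(s, weighting="total") == pytest.approx(0.3)

    def test_stop_symbol_never_counts(self):
        s = make_sample([("TGTTACTAA", "V1", "J1", 1)])  # CY*
        assert y_index(s, include_stop_clones=True) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            y_index(s, include_stop_clones=False)


class TestPositionComposition:
    def test_one_based_position_lookup(self):
        nt = "TGTGCCAGCAGTCTGGACAGGGGCAACACTGAAGCTTTC"
        s = make_sample([(nt, "V1", "J1", 1)])
        aa = s.clonotypes[0].cdr3_aa
        assert len(aa) == 13
        dist, _ = position_aa_composition(s, 6)
        assert dist == {aa[5]: 1.0}

    def test_hydrophobic_fraction(self):
        # two 13-mers, position 6 residues L (hydrophobic) and D (not)
        nt_l = "TGTGCCAGCAGTCTGCTGGACGGCAACACTGAAGCTTTC"
        nt_d = "TGTGCCAGCAGTCTGGACGACGGCAACACTGAAGCTTTC"
        sl = make_sample([(nt_l, "V1", "J1", 1)])
        assert position_aa_composition(sl, 6)[1] == 1.0
        s2 = make_sample([(nt_l, "V1", "J1", 1), (nt_d, "V1", "J2", 1)])
        dist, hydro = position_aa_composition(s2, 6)
        assert sum(dist.values()) == pytest.approx(1.0)
        assert hydro == pytest.approx(0.5)

    def test_no_13mers_errors(self):
        s = make_sample([(NT36, "V1", "J1", 1)])  # 12 residues
        with pytest.raises(ValueError):
            position_aa_composition(s, 6)


class TestInsertionGc:
    def test_pure_gc_and_pure_at(self):
        j_gc = JunctionDecomposition(0, 0, 0, 0, "GG", "CC", True)
        j_at = JunctionDecomposition(0, 0, 0, 0, "AA", "TT", True)
        s_gc = RepertoireSample("a", "g", [_with_junction(NT36, "V1", "J1", 1, j_gc)])
        s_at = RepertoireSample("b", "g", [_with_junction(NT36, "V1", "J1", 1, j_at)])
        assert insertion_gc_content(s_gc)[0] == 1.0
        assert insertion_gc_content(s_at)[0] == 0.0

    def test_no_insertions_returns_absent(self):
        j = JunctionDecomposition(0, 0, d_identified=False, merged_ins_seq="")
        s = RepertoireSample("a", "g", [_with_junction(NT36, "V1", "J1", 1, j)])
        gc, comp = insertion_gc_content(s)
        assert gc is None and comp == {}

    def test_simulated_gc_tracks_configured_bias(self, germline):
        from tcrrep.annotate import annotate_sample
        from tcrrep.simulate import preset_config, simulate_repertoire

        s, _ = simulate_repertoire(
            preset_config("control", germline, seed=9, n_clones=3000, n_reads=30000), "x", "control"
        )
        ann, _ = annotate_sample(s, germline, seed=3)
        gc, comp = insertion_gc_content(ann)
        n_bases = sum(
            len(x)
            for c in ann.clonotypes
            if c.junction
            for x in (c.junction.ins_vd_seq, c.junction.ins_dj_seq, c.junction.merged_ins_seq)
            if x
        )
        se = np.sqrt(0.6 * 0.4 / n_bases)
        assert abs(gc - 0.6) < 3 * se + 0.01  # small allowance for boundary resolution noise
        assert sum(comp.values()) == pytest.approx(1.0)
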