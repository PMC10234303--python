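import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutaccum import genome_context as gcm
from tests._oracles import brute_trinuc_tally, regex_homopolymers, revcomp_str

from tests.conftest import write_bed, write_fasta


class TestLoadAnnotation:
    def test_euchromatin_is_complement_of_marked_domains(self, tmp_path):
        write_fasta(tmp_path / "g.fa", {"c": "A" * 1000})
        write_bed(tmp_path / "k9.bed", [("c", 200, 400)])
        write_bed(tmp_path / "k27.bed", [])
        write_bed(tmp_path / "cen.bed", [])
        ann = gcm.load_annotation(tmp_path / "g.fa", tmp_path / "k9.bed",
                                  tmp_path / "k27.bed", tmp_path / "cen.bed")
        assert ann.partition.eu["c"] == [(0, 200), (400, 1000)]
        assert ann.partition.k9["c"] == [(200, 400)]

    def test_centromere_contained_in_k9(self, mini_genome):
        ann = gcm.load_annotation(mini_genome["fasta"], mini_genome["k9"],
                                  mini_genome["k27"], mini_genome["cen"])
        cen = ann.cen_mask("chr1")
        lab = ann.labels("chr1")
        assert np.all(lab[cen] == gcm.K9)

    def test_k27_truncated_under_k9_priority(self, tmp_path):
        # overlap [250,300) must be removed from K27, matching plain
        # interval subtraction on the same inputs
        write_fasta(tmp_path / "g.fa", {"c": "C" * 500})
        write_bed(tmp_path / "k9.bed", [("c", 100, 300)])
        write_bed(tmp_path / "k27.bed", [("c", 250, 350)])
        write_bed(tmp_path / "cen.bed", [])
        ann = gcm.load_annotation(tmp_path / "g.fa", tmp_path / "k9.bed",
                                  tmp_path / "k27.bed", tmp_path / "cen.bed")
        expected = gcm.subtract_intervals([(250, 350)], [(100, 300)])
        assert ann.partition.k27["c"] == expected == [(300, 350)]

    def test_centromere_outside_k9_extends_k9(self, tmp_path, caplog):
        write_fasta(tmp_path / "g.fa", {"c": "G" * 400})
        write_bed(tmp_path / "k9.bed", [("c", 100, 200)])
        write_bed(tmp_path / "k27.bed", [])
        write_bed(tmp_path / "cen.bed", [("c", 150, 250)])
        with caplog.at_level("WARNING"):
            ann = gcm.load_annotation(tmp_path / "g.fa", tmp_path / "k9.bed",
                                      tmp_path / "k27.bed",
                                      tmp_path / "cen.bed")
        assert ann.partition.k9["c"] == [(100, 250)]
        assert any("centromeric" in r.message for r in caplog.records)

    def test_unknown_contig_and_malformed_bed_are_errors(self, tmp_path):
        write_fasta(tmp_path / "g.fa", {"c": "ACGT" * 10})
        write_bed(tmp_path / "bad.bed", [("nope", 0, 5)])
        write_bed(tmp_path / "empty.bed", [])
        with pytest.raises(ValueError, match="not present in FASTA"):
            gcm.load_annotation(tmp_path / "g.fa", tmp_path / "bad.bed",
                                tmp_path / "empty.bed", tmp_path / "empty.bed")
        (tmp_path / "mal.bed").write_text("c\t10\n")
        with pytest.raises(ValueError, match="mal.bed:1"):
            gcm.load_annotation(tmp_path / "g.fa", tmp_path / "mal.bed",
                                tmp_path / "empty.bed", tmp_path / "empty.bed")

    def test_non_nucleotide_characters_rejected(self, tmp_path):
        write_fasta(tmp_path / "g.fa", {"c": "ACGTX"})
        with pytest.raises(ValueError, match="non-ACGTN"):
            gcm.GenomeSequence.from_fasta(tmp_path / "g.fa")


class TestTrinucleotideCollapse:
    def test_collapse_is_strand_involutive_with_32_classes(self):
        classes = set()
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    tri = a + b + c
                    assert gcm.canonical_trinuc(tri) == \
                        gcm.canonical_trinuc(revcomp_str(tri))
                    classes.add(gcm.canonical_trinuc(tri))
        assert len(classes) == 32
        assert classes == set(gcm.TRINUC_CLASSES)

    def test_manual_examples(self):
        assert gcm.canonical_trinuc("ATC") == "ATC:GAT"
        assert gcm.canonical_trinuc("TCT") == "AGA:TCT"

    @pytest.mark.parametrize("seq,expected", [
        ("ATC", {"ATC:GAT": 1}),
        ("AAAA", {"AAA:TTT": 2}),
        ("AA", {}),  # shorter than 3: zero counts
    ])
    def test_census_small_sequences(self, seq, expected):
        ann = _annotation_from_seq(seq)
        comp = gcm.trinucleotide_census(ann)
        got = {c: int(n) for c, n in comp.trinuc.loc["genome"].items() if n}
        assert got == expected

    def test_census_matches_bruteforce_tally(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGTN"), size=10_000,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        ann = _annotation_from_seq(seq)
        comp = gcm.trinucleotide_census(ann)
        expected = brute_trinuc_tally(seq)
        got = {c: int(n) for c, n in comp.trinuc.loc["genome"].items() if n}
        assert got == expected

    def test_census_conservation_per_stratum(self, sim_annotation,
                                             sim_composition):
        # class counts sum to the number of interior non-N positions
        tri = sim_composition.trinuc
        total_interior = sum(
            len(s) - 2 for s in sim_annotation.sequence.contigs.values())
        assert int(tri.loc["genome"].sum()) == total_interior
        bp = sim_composition.base_pairs
        assert (bp["at_pairs"] + bp["cg_pairs"]).equals(bp["callable_bp"])


class TestHomopolymers:
    @pytest.mark.parametrize("seq,min_len,expected", [
        ("GGAAAAAG", 5, [(2, 7, "A")]),
        ("CCCC", 5, []),
        ("CCCC", 4, [(0, 4, "C")]),
    ])
    def test_examples(self, seq, min_len, expected):
        cat = gcm.find_homopolymers(_annotation_from_seq(seq), min_len=min_len)
        got = [(r.start, r.end, r.base) for r in cat.itertuples()]
        assert got == expected

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        for rep in range(100):
            seq = "".join(rng.choice(list("AACGT"), size=500))
            cat = gcm.find_homopolymers(_annotation_from_seq(seq))
            got = [(r.start, r.end, r.base) for r in cat.itertuples()]
            assert got == regex_homopolymers(seq)

    def test_runs_never_overlap_and_min_len_validated(self, sim_catalog):
        for _, grp in sim_catalog.groupby("contig"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert np.all(starts[1:] >= ends[:-1])
        with pytest.raises(ValueError):
            gcm.find_homopolymers(_annotation_from_seq("AAAA"), min_len=1)


class TestWindows:
    def test_tiling_and_gc(self):
        ann = _annotation_from_seq("AT" * 100 + "GC" * 100)
        w = gcm.make_windows(ann, width=200)
        assert len(w) == 2
        assert w.loc[0, "gc_fraction"] == 0.0
        assert w.loc[1, "gc_fraction"] == 1.0

    def test_majority_label_with_tie_toward_k9(self):
        seq = "A" * 400
        part = gcm.DomainPartition(
            k9={"c": [(0, 101)]}, k27={}, eu={"c": [(101, 400)]},
            centromeres={}, lengths={"c": 400})
        ann = gcm.GenomeAnnotation(gcm.GenomeSequence({"c": seq}), part)
        w = gcm.make_windows(ann, width=200)
        assert w.loc[0, "domain_label"] == "H3K9me3"   # 101 vs 99 bases
        assert w.loc[1, "domain_label"] == "euchromatin"

    def test_all_n_window_flagged_missing(self):
        ann = _annotation_from_seq("N" * 200 + "ACGT" * 50)
        w = gcm.make_windows(ann, width=200)
        assert np.isnan(w.loc[0, "gc_fraction"])
        assert w.loc[0, "callable_bp"] == 0

    def test_width_validation(self, sim_annotation):
        with pytest.raises(ValueError):
            gcm.make_windows(sim_annotation, width=10)

    def test_purity_excludes_boundary_windows(self, sim_annotation,
                                              sim_windows):
        pure = gcm.window_purity(sim_annotation, sim_windows)
        # domain blocks exist, so some windows straddle boundaries
        assert 0 < (~pure).sum() < 0.05 * len(sim_windows)


class TestAnnotateMutations:
    def test_domain_trinuc_and_homopolymer_context(self):
        seq = "TTGCC" + "A" * 7 + "GTCTG"   # A7 run at [5,12)
        part = gcm.DomainPartition(
            k9={"c": [(0, 8)]}, k27={}, eu={"c": [(8, 17)]},
            centromeres={}, lengths={"c": 17})
        ann = gcm.GenomeAnnotation(gcm.GenomeSequence({"c": seq}), part)
        muts = pd.DataFrame([
            {"line_id": "L1", "contig": "c", "pos": 3, "kind": "SNM",
             "ref": "C", "alt": "T", "length": 1},
            {"line_id": "L1", "contig": "c", "pos": 7, "kind": "deletion",
             "ref": "", "alt": "", "length": 1},
            {"line_id": "L1", "contig": "c", "pos": 14, "kind": "SNM",
             "ref": "C", "alt": "A", "length": 1},
        ])
        out = gcm.annotate_mutations(muts, ann)
        assert out.loc[0, "domain_label"] == "H3K9me3"
        assert out.loc[0, "trinuc_class"] == gcm.canonical_trinuc("GCC")
        assert out.loc[1, "hp_base"] == "A"
        assert out.loc[1, "hp_length"] == 7
        # T C T context with ref C -> the TCT:AGA class
        assert out.loc[2, "trinuc_class"] == "AGA:TCT"
        assert out.loc[2, "snm_class"] == "C:G→A:T"

    def test_ref_mismatch_is_hard_error(self):
        ann = _annotation_from_seq("ACGTACGT")
        muts = pd.DataFrame([{"line_id": "L1", "contig": "c", "pos": 0,
                              "kind": "SNM", "ref": "G", "alt": "T",
                              "length": 1}])
        with pytest.raises(ValueError, match="reference allele mismatch"):
            gcm.annotate_mutations(muts, ann)


class TestIntervalArithmetic:
    @given(st.lists(st.tuples(st.integers(0, 99), st.integers(1, 30)),
                    max_size=8),
           st.lists(st.tuples(st.integers(0, 99), st.integers(1, 30)),
                    max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_subtract_matches_setwise_difference(self, a_raw, b_raw):
        a = gcm.merge_intervals([(s, s + l) for s, l in a_raw])
        b = gcm.merge_intervals([(s, s + l) for s, l in b_raw])
        got = gcm.subtract_intervals(a, b)
        set_a = {x for s, e in a for x in range(s, e)}
        set_b = {x for s, e in b for x in range(s, e)}
        got_set = {x for s, e in got for x in range(s, e)}
        assert got_set == set_a - set_b
        assert all(s < e for s, e in got)


def _annotation_from_seq(seq: str, name: str = "c") -> gcm.GenomeAnnotation:
    part = gcm.DomainPartition(k9={}, k27={}, eu={name: [(0, len(seq))]},
                               centromeres={}, lengths={name: len(seq)})
    return gcm.GenomeAnnotation(gcm.GenomeSequence({name: seq}), part)
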