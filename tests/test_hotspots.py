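"""Hotspot scanners vs brute-force oracles; mutation overlay; codon labels."""

import numpy as np
import pytest

from damageclock.hotspots import (
    AnnotatedSequence,
    MutationRecord,
    MutationValidationError,
    annotate,
    codon_consequence,
    map_mutations,
    parse_annotation_tsv,
    render_annotation,
    scan_gc_rich,
    scan_rgyw,
)

R, Y, W = set("AG"), set("CT"), set("AT")


def brute_rgyw(s: str, max_mismatch: int):
    """Position-by-position reference matcher, independent of the scanner."""
    hits = []
    for i in range(len(s) - 3):
        mm = 0
        if s[i] not in R:
            mm += 1
        if s[i + 1] != "G":
            mm += 1
        if s[i + 2] not in Y:
            mm += 1
        if s[i + 3] not in W:
            mm += 1
        if mm <= max_mismatch:
            hits.append((i, "exact" if mm == 0 else "mismatch"))
    return hits


def brute_gc_runs(s: str, min_len: int):
    hits, run_start = [], None
    for i, b in enumerate(s + "$"):
        if b in "GC":
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_len:
                hits.append((run_start, i))
            run_start = None
    return hits


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestRgywScan:
    def test_tggct_single_exact(self):
        seq = AnnotatedSequence(id="x", sequence="TGGCT")
        hits = scan_rgyw(seq, max_mismatch=0)
        assert len(hits) == 1
        a = hits[0]
        assert (a.start, a.end) == (2, 5)
        assert a.matched_text == "GGCT"
        assert a.display_span == "TGGCT"
        assert a.category == "exact_rgyw"

    def test_all_t_has_no_hits(self):
        seq = AnnotatedSequence(id="x", sequence="TTTTT")
        assert scan_rgyw(seq, max_mismatch=1) == []

    def test_exact_reported_as_exact_under_mismatch_scan(self):
        seq = AnnotatedSequence(id="x", sequence="TGGCT")
        hits = scan_rgyw(seq, max_mismatch=1)
        assert [a.category for a in hits if (a.start, a.end) == (2, 5)] == ["exact_rgyw"]

    @pytest.mark.parametrize("max_mismatch", [0, 1])
    def test_oracle_equivalence_on_random_sequences(self, max_mismatch):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            s = _random_seq(rng, 60)
            seq = AnnotatedSequence(id="r", sequence=s)
            got = [(a.start - 1, "exact" if a.category == "exact_rgyw" else "mismatch")
                   for a in scan_rgyw(seq, max_mismatch)]
            assert got == brute_rgyw(s, max_mismatch)

    def test_coord_offset_respected(self):
        seq = AnnotatedSequence(id="x", sequence="TGGCT", coord_offset=690)
        a = scan_rgyw(seq)[0]
        assert (a.start, a.end) == (691, 694)

    def test_strand_locality_rgyw_equals_wrcy_on_reverse(self):
        # scanning the reverse complement for RGYW must equal scanning
        # the forward strand for WRCY (the reverse-complement motif)
        comp = str.maketrans("ACGT", "TGCA")

        def brute_wrcy(s):
            out = []
            for i in range(len(s) - 3):
                if s[i] in W and s[i + 1] in R and s[i + 2] == "C" and s[i + 3] in Y:
                    out.append((i, i + 3))
            return sorted(out)

        rng = np.random.default_rng(11)
        for _ in range(200):
            s = _random_seq(rng, 50)
            rc = s.translate(comp)[::-1]
            hits_rc = scan_rgyw(AnnotatedSequence(id="rc", sequence=rc), 0)
            n = len(s)
            mapped = sorted((n - (a.end - 1) - 1, n - (a.start - 1) - 1) for a in hits_rc)
            assert mapped == brute_wrcy(s)


class TestGcScan:
    def test_exact_threshold(self):
        assert len(scan_gc_rich(AnnotatedSequence(id="x", sequence="GCGCGCGCG"))) == 1
        assert scan_gc_rich(AnnotatedSequence(id="x", sequence="GCGCGCGC")) == []

    def test_run_boundaries(self):
        seq = AnnotatedSequence(id="x", sequence="ATGCGCGCGCCTA")
        (a,) = scan_gc_rich(seq, min_len=9)
        assert (a.start, a.end) == (3, 11)
        assert a.matched_text == "GCGCGCGCC"

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            s = "".join(rng.choice(list("ACGT"), p=[0.15, 0.35, 0.35, 0.15], size=80))
            got = [(a.start - 1, a.end) for a in scan_gc_rich(AnnotatedSequence(id="r", sequence=s), 6)]
            assert got == brute_gc_runs(s, 6)


class TestMutationOverlay:
    def test_mutation_outside_any_annotation(self):
        seq = AnnotatedSequence(id="x", sequence="TTTTTAGCTTTTT")
        annotate(seq, max_mismatch=0)
        seq.mutations = [MutationRecord(position=2, ref="T", alt="A")]
        resolved, summary = map_mutations(seq)
        assert resolved[0].in_hotspot is None
        assert summary.n_outside == 1

    def test_planted_motif_membership(self):
        # motif core at positions 11-14 by construction
        seq = AnnotatedSequence(id="x", sequence="TTTTTTTTTTAGCTTTTTTT")
        annotate(seq, max_mismatch=0)
        assert [(a.start, a.end) for a in seq.annotations] == [(11, 14)]
        seq.mutations = [MutationRecord(position=12, ref="G", alt="C")]
        resolved, _ = map_mutations(seq)
        assert resolved[0].in_hotspot == "exact_rgyw"

    def test_ref_mismatch_reported_with_positions(self):
        seq = AnnotatedSequence(id="x", sequence="ACGTACGT")
        seq.mutations = [MutationRecord(position=1, ref="G", alt="T")]
        with pytest.raises(MutationValidationError, match="position 1"):
            map_mutations(seq)

    def test_copa_like_summary_seven_of_ten_in_first_four(self, copa):
        from damageclock.data import COPA_OTHER_MOTIFS

        seq, _ = copa
        annotate(seq, max_mismatch=1, other_motifs=COPA_OTHER_MOTIFS)
        _, summary = map_mutations(seq, hotspot_rank_limit=4)
        assert summary.n_mutations == 10
        assert summary.n_in_first_k == 7


class TestCodonConsequence:
    def test_g755r(self, plb1):
        seq, _ = plb1
        assert codon_consequence(seq, 2263, "C") == "G755R"

    def test_synonymous_flagged(self):
        seq = AnnotatedSequence(id="x", sequence="GGAGGG")
        label = codon_consequence(seq, 3, "G")  # GGA -> GGG
        assert label.startswith("G1G")
        assert "synonymous" in label

    def test_stop_gain_labelled_with_star(self):
        seq = AnnotatedSequence(id="x", sequence="TACAAA")
        assert codon_consequence(seq, 3, "A") == "Y1*"  # TAC -> TAA

    def test_all_single_base_changes_vs_translation_oracle(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(17)
        s = "ATG" + "".join(rng.choice(list("ACGT"), size=27))
        seq = AnnotatedSequence(id="cds", sequence=s)
        codon_i = 4  # codon 4, CDS positions 10-12
        for off in range(3):
            pos = 9 + off + 1
            ref = s[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                label = codon_consequence(seq, pos, alt)
                mutated = s[: pos - 1] + alt + s[pos:]
                ref_aa = str(Seq(s).translate())[codon_i - 1]
                alt_aa = str(Seq(mutated).translate())[codon_i - 1]
                expected = f"{ref_aa}{codon_i}{alt_aa}"
                if ref_aa == alt_aa:
                    expected += " (synonymous)"
                assert label == expected

    def test_position_outside_sequence(self):
        seq = AnnotatedSequence(id="x", sequence="ATGAAA")
        with pytest.raises(ValueError):
            codon_consequence(seq, 9, "A")


class TestRendering:
    def test_empty_annotations_render_plain(self):
        seq = AnnotatedSequence(id="x", sequence="ACGTT")
        html = render_annotation(seq, "html")
        assert "ACGTT" in html.replace("</span>", "").replace('<span class="mutation">', "")
        assert render_annotation(seq, "tsv").splitlines() == ["start\tend\tcategory\tmatched_text\tdisplay_span"]
        assert render_annotation(seq, "bed") == ""

    def test_single_hotspot_bed_interval(self):
        seq = AnnotatedSequence(id="x", sequence="TGGCT")
        annotate(seq, max_mismatch=0)
        (line,) = render_annotation(seq, "bed").strip().splitlines()
        chrom, start, end, cat = line.split("\t")
        assert (chrom, int(start), int(end), cat) == ("x", 1, 5, "exact_rgyw")

    def test_tsv_round_trip(self, copa):
        from damageclock.data import COPA_OTHER_MOTIFS

        seq, _ = copa
        annotate(seq, max_mismatch=1, other_motifs=COPA_OTHER_MOTIFS)
        text = render_annotation(seq, "tsv")
        assert parse_annotation_tsv(text) == seq.annotations

    def test_bed_tsv_describe_identical_intervals(self):
        seq = AnnotatedSequence(id="x", sequence="AATGGCTAAGCGCGCGCGCTT", coord_offset=101)
        annotate(seq, max_mismatch=0, gc_min_len=9)
        tsv = [ln.split("\t") for ln in render_annotation(seq, "tsv").strip().splitlines()[1:]]
        bed = [ln.split("\t") for ln in render_annotation(seq, "bed").strip().splitlines()]
        assert len(tsv) == len(bed) >= 2
        for trow, brow in zip(tsv, bed):
            start1, end1 = int(trow[0]), int(trow[1])
            start0, end0 = int(brow[1]), int(brow[2])
            assert start0 == start1 - seq.coord_offset
            assert end0 == end1 - seq.coord_offset + 1


class TestSequenceValidation:
    def test_rejects_invalid_bases(self):
        with pytest.raises(ValueError):
            AnnotatedSequence(id="x", sequence="ACGU")
        with pytest.raises(ValueError):
            AnnotatedSequence(id="x", sequence="")

    def test_uppercases(self):
        assert AnnotatedSequence(id="x", sequence="acgt").sequence == "ACGT"
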