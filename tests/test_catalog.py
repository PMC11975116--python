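"""Catalog parsing, curation filters, annotation labels and GC content."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vntrspan.catalog import (
    AnnotationSet,
    Gene,
    GenomicInterval,
    VntrLocus,
    curate,
    gc_content,
    read_trf_records,
)

from .conftest import make_locus, make_reference


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParsing:
    def test_bed_line_maps_fields_directly(self, tmp_path):
        p = _write(tmp_path, "c.bed", "chr1\t1000\t1100\tACGTGG\n")
        (locus,) = read_trf_records(p, format="bed")
        assert locus.motif_length == 6
        assert locus.ref_array_length == 100
        assert locus.interval == GenomicInterval("chr1", 1000, 1100)

    def test_parser_does_not_filter_short_motifs(self, tmp_path):
        dat = (
            "Sequence: chr2\n"
            "101 150 5 10.0 5 95 0 90 30 20 20 30 1.5 AAAAG AAAAGAAAAG\n"
        )
        p = _write(tmp_path, "c.dat", dat)
        (locus,) = read_trf_records(p, format="trf_dat")
        assert locus.motif == "AAAAG"  # candidate survives parsing; curation filters it
        assert locus.interval == GenomicInterval("chr2", 100, 150)  # 1-based -> 0-based

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert read_trf_records(_write(tmp_path, "e.bed", ""), format="bed") == []

    def test_malformed_record_names_line_number(self, tmp_path):
        p = _write(tmp_path, "bad.bed", "chr1\t0\t10\tAAAAAA\nchr1\t50\n")
        with pytest.raises(ValueError, match="bad.bed:2"):
            read_trf_records(p, format="bed")

    def test_unknown_format_rejected(self, tmp_path):
        p = _write(tmp_path, "x.bed", "chr1\t0\t10\tAAAAAA\n")
        with pytest.raises(ValueError, match="unknown catalog format"):
            read_trf_records(p, format="gff")


def _gene_over(locus, **kw):
    iv = locus.interval
    return Gene(GenomicInterval(iv.chrom, iv.start - 200, iv.end + 200), "+", **kw)


class TestCuration:
    def test_short_motif_excluded(self):
        locus = make_locus(motif="AAAAG", copies=10)
        res = curate([locus], AnnotationSet(genes=[_gene_over(locus)]))
        assert res.kept == []
        assert res.excluded[0][1] == "motif"

    def test_one_bp_segdup_overlap_excludes(self):
        locus = make_locus()
        segdup = GenomicInterval("chr1", locus.interval.end - 1, locus.interval.end + 500)
        res = curate([locus], AnnotationSet(genes=[_gene_over(locus)], segdups=[segdup]))
        assert res.excluded[0][1] == "segdup"

    def test_containment_mode_keeps_partial_overlap(self):
        locus = make_locus()
        segdup = GenomicInterval("chr1", locus.interval.end - 1, locus.interval.end + 500)
        res = curate(
            [locus],
            AnnotationSet(genes=[_gene_over(locus)], segdups=[segdup]),
            containment=True,
        )
        assert len(res.kept) == 1

    def test_upstream_of_tss_retained_as_promoter(self):
        locus = make_locus("chr1", 1000, "ACGTGG", 10)  # [1000, 1060)
        gene = Gene(GenomicInterval("chr1", 1400, 2400), "+")  # TSS 400 bp downstream
        res = curate([locus], AnnotationSet(genes=[gene]))
        assert [l.annotation for l in res.kept] == ["promoter"]

    def test_beyond_tss_flank_excluded(self):
        locus = make_locus("chr1", 1000, "ACGTGG", 10)
        gene = Gene(GenomicInterval("chr1", 1700, 2700), "+")  # 700 bp downstream
        res = curate([locus], AnnotationSet(genes=[gene]))
        assert res.excluded[0][1] == "proximity"

    def test_promoter_is_strand_aware(self):
        locus = make_locus("chr1", 1000, "ACGTGG", 10)
        # minus-strand gene downstream: its TSS is at the far end, locus is not upstream
        gene = Gene(GenomicInterval("chr1", 1400, 2400), "-")
        assert curate([locus], AnnotationSet(genes=[gene])).kept == []
        # but a minus-strand gene ending just before the locus has its TSS there
        gene2 = Gene(GenomicInterval("chr1", 100, 700), "-")  # TSS at 699, locus ≤500 bp upstream
        res = curate([locus], AnnotationSet(genes=[gene2]))
        assert [l.annotation for l in res.kept] == ["promoter"]

    def test_chrx_excluded_when_autosomes_only(self):
        locus = make_locus("chrX", 1000)
        res = curate([locus], AnnotationSet(genes=[_gene_over(locus)]), autosomes_only=True)
        assert res.excluded[0][1] == "chromosome"

    def test_annotation_precedence_labels(self):
        locus = make_locus("chr1", 1000, "ACGTGG", 10)
        iv = locus.interval
        body = GenomicInterval("chr1", iv.start - 200, iv.end + 200)
        cases = {
            "exonic": Gene(body, "+", exons=(body,)),
            "utr": Gene(body, "+", utrs=(body,)),
            "intronic": Gene(body, "+"),
            "multiple": Gene(body, "+", exons=(GenomicInterval("chr1", body.start, iv.start + 30),)),
        }
        for expect, gene in cases.items():
            res = curate([locus], AnnotationSet(genes=[gene]))
            assert [l.annotation for l in res.kept] == [expect], expect

    def test_idempotent_and_subset(self):
        loci = [
            make_locus("chr1", 1000),
            make_locus("chr1", 5000, motif="AAAAG"),
            make_locus("chr2", 1000),
        ]
        ann = AnnotationSet(genes=[_gene_over(l) for l in loci])
        once = curate(loci, ann)
        twice = curate(once.kept, ann)
        assert [l.locus_id for l in twice.kept] == [l.locus_id for l in once.kept]
        assert set(l.locus_id for l in once.kept) <= set(l.locus_id for l in loci)
        # every exclusion attributed to exactly one reason
        assert len(once.excluded) + len(once.kept) == len(loci)


class TestGcContent:
    def test_hand_counted_windows(self):
        ref = make_reference({"c": "AATTGGCC"})
        locus = VntrLocus("l", GenomicInterval("c", 0, 8), "AATTGGCC")
        assert gc_content(locus, ref, flank=0) == pytest.approx(0.5)  # 4/8
        all_a = make_reference({"c": "A" * 50})
        assert gc_content(VntrLocus("l", GenomicInterval("c", 10, 20), "AAAAAAAAAA"), all_a) == 0.0
        gcgc = make_reference({"c": "GCGC"})
        assert gc_content(VntrLocus("l", GenomicInterval("c", 0, 4), "GCGC"), gcgc, flank=0) == 1.0

    def test_n_bases_excluded_from_denominator(self):
        ref = make_reference({"c": "GCNNNNAT"})
        locus = VntrLocus("l", GenomicInterval("c", 0, 8), "GCNNNNAT")
        assert gc_content(locus, ref, flank=0) == pytest.approx(2 / 4)

    def test_all_n_window_is_missing(self):
        ref = make_reference({"c": "N" * 30})
        locus = VntrLocus("l", GenomicInterval("c", 5, 15), "NNNNNNNNNN")
        assert gc_content(locus, ref, flank=5) is None

    def test_missing_chromosome_errors(self):
        ref = make_reference({"c": "ACGT" * 10})
        locus = make_locus("chrZ", 4, "ACGTGG", 2)
        with pytest.raises(KeyError):
            gc_content(locus, ref)

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=60))
    def test_invariant_under_reverse_complement(self, seq):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        locus_f = VntrLocus("f", GenomicInterval("c", 0, len(seq)), seq[:6])
        got_f = gc_content(locus_f, make_reference({"c": seq}), flank=0)
        got_r = gc_content(locus_f, make_reference({"c": rc}), flank=0)
        assert got_f == pytest.approx(got_r)
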