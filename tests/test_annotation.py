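import io

import pytest
from hypothesis import given, settings, strategies as st

from fisherseq.annotation import (
    GenomicInterval,
    derive_constitutive_exons,
    enumerate_retained_introns,
    enumerate_skipped_exons,
    iter_all_events,
    load_gene_models,
    merge_intervals,
    write_events_tsv,
)
from fisherseq.errors import DataError, ParseError

from conftest import constitutive_bases_oracle, make_gene

GTF = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "ENSG1"; transcript_id "T1"; gene_name "GENE1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "ENSG1"; transcript_id "T1";
chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "ENSG1"; transcript_id "T1";
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "ENSG1"; transcript_id "T2";
chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "ENSG1"; transcript_id "T2";
"""

BED12 = (
    "chr1\t100\t600\tENSG1|T1\t0\t+\t100\t600\t0\t3\t100,100,100,\t0,200,400,\n"
    "chr1\t100\t600\tENSG1|T2\t0\t+\t100\t600\t0\t2\t100,100,\t0,400,\n"
)


class TestLoaders:
    def test_gtf_two_transcripts_one_gene(self):
        genes = load_gene_models(io.StringIO(GTF), fmt="gtf")
        assert set(genes) == {"ENSG1"}
        gene = genes["ENSG1"]
        assert len(gene.transcripts) == 2
        assert gene.symbol == "GENE1"
        t1 = next(t for t in gene.transcripts if t.transcript_id == "T1")
        # 1-based inclusive GTF converted to 0-based half-open
        assert [(e.start, e.end) for e in t1.exons] == [
            (100, 200), (300, 400), (500, 600)]

    def test_bed12_block_mapping(self):
        genes = load_gene_models(io.StringIO(BED12), fmt="bed12")
        gene = genes["ENSG1"]
        assert len(gene.transcripts) == 2
        t1 = next(t for t in gene.transcripts if t.transcript_id == "T1")
        assert [(e.start, e.end) for e in t1.exons] == [
            (100, 200), (300, 400), (500, 600)]

    def test_gtf_and_bed12_agree(self):
        g1 = load_gene_models(io.StringIO(GTF), fmt="gtf")["ENSG1"]
        g2 = load_gene_models(io.StringIO(BED12), fmt="bed12")["ENSG1"]
        for a, b in zip(g1.transcripts, g2.transcripts):
            assert [(e.start, e.end) for e in a.exons] == [
                (e.start, e.end) for e in b.exons]

    def test_malformed_record_names_line(self):
        bad = GTF + "chr1\tbroken line without tabs\n"
        with pytest.raises(ParseError, match="line 6"):
            load_gene_models(io.StringIO(bad), fmt="gtf")

    def test_exon_end_before_start_rejected(self):
        bad = 'chr1\tt\texon\t200\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        with pytest.raises(ParseError):
            load_gene_models(io.StringIO(bad), fmt="gtf")

    def test_bed12_zero_exons_rejected(self):
        bad = "chr1\t100\t600\tT0\t0\t+\t100\t600\t0\t0\t,\t,\n"
        with pytest.raises(ParseError, match="zero exons|blockCount"):
            load_gene_models(io.StringIO(bad), fmt="bed12")


class TestConstitutiveExons:
    def test_single_transcript_is_its_own_intersection(self):
        gene = make_gene("G", [[(0, 10), (20, 30)]])
        derive_constitutive_exons(gene)
        assert [(e.start, e.end) for e in gene.constitutive_exons] == [
            (0, 10), (20, 30)]
        assert gene.constitutive_length_bp == 20

    def test_cassette_excluded(self, two_transcript_gene):
        derive_constitutive_exons(two_transcript_gene)
        assert [(e.start, e.end)
                for e in two_transcript_gene.constitutive_exons] == [
            (100, 200), (500, 600)]

    def test_disjoint_transcripts_empty(self):
        gene = make_gene("G", [[(0, 10)], [(20, 30)]])
        derive_constitutive_exons(gene)
        assert gene.constitutive_exons == []
        assert gene.constitutive_length_bp == 0

    def test_partial_overlap_base_resolution(self):
        gene = make_gene("G", [[(0, 100)], [(50, 150)]])
        derive_constitutive_exons(gene)
        assert [(e.start, e.end) for e in gene.constitutive_exons] == [(50, 100)]

    def test_idempotent(self, two_transcript_gene):
        derive_constitutive_exons(two_transcript_gene)
        first = list(two_transcript_gene.constitutive_exons)
        derive_constitutive_exons(two_transcript_gene)
        assert two_transcript_gene.constitutive_exons == first

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_matches_per_base_oracle(self, data):
        n_tx = data.draw(st.integers(1, 5))
        transcripts = []
        for _ in range(n_tx):
            n_ex = data.draw(st.integers(1, 10))
            starts = sorted(data.draw(st.lists(
                st.integers(0, 500), min_size=n_ex, max_size=n_ex,
                unique=True)))
            exons, cursor = [], 0
            for s in starts:
                s = max(s, cursor)
                length = data.draw(st.integers(1, 40))
                exons.append((s, s + length))
                cursor = s + length + 1
            transcripts.append(exons)
        gene = make_gene("G", transcripts)
        derive_constitutive_exons(gene)
        got = {(e.chrom, pos)
               for e in gene.constitutive_exons
               for pos in range(e.start, e.end)}
        assert got == constitutive_bases_oracle(gene)
        assert gene.constitutive_length_bp == len(got)


def _oracle_skipped_exons(gene):
    """Exhaustive (u, c, d) triple check over all exon combinations."""
    key = lambda iv: (iv.start, iv.end)  # noqa: E731
    triples, pairs = set(), set()
    for tx in gene.transcripts:
        ex = tx.exons
        for i in range(len(ex) - 2):
            triples.add((key(ex[i]), key(ex[i + 1]), key(ex[i + 2])))
        for i in range(len(ex) - 1):
            pairs.add((key(ex[i]), key(ex[i + 1])))
    return sorted((u, c, d) for (u, c, d) in triples if (u, d) in pairs)


class TestEvents:
    def test_cassette_gene_one_event(self, two_transcript_gene):
        events = enumerate_skipped_exons(two_transcript_gene)
        assert len(events) == 1
        ev = events[0]
        assert (ev.cassette_exon.start, ev.cassette_exon.end) == (300, 400)

    def test_single_transcript_no_skipping(self):
        gene = make_gene("G", [[(0, 10), (20, 30), (40, 50)]])
        assert enumerate_skipped_exons(gene) == []

    def test_two_independent_cassettes(self):
        full = [(0, 10), (20, 30), (40, 50), (60, 70), (80, 90)]
        skip_b = [(0, 10), (40, 50), (60, 70), (80, 90)]
        skip_d = [(0, 10), (20, 30), (40, 50), (80, 90)]
        gene = make_gene("G", [full, skip_b, skip_d])
        events = enumerate_skipped_exons(gene)
        got = [(e.cassette_exon.start, e.cassette_exon.end) for e in events]
        oracle = [(c[0], c[1]) for (u, c, d) in _oracle_skipped_exons(gene)]
        assert got == sorted(oracle)
        assert got == [(20, 30), (60, 70)]

    def test_cassette_disjoint_from_constitutive(self, two_transcript_gene):
        derive_constitutive_exons(two_transcript_gene)
        for ev in enumerate_skipped_exons(two_transcript_gene):
            for c in two_transcript_gene.constitutive_exons:
                assert not ev.cassette_exon.overlaps(c)

    def test_three_exons_two_introns(self):
        gene = make_gene("G", [[(0, 10), (20, 30), (40, 50)]])
        events = enumerate_retained_introns(gene)
        assert [(e.intron.start, e.intron.end) for e in events] == [
            (10, 20), (30, 40)]
        for ev in events:
            assert ev.left_exon.end == ev.intron.start
            assert ev.intron.end == ev.right_exon.start

    def test_single_exon_no_introns(self):
        gene = make_gene("G", [[(0, 100)]])
        assert enumerate_retained_introns(gene) == []

    def test_shared_intron_deduplicated(self, two_transcript_gene):
        # intron (200, 300)+(400, 500) in T1; (200, 500) in T2
        events = enumerate_retained_introns(two_transcript_gene)
        coords = [(e.intron.start, e.intron.end) for e in events]
        assert coords == sorted(set(coords))
        gene = make_gene("G", [[(0, 10), (20, 30)], [(0, 10), (20, 30)]])
        assert len(enumerate_retained_introns(gene)) == 1


class TestIntervalUtilities:
    def test_merge_adjacent_and_overlapping(self):
        ivs = [GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20),
               GenomicInterval("c", 15, 30), GenomicInterval("c", 40, 50)]
        merged = merge_intervals(ivs)
        assert [(m.start, m.end) for m in merged] == [(0, 30), (40, 50)]

    def test_invalid_interval_rejected(self):
        with pytest.raises(DataError):
            GenomicInterval("c", 10, 10)


def test_events_tsv_roundtrip_columns(two_transcript_gene):
    out = io.StringIO()
    write_events_tsv(list(iter_all_events([two_transcript_gene])), out)
    lines = out.getvalue().splitlines()
    assert lines[0] == "event_id\tgene_id\ttype\tcoordinates"
    types = [ln.split("\t")[2] for ln in lines[1:]]
    assert types.count("skipped_exon") == 1
    assert types.count("retained_intron") == 3
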