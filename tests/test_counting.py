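import io
import random

import pytest

from fisherseq.annotation import GenomicInterval, derive_constitutive_exons
from fisherseq.counting import (
    FLANKING,
    INCLUSION,
    IRRELEVANT,
    SKIPPING,
    ClassCounts,
    EventCounts,
    ReadAlignment,
    SampleCounts,
    classify_read_for_event,
    count_events,
    count_gene_reads,
)
from fisherseq.errors import DataError
from fisherseq.io import read_gene_counts, write_gene_counts

from conftest import make_gene


def read(chrom, *blocks, unique=True):
    return ReadAlignment(
        chrom=chrom,
        blocks=tuple(GenomicInterval(chrom, s, e) for s, e in blocks),
        unique=unique,
    )


@pytest.fixture
def se_event(two_transcript_gene):
    from fisherseq.annotation import enumerate_skipped_exons
    return enumerate_skipped_exons(two_transcript_gene)[0]


@pytest.fixture
def ri_event():
    gene = make_gene("G", [[(0, 100), (200, 300)]])
    from fisherseq.annotation import enumerate_retained_introns
    return enumerate_retained_introns(gene)[0]


class TestGeneCounting:
    def setup_method(self):
        self.gene_a = derive_constitutive_exons(
            make_gene("A", [[(100, 200), (300, 400), (500, 600)],
                            [(100, 200), (500, 600)]]))
        self.gene_b = derive_constitutive_exons(
            make_gene("B", [[(1000, 1100)]]))
        self.genes = [self.gene_a, self.gene_b]

    def test_read_in_constitutive_exon_counts(self):
        sc = count_gene_reads([read("chr1", (120, 150))], self.genes)
        assert sc.gene_counts == {"A": 1, "B": 0}
        assert sc.total_uniquely_mapped == 1

    def test_cassette_only_read_counts_nothing(self):
        # (300, 400) is the cassette of gene A, not constitutive
        sc = count_gene_reads([read("chr1", (310, 340))], self.genes)
        assert sc.gene_counts == {"A": 0, "B": 0}
        assert sc.total_uniquely_mapped == 1

    def test_ambiguous_read_discarded(self):
        sc = count_gene_reads([read("chr1", (150, 1050))], self.genes)
        assert sc.gene_counts == {"A": 0, "B": 0}
        assert sc.total_uniquely_mapped == 1

    def test_non_unique_read_outside_universe(self):
        sc = count_gene_reads([read("chr1", (120, 150), unique=False)],
                              self.genes)
        assert sc.total_uniquely_mapped == 0
        assert sc.gene_counts == {"A": 0, "B": 0}

    def test_empty_gene_collection_error(self):
        with pytest.raises(DataError):
            count_gene_reads([read("chr1", (0, 10))], [])


class TestEventClassification:
    def test_skipping_junction(self, se_event):
        # blocks end at upstream end and start at downstream start
        r = read("chr1", (150, 200), (500, 550))
        assert classify_read_for_event(r, se_event) == SKIPPING

    def test_cassette_body_inclusion(self, se_event):
        assert classify_read_for_event(read("chr1", (310, 360)), se_event) \
            == INCLUSION

    def test_inclusion_junction(self, se_event):
        r = read("chr1", (150, 200), (300, 350))
        assert classify_read_for_event(r, se_event) == INCLUSION

    def test_flanking_body_only(self, se_event):
        assert classify_read_for_event(read("chr1", (110, 160)), se_event) \
            == FLANKING

    def test_outside_event_irrelevant(self, se_event):
        assert classify_read_for_event(read("chr1", (700, 750)), se_event) \
            == IRRELEVANT

    def test_intron_interior_inclusion(self, ri_event):
        assert classify_read_for_event(read("chr1", (120, 150)), ri_event) \
            == INCLUSION

    def test_spliced_junction_flanking(self, ri_event):
        r = read("chr1", (60, 100), (200, 240))
        assert classify_read_for_event(r, ri_event) == FLANKING

    def test_exon_body_flanking(self, ri_event):
        assert classify_read_for_event(read("chr1", (10, 50)), ri_event) \
            == FLANKING

    def test_partition_exhaustive_and_exclusive(self, se_event, ri_event):
        """Every random read gets exactly one class; totals are conserved."""
        rng = random.Random(0)
        for event in (se_event, ri_event):
            reads = []
            for _ in range(300):
                if rng.random() < 0.5:
                    s = rng.randrange(0, 700)
                    reads.append(read("chr1", (s, s + rng.randrange(1, 80))))
                else:
                    s = rng.randrange(0, 300)
                    gap = rng.randrange(1, 300)
                    length = rng.randrange(1, 50)
                    reads.append(read("chr1", (s, s + length),
                                      (s + length + gap,
                                       s + length + gap + length)))
            classes = [classify_read_for_event(r, event) for r in reads]
            assert all(c in {INCLUSION, SKIPPING, FLANKING, IRRELEVANT}
                       for c in classes)
            counted = count_events(reads, [event]).counts[event.event_id]
            n_irrelevant = sum(1 for c in classes if c == IRRELEVANT)
            assert sum(counted) + n_irrelevant == len(reads)

    def test_order_invariance(self, se_event):
        rng = random.Random(1)
        reads = [read("chr1", (s, s + 50))
                 for s in rng.sample(range(0, 650), 60)]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        a = count_events(reads, [se_event]).counts[se_event.event_id]
        b = count_events(shuffled, [se_event]).counts[se_event.event_id]
        assert a == b

    def test_zero_reads_all_zero(self, se_event):
        ec = count_events([], [se_event])
        assert ec.counts[se_event.event_id] == ClassCounts(0, 0, 0)

    def test_toy_counts(self, se_event):
        reads = (
            [read("chr1", (320, 350))] * 3                 # inclusion
            + [read("chr1", (150, 200), (500, 550))]       # skipping
            + [read("chr1", (110, 140))] * 2               # flanking
        )
        ec = count_events(reads, [se_event])
        assert ec.counts[se_event.event_id] == ClassCounts(3, 1, 2)


def test_gene_count_table_roundtrip():
    samples = {
        "vector": SampleCounts("vector", 1000, {"A": 10, "B": 0}),
        "treated": SampleCounts("treated", 2000, {"A": 25, "B": 3}),
    }
    buf = io.StringIO()
    write_gene_counts(samples, buf)
    buf.seek(0)
    back = read_gene_counts(buf)
    assert back.keys() == samples.keys()
    for c in samples:
        assert back[c].total_uniquely_mapped == samples[c].total_uniquely_mapped
        assert back[c].gene_counts == samples[c].gene_counts


def test_negative_counts_rejected():
    with pytest.raises(DataError):
        SampleCounts("x", 10, {"A": -1})
    with pytest.raises(DataError):
        EventCounts("x", {"e": ClassCounts(-1, 0, 0)})
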