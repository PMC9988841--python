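import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from readermap import (ChromosomeDomains, GeneModel, GenomicInterval, ParseError,
                       PeakSet, assign_feature, classify_gene_activity,
                       merge_intervals, partition_by_domain, read_gene_models,
                       read_intervals, repeat_family_overlap)


# ---------------------------------------------------------------------------
# file parsing
# ---------------------------------------------------------------------------

def test_read_bed_line(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chrI\t0\t10\tp1\n")
    ps = read_intervals(p, "bed")
    (iv,) = ps.intervals
    assert (iv.chrom, iv.start, iv.end, iv.name) == ("chrI", 0, 10, "p1")


def test_narrowpeak_summit_becomes_reference_point(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chrI\t0\t10\tp1\t100\t.\t5.0\t-1\t-1\t4\n")
    (iv,) = read_intervals(p, "narrowPeak").intervals
    assert iv.summit == 4
    assert iv.reference_point == 4


def test_inverted_record_rejected_with_warning(tmp_path, caplog):
    p = tmp_path / "a.bed"
    p.write_text("chrI\t10\t5\nchrI\t0\t10\n")
    with caplog.at_level(logging.WARNING, logger="readermap"):
        ps = read_intervals(p, "bed")
    assert len(ps) == 1
    assert "start >= end" in caplog.text


def test_malformed_line_raises_with_line_number(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chrI\t0\t10\nchrI\tnot_a_number\t20\n")
    with pytest.raises(ParseError, match=":2"):
        read_intervals(p, "bed")


def test_gff3_coordinates_converted(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("chrI\t.\tgene\t101\t400\t.\t+\t.\tID=g1\n"
                 "chrI\t.\texon\t101\t200\t.\t+\t.\tParent=g1\n"
                 "chrI\t.\texon\t301\t400\t.\t+\t.\tParent=g1\n")
    (g,) = read_gene_models(p, "gff3")
    assert g.exons == [(100, 200), (300, 400)]
    assert g.introns == [(200, 300)]
    assert g.tss == 100


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("spans,expected", [
    ([(0, 10), (5, 15)], [(0, 15)]),
    ([(0, 10), (10, 20)], [(0, 20)]),     # book-ended intervals merge
    ([(0, 5), (10, 15)], [(0, 5), (10, 15)]),
])
def test_merge_intervals(spans, expected):
    ivs = [GenomicInterval("chrI", s, e) for s, e in spans]
    assert [(iv.start, iv.end) for iv in merge_intervals(ivs)] == expected


def test_merge_empty():
    assert merge_intervals([]) == []


@given(st.lists(st.tuples(st.integers(0, 1000), st.integers(1, 50)), min_size=1, max_size=40))
@settings(deadline=None, max_examples=60)
def test_merge_idempotent_and_coverage_preserving(raw):
    ivs = [GenomicInterval("chrI", s, s + ln) for s, ln in raw]
    merged = merge_intervals(ivs)
    # idempotent
    again = merge_intervals(merged)
    assert [(m.start, m.end) for m in merged] == [(m.start, m.end) for m in again]
    # disjoint, sorted, and covering exactly the union of bases
    covered = set()
    for iv in ivs:
        covered.update(range(iv.start, iv.end))
    merged_bases = set()
    for m in merged:
        assert m.start < m.end
        assert merged_bases.isdisjoint(range(m.start, m.end))
        merged_bases.update(range(m.start, m.end))
    assert merged_bases == covered


# ---------------------------------------------------------------------------
# arm/center partition
# ---------------------------------------------------------------------------

@pytest.fixture
def domains():
    return ChromosomeDomains({"chrI": (1000, 3000, 4000)})


def test_partition_midpoint_rule(domains):
    peaks = PeakSet("x", [
        GenomicInterval("chrI", 100, 300),     # midpoint 200 -> left arm
        GenomicInterval("chrI", 2900, 3300),   # midpoint 3100 -> right arm
        GenomicInterval("chrI", 1500, 1700),   # midpoint 1600 -> center
        GenomicInterval("chrI", 900, 1100),    # midpoint exactly 1000 -> center
    ])
    sets, fracs = partition_by_domain(peaks, domains)
    assert len(sets["arm"]) == 2 and len(sets["center"]) == 2
    assert fracs["arm"] == 0.5


def test_partition_fraction_example(domains):
    arm = [GenomicInterval("chrI", 10 * i, 10 * i + 4) for i in range(6)]
    center = [GenomicInterval("chrI", 1500 + 10 * i, 1504 + 10 * i) for i in range(4)]
    _, fracs = partition_by_domain(PeakSet("x", arm + center), domains)
    assert fracs["arm"] == pytest.approx(0.6)


def test_partition_unknown_chrom_errors(domains):
    with pytest.raises(KeyError, match="chrX"):
        partition_by_domain(PeakSet("x", [GenomicInterval("chrX", 0, 10)]), domains)


@given(st.lists(st.tuples(st.integers(0, 3900), st.integers(1, 100)), min_size=1, max_size=60))
@settings(deadline=None, max_examples=60)
def test_partition_conserves_counts(raw):
    doms = ChromosomeDomains({"chrI": (1000, 3000, 4000)})
    peaks = PeakSet("x", [GenomicInterval("chrI", s, min(s + ln, 4000)) for s, ln in raw])
    sets, _ = partition_by_domain(peaks, doms)
    assert len(sets["arm"]) + len(sets["center"]) == len(peaks)


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------

def test_assign_feature_priority_and_partition():
    # promoter [4000,5100) for + gene with TSS 5000; exon [5000,5200)
    gene = GeneModel("g1", "chrI", "+", [(5000, 5200), (5400, 5600)])
    peaks = PeakSet("x", [
        GenomicInterval("chrI", 5040, 5060),   # ref 5050: promoter AND exon -> promoter
        GenomicInterval("chrI", 5240, 5260),   # ref 5250: intron
        GenomicInterval("chrI", 9000, 9100),   # intergenic
    ])
    labels, fracs = assign_feature(peaks, [gene])
    assert labels == ["promoter", "intron", "intergenic"]
    assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-12)


def test_promoter_strand_awareness():
    gene = GeneModel("g1", "chrI", "-", [(5000, 5200)])
    lo, hi = gene.promoter  # TSS at 5199; window extends upstream = rightward
    assert lo == 5100 and hi == 6200


# ---------------------------------------------------------------------------
# gene activity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fpkm,eu,het,expected", [
    (2.0, True, False, "active"),
    (2.0, True, True, "active"),
    (2.0, False, False, "unclassified"),
    (2.0, False, True, "unclassified"),
    (0.5, False, True, "silent"),
    (0.5, True, True, "silent"),
    (0.5, False, False, "unclassified"),
    (0.5, True, False, "unclassified"),
])
def test_activity_truth_table(fpkm, eu, het, expected):
    (call,) = classify_gene_activity({"g": fpkm}, {"g": eu}, {"g": het})
    assert call.label == expected


def test_negative_fpkm_errors():
    with pytest.raises(ValueError, match="negative"):
        classify_gene_activity({"g": -1.0}, {"g": True}, {"g": False})


def test_missing_fpkm_treated_as_zero(caplog):
    with caplog.at_level(logging.WARNING, logger="readermap"):
        (call,) = classify_gene_activity({}, {"g": False}, {"g": True})
    assert call.label == "silent" and call.fpkm == 0.0


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

def test_repeat_overlap_counts_and_fraction():
    peaks = PeakSet("x", [GenomicInterval("chrI", 100 * i, 100 * i + 50) for i in range(20)])
    repeats = [GenomicInterval("chrI", 10, 30, name="LTR"),
               GenomicInterval("chrI", 20, 40, name="LINE"),
               GenomicInterval("chrI", 120, 130, name="LTR"),
               GenomicInterval("chrI", 220, 230, name="LTR"),
               GenomicInterval("chrI", 330, 340, name="LINE")]
    counts, frac = repeat_family_overlap(peaks, repeats)
    # peak 0 overlaps both families: counted once per family, once overall
    assert counts == {"LTR": 3, "LINE": 2}
    assert frac == pytest.approx(4 / 20)


def test_repeat_overlap_empty_annotation():
    peaks = PeakSet("x", [GenomicInterval("chrI", 0, 50)])
    counts, frac = repeat_family_overlap(peaks, [])
    assert counts == {} and frac == 0.0
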