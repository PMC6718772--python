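"""Filter engine: range parsing, PASS/range/position predicates, streaming
conjunction filtering, sample selection, filtered-VCF export."""

import pytest

from vcfviz import (EmptyResultError, FilterSpec, GenomicRange, PositionList,
                    UsageError, export_filtered_vcf, open_vcf,
                    parse_genomic_range, read_position_list, read_sample_list,
                    record_in_position_list, record_in_ranges, record_passes,
                    select_samples, stream_filter, truth_count)
from vcfviz.vcf_stream import VCFHeader, parse_record


def _rec(chrom, pos, filt="PASS"):
    header = VCFHeader(sample_ids=["S1"])
    return parse_record(f"{chrom}\t{pos}\t.\tA\tT\t.\t{filt}\t.\tGT\t0/1", header)


@pytest.mark.parametrize("text,expected", [
    ("chr1:8900000-12000000", ("chr1", 8900000, 12000000)),
    ("chr3:1-4500000", ("chr3", 1, 4500000)),
    ("chrX:5-5", ("chrX", 5, 5)),
    ("chr1:8900000–12000000", ("chr1", 8900000, 12000000)),  # en dash
])
def test_parse_genomic_range(text, expected):
    r = parse_genomic_range(text)
    assert (r.chrom, r.start, r.stop) == expected


@pytest.mark.parametrize("bad", ["chr1", "chr1:5", "chr1:9-2", "chr1:a-b", ":1-2"])
def test_parse_genomic_range_rejects(bad):
    with pytest.raises(UsageError):
        parse_genomic_range(bad)


@pytest.mark.parametrize("filt,expected", [
    ("PASS", True), ("q10", False), (".", False), ("q10;s50", False),
    ("pass", False),  # case-sensitive
])
def test_record_passes(filt, expected):
    assert record_passes(_rec("chr1", 10, filt)) is expected


def test_range_inclusive_bounds_and_normalization():
    rng = [GenomicRange("chr3", 1, 4500000)]
    assert record_in_ranges(_rec("chr3", 4500000), rng)
    assert not record_in_ranges(_rec("chr3", 4500001), rng)
    assert record_in_ranges(_rec("3", 100), rng)       # "3" vs "chr3"
    assert record_in_ranges(_rec("CHR3", 100), rng)    # case-insensitive
    assert not record_in_ranges(_rec("chr1", 100), rng)


def test_position_list_membership_and_dedup():
    pl = PositionList([("chr1", 100), ("chr1", 100), ("1", 200)])
    assert record_in_position_list(_rec("chr1", 100), pl)
    assert record_in_position_list(_rec("chr1", 200), pl)
    assert not record_in_position_list(_rec("chr1", 101), pl)


def test_stream_filter_conjunction(tiny_vcf):
    _, records = open_vcf(tiny_vcf)
    spec = FilterSpec(pass_only=True,
                      ranges=[GenomicRange("chr1", 1, 10_000_000)])
    kept = stream_filter(records, spec)
    assert [(r.chrom, r.pos) for r in kept] == [("chr1", 100)]


def test_stream_filter_empty_raises(tiny_vcf):
    _, records = open_vcf(tiny_vcf)
    with pytest.raises(EmptyResultError):
        stream_filter(records, FilterSpec(ranges=[GenomicRange("chr9", 1, 10)]))


def test_stream_filter_no_criteria_keeps_all_and_warns(tiny_vcf, caplog):
    _, records = open_vcf(tiny_vcf)
    with caplog.at_level("WARNING"):
        kept = stream_filter(records, FilterSpec())
    assert len(kept) == 5
    assert any("no record-level filter" in m for m in caplog.messages)


def test_pass_count_matches_manifest(gen_dataset):
    _, records = open_vcf(gen_dataset["vcf"])
    kept = stream_filter(records, FilterSpec(pass_only=True))
    assert len(kept) == gen_dataset["manifest"].n_pass


def test_conjunction_equals_intersection(gen_dataset):
    """pass AND range == intersection of the two single-filter outputs."""
    rng = [GenomicRange("chr1", 1, 150_000)]
    def run(spec):
        _, records = open_vcf(gen_dataset["vcf"])
        return stream_filter(records, spec, allow_empty=True)
    both = run(FilterSpec(pass_only=True, ranges=rng))
    only_pass = run(FilterSpec(pass_only=True))
    only_rng = run(FilterSpec(ranges=rng))
    keys = lambda recs: [(r.chrom, r.pos) for r in recs]
    assert keys(both) == [k for k in keys(only_pass) if k in set(keys(only_rng))]
    assert len(both) == truth_count(
        gen_dataset["manifest"], FilterSpec(pass_only=True, ranges=rng))


def test_monotonicity(gen_dataset):
    """Adding a criterion never increases the retained count."""
    rng = [GenomicRange("chr2", 1, 200_000)]
    def count(spec):
        _, records = open_vcf(gen_dataset["vcf"])
        return len(stream_filter(records, spec, allow_empty=True))
    assert count(FilterSpec(pass_only=True, ranges=rng)) <= count(FilterSpec(ranges=rng))
    assert count(FilterSpec(ranges=rng)) <= count(FilterSpec())


def test_select_samples(tiny_vcf):
    header, records = open_vcf(tiny_vcf)
    recs = list(records)
    # identity
    h2, r2 = select_samples(header, recs, ["A", "B", "C"])
    assert h2.sample_ids == ["A", "B", "C"] and r2 == recs
    # reversal: values follow labels
    h3, r3 = select_samples(header, recs, ["C", "B", "A"])
    assert h3.sample_ids == ["C", "B", "A"]
    assert list(r3[0].calls) == ["C", "B", "A"]
    assert r3[0].calls["C"] == recs[0].calls["C"]
    # subset
    h4, r4 = select_samples(header, recs, ["B"])
    assert all(len(r.calls) == 1 for r in r4)
    assert r4[1].calls["B"] == {"GT": "0|1", "DP": "15"}
    with pytest.raises(UsageError, match="ZZZ"):
        select_samples(header, recs, ["ZZZ"])


def test_export_round_trip(tiny_vcf, tmp_path):
    header, records = open_vcf(tiny_vcf)
    kept = stream_filter(records, FilterSpec(pass_only=True))
    out = tmp_path / "filtered.vcf"
    export_filtered_vcf(header, kept, out)
    header2, records2 = open_vcf(out)
    recs2 = list(records2)
    assert recs2 == kept
    # idempotence: same filter on the export returns the same set
    _, records3 = open_vcf(out)
    assert stream_filter(records3, FilterSpec(pass_only=True)) == kept


def test_export_sample_subset_round_trip(tiny_vcf, tmp_path):
    header, records = open_vcf(tiny_vcf)
    h, recs = select_samples(header, list(records), ["C", "A"])
    out = tmp_path / "subset.vcf"
    export_filtered_vcf(h, recs, out)
    h2, records2 = open_vcf(out)
    assert h2.sample_ids == ["C", "A"]
    assert all(set(r.calls) == {"C", "A"} for r in records2)


def test_read_position_list(tmp_path):
    p = tmp_path / "pos.csv"
    p.write_text("chr,position\nchr1,100\nchr1,100\n1,200\n")
    pl = read_position_list(p)
    assert ("chr1", 100) in pl and ("CHR1", 200) in pl
    headerless = tmp_path / "pos2.csv"
    headerless.write_text("chr1,100\n")
    assert ("chr1", 100) in read_position_list(headerless)


def test_read_sample_list(tmp_path):
    p = tmp_path / "samples.csv"
    p.write_text("sample_id\nS001\nS003\n")
    assert read_sample_list(p) == ["S001", "S003"]
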