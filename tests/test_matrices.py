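"""Genotype encoding, matrix extraction, averages, metadata and grouping."""

import numpy as np
import pytest

from vcfviz import (DepthMatrix, GenotypeCategory, GenotypeMatrix,
                    MalformedDepthError, MalformedGenotypeError,
                    MalformedMetadataError, MissingFieldError, SampleMetadata,
                    avg_sample_depth, avg_variant_depth, encode_genotype,
                    export_tabular, extract_depth_matrix,
                    extract_genotype_matrix, group_by_trait, open_vcf,
                    read_metadata, stream_filter, FilterSpec)

HOM_REF, HET, HOM_VAR, NO_CALL = GenotypeCategory


@pytest.mark.parametrize("gt,expected", [
    ("0/0", HOM_REF), ("0|0", HOM_REF), ("0", HOM_REF), ("0/0/0", HOM_REF),
    ("0/1", HET), ("0|1", HET), ("1/0", HET), ("1/2", HET), ("0/1/2", HET),
    ("1/1", HOM_VAR), ("2|2", HOM_VAR), ("1", HOM_VAR), ("2/2/2", HOM_VAR),
    ("./.", NO_CALL), (".", NO_CALL), ("./1", NO_CALL), ("1/.", NO_CALL),
    (".|.", NO_CALL), ("0/.", NO_CALL),
])
def test_encode_genotype(gt, expected):
    assert encode_genotype(gt) is expected


def test_encode_genotype_rejects_garbage():
    for bad in ("x/0", "0/,", "", "0/-1"):
        with pytest.raises(MalformedGenotypeError):
            encode_genotype(bad)


def test_encoding_exhaustive_partition():
    """Every GT over alleles {0,1,2,.} up to ploidy 3, both separators,
    maps to exactly one category per a hand-written truth table."""
    alleles = ["0", "1", "2", "."]
    def truth(parts):
        if "." in parts:
            return NO_CALL
        if all(p == "0" for p in parts):
            return HOM_REF
        if len(set(parts)) == 1:
            return HOM_VAR
        return HET
    import itertools
    n_checked = 0
    for ploidy in (1, 2, 3):
        for parts in itertools.product(alleles, repeat=ploidy):
            for sep in ("/", "|"):
                got = encode_genotype(sep.join(parts))
                assert got is truth(parts), (parts, sep)
                n_checked += 1
    assert n_checked == (4 + 16 + 64) * 2


def test_extract_matrices_tiny(tiny_vcf):
    header, records = open_vcf(tiny_vcf)
    recs = list(records)
    g = extract_genotype_matrix(header, recs)
    assert g.row_labels[0] == "chr1:100" and g.col_labels == ["A", "B", "C"]
    assert g.values.tolist()[0] == [0, 1, 2]
    assert g.values.tolist()[1] == [3, 1, 1]   # ./., 0|1, 1/2
    assert g.values.tolist()[3] == [2, 0, 3]   # 1|1, 0/0, ./1
    d = extract_depth_matrix(header, recs)
    assert d.values[0].tolist() == [10, 20, 30]
    assert np.isnan(d.values[1][0]) and np.isnan(d.values[2][1])
    assert d.values[2][0] == 7


def test_extract_matrices_match_manifest(gen_dataset):
    header, records = open_vcf(gen_dataset["vcf"])
    recs = list(records)
    m = gen_dataset["manifest"]
    g = extract_genotype_matrix(header, recs)
    assert np.array_equal(g.values, m.gt_codes)
    d = extract_depth_matrix(header, recs)
    assert np.array_equal(d.values, m.depths, equal_nan=True)


def test_missing_format_fields(tiny_vcf, tmp_path):
    p = tmp_path / "nogt.vcf"
    p.write_text("##fileformat=VCFv4.2\n"
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
                 "chr1\t5\t.\tA\tT\t.\tPASS\t.\tDP\t9\n")
    header, records = open_vcf(p)
    recs = list(records)
    with pytest.raises(MissingFieldError, match="chr1:5"):
        extract_genotype_matrix(header, recs)
    assert extract_depth_matrix(header, recs).values[0][0] == 9


def test_malformed_depth(tmp_path):
    p = tmp_path / "baddp.vcf"
    p.write_text("##fileformat=VCFv4.2\n"
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
                 "chr1\t5\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:x\n")
    header, records = open_vcf(p)
    with pytest.raises(MalformedDepthError):
        extract_depth_matrix(header, list(records))


def test_averages_against_brute_force():
    rng = np.random.default_rng(42)
    vals = rng.integers(0, 100, size=(50, 8)).astype(float)
    vals[rng.random((50, 8)) < 0.15] = np.nan
    vals[:, 3] = np.nan  # one all-missing column
    m = DepthMatrix([f"chr1:{i+1}" for i in range(50)],
                    [f"S{j}" for j in range(8)], vals)
    by_sample = dict(avg_sample_depth(m))
    by_variant = dict(avg_variant_depth(m))
    for j, sid in enumerate(m.col_labels):
        col = [v for v in vals[:, j] if not np.isnan(v)]
        if not col:
            assert np.isnan(by_sample[sid])
        else:
            assert by_sample[sid] == pytest.approx(sum(col) / len(col), rel=1e-9)
    for i, lab in enumerate(m.row_labels):
        row = [v for v in vals[i] if not np.isnan(v)]
        assert by_variant[lab] == pytest.approx(sum(row) / len(row), rel=1e-9)


def test_avg_excludes_missing_simple():
    m = DepthMatrix(["chr1:1", "chr1:2"], ["a", "b"],
                    np.array([[10.0, 30.0], [20.0, np.nan]]))
    assert dict(avg_sample_depth(m))["a"] == 15.0
    assert dict(avg_sample_depth(m))["b"] == 30.0
    assert dict(avg_variant_depth(m))["chr1:2"] == 20.0


def test_read_metadata(tmp_path):
    p = tmp_path / "meta.csv"
    p.write_text("trait,S1,S2,S3,S4\n"
                 "case_control,1,2,--,1\n"
                 "facility,2,1,1,2\n")
    meta = read_metadata(p)
    assert meta.trait_names == ["case_control", "facility"]
    assert meta.values.tolist() == [[1, 2, 0, 1], [2, 1, 1, 2]]
    # realignment to VCF order, with warnings for mismatches
    meta2 = read_metadata(p, vcf_sample_ids=["S3", "S1", "S9"])
    assert meta2.sample_ids == ["S3", "S1", "S9"]
    assert meta2.trait_values("case_control").tolist() == [0, 1, 0]


def test_read_metadata_rejects_bad_value(tmp_path):
    p = tmp_path / "meta.csv"
    p.write_text("trait,S1,S2\ncase_control,1,3\n")
    with pytest.raises(MalformedMetadataError, match="'3'"):
        read_metadata(p)


def _toy_matrix_meta():
    g = GenotypeMatrix(["chr1:1"], ["A", "B", "C", "D"],
                       np.array([[0, 1, 2, 3]]))
    meta = SampleMetadata(["t"], ["A", "B", "C", "D"],
                          np.array([[2, 1, 2, 1]]))
    return g, meta


def test_group_by_trait_stable_order():
    g, meta = _toy_matrix_meta()
    out, m2 = group_by_trait(g, meta, "t")
    assert out.col_labels == ["B", "D", "A", "C"]
    assert out.values.tolist() == [[1, 3, 0, 2]]
    assert m2.sample_ids == out.col_labels
    # idempotent
    out2, m3 = group_by_trait(out, m2, "t")
    assert out2.col_labels == out.col_labels
    assert out2.values.tolist() == out.values.tolist()


def test_group_by_trait_permutation_property():
    """Random assignments: matches a stable-sort oracle and is a pure
    column permutation (labeled columns invariant as a multiset)."""
    rng = np.random.default_rng(13)
    for _ in range(50):
        n = int(rng.integers(2, 30))
        ids = [f"S{j}" for j in range(n)]
        tvals = rng.integers(0, 3, size=n)  # 0 = missing
        vals = rng.integers(0, 4, size=(5, n))
        g = GenotypeMatrix([f"chr1:{i+1}" for i in range(5)], ids, vals)
        meta = SampleMetadata(["t"], ids, tvals.reshape(1, -1))
        out, _ = group_by_trait(g, meta, "t")
        oracle = sorted(range(n), key=lambda j: {1: 0, 2: 1, 0: 2}[int(tvals[j])])
        assert out.col_labels == [ids[j] for j in oracle]
        before = {ids[j]: vals[:, j].tolist() for j in range(n)}
        after = {c: out.values[:, k].tolist() for k, c in enumerate(out.col_labels)}
        assert before == after


def test_group_missing_last():
    g = GenotypeMatrix(["chr1:1"], ["A", "B", "C"], np.array([[0, 1, 2]]))
    meta = SampleMetadata(["t"], ["A", "B", "C"], np.array([[0, 2, 1]]))
    out, _ = group_by_trait(g, meta, "t")
    assert out.col_labels == ["C", "B", "A"]


def test_export_tabular_round_trip(tmp_path):
    g, meta = _toy_matrix_meta()
    out, m2 = group_by_trait(g, meta, "t")
    path = tmp_path / "tab.csv"
    export_tabular(out, m2, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0] == ",B,D,A,C"
    assert lines[1] == "t,1,1,2,2"
    assert lines[2] == "chr1:1,HET,NO_CALL,HOM_REF,HOM_VAR"
    d = DepthMatrix(["chr1:1"], ["A", "B"], np.array([[5.0, np.nan]]))
    dpath = tmp_path / "dep.csv"
    export_tabular(d, None, dpath)
    assert dpath.read_text().strip().split("\n")[1] == "chr1:1,5,--"
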