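import gzip

import pytest

from vcfviz import GeneratorConfig, generate

TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##contig=<ID=chr3>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT:DP\t0/0:10\t0/1:20\t1/1:30
chr1\t200\trs7\tG\tC\t40\tq10;s50\t.\tGT:DP\t./.:.\t0|1:15\t1/2:8
chr2\t5\t.\tT\tA\t.\t.\t.\tGT:DP\t0/0:7\t0/0:.\t1/1:12
chr2\t300\t.\tC\tG\t99\tPASS\t.\tGT:DP\t1|1:25\t0/0:18\t./1:9
chr3\t4500000\t.\tA\tG,C\t10\tLowQual\t.\tGT:DP\t0/1:5\t2/2:40\t0/2:3
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    """Hand-written 3-sample, 5-record VCF exercising every parsing corner."""
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return str(path)


@pytest.fixture
def tiny_vcf_gz(tmp_path):
    path = tmp_path / "tiny.vcf.gz"
    with gzip.open(path, "wt") as out:
        out.write(TINY_VCF)
    return str(path)


@pytest.fixture(scope="session")
def gen_dataset(tmp_path_factory):
    """One mid-sized generated dataset shared across the session."""
    outdir = tmp_path_factory.mktemp("gen")
    config = GeneratorConfig(n_samples=24, n_variants=1000, seed=7)
    vcf_path, meta_path, manifest = generate(config, outdir)
    return {"vcf": vcf_path, "meta": meta_path, "manifest": manifest,
            "outdir": str(outdir)}
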