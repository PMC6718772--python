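"""Seeded synthetic VCF generator with a ground-truth manifest.

Provides a download-free test surface for the whole pipeline: sorted
multi-chromosome VCFs with GT:DP FORMAT fields, configurable PASS fraction,
missing calls, case/control alt-allele enrichment (a differential variant
burden between phenotype groups) and facility-dependent depth shifts (a
sequencing batch effect), plus the matching metadata CSV and a position
list.  Everything planted — per-record FILTER, per-cell genotype category
and depth, per-sample traits — is returned in a :class:`Manifest`, so tests
can check parser/filter/matrix output against ground truth without ever
re-parsing the file.

Identical seeds give byte-identical outputs.

Defaults sketch a desk-scale study: 24 samples x 1000 variants over three
chromosomes, about half the records PASS, 5% no-calls, mean coverage 40x
(facility A) vs 20x (facility B) with negative-binomial over-dispersion,
and a +0.15 alt-allele probability shift in cases.
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import UsageError
from .filters import FilterSpec, normalize_chrom

_FAIL_FILTERS = ("q10", "s50", "LowQual")
_BASES = ("A", "C", "G", "T")


@dataclass
class DepthModel:
    """Negative-binomial depth per facility: means and common dispersion."""

    mean_facility_a: float = 40.0
    mean_facility_b: float = 20.0
    dispersion: float = 5.0
    missing_rate: float = 0.02


@dataclass
class GeneratorConfig:
    n_samples: int = 24
    n_variants: int = 1000
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3")
    pass_fraction: float = 0.5
    nocall_rate: float = 0.05
    base_alt_prob: float = 0.25
    case_fraction: float = 0.5
    case_alt_enrichment: float = 0.15
    facility_split: float = 0.5
    multiallelic_fraction: float = 0.2
    depth_model: DepthModel = field(default_factory=DepthModel)
    seed: int = 0
    gzip_output: bool = False

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_variants < 1:
            raise UsageError("n_samples and n_variants must be >= 1")
        if not self.chroms:
            raise UsageError("at least one chromosome name is required")
        for name, p in (("pass_fraction", self.pass_fraction),
                        ("nocall_rate", self.nocall_rate),
                        ("base_alt_prob", self.base_alt_prob),
                        ("case_fraction", self.case_fraction),
                        ("facility_split", self.facility_split),
                        ("multiallelic_fraction", self.multiallelic_fraction),
                        ("depth missing_rate", self.depth_model.missing_rate)):
            if not 0.0 <= p <= 1.0:
                raise UsageError(f"{name} must be in [0, 1], got {p}")
        if self.base_alt_prob + self.case_alt_enrichment > 1.0:
            raise UsageError("base_alt_prob + case_alt_enrichment exceeds 1")
        if (self.depth_model.mean_facility_a <= 0
                or self.depth_model.mean_facility_b <= 0
                or self.depth_model.dispersion <= 0):
            raise UsageError("depth means and dispersion must be > 0")


@dataclass
class Manifest:
    """Planted ground truth for one generated dataset."""

    sample_ids: list[str]
    chrom: list[str]               # per record
    pos: list[int]                 # per record
    filter: list[str]              # raw FILTER column per record
    gt_codes: np.ndarray           # int8 (n_variants, n_samples), category codes
    depths: np.ndarray             # float (n_variants, n_samples), NaN = missing
    case_control: np.ndarray      # int8 per sample: 1 = case, 2 = control
    facility: np.ndarray          # int8 per sample: 1 = A, 2 = B
    config: GeneratorConfig

    @property
    def n_pass(self) -> int:
        return sum(f == "PASS" for f in self.filter)

    def to_json(self) -> str:
        d = {
            "sample_ids": self.sample_ids,
            "chrom": self.chrom,
            "pos": self.pos,
            "filter": self.filter,
            "gt_codes": self.gt_codes.tolist(),
            "depths": [[None if np.isnan(v) else int(v) for v in row]
                       for row in self.depths],
            "case_control": self.case_control.tolist(),
            "facility": self.facility.tolist(),
            "config": asdict(self.config),
            "n_pass": self.n_pass,
        }
        return json.dumps(d, indent=None, separators=(",", ":"))


def truth_count(manifest: Manifest, spec: FilterSpec) -> int:
    """Number of planted records satisfying *spec*, from the manifest alone."""
    n = 0
    for chrom, pos, filt in zip(manifest.chrom, manifest.pos, manifest.filter):
        if spec.pass_only and filt != "PASS":
            continue
        if spec.ranges and not any(
                normalize_chrom(chrom) == normalize_chrom(r.chrom)
                and r.start <= pos <= r.stop for r in spec.ranges):
            continue
        if spec.positions is not None and (chrom, pos) not in spec.positions:
            continue
        n += 1
    return n


def _split_counts(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def generate(config: GeneratorConfig,
             outdir: str | os.PathLike) -> tuple[str, str, Manifest]:
    """Write the VCF, metadata CSV, position list and manifest; return paths.

    Raises a validation error before touching the filesystem if the config
    is inconsistent.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ns, nv = config.n_samples, config.n_variants
    sample_ids = [f"S{i + 1:03d}" for i in range(ns)]

    # per-sample traits: 1 = case / facility A, 2 = control / facility B
    case_control = np.where(rng.random(ns) < config.case_fraction, 1, 2).astype(np.int8)
    facility = np.where(rng.random(ns) < config.facility_split, 1, 2).astype(np.int8)

    # sorted positions per chromosome, drawn without replacement
    chroms: list[str] = []
    positions: list[int] = []
    for name, count in zip(config.chroms, _split_counts(nv, len(config.chroms))):
        span = max(count * 1000, 10_000)
        pos = np.sort(rng.choice(span, size=count, replace=False) + 1)
        chroms.extend([name] * count)
        positions.extend(int(p) for p in pos)

    filters = [
        "PASS" if rng.random() < config.pass_fraction
        else ";".join(rng.choice(_FAIL_FILTERS,
                                 size=rng.integers(1, 3), replace=False))
        for _ in range(nv)
    ]

    dm = config.depth_model
    depth_mean = np.where(facility == 1, dm.mean_facility_a, dm.mean_facility_b)
    p_nb = dm.dispersion / (dm.dispersion + depth_mean)
    alt_prob = config.base_alt_prob + np.where(
        case_control == 1, config.case_alt_enrichment, 0.0)

    gt_codes = np.empty((nv, ns), dtype=np.int8)
    depths = np.full((nv, ns), np.nan)
    gt_strings: list[list[str]] = []
    dp_strings: list[list[str]] = []
    alts: list[list[str]] = []
    refs: list[str] = []
    quals: list[int] = []

    for i in range(nv):
        multi = rng.random() < config.multiallelic_fraction
        ref = _BASES[rng.integers(0, 4)]
        alt_pool = [b for b in _BASES if b != ref]
        n_alt = 2 if multi else 1
        alt = list(rng.choice(alt_pool, size=n_alt, replace=False))
        refs.append(ref)
        alts.append(alt)
        quals.append(int(rng.integers(20, 100)))

        row_gt: list[str] = []
        row_dp: list[str] = []
        for j in range(ns):
            dp = int(rng.negative_binomial(dm.dispersion, p_nb[j]))
            dp_missing = rng.random() < dm.missing_rate
            if dp_missing:
                row_dp.append(".")
            else:
                depths[i, j] = dp
                row_dp.append(str(dp))
            if rng.random() < config.nocall_rate:
                row_gt.append("./.")
                gt_codes[i, j] = 3
                continue
            allele_vals = []
            for _ in range(2):
                if rng.random() < alt_prob[j]:
                    a = 2 if (multi and rng.random() < 0.2) else 1
                else:
                    a = 0
                allele_vals.append(a)
            sep = "|" if rng.random() < 0.1 else "/"
            row_gt.append(sep.join(str(a) for a in allele_vals))
            if allele_vals[0] == allele_vals[1]:
                gt_codes[i, j] = 0 if allele_vals[0] == 0 else 2
            else:
                gt_codes[i, j] = 1
        gt_strings.append(row_gt)
        dp_strings.append(row_dp)

    manifest = Manifest(sample_ids, chroms, positions, filters, gt_codes,
                        depths, case_control, facility, config)

    # ---- write files -----------------------------------------------------
    vcf_name = "synthetic.vcf.gz" if config.gzip_output else "synthetic.vcf"
    vcf_path = os.path.join(outdir, vcf_name)
    lines: list[str] = []
    lines.append("##fileformat=VCFv4.2")
    lines.append("##source=vcfviz-synthvcf")
    for name in config.chroms:
        lines.append(f"##contig=<ID={name}>")
    for f in _FAIL_FILTERS:
        lines.append(f'##FILTER=<ID={f},Description="Synthetic fail filter">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">')
    lines.append("\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                            "FILTER", "INFO", "FORMAT"] + sample_ids))
    for i in range(nv):
        cols = [chroms[i], str(positions[i]), ".", refs[i], ",".join(alts[i]),
                str(quals[i]), filters[i], ".", "GT:DP"]
        cols.extend(f"{gt_strings[i][j]}:{dp_strings[i][j]}" for j in range(ns))
        lines.append("\t".join(cols))
    text = "\n".join(lines) + "\n"
    if config.gzip_output:
        with open(vcf_path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                gz.write(text.encode())
    else:
        with open(vcf_path, "w", encoding="utf-8") as out:
            out.write(text)

    meta_path = os.path.join(outdir, "metadata.csv")
    with open(meta_path, "w", encoding="utf-8") as out:
        out.write(",".join(["trait"] + sample_ids) + "\n")
        out.write(",".join(["case_control"] + [str(v) for v in case_control]) + "\n")
        out.write(",".join(["facility"] + [str(v) for v in facility]) + "\n")

    pos_path = os.path.join(outdir, "positions.csv")
    with open(pos_path, "w", encoding="utf-8") as out:
        out.write("chr,position\n")
        for i in range(0, nv, 10):
            out.write(f"{chroms[i]},{positions[i]}\n")

    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as out:
        out.write(manifest.to_json())

    return vcf_path, meta_path, manifest
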