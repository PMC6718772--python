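# vcfviz

Streaming VCF filtering and multi-sample variant visualization.

Variant Call Format (VCF) files from sequencing studies are dense and often
far larger than memory, and inspecting them today means chaining several
tools (subset, index, extract, reshape, plot). `vcfviz` is a single-command
tool and library for researchers and clinicians doing variant analysis or
sequencing quality control: it reads a VCF line by line — no tabix index, no
preprocessing, compressed or not — keeps only the records that match the
chosen filters, and renders multi-sample heatmaps of genotype calls and read
depths plus average-depth scatter plots, with samples optionally grouped by
binary metadata traits (case/control, sequencing facility, ...).

## What it computes

For each retained variant record *i* and sample *j*:

* **Genotype category** G<sub>ij</sub> ∈ {0: homozygous reference, 1:
  heterozygous variant, 2: homozygous variant, 3: no call}, derived from the
  GT field ("/" or "|" separators; any missing allele ⇒ no call; mixed
  non-reference alleles such as `1/2` ⇒ heterozygous).
* **Read depth** D<sub>ij</sub> from the DP field, with "." kept as missing
  (never imputed as zero).
* Column/row summaries: mean sample depth D̄<sub>·j</sub> and mean variant
  depth D̄<sub>i·</sub> over non-missing entries.

Record-level filters (combinable; each one narrows the selection):
`FILTER == PASS`, membership in a chromosome/position list, and genomic
ranges `chr:start-stop` (inclusive, union over repeated ranges). Chromosome
names are compared case-insensitively with an optional `chr` prefix, so
`1` and `chr1` match. Filtering is streaming: a record that fails is
released before the next line is read, so memory holds only the matches.

Genotype heatmaps use a four-level Viridis-derived categorical scale;
depth heatmaps a monochrome blue ramp (light = low coverage — batch
effects and hard-to-sequence regions show up as light streaks) with
missing cells in neutral gray. HTML output is a self-contained HTML5
document with hover labels (position, sample, value), pan and zoom;
PDF/SVG/PNG/EPS are publication-quality static exports.

## Worked example

Generate a seeded synthetic dataset (24-sample-style cohort scaled to 12
samples here: case/control genotype enrichment plus a two-facility depth
shift), then filter and plot:

```sh
$ vcfviz simulate --seed 42 --samples 12 --variants 200 -o demo/sim
wrote demo/sim/synthetic.vcf (200 variants, 12 samples, 101 PASS) and demo/sim/metadata.csv

$ vcfviz -f demo/sim/synthetic.vcf --pass --range chr1:1-40000 \
    --metadata demo/sim/metadata.csv --group case_control \
    -o demo/plots --prefix demo --export-tabular -v
INFO vcfviz: opened demo/sim/synthetic.vcf with 12 samples
INFO vcfviz.filters: filtered 21 of 200 records
INFO vcfviz: retained 21 records x 12 samples
INFO vcfviz: genotype matrix: 21 x 12
INFO vcfviz: depth matrix: 21 x 12
INFO vcfviz: wrote demo/plots/demo_genotype-heatmap.html
INFO vcfviz: wrote demo/plots/demo_depth-heatmap.html
INFO vcfviz: wrote demo/plots/demo_sample-depth-scatter.html
INFO vcfviz: wrote demo/plots/demo_variant-depth-scatter.html
INFO vcfviz: wrote demo/plots/demo_genotypes.csv
INFO vcfviz: wrote demo/plots/demo_depths.csv
```

Of the 200 simulated records, 101 are PASS and 21 of those fall in
`chr1:1-40000`; the four plots show those 21 variants × 12 samples. With
`--group case_control` the columns are reordered so all group-1 (case)
samples come first, and the exported table carries the trait rows above the
variant rows:

```
,S002,S005,S009,S010,S011,S001,S003,S004,S006,S007,S008,S012
case_control,1,1,1,1,1,2,2,2,2,2,2,2
facility,2,2,2,1,2,2,1,1,1,2,2,2
chr1:2933,HET,HET,HET,NO_CALL,HOM_REF,HOM_REF,HOM_REF,HOM_REF,HET,HET,HET,HOM_REF
```

`--export-vcf` additionally writes the retained records back out as a valid
VCF; `--plots` selects a subset of the four plot types; `--format pdf`
(or svg/png/eps) switches to static output.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
exercises the whole pipeline end to end — generates a seeded 24-sample ×
1000-variant dataset, PASS-filters it, extracts both matrices, and renders
all four plot types grouped by metadata — and writes the JSON results
summary to `--out`.
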