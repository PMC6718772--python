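# Methods

## Streaming model and memory contract

The reader (`vcf_stream`) is an index-free, single-pass line parser.
Compression is detected from gzip magic bytes, never the file extension.
The record iterator is a plain generator: consuming record *k* requires
reading lines 1..*k* only, and the filter (`filters.stream_filter`) tests
each record as it arrives, appending matches and explicitly dropping the
reference to a non-match before the next line is parsed. Peak memory is
therefore the set of matching records plus one in-flight record — the
property the acceptance suite asserts directly on a 100,000-record file
with instrumented (weakref-tracked) record construction. The file is
assumed position-sorted but this is not enforced, and no early termination
is attempted after a range's end: a single full pass tolerates unsorted
files and multiple disjoint ranges at the cost of scanning to EOF.

Per-sample values are stored as raw strings paired positionally to the
FORMAT keys; nothing is interpreted at parse time. This keeps the parser
tolerant of dialect drift (FORMAT keys are not validated against `##FORMAT`
meta lines) and makes filtered-VCF export byte-faithful. Lines are decoded
as UTF-8 with replacement characters rather than failing on stray bytes.

## Filter semantics

* **PASS**: `FILTER == ["PASS"]`, case-sensitive. A missing FILTER (`.`)
  is *not* a pass — absence of filtering is not evidence of passing.
* **Genomic ranges**: 1-based, both endpoints inclusive; repeated ranges
  are a union, and overlapping ranges are not merged (a record matching
  several still appears once, in file order).
* **Position list**: set membership on (chromosome, position); duplicates
  deduplicate.
* Multiple active criteria combine by conjunction (AND) — the only reading
  under which each added filter narrows the view; this is a package choice
  where the combination rule was ambiguous.
* Chromosome names are normalized only at comparison time (case-fold,
  strip leading `chr`), so `1`/`chr1`/`CHR1` interoperate between the VCF
  and user CSVs while exports keep verbatim names.
* Zero matches raise an explicit empty-result error (exit code 4 on the
  CLI) instead of producing empty plots.

## Genotype classification

Four categories with fixed codes (they key the color scale and must be
stable across runs): HOM_REF=0, HET=1, HOM_VAR=2, NO_CALL=3. Separators
`/` and `|` are equivalent (phasing ignored). Rules, applied in order to
the allele list of any ploidy: any `.` allele ⇒ NO_CALL (a partially
missing call like `./1` cannot be confidently categorized); all alleles
`0` ⇒ HOM_REF; all alleles equal and non-zero ⇒ HOM_VAR; otherwise ⇒ HET.
Multi-allelic heterozygotes (`1/2`) are HET: only all-identical
non-reference alleles count as homozygous variant. The classification is
total over syntactically valid GT strings (checked exhaustively up to
ploidy 3) and is cross-checked against cyvcf2's independent `gt_types`
classification on generated files.

## Depth handling

DP values are non-negative integers; `.` or an absent trailing subfield is
missing (NaN internally, `--` in exports). Averages are arithmetic means
over non-missing entries only — missing means unmeasured, not zero — and an
all-missing row/column yields a missing mean, which scatter plots omit with
a logged count. Stored depths are never capped; `depth_ceiling` clips the
*displayed* color ramp only, for contrast when a few cells dominate.

## Grouping

`group_by_trait` stably reorders columns by one binary trait: group 1
first, then group 2, then missing, preserving original order within each
group (left-first ordering of the lower code is a package convention; which
group comes first was unspecified). It is a pure column permutation —
values and metadata move with their sample labels — and idempotent.
Metadata CSVs encode traits as rows and samples as columns, values in
{1, 2} with `--` for missing; rows are realigned to VCF sample order by ID,
with warnings for samples present on only one side.

## Visualization choices

* Genotype scale: 4 evenly spaced Viridis samples (`#440154, #31688e,
  #35b779, #fde725`) in code order — colorblind-safe and
  grayscale-convertible; the legend always shows all four categories
  regardless of which occur.
* Depth scale: matplotlib `Blues`, low = light / high = dark, so low
  coverage reads as light streaks; missing cells are neutral gray outside
  the ramp.
* Rows are drawn in filtered-record (file) order, top row first; no
  clustering or downsampling is ever applied (a warning reports large row
  counts; the remedy is filtering).
* Static formats (PDF/SVG/PNG/EPS) are rendered by matplotlib. HTML output
  is generated by a small built-in SVG backend: a self-contained HTML5
  document with every row/column label embedded as text, per-cell
  `<title>` hover labels (position | sample | value) and an inline script
  for wheel-zoom and drag-pan. The original design target for plotting was
  Plotly; this package deliberately ships its own HTML backend instead so
  the interactive output has zero runtime dependencies.
* All artifacts are written to a temporary name and atomically renamed, so
  error paths leave no partial files.

## Synthetic data generator

`synthvcf.generate` emulates the two study designs the visualizations are
for: a differential burden of variants between cases and controls, and a
sequencing-facility batch effect in coverage. Defaults (a "stated world",
not tuning knobs): 24 samples × 1000 variants over chr1–chr3; PASS fraction
0.5 (non-PASS records draw 1–2 names from {q10, s50, LowQual}, exercising
the `;`-split); no-call rate 0.05; per-allele alternate probability 0.25
with +0.15 for case samples (case fraction 0.5); 20% of sites
multi-allelic (second ALT drawn with probability 0.2 per non-reference
allele); depths negative-binomial with dispersion 5 and mean 40× for
facility A vs 20× for facility B (facility split 0.5), depth missing rate
0.02; ~10% of calls use the phased `|` separator. Positions are drawn
without replacement per chromosome and sorted, so the output is a valid
sorted VCF. Identical seeds give byte-identical files, and every planted
value (FILTER, per-cell category and depth, traits) is returned in a
manifest that tests use as ground truth.

What the generator does **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, indel/SV alleles, INFO annotations, or
correlated missingness. A green test therefore establishes parsing,
filtering, bookkeeping and rendering correctness — not robustness to every
real-world VCF dialect quirk.

## Numerical and degenerate-input notes

* Mean-depth agreement with brute force is exact in floating point
  (asserted at 1e-9 relative tolerance).
* The expected case-minus-control mean category difference used in the
  use-case reconstruction test is computed in closed form from the
  generator model (two iid alleles; heterozygosity/homozygosity
  probabilities combined over multi-allelic site frequency and no-call
  rate), and the measured difference must fall within 3 standard errors,
  pooled over 10 seeds.
* Degenerate inputs: single-position ranges (`chrX:5-5`) are valid; an
  all-missing depth column is legal and yields a missing mean; a VCF
  without a `##fileformat` line parses with a warning; a missing `#CHROM`
  line is a hard error.

## Known limitations

One trait at a time for grouping; binary traits only; no INFO/QUAL
filtering or annotation support; no BCF or tabix-indexed access (by
design); EPS export inherits matplotlib's limitations (no transparency).
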