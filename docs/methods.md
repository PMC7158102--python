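# Methods

## Model and procedure

The engine operates on a targeted capture panel: a fixed set of genomic
intervals (BED, 0-based half-open) grouped into named gene regions, stored
together with per-sample data in one SQLite file per panel. Contig names
are normalized to the `chr`-prefixed spelling of the 24 canonical human
contigs; the supported reference builds are hg19 and hg38 (bundled contig
lengths provide cumulative coordinates for whole-genome and Circos views).
Interval coordinates keep BED convention; variant positions keep VCF
1-based convention.

### Copy-number ratio

Per interval, `R = (T/T_nf)/(N/N_nf)` with `T`, `N` the mean tumor and
normal depths and `T_nf`, `N_nf` the arithmetic mean depth over the
normalization set. Assumptions: the normal is diploid over the
normalization set, and library size is the only systematic difference the
factors need to remove — per-interval capture bias is assumed shared
between the pair and cancels in the ratio. Three normalization modes:

* `autosome_default` — mean over chr1–chr22 (sex chromosomes excluded so
  patient sex does not shift the factor);
* `user_chromosomes` — mean over an explicit chromosome set, for samples
  whose autosomes are themselves widely aberrant (e.g. hyperdiploid
  myeloma);
* `provider_ratio` — pass through ratios computed upstream; a `log2`
  depth-table column is exponentiated to linear scale at import.

Degenerate inputs: intervals overlapping a blacklist region by ≥1 bp are
excluded from both the track and the factors (the blacklist marks
unreliable capture; letting it into a mean would defeat it); intervals with
zero normal depth are dropped with a warning rather than yielding infinite
ratios; an empty normalization selection or a zero-mean factor is an error.

### Calls

Per-interval states use two linear-scale thresholds, `loss_max = 0.75` and
`gain_min = 1.25` by default: `R ≤ loss_max` → deleted, `R ≥ gain_min` →
gained, otherwise neutral (boundaries inclusive toward the aberrant state,
so a ratio sitting exactly on a threshold is flagged rather than hidden).
The defaults are the midpoints between clonal integer states (1, 2, 3
copies in a pure diploid tumor → ratios 0.5, 1.0, 1.5); subclonality or low
purity compresses ratios toward 1 and may require tighter thresholds, which
are exposed in config and on the CLI. Gene-group calls summarize member
ratios by the median (robust to a single noisy probe; mean available) and
apply the same thresholds. No segmentation, purity/ploidy fitting or
integer copy-number inference is attempted — calls are deliberately
per-interval/per-gene.

### Variant filter semantics

A record passes when its FILTER field is exactly `PASS` or `.`;
multi-value, semicolon-joined fields count as failed. Multi-allelic
records are split one row per ALT at import. The failed records stay in
the database and are shown on request, so passed + failed always equals
imported. A breakend matches a chromosome filter from either end.

### Annotation extraction

VEP `CSQ` strings are split per transcript entry on commas and per subfield
on pipes, using the order declared in the VCF header. Gene symbol,
consequence, protein change and codon change come from `SYMBOL`,
`Consequence`, `HGVSp` and `HGVSc`; when `HGVSp` is empty the protein
change falls back to the amino-acid code `REF<pos>ALT` assembled from
`Amino_acids` and `Protein_position`. Absent subfields stay empty — nothing
is invented. Entries with the wrong subfield count are skipped with a
warning. For multi-allelic rows the entry whose `Allele` matches the ALT is
preferred. Records without CSQ keep their raw INFO string for display.

### BAF / LOH view

VAF = alt/(ref+alt) per sample; a site is heterozygous-in-normal when its
normal VAF lies in the (inclusive) band [0.4, 0.6] (configurable; the band
is a pragmatic depth-robust proxy for a genotype call). Sites with zero
total depth in either sample are excluded. The SNP panel plots only
heterozygous-in-normal sites: tumor VAF divergence from 0.5 there indicates
allelic imbalance, corroborating deletions and exposing copy-neutral LOH.

### Views

Each view is built as a `PlotSpec` — points, arcs and axis metadata —
and rasterized separately; all testing is against the `PlotSpec` data, never pixels
(SVG output is additionally byte-deterministic: fixed hash salt, stripped
timestamps). Whole-genome x is the cumulative genomic coordinate; the
continuous chromosome view uses ranks 0..n−1 in genomic order. Colors:
gained red, neutral black, deleted blue; gene groups get deterministic
palette colors from a hash of the group name. Circos arcs: intra-chromosomal
SVs always (their second endpoint is the stored END coordinate),
inter-chromosomal only when requested; breakend mate pairs collapse to a
single arc keyed by the unordered endpoint pair.

## Synthetic data generator

The generator emulates a myeloma-like mutation + copy-number +
translocation panel: 8 chromosomes × 6 genes × 10 intervals (480 intervals,
120 bp, 1 kb apart, genes 1 Mb apart — small synthetic positions on real
contig names), base depth 500×, and a balanced event set of four
single-copy deletions (true R = 0.5: TP53, RB1, CYLD, TRAF3) and four gains
(true R = 1.5: CKS1B, MYC, NSD2, MAF). Balance makes the panel-wide mean
true ratio exactly 1, so the noiseless (CV = 0) track reproduces the truth
table exactly — a useful algebraic check.

Depth noise is multiplicative log-normal. Each observed depth is
`base × true_ratio × exp(capture + eps)` where `capture` is a per-interval
log-deviate shared by the tumor/normal pair and `eps` is sample-specific;
`depth_cv` (default 0.10) is the marginal CV of one depth and
`capture_bias_fraction` (default 0.5) the shared share of its log-variance.
The shared component models reproducible bait-capture efficiency — the
empirical property that makes tumor/normal ratio methods work at all — and
cancels in R; real capture pairs are typically more correlated than 0.5,
so the default is conservative for ratio noise. Under these defaults the
ratio log-sd is ≈0.10, giving near-complete recovery of 0.5/1.5 events at
thresholds (0.75, 1.25) with a low neutral miscall rate, as measured by the
test suite and acceptance script.

VCFs are written as standards-conformant text: five small variants with
VEP-style CSQ (FILTER mix 3 PASS / 1 `.` / 1 `LowEVS`; the first sits in
TP53 so the mutation-plus-deletion bi-allelic inactivation pattern appears),
and four SV events — three intra-chromosomal (DEL/DUP/INV with END, one `.`
and one `MinQUAL`) plus one t(4;14)-style translocation emitted as a
reciprocal BND mate pair with MATEID. The SNP backbone places four sites
per gene (round-robin, so every event region is covered, as real panels
arrange), two-thirds heterozygous in the normal at ~100× depth; tumor
allele fractions over aberrant intervals follow a purity-0.8 clonal model
(loss: VAF → 1/6 or 5/6; gain: → 5/14 or 9/14).

What the generator does not emulate: GC-dependent bias trends, off-target
reads, FFPE artifacts, subclonal mixtures, germline CNVs, mapping-ambiguity
hotspots, or realistic inter-gene spacing. Passing tests therefore
demonstrate the correctness of the arithmetic, filter logic and plumbing
under a clean noise model — not calling performance on real capture data.

## Numerical and design choices

* Depth rows match panel targets exactly on (chromosome, start, end) after
  name normalization — both derive from the same BED, so fuzzy matching
  would only mask pipeline mix-ups; zero matches is a hard error.
* Imports are idempotent per (sample, data type): previous rows are
  replaced, never duplicated.
* Normalization uses plain arithmetic means (the definition of the
  factors), computed in float64; the oracle-equivalence tests hold to
  1e-12.
* Sorting is total: (chromosome rank chr1..chr22, X, Y; start; end; label),
  making every table and spec deterministic.
* The SQLite schema (panel meta, targets, groups, membership, blacklist,
  samples, depths, variants, SVs, SNP records) is an internal design,
  constrained by the round-trip property: reopening a database recovers the
  creating panel definition field-for-field.
* Problem sizes in tests and the acceptance script (480-interval fixture,
  100 random oracle panels ≤200 intervals, 1000 CSQ round-trips) keep a
  full run in seconds while leaving binomial noise on recovery rates small
  against the tested margins.

## Known limitations

* Human panels only (chr1–22, X, Y; hg19/hg38); no liftover.
* Tumor-only samples are unsupported — the ratio needs a matched normal.
* Non-VEP annotation formats are stored raw, not parsed.
* The heterozygosity band is a VAF heuristic, not a genotype likelihood;
  very deep or very shallow SNP data may warrant adjusting it.
* Breakend mate deduplication assumes reciprocal mate coordinates; mates
  recorded with off-by-one positions would draw two arcs.
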