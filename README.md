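# tarpan

A targeted sequencing panel engine for cancer genomics. Targeted panels
capture a few hundred intervals over disease-relevant genes (mutation
hotspots, copy-number regions, translocation partners) and sequence them
deeply in tumor/normal pairs. `tarpan` turns the standard caller outputs —
per-interval depth tables, small-variant and structural-variant VCFs, SNP
allelic depths — into a single-file SQLite database per panel, and provides
the analysis layer a reviewer of such samples needs: normalized copy-number
ratios, automatic per-interval and per-gene calls, filtered variant tables,
B-allele-frequency inspection for loss of heterozygosity (LOH), and five
deterministic genome views.

It is aimed at bioinformaticians and cancer biologists who already run a
calling pipeline (e.g. CNVKit for depths, Strelka2 for somatic variants,
Manta for structural variants, Ensembl VEP for annotation) and want a
queryable, scriptable store plus reproducible figures, with every stored
artifact openable in any standard SQLite client.

## The copy-number model

For each captured interval the engine computes the tumor/normal copy-number
ratio

```
R = (T / T_nf) / (N / N_nf)
```

where `T` and `N` are the interval's mean read depths in tumor and normal,
and `T_nf`, `N_nf` are normalization factors: the mean interval depth over a
chosen chromosome set. The default set is the autosomes chr1–chr22; the
user may restrict it to specific chromosomes, which matters when whole
chromosomes are aberrant and would otherwise bias the factor. When the
upstream depth tool already supplies ratios (e.g. a CNVKit `log2` column)
those are passed through instead. `R ≈ 1` is copy-neutral; with default
thresholds, `R ≤ 0.75` is called deleted and `R ≥ 1.25` gained (midpoints
between clonal one/two/three-copy states). Gene-group calls summarize
member intervals by their median ratio. Blacklisted intervals are hidden
from views and excluded from normalization.

Variant tables follow the viewer convention: a record passes when its
FILTER column is exactly `PASS` or `.`; everything else is hidden unless
failed records are requested. VEP `CSQ` annotations are parsed into gene
symbol, consequence, protein and codon change. Breakend (`BND`) records get
their partner coordinates parsed from the bracket ALT notation, so
translocations such as t(4;14) are discoverable from either chromosome and
drawn as Circos links.

## Worked example

The package ships a synthetic-data module that generates a complete
myeloma-like input set: 480 intervals over 48 genes on 8 chromosomes, four
injected single-copy deletions (TP53, RB1, CYLD, TRAF3, true ratio 0.5) and
four gains (CKS1B, MYC, NSD2, MAF, true ratio 1.5), a t(4;14)-style
breakend pair, and a SNP backbone with LOH shifts over the deletions.

```sh
tarpan fixtures --out fx --seed 5
tarpan create-db --name demo --genome hg38 \
    --targets fx/targets.bed --groups fx/groups.bed --out demo.sqlite
tarpan import depths    --db demo.sqlite --sample S1 \
    --tumor fx/tumor_depths.tsv --normal fx/normal_depths.tsv
tarpan import mutations --db demo.sqlite --sample S1 --vcf fx/small_variants.vcf
tarpan import svs       --db demo.sqlite --sample S1 --vcf fx/structural_variants.vcf
tarpan import snps      --db demo.sqlite --sample S1 --source fx/snp_records.tsv
tarpan call --db demo.sqlite --sample S1 --groups | head -4
```

prints

```
group	summary_ratio	state	n_intervals
CKS1B	1.5162	gained	10
MCL1	0.9882	neutral	10
G1_2	0.9965	neutral	10
```

i.e. the injected CKS1B gain is called from the median of its ten interval
ratios while its unaltered neighbors stay neutral. The structural-variant
table shows the translocation from both ends:

```sh
tarpan query svs --db demo.sqlite --sample S1 --chrom chr14
```

```
chromosome	position	sv_type	partner_chromosome	partner_position	filter	passed	interchromosomal
chr4	1000050	BND	chr14	2000050	PASS	1	1
chr14	2000050	BND	chr4	1000050	PASS	1	1
```

and the five views render to image files:

```sh
for v in whole-genome chromosome chromosome-continuous snp circos; do
    tarpan plot --db demo.sqlite --sample S1 --view $v --chrom chr17 --out $v.png
done
```

The same operations are available as library functions
(`tarpan.compute_ratio_track`, `tarpan.auto_cn_calls`,
`tarpan.mutation_table`, `tarpan.whole_genome_spec`, ...), all of which
return plain data structures; plotting is split into spec-building (tested)
and rasterization (matplotlib).

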