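"""Synthetic inputs: panel BEDs, tumor/normal depths, VCFs, SNP tables.

The generator emulates a myeloma-style mutation + copy-number +
translocation panel: a few hundred capture intervals across eight
chromosomes, gene groups named after recurrently altered genes, balanced
clonal events (single-copy deletions at true ratio 0.5, gains at 1.5),
a t(4;14)-style translocation emitted as a reciprocal breakend mate pair,
and heterozygous SNPs whose tumor allele fractions shift over aberrant
regions.

Depth noise model
-----------------
Each observed mean interval depth is ``base_depth x true_ratio x
exp(capture_i + eps)``: ``capture_i`` is a per-interval capture-efficiency
log-deviate shared by the tumor and normal aliquots (bait efficiency is a
property of the interval, reproducible across the pair, and cancels in the
tumor/normal ratio), while ``eps`` is sample-specific. ``depth_cv`` is the
marginal coefficient of variation of one observed depth;
``capture_bias_fraction`` says how much of its log-variance is the shared
component (0.5 by default — conservative, real capture data are usually
more correlated than that).

Everything is reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import CONTIG_LENGTHS

FIXTURE_CHROMS = ("chr1", "chr4", "chr8", "chr13", "chr14", "chr16", "chr17", "chr21")

# Recurrently altered myeloma genes, used to name the first group(s) on
# each fixture chromosome so event injections read naturally.
KNOWN_GENES = {
    "chr1": ["CKS1B", "MCL1"],
    "chr4": ["NSD2", "FGFR3"],
    "chr8": ["MYC"],
    "chr13": ["RB1", "DIS3"],
    "chr14": ["TRAF3", "IGH"],
    "chr16": ["CYLD", "MAF"],
    "chr17": ["TP53"],
    "chr21": ["U2AF1"],
}

# Balanced by construction: four single-copy deletions (0.5) and four
# gains (1.5) over equally sized genes, so the panel-wide mean true ratio
# is exactly 1 and the noiseless track reproduces the truth exactly.
DEFAULT_EVENTS = (
    ("TP53", 0.5),
    ("RB1", 0.5),
    ("CYLD", 0.5),
    ("TRAF3", 0.5),
    ("CKS1B", 1.5),
    ("MYC", 1.5),
    ("NSD2", 1.5),
    ("MAF", 1.5),
)

CSQ_FORMAT = [
    "Allele", "Consequence", "IMPACT", "SYMBOL", "Gene",
    "HGVSc", "HGVSp", "Protein_position", "Amino_acids",
]

_CONSEQUENCES = [
    "missense_variant", "stop_gained", "synonymous_variant",
    "frameshift_variant", "splice_donor_variant", "intron_variant",
]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 8
    genes_per_chromosome: int = 6
    intervals_per_gene: int = 10
    base_depth: float = 500.0
    depth_cv: float = 0.10
    capture_bias_fraction: float = 0.5
    tumor_purity: float = 0.8
    events: tuple = DEFAULT_EVENTS
    n_mutations: int = 5
    n_svs: int = 4
    sv_inter_fraction: float = 0.25
    # ~4 backbone SNPs per gene region: LOH assessment needs several
    # normal-heterozygous sites per gene, as real panels provide
    n_snps: int = 192
    blacklist_genes: tuple = ()

    def chromosomes(self) -> tuple[str, ...]:
        return FIXTURE_CHROMS[: self.n_chromosomes]


@dataclass(frozen=True)
class FixtureInterval:
    chromosome: str
    start: int
    end: int
    gene: str
    true_ratio: float


def panel_layout(config: SimulationConfig) -> list[FixtureInterval]:
    """Deterministic interval layout: genes spaced 1 Mb apart, intervals
    every 1 kb within a gene, 120 bp each.  Small synthetic positions on
    real contig names so both genome builds' code paths run."""
    ratio_of = dict(config.events)
    out = []
    for chrom in config.chromosomes():
        names = list(KNOWN_GENES.get(chrom, []))
        for j in range(config.genes_per_chromosome):
            gene = names[j] if j < len(names) else f"G{chrom[3:]}_{j}"
            gene_start = 1_000_000 * (j + 1)
            for k in range(config.intervals_per_gene):
                start = gene_start + 1000 * k
                out.append(
                    FixtureInterval(
                        chrom, start, start + 120, gene, ratio_of.get(gene, 1.0)
                    )
                )
    unknown = set(ratio_of) - {iv.gene for iv in out}
    if unknown:
        raise ValueError(f"events reference genes not on the panel: {sorted(unknown)}")
    return out


def generate_panel(config: SimulationConfig, out_dir) -> dict:
    """Write targets/groups (and optional blacklist) BEDs; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = panel_layout(config)
    targets_bed = out_dir / "targets.bed"
    with open(targets_bed, "w") as fh:
        for iv in layout:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.gene}\n")
    groups_bed = out_dir / "groups.bed"
    span: dict[str, list] = {}
    for iv in layout:
        if iv.gene not in span:
            span[iv.gene] = [iv.chromosome, iv.start, iv.end]
        else:
            span[iv.gene][2] = iv.end
    with open(groups_bed, "w") as fh:
        for gene, (chrom, s, e) in span.items():
            fh.write(f"{chrom}\t{s}\t{e}\t{gene}\n")
    paths = {"targets_bed": targets_bed, "groups_bed": groups_bed, "blacklist_bed": None}
    if config.blacklist_genes:
        blacklist_bed = out_dir / "blacklist.bed"
        with open(blacklist_bed, "w") as fh:
            for gene in config.blacklist_genes:
                chrom, s, e = span[gene]
                fh.write(f"{chrom}\t{s}\t{e}\t{gene}\n")
        paths["blacklist_bed"] = blacklist_bed
    return paths


def generate_depths(config: SimulationConfig, out_dir) -> dict:
    """Write tumor/normal depth tables and the per-interval truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = panel_layout(config)
    rng = np.random.default_rng(config.seed)
    n = len(layout)
    sigma2 = math.log(1.0 + config.depth_cv**2)
    sigma_shared = math.sqrt(config.capture_bias_fraction * sigma2)
    sigma_resid = math.sqrt((1.0 - config.capture_bias_fraction) * sigma2)
    capture = rng.normal(0.0, sigma_shared, n) if sigma_shared > 0 else np.zeros(n)
    eps_n = rng.normal(0.0, sigma_resid, n) if sigma_resid > 0 else np.zeros(n)
    eps_t = rng.normal(0.0, sigma_resid, n) if sigma_resid > 0 else np.zeros(n)
    normal = config.base_depth * np.exp(capture + eps_n)
    tumor = (
        config.base_depth
        * np.array([iv.true_ratio for iv in layout])
        * np.exp(capture + eps_t)
    )
    paths = {
        "tumor_table": out_dir / "tumor_depths.tsv",
        "normal_table": out_dir / "normal_depths.tsv",
        "truth_table": out_dir / "truth.tsv",
    }
    for key, depths in (("tumor_table", tumor), ("normal_table", normal)):
        with open(paths[key], "w") as fh:
            fh.write("chromosome\tstart\tend\tgene\tdepth\n")
            for iv, d in zip(layout, depths):
                fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.gene}\t{float(d)!r}\n")
    with open(paths["truth_table"], "w") as fh:
        fh.write("chromosome\tstart\tend\tgene\ttrue_ratio\n")
        for iv in layout:
            fh.write(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.gene}\t{iv.true_ratio}\n"
            )
    return paths


# ---------------------------------------------------------------------------
# VCFs and SNP table


def format_csq_entry(subfields: dict) -> str:
    """Serialize one annotation to a pipe-joined CSQ entry (inverse of the
    importer's parser for the fixture format)."""
    return "|".join(subfields.get(name, "") for name in CSQ_FORMAT)


def random_csq_subfields(rng: np.random.Generator) -> dict:
    """Random plausible CSQ subfield values, including empty ones."""
    symbol = "" if rng.random() < 0.1 else f"GENE{rng.integers(1, 500)}"
    aa_pairs = ["R/Q", "G/E", "L/P", "K/*", "A"]
    has_hgvsp = rng.random() < 0.6
    pos = int(rng.integers(1, 900))
    sub = {
        "Allele": "ACGT"[rng.integers(0, 4)],
        "Consequence": _CONSEQUENCES[rng.integers(0, len(_CONSEQUENCES))],
        "IMPACT": ["HIGH", "MODERATE", "LOW", "MODIFIER"][rng.integers(0, 4)],
        "SYMBOL": symbol,
        "Gene": f"ENSG{rng.integers(1, 10**6):011d}" if symbol else "",
        "HGVSc": "" if rng.random() < 0.2 else f"c.{rng.integers(1, 3000)}G>A",
        "HGVSp": f"p.Arg{pos}His" if has_hgvsp else "",
        "Protein_position": str(pos) if rng.random() < 0.9 else "",
        "Amino_acids": aa_pairs[rng.integers(0, len(aa_pairs))] if rng.random() < 0.9 else "",
    }
    return sub


def _vcf_header(config: SimulationConfig, extra_lines: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for chrom in config.chromosomes():
        lines.append(
            f"##contig=<ID={chrom},length={CONTIG_LENGTHS['hg38'][chrom]}>"
        )
    lines.extend(extra_lines)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def _filter_plan(n: int, fail_value: str) -> list[str]:
    """Deterministic FILTER mix: ~60% PASS, ~20% '.', ~20% failing."""
    n_dot = max(1, n // 5) if n >= 2 else 0
    n_fail = max(1, n // 5) if n >= 3 else 0
    n_pass = n - n_dot - n_fail
    return ["PASS"] * n_pass + ["."] * n_dot + [fail_value] * n_fail


def generate_vcfs(config: SimulationConfig, out_dir) -> dict:
    """Write the small-variant VCF (with CSQ), SV VCF (with BND mates) and
    the SNP allelic-depth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = panel_layout(config)
    rng = np.random.default_rng(config.seed + 1)
    by_gene: dict[str, list[FixtureInterval]] = {}
    for iv in layout:
        by_gene.setdefault(iv.gene, []).append(iv)

    # --- small variants ---------------------------------------------------
    snv_path = out_dir / "small_variants.vcf"
    header = _vcf_header(
        config,
        [
            '##FILTER=<ID=LowEVS,Description="Low somatic evidence score">',
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
            'annotations from Ensembl VEP. Format: ' + "|".join(CSQ_FORMAT) + '">',
        ],
    )
    filters = _filter_plan(config.n_mutations, "LowEVS")
    bases = "ACGT"
    records = []
    # first mutation sits in TP53 when present: mutation + deletion is the
    # classic bi-allelic inactivation picture
    genes = list(by_gene)
    for i in range(config.n_mutations):
        gene = "TP53" if i == 0 and "TP53" in by_gene else genes[rng.integers(0, len(genes))]
        iv = by_gene[gene][rng.integers(0, len(by_gene[gene]))]
        pos = int(iv.start + 1 + rng.integers(0, iv.end - iv.start))
        ref = bases[rng.integers(0, 4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(0, 3)) % 4]
        sub = random_csq_subfields(rng)
        sub["Allele"] = alt
        sub["SYMBOL"] = gene
        csq = format_csq_entry(sub)
        records.append(
            (iv.chromosome, pos, f"{iv.chromosome}\t{pos}\tmut{i}\t{ref}\t{alt}\t"
             f"100\t{filters[i]}\tCSQ={csq}")
        )
    with open(snv_path, "w") as fh:
        fh.write(header)
        for _, _, line in records:
            fh.write(line + "\n")

    # --- structural variants ---------------------------------------------
    sv_path = out_dir / "structural_variants.vcf"
    sv_header = _vcf_header(
        config,
        [
            '##FILTER=<ID=MinQUAL,Description="QUAL below threshold">',
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End of SV">',
            '##INFO=<ID=MATEID,Number=.,Type=String,Description="Mate breakend id">',
            '##ALT=<ID=DEL,Description="Deletion">',
            '##ALT=<ID=DUP,Description="Duplication">',
            '##ALT=<ID=INV,Description="Inversion">',
        ],
    )
    n_inter = max(1, round(config.sv_inter_fraction * config.n_svs)) if config.n_svs else 0
    n_intra = config.n_svs - n_inter
    intra_filters = _filter_plan(n_intra, "MinQUAL") if n_intra else []
    sv_lines = []
    intra_types = ["DEL", "DUP", "INV"]
    intra_genes = [g for g in ("TP53", "CKS1B", "RB1") if g in by_gene] or genes[:1]
    for i in range(n_intra):
        gene = intra_genes[i % len(intra_genes)]
        ivs = by_gene[gene]
        svtype = intra_types[i % 3]
        pos = ivs[0].start + 1
        end = ivs[-1].end
        sv_lines.append(
            f"{ivs[0].chromosome}\t{pos}\tManta{svtype}:{i}\tN\t<{svtype}>\t"
            f"200\t{intra_filters[i]}\tSVTYPE={svtype};END={end}"
        )
    # translocation breakend mate pairs, t(4;14)-style when those contigs
    # are on the fixture panel
    for i in range(n_inter):
        if "NSD2" in by_gene and "IGH" in by_gene and i == 0:
            a, b = by_gene["NSD2"][0], by_gene["IGH"][0]
        else:
            ga, gb = genes[rng.integers(0, len(genes))], genes[rng.integers(0, len(genes))]
            while by_gene[gb][0].chromosome == by_gene[ga][0].chromosome:
                gb = genes[rng.integers(0, len(genes))]
            a, b = by_gene[ga][0], by_gene[gb][0]
        pa, pb = a.start + 50, b.start + 50
        sv_lines.append(
            f"{a.chromosome}\t{pa}\tMantaBND:{i}:0\tN\tN[{b.chromosome}:{pb}[\t"
            f"300\tPASS\tSVTYPE=BND;MATEID=MantaBND:{i}:1"
        )
        sv_lines.append(
            f"{b.chromosome}\t{pb}\tMantaBND:{i}:1\tN\tN]{a.chromosome}:{pa}]\t"
            f"300\tPASS\tSVTYPE=BND;MATEID=MantaBND:{i}:0"
        )
    with open(sv_path, "w") as fh:
        fh.write(sv_header)
        for line in sv_lines:
            fh.write(line + "\n")

    # --- SNP allelic depths -----------------------------------------------
    snp_path = out_dir / "snp_records.tsv"
    purity = config.tumor_purity
    with open(snp_path, "w") as fh:
        fh.write(
            "chromosome\tposition\tnormal_ref_depth\tnormal_alt_depth"
            "\ttumor_ref_depth\ttumor_alt_depth\n"
        )
        # round-robin over genes so every gene group (and hence every event
        # region) carries SNPs, like the SNP backbone of a real panel
        for i in range(config.n_snps):
            gene_ivs = by_gene[genes[i % len(genes)]]
            iv = gene_ivs[int(rng.integers(0, len(gene_ivs)))]
            pos = int(iv.start + 1 + rng.integers(0, iv.end - iv.start))
            het = rng.random() < 2 / 3
            n_total = int(rng.poisson(100)) + 1
            t_total = int(rng.poisson(100)) + 1
            if het:
                n_alt = int(rng.binomial(n_total, 0.5))
                # tumor allele fraction under the interval's true CN state
                if iv.true_ratio < 1.0:  # single-copy loss, one allele gone
                    lost_alt = rng.random() < 0.5
                    t_frac = (
                        (1 - purity) / (2 * (1 - purity) + purity)
                        if lost_alt
                        else (1 - purity + purity) / (2 * (1 - purity) + purity)
                    )
                elif iv.true_ratio > 1.0:  # one extra copy of one allele
                    dup_alt = rng.random() < 0.5
                    t_frac = (
                        (1 - purity + 2 * purity) / (2 * (1 - purity) + 3 * purity)
                        if dup_alt
                        else (1 - purity + purity) / (2 * (1 - purity) + 3 * purity)
                    )
                else:
                    t_frac = 0.5
            else:
                n_alt = 0
                t_frac = 0.0
            t_alt = int(rng.binomial(t_total, t_frac))
            fh.write(
                f"{iv.chromosome}\t{pos}\t{n_total - n_alt}\t{n_alt}"
                f"\t{t_total - t_alt}\t{t_alt}\n"
            )
    return {"snv_vcf": snv_path, "sv_vcf": sv_path, "snp_table": snp_path}


def generate_all(config: SimulationConfig, out_dir) -> dict:
    """Write every fixture input into ``out_dir``; returns all paths."""
    paths = {}
    paths.update(generate_panel(config, out_dir))
    paths.update(generate_depths(config, out_dir))
    paths.update(generate_vcfs(config, out_dir))
    return paths
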