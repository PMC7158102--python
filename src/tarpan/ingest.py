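"""Importers: depth tables, small-variant and SV VCFs, SNP allelic records.

Each importer is idempotent per (sample, data type): re-importing a file
replaces the sample's previous rows of that type.  Rows that cannot be used
are skipped with a logged warning, never silently dropped, so that
``stored + skipped == read`` always holds.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .errors import ImportError_
from .genome import normalize_chrom
from .panel_db import DatabaseHandle

log = logging.getLogger("tarpan.ingest")

# One breakend of a rearrangement:  t[chr:pos[  t]chr:pos]  [chr:pos[t  ]chr:pos]t
_BND_RE = re.compile(r"[\[\]]([^:\[\]]+):([0-9]+)[\[\]]")


@dataclass(frozen=True)
class ImportResult:
    """Outcome of one import: rows stored vs rows skipped with a warning."""

    stored: int
    skipped: int = 0

    @property
    def read(self) -> int:
        return self.stored + self.skipped

    def __int__(self) -> int:
        return self.stored


@dataclass(frozen=True)
class ExtractedAnnotation:
    """Fields pulled out of one VEP consequence (CSQ) entry.

    Subfields absent from the annotation string stay empty; nothing is
    invented.  ``extras`` keeps every subfield not mapped to a named field.
    """

    gene_symbol: str = ""
    consequence: str = ""
    protein_change: str = ""
    codon_change: str = ""
    extras: dict = field(default_factory=dict)


def parse_csq(info_value: str, csq_format: list[str]) -> list[ExtractedAnnotation]:
    """Parse a VEP CSQ INFO value into one annotation per transcript entry.

    ``csq_format`` is the ordered list of pipe-separated subfield names
    declared in the VCF header.  Gene symbol, consequence, protein change
    and codon change are taken from the subfields named SYMBOL, Consequence,
    HGVSp and HGVSc; when HGVSp is absent or empty, the protein change falls
    back to the amino-acid code built from Amino_acids + Protein_position
    (e.g. ``R/Q`` at 175 -> ``R175Q``).  Entries whose subfield count does
    not match the header are skipped with a warning.
    """
    out: list[ExtractedAnnotation] = []
    for entry in str(info_value).split(","):
        parts = entry.split("|")
        if len(parts) != len(csq_format):
            log.warning(
                "CSQ entry has %d subfields, header declares %d; skipping: %r",
                len(parts), len(csq_format), entry,
            )
            continue
        sub = dict(zip(csq_format, parts))
        protein = sub.get("HGVSp", "")
        if not protein:
            aa, pos = sub.get("Amino_acids", ""), sub.get("Protein_position", "")
            if aa and pos:
                protein = (
                    f"{aa.split('/')[0]}{pos}{aa.split('/')[1]}"
                    if "/" in aa
                    else f"{aa}{pos}"
                )
        consumed = {"SYMBOL", "Consequence", "HGVSp", "HGVSc"}
        out.append(
            ExtractedAnnotation(
                gene_symbol=sub.get("SYMBOL", ""),
                consequence=sub.get("Consequence", ""),
                protein_change=protein,
                codon_change=sub.get("HGVSc", ""),
                extras={k: v for k, v in sub.items() if k not in consumed},
            )
        )
    return out


# ---------------------------------------------------------------------------
# depth tables


def _read_depth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chromosome", "start", "end", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ImportError_(
            f"{path}: depth table lacks required column(s) {sorted(missing)}"
        )
    return df


def _depth_rows(path, target_ids):
    """Yield (target_id, depth, precomputed_ratio) per usable row.

    A ``ratio`` column is taken as a linear tumor/normal ratio; a ``log2``
    column (CNVKit convention) is exponentiated to linear scale.
    """
    df = _read_depth_table(path)
    stored, skipped = [], 0
    for row in df.itertuples(index=False):
        try:
            chrom = normalize_chrom(str(row.chromosome))
        except ValueError:
            log.warning("%s: unrecognized contig %r; row skipped", path, row.chromosome)
            skipped += 1
            continue
        key = (chrom, int(row.start), int(row.end))
        tid = target_ids.get(key)
        if tid is None:
            log.warning("%s: interval %s not on panel; row skipped", path, key)
            skipped += 1
            continue
        depth = float(row.depth)
        if depth < 0:
            log.warning("%s: negative depth %s at %s; row skipped", path, depth, key)
            skipped += 1
            continue
        ratio = None
        if "ratio" in df.columns:
            ratio = float(getattr(row, "ratio"))
        elif "log2" in df.columns:
            ratio = float(2.0 ** float(getattr(row, "log2")))
        stored.append((tid, depth, ratio))
    return stored, skipped


def import_depths(
    db: DatabaseHandle, sample_id: str, tumor_table, normal_table
) -> ImportResult:
    """Import per-interval mean depths for the tumor and normal of a sample.

    Rows are matched to panel targets exactly on (chromosome, start, end)
    after contig-name normalization; off-panel rows are skipped with a
    warning.  A table matching zero rows is a hard error (wrong panel).
    """
    db.require_sample(sample_id)
    target_ids = db.target_ids()
    total_stored = total_skipped = 0
    db.conn.execute("DELETE FROM depth WHERE sample_id=?", (sample_id,))
    for role, path in (("tumor", tumor_table), ("normal", normal_table)):
        rows, skipped = _depth_rows(path, target_ids)
        if not rows:
            db.conn.rollback()
            raise ImportError_(
                f"{path}: no row matched any panel interval; is this the right panel?"
            )
        db.conn.executemany(
            "INSERT INTO depth (sample_id, role, target_id, depth, precomputed_ratio)"
            " VALUES (?,?,?,?,?)",
            [(sample_id, role, tid, d, r) for tid, d, r in rows],
        )
        total_stored += len(rows)
        total_skipped += skipped
    db.conn.commit()
    db.set_flag(sample_id, "has_depths")
    return ImportResult(total_stored, total_skipped)


# ---------------------------------------------------------------------------
# VCFs


def _filter_string(record) -> str:
    """FILTER column preserved verbatim ('.' when the caller left it unset)."""
    keys = list(record.filter.keys())
    return ";".join(keys) if keys else "."


def _csq_format_from_header(vcf: pysam.VariantFile) -> list[str] | None:
    rec = vcf.header.info.get("CSQ")
    if rec is None or not rec.description:
        return None
    desc = rec.description
    marker = "Format:"
    if marker not in desc:
        return None
    return [f.strip() for f in desc.split(marker, 1)[1].strip().strip('"').split("|")]


def _raw_info(record) -> str:
    fields = str(record).rstrip("\n").split("\t")
    return fields[7] if len(fields) > 7 else ""


def import_small_variants(db: DatabaseHandle, sample_id: str, vcf_path) -> ImportResult:
    """Import small variants from a VCF, splitting multi-allelic records.

    One row is stored per ALT allele.  FILTER is preserved verbatim.  When
    the header declares a VEP CSQ field, annotations are extracted with
    :func:`parse_csq` (the entry whose Allele matches the ALT is preferred);
    otherwise the raw INFO string is kept for display.
    """
    db.require_sample(sample_id)
    if not Path(vcf_path).exists():
        raise ImportError_(f"VCF not found: {vcf_path}")
    vcf = pysam.VariantFile(str(vcf_path))
    csq_format = _csq_format_from_header(vcf)
    rows, skipped = [], 0
    for record in vcf:
        try:
            chrom = normalize_chrom(record.chrom)
        except ValueError:
            log.warning("%s: contig %r not supported; record skipped", vcf_path, record.chrom)
            skipped += len(record.alts or (None,))
            continue
        filt = _filter_string(record)
        raw_info = _raw_info(record)
        annotations: list[ExtractedAnnotation] = []
        if csq_format is not None and "CSQ" in record.info:
            value = record.info["CSQ"]
            if isinstance(value, tuple):
                value = ",".join(value)
            annotations = parse_csq(value, csq_format)
        for alt in record.alts or ():
            ann = None
            if annotations:
                ann = next(
                    (a for a in annotations if a.extras.get("Allele") == alt),
                    annotations[0],
                )
            rows.append(
                (
                    sample_id, chrom, record.pos, record.ref, alt, filt,
                    ann.gene_symbol if ann else "",
                    ann.consequence if ann else "",
                    ann.protein_change if ann else "",
                    ann.codon_change if ann else "",
                    json.dumps(ann.extras) if ann else "",
                    raw_info,
                )
            )
    db.conn.execute("DELETE FROM small_variant WHERE sample_id=?", (sample_id,))
    db.conn.executemany(
        "INSERT INTO small_variant VALUES (?,?,?,?,?,?,?,?,?,?,?,?)", rows
    )
    db.conn.commit()
    db.set_flag(sample_id, "has_small_variants")
    return ImportResult(len(rows), skipped)


def parse_bnd_alt(alt: str) -> tuple[str, int] | None:
    """Extract (partner contig, 1-based partner position) from breakend ALT
    bracket notation, e.g. ``A[chr8:128000000[`` -> ("chr8", 128000000).
    Returns None when the ALT does not follow the notation."""
    m = _BND_RE.search(alt)
    if m is None:
        return None
    try:
        return normalize_chrom(m.group(1)), int(m.group(2))
    except ValueError:
        return None


def import_structural_variants(db: DatabaseHandle, sample_id: str, vcf_path) -> ImportResult:
    """Import structural variants; BND partners are parsed from the ALT.

    Both mates of a breakend pair are stored (the Circos builder
    deduplicates them).  A BND whose ALT cannot be parsed is stored without
    partner coordinates and flagged.
    """
    db.require_sample(sample_id)
    if not Path(vcf_path).exists():
        raise ImportError_(f"VCF not found: {vcf_path}")
    vcf = pysam.VariantFile(str(vcf_path))
    rows, skipped = [], 0
    for record in vcf:
        try:
            chrom = normalize_chrom(record.chrom)
        except ValueError:
            log.warning("%s: contig %r not supported; record skipped", vcf_path, record.chrom)
            skipped += 1
            continue
        alt = (record.alts or ("",))[0]
        svtype = record.info.get("SVTYPE")
        if svtype is None:
            svtype = "BND" if _BND_RE.search(alt) else alt.strip("<>")
        mate_id = record.info.get("MATEID")
        if isinstance(mate_id, tuple):
            mate_id = mate_id[0]
        partner_chrom = partner_pos = None
        unparsed = 0
        if svtype == "BND":
            parsed = parse_bnd_alt(alt)
            if parsed is None:
                log.warning(
                    "%s: BND ALT %r not in bracket notation; stored without partner",
                    vcf_path, alt,
                )
                unparsed = 1
            else:
                partner_chrom, partner_pos = parsed
        elif record.stop and record.stop > record.pos:
            # intra-chromosomal event: keep the END endpoint (pysam exposes
            # the END INFO key as record.stop) so arc builders have both ends
            partner_chrom, partner_pos = chrom, int(record.stop)
        inter = int(partner_chrom is not None and partner_chrom != chrom)
        rows.append(
            (
                sample_id, chrom, record.pos, svtype, partner_chrom, partner_pos,
                _filter_string(record), inter, mate_id, unparsed,
            )
        )
    db.conn.execute("DELETE FROM structural_variant WHERE sample_id=?", (sample_id,))
    db.conn.executemany(
        "INSERT INTO structural_variant VALUES (?,?,?,?,?,?,?,?,?,?)", rows
    )
    db.conn.commit()
    db.set_flag(sample_id, "has_svs")
    return ImportResult(len(rows), skipped)


# ---------------------------------------------------------------------------
# SNP allelic records


def _containing_targets(db: DatabaseHandle) -> list[tuple[str, int, int]]:
    return [
        (c, s, e)
        for c, s, e in db.conn.execute("SELECT chromosome, start, end FROM target")
    ]


def _snp_rows_from_table(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = [
        "chromosome", "position",
        "normal_ref_depth", "normal_alt_depth",
        "tumor_ref_depth", "tumor_alt_depth",
    ]
    missing = set(required) - set(df.columns)
    if missing:
        raise ImportError_(f"{path}: SNP table lacks column(s) {sorted(missing)}")
    for row in df.itertuples(index=False):
        yield (
            str(row.chromosome), str(row.position),
            str(row.normal_ref_depth), str(row.normal_alt_depth),
            str(row.tumor_ref_depth), str(row.tumor_alt_depth),
        )


def _snp_rows_from_vcf(path):
    vcf = pysam.VariantFile(str(path))
    names = list(vcf.header.samples)
    if len(names) < 2:
        raise ImportError_(f"{path}: SNP VCF needs a normal and a tumor sample")
    lowered = [n.lower() for n in names]
    normal = names[lowered.index("normal")] if "normal" in lowered else names[0]
    tumor = names[lowered.index("tumor")] if "tumor" in lowered else names[1]
    for record in vcf:
        def _ad(sample):
            ad = record.samples[sample].get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None or ad[1] is None:
                return None, None
            return ad[0], ad[1]

        nr, na = _ad(normal)
        tr, ta = _ad(tumor)
        yield (record.chrom, str(record.pos), str(nr), str(na), str(tr), str(ta))


def import_snp_records(db: DatabaseHandle, sample_id: str, source) -> ImportResult:
    """Import per-site ref/alt allele depths for the heterozygosity view.

    ``source`` is either a tab-separated table with columns chromosome,
    position, normal_ref_depth, normal_alt_depth, tumor_ref_depth,
    tumor_alt_depth, or a two-sample VCF carrying AD.  Sites missing an
    allele depth are skipped with a warning; sites outside every target
    interval are kept but flagged off-panel.
    """
    db.require_sample(sample_id)
    source = Path(source)
    if not source.exists():
        raise ImportError_(f"SNP source not found: {source}")
    raw = (
        _snp_rows_from_vcf(source)
        if source.suffix.lower() in (".vcf", ".bcf") or str(source).endswith(".vcf.gz")
        else _snp_rows_from_table(source)
    )
    targets = _containing_targets(db)
    rows, skipped = [], 0
    for chrom_s, pos_s, nr, na, tr, ta in raw:
        try:
            chrom = normalize_chrom(chrom_s)
            pos = int(pos_s)
            depths = [int(x) for x in (nr, na, tr, ta)]
            if any(d < 0 for d in depths):
                raise ValueError("negative depth")
        except ValueError:
            log.warning(
                "%s: unusable SNP row at %s:%s (missing or invalid depths); skipped",
                source, chrom_s, pos_s,
            )
            skipped += 1
            continue
        on_panel = any(c == chrom and s < pos <= e for c, s, e in targets)
        rows.append((sample_id, chrom, pos, *depths, int(not on_panel)))
    db.conn.execute("DELETE FROM snp_record WHERE sample_id=?", (sample_id,))
    db.conn.executemany("INSERT INTO snp_record VALUES (?,?,?,?,?,?,?,?)", rows)
    db.conn.commit()
    db.set_flag(sample_id, "has_snps")
    return ImportResult(len(rows), skipped)
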