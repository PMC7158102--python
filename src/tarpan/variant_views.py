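"""Filtered, deterministically ordered mutation and SV tables.

A record passes the viewer's filter when its FILTER column is exactly
"PASS" or "." — anything else, including semicolon-joined multi-value
fields, counts as failed.  Failed records are hidden by default and shown
on request; nothing is ever dropped from the union of the two views.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .genome import chrom_rank, normalize_chrom
from .panel_db import DatabaseHandle

PASSING_FILTERS = frozenset({"PASS", "."})


def passes_filter(filter_status: str) -> bool:
    return filter_status in PASSING_FILTERS


@dataclass(frozen=True)
class VariantTableRow:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene_symbol: str
    consequence: str
    protein_change: str
    codon_change: str
    filter_status: str
    passed_filter: bool
    raw_info: str = ""
    extras: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class SvTableRow:
    chromosome: str
    position: int
    sv_type: str
    partner_chromosome: str | None
    partner_position: int | None
    filter_status: str
    passed_filter: bool
    is_interchromosomal: bool


def mutation_table(
    db: DatabaseHandle,
    sample_id: str,
    chromosome: str | None = None,
    show_failed: bool = False,
) -> list[VariantTableRow]:
    """Small-variant table rows for one sample.

    Default shows only records with FILTER in {"PASS", "."}; ``show_failed``
    shows everything.  Sorted by (chromosome, position, alt allele).
    """
    db.require_sample(sample_id)
    if chromosome is not None:
        chromosome = normalize_chrom(chromosome)
    rows = []
    for (
        chrom, pos, ref, alt, filt, gene, csq, prot, codon, extras, raw_info
    ) in db.conn.execute(
        "SELECT chromosome, position, ref_allele, alt_allele, filter_status,"
        " gene_symbol, consequence, protein_change, codon_change, extras, raw_info"
        " FROM small_variant WHERE sample_id=?",
        (sample_id,),
    ):
        ok = passes_filter(filt)
        if not ok and not show_failed:
            continue
        if chromosome is not None and chrom != chromosome:
            continue
        rows.append(
            VariantTableRow(
                chrom, pos, ref, alt, gene, csq, prot, codon, filt, ok,
                raw_info, json.loads(extras) if extras else {},
            )
        )
    rows.sort(key=lambda r: (chrom_rank(r.chromosome), r.position, r.alt_allele))
    return rows


def sv_table(
    db: DatabaseHandle,
    sample_id: str,
    chromosome: str | None = None,
    show_failed: bool = False,
) -> list[SvTableRow]:
    """Structural-variant table rows for one sample.

    Same filter contract as :func:`mutation_table`.  A breakend matches a
    chromosome filter if either its own or its partner chromosome matches,
    so inter-chromosomal events are discoverable from both ends.
    """
    db.require_sample(sample_id)
    if chromosome is not None:
        chromosome = normalize_chrom(chromosome)
    rows = []
    for chrom, pos, svtype, pchrom, ppos, filt, inter in db.conn.execute(
        "SELECT chromosome, position, sv_type, partner_chromosome,"
        " partner_position, filter_status, is_interchromosomal"
        " FROM structural_variant WHERE sample_id=?",
        (sample_id,),
    ):
        ok = passes_filter(filt)
        if not ok and not show_failed:
            continue
        if chromosome is not None and chrom != chromosome and pchrom != chromosome:
            continue
        rows.append(
            SvTableRow(chrom, pos, svtype, pchrom, ppos, filt, ok, bool(inter))
        )
    rows.sort(
        key=lambda r: (chrom_rank(r.chromosome), r.position, r.sv_type)
    )
    return rows
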