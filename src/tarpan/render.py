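"""Deterministic plot specifications for the five views, plus rasterization.

Every view is first built as a :class:`PlotSpec` — plain data (points, arcs,
axis metadata) that tests can assert on — and only then handed to
:func:`rasterize`, which draws it with matplotlib.  Rendering consumes
nothing but the spec, so two identical specs produce identical vector
output.

Views:

* ``whole_genome`` — every interval at its cumulative genomic coordinate,
  colored by copy-number call state (gained red, neutral black, deleted blue).
* ``chromosome`` — one chromosome, intervals at genomic positions, colored
  by gene group.
* ``chromosome_continuous`` — same but intervals placed equidistantly
  (x = 0, 1, 2, ... in genomic order) so per-gene patterns stand out.
* ``snp_panel`` — normal-heterozygous SNPs with paired normal/tumor VAF
  series, for spotting loss of heterozygosity.
* ``circos`` — genome wheel with copy-number and mutation rings and SV
  link arcs; inter-chromosomal links shown on request.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .copynumber import CnCall, RatioTrack
from .errors import TarpanError
from .genome import CANONICAL_CHROMS, CONTIG_LENGTHS, chrom_offsets, normalize_chrom

STATE_COLORS = {"gained": "red", "neutral": "black", "deleted": "blue"}
FORMATS = ("png", "svg", "pdf")

# deterministic svg output (no per-process hash salt, no timestamp)
matplotlib.rcParams["svg.hashsalt"] = "tarpan"


@dataclass(frozen=True)
class PlotSpec:
    view: str
    points: tuple[tuple[float, float, str, str], ...]  # (x, y, color_class, label)
    arcs: tuple[tuple[str, int, str, int], ...] = ()
    axes: dict = field(default_factory=dict)


def group_color(group_name: str) -> str:
    """Deterministic color for a gene group, from a hash of its name."""
    digest = hashlib.sha256(group_name.encode()).digest()
    palette = plt.get_cmap("tab20").colors
    return matplotlib.colors.to_hex(palette[digest[0] % len(palette)])


def whole_genome_spec(
    track: RatioTrack, calls: list[CnCall], genome: str = "hg38"
) -> PlotSpec:
    """All intervals at cumulative genomic x, colored by call state."""
    if not track.entries:
        raise TarpanError("cannot build a whole-genome view from an empty track")
    if len(calls) != len(track.entries):
        raise TarpanError("calls are not aligned to track entries")
    offsets = chrom_offsets(genome)
    points = []
    for (iv, r), call in zip(track.entries, calls):
        x = offsets[iv.chromosome] + (iv.start + iv.end) / 2
        points.append((float(x), float(r), call.state.value, iv.label))
    boundaries = {c: offsets[c] for c in CANONICAL_CHROMS}
    return PlotSpec(
        view="whole_genome",
        points=tuple(points),
        axes={
            "genome": genome,
            "chrom_offsets": boundaries,
            "xlabel": "genomic position",
            "ylabel": "copy number ratio",
        },
    )


def chromosome_spec(
    track: RatioTrack,
    chromosome: str,
    continuous: bool = False,
    groups=None,
) -> PlotSpec:
    """One chromosome's intervals, colored by gene group.

    ``continuous=True`` places intervals equidistantly (x = 0..n-1 in
    genomic order); otherwise x is the genomic midpoint.  ``groups`` is a
    list of :class:`GeneGroup` used to name each interval's color class;
    intervals outside every group fall back to their own label.
    """
    chromosome = normalize_chrom(chromosome)
    entries = [(iv, r) for iv, r in track.entries if iv.chromosome == chromosome]
    if not entries:
        raise TarpanError(f"track has no intervals on {chromosome}")
    entries.sort(key=lambda e: e[0].sort_key())
    group_of = {}
    for g in groups or ():
        for m in g.member_intervals:
            group_of[(m.chromosome, m.start, m.end)] = g.group_name
    points = []
    for i, (iv, r) in enumerate(entries):
        x = float(i) if continuous else (iv.start + iv.end) / 2
        cls = group_of.get((iv.chromosome, iv.start, iv.end), iv.label or "ungrouped")
        points.append((float(x), float(r), cls, iv.label))
    return PlotSpec(
        view="chromosome_continuous" if continuous else "chromosome",
        points=tuple(points),
        axes={
            "chromosome": chromosome,
            "xlabel": "interval rank" if continuous else "position",
            "ylabel": "copy number ratio",
        },
    )


def snp_panel_spec(baf_points, region) -> PlotSpec:
    """Normal-heterozygous SNPs in a region, tumor VAF as the point series.

    ``region`` is a chromosome name or a (chromosome, start, end) tuple
    (1-based inclusive positions).  The paired normal VAFs travel in the
    axes metadata as ``normal_series``.  An empty selection is a valid,
    empty spec.
    """
    if isinstance(region, str):
        chrom, lo, hi = normalize_chrom(region), None, None
    else:
        chrom, lo, hi = normalize_chrom(region[0]), region[1], region[2]
    selected = [
        p
        for p in baf_points
        if p.heterozygous_in_normal
        and p.chromosome == chrom
        and (lo is None or lo <= p.position <= hi)
    ]
    selected.sort(key=lambda p: p.position)
    points = tuple(
        (float(p.position), float(p.tumor_vaf), "tumor", f"n={p.normal_vaf:.3f}")
        for p in selected
    )
    return PlotSpec(
        view="snp_panel",
        points=points,
        axes={
            "region": (chrom, lo, hi),
            "normal_series": [(float(p.position), float(p.normal_vaf)) for p in selected],
            "xlabel": "position",
            "ylabel": "variant allele fraction",
        },
    )


@dataclass(frozen=True)
class CircosOptions:
    show_cn: bool = True
    show_mutations: bool = True
    show_svs: bool = True
    show_interchromosomal: bool = False


def circos_spec(
    track: RatioTrack | None,
    calls: list[CnCall] | None,
    variants,
    svs,
    options: CircosOptions = CircosOptions(),
    genome: str = "hg38",
) -> PlotSpec:
    """Genome-wide wheel: CN ring, mutation ring, SV link arcs.

    Intra-chromosomal SV arcs always appear when ``show_svs``;
    inter-chromosomal arcs only when ``show_interchromosomal`` is also set.
    Breakend mate pairs (two stored records describing the same junction)
    collapse to a single arc, keyed by their unordered endpoint pair.
    """
    if not (options.show_cn or options.show_mutations or options.show_svs):
        raise TarpanError("circos view requested with every feature class disabled")
    offsets = chrom_offsets(genome)
    points = []
    if options.show_cn and track is not None and calls is not None:
        for (iv, r), call in zip(track.entries, calls):
            x = offsets[iv.chromosome] + (iv.start + iv.end) / 2
            points.append((float(x), float(r), f"cn:{call.state.value}", iv.label))
    if options.show_mutations:
        for v in variants or ():
            x = offsets[v.chromosome] + v.position
            points.append((float(x), 1.0, "mutation", v.gene_symbol))
    arcs = []
    seen = set()
    if options.show_svs:
        for sv in svs or ():
            pchrom = sv.partner_chromosome or sv.chromosome
            ppos = sv.partner_position if sv.partner_position is not None else sv.position
            if sv.is_interchromosomal and not options.show_interchromosomal:
                continue
            key = frozenset({(sv.chromosome, sv.position), (pchrom, ppos)})
            if key in seen:
                continue
            seen.add(key)
            arcs.append((sv.chromosome, sv.position, pchrom, ppos))
    return PlotSpec(
        view="circos",
        points=tuple(points),
        arcs=tuple(arcs),
        axes={"genome": genome, "chrom_offsets": dict(offsets)},
    )


# ---------------------------------------------------------------------------
# rasterization


def _point_color(color_class: str) -> str:
    cls = color_class.split(":")[-1]
    if cls in STATE_COLORS:
        return STATE_COLORS[cls]
    if color_class == "mutation":
        return "darkorange"
    if color_class == "tumor":
        return "firebrick"
    return group_color(color_class)


def _draw_linear(spec: PlotSpec, ax) -> None:
    for x, y, cls, _ in spec.points:
        ax.plot(x, y, "o", ms=3, color=_point_color(cls))
    if spec.view == "snp_panel":
        for x, y in spec.axes.get("normal_series", []):
            ax.plot(x, y, "s", ms=3, color="steelblue")
        ax.set_ylim(-0.02, 1.02)
    elif spec.points:
        ax.axhline(1.0, lw=0.5, color="grey")
    if spec.view == "whole_genome":
        for c, off in spec.axes["chrom_offsets"].items():
            ax.axvline(off, lw=0.3, color="lightgrey")
    ax.set_xlabel(spec.axes.get("xlabel", ""))
    ax.set_ylabel(spec.axes.get("ylabel", ""))


def _draw_circos(spec: PlotSpec, ax) -> None:
    genome = spec.axes["genome"]
    total = sum(CONTIG_LENGTHS[genome][c] for c in CANONICAL_CHROMS)
    offsets = spec.axes["chrom_offsets"]

    def angle(chrom, pos):
        return 2 * math.pi * (offsets[chrom] + pos) / total

    for c in CANONICAL_CHROMS:
        a0 = angle(c, 0)
        a1 = angle(c, CONTIG_LENGTHS[genome][c])
        ts = [a0 + (a1 - a0) * i / 32 for i in range(33)]
        ax.plot(
            [math.cos(t) for t in ts], [math.sin(t) for t in ts], lw=2, color="grey"
        )
        mid = (a0 + a1) / 2
        ax.text(
            1.12 * math.cos(mid), 1.12 * math.sin(mid), c[3:],
            ha="center", va="center", fontsize=5,
        )
    for x, y, cls, _ in spec.points:
        t = 2 * math.pi * x / total
        radius = 0.85 if cls.startswith("cn:") else 0.7
        ax.plot(
            radius * math.cos(t), radius * math.sin(t), "o", ms=2,
            color=_point_color(cls),
        )
    for ca, pa, cb, pb in spec.arcs:
        t0, t1 = angle(ca, pa), angle(cb, pb)
        x0, y0 = 0.65 * math.cos(t0), 0.65 * math.sin(t0)
        x1, y1 = 0.65 * math.cos(t1), 0.65 * math.sin(t1)
        # quadratic bezier through the center region
        ts = [i / 32 for i in range(33)]
        xs = [(1 - t) ** 2 * x0 + t**2 * x1 for t in ts]
        ys = [(1 - t) ** 2 * y0 + t**2 * y1 for t in ts]
        ax.plot(xs, ys, lw=0.8, color="purple")
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")


def rasterize(spec: PlotSpec, out, format: str = "png"):
    """Draw a spec to an image file (png, svg or pdf).

    Rendering reads only the spec, so identical specs give identical svg
    bytes (timestamps are stripped from vector metadata).
    """
    if format not in FORMATS:
        raise TarpanError(
            f"unsupported format {format!r}; supported: {', '.join(FORMATS)}"
        )
    fig, ax = plt.subplots(figsize=(8, 4) if spec.view != "circos" else (6, 6))
    try:
        if spec.view == "circos":
            _draw_circos(spec, ax)
        else:
            _draw_linear(spec, ax)
        ax.set_title(spec.view.replace("_", " "))
        metadata = {"Date": None} if format in ("svg", "pdf") else None
        if format == "pdf":
            metadata = {"CreationDate": None}
        fig.savefig(str(out), format=format, metadata=metadata, dpi=100)
    finally:
        plt.close(fig)
    return out
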