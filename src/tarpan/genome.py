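"""Human contig naming, ordering and lengths.

The engine supports the two human reference builds commonly used by targeted
panels, hg19 (GRCh37) and hg38 (GRCh38), and the 24 canonical contigs
chr1..chr22, chrX, chrY.  Contig names are accepted with or without the
"chr" prefix and are stored normalized with the prefix.
"""

from __future__ import annotations

SUPPORTED_GENOMES = ("hg19", "hg38")

CANONICAL_CHROMS: tuple[str, ...] = tuple(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))

_CHROM_RANK = {c: i for i, c in enumerate(CANONICAL_CHROMS)}

# UCSC main-assembly contig lengths.
CONTIG_LENGTHS: dict[str, dict[str, int]] = {
    "hg19": {
        "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
        "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
        "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
        "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
        "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
        "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
        "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
        "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
    },
    "hg38": {
        "chr1": 248956422, "chr2": 242193529, "chr3": 198295559,
        "chr4": 190214555, "chr5": 181538259, "chr6": 170805979,
        "chr7": 159345973, "chr8": 145138636, "chr9": 138394717,
        "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
        "chr13": 114364328, "chr14": 107043718, "chr15": 101991189,
        "chr16": 90338345, "chr17": 83257441, "chr18": 80373285,
        "chr19": 58617616, "chr20": 64444167, "chr21": 46709983,
        "chr22": 50818468, "chrX": 156040895, "chrY": 57227415,
    },
}


def normalize_chrom(name: str) -> str:
    """Normalize a contig name to the canonical "chr"-prefixed spelling.

    Accepts "17", "chr17", "X", "chrx", "MT" is rejected (not a panel
    contig).  Raises ``ValueError`` for anything outside chr1-22, X, Y.
    """
    s = name.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper() if s.upper() in ("X", "Y") else s
    cand = f"chr{s}"
    if cand not in _CHROM_RANK:
        raise ValueError(
            f"unrecognized human contig {name!r}; expected chr1-chr22, chrX or chrY"
        )
    return cand


def chrom_rank(chrom: str) -> int:
    """Sort rank of a normalized contig (chr1 < ... < chr22 < chrX < chrY)."""
    return _CHROM_RANK[chrom]


def chrom_offsets(genome: str) -> dict[str, int]:
    """Cumulative start offset of each contig for whole-genome x coordinates."""
    lengths = CONTIG_LENGTHS[genome]
    offsets: dict[str, int] = {}
    acc = 0
    for c in CANONICAL_CHROMS:
        offsets[c] = acc
        acc += lengths[c]
    return offsets
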