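"""Panel definitions and the SQLite persistence layer.

A panel database is a single SQLite file holding one targeted panel (its
capture intervals, gene-group annotations and optional blacklist) together
with any number of samples processed against that panel.  Every other module
reads and writes through the :class:`DatabaseHandle` defined here; the file
itself stays openable by any standard SQLite client.

Coordinate convention: intervals are stored 0-based half-open (BED native);
variant positions are stored 1-based (VCF native).  Contig names are
normalized to the "chr"-prefixed spelling at ingest.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import BedParseError, ConfigError, TarpanError
from .genome import SUPPORTED_GENOMES, chrom_rank, normalize_chrom

SCHEMA = """
CREATE TABLE panel_meta (
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
CREATE TABLE target (
    target_id INTEGER PRIMARY KEY,
    chromosome TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    label TEXT NOT NULL DEFAULT '',
    CHECK (start < end)
);
CREATE TABLE gene_group (
    group_id INTEGER PRIMARY KEY,
    group_name TEXT NOT NULL UNIQUE
);
CREATE TABLE group_member (
    group_id INTEGER NOT NULL REFERENCES gene_group(group_id),
    target_id INTEGER NOT NULL REFERENCES target(target_id),
    PRIMARY KEY (group_id, target_id)
);
CREATE TABLE blacklist (
    chromosome TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL
);
CREATE TABLE sample (
    sample_id TEXT PRIMARY KEY,
    insert_order INTEGER NOT NULL,
    has_depths INTEGER NOT NULL DEFAULT 0,
    has_small_variants INTEGER NOT NULL DEFAULT 0,
    has_svs INTEGER NOT NULL DEFAULT 0,
    has_snps INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE depth (
    sample_id TEXT NOT NULL REFERENCES sample(sample_id),
    role TEXT NOT NULL CHECK (role IN ('tumor','normal')),
    target_id INTEGER NOT NULL REFERENCES target(target_id),
    depth REAL NOT NULL CHECK (depth >= 0),
    precomputed_ratio REAL,
    PRIMARY KEY (sample_id, role, target_id)
);
CREATE TABLE small_variant (
    sample_id TEXT NOT NULL REFERENCES sample(sample_id),
    chromosome TEXT NOT NULL,
    position INTEGER NOT NULL,
    ref_allele TEXT NOT NULL,
    alt_allele TEXT NOT NULL,
    filter_status TEXT NOT NULL,
    gene_symbol TEXT NOT NULL DEFAULT '',
    consequence TEXT NOT NULL DEFAULT '',
    protein_change TEXT NOT NULL DEFAULT '',
    codon_change TEXT NOT NULL DEFAULT '',
    extras TEXT NOT NULL DEFAULT '',
    raw_info TEXT NOT NULL DEFAULT ''
);
CREATE TABLE structural_variant (
    sample_id TEXT NOT NULL REFERENCES sample(sample_id),
    chromosome TEXT NOT NULL,
    position INTEGER NOT NULL,
    sv_type TEXT NOT NULL,
    partner_chromosome TEXT,
    partner_position INTEGER,
    filter_status TEXT NOT NULL,
    is_interchromosomal INTEGER NOT NULL,
    mate_id TEXT,
    partner_unparsed INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE snp_record (
    sample_id TEXT NOT NULL REFERENCES sample(sample_id),
    chromosome TEXT NOT NULL,
    position INTEGER NOT NULL,
    normal_ref_depth INTEGER NOT NULL CHECK (normal_ref_depth >= 0),
    normal_alt_depth INTEGER NOT NULL CHECK (normal_alt_depth >= 0),
    tumor_ref_depth INTEGER NOT NULL CHECK (tumor_ref_depth >= 0),
    tumor_alt_depth INTEGER NOT NULL CHECK (tumor_alt_depth >= 0),
    off_panel INTEGER NOT NULL DEFAULT 0
);
"""


@dataclass(frozen=True, order=False)
class TargetInterval:
    """One captured region of the panel (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    label: str = ""

    def sort_key(self):
        return (chrom_rank(self.chromosome), self.start, self.end, self.label)

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return (
            self.chromosome == chromosome and self.start < end and start < self.end
        )


@dataclass(frozen=True)
class GeneGroup:
    """A named set of panel intervals, usually one gene."""

    group_name: str
    member_intervals: tuple[TargetInterval, ...]


@dataclass(frozen=True)
class PanelDefinition:
    name: str
    reference_genome: str
    pipeline_version: str
    targets: tuple[TargetInterval, ...]
    gene_groups: tuple[GeneGroup, ...]
    blacklist: tuple[TargetInterval, ...] = ()


@dataclass
class SampleRecord:
    sample_id: str
    panel_name: str
    has_depths: bool = False
    has_small_variants: bool = False
    has_svs: bool = False
    has_snps: bool = False


def parse_bed(path) -> list[TargetInterval]:
    """Parse a BED file (3+ columns, column 4 kept as label).

    Comment (#), ``track``/``browser`` and blank lines are skipped.  Raises
    :class:`BedParseError` with the offending line number on malformed input.
    """
    path = Path(path)
    out: list[TargetInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip() or s.startswith(("#", "track", "browser")):
                continue
            fields = s.split("\t")
            if len(fields) == 1:
                fields = s.split()
            if len(fields) < 3:
                raise BedParseError(path, lineno, "fewer than 3 columns")
            try:
                chrom = normalize_chrom(fields[0])
            except ValueError as e:
                raise BedParseError(path, lineno, str(e)) from None
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(path, lineno, "start/end are not integers") from None
            if start < 0:
                raise BedParseError(path, lineno, f"negative start {start}")
            if start >= end:
                raise BedParseError(path, lineno, f"start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 else ""
            out.append(TargetInterval(chrom, start, end, label))
    return out


class DatabaseHandle:
    """Open connection to a single-file panel database."""

    def __init__(self, path, conn: sqlite3.Connection):
        self.path = Path(path)
        self.conn = conn

    # -- lifecycle ---------------------------------------------------------
    @classmethod
    def open(cls, path) -> "DatabaseHandle":
        path = Path(path)
        if not path.exists():
            raise TarpanError(f"database file not found: {path}")
        conn = sqlite3.connect(str(path))
        conn.execute("PRAGMA foreign_keys = ON")
        return cls(path, conn)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- panel -------------------------------------------------------------
    @property
    def panel(self) -> PanelDefinition:
        meta = dict(self.conn.execute("SELECT key, value FROM panel_meta"))
        targets = tuple(
            TargetInterval(c, s, e, lbl)
            for c, s, e, lbl in self.conn.execute(
                "SELECT chromosome, start, end, label FROM target ORDER BY target_id"
            )
        )
        by_id = {
            tid: t
            for tid, t in zip(
                (r[0] for r in self.conn.execute("SELECT target_id FROM target ORDER BY target_id")),
                targets,
            )
        }
        groups = []
        for gid, gname in self.conn.execute(
            "SELECT group_id, group_name FROM gene_group ORDER BY group_id"
        ):
            members = tuple(
                by_id[tid]
                for (tid,) in self.conn.execute(
                    "SELECT target_id FROM group_member WHERE group_id=? ORDER BY target_id",
                    (gid,),
                )
            )
            groups.append(GeneGroup(gname, members))
        blacklist = tuple(
            TargetInterval(c, s, e, "")
            for c, s, e in self.conn.execute(
                "SELECT chromosome, start, end FROM blacklist ORDER BY rowid"
            )
        )
        return PanelDefinition(
            name=meta["name"],
            reference_genome=meta["reference_genome"],
            pipeline_version=meta["pipeline_version"],
            targets=targets,
            gene_groups=tuple(groups),
            blacklist=blacklist,
        )

    @property
    def samples(self) -> list[SampleRecord]:
        name = self.conn.execute(
            "SELECT value FROM panel_meta WHERE key='name'"
        ).fetchone()[0]
        return [
            SampleRecord(sid, name, bool(d), bool(sv), bool(svs), bool(sn))
            for sid, d, sv, svs, sn in self.conn.execute(
                "SELECT sample_id, has_depths, has_small_variants, has_svs, has_snps"
                " FROM sample ORDER BY insert_order"
            )
        ]

    def target_ids(self) -> dict[tuple[str, int, int], int]:
        """Map (chromosome, start, end) -> target_id for exact depth matching."""
        return {
            (c, s, e): tid
            for tid, c, s, e in self.conn.execute(
                "SELECT target_id, chromosome, start, end FROM target"
            )
        }

    def require_sample(self, sample_id: str) -> None:
        row = self.conn.execute(
            "SELECT 1 FROM sample WHERE sample_id=?", (sample_id,)
        ).fetchone()
        if row is None:
            raise TarpanError(f"sample {sample_id!r} is not registered in {self.path}")

    def set_flag(self, sample_id: str, flag: str) -> None:
        assert flag in ("has_depths", "has_small_variants", "has_svs", "has_snps")
        self.conn.execute(
            f"UPDATE sample SET {flag}=1 WHERE sample_id=?", (sample_id,)
        )
        self.conn.commit()

    def blacklisted_target_ids(self) -> set[int]:
        """target_ids overlapping any blacklist region by >= 1 bp."""
        bl = list(self.conn.execute("SELECT chromosome, start, end FROM blacklist"))
        if not bl:
            return set()
        out: set[int] = set()
        for tid, c, s, e in self.conn.execute(
            "SELECT target_id, chromosome, start, end FROM target"
        ):
            for bc, bs, be in bl:
                if c == bc and s < be and bs < e:
                    out.add(tid)
                    break
        return out


def create_database(
    name: str,
    genome: str,
    pipeline_version: str,
    targets_bed,
    groups_bed,
    blacklist_bed=None,
    *,
    out_path=None,
    overwrite: bool = False,
) -> DatabaseHandle:
    """Create a new, sample-free panel database from BED inputs.

    Parameters
    ----------
    name : display name of the database (also the default file stem).
    genome : reference build, one of ``hg19`` / ``hg38``.
    pipeline_version : free-text provenance recorded in the database.
    targets_bed : BED of captured intervals; column 4 is kept as the label.
    groups_bed : BED of gene-group annotations; column 4 names the group and
        every target falling inside a group interval becomes a member.
    blacklist_bed : optional BED of unreliable regions, hidden by default
        and excluded from normalization.
    out_path : database file location; defaults to ``<name>.sqlite`` in the
        current directory.
    overwrite : refuse to clobber an existing file unless set.
    """
    if genome not in SUPPORTED_GENOMES:
        raise TarpanError(
            f"unsupported reference genome {genome!r}; supported: "
            + ", ".join(SUPPORTED_GENOMES)
        )
    targets = parse_bed(targets_bed)
    if not targets:
        raise TarpanError(f"targets BED {targets_bed} contains no intervals")
    group_regions = parse_bed(groups_bed)
    blacklist = parse_bed(blacklist_bed) if blacklist_bed else []

    path = Path(out_path) if out_path is not None else Path(f"{name}.sqlite")
    if path.exists():
        if not overwrite:
            raise TarpanError(
                f"database file {path} already exists (pass overwrite to replace)"
            )
        path.unlink()

    targets = sorted(targets, key=TargetInterval.sort_key)

    conn = sqlite3.connect(str(path))
    conn.executescript(SCHEMA)
    conn.executemany(
        "INSERT INTO panel_meta (key, value) VALUES (?, ?)",
        [
            ("name", name),
            ("reference_genome", genome),
            ("pipeline_version", pipeline_version),
        ],
    )
    conn.executemany(
        "INSERT INTO target (chromosome, start, end, label) VALUES (?,?,?,?)",
        [(t.chromosome, t.start, t.end, t.label) for t in targets],
    )
    tid_of = {
        (c, s, e, lbl): tid
        for tid, c, s, e, lbl in conn.execute(
            "SELECT target_id, chromosome, start, end, label FROM target"
        )
    }
    # Group membership: a target belongs to a group when it overlaps one of
    # the group's BED intervals.  Each group BED line names its group in
    # column 4; an unlabeled line is its own group named by position.
    seen_groups: dict[str, int] = {}
    memberships: set[tuple[int, int]] = set()
    for region in group_regions:
        gname = region.label or f"{region.chromosome}:{region.start}-{region.end}"
        if gname not in seen_groups:
            cur = conn.execute(
                "INSERT INTO gene_group (group_name) VALUES (?)", (gname,)
            )
            seen_groups[gname] = cur.lastrowid
        gid = seen_groups[gname]
        for t in targets:
            if t.overlaps(region.chromosome, region.start, region.end):
                memberships.add((gid, tid_of[(t.chromosome, t.start, t.end, t.label)]))
    conn.executemany(
        "INSERT INTO group_member (group_id, target_id) VALUES (?,?)",
        sorted(memberships),
    )
    conn.executemany(
        "INSERT INTO blacklist (chromosome, start, end) VALUES (?,?,?)",
        [(b.chromosome, b.start, b.end) for b in blacklist],
    )
    conn.commit()
    conn.execute("PRAGMA foreign_keys = ON")
    return DatabaseHandle(path, conn)


def register_sample(db: DatabaseHandle, sample_id: str) -> SampleRecord:
    """Add a sample row with all data-presence flags false."""
    dup = db.conn.execute(
        "SELECT 1 FROM sample WHERE sample_id=?", (sample_id,)
    ).fetchone()
    if dup is not None:
        raise TarpanError(f"sample {sample_id!r} already registered")
    order = db.conn.execute("SELECT COUNT(*) FROM sample").fetchone()[0]
    db.conn.execute(
        "INSERT INTO sample (sample_id, insert_order) VALUES (?, ?)",
        (sample_id, order),
    )
    db.conn.commit()
    name = db.conn.execute(
        "SELECT value FROM panel_meta WHERE key='name'"
    ).fetchone()[0]
    return SampleRecord(sample_id, name)


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    path: str
    missing: bool


def list_databases(config_path) -> list[RegistryEntry]:
    """Read the config.yml registry mapping display names to database files.

    Entries come back in file order; a named file that does not exist is
    flagged ``missing`` rather than raising.
    """
    config_path = Path(config_path)
    try:
        with open(config_path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {config_path}: {e}") from None
    if data is None:
        return []
    if not isinstance(data, dict):
        raise ConfigError(
            f"{config_path}: expected a mapping of database name -> file path"
        )
    out = []
    for name, p in data.items():
        out.append(RegistryEntry(str(name), str(p), not Path(str(p)).exists()))
    return out


def query_intervals(
    db: DatabaseHandle,
    chromosome: str | None = None,
    include_blacklisted: bool = False,
) -> list[TargetInterval]:
    """Return panel targets, optionally restricted to one chromosome.

    Intervals overlapping a blacklist region by >= 1 bp are hidden unless
    ``include_blacklisted``.  An unknown chromosome yields an empty list.
    Result is sorted by (chromosome order, start, end, label).
    """
    if chromosome is not None:
        try:
            chromosome = normalize_chrom(chromosome)
        except ValueError:
            return []
    hidden = set() if include_blacklisted else db.blacklisted_target_ids()
    rows = db.conn.execute(
        "SELECT target_id, chromosome, start, end, label FROM target"
    ).fetchall()
    out = [
        TargetInterval(c, s, e, lbl)
        for tid, c, s, e, lbl in rows
        if tid not in hidden and (chromosome is None or c == chromosome)
    ]
    out.sort(key=TargetInterval.sort_key)
    return out
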