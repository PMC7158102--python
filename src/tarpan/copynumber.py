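"""Tumor/normal copy-number ratios, BAF, and automatic per-interval calls.

The central quantity is the per-interval copy-number ratio

    R = (T / T_nf) / (N / N_nf)

where T and N are the mean read depths of a captured interval in the tumor
and the matched normal, and T_nf / N_nf are library-size normalization
factors: the mean interval depth over a chosen chromosome set.  By default
that set is the autosomes (chr1-chr22); a user may restrict it to specific
chromosomes, which matters when whole chromosomes are aberrant and would
otherwise drag the factor with them.  When the upstream depth tool already
provides ratios they can be passed through unchanged (``provider_ratio``).

Blacklisted intervals are excluded both from the track and from the
normalization factors: the blacklist exists because capture is unreliable
there, so letting those depths into a mean would defeat its purpose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from statistics import median

from .errors import NormalizationError, TarpanError
from .genome import AUTOSOMES, normalize_chrom
from .panel_db import DatabaseHandle, TargetInterval

log = logging.getLogger("tarpan.copynumber")

DEFAULT_LOSS_MAX = 0.75
DEFAULT_GAIN_MIN = 1.25
DEFAULT_HET_BAND = (0.4, 0.6)


class NormalizationMode(str, Enum):
    provider_ratio = "provider_ratio"
    autosome_default = "autosome_default"
    user_chromosomes = "user_chromosomes"


@dataclass(frozen=True)
class NormalizationSpec:
    """How T_nf and N_nf are formed (or bypassed)."""

    mode: NormalizationMode = NormalizationMode.autosome_default
    chromosomes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.mode == NormalizationMode.user_chromosomes:
            if not self.chromosomes:
                raise TarpanError(
                    "user_chromosomes normalization requires a non-empty chromosome set"
                )
            object.__setattr__(
                self, "chromosomes", frozenset(normalize_chrom(c) for c in self.chromosomes)
            )

    def selected(self) -> frozenset[str]:
        if self.mode == NormalizationMode.user_chromosomes:
            return self.chromosomes
        return frozenset(AUTOSOMES)


class CnState(str, Enum):
    deleted = "deleted"
    neutral = "neutral"
    gained = "gained"


@dataclass(frozen=True)
class CnCall:
    interval: TargetInterval
    ratio: float
    state: CnState


@dataclass(frozen=True)
class GroupCnCall:
    group_name: str
    summary_ratio: float
    state: CnState
    n_intervals: int


@dataclass(frozen=True)
class RatioTrack:
    sample_id: str
    spec: NormalizationSpec
    tumor_norm_factor: float
    normal_norm_factor: float
    entries: tuple[tuple[TargetInterval, float], ...]


@dataclass(frozen=True)
class BafPoint:
    chromosome: str
    position: int
    normal_vaf: float
    tumor_vaf: float
    heterozygous_in_normal: bool


def normalization_factor(depths, spec: NormalizationSpec) -> float:
    """Mean depth over intervals on the chromosomes selected by ``spec``.

    ``depths`` is an iterable of (TargetInterval, depth) pairs for one role,
    already restricted to non-blacklisted intervals.
    """
    chroms = spec.selected()
    vals = [d for iv, d in depths if iv.chromosome in chroms]
    if not vals:
        raise NormalizationError(
            f"no intervals on the normalization chromosomes {sorted(chroms)}"
        )
    mean = sum(vals) / len(vals)
    if mean == 0:
        raise NormalizationError("normalization factor is zero (degenerate sample)")
    return mean


def _sample_depths(db: DatabaseHandle, sample_id: str):
    """(interval, tumor depth, normal depth, precomputed ratio) per target
    with both roles present, blacklisted targets excluded, genomic order."""
    db.require_sample(sample_id)
    hidden = db.blacklisted_target_ids()
    rows = db.conn.execute(
        """
        SELECT t.target_id, t.chromosome, t.start, t.end, t.label,
               dt.depth, dn.depth, dt.precomputed_ratio
        FROM target t
        JOIN depth dt ON dt.target_id = t.target_id
            AND dt.sample_id = ? AND dt.role = 'tumor'
        JOIN depth dn ON dn.target_id = t.target_id
            AND dn.sample_id = ? AND dn.role = 'normal'
        """,
        (sample_id, sample_id),
    ).fetchall()
    if not rows:
        raise TarpanError(f"sample {sample_id!r} has no paired tumor/normal depths")
    out = [
        (TargetInterval(c, s, e, lbl), float(td), float(nd), pr)
        for tid, c, s, e, lbl, td, nd, pr in rows
        if tid not in hidden
    ]
    out.sort(key=lambda r: r[0].sort_key())
    return out


def compute_ratio_track(
    db: DatabaseHandle, sample_id: str, spec: NormalizationSpec | None = None
) -> RatioTrack:
    """Compute R = (T/T_nf)/(N/N_nf) per interval for one sample.

    Intervals with zero normal depth are excluded (and reported) rather
    than producing infinite ratios.  In ``provider_ratio`` mode the ratios
    stored at ingest are passed through verbatim and no factors are formed.
    """
    spec = spec or NormalizationSpec()
    depths = _sample_depths(db, sample_id)

    if spec.mode == NormalizationMode.provider_ratio:
        missing = [iv for iv, _, _, pr in depths if pr is None]
        if missing:
            raise TarpanError(
                f"provider_ratio requested but {len(missing)} interval(s) lack a "
                "precomputed ratio (first: "
                f"{missing[0].chromosome}:{missing[0].start}-{missing[0].end})"
            )
        entries = tuple((iv, float(pr)) for iv, _, _, pr in depths)
        return RatioTrack(sample_id, spec, 1.0, 1.0, entries)

    t_nf = normalization_factor([(iv, t) for iv, t, _, _ in depths], spec)
    n_nf = normalization_factor([(iv, n) for iv, _, n, _ in depths], spec)
    entries = []
    for iv, t, n, _ in depths:
        if n == 0:
            log.warning(
                "interval %s:%d-%d has zero normal depth; excluded from track",
                iv.chromosome, iv.start, iv.end,
            )
            continue
        entries.append((iv, (t / t_nf) / (n / n_nf)))
    return RatioTrack(sample_id, spec, t_nf, n_nf, tuple(entries))


def auto_cn_calls(
    track: RatioTrack,
    thresholds: tuple[float, float] = (DEFAULT_LOSS_MAX, DEFAULT_GAIN_MIN),
) -> list[CnCall]:
    """Classify every track interval as deleted / neutral / gained.

    ``thresholds`` is (loss_max, gain_min) on the linear ratio scale;
    boundaries are inclusive toward the aberrant state (R <= loss_max is
    deleted, R >= gain_min is gained).
    """
    loss_max, gain_min = thresholds
    if not loss_max < gain_min:
        raise TarpanError(
            f"invalid thresholds: loss_max {loss_max} must be < gain_min {gain_min}"
        )
    out = []
    for iv, r in track.entries:
        if r <= loss_max:
            state = CnState.deleted
        elif r >= gain_min:
            state = CnState.gained
        else:
            state = CnState.neutral
        out.append(CnCall(iv, r, state))
    return out


def auto_cn_group_calls(
    track: RatioTrack,
    groups,
    thresholds: tuple[float, float] = (DEFAULT_LOSS_MAX, DEFAULT_GAIN_MIN),
    summary: str = "median",
) -> list[GroupCnCall]:
    """Summarize member-interval ratios per gene group and call each group.

    The summary statistic is the median by default (robust to a single
    noisy probe); mean is available.  Groups whose members all lack a
    ratio are reported as uncallable via a warning and omitted.
    """
    if summary not in ("median", "mean"):
        raise TarpanError(f"unknown group summary {summary!r}; use median or mean")
    ratio_of = {(iv.chromosome, iv.start, iv.end): r for iv, r in track.entries}
    out = []
    for g in groups:
        rs = [
            ratio_of[(m.chromosome, m.start, m.end)]
            for m in g.member_intervals
            if (m.chromosome, m.start, m.end) in ratio_of
        ]
        if not rs:
            log.warning("group %s has no scored member intervals; uncallable", g.group_name)
            continue
        summary_ratio = median(rs) if summary == "median" else sum(rs) / len(rs)
        loss_max, gain_min = thresholds
        if not loss_max < gain_min:
            raise TarpanError(
                f"invalid thresholds: loss_max {loss_max} must be < gain_min {gain_min}"
            )
        if summary_ratio <= loss_max:
            state = CnState.deleted
        elif summary_ratio >= gain_min:
            state = CnState.gained
        else:
            state = CnState.neutral
        out.append(GroupCnCall(g.group_name, summary_ratio, state, len(rs)))
    return out


def compute_baf(
    records, het_band: tuple[float, float] = DEFAULT_HET_BAND
) -> list[BafPoint]:
    """Turn allelic-depth records into BAF points for the SNP view.

    ``records`` is an iterable of (chromosome, position, normal_ref,
    normal_alt, tumor_ref, tumor_alt).  VAF = alt/(ref+alt); a site with
    zero total depth in either sample is excluded.  A point is flagged
    heterozygous-in-normal when the normal VAF falls inside ``het_band``
    (inclusive); the SNP view shows only those points, where divergence of
    the tumor VAF from 0.5 indicates allelic imbalance / LOH.
    """
    low, high = het_band
    if not (0.0 <= low < high <= 1.0):
        raise TarpanError(f"het band must satisfy 0 <= low < high <= 1, got {het_band}")
    out = []
    for chrom, pos, nr, na, tr, ta in records:
        n_total, t_total = nr + na, tr + ta
        if n_total == 0 or t_total == 0:
            continue
        n_vaf = na / n_total
        t_vaf = ta / t_total
        out.append(
            BafPoint(chrom, pos, n_vaf, t_vaf, low <= n_vaf <= high)
        )
    return out


def snp_records_for_sample(db: DatabaseHandle, sample_id: str, include_off_panel=False):
    """Fetch stored allelic-depth tuples for :func:`compute_baf`."""
    db.require_sample(sample_id)
    rows = db.conn.execute(
        "SELECT chromosome, position, normal_ref_depth, normal_alt_depth,"
        " tumor_ref_depth, tumor_alt_depth, off_panel FROM snp_record"
        " WHERE sample_id=? ORDER BY chromosome, position",
        (sample_id,),
    ).fetchall()
    return [
        (c, p, nr, na, tr, ta)
        for c, p, nr, na, tr, ta, off in rows
        if include_off_panel or not off
    ]
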