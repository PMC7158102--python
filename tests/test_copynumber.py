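"""Ratio formula, normalization modes, auto calls, group calls, BAF."""

import numpy as np
import pytest

import tarpan
from tarpan.copynumber import (
    CnState,
    NormalizationMode,
    NormalizationSpec,
    auto_cn_calls,
    auto_cn_group_calls,
    compute_baf,
    compute_ratio_track,
    normalization_factor,
)
from tarpan.errors import NormalizationError, TarpanError
from tarpan.panel_db import GeneGroup, TargetInterval

from conftest import write_bed, write_depth_table

AUTOSOME_SET = frozenset(f"chr{i}" for i in range(1, 23))


def iv(chrom, start, label="G"):
    return TargetInterval(chrom, start, start + 100, label)


def make_db(tmp_path, intervals, tumor, normal, name="p", tumor_extra=None):
    """Small helper: one-sample database from parallel depth lists."""
    t_bed = write_bed(
        tmp_path / f"{name}_t.bed",
        [(i.chromosome, i.start, i.end, i.label) for i in intervals],
    )
    g_bed = write_bed(
        tmp_path / f"{name}_g.bed",
        [(i.chromosome, i.start, i.end, i.label) for i in intervals],
    )
    db = tarpan.create_database(
        name, "hg38", "v", t_bed, g_bed, out_path=tmp_path / f"{name}.sqlite"
    )
    tarpan.register_sample(db, "S")
    rows_t = [
        (i.chromosome, i.start, i.end, d) for i, d in zip(intervals, tumor)
    ]
    rows_n = [
        (i.chromosome, i.start, i.end, d) for i, d in zip(intervals, normal)
    ]
    if tumor_extra is not None:
        col, vals = tumor_extra
        rows_t = [r + (v,) for r, v in zip(rows_t, vals)]
        t_tab = write_depth_table(tmp_path / f"{name}_td.tsv", rows_t, extra_col=col)
    else:
        t_tab = write_depth_table(tmp_path / f"{name}_td.tsv", rows_t)
    n_tab = write_depth_table(tmp_path / f"{name}_nd.tsv", rows_n)
    tarpan.import_depths(db, "S", t_tab, n_tab)
    return db


def brute_force_ratios(intervals, tumor, normal, norm_chroms):
    """Independent oracle: plain-Python arithmetic for R=(T/T_nf)/(N/N_nf)."""
    t_sel = [t for i, t in zip(intervals, tumor) if i.chromosome in norm_chroms]
    n_sel = [n for i, n in zip(intervals, normal) if i.chromosome in norm_chroms]
    t_nf = sum(t_sel) / len(t_sel)
    n_nf = sum(n_sel) / len(n_sel)
    return [
        (t / t_nf) / (n / n_nf)
        for i, t, n in zip(intervals, tumor, normal)
        if n != 0
    ]


class TestNormalizationFactor:
    def test_mean_of_selected_depths(self):
        depths = [(iv("chr1", 0), 10.0), (iv("chr1", 200), 20.0), (iv("chr1", 400), 30.0)]
        assert normalization_factor(depths, NormalizationSpec()) == 20.0

    def test_user_chromosomes_restrict_the_mean(self):
        depths = [(iv("chr1", 0), 10.0), (iv("chr1", 200), 10.0), (iv("chr2", 0), 40.0)]
        spec = NormalizationSpec(NormalizationMode.user_chromosomes, frozenset({"chr2"}))
        assert normalization_factor(depths, spec) == 40.0

    def test_empty_selection_is_an_error(self):
        depths = [(iv("chr1", 0), 10.0)]
        spec = NormalizationSpec(NormalizationMode.user_chromosomes, frozenset({"chrX"}))
        with pytest.raises(NormalizationError, match="chrX"):
            normalization_factor(depths, spec)

    def test_empty_chromosome_set_rejected_at_construction(self):
        with pytest.raises(TarpanError):
            NormalizationSpec(NormalizationMode.user_chromosomes, frozenset())


class TestComputeRatioTrack:
    def test_hand_computed_ratios(self, tmp_path):
        ivs = [iv("chr1", 0), iv("chr1", 200), iv("chr1", 400)]
        db = make_db(tmp_path, ivs, tumor=[10, 10, 40], normal=[10, 10, 10])
        track = compute_ratio_track(db, "S")
        assert track.tumor_norm_factor == 20.0
        assert track.normal_norm_factor == 10.0
        assert [r for _, r in track.entries] == pytest.approx([0.5, 0.5, 2.0])
        db.close()

    def test_identical_depths_give_unit_ratio(self, tmp_path):
        ivs = [iv("chr1", i * 200) for i in range(4)]
        depths = [13.0, 99.5, 7.25, 400.0]
        db = make_db(tmp_path, ivs, tumor=depths, normal=depths)
        track = compute_ratio_track(db, "S")
        assert [r for _, r in track.entries] == pytest.approx([1.0] * 4, abs=1e-12)
        db.close()

    def test_uniform_doubling_is_normalized_away(self, tmp_path):
        ivs = [iv("chr2", i * 200) for i in range(3)]
        normal = [10.0, 30.0, 50.0]
        db = make_db(tmp_path, ivs, tumor=[2 * d for d in normal], normal=normal)
        track = compute_ratio_track(db, "S")
        assert [r for _, r in track.entries] == pytest.approx([1.0] * 3, abs=1e-12)
        db.close()

    def test_scale_invariance_of_tumor_depths(self, tmp_path):
        rng = np.random.default_rng(5)
        ivs = [iv("chr1", i * 200) for i in range(10)] + [
            iv("chr9", i * 200) for i in range(5)
        ]
        tumor = list(rng.uniform(5, 100, 15))
        normal = list(rng.uniform(5, 100, 15))
        base = compute_ratio_track(
            make_db(tmp_path, ivs, tumor, normal, name="a"), "S"
        )
        scaled = compute_ratio_track(
            make_db(tmp_path, ivs, [7.3 * t for t in tumor], normal, name="b"), "S"
        )
        for (_, r0), (_, r1) in zip(base.entries, scaled.entries):
            assert r1 == pytest.approx(r0, abs=1e-12)

    def test_user_chromosomes_1_22_reproduces_autosome_default(self, tmp_path):
        rng = np.random.default_rng(6)
        ivs = [iv(c, i * 200) for c in ("chr1", "chr5", "chrX") for i in range(4)]
        tumor = list(rng.uniform(5, 100, 12))
        normal = list(rng.uniform(5, 100, 12))
        db = make_db(tmp_path, ivs, tumor, normal)
        default = compute_ratio_track(db, "S", NormalizationSpec())
        explicit = compute_ratio_track(
            db, "S", NormalizationSpec(NormalizationMode.user_chromosomes, AUTOSOME_SET)
        )
        assert default.tumor_norm_factor == explicit.tumor_norm_factor
        assert [r for _, r in default.entries] == [r for _, r in explicit.entries]
        db.close()

    def test_post_normalization_identity(self, tmp_path):
        """Mean of T/T_nf over the normalization set equals 1."""
        rng = np.random.default_rng(7)
        ivs = [iv("chr3", i * 200) for i in range(20)]
        tumor = list(rng.uniform(5, 500, 20))
        normal = list(rng.uniform(5, 500, 20))
        db = make_db(tmp_path, ivs, tumor, normal)
        track = compute_ratio_track(db, "S")
        assert np.mean([t / track.tumor_norm_factor for t in tumor]) == pytest.approx(
            1.0, abs=1e-12
        )
        assert np.mean([n / track.normal_norm_factor for n in normal]) == pytest.approx(
            1.0, abs=1e-12
        )
        db.close()

    def test_matches_brute_force_oracle_on_random_panels(self, tmp_path):
        rng = np.random.default_rng(2024)
        chroms = ["chr1", "chr2", "chr7", "chr17", "chrX"]
        for trial in range(20):
            n = int(rng.integers(3, 60))
            ivs = [
                iv(chroms[int(rng.integers(0, len(chroms)))], 1000 * k)
                for k in range(n)
            ]
            tumor = list(rng.uniform(1, 1000, n))
            normal = list(rng.uniform(1, 1000, n))
            if not any(i.chromosome != "chrX" for i in ivs):
                ivs[0] = iv("chr1", 0)
            db = make_db(tmp_path, ivs, tumor, normal, name=f"r{trial}")
            got = [r for _, r in compute_ratio_track(db, "S").entries]
            order = sorted(range(n), key=lambda k: ivs[k].sort_key())
            expected = brute_force_ratios(
                [ivs[k] for k in order], [tumor[k] for k in order],
                [normal[k] for k in order], AUTOSOME_SET,
            )
            assert got == pytest.approx(expected, abs=1e-12)
            db.close()

    def test_provider_ratio_passthrough(self, tmp_path):
        ivs = [iv("chr1", 0), iv("chr1", 200), iv("chr1", 400)]
        db = make_db(
            tmp_path, ivs, tumor=[10, 10, 40], normal=[10, 10, 10],
            tumor_extra=("ratio", [0.41, 1.02, 1.97]),
        )
        track = compute_ratio_track(
            db, "S", NormalizationSpec(NormalizationMode.provider_ratio)
        )
        assert [r for _, r in track.entries] == pytest.approx([0.41, 1.02, 1.97])
        db.close()

    def test_provider_ratio_missing_is_an_error(self, tmp_path):
        ivs = [iv("chr1", 0)]
        db = make_db(tmp_path, ivs, tumor=[10], normal=[10])
        with pytest.raises(TarpanError, match="precomputed ratio"):
            compute_ratio_track(
                db, "S", NormalizationSpec(NormalizationMode.provider_ratio)
            )
        db.close()

    def test_zero_normal_interval_excluded(self, tmp_path):
        ivs = [iv("chr1", 0), iv("chr1", 200), iv("chr1", 400)]
        db = make_db(tmp_path, ivs, tumor=[10, 10, 10], normal=[10, 0, 10])
        track = compute_ratio_track(db, "S")
        assert len(track.entries) == 2
        assert all(np.isfinite(r) for _, r in track.entries)
        db.close()

    def test_blacklisted_intervals_excluded_from_factors(self, tmp_path):
        ivs = [iv("chr1", 0, "A"), iv("chr1", 200, "A"), iv("chr1", 400, "B")]
        t_bed = write_bed(tmp_path / "t.bed", [(i.chromosome, i.start, i.end, i.label) for i in ivs])
        g_bed = write_bed(tmp_path / "g.bed", [("chr1", 0, 500, "A")])
        b_bed = write_bed(tmp_path / "b.bed", [("chr1", 400, 500, "")])
        db = tarpan.create_database("bl", "hg38", "v", t_bed, g_bed, b_bed,
                                    out_path=tmp_path / "bl.sqlite")
        tarpan.register_sample(db, "S")
        rows = lambda ds: [(i.chromosome, i.start, i.end, d) for i, d in zip(ivs, ds)]
        tarpan.import_depths(
            db, "S",
            write_depth_table(tmp_path / "td.tsv", rows([10.0, 10.0, 1000.0])),
            write_depth_table(tmp_path / "nd.tsv", rows([10.0, 10.0, 1000.0])),
        )
        track = compute_ratio_track(db, "S")
        # the huge blacklisted interval influences neither factor nor track
        assert track.tumor_norm_factor == 10.0
        assert len(track.entries) == 2
        db.close()


class TestAutoCnCalls:
    def _track(self, ratios):
        entries = tuple((iv("chr1", 200 * k), r) for k, r in enumerate(ratios))
        return tarpan.RatioTrack("S", NormalizationSpec(), 1.0, 1.0, entries)

    def test_threshold_application(self):
        calls = auto_cn_calls(self._track([0.5, 1.0, 2.0]), (0.75, 1.25))
        assert [c.state for c in calls] == [
            CnState.deleted, CnState.neutral, CnState.gained,
        ]

    def test_all_unity_is_all_neutral(self):
        for thresholds in [(0.75, 1.25), (0.5, 1.5), (0.99, 1.01)]:
            calls = auto_cn_calls(self._track([1.0] * 5), thresholds)
            assert all(c.state == CnState.neutral for c in calls)

    def test_boundary_is_inclusive_toward_aberrant(self):
        calls = auto_cn_calls(self._track([0.75, 1.25]), (0.75, 1.25))
        assert [c.state for c in calls] == [CnState.deleted, CnState.gained]

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(TarpanError):
            auto_cn_calls(self._track([1.0]), (1.25, 0.75))


class TestGroupCalls:
    def _track_and_groups(self, ratios_by_group):
        entries, groups, pos = [], [], 0
        for name, ratios in ratios_by_group.items():
            members = []
            for r in ratios:
                interval = iv("chr1", 200 * pos, name)
                entries.append((interval, r))
                members.append(interval)
                pos += 1
            groups.append(GeneGroup(name, tuple(members)))
        track = tarpan.RatioTrack("S", NormalizationSpec(), 1.0, 1.0, tuple(entries))
        return track, groups

    def test_median_summary_and_state(self):
        track, groups = self._track_and_groups({"A": [0.5, 0.52, 0.48]})
        (call,) = auto_cn_group_calls(track, groups, (0.75, 1.25))
        assert call.summary_ratio == pytest.approx(0.5)
        assert call.state == CnState.deleted
        assert call.n_intervals == 3

    def test_single_member_group(self):
        track, groups = self._track_and_groups({"A": [1.0]})
        (call,) = auto_cn_group_calls(track, groups)
        assert (call.summary_ratio, call.state) == (1.0, CnState.neutral)

    def test_median_robust_to_one_outlier_each_way(self):
        track, groups = self._track_and_groups({"A": [0.5, 1.0, 1.5]})
        (call,) = auto_cn_group_calls(track, groups)
        assert call.summary_ratio == pytest.approx(1.0)
        assert call.state == CnState.neutral

    def test_group_without_scored_members_omitted(self):
        track, groups = self._track_and_groups({"A": [1.0]})
        orphan = GeneGroup("B", (iv("chr2", 0, "B"),))
        calls = auto_cn_group_calls(track, groups + [orphan])
        assert [c.group_name for c in calls] == ["A"]


class TestComputeBaf:
    def test_loh_suggestive_divergence(self):
        (p,) = compute_baf([("chr17", 100, 10, 10, 18, 2)], (0.4, 0.6))
        assert p.normal_vaf == pytest.approx(0.5)
        assert p.tumor_vaf == pytest.approx(0.1)
        assert p.heterozygous_in_normal

    def test_homozygous_normal_not_flagged(self):
        (p,) = compute_baf([("chr1", 100, 20, 0, 10, 10)])
        assert p.normal_vaf == 0.0
        assert not p.heterozygous_in_normal

    def test_zero_depth_site_excluded(self):
        assert compute_baf([("chr1", 100, 0, 0, 10, 10)]) == []
        assert compute_baf([("chr1", 100, 10, 10, 0, 0)]) == []

    def test_invalid_band_rejected(self):
        with pytest.raises(TarpanError):
            compute_baf([], (0.6, 0.4))
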