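"""Dead-zone calling: depth semantics, per-base oracle, monotonicity, coverage."""

import numpy as np
import pytest

from shadowzones.core import GenomicInterval
from shadowzones.deadzones import (
    DeadZoneParams,
    DeadZoneSet,
    DepthProfile,
    call_dead_zones,
    deadzone_coverage_fraction,
    depth_profile_from_alignments,
    read_depth_tsv,
    uncallable_residual,
    write_depth_tsv,
)
from shadowzones.forcecall import AlignedRead

from conftest import CONTIG, bitmap, mask_to_intervals, random_intervals

LEN = 2000


def random_reads(rng, n, contig_len=LEN, read_len=80):
    out = []
    for i in range(n):
        pos = int(rng.integers(0, contig_len - read_len))
        mapq = int(rng.choice([0, 10, 30, 60]))
        out.append(AlignedRead(f"r{i}", CONTIG, pos, "A" * read_len, mapq))
    return out


def oracle_depth(reads, contig_len, mapq_min):
    d = np.zeros(contig_len, dtype=int)
    for r in reads:
        if r.mapq >= mapq_min:
            for i in range(max(0, r.pos), min(contig_len, r.end)):
                d[i] += 1
    return d


def oracle_dead_mask(depths, params):
    stack = np.stack(depths)
    frac_fail = (stack < params.min_depth).mean(axis=0)
    return frac_fail >= params.min_sample_fraction


def make_profiles(rng, n_samples, params, contig_len=LEN):
    profs = []
    for k in range(n_samples):
        reads = random_reads(rng, int(rng.integers(20, 120)), contig_len)
        profs.append(
            depth_profile_from_alignments(
                reads, CONTIG, contig_len, params.mapq_min, sample_id=f"s{k}"
            )
        )
    return profs


class TestDepthProfile:
    def test_tiling_reads_give_flat_depth(self):
        reads = [AlignedRead(f"r{i}", CONTIG, 100, "A" * 50, 60) for i in range(10)]
        p = depth_profile_from_alignments(reads, CONTIG, 300, mapq_min=20)
        assert (p.depth[100:150] == 10).all()
        assert (p.depth[:100] == 0).all() and (p.depth[150:] == 0).all()

    def test_low_mapq_reads_do_not_count(self):
        reads = [AlignedRead(f"r{i}", CONTIG, 100, "A" * 50, 0) for i in range(10)]
        p = depth_profile_from_alignments(reads, CONTIG, 300, mapq_min=20)
        assert (p.depth == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_random_reads_match_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        reads = random_reads(rng, 200)
        for mapq_min in (0, 20, 61):
            p = depth_profile_from_alignments(reads, CONTIG, LEN, mapq_min)
            assert (p.depth == oracle_depth(reads, LEN, mapq_min)).all()


class TestCallDeadZones:
    def test_high_depth_everywhere_gives_no_zones(self):
        profs = [
            DepthProfile(f"s{k}", CONTIG, np.full(LEN, 30), 20) for k in range(5)
        ]
        assert call_dead_zones(profs).zones == []

    def test_zero_depth_everywhere_gives_one_contig_zone(self):
        profs = [DepthProfile(f"s{k}", CONTIG, np.zeros(LEN), 20) for k in range(5)]
        zones = call_dead_zones(profs).zones
        assert zones == [GenomicInterval(CONTIG, 0, LEN)]

    def test_inconsistent_lengths_rejected(self):
        profs = [
            DepthProfile("a", CONTIG, np.zeros(100), 20),
            DepthProfile("b", CONTIG, np.zeros(200), 20),
        ]
        with pytest.raises(ValueError, match="lengths"):
            call_dead_zones(profs)

    @pytest.mark.parametrize("seed", range(5))
    def test_called_zones_match_per_base_oracle(self, seed):
        params = DeadZoneParams(min_length=1)
        rng = np.random.default_rng(seed)
        profs = make_profiles(rng, 6, params)
        zones = call_dead_zones(profs, params).zones
        mask = oracle_dead_mask([p.depth for p in profs], params)
        assert zones == mask_to_intervals(mask)

    def test_min_length_drops_short_zones(self):
        depth = np.full(LEN, 30)
        depth[100:120] = 0  # 20 bp < min_length 50
        depth[500:600] = 0  # 100 bp kept
        profs = [DepthProfile(f"s{k}", CONTIG, depth, 20) for k in range(3)]
        zones = call_dead_zones(profs, DeadZoneParams(min_length=50)).zones
        assert zones == [GenomicInterval(CONTIG, 500, 600)]

    def test_synthetic_cohort_covers_identical_segment(self, pseudogene_truth):
        """The gene+pseudogene cohort's called zones cover the identical core."""
        from shadowzones.simulate import cohort_depth_profiles

        t = pseudogene_truth
        profs = cohort_depth_profiles(t, n_samples=6, seed=2)
        zones = call_dead_zones(profs, DeadZoneParams())
        # oracle equivalence on the exact same profiles
        params_raw = DeadZoneParams(min_length=1)
        mask = oracle_dead_mask([p.depth for p in profs], params_raw)
        assert call_dead_zones(profs, params_raw).zones == mask_to_intervals(
            mask, chrom=t.contig
        )
        # the deep interior of the identical core must be dead
        core_len = int(0.4 * t.copy_length)
        core_start = t.gene_region.start + (t.copy_length - core_len) // 2
        core = GenomicInterval(t.contig, core_start + 150, core_start + core_len - 150)
        assert deadzone_coverage_fraction(zones, [core]) < 1.0  # zones extend beyond
        from shadowzones.core import intersect_length

        assert intersect_length(zones.zones, [core]) == core.length


class TestMonotonicity:
    def test_dead_bases_grow_with_min_depth(self):
        rng = np.random.default_rng(42)
        base = DeadZoneParams(min_length=1)
        profs = make_profiles(rng, 6, base)
        depths = [p.depth for p in profs]
        m1 = oracle_dead_mask(depths, DeadZoneParams(min_depth=3, min_length=1))
        z1 = bitmap(call_dead_zones(profs, DeadZoneParams(min_depth=3, min_length=1)).zones, LEN)
        z2 = bitmap(call_dead_zones(profs, DeadZoneParams(min_depth=8, min_length=1)).zones, LEN)
        assert (z1 == m1).all()
        assert not (z1 & ~z2).any()  # D=3 dead bases subset of D=8 dead bases

    def test_dead_bases_shrink_with_sample_fraction(self):
        rng = np.random.default_rng(43)
        profs = make_profiles(rng, 6, DeadZoneParams(min_length=1))
        z_lo = bitmap(call_dead_zones(profs, DeadZoneParams(min_sample_fraction=0.5, min_length=1)).zones, LEN)
        z_hi = bitmap(call_dead_zones(profs, DeadZoneParams(min_sample_fraction=0.99, min_length=1)).zones, LEN)
        assert not (z_hi & ~z_lo).any()

    def test_raising_mapq_min_never_shrinks_dead_set(self):
        rng = np.random.default_rng(44)
        read_sets = [random_reads(rng, int(rng.integers(20, 120))) for _ in range(6)]
        masks = []
        for mapq_min in (10, 30):
            params = DeadZoneParams(mapq_min=mapq_min, min_length=1)
            profs = [
                depth_profile_from_alignments(rs, CONTIG, LEN, mapq_min, f"s{k}")
                for k, rs in enumerate(read_sets)
            ]
            masks.append(bitmap(call_dead_zones(profs, params).zones, LEN))
        low, high = masks
        assert not (low & ~high).any()


class TestCoverageAccounting:
    def zones(self, ivs):
        return DeadZoneSet(ivs, DeadZoneParams(), n_samples=1)

    def test_full_and_zero_coverage(self):
        z = self.zones([GenomicInterval(CONTIG, 100, 200)])
        assert deadzone_coverage_fraction(z, [GenomicInterval(CONTIG, 0, 500)]) == 1.0
        assert deadzone_coverage_fraction(z, [GenomicInterval(CONTIG, 300, 400)]) == 0.0
        assert uncallable_residual(z, [GenomicInterval(CONTIG, 0, 500)]) == []
        assert uncallable_residual(z, []) == z.zones

    def test_empty_zones_covered_by_convention(self):
        assert deadzone_coverage_fraction([], [GenomicInterval(CONTIG, 0, 10)]) == 1.0

    def test_two_percent_residual_mirrors_98_percent_coverage(self):
        """9,000 bp of zones with one 180 bp hole -> coverage 0.98."""
        z = self.zones([GenomicInterval(CONTIG, 0, 9000)])
        callable_ivs = [
            GenomicInterval(CONTIG, 0, 4000),
            GenomicInterval(CONTIG, 4180, 9000),
        ]
        assert deadzone_coverage_fraction(z, callable_ivs) == pytest.approx(0.98)
        residual = uncallable_residual(z, callable_ivs)
        assert residual == [GenomicInterval(CONTIG, 4000, 4180)]

    @pytest.mark.parametrize("seed", range(5))
    def test_fraction_and_residual_are_consistent(self, seed):
        rng = np.random.default_rng(seed)
        from shadowzones.core import total_length

        zs = random_intervals(rng)
        if not zs:
            return
        callable_ivs = random_intervals(rng)
        z = self.zones(zs)
        frac = deadzone_coverage_fraction(z, callable_ivs)
        resid = uncallable_residual(z, callable_ivs)
        assert abs(total_length(resid) - (1 - frac) * z.total_bases) <= 1
        # residual matches the bitmap difference oracle
        assert resid == mask_to_intervals(bitmap(zs) & ~bitmap(callable_ivs))


class TestDepthIO:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        p = DepthProfile("s1", CONTIG, rng.integers(0, 50, 300), 20)
        path = tmp_path / "depth_s1.tsv"
        write_depth_tsv(p, path)
        q = read_depth_tsv(path)
        assert q.sample_id == "s1" and q.mapq_min == 20 and q.chrom == CONTIG
        assert (q.depth == p.depth).all()

    def test_bedgraph_rows_expand_per_base(self, tmp_path):
        path = tmp_path / "d.bedgraph"
        path.write_text("chrT\t0\t5\t7\nchrT\t5\t10\t0\nchrT\t10\t12\t3\n")
        p = read_depth_tsv(path)
        assert list(p.depth) == [7] * 5 + [0] * 5 + [3] * 2
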