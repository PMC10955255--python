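"""Sequencing-profile estimation, fragment simulation and analytic lifting."""

import edlib
import numpy as np
import pytest

from svembed.reads import CIGAR_D, CIGAR_I, CIGAR_M, CIGAR_S
from svembed.simulate import (
    SeqStats,
    estimate_stats,
    lift_alignment,
    sample_fragments,
    simulate_replicate,
)
from svembed.variants import GenotypeHypothesis, MapBlock, construct_haplotype


class TestSeqStats:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SeqStats(30, 100, 90, 10, 0.001)  # insert_mean <= read_length
        with pytest.raises(ValueError):
            SeqStats(-1, 100, 400, 50, 0.001)

    def test_round_trip_dict(self, stats):
        assert SeqStats.from_dict(stats.to_dict()) == stats


@pytest.fixture(scope="module")
def flat_study_bam(tmp_path_factory):
    """Reads over an SV-free contig so depth/insert estimates are clean."""
    from svembed import synthetic as syn

    out = tmp_path_factory.mktemp("est")
    truth = SeqStats(30, 100, 500, 100, 0.0)
    study = syn.generate_study(length=200_000, n_svs=0, samples=("S",), seed=5)
    path = syn.generate_actual_reads(study, "S", truth, seed=9, out_dir=str(out))
    return path, truth


class TestEstimateStats:
    def test_round_trip_within_5pct(self, flat_study_bam):
        path, truth = flat_study_bam
        est = estimate_stats(path, [("chr1", 20_000, 180_000)])
        assert est.mean_coverage == pytest.approx(truth.mean_coverage, rel=0.05)
        assert est.insert_mean == pytest.approx(truth.insert_mean, rel=0.05)
        assert est.insert_sd == pytest.approx(truth.insert_sd, rel=0.05)
        assert est.read_length == truth.read_length

    def test_error_free_reads_rate_below_1e3(self, flat_study_bam):
        path, _ = flat_study_bam
        est = estimate_stats(path, [("chr1", 20_000, 180_000)])
        assert est.base_error_rate < 1e-3

    def test_deterministic(self, flat_study_bam):
        path, _ = flat_study_bam
        a = estimate_stats(path, [("chr1", 20_000, 100_000)], seed=3)
        b = estimate_stats(path, [("chr1", 20_000, 100_000)], seed=3)
        assert a == b

    def test_too_few_pairs_is_actionable_error(self, flat_study_bam):
        path, _ = flat_study_bam
        with pytest.raises(ValueError, match="explicit"):
            estimate_stats(path, [("chr1", 0, 500)])


class TestLiftAlignment:
    # a 200 bp DEL: hap [0,1000) -> ref [0,1000), hap [1000,...) -> ref 1200+
    DEL_BLOCKS = [MapBlock(0, 1000, 0), MapBlock(1000, 2000, 1200)]
    # a 150 bp INS at ref 1000: novel hap block [1000, 1150)
    INS_BLOCKS = [
        MapBlock(0, 1000, 0),
        MapBlock(1000, 1150, None),
        MapBlock(1150, 2150, 1000),
    ]

    def _read(self, hap_start, length=70):
        seq = "A" * length
        return hap_start, seq, np.full(length, 30, np.uint8)

    def test_left_flank_identity(self):
        s, seq, q = self._read(100)
        read = lift_alignment(s, seq, q, self.DEL_BLOCKS, "r")
        assert read.ref_start == 100
        assert read.cigar == [(CIGAR_M, 70)]

    def test_del_junction_split(self):
        # read straddling the junction with 40 bp on the right side
        s, seq, q = self._read(1000 - 30, length=70)
        read = lift_alignment(s, seq, q, self.DEL_BLOCKS, "r")
        assert read.cigar == [(CIGAR_M, 30), (CIGAR_D, 200), (CIGAR_M, 40)]
        assert read.ref_start == 970

    def test_ins_overhang_soft_clipped(self):
        s, seq, q = self._read(960, length=70)  # 40 M then 30 into the insertion
        read = lift_alignment(s, seq, q, self.INS_BLOCKS, "r")
        assert read.cigar == [(CIGAR_M, 40), (CIGAR_S, 30)]

    def test_read_spanning_whole_insertion_gets_I(self):
        blocks = [MapBlock(0, 1000, 0), MapBlock(1000, 1020, None), MapBlock(1020, 2020, 1000)]
        s, seq, q = self._read(980, length=70)  # 20 M + 20 I + 30 M
        read = lift_alignment(s, seq, q, blocks, "r")
        assert read.cigar == [(CIGAR_M, 20), (CIGAR_I, 20), (CIGAR_M, 30)]

    def test_read_inside_novel_sequence_is_anchored_clip(self):
        s, seq, q = self._read(1010, length=70)
        blocks = [MapBlock(0, 1000, 0), MapBlock(1000, 1150, None), MapBlock(1150, 2150, 1000)]
        read = lift_alignment(s, seq, q, blocks, "r")
        assert read.anchored_only
        assert read.ref_start == 1000  # the insertion anchor
        assert read.cigar == [(CIGAR_S, 70)]

    def test_repeat_interval_degrades_mapq(self):
        s, seq, q = self._read(100)
        read = lift_alignment(s, seq, q, self.DEL_BLOCKS, "r", mapq_intervals=[(50, 300)])
        assert read.mapq == 20
        read2 = lift_alignment(s, seq, q, self.DEL_BLOCKS, "r", mapq_intervals=[(150, 300)])
        assert read2.mapq == 60

    @pytest.mark.parametrize("sv_fixture", ["del_sv", "ins_sv"])
    def test_lift_agrees_with_dp_alignment_oracle(
        self, sv_fixture, tiny_reference, request
    ):
        """Every aligned (M) segment of a lifted error-free read must place
        exactly (edit distance 0) at its lifted reference interval when
        aligned independently by a DP aligner against the reference window."""
        sv = request.getfixturevalue(sv_fixture)
        hap = construct_haplotype(sv, 1, tiny_reference, flank_bp=600)
        window = tiny_reference["chr1"][hap.window_start : hap.window_end]
        rng = np.random.default_rng(13)
        checked = 0
        for _ in range(120):
            if checked >= 30:
                break
            start = int(rng.integers(0, len(hap.sequence) - 70))
            seq = hap.sequence[start : start + 70]
            read = lift_alignment(
                start, seq, np.full(70, 30, np.uint8), hap.blocks, "r"
            )
            if read.anchored_only:
                continue  # no reference interval to compare
            qpos, rpos = 0, read.ref_start
            for op, length in read.cigar:
                if op == CIGAR_M:
                    if length >= 20:  # long enough for unique placement
                        segment = seq[qpos : qpos + length]
                        res = edlib.align(segment, window, mode="HW", task="locations")
                        assert res["editDistance"] == 0
                        locs = [(s0, e0 + 1) for s0, e0 in res["locations"]]
                        lifted = (
                            rpos - hap.window_start,
                            rpos + length - hap.window_start,
                        )
                        assert lifted in locs
                    qpos += length
                    rpos += length
                elif op == CIGAR_D:
                    rpos += length
                else:  # I or S consume query only
                    qpos += length
            checked += 1
        assert checked >= 30


class TestSimulateReplicate:
    def test_homref_has_no_breakpoint_artifacts(self, del_sv, stats, tiny_reference):
        rep = simulate_replicate(
            del_sv, GenotypeHypothesis((0, 0)), stats, tiny_reference, seed=3
        )
        for frag in rep.fragments:
            for read in frag.reads:
                assert all(op == CIGAR_M for op, _ in read.cigar)

    def test_homalt_del_shifts_spanning_inserts(self, del_sv, stats, tiny_reference):
        """Pairs spanning a 200 bp DEL junction have lifted insert sizes
        shifted by +200 on average (direct computation from the map)."""
        rep = simulate_replicate(
            del_sv, GenotypeHypothesis((1, 1)), stats, tiny_reference, seed=4
        )
        spanning, non_spanning = [], []
        for frag in rep.fragments:
            lo, hi = frag.ref_start, frag.ref_end
            if lo < del_sv.start and hi > del_sv.end:
                spanning.append(frag.insert_size)
            elif hi < del_sv.start or lo > del_sv.end:
                non_spanning.append(frag.insert_size)
        assert len(spanning) > 5
        shift = np.mean(spanning) - np.mean(non_spanning)
        assert shift == pytest.approx(200, abs=4 * stats.insert_sd / np.sqrt(len(spanning)) + 10)

    def test_same_seed_identical_replicates(self, del_sv, stats, tiny_reference):
        a = simulate_replicate(del_sv, GenotypeHypothesis((0, 1)), stats, tiny_reference, seed=8)
        b = simulate_replicate(del_sv, GenotypeHypothesis((0, 1)), stats, tiny_reference, seed=8)
        assert len(a.fragments) == len(b.fragments)
        for fa, fb in zip(a.fragments, b.fragments):
            assert fa.reads[0].seq == fb.reads[0].seq
            assert fa.reads[0].ref_start == fb.reads[0].ref_start

    def test_coverage_and_insert_match_profile(self, del_sv, stats, tiny_reference):
        """Realized depth within 4 binomial SDs; insert mean within 3 SE."""
        rep = simulate_replicate(
            del_sv, GenotypeHypothesis((0, 0)), stats, tiny_reference, seed=5
        )
        depth = np.zeros(len(tiny_reference["chr1"]), dtype=int)
        inserts = []
        for frag in rep.fragments:
            inserts.append(frag.insert_size)
            for read in frag.reads:
                pos = read.ref_start
                for op, length in read.cigar:
                    if op == CIGAR_M:
                        depth[pos : pos + length] += 1
                        pos += length
                    elif op == CIGAR_D:
                        pos += length
        # interior of the simulated window
        interior = depth[del_sv.start - 500 : del_sv.start - 100]
        mean_depth = interior.mean()
        sd = np.sqrt(stats.mean_coverage)
        assert abs(mean_depth - stats.mean_coverage) < 4 * sd
        se = stats.insert_sd / np.sqrt(len(inserts))
        assert abs(np.mean(inserts) - stats.insert_mean) < 3 * se + 2

    def test_window_too_short_raises(self, del_sv, tiny_reference):
        tight = SeqStats(30, 100, 5000, 2000, 0.001)
        hap = construct_haplotype(del_sv, 0, tiny_reference, flank_bp=1000)
        with pytest.raises(ValueError, match="insert"):
            sample_fragments(hap, 10, tight, np.random.default_rng(0))
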