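"""Pileup image encoding: channels, downsampling, rendering, compression."""

import numpy as np
import pytest

from svembed.pileup import (
    CH_BASE,
    CH_BASEQ,
    CH_CLIP,
    CH_HAPLOTYPE,
    CH_INSERT,
    CH_MAPQ,
    CH_PAIR,
    CH_REALIGN,
    CH_STRAND,
    ImageConfig,
    ImageTensor,
    Window,
    compress_width,
    encode_base_features,
    gather_fragments,
    realign_fragment,
    render_image,
    support_value,
)
from svembed.reads import CIGAR_M, CIGAR_S, AlignedRead, Fragment
from svembed.variants import construct_haplotype

from conftest import make_fragment, make_read


def _rand_fragments(ref, n, rng, region_start=0, region_len=2000):
    frags = []
    for i in range(n):
        start = region_start + int(rng.integers(0, region_len - 300))
        frags.append(make_fragment(ref, start, insert=250, name=f"f{i}"))
    return frags


class TestGatherFragments:
    def test_downsampling_is_exact_and_reproducible(self, tiny_reference):
        rng = np.random.default_rng(0)
        frags = _rand_fragments(tiny_reference["chr1"], 250, rng, 1000, 2000)
        region = Window("chr1", 1000, 3300)
        kept1 = gather_fragments(frags, region, max_rows=100, seed=42)
        kept2 = gather_fragments(frags, region, max_rows=100, seed=42)
        assert len(kept1) == 100
        assert [f.name for f in kept1] == [f.name for f in kept2]
        starts = [f.ref_start for f in kept1]
        assert starts == sorted(starts)

    def test_no_downsampling_below_capacity(self, tiny_reference):
        rng = np.random.default_rng(1)
        frags = _rand_fragments(tiny_reference["chr1"], 80, rng, 1000, 2000)
        kept = gather_fragments(frags, Window("chr1", 1000, 3300), max_rows=100, seed=0)
        assert len(kept) == 80

    def test_empty_region(self, tiny_reference):
        assert gather_fragments([], Window("chr1", 0, 100), 10) == []


class TestRealign:
    def test_breakpoint_read_supports_alt(self, tiny_reference, del_sv):
        alt_hap = construct_haplotype(del_sv, 1, tiny_reference, 500)
        ref_hap = construct_haplotype(del_sv, 0, tiny_reference, 500)
        # read sampled verbatim from the alt haplotype across the junction
        junction = alt_hap.sequence[460:530]
        frag = Fragment(
            reads=[AlignedRead("j", junction, np.full(70, 30, np.uint8), 0, [(CIGAR_M, 70)])],
            insert_size=250,
        )
        ref_score, alt_scores = realign_fragment(frag, ref_hap, alt_hap)
        assert support_value(ref_score, alt_scores) > 0.5

    def test_flank_read_is_uninformative(self, tiny_reference, del_sv):
        alt_hap = construct_haplotype(del_sv, 1, tiny_reference, 500)
        ref_hap = construct_haplotype(del_sv, 0, tiny_reference, 500)
        frag = make_fragment(tiny_reference["chr1"], 14_550, name="flank")
        ref_score, alt_scores = realign_fragment(frag, ref_hap, alt_hap)
        assert support_value(ref_score, alt_scores) == pytest.approx(0.5, abs=1e-9)

    def test_scores_match_bruteforce_dp_oracle(self):
        """Glocal (read vs haplotype-infix) scores equal an exhaustive DP."""

        def infix_edit_distance(query, target):
            prev = [0] * (len(target) + 1)
            for i, qc in enumerate(query, 1):
                cur = [i] + [0] * len(target)
                for j, tc in enumerate(target, 1):
                    cur[j] = min(
                        prev[j] + 1,
                        cur[j - 1] + 1,
                        prev[j - 1] + (qc != tc),
                    )
                prev = cur
            return min(prev)

        from svembed.pileup import _glocal_score

        rng = np.random.default_rng(7)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for _ in range(20):
            target = rng.choice(bases, size=200).tobytes().decode()
            pos = int(rng.integers(0, 160))
            read = list(target[pos : pos + 40])
            for k in rng.integers(0, 40, size=3):  # plant mismatches
                read[int(k)] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
            assert _glocal_score(read, target) == -infix_edit_distance(read, target)


class TestEncodeBaseFeatures:
    def test_perfect_proper_forward_read(self, tiny_reference, stats):
        ref = tiny_reference["chr1"]
        frag = Fragment(
            reads=[make_read(ref, 1000, 70, is_reverse=False, is_proper=True)],
            insert_size=250,
        )
        window = Window("chr1", 900, 1200)
        arr = encode_base_features(frag, window, stats, ref[900:1200])
        covered = slice(100, 170)
        assert np.all(arr[covered, CH_BASE] == 1.0)
        assert np.all(arr[covered, CH_STRAND] == 1.0)
        assert np.all(arr[covered, CH_PAIR] == 1.0)
        assert np.all(arr[covered, CH_HAPLOTYPE] == pytest.approx(0.33))
        assert np.all(arr[covered, CH_BASEQ] == pytest.approx(30 / 60))
        assert np.all(arr[:100] == 0.0) and np.all(arr[170:] == 0.0)

    def test_median_insert_maps_to_half(self, tiny_reference, stats):
        """Empirical-CDF oracle: an insert at the distribution median -> 0.5."""
        ref = tiny_reference["chr1"]
        frag = make_fragment(ref, 1000, insert=int(stats.insert_mean))
        window = Window("chr1", 900, 1400)
        arr = encode_base_features(frag, window, stats, ref[900:1400])
        covered = arr[:, CH_BASE] > 0
        assert np.allclose(arr[covered, CH_INSERT], 0.5, atol=0.02)

    def test_mismatch_and_softclip_values(self, tiny_reference, stats):
        ref = tiny_reference["chr1"]
        seq = list(ref[1000:1070])
        seq[10] = "A" if seq[10] != "A" else "C"
        read = AlignedRead(
            "sc", "".join(seq), np.full(70, 30, np.uint8), 1005,
            [(CIGAR_S, 5), (CIGAR_M, 65)],
        )
        frag = Fragment(reads=[read], insert_size=0)
        window = Window("chr1", 950, 1150)
        arr = encode_base_features(frag, window, stats, ref[950:1150])
        assert np.all(arr[50:55, CH_BASE] == pytest.approx(0.3))  # clipped
        assert np.all(arr[50:55, CH_CLIP] == 1.0)
        assert arr[60, CH_BASE] == pytest.approx(0.6)  # planted mismatch
        assert arr[61, CH_BASE] == 1.0


class TestRenderImage:
    def test_zero_fragments_all_zero(self, tiny_reference, stats):
        window = Window("chr1", 1000, 1300)
        cfg = ImageConfig(height=20, width=300)
        img = render_image([], window, cfg, stats, tiny_reference["chr1"][1000:1300])
        assert img.data.shape == (20, 300, 9)
        assert np.all(img.data == 0.0)

    def test_single_read_pixel_count(self, tiny_reference, stats):
        ref = tiny_reference["chr1"]
        frag = Fragment(reads=[make_read(ref, 1050, 148)], insert_size=0)
        window = Window("chr1", 1000, 1300)  # width == config width: no compression
        cfg = ImageConfig(height=20, width=300)
        img = render_image([frag], window, cfg, stats, ref[1000:1300])
        assert np.count_nonzero(img.data[0, :, CH_BASE]) == 148
        assert np.all(img.data[1:] == 0.0)

    def test_rendering_is_deterministic(self, tiny_reference, stats):
        rng = np.random.default_rng(3)
        ref = tiny_reference["chr1"]
        frags = _rand_fragments(ref, 30, rng, 1000, 1500)
        window = Window("chr1", 1000, 2800)
        cfg = ImageConfig(height=40, width=120)
        a = render_image(frags, window, cfg, stats, ref[1000:2800])
        b = render_image(frags, window, cfg, stats, ref[1000:2800])
        assert np.array_equal(a.data, b.data)

    def test_invariants_over_random_windows(self, tiny_reference, stats):
        """Shape, range and masking invariants on random pileups."""
        rng = np.random.default_rng(11)
        ref = tiny_reference["chr1"]
        cfg = ImageConfig(height=24, width=80)
        for _ in range(20):
            start = int(rng.integers(0, 25_000))
            n = int(rng.integers(0, 60))
            frags = _rand_fragments(ref, n, rng, start, 1200)
            window = Window("chr1", start, start + int(rng.integers(400, 2000)))
            img = render_image(
                frags, window, cfg, stats, ref[window.start : window.end]
            )
            assert img.data.shape == (24, 80, 9)
            assert img.data.min() >= 0.0 and img.data.max() <= 1.0
            mask = img.data[:, :, CH_BASE] == 0.0
            assert np.all(img.data[mask] == 0.0)  # black pixel => all channels zero

    def test_zero_width_window_is_error(self, tiny_reference, stats):
        with pytest.raises(ValueError):
            render_image([], Window("chr1", 100, 100), ImageConfig(20, 50), stats, "")


class TestCompressWidth:
    def test_identity_at_target_width(self):
        rng = np.random.default_rng(0)
        img = rng.random((5, 64, 9)).astype(np.float32)
        assert np.array_equal(compress_width(img, 64), img)

    def test_constant_channel_preserved(self):
        img = np.full((3, 600, 9), 0.7, dtype=np.float32)
        out = compress_width(img, 300)
        assert np.allclose(out, 0.7, atol=1e-6)

    def test_two_to_one_matches_bruteforce_average(self):
        rng = np.random.default_rng(5)
        img = rng.random((4, 600, 9)).astype(np.float32)
        out = compress_width(img, 300)
        oracle = np.zeros((4, 300, 9))
        for j in range(300):  # each output pixel = mean of 2 input pixels
            oracle[:, j] = img[:, 2 * j : 2 * j + 2].mean(axis=1)
        assert np.allclose(out, oracle, atol=1e-6)

    def test_mean_conserved_for_divisible_widths(self):
        rng = np.random.default_rng(6)
        for w, t in [(160, 80), (240, 80), (400, 80)]:
            img = rng.random((3, w, 9)).astype(np.float32)
            out = compress_width(img, t)
            assert np.allclose(img.mean(axis=1), out.mean(axis=1), atol=1e-6)

    def test_narrow_image_left_anchored_zero_padded(self):
        img = np.ones((2, 50, 9), dtype=np.float32)
        out = compress_width(img, 80)
        assert np.all(out[:, :50] == 1.0) and np.all(out[:, 50:] == 0.0)

    def test_fractional_bin_edges_conserve_mass(self):
        rng = np.random.default_rng(9)
        img = rng.random((2, 97, 9)).astype(np.float32)  # not divisible by 40
        out = compress_width(img, 40)
        assert np.allclose(img.sum(axis=1) / 97, out.sum(axis=1) / 40, atol=1e-5)


class TestImageConfig:
    def test_channel_count_is_fixed(self):
        with pytest.raises(ValueError):
            ImageConfig(channels=5)

    def test_tensor_shape_validation(self):
        with pytest.raises(ValueError):
            ImageTensor(np.zeros((10, 10, 5)), Window("chr1", 0, 10))
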