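"""Synthetic frame/case generator: score bins, masks, determinism, tertiles."""

import numpy as np
import pytest

from capclean import CaseSpec, FrameSpec, generate_case, generate_frame, visible_fraction_to_score
from capclean.synth import tertile_sizes


class TestVisibleFractionToScore:
    @pytest.mark.parametrize(
        "fraction,score",
        [
            (0.95, 5),  # >90% visible
            (0.90, 5),
            (0.10, 1),  # <25% visible
            (0.0, 1),
            (0.25, 2),  # half-open boundary
            (0.4999, 2),
            (0.50, 3),
            (0.75, 4),
            (0.8999, 4),
            (1.0, 5),
        ],
    )
    def test_bin_mapping(self, fraction, score):
        assert visible_fraction_to_score(fraction) == score

    def test_rejects_out_of_range(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError):
                visible_fraction_to_score(bad)

    def test_step_function_covers_unit_interval(self):
        """Exactly 5 plateaus, no gaps, monotone nondecreasing on a fine grid."""
        grid = np.arange(0, 1.0005, 0.001)
        scores = np.array([visible_fraction_to_score(f) for f in grid])
        assert set(scores) == {1, 2, 3, 4, 5}
        assert (np.diff(scores) >= 0).all()
        # each plateau is a single contiguous run
        assert (np.diff(scores) > 0).sum() == 4


class TestGenerateFrame:
    def test_fully_visible_clean_frame(self):
        f = generate_frame(FrameSpec(visible_fraction=1.0, category="clean"))
        assert f.mask.all()
        assert f.true_visible_fraction == 1.0
        assert f.true_score == 5

    def test_fully_obscured_debris_frame(self):
        f = generate_frame(FrameSpec(visible_fraction=0.0, category="debris"))
        assert not f.mask.any()
        assert f.true_score == 1

    def test_achieved_fraction_and_seed_reproducibility(self):
        spec = FrameSpec(visible_fraction=0.60, category="bubble", seed=7)
        f1, f2 = generate_frame(spec), generate_frame(spec)
        assert 0.58 <= f1.true_visible_fraction <= 0.62
        assert np.array_equal(f1.pixels, f2.pixels)
        assert np.array_equal(f1.mask, f2.mask)

    def test_mask_mean_is_true_visible_fraction(self, small_frame_set):
        for f in small_frame_set:
            assert f.true_visible_fraction == f.mask.mean()
            assert f.true_score == visible_fraction_to_score(f.true_visible_fraction)
            assert f.pixels.shape[:2] == f.mask.shape

    @pytest.mark.parametrize("category", ["bubble", "bile", "debris"])
    def test_achieved_fraction_within_tolerance(self, category):
        """Requested vs achieved visible fraction agree to +/-0.02 over random specs."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            vf = float(rng.uniform(0, 1))
            f = generate_frame(
                FrameSpec(visible_fraction=vf, category=category, seed=int(rng.integers(2**31)))
            )
            assert abs(f.true_visible_fraction - vf) <= 0.02

    def test_rejects_small_image(self):
        with pytest.raises(ValueError, match="image_size"):
            FrameSpec(image_size=8)

    def test_clean_requires_high_visibility(self):
        with pytest.raises(ValueError, match="clean"):
            FrameSpec(visible_fraction=0.5, category="clean")

    def test_rejects_unknown_category(self):
        with pytest.raises(ValueError, match="category"):
            FrameSpec(category="fog")


class TestGenerateCase:
    @pytest.mark.parametrize("n,sizes", [(9, (3, 3, 3)), (10, (4, 3, 3)), (31, (11, 10, 10))])
    def test_tertile_remainder_allocation(self, n, sizes):
        assert tertile_sizes(n) == sizes

    def test_invisible_counts_match_nearest_achievable(self):
        spec = CaseSpec(n_frames=31, tertile_invisibility=(0.3, 0.0, 1.0), seed=5)
        case = generate_case(spec, render=False)
        sizes = tertile_sizes(31)
        t = np.asarray(case.tertile_of)
        vf = case.visible_fractions
        for tert, (size, rate) in enumerate(zip(sizes, spec.tertile_invisibility), start=1):
            n_inv = int((vf[t == tert] < 0.5).sum())
            assert n_inv == round(rate * size)

    def test_timestamps_strictly_increasing(self, dirty_case):
        ts = [f.timestamp_s for f in dirty_case.frames]
        assert all(b > a for a, b in zip(ts, ts[1:]))

    def test_case_determinism(self):
        spec = CaseSpec(n_frames=12, tertile_invisibility=(0.2, 0.2, 0.5), seed=77)
        c1 = generate_case(spec, render=True)
        c2 = generate_case(spec, render=True)
        for f1, f2 in zip(c1.frames, c2.frames):
            assert np.array_equal(f1.pixels, f2.pixels)
            assert f1.timestamp_s == f2.timestamp_s

    def test_rendered_and_unrendered_share_ground_truth(self):
        spec = CaseSpec(n_frames=9, tertile_invisibility=(0.4, 0.0, 0.4), seed=3)
        full = generate_case(spec, render=True)
        lazy = generate_case(spec, render=False)
        assert [f.true_score for f in full.frames] == [f.true_score for f in lazy.frames]
        # rendered masks quantize to the same pixel count
        for f1, f2 in zip(full.frames, lazy.frames):
            assert f1.mask.sum() == f2.mask.sum()

    def test_rejects_undersized_case(self):
        with pytest.raises(ValueError):
            CaseSpec(n_frames=2)
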