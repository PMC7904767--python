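import numpy as np
import pytest

from capclean import CaseSpec, FrameSpec, generate_case, generate_frame


@pytest.fixture(scope="session")
def small_frame_set():
    """60 rendered frames spanning all five score classes, with ground truth."""
    frames = []
    seeds = np.random.SeedSequence(42).generate_state(60, dtype=np.uint32)
    i = 0
    for lo, hi in [(0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 0.9), (0.9, 1.0)]:
        for j in range(12):
            vf = lo + (hi - lo) * (j + 0.5) / 12
            cat = "clean" if vf >= 0.9 else ("bubble", "bile", "debris")[j % 3]
            frames.append(
                generate_frame(
                    FrameSpec(visible_fraction=vf, category=cat, seed=int(seeds[i]))
                )
            )
            i += 1
    return frames


@pytest.fixture
def clean_case():
    return generate_case(
        CaseSpec(n_frames=30, tertile_invisibility=(0.0, 0.0, 0.0), seed=11),
        case_id="clean",
        render=False,
    )


@pytest.fixture
def dirty_case():
    return generate_case(
        CaseSpec(n_frames=30, tertile_invisibility=(0.3, 0.3, 0.3), seed=12),
        case_id="dirty",
        render=False,
    )
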