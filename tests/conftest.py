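import numpy as np
import pytest

import mircascade as mc


@pytest.fixture()
def days7() -> np.ndarray:
    """The default sampled differentiation days."""
    return np.array([0.0, 2.0, 4.0, 6.0, 8.0, 15.0, 30.0])


@pytest.fixture()
def toy_ds() -> mc.ExpressionDataset:
    """3 transcripts x 6 samples (3 days x 2 replicates), hand-built."""
    samples = [
        mc.SampleMeta(f"s{d}{r}", day=float(d), replicate=r)
        for d in (0, 7, 14)
        for r in (1, 2)
    ]
    values = np.array(
        [
            [1.0, 3.0, 4.0, 4.0, 6.0, 6.0],  # rising
            [6.0, 6.0, 4.0, 4.0, 1.0, 3.0],  # falling
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],  # flat
        ]
    )
    return mc.ExpressionDataset("gene", ["up1", "down1", "flat1"], values, samples)


@pytest.fixture()
def scheme030() -> mc.SegmentScheme:
    """Three-phase segment scheme matching the 0-30 day design."""
    return mc.SegmentScheme((("early", 0, 4), ("mid", 6, 8), ("late", 15, 30)))


@pytest.fixture(scope="session")
def canonical_bundle() -> "mc.simulate.SynthBundle":
    """The canonical planted fixture (10 pairs, 500+200 background, 500 decoys)."""
    return mc.generate(mc.canonical_config(seed=42))


@pytest.fixture(scope="session")
def canonical_result(canonical_bundle):
    """Full cascade run on the canonical fixture (shared across tests)."""
    scheme = mc.SegmentScheme((("early", 0, 4), ("mid", 6, 8), ("late", 15, 30)))
    return mc.run_cascade(
        canonical_bundle.genes,
        canonical_bundle.mirnas,
        canonical_bundle.interactions,
        mc.PipelineParams(segments=scheme),
    )


def make_profile(tid, days, values) -> mc.TimeProfile:
    return mc.TimeProfile(tid, np.asarray(days, float), np.asarray(values, float))
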