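import numpy as np
import pytest

from tcrdiff.pipeline import (
    build_predictor_pairs,
    demo_corpus,
    train_demo_generator,
)


@pytest.fixture(scope="session")
def corpus():
    """Two-class mutation-free synthetic corpus with a 300-TCR healthy pool."""
    by_class, epitopes, healthy, spec = demo_corpus(seed=7, healthy_n=300)
    return {"by_class": by_class, "epitopes": epitopes, "healthy": healthy, "spec": spec}


@pytest.fixture(scope="session")
def trained_generator(corpus):
    """Small denoiser trained on the first synthetic class (a few CPU-minutes)."""
    net, schedule, trace = train_demo_generator(corpus["by_class"][0], seed=1)
    return {"net": net, "schedule": schedule, "trace": trace}


@pytest.fixture(scope="session")
def predictor_pairs(corpus):
    """Balanced separable binder/non-binder fixture (200 pairs)."""
    return build_predictor_pairs(
        corpus["by_class"], corpus["epitopes"], corpus["healthy"], seed=3
    )


@pytest.fixture(scope="session")
def reconstructions(corpus, trained_generator):
    """Class-A reconstruction-style samples from the session model."""
    from tcrdiff.diffusion import reconstruct_sequences

    seqs, mats = reconstruct_sequences(
        trained_generator["net"],
        trained_generator["schedule"],
        corpus["by_class"][0],
        corpus["epitopes"][0],
        seed=5,
    )
    return {"seqs": seqs, "mats": mats}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
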