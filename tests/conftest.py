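import random

import pytest

from mitodraw import Style, make_canonical_mitogenome
from mitodraw.model import Feature, FeatureClass, GenomeAnnotation, Strand, Topology


@pytest.fixture(scope="session")
def canonical():
    return make_canonical_mitogenome()


@pytest.fixture()
def style():
    return Style()


@pytest.fixture()
def small_style():
    # compact canvas keeps render-based tests fast
    return Style(
        canvas_size=(300.0, 300.0),
        ring_thickness=12.0,
        ring_gap=8.0,
        font_size=6.0,
        char_advance=4.0,
        margin=10.0,
    )


def make_toy_annotation(seed, genome_length=None, n_features=None, allow_wrap=True):
    """Small random annotation on a 1-2 kb toy genome, independent of the
    package's own generator (used by the base-painting oracle)."""
    rng = random.Random(seed)
    L = genome_length or rng.randint(1000, 2000)
    n = n_features or rng.randint(3, 10)
    features = []
    for i in range(n):
        length = rng.randint(1, max(1, L // 4))
        start = rng.randint(0, L - 1)
        if not allow_wrap and start + length > L:
            start = L - length
        features.append(
            Feature(
                name=f"f{i}",
                feature_class=rng.choice(list(FeatureClass)),
                start=start,
                length=length,
                strand=rng.choice([Strand.forward, Strand.reverse]),
            )
        )
    return GenomeAnnotation(
        genome_length=L, topology=Topology.circular, features=tuple(features)
    )


def paint_genome(annotation):
    """Base-painting oracle: per-base sets of feature names (wrap-aware)."""
    L = annotation.genome_length
    painted = [set() for _ in range(L)]
    for f in annotation.features:
        for pos in f.covered_positions(L):
            painted[pos].add(f.name)
    return painted
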