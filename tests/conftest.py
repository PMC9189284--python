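import numpy as np
import pytest

from scmarkers import LabelledMatrix, SyntheticConfig, generate


@pytest.fixture
def small_matrix() -> LabelledMatrix:
    """A tiny 3-class matrix with one clean marker per class."""
    cfg = SyntheticConfig(
        n_classes=3, class_sizes=(8, 10, 6), n_genes=12, markers_per_class=1,
        effect_size=4.0, dropout_rate=0.0, seed=7,
    )
    data, _ = generate(cfg)
    return data


@pytest.fixture
def separable_matrix() -> LabelledMatrix:
    """Two classes separated perfectly by the first feature (values 0 vs 1)."""
    rng = np.random.default_rng(3)
    n = 20
    values = np.column_stack([
        np.repeat([0.0, 1.0], n // 2),
        rng.random(n),
        rng.random(n),
    ])
    return LabelledMatrix(
        values,
        [f"c{i}" for i in range(n)],
        ["sep", "noise1", "noise2"],
        ["a"] * (n // 2) + ["b"] * (n // 2),
    )
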