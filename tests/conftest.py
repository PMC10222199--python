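import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import funcmotif as fm
from funcmotif.discretize import ClassDescriptor, ClassEncoding

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_encoding(Z: np.ndarray, prefix: str = "c") -> ClassEncoding:
    """Wrap a binary matrix as an encoding of single-class families."""
    Z = np.asarray(Z, dtype=np.int8)
    n, m = Z.shape
    classes = [
        ClassDescriptor(
            family_id=f"{prefix}{j}",
            class_index=1,
            n_classes=1,
            lower=0.0,
            upper=1.0,
            frequency=float(Z[:, j].mean()),
        )
        for j in range(m)
    ]
    return ClassEncoding(
        sample_ids=[f"s{i}" for i in range(n)], classes=classes, indicators=Z
    )


def random_instance(rng, n=30, m=8, p_lo=0.2, p_hi=0.8):
    """A random binary encoding plus Gaussian property, for search audits."""
    Z = (rng.random((n, m)) < rng.uniform(p_lo, p_hi, m)).astype(np.int8)
    y = rng.normal(size=n)
    return make_encoding(Z), y


@pytest.fixture
def small_table() -> fm.AbundanceTable:
    return fm.AbundanceTable(
        sample_ids=["s1", "s2", "s3", "s4", "s5", "s6"],
        family_ids=["famA", "famB", "famC"],
        counts=np.array(
            [
                [0, 5, 2],
                [5, 0, 3],
                [1, 2, 0],
                [3, 1, 4],
                [0, 9, 1],
                [2, 0, 6],
            ]
        ),
        community_label="test",
    )
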