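import numpy as np
import pytest

from senscreen import chemlib
from senscreen.fixtures import LibrarySpec, gen_compound_library


def record(id, smiles, label="unknown", source=""):
    rec = chemlib.make_record(id, smiles, label=label, source=source)
    assert rec is not None, f"fixture SMILES {smiles!r} must parse"
    return rec


@pytest.fixture(scope="session")
def small_library():
    """120 labeled structures from the synthetic generator (noise-free)."""
    records, truth = gen_compound_library(
        LibrarySpec(n_actives=60, n_inactives=60, label_noise=0.0, seed=11)
    )
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def prototype_fingerprints(rng, n=80, bits=48, k=4, flip=0.08):
    """Fingerprint-like binary data: k prototypes with independent bit flips."""
    protos = rng.integers(0, 2, size=(k, bits)).astype(float)
    rows = []
    for i in range(n):
        p = protos[i % k].copy()
        mask = rng.random(bits) < flip
        p[mask] = 1 - p[mask]
        rows.append(p)
    return np.array(rows)
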