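import numpy as np
import pytest

from nanpqsar import (
    IFNB,
    IL6,
    NANPDataset,
    NANPRecord,
    NucleicType,
    Shape,
    Strand,
    build_vocabulary,
    generate_library,
    log10_transform_targets,
)
from nanpqsar.simulate import GeneratorParams


def make_record(nanp_id="N1", shape=Shape.OTHER, seqs=("ACGUACGUAC", "ACGTACGTAC"),
                endpoints=None):
    strands = []
    for i, seq in enumerate(seqs):
        ntype = NucleicType.RNA if "U" in seq else NucleicType.DNA
        strands.append(Strand(f"{nanp_id}_s{i+1}", seq, ntype))
    return NANPRecord(nanp_id, shape, tuple(strands), endpoints)


@pytest.fixture
def toy_record():
    return make_record(endpoints={IFNB: 100.0, IL6: 1000.0})


@pytest.fixture
def triangle_record():
    rng = np.random.default_rng(7)
    seqs = ["".join(rng.choice(list("ACGU"), size=12)) for _ in range(4)]
    return make_record("T1", Shape.TRIANGLE, seqs, {IFNB: 500.0, IL6: 900.0})


@pytest.fixture
def toy_dataset(toy_record):
    other = make_record("N2", Shape.OTHER, ("GGGGCCCCGG", "TTTTAAAATT"),
                        {IFNB: 10.0, IL6: 20.0})
    return NANPDataset([toy_record, other])


@pytest.fixture(scope="session")
def small_library():
    """A 36-record library, log10-transformed: shared by model tests."""
    params = GeneratorParams(
        n_per_shape={Shape.TRIANGLE: 6, Shape.SQUARE: 8, Shape.PENTAGON: 10,
                     Shape.CUBE: 12},
        seed=42,
    )
    return log10_transform_targets(generate_library(params))


@pytest.fixture(scope="session")
def small_vocab(small_library):
    return build_vocabulary(small_library)
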