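import numpy as np
import pandas as pd
import pytest

from sigconn.io import CountMatrix, QuerySignature, ReferenceDatabase


@pytest.fixture
def small_counts():
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 5, 100],
            "s2": [12, 1, 6, 90],
            "s3": [40, 2, 20, 400],
            "s4": [35, 3, 22, 380],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    meta = pd.DataFrame(
        {
            "perturbagen": ["none", "none", "venomA", "venomA"],
            "time_point": ["24h"] * 4,
            "replicate": [0, 1, 0, 1],
            "is_control": [True, True, False, False],
            "control_kind": ["water", "water", "na", "na"],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return CountMatrix(counts=counts, sample_meta=meta)


@pytest.fixture
def tiny_db():
    rng = np.random.default_rng(0)
    genes = [f"g{i:02d}" for i in range(20)]
    refs = ["r1", "r2", "r3", "r4"]
    zscores = pd.DataFrame(rng.normal(size=(20, 4)), index=genes, columns=refs)
    meta = pd.DataFrame(
        {
            "cell_line": ["A", "A", "B", "B"],
            "perturbagen_type": ["trt_cp"] * 4,
            "perturbagen_id": ["d1", "d2", "d3", "d4"],
        },
        index=refs,
    )
    pcls = {"P1": ["r1", "r2"], "P2": ["r3", "r4"]}
    return ReferenceDatabase(zscores=zscores, meta=meta, pcls=pcls)


@pytest.fixture
def simple_signature():
    return QuerySignature("q1", up=["g00", "g01"], down=["g18", "g19"])
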