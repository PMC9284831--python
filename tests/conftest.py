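import numpy as np
import pandas as pd
import pytest

from chemnet import fixtures as fx
from chemnet.encoding import encode_dataset

ASPIRIN = "CC(=O)Oc1ccccc1C(=O)O"


@pytest.fixture(scope="session")
def default_fixture():
    """Planted 4-cluster network (30 chemicals each) plus motif library."""
    return fx.make_default_fixture(seed=11)


@pytest.fixture(scope="session")
def labeled_frame(default_fixture):
    spec, graph, truth, library = default_fixture
    rows = [
        {"id": cid, "smiles": library[cid], "cluster": truth.chemical_cluster[cid]}
        for cid in sorted(library)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def fingerprint_dataset(labeled_frame):
    return encode_dataset(
        list(labeled_frame["id"]),
        list(labeled_frame["smiles"]),
        list(labeled_frame["cluster"]),
        "fingerprint",
    )


@pytest.fixture(scope="session")
def token_dataset(labeled_frame):
    return encode_dataset(
        list(labeled_frame["id"]),
        list(labeled_frame["smiles"]),
        list(labeled_frame["cluster"]),
        "atomwise",
    )


@pytest.fixture(scope="session")
def memorization_fixture():
    """40-sample, 2-class linearly separable SMILES set: alkane chains vs
    substituted benzenes."""
    rows = []
    for i in range(20):
        rows.append({"id": f"a{i}", "smiles": "C" * (i + 2) + "O", "cluster": "chain"})
    ring_subs = ["F", "Cl", "N", "O", "C", "CC", "CCC", "OC", "CO", "CN"]
    for i in range(20):
        sub = ring_subs[i % len(ring_subs)]
        extra = "C" * (i // len(ring_subs))
        rows.append(
            {"id": f"b{i}", "smiles": f"{sub}{extra}c1ccccc1", "cluster": "ring"}
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def random_smiles_pool(default_fixture):
    """>=1000 valid SMILES strings: enumerated variants of the fixture
    library molecules."""
    from chemnet.augmentation import enumerate_smiles

    _, _, _, library = default_fixture
    pool = []
    for i, smiles in enumerate(sorted(set(library.values()))):
        pool.extend(enumerate_smiles(smiles, max_variants=40, seed=i))
        if len(pool) >= 1200:
            break
    assert len(pool) >= 1000
    return pool[:1200]
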