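import numpy as np
import pytest

import drugrepo as dr


@pytest.fixture(scope="session")
def planted_dti():
    """Default planted low-rank interaction matrix (seeded)."""
    return dr.make_planted_dti(seed=11)


@pytest.fixture(scope="session")
def small_scenario():
    """One planted end-to-end scenario (seeded)."""
    return dr.make_pipeline_scenario(seed=7)


@pytest.fixture()
def edge_file(tmp_path):
    """6-row edge list: 4 drugs x 3 targets, 6 observed pairs."""
    p = tmp_path / "edges.tsv"
    rows = [
        ("d1", "t1"), ("d2", "t1"), ("d1", "t2"),
        ("d3", "t3"), ("d4", "t2"), ("d2", "t3"),
    ]
    p.write_text("".join(f"{d}\t{t}\n" for d, t in rows))
    return p


def rand_descriptor(drug_id, rng, length=128, density=0.3):
    return dr.MoleculeDescriptor(
        drug_id=drug_id,
        fp_structural=rng.random(length) < density,
        fp_feature=rng.random(length) < density,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
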