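import dataclasses

import numpy as np
import pytest

from tnmpls.atlas import RegionRecord, RegionTable, assign_tnm_membership, build_edge_mask
from tnmpls.simulate import default_paper_like_spec, generate_cohort


def make_table(class_counts):
    """RegionTable with the given number of SN/FPN/DMN/excluded regions."""
    nets = {
        "SN": ["SalVentAttnA", "SalVentAttnB"],
        "FPN": ["ContA", "ContB", "ContC"],
        "DMN": ["DefaultA", "DefaultB", "DefaultC"],
        "EXCLUDED": ["VisCent", "SomMotA"],
    }
    records = []
    rid = 0
    for cls, count in class_counts.items():
        for i in range(count):
            net = nets[cls][i % len(nets[cls])]
            hemi = "LH" if rid % 2 == 0 else "RH"
            records.append(
                RegionRecord(rid, f"17Networks_{hemi}_{net}_T_{i}", net, hemi)
            )
            rid += 1
    return assign_tnm_membership(RegionTable(records))


@pytest.fixture(scope="session")
def toy_table():
    """Six regions: 2 SN, 2 FPN, 2 DMN (ids 0-5 in that order)."""
    return make_table({"SN": 2, "FPN": 2, "DMN": 2})


@pytest.fixture(scope="session")
def toy_mask(toy_table):
    return build_edge_mask(toy_table)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced synthetic cohort: 24 regions, n = 20, planted defaults."""
    spec = default_paper_like_spec()
    return dataclasses.replace(spec, n=20, n_sn=8, n_fpn=8, n_dmn=8)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
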