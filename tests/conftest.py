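import numpy as np
import pandas as pd
import pytest

from organoidscreen import (
    HitSpec,
    ScreenDataset,
    SimulationConfig,
    generate_primary_screen,
)


def make_toy_frame():
    """Two wells x three assays on one 2x3 plate."""
    rows = []
    for r, c, role, tid, tgt, dose in [
        (1, 1, "COMPOUND", "C0001", "T001", 10.0),
        (1, 2, "VEHICLE_A", "", "", np.nan),
    ]:
        for assay, val in [("ATP", 100000.0), ("LYZ.NS", 9000.0), ("LYZ.S", 12000.0)]:
            rows.append(
                {
                    "screen_id": "toy",
                    "donor": "m1",
                    "plate": "P1",
                    "well_row": r,
                    "well_col": c,
                    "role": role,
                    "treatment_id": tid,
                    "target_annotation": tgt,
                    "dose_uM": dose,
                    "assay": assay,
                    "raw_value": val + 10 * r + c,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_dataset():
    return ScreenDataset(make_toy_frame(), geometry=(2, 3))


@pytest.fixture(scope="session")
def small_screen():
    """A reduced primary screen with spiked truth, shared across tests.

    120 compounds x 4 doses on 2 plates per donor, 3 donors; compounds
    C0001-C0010 are abundance hits (true SSMD 3 in both LYZ assays),
    C0011-C0015 secretion-only, C0016-C0018 toxic at high dose.
    """
    config = SimulationConfig(
        seed=20240917,
        donors=3,
        plates_per_donor=2,
        n_compounds=120,
        n_targets=60,
        hit_spec=[HitSpec(f"C{i:04d}", "LYZ.BOTH", 3.0) for i in range(1, 11)]
        + [HitSpec(f"C{i:04d}", "LYZ.S", 3.0) for i in range(11, 16)],
    )
    dataset, truth = generate_primary_screen(config)
    return config, dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
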