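import numpy as np
import pandas as pd
import pytest

from metakin.synthetic import gen_feature_dataset


@pytest.fixture(scope="session")
def small_feature_dataset():
    """Compact planted-modulator dataset shared by the ML tests."""
    tables, log10_tau, truth = gen_feature_dataset(
        n_ligands=8, n_pairs=10, frames_per_ligand=300, seed=11
    )
    return tables, log10_tau, truth


@pytest.fixture()
def tiny_energy_table():
    """Hand-sized energy table for oracle comparisons (2 ligands, 2 pairs)."""
    rows = []
    for lid, e_off in (("A", 0.0), ("B", 1.0)):
        for j in range(6):
            for res, sub, e in (("D147", "R1", -5.0 + e_off), ("H297", "R4", -1.0)):
                rows.append(
                    {
                        "ligand_id": lid,
                        "trajectory_id": "t0",
                        "frame_time": 10.0 * (j + 1),
                        "residue_id": res,
                        "substituent": sub,
                        "energy": e + 0.1 * j,
                        "frame_bias": 0.5 * j,
                        "z": 5.0 + j,
                    }
                )
    return pd.DataFrame(rows)
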