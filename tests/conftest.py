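import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import germase as g

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trio():
    """Small simulated trio with truth phase."""
    cfg = g.TrioSimConfig(n_snps=1000, seed=7)
    fetal, maternal, truth = g.simulate_trio(cfg)
    return cfg, fetal, maternal, truth


@pytest.fixture(scope="session")
def germ_annotation():
    """Gene annotation: 22 autosomes x 3 genes, 4 proper X genes, 2 escapees,
    plus two imprinted clusters."""
    rows = []
    for c in range(1, 23):
        for j in range(3):
            rows.append((f"a{c}_{j}", str(c), False, None, None, None))
    for j in range(4):
        rows.append((f"x{j}", "X", False, None, None, None))
    rows.append(("esc0", "X", True, None, None, None))
    rows.append(("esc1", "X", True, None, None, None))
    rows.append(("imp_m", "19", False, "PEG3/ZIM", "paternal", "confirmed"))
    rows.append(("imp_k", "11", False, "KCNQ1/KCNQ1OT1", "paternal", "confirmed"))
    rows.append(("imp_h", "11", False, "H19/IGF2", "maternal", "confirmed"))
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "chromosome", "escapee", "imprint_cluster",
            "expected_allele", "status",
        ],
    )


def make_profiles(n_xaxa, n_xixa, depth=4000.0, dropout=0.1, seed=0,
                  stage="PGC", x_bias=0.98):
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_xaxa + n_xixa):
        state = "XaXa" if i < n_xaxa else "XiXa"
        profiles.append(
            g.CellSimProfile(
                cell_id=f"c{i}",
                stage_truth=stage,
                x_state_truth=state,
                active_x_parent_truth=(
                    "maternal" if rng.random() < 0.5 else "paternal"
                ),
                depth=depth,
                dropout_rate=dropout,
                x_bias=x_bias,
            )
        )
    return profiles


@pytest.fixture(scope="session")
def germ_sim(germ_annotation):
    """Mixed XaXa/XiXa germ-cell population with truth labels."""
    profiles = make_profiles(100, 60, seed=5)
    matrix, truth = g.simulate_allelic_counts(
        profiles, germ_annotation, seed=11
    )
    return matrix, truth, profiles
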