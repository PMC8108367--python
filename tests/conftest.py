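import numpy as np
import pandas as pd
import pytest

from spotdecon.simulate import SyntheticScenario, simulate_tissue, synthesize_reference


@pytest.fixture(scope="session")
def small_scenario():
    """A fast 3-type scenario used by pipeline-level tests."""
    return SyntheticScenario(
        n_types=3, n_genes=120, markers_per_type=10, n_cells_per_type=20,
        n_spots=16, cells_per_spot=5.0, marker_effect=10.0, depth=300,
        n_regions=3, seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_scenario):
    expr, labels, markers = synthesize_reference(small_scenario)
    return expr, labels, markers


@pytest.fixture(scope="session")
def small_tissue(small_scenario):
    return simulate_tissue(small_scenario)


@pytest.fixture
def planted_reference():
    """Tiny deterministic reference: 3 types x 30 genes, 5 planted markers each.

    Marker genes of a type are expressed (value 9) only in that type's cells
    and exactly zero elsewhere; background genes sit near 1 everywhere, so
    marker ranks are unambiguous.
    """
    rng = np.random.default_rng(5)
    genes = [f"g{i:02d}" for i in range(30)]
    labels = {}
    data = {}
    for k, t in enumerate(["A", "B", "C"]):
        for c in range(6):
            cid = f"{t}{c}"
            col = np.ones(30) + rng.uniform(0, 0.01, 30)  # jitter breaks exact ties
            col[:15] = 0.0  # marker block: off unless this is the owning type
            col[k * 5:(k + 1) * 5] = 9.0
            data[cid] = col
            labels[cid] = t
    expr = pd.DataFrame(data, index=genes)
    return expr, pd.Series(labels), {
        "A": genes[0:5], "B": genes[5:10], "C": genes[10:15]
    }
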