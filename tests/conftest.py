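import numpy as np
import pandas as pd
import pytest

import palaeosom as ps


@pytest.fixture(scope="session")
def study_scenario():
    """One study-scale synthetic scenario (4 cores, 100 slices, 97 taxa)."""
    profiles, layout, data = ps.default_scenario(seed=11)
    matrix, sample, geochem, truth = data
    return {"profiles": profiles, "layout": layout, "matrix": matrix,
            "sample": sample, "geochem": geochem, "truth": truth}


@pytest.fixture(scope="session")
def small_counts():
    """Tiny labelled count matrix: taxon t0 is a perfect indicator of group B."""
    rng = np.random.default_rng(7)
    idx = [f"W1-{20 + 2 * i}" for i in range(12)]
    counts = pd.DataFrame(rng.poisson(3.0, size=(12, 4)),
                          index=pd.Index(idx, name="sample_code"),
                          columns=["t0", "t1", "t2", "t3"])
    groups = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=idx)
    counts.loc[groups != "B", "t0"] = 0
    counts.loc[groups == "B", "t0"] = rng.integers(1, 6, size=4)
    counts["t1"] = 2  # constant everywhere
    return counts, groups
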