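import numpy as np
import pandas as pd
import pytest

import gutstress as gs


@pytest.fixture(scope="session")
def cohort():
    """One-site synthetic cohort with default planted truth (seed 7)."""
    design = gs.CohortDesign(seed=7, sites=("caecum",))
    truth = gs.default_truth(design)
    counts, meta = gs.generate_counts(design, truth)
    return design, truth, counts, meta


@pytest.fixture(scope="session")
def caecum(cohort):
    design, truth, counts, meta = cohort
    table = counts["caecum"]
    site_meta = meta[meta["site"] == "caecum"].reset_index(drop=True)
    return table, site_meta


@pytest.fixture()
def toy_counts():
    return pd.DataFrame(
        [[5, 0], [1, 2], [0, 7]],
        index=["s1", "s2", "s3"],
        columns=["gA", "gB"],
    )


@pytest.fixture()
def toy_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "animal_id": ["a1", "a2", "a3"],
            "treatment": ["stress", "control", "stress"],
            "litter": ["L1", "L1", "L2"],
            "pen": ["P1", "P2", "P1"],
            "site": ["caecum"] * 3,
        }
    )
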