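import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from raspdx import ExpressionMatrix, GeneSignature, VolumeSeries, load_cetuximab_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_table():
    """The bundled 25-model CRC-PDX cetuximab trial table."""
    return load_cetuximab_cohort()


@pytest.fixture
def tiny_matrix():
    """3 genes x 3 samples, easy to hand-compute."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 6.0, 8.0], [5.0, 5.0, 2.0]],
        index=["UPA", "UPB", "DNA"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(values, scale_tag="log2")


@pytest.fixture
def tiny_signature():
    return GeneSignature(name="TOY", up=("UPA", "UPB"), down=("DNA",))


def make_volumes(
    *,
    treated_changes,
    control_changes,
    model="M1",
    v0=100.0,
    days=(0, 14),
):
    """Build a two-arm volume table with the given per-animal volume changes."""
    rows = []
    for arm, changes in (("treated", treated_changes), ("control", control_changes)):
        for i, change in enumerate(changes):
            animal = f"{model}-{arm[0]}{i}"
            rows.append({"model": model, "animal": animal, "arm": arm, "day": days[0], "volume": v0})
            rows.append(
                {"model": model, "animal": animal, "arm": arm, "day": days[-1], "volume": v0 + change}
            )
    return VolumeSeries(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
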