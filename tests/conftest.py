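import numpy as np
import pandas as pd
import pytest

from omixnet.matrix import OmicsMatrix
from omixnet.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_group_a=20,
        n_group_b=12,
        p_metabolites=30,
        p_proteins=20,
        frac_differential=0.1,
        effect_size_log2=3.0,
        missing_rate=0.05,
        dilution_sigma=0.3,
        n_overfiltered_features=4,
        duplicate_protein_pairs=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def tiny_matrix():
    """3 features x 4 samples, no missing values, raw scale."""
    data = pd.DataFrame(
        [[2.0, 4.0, 8.0, 16.0], [1.0, 2.0, 4.0, 8.0], [3.0, 6.0, 12.0, 24.0]],
        index=["m1", "m2", "p1"],
        columns=["s1", "s2", "s3", "s4"],
    )
    omics = pd.Series(["metabolite", "metabolite", "protein"], index=data.index)
    return OmicsMatrix(data=data, omics=omics, scale_state="raw")


def make_imputed(values: np.ndarray, prefix: str = "f") -> OmicsMatrix:
    """Wrap a p x n array as an imputed-scale matrix with metabolite labels."""
    p, n = values.shape
    ids = [f"{prefix}{i:03d}" for i in range(p)]
    data = pd.DataFrame(values, index=ids, columns=[f"s{j:03d}" for j in range(n)])
    return OmicsMatrix(
        data=data, omics=pd.Series("metabolite", index=ids), scale_state="imputed"
    )
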