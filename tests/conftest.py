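import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crcmeth.screening import BetaMatrix

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_matrix() -> BetaMatrix:
    """Three-site matrix with hand-computable stage-1 outcomes.

    site A: strong tumor hypermethylation (delta 0.5, tumor mean 0.6)
    site B: negligible difference (delta 0.1)
    site C: big delta but tumor mean below the 0.2 floor
    """
    samples = [f"T{i}" for i in range(9)] + [f"N{i}" for i in range(9)] + ["B0", "B1", "B2"]
    groups = pd.Series(["tumor"] * 9 + ["normal"] * 9 + ["blood"] * 3, index=samples)
    tumor_a = [0.55, 0.60, 0.65, 0.58, 0.62, 0.59, 0.61, 0.57, 0.63]
    normal_a = [0.05, 0.10, 0.15, 0.08, 0.12, 0.09, 0.11, 0.07, 0.13]
    tumor_b = [0.32, 0.28, 0.30, 0.31, 0.29, 0.33, 0.27, 0.30, 0.30]
    normal_b = [0.22, 0.18, 0.20, 0.21, 0.19, 0.23, 0.17, 0.20, 0.20]
    tumor_c = [0.13, 0.17, 0.15, 0.14, 0.16, 0.15, 0.12, 0.18, 0.15]
    normal_c = [0.001, 0.002, 0.001, 0.003, 0.001, 0.002, 0.001, 0.002, 0.001]
    blood = {"A": [0.10, 0.10, 0.10], "B": [0.20, 0.20, 0.20], "C": [0.05, 0.05, 0.05]}
    values = pd.DataFrame(
        [tumor_a + normal_a + blood["A"], tumor_b + normal_b + blood["B"], tumor_c + normal_c + blood["C"]],
        index=["cgA", "cgB", "cgC"],
        columns=samples,
    )
    return BetaMatrix(values, groups)


def triplicate(sample_id: str, matrix: str, target: str, cts) -> pd.DataFrame:
    """Long-format plate rows for one (sample, target) triplicate;
    None entries become undetected wells."""
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "matrix": matrix,
            "target": target,
            "well": [1, 2, 3],
            "ct": [np.nan if c is None else float(c) for c in cts],
        }
    )


@pytest.fixture
def plate_rows():
    return triplicate
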