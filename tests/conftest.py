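import numpy as np
import pandas as pd
import pytest

from dcbnet.cohort_io import FeatureSpec
from dcbnet.synthetic import default_ground_truth, sample_cohort


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def cohort_5k(truth):
    return sample_cohort(truth, 5000, seed=42)


@pytest.fixture(scope="session")
def cohort_290(truth):
    return sample_cohort(truth, 290, seed=7)


@pytest.fixture()
def binary_spec():
    """A small all-binary feature spec for hand-built examples."""
    return FeatureSpec(
        features=(("x1", ("0", "1")), ("x2", ("0", "1"))),
        class_var="c",
        class_domain=("0", "1"),
    )


def random_discrete_frame(rng, n, cards):
    """Random categorical data frame with columns v0..vk, domains '0'..'c-1'."""
    data = {
        f"v{k}": rng.integers(0, card, size=n).astype(str)
        for k, card in enumerate(cards)
    }
    return pd.DataFrame(data)


def brute_force_cmi(df, xi, xj, cvar):
    """Independent triple-summation oracle for conditional mutual information."""
    n = len(df)
    total = 0.0
    for a in df[xi].unique():
        for b in df[xj].unique():
            for c in df[cvar].unique():
                p_abc = ((df[xi] == a) & (df[xj] == b) & (df[cvar] == c)).mean()
                if p_abc == 0:
                    continue
                p_c = (df[cvar] == c).mean()
                p_ac = ((df[xi] == a) & (df[cvar] == c)).mean()
                p_bc = ((df[xj] == b) & (df[cvar] == c)).mean()
                total += p_abc * np.log((p_abc / p_c) / ((p_ac / p_c) * (p_bc / p_c)))
    return total
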