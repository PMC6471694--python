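import numpy as np
import pandas as pd
import pytest

from ripchip.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def ago2_dataset():
    """A mid-sized AGO2-like study with the F6 signal planted."""
    return generate_dataset(SyntheticConfig(n_genes=1000, n_mirnas=40, seed=11))


@pytest.fixture(scope="session")
def gw182_dataset():
    """A GW182-like study where coding-region length drives the labels."""
    return generate_dataset(
        SyntheticConfig(n_genes=1000, n_mirnas=40, mode="gw182_like", seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def naive_site_scan(sequence: str, site: str) -> int:
    """Independent oracle: test the site at every start position."""
    return sum(
        sequence[i : i + len(site)] == site
        for i in range(len(sequence) - len(site) + 1)
    )


def brute_force_auc(scores, labels) -> float:
    """All-pairs concordance count with ties worth one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
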