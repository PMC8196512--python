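import numpy as np
import pytest

from canopyk import CanopyObservation, Dataset, paper_like_config, simulate_dataset


def make_noiseless_dataset(k_by_genotype=None, n=20, lai_low=0.3, lai_high=7.6):
    """Observations lying exactly on the mean curve (no noise)."""
    k_by_genotype = k_by_genotype or {"A": 0.5}
    obs = []
    lai = np.linspace(lai_low, lai_high, n)
    for g, k in k_by_genotype.items():
        for a in lai:
            obs.append(CanopyObservation(g, float(a), float(-np.expm1(-k * a))))
    return Dataset.from_observations(obs)


@pytest.fixture
def noiseless_dataset():
    return make_noiseless_dataset()


@pytest.fixture
def noiseless_two_genotypes():
    return make_noiseless_dataset({"A": 0.5, "B": 0.65})


@pytest.fixture(scope="session")
def paper_like_dataset():
    return simulate_dataset(paper_like_config(seed=11))


@pytest.fixture
def csv_file(tmp_path):
    def _write(text, name="data.csv"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write
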