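import warnings

import numpy as np
import pandas as pd
import pytest

import woundtraj as wt


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (64 samples / 21 wounds / 18 patients)."""
    return wt.generate_cohort(wt.CohortDesign(seed=1))


@pytest.fixture(scope="session")
def cohort_tpm(cohort):
    return wt.tpm(cohort.counts)


@pytest.fixture()
def small_counts():
    """3 genes x 2 samples with sample B = 2 x sample A."""
    values = pd.DataFrame([[10, 20], [20, 40], [30, 60]],
                          index=["g1", "g2", "g3"], columns=["a", "b"])
    lengths = pd.Series([1000.0, 2000.0, 1500.0], index=values.index)
    return wt.CountsMatrix(values=values, gene_lengths=lengths)


def random_counts(n_genes, n_samples, seed, mean=200.0, dispersion=0.1):
    """Negative-binomial test matrix with lognormal gene baselines."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(mean), 1.0, n_genes)[:, None] * np.ones(n_samples)
    from woundtraj.synthetic import nb_counts
    values = pd.DataFrame(nb_counts(mu, dispersion, rng),
                          index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{j}" for j in range(n_samples)])
    lengths = pd.Series(rng.integers(500, 5001, n_genes).astype(float),
                        index=values.index)
    return wt.CountsMatrix(values=values, gene_lengths=lengths)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
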