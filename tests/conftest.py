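import numpy as np
import pytest
import scipy.sparse as sp

from hinadr import DrugHIN, SynthConfig, fixture_small, generate_hin


@pytest.fixture(scope="session")
def small_hin():
    hin, truth = fixture_small()
    return hin, truth


@pytest.fixture(scope="session")
def desk_hin():
    """A 40-drug instance small enough for fast end-to-end tests."""
    cfg = SynthConfig(
        n_drugs=40, n_chems=25, n_prots=60, n_ses=15, n_dis=12,
        n_clusters=3, targets_per_drug=2, ppi_within_p=0.15,
        ppi_between_p=0.01, seed=77,
    )
    return generate_hin(cfg)


def random_hin(rng: np.random.Generator, n_drugs=8, n_chems=5, n_prots=6,
               n_ses=4, n_dis=3, density=0.35) -> DrugHIN:
    """Random valid HIN for round-trip / invariant tests."""
    def bip(nr, nc):
        return sp.csr_matrix((rng.random((nr, nc)) < density).astype(float))

    def symm(n):
        A = np.triu((rng.random((n, n)) < density).astype(float), k=1)
        return sp.csr_matrix(A + A.T)

    return DrugHIN(
        drugs=[f"d{i}" for i in range(n_drugs)],
        chems=[f"c{i}" for i in range(n_chems)],
        prots=[f"p{i}" for i in range(n_prots)],
        ses=[f"s{i}" for i in range(n_ses)],
        dis=[f"i{i}" for i in range(n_dis)],
        A_dd=symm(n_drugs),
        M_dc=bip(n_drugs, n_chems),
        M_dp=bip(n_drugs, n_prots),
        M_dse=bip(n_drugs, n_ses),
        M_ddi=bip(n_drugs, n_dis),
        A_pp=symm(n_prots),
    ).validate()
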