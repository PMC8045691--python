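import numpy as np
import pytest
from hypothesis import settings

import polyblup as pb
from polyblup.pedigree import Individual, Pedigree

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def chain_ped() -> Pedigree:
    """Canonical D x T -> S, S x V -> F1, three backcrosses to V."""
    return pb.backcross_chain(3)


@pytest.fixture(scope="session")
def chain_kinship(chain_ped):
    return pb.build_partial_matrices(chain_ped)


@pytest.fixture(scope="session")
def sawyt_vc():
    """Published posterior-mean variance components for grain yield."""
    return pb.SAWYT_GRAIN_YIELD_MULTIBREED


def random_pedigree(seed: int, n_crosses: int = 20) -> Pedigree:
    """A small random grammar-valid pedigree for property tests."""
    rng = np.random.default_rng(seed)
    scheme = pb.SimScheme(
        n_diploid=int(rng.integers(2, 5)),
        n_tetraploid=int(rng.integers(2, 5)),
        n_hexaploid=int(rng.integers(4, 9)),
        n_synthetic=int(rng.integers(2, 5)),
        crosses_by_depth=tuple(
            int(rng.integers(1, 1 + max(1, n_crosses // 4)))
            for _ in range(int(rng.integers(1, 5)))
        ),
        seed=seed,
    )
    return pb.simulate_pedigree(scheme)


@pytest.fixture(scope="session")
def shared_s_ped() -> Pedigree:
    """Eleven individuals; two F1 lines share the synthetic S1, plus two
    backcross generations.  Used by the gene-dropping comparisons."""
    inds = [
        Individual("D1", None, None, "D"),
        Individual("T1", None, None, "T"),
        Individual("S1", "D1", "T1", "S"),
        Individual("V0", None, None, "V"),
        Individual("V1", None, None, "V"),
        Individual("V2", None, None, "V"),
        Individual("V4", None, None, "V"),
        Individual("F1", "S1", "V0", "SD"),
        Individual("F1b", "S1", "V4", "SD"),
        Individual("BC1", "V1", "F1", "SD"),
        Individual("BC2", "V2", "BC1", "SD"),
    ]
    return Pedigree(inds)
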