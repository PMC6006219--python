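import numpy as np
import pytest

from mhchap.model import AbHaplotype, PedigreeRecord
from mhchap.synthetic_data import SimConfig


def pytest_configure(config):
    import warnings
    warnings.filterwarnings("ignore", message=".*experimental.*")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small, fast cohort configuration used by unit tests."""
    return SimConfig(seed=7, n_haplotypes=4, n_founders=4, n_generations=1,
                     n_offspring_per_gen=4, reads_per_animal=120,
                     recomb_prob_AB=0.0, recomb_prob_withinB=0.0,
                     pseudogene_prob=0.0, missing_a_prob=0.0)


def make_ab(hap_id, a=(), b=(), ps=()):
    return AbHaplotype(hap_id=hap_id, a_alleles=frozenset(a),
                       b_alleles=frozenset(b), pseudogenes=frozenset(ps))


def trio(child="C", dam="D", sire="S"):
    return [PedigreeRecord(dam), PedigreeRecord(sire),
            PedigreeRecord(child, dam_id=dam, sire_ids=(sire,))]
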