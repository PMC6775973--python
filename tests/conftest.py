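import numpy as np
import pytest

from cobascan import synthetic as sy
from cobascan.records import SequenceRecord

AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@pytest.fixture(scope="session")
def genome40():
    """Default 40 kb simulated genome with planted DTR and terminator."""
    return sy.simulate_genome(sy.GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def small_genome():
    """Small genome for fast alignment tests."""
    return sy.simulate_genome(sy.GenomeSpec(length=4000, dtr_length=120, seed=11))


@pytest.fixture
def protein_families():
    """Three synthetic protein families mutated from distinct ancestors."""

    def make(seed=0, n_families=3, members=4, length=120, divergence=0.15):
        rng = np.random.default_rng(seed)
        proteins = []
        truth = []
        for f in range(n_families):
            anc = rng.choice(AAS, length)
            fam = []
            for m in range(members):
                s = anc.copy()
                k = rng.binomial(length, divergence)
                if k:
                    idx = rng.choice(length, k, replace=False)
                    s[idx] = rng.choice(AAS, k)
                pid = f"f{f}_m{m}"
                proteins.append(SequenceRecord(pid, "".join(s)))
                fam.append(pid)
            truth.append(frozenset(fam))
        return proteins, set(truth)

    return make
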