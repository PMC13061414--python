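import numpy as np
import pytest

from dolsim import (
    Parameters, Population, Role, ScenarioConfig, Task, init_population,
    validate_parameters,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_population(N_b, breeders=(), subordinates=(), floaters=()):
    """Build a small population by hand.

    ``breeders`` is a list of territory ids; ``subordinates`` a list of
    (territory, age, alpha) triples; ``floaters`` a list of (age, alpha)
    pairs.  All other loci sit at their ancestral values and the neutral
    locus at 0 unless modified afterwards.
    """
    from dolsim.model_core import ALPHA, INITIAL_ALLELES, N_LOCI

    pop = Population(N_b)
    rows = []
    for g in breeders:
        rows.append((0.0, 1, Role.BREEDER, g))
    for g, age, alpha in subordinates:
        rows.append((alpha, age, Role.SUBORDINATE, g))
    for age, alpha in floaters:
        rows.append((alpha, age, Role.FLOATER, -1))
    n = len(rows)
    genes = np.tile(np.asarray(INITIAL_ALLELES), (n, 1))
    genes[:, ALPHA] = [r[0] for r in rows]
    pop.append(genes,
               np.array([r[1] for r in rows], dtype=np.int64),
               np.array([int(r[2]) for r in rows], dtype=np.int8),
               np.array([r[3] for r in rows], dtype=np.int64),
               np.full(n, Task.NONE, dtype=np.int8))
    return pop
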