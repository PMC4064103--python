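import random

import pytest

from hierfold import RnaSequence, SecondaryStructure, crosses
from hierfold.energy import INF, default_model, evaluate_centi
from hierfold.structures import BasePair


@pytest.fixture(scope="session")
def model():
    return default_model()


def random_sequence(rng: random.Random, n: int, alphabet: str = "ACGU") -> RnaSequence:
    return RnaSequence("".join(rng.choice(alphabet) for _ in range(n)))


def random_input_structure(
    rng: random.Random, seq: RnaSequence, model, max_pairs: int = 3
):
    """A random small pseudoknot-free canonical structure that the energy
    model can realise (finite energy), or None."""
    n = seq.n
    cands = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + 3, n + 1)
        if seq.can_pair(i, j)
    ]
    rng.shuffle(cands)
    chosen = []
    target = rng.randint(1, max_pairs)
    for c in cands:
        if len(chosen) >= target:
            break
        ok = all(
            c[0] != q[0]
            and c[0] != q[1]
            and c[1] != q[0]
            and c[1] != q[1]
            and not crosses(BasePair(*c), BasePair(*q))
            for q in chosen
        )
        if ok:
            chosen.append(c)
    g = SecondaryStructure(chosen)
    if evaluate_centi(g, seq, model) >= INF:
        return None
    return g
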