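"""Input-structure seeding: hotspot stems and suboptimal-structure surrogate.

When no pseudoknot-free input structure is available, the orchestrator is
seeded from candidate structures derived from the sequence alone:

* *hotspots* — the k lowest-energy maximal relaxed stems (HotKnots-style
  first phase), each offered as an input structure; the caller runs the
  predictor on each and keeps the lowest-energy final result;
* *suboptimal inputs* — a documented surrogate for an MFE engine's first-k
  suboptimal structures: the MFE structure plus constrained refoldings
  seeded from each hotspot stem, deduplicated and sorted by energy.

Stem ranking is an approximation: each stem is scored by the sum of its
plain stack / internal-loop connection terms, and for every outermost
candidate pair the single best inward extension is kept.
"""

from __future__ import annotations

from typing import Optional

from .energy import INF, EnergyModel, default_model
from .pkfree import RELAXED_GAPS, constrained_fold, mfe_fold
from .structures import BasePair, RnaSequence, SecondaryStructure

__all__ = ["enumerate_stems", "hotspots", "suboptimal_inputs"]

#: minimum number of pairs for a hotspot stem
MIN_STEM_PAIRS = 3


def _best_extension(
    seq: RnaSequence, model: EnergyModel, cache: dict
) -> "dict[BasePair, tuple[int, Optional[BasePair]]]":
    """For every canonical pair, the best-scoring inward relaxed chain:
    pair -> (chain energy in centi-kcal, next pair or None)."""

    def rec(p: BasePair) -> tuple[int, Optional[BasePair]]:
        if p in cache:
            return cache[p]
        # a chain may only terminate on a pair that can close a legal hairpin
        if p.j - p.i - 1 >= model.min_hairpin_unpaired:
            best, nxt = 0, None
        else:
            best, nxt = INF, None
        for dl, dr in sorted(RELAXED_GAPS):
            k, l = p.i + 1 + dl, p.j - 1 - dr
            if not (k < l) or not seq.can_pair(k, l):
                continue
            q = BasePair(k, l)
            conn = (
                model.stack(seq, p, q) if (dl, dr) == (0, 0) else model.internal(dl, dr)
            )
            sub, _ = rec(q)
            if sub < INF and conn + sub < best:
                best, nxt = conn + sub, q
        cache[p] = (best, nxt)
        return cache[p]

    for i in range(1, seq.n + 1):
        for j in range(i + 2, seq.n + 1):
            if seq.can_pair(i, j):
                rec(BasePair(i, j))
    return cache


def enumerate_stems(
    seq: RnaSequence, model: Optional[EnergyModel] = None
) -> list[tuple[SecondaryStructure, float]]:
    """Maximal relaxed stems with >= 3 pairs, sorted by energy then 5' index.

    Each stem is the best inward chain from an outermost canonical pair
    that is not itself absorbed into a better enclosing chain; the score is
    the sum of its stack / internal connection terms (kcal/mol).
    """
    model = model or default_model()
    cache: dict[BasePair, tuple[int, Optional[BasePair]]] = {}
    _best_extension(seq, model, cache)

    # pairs that appear as an extension of some other pair are not stem heads
    extended: set[BasePair] = set()
    for p, (_, nxt) in cache.items():
        cur = nxt
        while cur is not None:
            extended.add(cur)
            cur = cache[cur][1]

    stems: list[tuple[int, int, tuple[BasePair, ...]]] = []
    seen: set[tuple] = set()
    for head, (energy, _) in cache.items():
        if head in extended or energy >= 0:
            continue
        chain = [head]
        while cache[chain[-1]][1] is not None:
            chain.append(cache[chain[-1]][1])
        if len(chain) < MIN_STEM_PAIRS:
            continue
        key = tuple(map(tuple, chain))
        if key not in seen:
            seen.add(key)
            stems.append((energy, head.i, tuple(chain)))
    stems.sort()
    return [
        (SecondaryStructure(chain), energy / 100.0) for energy, _, chain in stems
    ]


def hotspots(
    seq: RnaSequence, model: Optional[EnergyModel] = None, k: int = 20
) -> list[SecondaryStructure]:
    """The top-``k`` lowest-energy stems, as candidate input structures.

    The default ``k=20`` mirrors the hotspot phase of HotKnots.  If fewer
    stems exist, all are returned; the order is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    model = model or default_model()
    return [s for s, _ in enumerate_stems(seq, model)[:k]]


def suboptimal_inputs(
    seq: RnaSequence, model: Optional[EnergyModel] = None, k: int = 50
) -> list[SecondaryStructure]:
    """Up to ``k`` distinct pseudoknot-free structures, ascending energy,
    with the MFE structure first.

    Surrogate construction: the MFE structure plus one constrained
    refolding per hotspot stem, deduplicated and truncated to ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    model = model or default_model()
    mfe = mfe_fold(seq, model)
    ranked: list[tuple[float, str, SecondaryStructure]] = []
    seen = {mfe.structure}
    for stem in hotspots(seq, model, k=k):
        res = constrained_fold(seq, stem, model)
        if res.structure not in seen:
            seen.add(res.structure)
            from .structures import write_structure

            ranked.append(
                (res.energy, write_structure(res.structure, seq.n), res.structure)
            )
    ranked.sort(key=lambda t: (t[0], t[1]))
    out = [mfe.structure] + [s for _, _, s in ranked]
    return out[:k]
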