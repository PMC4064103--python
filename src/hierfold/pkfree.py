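"""Pseudoknot-free MFE folding, with and without a forced input structure.

These are the SimFold-equivalent operations the iterative orchestrator
builds on: :func:`mfe_fold` is plain Zuker-style minimum-free-energy
folding, :func:`constrained_fold` additionally forces every pair of an
input structure ``g`` into the result, and :func:`relaxed_stems` extracts
the maximal relaxed stems of a structure that touch ``g``.
"""

from __future__ import annotations

from typing import Optional

from .energy import EnergyModel, default_model
from .engine import Folder, FoldResult, _check_input_structure
from .structures import BasePair, RnaSequence, SecondaryStructure, StructureError

__all__ = ["mfe_fold", "constrained_fold", "relaxed_stems"]

#: gap geometries (left unpaired, right unpaired) linking consecutive pairs
#: of a relaxed stem: stacks, bulges of 1 and internal loops of size <= 3.
RELAXED_GAPS = frozenset({(0, 0), (0, 1), (1, 0), (1, 1), (1, 2), (2, 1)})


def mfe_fold(seq: RnaSequence, model: Optional[EnergyModel] = None) -> FoldResult:
    """Minimum free energy pseudoknot-free structure of ``seq``.

    O(n^3) dynamic program over hairpin / stack / internal-loop / multiloop
    terms with a deterministic traceback.
    """
    model = model or default_model()
    empty = SecondaryStructure()
    return Folder(seq, model, empty, "mfe").fold("mfe")


def constrained_fold(
    seq: RnaSequence,
    g: SecondaryStructure,
    model: Optional[EnergyModel] = None,
) -> FoldResult:
    """Minimum-energy pseudoknot-free structure whose pair set contains ``g``.

    ``g`` must be pseudoknot-free and canonical; with ``g`` empty this is
    identical to :func:`mfe_fold`.
    """
    model = model or default_model()
    _check_input_structure(seq, g)
    return Folder(seq, model, g, "constrained").fold("constrained")


def _stem_components(s: SecondaryStructure) -> list[tuple[BasePair, ...]]:
    """Split ``s`` into maximal relaxed stems.

    Two pairs are linked when they are directly nested, their gaps match a
    relaxed-stem geometry, and no other pair of ``s`` intervenes.
    """
    pairs = sorted(s.pairs)
    paired = sorted(s.paired_bases())

    def occupied_between(lo: int, hi: int) -> bool:
        # any paired base strictly inside (lo, hi)?
        import bisect

        k = bisect.bisect_right(paired, lo)
        return k < len(paired) and paired[k] < hi

    comp: dict[BasePair, BasePair] = {p: p for p in pairs}

    def find(p: BasePair) -> BasePair:
        while comp[p] != p:
            comp[p] = comp[comp[p]]
            p = comp[p]
        return p

    by_i = {p.i: p for p in pairs}
    for p in pairs:
        # candidate inner partners start just after p.i
        for di in range(0, 3):
            q = by_i.get(p.i + 1 + di)
            if q is None or q.j >= p.j:
                continue
            gap = (q.i - p.i - 1, p.j - q.j - 1)
            if gap not in RELAXED_GAPS:
                continue
            if occupied_between(p.i, q.i) or occupied_between(q.j, p.j):
                continue
            comp[find(p)] = find(q)
    groups: dict[BasePair, list[BasePair]] = {}
    for p in pairs:
        groups.setdefault(find(p), []).append(p)
    return [tuple(sorted(gr)) for gr in sorted(groups.values(), key=lambda g: g[0])]


def relaxed_stems(
    gprime: SecondaryStructure, g: SecondaryStructure
) -> SecondaryStructure:
    """Union of the maximal relaxed stems of ``gprime`` containing a pair of ``g``.

    A relaxed stem is a run of pairs connected by stacks, bulges of size 1
    or internal loops of total size <= 3 (1x1, 1x2, 2x1).  ``g`` must be a
    subset of ``gprime``; the result always contains ``g`` and the
    operation is idempotent.
    """
    if not g.issubset(gprime):
        raise StructureError("relaxed_stems requires g to be a subset of gprime")
    keep: list[BasePair] = []
    for stem in _stem_components(gprime):
        if any(p in g for p in stem):
            keep.extend(stem)
    return SecondaryStructure(keep)
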