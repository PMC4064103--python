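"""Hierarchical folding engines: HFold, HFold-PKonly and exhaustive oracles.

Given a sequence ``S`` and a pseudoknot-free input structure ``G``, HFold
finds a pseudoknot-free layer ``G'`` over the bases unpaired in ``G`` such
that ``G ∪ G'`` has minimum free energy among density-2 structures
containing ``G``.  HFold-PKonly restricts ``G'`` to pairs that cross ``G``.

The engine is a single dynamic program with four entry modes (plain MFE,
constrained MFE, HFold, HFold-PKonly).  It combines

* a Zuker-style layer for ordinary (non-crossing) loops — hairpins,
  stacked pairs, internal loops and multiloops (matrices V / WM / W), and
* a chain-of-bands pseudoloop layer: a pseudoloop is a chain of two or
  more bands that alternate between the fixed input layer and the added
  layer, scored with the band-spanning stack/internal factors, the band
  penalty per band, and per-unpaired / per-closed-subregion interior terms
  (matrices P / PK / WI).

Because all crossings in a two-layer structure are between a ``G`` pair and
a ``G'`` pair, bands strictly alternate layers along a chain; with ``G``
empty no pseudoloop can form and HFold reduces to plain MFE folding.

The exhaustive oracle :func:`brute_force_hfold` defines the normative
semantics on small instances: it enumerates every admissible ``G'``,
filters unions through the shared density-2 checker, and scores them with
the shared evaluator.  The engine's search grammar excludes two structure
shapes the evaluator can score — branched pseudoloops and band-spanning
multiloops — which require more dedicated bases than the oracle scale can
hold; see docs/methods.md for the operational class.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterator, Literal, Optional

from .energy import INF, EnergyModel, default_model, evaluate_centi
from .structures import (
    BasePair,
    RnaSequence,
    SecondaryStructure,
    StructureError,
    crosses,
    is_density_two,
    is_pseudoknot_free,
)

__all__ = [
    "FoldResult",
    "hfold",
    "hfold_pkonly",
    "brute_force_hfold",
    "brute_force_pkfree",
    "Folder",
]

#: cap on unpaired bases per side of an internal loop in the search
MAX_INTERNAL_SIDE = 30

#: size cap for the exhaustive oracles
ORACLE_CAP = 18


@dataclass(frozen=True)
class FoldResult:
    """A predicted structure, its free energy (kcal/mol) and provenance."""

    structure: SecondaryStructure
    energy: float
    method_tag: str


def _make_result(
    structure: SecondaryStructure,
    energy_centi: int,
    tag: str,
    seq: RnaSequence,
    model: EnergyModel,
) -> FoldResult:
    check = evaluate_centi(structure, seq, model)
    if check != energy_centi:  # pragma: no cover - internal consistency guard
        raise AssertionError(
            f"engine energy {energy_centi} != evaluator energy {check} "
            f"for {structure!r}"
        )
    return FoldResult(structure=structure, energy=energy_centi / 100.0, method_tag=tag)


Mode = Literal["mfe", "constrained", "hfold", "pkonly"]


class Folder:
    """One folding problem: sequence, model, input structure and mode.

    All energies are integer hundredths of kcal/mol.  Matrices are
    dictionaries filled by memoised recursion; every cell records the
    branch that achieved its optimum, so the traceback is exact and
    deterministic (candidates are scanned in a fixed order and only a
    strict improvement replaces the incumbent).
    """

    def __init__(
        self,
        seq: RnaSequence,
        model: EnergyModel,
        g: SecondaryStructure,
        mode: Mode,
    ):
        self.seq = seq
        self.model = model
        self.g = g
        self.mode = mode
        self.n = seq.n
        self.allow_pk = mode in ("hfold", "pkonly")
        self.pkonly = mode == "pkonly"

        self.gp = [0] * (self.n + 2)  # partner in g, 0 = free
        for p in g.pairs:
            if p.j > self.n:
                raise StructureError("input structure does not fit the sequence")
            self.gp[p.i] = p.j
            self.gp[p.j] = p.i
        #: positions opening a g pair, ascending — band starts on the fixed layer
        self.g_starts = [i for i in range(1, self.n + 1) if self.gp[i] > i]

        # prefix counts of g-paired bases for O(1) "gap is free" checks
        self._gcount = [0] * (self.n + 2)
        for i in range(1, self.n + 1):
            self._gcount[i] = self._gcount[i - 1] + (1 if self.gp[i] else 0)

        self._memo: dict[tuple, int] = {}
        self._choice: dict[tuple, tuple] = {}
        self._bands: dict[tuple, dict] = {}

        # precomputed pairability and loop-energy tables (hot-path caches)
        n = self.n
        self._ord_ok = [bytearray(n + 2) for _ in range(n + 2)]
        self._free_ok = [bytearray(n + 2) for _ in range(n + 2)]
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if self._can_pair_ord_slow(i, j):
                    self._ord_ok[i][j] = 1
                if not self.gp[i] and not self.gp[j] and seq.can_pair(i, j):
                    self._free_ok[i][j] = 1
        self._hp = [model.hairpin(sz) for sz in range(0, n + 1)]
        side = MAX_INTERNAL_SIDE
        self._int_e = [[0] * (side + 1) for _ in range(side + 1)]
        self._bint = [[0] * (side + 1) for _ in range(side + 1)]
        for n1 in range(side + 1):
            for n2 in range(side + 1):
                if n1 or n2:
                    self._int_e[n1][n2] = model.internal(n1, n2)
                    self._bint[n1][n2] = model.band_internal(n1, n2)
        #: ascending free canonical partners j > i, for band construction
        self._free_partners: list[list[int]] = [[] for _ in range(n + 2)]
        for i in range(1, n + 1):
            self._free_partners[i] = [
                j for j in range(i + 1, n + 1) if self._free_ok[i][j]
            ]
        #: smallest right end of a g pair starting at or after i (INF if none)
        self._minend_from = [INF] * (n + 3)
        for i in range(n, 0, -1):
            self._minend_from[i] = self._minend_from[i + 1]
            if self.gp[i] > i:
                self._minend_from[i] = min(self._minend_from[i], self.gp[i])

    # -- small helpers ------------------------------------------------------

    def _free_span(self, i: int, j: int) -> bool:
        """True iff no base in [i, j] is paired in g (empty span -> True)."""
        if i > j:
            return True
        return self._gcount[j] - self._gcount[i - 1] == 0

    def _can_pair_ord_slow(self, i: int, j: int) -> bool:
        """May (i, j) appear as an ordinary (non-crossing) pair?"""
        if self.gp[i] or self.gp[j]:
            return self.gp[i] == j
        if self.pkonly:
            return False  # PKonly adds no ordinary pairs
        return self.seq.can_pair(i, j)

    def _can_pair_ord(self, i: int, j: int) -> bool:
        return bool(self._ord_ok[i][j])

    def _can_pair_free(self, i: int, j: int) -> bool:
        """May (i, j) appear as an added-layer band pair?"""
        return bool(self._free_ok[i][j])

    # -- ordinary layer: V, WM, W -------------------------------------------

    def V(self, i: int, j: int) -> int:
        key = ("V", i, j)
        if key in self._memo:
            return self._memo[key]
        best, choice = INF, None
        if j - i >= 2 and self._ord_ok[i][j]:
            m = self.model
            # hairpin
            if self._free_span(i + 1, j - 1):
                e = self._hp[j - i - 1]
                if e < best:
                    best, choice = e, ("hairpin",)
            # stacked pair / internal loop
            int_e = self._int_e
            for k in range(i + 1, min(i + MAX_INTERNAL_SIDE + 1, j - 1) + 1):
                if not self._free_span(i + 1, k - 1):
                    break
                row = self._ord_ok[k]
                n1 = k - i - 1
                for l in range(j - 1, max(k, j - MAX_INTERNAL_SIDE - 2), -1):
                    if not row[l]:
                        continue
                    if not self._free_span(l + 1, j - 1):
                        continue
                    inner = self.V(k, l)
                    if inner >= INF:
                        continue
                    n2 = j - l - 1
                    conn = m.stack(self.seq, BasePair(i, j), BasePair(k, l)) \
                        if n1 == 0 and n2 == 0 else int_e[n1][n2]
                    e = conn + inner
                    if e < best:
                        best, choice = e, ("internal", k, l)
            # multiloop: >=2 elements, or a lone pseudoloop child
            for r in range(i + 1, j - 1):
                left = self.WM(i + 1, r)
                if left >= INF:
                    continue
                right = self.WM(r + 1, j - 1)
                if right >= INF:
                    continue
                e = m.a + m.b + left + right
                if e < best:
                    best, choice = e, ("ml_split", r)
            if self.allow_pk:
                for k in range(i + 1, j - 1):
                    if not self._free_span(i + 1, k - 1):
                        break
                    for l in range(j - 1, k + 1, -1):
                        if not self._free_span(l + 1, j - 1):
                            continue
                        pl = self.P(k, l)
                        if pl >= INF:
                            continue
                        e = (
                            m.a + m.b + m.P_sm + pl
                            + m.c * ((k - i - 1) + (j - l - 1))
                        )
                        if e < best:
                            best, choice = e, ("ml_pseudoloop", k, l)
        self._memo[key] = best
        self._choice[key] = choice
        return best

    def WM(self, i: int, j: int) -> int:
        """Multiloop partial region [i, j]: >=1 element plus unpaired bases.

        Elements are ordinary branches (charged ``b``) or pseudoloops
        (charged ``P_sm``); unpaired bases cost ``c`` and must be free.
        """
        if i > j:
            return INF
        key = ("WM", i, j)
        if key in self._memo:
            return self._memo[key]
        m = self.model
        best, choice = INF, None
        if not self.gp[j]:
            e = self.WM(i, j - 1) + m.c
            if e < best:
                best, choice = e, ("unpaired",)
        for k in range(i, j - 1):
            elem, kind = self._element(k, j)
            if elem >= INF:
                continue
            if k == i:
                e = elem
                if e < best:
                    best, choice = e, (kind, k, "start")
            else:
                if self._free_span(i, k - 1):
                    e = elem + m.c * (k - i)
                    if e < best:
                        best, choice = e, (kind, k, "lead")
                prefix = self.WM(i, k - 1)
                if prefix < INF:
                    e = elem + prefix
                    if e < best:
                        best, choice = e, (kind, k, "chain")
        self._memo[key] = best
        self._choice[key] = choice
        return best

    def _element(self, k: int, j: int) -> tuple[int, str]:
        m = self.model
        v = self.V(k, j)
        best, kind = (v + m.b, "elemV") if v < INF else (INF, "elemV")
        if self.allow_pk:
            p = self.P(k, j)
            if p < INF and p + m.P_sm < best:
                best, kind = p + m.P_sm, "elemP"
        return best, kind

    def W(self, j: int) -> int:
        """External region [1, j]."""
        if j <= 0:
            return 0
        key = ("W", j)
        if key in self._memo:
            return self._memo[key]
        best, choice = INF, None
        if not self.gp[j]:
            e = self.W(j - 1)
            if e < best:
                best, choice = e, ("unpaired",)
        for i in range(1, j):
            prefix = self.W(i - 1)
            if prefix >= INF:
                continue
            v = self.V(i, j)
            if v < INF and prefix + v < best:
                best, choice = prefix + v, ("pair", i)
            if self.allow_pk:
                p = self.P(i, j)
                if p < INF and prefix + p + self.model.P_s < best:
                    best, choice = prefix + p + self.model.P_s, ("pseudoloop", i)
        self._memo[key] = best
        self._choice[key] = choice
        return best

    # -- pseudoloop layer: WI, bands, P, PK ----------------------------------

    def WI(self, i: int, j: int) -> int:
        """Pseudoloop interior region [i, j] (may be empty).

        Unpaired bases cost ``P_up``; a closed subregion costs ``P_ps`` plus
        its own energy; a nested pseudoloop costs ``P_sp`` plus its energy.
        """
        if i > j:
            return 0
        key = ("WI", i, j)
        if key in self._memo:
            return self._memo[key]
        m = self.model
        best, choice = INF, None
        if not self.gp[j]:
            e = self.WI(i, j - 1) + m.P_up
            if e < best:
                best, choice = e, ("unpaired",)
        for k in range(i, j - 1):
            prefix = self.WI(i, k - 1)
            if prefix >= INF:
                continue
            v = self.V(k, j)
            if v < INF and prefix + v + m.P_ps < best:
                best, choice = prefix + v + m.P_ps, ("closed", k)
            if self.allow_pk:
                p = self.P(k, j)
                if p < INF and prefix + p + m.P_sp < best:
                    best, choice = prefix + p + m.P_sp, ("nested", k)
        self._memo[key] = best
        self._choice[key] = choice
        return best

    def band_chains(self, i: int, j: int, side: str) -> dict[BasePair, tuple[int, Optional[BasePair]]]:
        """All band chains with outer pair (i, j) on the given layer.

        Returns inner pair -> (chain energy, next pair towards the inner),
        where the chain energy sums band-spanning stack / internal terms.
        On the fixed layer (side "g") chain pairs are input-structure pairs;
        on the added layer (side "f") they are canonical pairs of free
        bases.  Gaps between consecutive chain pairs must be free.
        """
        key = (i, j, side)
        if key in self._bands:
            return self._bands[key]
        m = self.model
        out: dict[BasePair, tuple[int, Optional[BasePair]]] = {BasePair(i, j): (0, None)}
        import bisect

        for k in range(i + 1, min(i + MAX_INTERNAL_SIDE + 1, j - 1) + 1):
            if not self._free_span(i + 1, k - 1):
                break
            if side == "g":
                l = self.gp[k]
                candidates = [l] if k < l < j else []
            else:
                partners = self._free_partners[k]
                lo_idx = bisect.bisect_right(partners, max(k, j - MAX_INTERNAL_SIDE - 2))
                hi_idx = bisect.bisect_left(partners, j)
                candidates = partners[lo_idx:hi_idx][::-1]
            for l in candidates:
                n1, n2 = k - i - 1, j - l - 1
                if n2 > MAX_INTERNAL_SIDE or not self._free_span(l + 1, j - 1):
                    continue
                conn = m.band_stack(self.seq, BasePair(i, j), BasePair(k, l)) \
                    if n1 == 0 and n2 == 0 else self._bint[n1][n2]
                for inner, (sub_e, _nxt) in self.band_chains(k, l, side).items():
                    e = conn + sub_e
                    if inner not in out or e < out[inner][0]:
                        out[inner] = (e, BasePair(k, l))
        self._bands[key] = out
        return out

    def _outer_candidates(self, x: int, side: str, lo: int, hi: int) -> list[int]:
        """Possible outer right ends for a band starting at x, within (lo, hi]."""
        if side == "g":
            y = self.gp[x]
            return [y] if x < y and lo < y <= hi else []
        if self.gp[x]:
            return []
        import bisect

        partners = self._free_partners[x]
        a = bisect.bisect_right(partners, lo)
        b = bisect.bisect_right(partners, hi)
        return partners[a:b][::-1]

    def _next_starts(self, side: str, lo: int, hi: int, min_partner: int) -> Iterator[int]:
        """Positions in (lo, hi) that can start a band on ``side`` whose
        outer pair reaches beyond ``min_partner``."""
        if side == "g":
            for x in self.g_starts:
                if lo < x < hi and self.gp[x] > min_partner:
                    yield x
        else:
            for x in range(lo + 1, hi):
                if not self.gp[x]:
                    partners = self._free_partners[x]
                    if partners and partners[-1] > min_partner:
                        yield x

    def P(self, i: int, j: int) -> int:
        """Pseudoloop spanning exactly [i, j]: a chain of >=2 alternating
        bands, including band penalties and interior terms but not the
        context initiation (the caller adds P_s / P_sm / P_sp)."""
        if not self.allow_pk or j - i < 3 or self._minend_from[i] > j:
            return INF  # every pseudoloop needs a fixed-layer band inside [i, j]
        return self.Popen(i).get(j, (INF, None))[0]

    def Popen(self, i: int) -> dict[int, tuple[int, tuple]]:
        """All pseudoloops whose chain starts at ``i``: end -> (energy, choice).

        Keying chains by their start only (the end emerges from the band
        placements) keeps the state space independent of the caller's
        region, which is what makes dense sequences tractable.
        """
        key = ("Po", i)
        if key in self._memo:
            return self._memo[key]
        m = self.model
        out: dict[int, tuple[int, tuple]] = {}
        for side in ("g", "f"):
            other = "f" if side == "g" else "g"
            for j1 in self._outer_candidates(i, side, i, self.n):
                for inner, (ebnd, _nxt) in self.band_chains(i, j1, side).items():
                    a, b = inner
                    for x2 in self._next_starts(other, a, b, j1):
                        wi = self.WI(a + 1, x2 - 1)
                        if wi >= INF:
                            continue
                        base = ebnd + m.P_b + wi
                        for end, (rest, _c) in self.PKopen(x2, b, j1, other).items():
                            e = base + rest
                            if end not in out or e < out[end][0]:
                                out[end] = (e, ("first", side, j1, a, b, x2))
        self._memo[key] = out
        return out

    def PKopen(self, x: int, pb: int, pj: int, side: str) -> dict[int, tuple[int, tuple]]:
        """Chain suffixes: the current band starts at ``x`` on ``side`` and
        its hole embeds the previous band's right interval [pb, pj].
        Returns chain end -> (energy, choice)."""
        if side == "g":
            if self.gp[x] <= pj:
                return {}
        else:
            partners = self._free_partners[x] if not self.gp[x] else ()
            if not partners or partners[-1] <= pj:
                return {}
        key = ("PKo", x, pb, pj, side)
        if key in self._memo:
            return self._memo[key]
        m = self.model
        out: dict[int, tuple[int, tuple]] = {}
        other = "f" if side == "g" else "g"
        for yc in self._outer_candidates(x, side, pj, self.n):
            for inner, (ebnd, _nxt) in self.band_chains(x, yc, side).items():
                a, b = inner
                if not (a < pb and pj < b):
                    continue
                left = self.WI(a + 1, pb - 1)
                if left >= INF:
                    continue
                # this band is the last of the chain: end = yc
                right = self.WI(pj + 1, b - 1)
                if right < INF:
                    e = ebnd + m.P_b + left + right
                    if yc not in out or e < out[yc][0]:
                        out[yc] = (e, ("last", a, b))
                # or the chain continues inside the hole
                for x2 in self._next_starts(other, pj, b, yc):
                    mid = self.WI(pj + 1, x2 - 1)
                    if mid >= INF:
                        continue
                    base = ebnd + m.P_b + left + mid
                    for end, (rest, _c) in self.PKopen(x2, b, yc, other).items():
                        e = base + rest
                        if end not in out or e < out[end][0]:
                            out[end] = (e, ("cont", yc, a, b, x2))
        self._memo[key] = out
        return out

    # -- traceback -----------------------------------------------------------

    def _trace_band(self, outer: BasePair, inner: BasePair, side: str, pairs: list) -> None:
        cur = outer
        while True:
            pairs.append(cur)
            if cur == inner:
                return
            nxt = self.band_chains(cur.i, cur.j, side)[inner][1]
            assert nxt is not None
            cur = nxt

    def _trace(self, key: tuple, pairs: list) -> None:
        kind = key[0]
        choice = self._choice.get(key)
        if kind == "W":
            j = key[1]
            if j <= 0:
                return
            assert choice is not None, "traceback on infeasible W"
            if choice[0] == "unpaired":
                self._trace(("W", j - 1), pairs)
            elif choice[0] == "pair":
                i = choice[1]
                self._trace(("W", i - 1), pairs)
                self._trace(("V", i, j), pairs)
            else:
                i = choice[1]
                self._trace(("W", i - 1), pairs)
                self._trace(("P", i, j), pairs)
        elif kind == "V":
            i, j = key[1], key[2]
            pairs.append(BasePair(i, j))
            assert choice is not None
            if choice[0] == "hairpin":
                return
            if choice[0] == "internal":
                self._trace(("V", choice[1], choice[2]), pairs)
            elif choice[0] == "ml_split":
                r = choice[1]
                self._trace(("WM", i + 1, r), pairs)
                self._trace(("WM", r + 1, j - 1), pairs)
            else:  # ml_pseudoloop
                self._trace(("P", choice[1], choice[2]), pairs)
        elif kind == "WM":
            i, j = key[1], key[2]
            assert choice is not None
            if choice[0] == "unpaired":
                self._trace(("WM", i, j - 1), pairs)
                return
            what, k, prefix = choice
            self._trace(("V" if what == "elemV" else "P", k, j), pairs)
            if prefix == "chain":
                self._trace(("WM", i, k - 1), pairs)
        elif kind == "WI":
            i, j = key[1], key[2]
            if i > j:
                return
            assert choice is not None
            if choice[0] == "unpaired":
                self._trace(("WI", i, j - 1), pairs)
                return
            k = choice[1]
            self._trace(("V" if choice[0] == "closed" else "P", k, j), pairs)
            self._trace(("WI", i, k - 1), pairs)
        elif kind == "P":
            i, j = key[1], key[2]
            _, side, j1, a, b, x2 = self.Popen(i)[j][1]
            self._trace_band(BasePair(i, j1), BasePair(a, b), side, pairs)
            self._trace(("WI", a + 1, x2 - 1), pairs)
            other = "f" if side == "g" else "g"
            self._trace_chain(x2, b, j1, other, j, pairs)
        else:  # pragma: no cover
            raise AssertionError(f"unknown traceback key {key!r}")

    def _trace_chain(
        self, x: int, pb: int, pj: int, side: str, end: int, pairs: list
    ) -> None:
        choice = self.PKopen(x, pb, pj, side)[end][1]
        other = "f" if side == "g" else "g"
        if choice[0] == "last":
            a, b = choice[1], choice[2]
            self._trace_band(BasePair(x, end), BasePair(a, b), side, pairs)
            self._trace(("WI", a + 1, pb - 1), pairs)
            self._trace(("WI", pj + 1, b - 1), pairs)
        else:
            _, yc, a, b, x2 = choice
            self._trace_band(BasePair(x, yc), BasePair(a, b), side, pairs)
            self._trace(("WI", a + 1, pb - 1), pairs)
            self._trace(("WI", pj + 1, x2 - 1), pairs)
            self._trace_chain(x2, b, yc, other, end, pairs)

    # -- entry point ----------------------------------------------------------

    def fold(self, tag: str) -> FoldResult:
        sys.setrecursionlimit(max(sys.getrecursionlimit(), 50 * self.n + 10000))
        energy = self.W(self.n)
        if energy >= INF:
            raise StructureError(
                "input structure admits no feasible folding "
                "(e.g. a hairpin below the minimum loop size)"
            )
        pairs: list[BasePair] = []
        self._trace(("W", self.n), pairs)
        structure = SecondaryStructure(pairs)
        return _make_result(structure, energy, tag, self.seq, self.model)


# ---------------------------------------------------------------------------
# public folding operations
# ---------------------------------------------------------------------------


def _check_input_structure(seq: RnaSequence, g: SecondaryStructure) -> None:
    if not is_pseudoknot_free(g):
        raise StructureError("input structure must be pseudoknot-free")
    g.check_canonical(seq)


def hfold(
    seq: RnaSequence,
    g: SecondaryStructure,
    model: Optional[EnergyModel] = None,
) -> FoldResult:
    """HFold: minimum-energy density-2 structure containing ``g``.

    The added layer is pseudoknot-free and disjoint in bases from ``g``;
    the union may or may not be pseudoknotted.  With ``g`` empty this
    reduces to plain pseudoknot-free MFE folding.
    """
    model = model or default_model()
    _check_input_structure(seq, g)
    return Folder(seq, model, g, "hfold").fold("hfold")


def hfold_pkonly(
    seq: RnaSequence,
    g: SecondaryStructure,
    model: Optional[EnergyModel] = None,
) -> FoldResult:
    """HFold-PKonly: like :func:`hfold`, but every added pair must cross a
    pair of ``g``; the added layer may be empty (the result is then ``g``)."""
    model = model or default_model()
    _check_input_structure(seq, g)
    return Folder(seq, model, g, "pkonly").fold("pkonly")


# ---------------------------------------------------------------------------
# exhaustive oracles
# ---------------------------------------------------------------------------


def _candidate_pairs(
    seq: RnaSequence,
    g: SecondaryStructure,
    min_model_hairpin: int,
    pkonly: bool,
) -> list[BasePair]:
    gp = {p.i: p.j for p in g.pairs} | {p.j: p.i for p in g.pairs}
    out = []
    for i in range(1, seq.n + 1):
        if i in gp:
            continue
        for j in range(i + 1, seq.n + 1):
            if j in gp or not seq.can_pair(i, j):
                continue
            cand = BasePair(i, j)
            crossing = any(crosses(cand, p) for p in g.pairs)
            if pkonly and not crossing:
                continue
            if not crossing and j - i - 1 < min_model_hairpin and not any(
                i < x < j for x in gp
            ):
                continue  # can only close an impossible hairpin
            out.append(cand)
    return out


def _enumerate_layers(cands: list[BasePair]) -> Iterator[tuple[BasePair, ...]]:
    """All subsets of candidates that are mutually non-crossing and
    base-disjoint (a valid pseudoknot-free added layer)."""
    n = len(cands)

    def rec(start: int, chosen: list[BasePair]) -> Iterator[tuple[BasePair, ...]]:
        yield tuple(chosen)
        for idx in range(start, n):
            c = cands[idx]
            ok = True
            for q in chosen:
                if c.i == q.i or c.i == q.j or c.j == q.i or c.j == q.j or crosses(c, q):
                    ok = False
                    break
            if ok:
                chosen.append(c)
                yield from rec(idx + 1, chosen)
                chosen.pop()

    return rec(0, [])


def _brute_force(
    seq: RnaSequence,
    g: SecondaryStructure,
    model: EnergyModel,
    mode: Literal["pkfree", "hfold", "pkonly"],
    tag: str,
    cap: int = ORACLE_CAP,
) -> FoldResult:
    if seq.n > cap:
        raise StructureError(f"oracle limited to n <= {cap} (got {seq.n})")
    _check_input_structure(seq, g)
    cands = _candidate_pairs(seq, g, model.min_hairpin_unpaired, pkonly=(mode == "pkonly"))
    if mode == "pkfree":
        cands = [c for c in cands if not any(crosses(c, p) for p in g.pairs)]
    best: tuple[int, int, tuple, SecondaryStructure] | None = None
    g_pairs = tuple(g.pairs)
    for layer in _enumerate_layers(cands):
        union = SecondaryStructure(g_pairs + layer)
        if layer and not is_density_two(union):
            continue
        e = evaluate_centi(union, seq, model)
        if e >= INF:
            continue
        rank = (e, len(union), tuple(map(tuple, union.pairs)), union)
        if best is None or rank[:3] < best[:3]:
            best = rank
    if best is None:
        raise StructureError("no feasible structure (input violates the model)")
    return _make_result(best[3], best[0], tag, seq, model)


def brute_force_hfold(
    seq: RnaSequence,
    g: SecondaryStructure,
    model: Optional[EnergyModel] = None,
    pkonly: bool = False,
    cap: int = ORACLE_CAP,
) -> FoldResult:
    """Exhaustive HFold oracle: enumerate every pseudoknot-free added layer
    over the bases unpaired in ``g`` (crossing-only if ``pkonly``), keep
    unions passing the density-2 check, and return the minimum-energy union.
    Ties break by fewest pairs, then lexicographic pair order."""
    model = model or default_model()
    return _brute_force(
        seq, g, model, "pkonly" if pkonly else "hfold", "oracle", cap=cap
    )


def brute_force_pkfree(
    seq: RnaSequence,
    g: SecondaryStructure,
    model: Optional[EnergyModel] = None,
    cap: int = ORACLE_CAP,
) -> FoldResult:
    """Exhaustive oracle for (constrained) pseudoknot-free MFE folding."""
    model = model or default_model()
    return _brute_force(seq, g, model, "pkfree", "oracle", cap=cap)
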