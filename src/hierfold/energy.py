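"""DP09-style free-energy model for density-2 pseudoknotted structures.

The model combines

* scalar pseudoknot constants: pseudoloop initiation by context
  (``P_s`` exterior, ``P_sm`` inside a multiloop, ``P_sp`` inside another
  pseudoloop), the per-band penalty ``P_b``, per-unpaired-base ``P_up`` and
  per-closed-subregion ``P_ps`` terms,
* nearest-neighbour loop tables (hairpin, stack, bulge, internal), and
* multiloop linear coefficients ``a + b*pairs + c*unpaired`` with primed
  counterparts for multiloops that span a band.

Stacked pairs and internal loops that span a band are scaled by the
dimensionless factors ``band_stack_factor`` (0.89) and
``band_internal_factor`` (0.74).

All energies are held internally as integers in hundredths of kcal/mol so
ties are exact and the band factors round deterministically
(half away from zero).  Public functions report kcal/mol floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Optional

from .structures import (
    Band,
    BasePair,
    RnaSequence,
    SecondaryStructure,
    StructureError,
    _bands_unchecked,
    is_density_two,
)

__all__ = [
    "EnergyError",
    "INF",
    "EnergyModel",
    "Loop",
    "LoopDecomposition",
    "load_params",
    "default_model",
    "loop_energy",
    "decompose",
    "evaluate_structure",
]


class EnergyError(ValueError):
    """Raised for malformed parameter files or invalid loop descriptors."""


#: Sentinel for an infeasible energy, safely summable in fixed point.
INF = 10**9

_REQUIRED_SCALARS = (
    "P_s", "P_sm", "P_sp", "P_b", "P_up", "P_ps",
    "a", "b", "c", "a_prime", "b_prime", "c_prime",
    "band_stack_factor", "band_internal_factor",
)
_OPTIONAL_SCALARS = {
    "min_hairpin_unpaired": 3.0,
    "internal_asymmetry": 0.50,
    "asymmetry_max": 3.00,
    "loop_extrapolation": 1.08,
}
_REQUIRED_TABLES = ("stack", "hairpin_loop", "internal_loop")


def _centi(x: float) -> int:
    """kcal/mol -> integer hundredths, rounding half away from zero."""
    scaled = x * 100.0
    return int(math.floor(scaled + 0.5)) if scaled >= 0 else -int(math.floor(-scaled + 0.5))


def _scale(value: int, factor_centi: int) -> int:
    """Fixed-point product ``value * (factor_centi/100)``, half away from zero."""
    num = value * factor_centi
    q, r = divmod(abs(num), 100)
    result = q + (1 if r >= 50 else 0)
    return result if num >= 0 else -result


@dataclass(frozen=True)
class EnergyModel:
    """A fully loaded energy parameter set (fixed-point, hundredths kcal/mol)."""

    P_s: int
    P_sm: int
    P_sp: int
    P_b: int
    P_up: int
    P_ps: int
    a: int
    b: int
    c: int
    a_prime: int
    b_prime: int
    c_prime: int
    band_stack_factor: int       # centi-units: 89 means 0.89
    band_internal_factor: int
    min_hairpin_unpaired: int
    internal_asymmetry: int
    asymmetry_max: int
    loop_extrapolation: int
    stack_table: dict[tuple[str, str], int] = field(repr=False)
    hairpin_table: dict[int, int] = field(repr=False)
    bulge_table: dict[int, int] = field(repr=False)
    internal_table: dict[int, int] = field(repr=False)

    # -- elementary terms (all return centi-kcal ints; INF = infeasible) ----

    def stack(self, seq: RnaSequence, outer: BasePair, inner: BasePair) -> int:
        key = (
            seq.base(outer.i) + seq.base(outer.j),
            seq.base(inner.i) + seq.base(inner.j),
        )
        try:
            return self.stack_table[key]
        except KeyError as exc:
            raise EnergyError(f"no stack entry for {key[0]}/{key[1]}") from exc

    def _extrapolate(self, table: dict[int, int], size: int) -> int:
        top = max(table)
        if size <= top:
            try:
                return table[size]
            except KeyError as exc:
                raise EnergyError(f"no loop entry for size {size}") from exc
        return table[top] + _centi(self.loop_extrapolation / 100 * math.log(size / top))

    def hairpin(self, size: int) -> int:
        """Hairpin initiation by loop size; below the minimum -> INF."""
        if size < self.min_hairpin_unpaired:
            return INF
        return self._extrapolate(self.hairpin_table, size)

    def internal(self, n1: int, n2: int) -> int:
        """Internal/bulge loop with ``n1``/``n2`` unpaired bases per side."""
        if n1 == 0 and n2 == 0:
            raise EnergyError("0x0 loop is a stacked pair, not an internal loop")
        if n1 == 0 or n2 == 0:
            return self._extrapolate(self.bulge_table, n1 + n2)
        asym = min(self.internal_asymmetry * abs(n1 - n2), self.asymmetry_max)
        return self._extrapolate(self.internal_table, n1 + n2) + asym

    def band_stack(self, seq: RnaSequence, outer: BasePair, inner: BasePair) -> int:
        return _scale(self.stack(seq, outer, inner), self.band_stack_factor)

    def band_internal(self, n1: int, n2: int) -> int:
        return _scale(self.internal(n1, n2), self.band_internal_factor)

    def multiloop(self, n_pairs: int, n_unpaired: int) -> int:
        return self.a + self.b * n_pairs + self.c * n_unpaired

    def band_multiloop(self, n_pairs: int, n_unpaired: int) -> int:
        return self.a_prime + self.b_prime * n_pairs + self.c_prime * n_unpaired

    def pseudoloop(self, context: str, n_bands: int, n_unpaired: int, n_closed: int) -> int:
        init = {"exterior": self.P_s, "multiloop": self.P_sm, "pseudoloop": self.P_sp}
        try:
            p0 = init[context]
        except KeyError as exc:
            raise EnergyError(f"unknown pseudoloop context {context!r}") from exc
        return p0 + self.P_b * n_bands + self.P_up * n_unpaired + self.P_ps * n_closed


# ---------------------------------------------------------------------------
# parameter file loading
# ---------------------------------------------------------------------------


def _parse_sections(lines: Iterable[str], origin: str):
    sections: dict[str, list[tuple[int, str]]] = {}
    current: Optional[str] = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip().lower()
            sections.setdefault(current, [])
        elif current is None:
            raise EnergyError(f"{origin}:{lineno}: content before any [section]")
        else:
            sections[current].append((lineno, line))
    return sections


def _load_from_lines(lines: Iterable[str], origin: str) -> EnergyModel:
    sections = _parse_sections(lines, origin)

    scalars: dict[str, float] = {}
    for lineno, line in sections.get("constants", []):
        if "=" not in line:
            raise EnergyError(f"{origin}:{lineno}: expected 'name = value'")
        name, _, value = line.partition("=")
        try:
            scalars[name.strip()] = float(value.strip())
        except ValueError as exc:
            raise EnergyError(f"{origin}:{lineno}: bad number {value.strip()!r}") from exc
    for name in _REQUIRED_SCALARS:
        if name not in scalars:
            raise EnergyError(f"missing constant: {name}")
    for name, default in _OPTIONAL_SCALARS.items():
        scalars.setdefault(name, default)

    for table in _REQUIRED_TABLES:
        if table not in sections or not sections[table]:
            raise EnergyError(f"missing table: {table}")

    stack_table: dict[tuple[str, str], int] = {}
    for lineno, line in sections["stack"]:
        parts = line.split()
        if len(parts) != 3:
            raise EnergyError(f"{origin}:{lineno}: stack rows are 'XY ZW energy'")
        try:
            stack_table[(parts[0].upper(), parts[1].upper())] = _centi(float(parts[2]))
        except ValueError as exc:
            raise EnergyError(f"{origin}:{lineno}: bad stack energy {parts[2]!r}") from exc

    def size_table(name: str) -> dict[int, int]:
        table: dict[int, int] = {}
        for lineno, line in sections.get(name, []):
            parts = line.split()
            if len(parts) != 2:
                raise EnergyError(f"{origin}:{lineno}: {name} rows are 'size energy'")
            try:
                table[int(parts[0])] = _centi(float(parts[1]))
            except ValueError as exc:
                raise EnergyError(f"{origin}:{lineno}: bad {name} row") from exc
        return table

    hairpin_table = size_table("hairpin_loop")
    internal_table = size_table("internal_loop")
    # bulge table is optional: fall back to the internal-loop initiation sizes
    bulge_table = size_table("bulge_loop") or dict(internal_table)

    return EnergyModel(
        P_s=_centi(scalars["P_s"]),
        P_sm=_centi(scalars["P_sm"]),
        P_sp=_centi(scalars["P_sp"]),
        P_b=_centi(scalars["P_b"]),
        P_up=_centi(scalars["P_up"]),
        P_ps=_centi(scalars["P_ps"]),
        a=_centi(scalars["a"]),
        b=_centi(scalars["b"]),
        c=_centi(scalars["c"]),
        a_prime=_centi(scalars["a_prime"]),
        b_prime=_centi(scalars["b_prime"]),
        c_prime=_centi(scalars["c_prime"]),
        band_stack_factor=_centi(scalars["band_stack_factor"]),
        band_internal_factor=_centi(scalars["band_internal_factor"]),
        min_hairpin_unpaired=int(scalars["min_hairpin_unpaired"]),
        internal_asymmetry=_centi(scalars["internal_asymmetry"]),
        asymmetry_max=_centi(scalars["asymmetry_max"]),
        loop_extrapolation=_centi(scalars["loop_extrapolation"]),
        stack_table=stack_table,
        hairpin_table=hairpin_table,
        bulge_table=bulge_table,
        internal_table=internal_table,
    )


def load_params(path: str) -> EnergyModel:
    """Load an energy model from a sectioned plain-text parameter file."""
    with open(path) as fh:
        return _load_from_lines(fh, origin=path)


_DEFAULT: Optional[EnergyModel] = None


def default_model() -> EnergyModel:
    """The parameter set shipped with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("hierfold").joinpath("params/default.par").read_text()
        _DEFAULT = _load_from_lines(text.splitlines(), origin="default.par")
    return _DEFAULT


# ---------------------------------------------------------------------------
# loop descriptors and the structure evaluator
# ---------------------------------------------------------------------------


LoopKind = Literal["hairpin", "stack", "internal", "multiloop", "pseudoloop"]


@dataclass(frozen=True)
class Loop:
    """One term of a loop decomposition.

    ``closing``/``inner`` locate stacked pairs and internal loops;
    ``n_pairs``/``n_unpaired`` carry multiloop counts (``n_pairs`` includes
    the closing pair); pseudoloops use ``context`` (exterior / multiloop /
    pseudoloop), ``n_bands``, ``n_unpaired`` and ``n_closed``.
    ``band_spanning`` marks loops lying on a band chain.
    """

    kind: LoopKind
    closing: Optional[BasePair] = None
    inner: Optional[BasePair] = None
    n1: int = 0
    n2: int = 0
    n_pairs: int = 0
    n_unpaired: int = 0
    band_spanning: bool = False
    context: str = "exterior"
    n_bands: int = 0
    n_closed: int = 0


@dataclass(frozen=True)
class LoopDecomposition:
    loops: tuple[Loop, ...]

    def total_centi(self, model: EnergyModel, seq: RnaSequence) -> int:
        total = 0
        for loop in self.loops:
            e = _loop_energy_centi(model, loop, seq)
            if e >= INF:
                return INF
            total += e
        return total


def _loop_energy_centi(model: EnergyModel, loop: Loop, seq: RnaSequence) -> int:
    if loop.kind == "hairpin":
        assert loop.closing is not None
        return model.hairpin(loop.closing.j - loop.closing.i - 1)
    if loop.kind == "stack":
        assert loop.closing is not None and loop.inner is not None
        if loop.band_spanning:
            return model.band_stack(seq, loop.closing, loop.inner)
        return model.stack(seq, loop.closing, loop.inner)
    if loop.kind == "internal":
        if loop.band_spanning:
            return model.band_internal(loop.n1, loop.n2)
        return model.internal(loop.n1, loop.n2)
    if loop.kind == "multiloop":
        if loop.band_spanning:
            return model.band_multiloop(loop.n_pairs, loop.n_unpaired)
        return model.multiloop(loop.n_pairs, loop.n_unpaired)
    if loop.kind == "pseudoloop":
        return model.pseudoloop(loop.context, loop.n_bands, loop.n_unpaired, loop.n_closed)
    raise EnergyError(f"unknown loop kind {loop.kind!r}")


def loop_energy(model: EnergyModel, loop: Loop, seq: RnaSequence) -> float:
    """Free energy of a single loop term, kcal/mol.

    Raises :class:`EnergyError` for hairpins below the minimum loop size.
    """
    e = _loop_energy_centi(model, loop, seq)
    if e >= INF:
        raise EnergyError(
            f"hairpin loop below the minimum of {model.min_hairpin_unpaired} unpaired bases"
        )
    return e / 100.0


# -- decomposition ----------------------------------------------------------


@dataclass(frozen=True)
class _Pseudoloop:
    bands: tuple[Band, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(b.outer.i for b in self.bands),
            max(b.outer.j for b in self.bands),
        )


def _group_pseudoloops(bands: list[Band]) -> list[_Pseudoloop]:
    """Connected components of the band-crossing graph."""
    from .structures import group_bands

    return [_Pseudoloop(tuple(g)) for g in group_bands(bands)]


def decompose(s: SecondaryStructure, seq: RnaSequence) -> LoopDecomposition:
    """Complete, deterministic loop decomposition of a density-2 structure.

    Every base pair closes or participates in exactly one loop term; each
    pseudoloop is tagged with the context that selects its initiation
    penalty (``P_s`` exterior, ``P_sm`` inside a multiloop, ``P_sp`` inside
    another pseudoloop).
    """
    s.check_canonical(seq)
    if not is_density_two(s):
        raise StructureError("decompose requires a density-2 structure")
    bands = _bands_unchecked(s)
    pk_pairs = frozenset(p for band in bands for p in band.pairs)
    pseudoloops = _group_pseudoloops(bands)

    # nodes: ordinary pairs and whole pseudoloop spans, nested or disjoint
    nodes: list[tuple[int, int, object]] = [
        (p.i, p.j, p) for p in s.pairs if p not in pk_pairs
    ] + [(pl.span[0], pl.span[1], pl) for pl in pseudoloops]
    nodes.sort(key=lambda t: (t[0], -t[1]))

    children: dict[object, list[tuple[int, int, object]]] = {"root": []}
    stack: list[tuple[int, int, object]] = []
    for node in nodes:
        lo, hi, payload = node
        while stack and not (stack[-1][0] < lo and hi < stack[-1][1]):
            stack.pop()
        owner = stack[-1][2] if stack else "root"
        children.setdefault(owner, []).append(node)
        children.setdefault(payload, [])
        stack.append(node)

    loops: list[Loop] = []

    def do_ordinary(pair: BasePair) -> None:
        kids = children[pair]
        kid_pairs = [k for k in kids if isinstance(k[2], BasePair)]
        kid_pls = [k for k in kids if isinstance(k[2], _Pseudoloop)]
        covered = sum(hi - lo + 1 for lo, hi, _ in kids)
        n_unpaired = (pair.j - pair.i - 1) - covered
        if not kids:
            loops.append(Loop("hairpin", closing=pair))
        elif len(kid_pairs) == 1 and not kid_pls:
            lo, hi, inner = kid_pairs[0]
            n1, n2 = lo - pair.i - 1, pair.j - hi - 1
            if n1 == 0 and n2 == 0:
                loops.append(Loop("stack", closing=pair, inner=inner))
            else:
                loops.append(Loop("internal", closing=pair, inner=inner, n1=n1, n2=n2))
        else:
            loops.append(
                Loop(
                    "multiloop",
                    closing=pair,
                    n_pairs=1 + len(kid_pairs),
                    n_unpaired=n_unpaired,
                )
            )
        for lo, hi, payload in kids:
            if isinstance(payload, BasePair):
                do_ordinary(payload)
            else:
                do_pseudoloop(payload, context="multiloop")

    def do_pseudoloop(pl: _Pseudoloop, context: str) -> None:
        kids = children[pl]
        span_lo, span_hi = pl.span

        # assign each child node to a band-connection gap or to the interior
        def gap_of(lo: int, hi: int):
            for band in pl.bands:
                for outer, inner in zip(band.pairs, band.pairs[1:]):
                    for g_lo, g_hi in ((outer.i + 1, inner.i - 1), (inner.j + 1, outer.j - 1)):
                        if g_lo <= lo and hi <= g_hi:
                            return (band, outer, inner)
            return None

        gap_children: dict[tuple, list[tuple[int, int, object]]] = {}
        interior_children: list[tuple[int, int, object]] = []
        for node in kids:
            key = gap_of(node[0], node[1])
            if key is None:
                interior_children.append(node)
            else:
                gap_children.setdefault(key, []).append(node)

        # band chains: stack / internal / band-spanning multiloop per link
        for band in pl.bands:
            for outer, inner in zip(band.pairs, band.pairs[1:]):
                sub = gap_children.get((band, outer, inner), [])
                g1 = inner.i - outer.i - 1
                g2 = outer.j - inner.j - 1
                if not sub:
                    if g1 == 0 and g2 == 0:
                        loops.append(Loop("stack", closing=outer, inner=inner, band_spanning=True))
                    else:
                        loops.append(
                            Loop("internal", closing=outer, inner=inner, n1=g1, n2=g2, band_spanning=True)
                        )
                else:
                    covered = sum(hi - lo + 1 for lo, hi, _ in sub)
                    sub_pairs = [k for k in sub if isinstance(k[2], BasePair)]
                    loops.append(
                        Loop(
                            "multiloop",
                            closing=outer,
                            n_pairs=2 + len(sub_pairs),
                            n_unpaired=g1 + g2 - covered,
                            band_spanning=True,
                        )
                    )
                for lo, hi, payload in sub:
                    if isinstance(payload, BasePair):
                        do_ordinary(payload)
                    else:
                        do_pseudoloop(payload, context="multiloop")

        # pseudoloop interior: unpaired bases and closed subregions
        owned = set()
        for band in pl.bands:
            for lo, hi in band.intervals:
                owned.update(range(lo, hi + 1))
        interior = set(range(span_lo, span_hi + 1)) - owned
        n_closed = 0
        for lo, hi, payload in interior_children:
            interior -= set(range(lo, hi + 1))
            if isinstance(payload, BasePair):
                n_closed += 1
                do_ordinary(payload)
            else:
                do_pseudoloop(payload, context="pseudoloop")
        loops.append(
            Loop(
                "pseudoloop",
                context=context,
                n_bands=len(pl.bands),
                n_unpaired=len(interior),
                n_closed=n_closed,
            )
        )

    for lo, hi, payload in children["root"]:
        if isinstance(payload, BasePair):
            do_ordinary(payload)
        else:
            do_pseudoloop(payload, context="exterior")

    return LoopDecomposition(tuple(loops))


def evaluate_centi(s: SecondaryStructure, seq: RnaSequence, model: EnergyModel) -> int:
    """Fixed-point total energy; INF if the structure is infeasible
    (e.g. a hairpin below the minimum loop size)."""
    if len(s) == 0:
        return 0
    return decompose(s, seq).total_centi(model, seq)


def evaluate_structure(s: SecondaryStructure, seq: RnaSequence, model: EnergyModel) -> float:
    """Free energy of structure ``s`` on ``seq``, kcal/mol.

    The empty structure scores exactly 0; infeasible structures score
    ``math.inf``.
    """
    e = evaluate_centi(s, seq, model)
    return math.inf if e >= INF else e / 100.0
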