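"""Sequences, base pairs and (pseudoknotted) secondary structures.

Conventions
-----------
* Indices are 1-based and inclusive throughout the public API.
* A secondary structure is a set of pairs ``i.j`` (``i < j``) in which every
  base has at most one partner.
* Two pairs ``i.j`` and ``k.l`` *cross* iff ``i < k < j < l``.  A structure
  with no crossing pairs is pseudoknot-free.
* The class of pseudoknotted structures handled by the folding engines is the
  operational *density-2* class: the crossing graph is bipartite (the pair set
  splits into two pseudoknot-free layers) and no base is covered by more than
  two band intervals.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

__all__ = [
    "StructureError",
    "CANONICAL_PAIRS",
    "RnaSequence",
    "BasePair",
    "SecondaryStructure",
    "Band",
    "crosses",
    "is_pseudoknot_free",
    "layers",
    "is_density_two",
    "find_bands",
    "parse_structure",
    "write_structure",
    "read_ct",
    "read_bpseq",
    "read_fasta",
]


class StructureError(ValueError):
    """Raised for malformed sequences, pairs or structure notation."""


#: Canonical (Watson-Crick plus wobble) base pairs.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over the alphabet {A, C, G, U}.

    Lowercase input is normalised to uppercase before validation; any other
    character (including T and N) is rejected.
    """

    bases: str

    def __post_init__(self) -> None:
        normalised = self.bases.upper()
        if not normalised:
            raise StructureError("empty sequence")
        bad = set(normalised) - _ALPHABET
        if bad:
            raise StructureError(
                f"invalid characters in RNA sequence: {sorted(bad)!r} "
                "(alphabet is A, C, G, U)"
            )
        object.__setattr__(self, "bases", normalised)

    @property
    def n(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, i: int) -> str:
        """Base at 1-based position ``i``."""
        if not 1 <= i <= self.n:
            raise StructureError(f"index {i} outside [1, {self.n}]")
        return self.bases[i - 1]

    def can_pair(self, i: int, j: int) -> bool:
        """True iff positions ``i`` and ``j`` form a canonical pair."""
        return (self.base(i), self.base(j)) in CANONICAL_PAIRS


class BasePair(NamedTuple):
    """A base pair ``i.j`` with ``1 <= i < j``."""

    i: int
    j: int

    @classmethod
    def make(cls, i: int, j: int) -> "BasePair":
        if not (1 <= i < j):
            raise StructureError(f"invalid base pair ({i}, {j}): need 1 <= i < j")
        return cls(i, j)


def crosses(p: BasePair, q: BasePair) -> bool:
    """True iff pairs ``p`` and ``q`` cross (``i < k < j < l`` either way)."""
    return (p.i < q.i < p.j < q.j) or (q.i < p.i < q.j < p.j)


class SecondaryStructure:
    """An immutable set of base pairs with the one-partner-per-base invariant."""

    __slots__ = ("_pairs", "_partner")

    def __init__(self, pairs: Iterable[tuple[int, int]] = ()):
        norm = sorted(BasePair.make(int(i), int(j)) for i, j in pairs)
        partner: dict[int, int] = {}
        for p in norm:
            for x, y in ((p.i, p.j), (p.j, p.i)):
                if x in partner and partner[x] != y:
                    raise StructureError(
                        f"base {x} pairs with both {partner[x]} and {y}"
                    )
                partner[x] = y
        self._pairs: tuple[BasePair, ...] = tuple(dict.fromkeys(norm))
        self._partner = partner

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[BasePair]:
        return iter(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: object) -> bool:
        try:
            i, j = pair  # type: ignore[misc]
        except TypeError:
            return False
        return self._partner.get(int(i)) == int(j) and int(i) < int(j)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SecondaryStructure):
            return NotImplemented
        return self._pairs == other._pairs

    def __hash__(self) -> int:
        return hash(self._pairs)

    def __repr__(self) -> str:
        return f"SecondaryStructure({list(map(tuple, self._pairs))!r})"

    # -- accessors ----------------------------------------------------------
    @property
    def pairs(self) -> tuple[BasePair, ...]:
        """Pairs in sorted order."""
        return self._pairs

    def partner(self, i: int) -> int:
        """Partner of base ``i``, or 0 if unpaired."""
        return self._partner.get(i, 0)

    def paired_bases(self) -> frozenset[int]:
        return frozenset(self._partner)

    def max_index(self) -> int:
        return max((p.j for p in self._pairs), default=0)

    # -- set algebra --------------------------------------------------------
    def union(self, other: "SecondaryStructure") -> "SecondaryStructure":
        return SecondaryStructure(tuple(self._pairs) + tuple(other._pairs))

    def difference(self, other: "SecondaryStructure") -> "SecondaryStructure":
        return SecondaryStructure(p for p in self._pairs if p not in other)

    def issubset(self, other: "SecondaryStructure") -> bool:
        return all(p in other for p in self._pairs)

    # -- validation ---------------------------------------------------------
    def check_canonical(self, seq: RnaSequence, permissive: bool = False) -> None:
        """Reject pairs that are non-canonical or out of range for ``seq``.

        With ``permissive=True`` non-canonical pairs are downgraded to a
        warning; out-of-range pairs are always an error.
        """
        import warnings

        for p in self._pairs:
            if p.j > seq.n:
                raise StructureError(f"pair {tuple(p)} outside sequence of length {seq.n}")
            if not seq.can_pair(p.i, p.j):
                msg = (
                    f"non-canonical pair {tuple(p)}: "
                    f"{seq.base(p.i)}-{seq.base(p.j)}"
                )
                if permissive:
                    warnings.warn(msg, stacklevel=2)
                else:
                    raise StructureError(msg)


# ---------------------------------------------------------------------------
# crossing predicates, layers and the density-2 class
# ---------------------------------------------------------------------------


def is_pseudoknot_free(s: SecondaryStructure) -> bool:
    """True iff no two pairs of ``s`` cross.

    Uses a single stack sweep (O(m log m)); equivalent to the all-pairs check.
    """
    stack: list[BasePair] = []
    events = sorted(
        [(p.i, 0, p) for p in s.pairs] + [(p.j, 1, p) for p in s.pairs]
    )
    for _, kind, p in events:
        if kind == 0:
            stack.append(p)
        else:
            if not stack or stack[-1] != p:
                return False
            stack.pop()
    return True


def _crossing_adjacency(s: SecondaryStructure) -> dict[BasePair, list[BasePair]]:
    pairs = s.pairs
    adj: dict[BasePair, list[BasePair]] = {p: [] for p in pairs}
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            if crosses(pairs[a], pairs[b]):
                adj[pairs[a]].append(pairs[b])
                adj[pairs[b]].append(pairs[a])
    return adj


def layers(s: SecondaryStructure) -> tuple[SecondaryStructure, SecondaryStructure]:
    """Split ``s`` into two pseudoknot-free layers by 2-colouring crossings.

    Components of the crossing graph are processed in order of their smallest
    pair, whose colour is fixed to the first layer, so the split is
    deterministic.  Raises :class:`StructureError` if the crossing graph is
    not bipartite (the structure is then outside the density-2 class).
    """
    adj = _crossing_adjacency(s)
    colour: dict[BasePair, int] = {}
    for root in s.pairs:
        if root in colour:
            continue
        colour[root] = 0
        queue = deque([root])
        while queue:
            p = queue.popleft()
            for q in adj[p]:
                if q not in colour:
                    colour[q] = 1 - colour[p]
                    queue.append(q)
                elif colour[q] == colour[p]:
                    raise StructureError(
                        "crossing graph is not bipartite: pairs "
                        f"{tuple(p)} and {tuple(q)} cannot be layered"
                    )
    first = SecondaryStructure(p for p in s.pairs if colour[p] == 0)
    second = SecondaryStructure(p for p in s.pairs if colour[p] == 1)
    return first, second


@dataclass(frozen=True)
class Band:
    """A maximal pseudoknotted stem region.

    The band runs from its ``outer`` pair down to its ``inner`` pair and
    occupies the two intervals ``[outer.i, inner.i]`` and
    ``[inner.j, outer.j]``.  Every base pair listed in ``pairs`` lies on the
    chain from outer to inner.
    """

    outer: BasePair
    inner: BasePair
    pairs: tuple[BasePair, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (self.outer.i <= self.inner.i < self.inner.j <= self.outer.j):
            raise StructureError("band outer pair must enclose its inner pair")

    @property
    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.outer.i, self.inner.i),
            (self.inner.j, self.outer.j),
        )

    def covers(self, x: int) -> bool:
        (a, b), (c, d) = self.intervals
        return a <= x <= b or c <= x <= d


def _split_between(s: SecondaryStructure, outer: BasePair, inner: BasePair) -> bool:
    """True if some pair has exactly one endpoint in a gap between two
    directly nested band pairs — such a pair forces a band boundary."""
    for gap_lo, gap_hi in ((outer.i, inner.i), (inner.j, outer.j)):
        for p in s.pairs:
            for end, other in ((p.i, p.j), (p.j, p.i)):
                if gap_lo < end < gap_hi and not (gap_lo < other < gap_hi):
                    return True
    return False


def _bands_of_layer(
    s: SecondaryStructure, layer_pairs: Sequence[BasePair], pk_involved: frozenset[BasePair]
) -> list[Band]:
    """Greedy chain grouping of one layer's crossing-involved pairs.

    The layer's crossing-involved pairs form a forest under nesting; a band
    is a maximal chain outer ⊃ ... ⊃ inner in which each link is an only
    child and no pair of the full structure splits the link's gaps.
    """
    chain_pairs = sorted(p for p in layer_pairs if p in pk_involved)
    # children within the chain forest
    children: dict[BasePair, list[BasePair]] = {p: [] for p in chain_pairs}
    parent: dict[BasePair, BasePair] = {}
    stack: list[BasePair] = []
    for p in chain_pairs:  # sorted by (i, j): enclosing pairs come first
        while stack and not (stack[-1].i < p.i and p.j < stack[-1].j):
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
            parent[p] = stack[-1]
        stack.append(p)

    def linked(outer: BasePair, inner: BasePair) -> bool:
        return len(children[outer]) == 1 and not _split_between(s, outer, inner)

    bands: list[Band] = []
    for p in chain_pairs:
        if p in parent and linked(parent[p], p):
            continue  # not a band head
        chain = [p]
        while len(children[chain[-1]]) == 1 and linked(
            chain[-1], children[chain[-1]][0]
        ):
            chain.append(children[chain[-1]][0])
        bands.append(Band(outer=chain[0], inner=chain[-1], pairs=tuple(chain)))
    return bands


def _bands_unchecked(s: SecondaryStructure) -> list[Band]:
    adj = _crossing_adjacency(s)
    pk_involved = frozenset(p for p, nbrs in adj.items() if nbrs)
    first, second = layers(s)  # raises if not bipartite
    bands = _bands_of_layer(s, first.pairs, pk_involved) + _bands_of_layer(
        s, second.pairs, pk_involved
    )
    return sorted(bands, key=lambda b: (b.outer.i, b.outer.j))


def group_bands(bands: Sequence[Band]) -> list[list[Band]]:
    """Group bands into pseudoloops: connected components under crossing."""
    m = len(bands)
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(m):
        for b in range(a + 1, m):
            if any(crosses(p, q) for p in bands[a].pairs for q in bands[b].pairs):
                parent[find(a)] = find(b)
    groups: dict[int, list[Band]] = {}
    for k in range(m):
        groups.setdefault(find(k), []).append(bands[k])
    return [
        sorted(g, key=lambda b: (b.outer.i, b.outer.j))
        for g in sorted(groups.values(), key=lambda g: min(b.outer.i for b in g))
    ]


def is_density_two(s: SecondaryStructure) -> bool:
    """Membership in the operational density-2 class.

    Two conditions: (a) the pair set splits into two pseudoknot-free layers
    (bipartite crossing graph), and (b) within each pseudoloop, no base is
    enclosed by the spans of more than two of its bands.  Condition (b)
    reads the class description literally — a base may sit inside at most
    two overlapping pseudoknotted stems — and admits exactly the linear
    chains of interleaved bands (H-type, kissing hairpins, longer chains),
    with arbitrary nested pseudoknotted substructures allowed because a
    nested pseudoknot forms its own pseudoloop.
    """
    try:
        bands = _bands_unchecked(s)
    except StructureError:
        return False
    for group in group_bands(bands):
        cover: dict[int, int] = {}
        for band in group:
            for x in range(band.outer.i, band.outer.j + 1):
                cover[x] = cover.get(x, 0) + 1
                if cover[x] > 2:
                    return False
    return True


def find_bands(s: SecondaryStructure) -> list[Band]:
    """Partition the crossing-involved pairs of ``s`` into maximal bands.

    Requires ``s`` to be density-2.  A pseudoknot-free structure yields an
    empty list; the band count is the number of band penalties the energy
    evaluator charges.
    """
    if not is_density_two(s):
        raise StructureError("find_bands requires a density-2 structure")
    return _bands_unchecked(s)


# ---------------------------------------------------------------------------
# structure notation I/O
# ---------------------------------------------------------------------------

_OPENERS = "([{<"
_CLOSERS = ")]}>"
_FAMILY_OF = {c: k for k, c in enumerate(_OPENERS)}
_FAMILY_OF.update({c: k for k, c in enumerate(_CLOSERS)})


def parse_structure(text: str, n: int | None = None) -> SecondaryStructure:
    """Parse (multi-family) dot-bracket notation into a structure.

    Each bracket family ``()``, ``[]``, ``{}``, ``<>`` is matched
    independently by stack matching; ``.`` marks an unpaired base.  ``n``
    (when given) must equal the notation length.
    """
    if n is not None and len(text) != n:
        raise StructureError(
            f"structure notation has length {len(text)}, expected {n}"
        )
    stacks: list[list[int]] = [[] for _ in _OPENERS]
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in _OPENERS:
            stacks[_FAMILY_OF[ch]].append(pos)
        elif ch in _CLOSERS:
            fam = _FAMILY_OF[ch]
            if not stacks[fam]:
                raise StructureError(
                    f"unbalanced '{ch}' at position {pos}: no matching opener"
                )
            pairs.append((stacks[fam].pop(), pos))
        else:
            raise StructureError(f"unknown structure symbol {ch!r} at position {pos}")
    for fam, stack in enumerate(stacks):
        if stack:
            raise StructureError(
                f"unbalanced '{_OPENERS[fam]}' at position {stack[-1]}: never closed"
            )
    return SecondaryStructure(pairs)


def write_structure(s: SecondaryStructure, n: int) -> str:
    """Render ``s`` as multi-family dot-bracket notation of length ``n``.

    Bracket families are assigned first-fit greedily over ``( ) [ ] { } < >``
    in pair order, so that no two crossing pairs share a family.  The
    assignment is deterministic and round-trips through
    :func:`parse_structure`.
    """
    if s.max_index() > n:
        raise StructureError(f"structure does not fit in length {n}")
    assigned: list[list[BasePair]] = [[] for _ in _OPENERS]
    family: dict[BasePair, int] = {}
    for p in s.pairs:
        for fam, members in enumerate(assigned):
            if all(not crosses(p, q) for q in members):
                members.append(p)
                family[p] = fam
                break
        else:
            raise StructureError(
                "structure needs more than "
                f"{len(_OPENERS)} bracket families to render"
            )
    out = ["."] * n
    for p, fam in family.items():
        out[p.i - 1] = _OPENERS[fam]
        out[p.j - 1] = _CLOSERS[fam]
    return "".join(out)


# ---------------------------------------------------------------------------
# file formats: CT, BPSEQ, FASTA
# ---------------------------------------------------------------------------


def _read_columns(path: str) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                rows.append(line.split())
    return rows


def read_ct(path: str) -> tuple[RnaSequence, SecondaryStructure]:
    """Read a connect-table (CT) file: 1-based indices, 0 = unpaired."""
    rows = _read_columns(path)
    if not rows:
        raise StructureError(f"empty CT file: {path}")
    try:
        count = int(rows[0][0])
    except (ValueError, IndexError) as exc:
        raise StructureError(f"malformed CT header in {path}") from exc
    body = rows[1 : 1 + count]
    if len(body) != count:
        raise StructureError(f"CT file {path} promises {count} rows, has {len(body)}")
    bases, pairs = [], []
    for row in body:
        if len(row) < 6:
            raise StructureError(f"short CT row in {path}: {row!r}")
        idx, base, partner = int(row[0]), row[1], int(row[4])
        bases.append(base)
        if partner and idx < partner:
            pairs.append((idx, partner))
    return RnaSequence("".join(bases)), SecondaryStructure(pairs)


def read_bpseq(path: str) -> tuple[RnaSequence, SecondaryStructure]:
    """Read a BPSEQ file: ``index base partner`` with 0 = unpaired."""
    rows = _read_columns(path)
    bases, pairs = [], []
    for row in rows:
        if len(row) != 3:
            raise StructureError(f"malformed BPSEQ row in {path}: {row!r}")
        idx, base, partner = int(row[0]), row[1], int(row[2])
        bases.append(base)
        if partner and idx < partner:
            pairs.append((idx, partner))
    if not bases:
        raise StructureError(f"empty BPSEQ file: {path}")
    return RnaSequence("".join(bases)), SecondaryStructure(pairs)


def read_fasta(path: str) -> list[tuple[str, RnaSequence]]:
    """Read FASTA records as validated RNA sequences."""
    from Bio import SeqIO

    records = [(rec.id, RnaSequence(str(rec.seq))) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise StructureError(f"no FASTA records in {path}")
    return records
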