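"""Synthetic fixture generator: sequences with planted reference structures.

Builds random sequences carrying planted complementary segments so that
the reference structure is known by construction:

* ``hairpin`` — a single helix closing a loop (pseudoknot-free);
* ``htype`` — two crossing helices (an H-type pseudoknot, 2 bands);
* ``kissing`` — two hairpins whose loops are joined by a third helix
  (a kissing-hairpin chain, 3 bands).

Every generated reference is canonical for its sequence, passes the
density-2 check and round-trips through dot-bracket notation.  Spacer
bases are drawn A-biased so planted stems dominate the pairing signal.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Optional

from .structures import (
    RnaSequence,
    SecondaryStructure,
    StructureError,
    is_density_two,
    parse_structure,
    write_structure,
)

__all__ = ["Fixture", "generate_fixtures"]

_STEM_PAIRS = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U")]
_STEM_WEIGHTS = [0.35, 0.35, 0.12, 0.12, 0.06]
_SPACER = "AAAC"  # A-biased spacer alphabet


@dataclass(frozen=True)
class Fixture:
    name: str
    kind: str
    sequence: RnaSequence
    reference: SecondaryStructure

    @property
    def dot_bracket(self) -> str:
        return write_structure(self.reference, self.sequence.n)


def _plant(
    rng: random.Random,
    length: int,
    segments: list[tuple[int, int, int, bool]],
) -> tuple[str, list[tuple[int, int]]]:
    """Fill a sequence of ``length`` with spacers and planted helices.

    Each segment is (left_start, right_start, n_pairs, antiparallel) in
    1-based coordinates; pair k links left_start+k with
    right_start+n_pairs-1-k.
    """
    seq = [rng.choice(_SPACER) for _ in range(length)]
    pairs: list[tuple[int, int]] = []
    for left, right, k, _ in segments:
        for off in range(k):
            i = left + off
            j = right + (k - 1 - off)
            x, y = rng.choices(_STEM_PAIRS, weights=_STEM_WEIGHTS)[0]
            seq[i - 1], seq[j - 1] = x, y
            pairs.append((i, j))
    return "".join(seq), pairs


def _hairpin(rng: random.Random, length: int):
    k = rng.randint(4, max(4, min(8, (length - 5) // 2)))
    loop = rng.randint(3, max(3, length - 2 * k - 2))
    left = rng.randint(1, max(1, length - (2 * k + loop) + 1))
    right = left + k + loop
    if right + k - 1 > length:
        return None
    return [(left, right, k, True)]


def _htype(rng: random.Random, length: int):
    # layout: L1 u1 L2 u2 R1 u3 R2 tail ; stem1 = L1-R1, stem2 = L2-R2
    k1 = rng.randint(3, 5)
    k2 = rng.randint(3, 5)
    gaps = [rng.randint(2, 4) for _ in range(3)]
    need = 2 * (k1 + k2) + sum(gaps)
    if need > length:
        return None
    p1 = 1 + rng.randint(0, length - need)
    p2 = p1 + k1 + gaps[0]
    p3 = p2 + k2 + gaps[1]
    p4 = p3 + k1 + gaps[2]
    return [(p1, p3, k1, True), (p2, p4, k2, True)]


def _kissing(rng: random.Random, length: int):
    # layout: A ... [K-left in loop A] ... A' spacer B ... [K-right in loop B] ... B'
    ka, kb, kk = rng.randint(3, 4), rng.randint(3, 4), rng.randint(3, 4)
    u = [rng.randint(1, 2) for _ in range(4)]
    spacer = rng.randint(2, 4)
    need = 2 * (ka + kb + kk) + sum(u) + spacer
    if need > length:
        return None
    aL = 1 + rng.randint(0, length - need)
    kL = aL + ka + u[0]
    aR = kL + kk + u[1]
    bL = aR + ka + spacer
    kR = bL + kb + u[2]
    bR = kR + kk + u[3]
    return [
        (aL, aR, ka, True),
        (kL, kR, kk, True),
        (bL, bR, kb, True),
    ]


_BUILDERS = {"hairpin": _hairpin, "htype": _htype, "kissing": _kissing}


def generate_fixtures(
    count: int,
    length_range: tuple[int, int] = (30, 60),
    rng: Optional[random.Random] = None,
    kinds: Iterable[str] = ("hairpin", "htype", "kissing"),
) -> list[Fixture]:
    """Generate ``count`` fixtures cycling through the requested kinds.

    Lengths are drawn uniformly from ``length_range`` (minimum 10).  A
    draw whose motif does not fit its length is skipped with a warning and
    retried; every returned reference is validated.
    """
    import warnings

    if length_range[0] < 10:
        raise ValueError("fixture lengths must be >= 10")
    rng = rng or random.Random(0)
    kinds = tuple(kinds)
    out: list[Fixture] = []
    attempts = 0
    while len(out) < count and attempts < 100 * count:
        attempts += 1
        kind = kinds[len(out) % len(kinds)]
        length = rng.randint(*length_range)
        segs = _BUILDERS[kind](rng, length)
        if segs is None:
            warnings.warn(f"{kind} motif does not fit length {length}; retrying")
            continue
        bases, pairs = _plant(rng, length, segs)
        seq = RnaSequence(bases)
        ref = SecondaryStructure(pairs)
        ref.check_canonical(seq)
        if not is_density_two(ref):  # pragma: no cover - construction guarantees it
            raise StructureError("generated reference failed the density-2 check")
        assert parse_structure(write_structure(ref, seq.n), seq.n) == ref
        out.append(Fixture(f"{kind}-{len(out):03d}", kind, seq, ref))
    if len(out) < count:
        raise StructureError("could not generate the requested fixtures")
    return out
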