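"""Secondary-structure string grammar.

A protein's topology class is coarse-grained to a string over {H, E, C}
(helix, strand, coil).  Evolutionary intermediates between two folds are
generated by elementary edits of this string — lengthen/shorten an element
by one residue, insert a minimal element into a coil window, or delete a
minimal element — subject to stereochemical bounds on element lengths,
separation and total structured content.  The module parses strings into
elements, validates them, enumerates legal moves, enumerates the
parsimonious element correspondences between two endpoint strings, and
builds concrete move-by-move paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALPHABET",
    "HELIX_BOUNDS",
    "STRAND_BOUNDS",
    "STRUCTURED_BOUNDS",
    "SS_1PGB",
    "SS_2GYC",
    "SSElement",
    "ElementMapping",
    "Move",
    "SSPath",
    "Violation",
    "PathDeadEndError",
    "parse_elements",
    "validate",
    "is_valid",
    "ss_distance",
    "enumerate_moves",
    "enumerate_pathways",
    "build_path",
]

ALPHABET = frozenset("HEC")

# Element-length bounds: helices 4-15 residues, strands 2-8; the total
# structured content (H+E residues) must stay within [20, 45].
HELIX_BOUNDS = (4, 15)
STRAND_BOUNDS = (2, 8)
STRUCTURED_BOUNDS = (20, 45)

# Minimal all-coil window needed to insert a minimal element with a coil
# residue kept on both flanks: C+HHHH+C and C+EE+C.
_HELIX_SEED = 4
_STRAND_SEED = 2

# Endpoint secondary-structure strings for the B1 domain of protein G (1PGB)
# and chain X of the 2GYC ribosome complex, both rendered at the shared
# length 56.  Element types and lengths follow the published assignments
# (1PGB: E7 E7 H15 E5 E5; 2GYC: E5 H8 E4 H7 E2); coil gaps are laid out so
# that no position carries a helix in one endpoint and a strand in the
# other, which keeps every elementary move on a parsimonious path strictly
# productive.
SS_1PGB = "C" + "E" * 7 + "C" * 9 + "E" * 7 + "C" + "H" * 15 + "CC" + "E" * 5 + "CC" + "E" * 5 + "CC"
SS_2GYC = "CC" + "E" * 5 + "C" + "H" * 8 + "C" + "E" * 4 + "CCCC" + "H" * 7 + "C" * 20 + "EE" + "CC"

assert len(SS_1PGB) == len(SS_2GYC) == 56


@dataclass(frozen=True, order=True)
class SSElement:
    """One maximal structured run: half-open interval [start, end)."""

    kind: str  # 'H' or 'E'
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Violation:
    rule: str
    position: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] at {self.position}: {self.message}"


@dataclass(frozen=True)
class ElementMapping:
    """An order- and type-preserving partial matching of internal elements.

    ``pairs`` maps source element indices to target element indices (full
    element numbering, 0-based); the terminal strands are always matched to
    each other and recorded in ``fixed_terminals``.  Unmatched source
    elements disappear along the path, unmatched target elements are
    created, matched elements move/morph.
    """

    pairs: tuple[tuple[int, int], ...]
    fixed_terminals: tuple[tuple[int, int], tuple[int, int]]

    def moved_source(self) -> frozenset[int]:
        return frozenset(i for i, _ in self.pairs)

    def moved_target(self) -> frozenset[int]:
        return frozenset(j for _, j in self.pairs)


@dataclass(frozen=True)
class Move:
    kind: str  # 'lengthen' | 'shorten' | 'insert' | 'delete'
    element_kind: str
    position: int  # leftmost modified index

    def describe(self) -> str:
        return f"{self.kind}:{self.element_kind}@{self.position}"


@dataclass
class SSPath:
    """A realized move-by-move path; ``states[0]`` is the source string."""

    states: list[str]
    moves: list[Move]
    mapping: ElementMapping | None = None
    distances: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.moves)


class PathDeadEndError(RuntimeError):
    """No strictly distance-decreasing legal move, but target not reached."""

    def __init__(self, stuck: str, target: str):
        self.stuck = stuck
        self.target = target
        super().__init__(
            f"dead end at distance {ss_distance(stuck, target)}: {stuck!r}"
        )


def _check_alphabet(ss: str) -> None:
    for i, ch in enumerate(ss):
        if ch not in ALPHABET:
            raise ValueError(f"illegal character {ch!r} at position {i}; alphabet is H/E/C")


def parse_elements(ss: str) -> list[SSElement]:
    """Maximal H/E runs in left-to-right order."""
    _check_alphabet(ss)
    out: list[SSElement] = []
    i = 0
    n = len(ss)
    while i < n:
        if ss[i] == "C":
            i += 1
            continue
        j = i
        while j < n and ss[j] == ss[i]:
            j += 1
        out.append(SSElement(ss[i], i, j))
        i = j
    return out


def validate(ss: str) -> list[Violation]:
    """Rule violations: element-length bounds, element separation and total
    structured content.  Empty list means the string is legal."""
    _check_alphabet(ss)
    violations: list[Violation] = []
    elements = parse_elements(ss)
    for el in elements:
        lo, hi = HELIX_BOUNDS if el.kind == "H" else STRAND_BOUNDS
        if not lo <= el.length <= hi:
            violations.append(
                Violation(
                    "element-length",
                    el.start,
                    f"{el.kind}-run of length {el.length} outside [{lo}, {hi}]",
                )
            )
    for a, b in itertools.pairwise(elements):
        if a.end == b.start:
            violations.append(
                Violation(
                    "separation",
                    b.start,
                    f"{a.kind}-run touches {b.kind}-run with no coil between",
                )
            )
    total = sum(el.length for el in elements)
    lo, hi = STRUCTURED_BOUNDS
    if not lo <= total <= hi:
        violations.append(
            Violation(
                "structured-total",
                0,
                f"{total} structured residues outside [{lo}, {hi}]",
            )
        )
    return violations


def is_valid(ss: str) -> bool:
    return not validate(ss)


def ss_distance(a: str, b: str) -> int:
    """Per-position mismatch count over {H, E, C}."""
    if len(a) != len(b):
        raise ValueError("SS strings must share one length")
    return sum(x != y for x, y in zip(a, b))


def _candidate_moves(ss: str) -> list[tuple[Move, str]]:
    """All elementary edits; legality is filtered by the caller."""
    n = len(ss)
    chars = list(ss)
    out: list[tuple[Move, str]] = []
    elements = parse_elements(ss)

    def rebuild(pos: int, repl: str) -> str:
        return "".join(chars[:pos]) + repl + "".join(chars[pos + len(repl):])

    for el in elements:
        # lengthen by one residue on either flank
        if el.start - 1 >= 0 and ss[el.start - 1] == "C":
            out.append((Move("lengthen", el.kind, el.start - 1), rebuild(el.start - 1, el.kind)))
        if el.end < n and ss[el.end] == "C":
            out.append((Move("lengthen", el.kind, el.end), rebuild(el.end, el.kind)))
        # shorten by one residue at either end
        out.append((Move("shorten", el.kind, el.start), rebuild(el.start, "C")))
        if el.length > 1:
            out.append((Move("shorten", el.kind, el.end - 1), rebuild(el.end - 1, "C")))
        # delete a minimal element outright
        minimal = _HELIX_SEED if el.kind == "H" else _STRAND_SEED
        if el.length == minimal:
            out.append((Move("delete", el.kind, el.start), rebuild(el.start, "C" * el.length)))

    # insert a minimal element into an all-coil window, coil kept on both flanks
    for kind, seed in (("H", _HELIX_SEED), ("E", _STRAND_SEED)):
        window = seed + 2
        for p in range(0, n - window + 1):
            if all(c == "C" for c in ss[p : p + window]):
                out.append((Move("insert", kind, p + 1), rebuild(p + 1, kind * seed)))
    return out


def enumerate_moves(ss: str, target: str | None = None) -> list[tuple[Move, str]]:
    """Legal single moves from ``ss``; with a target, only moves that
    strictly decrease the mismatch distance to it."""
    report = validate(ss)
    if report:
        raise ValueError("invalid SS string: " + "; ".join(map(str, report)))
    if target is not None and len(target) != len(ss):
        raise ValueError("target length mismatch")
    moves = [(m, s) for m, s in _candidate_moves(ss) if is_valid(s)]
    if target is not None:
        d0 = ss_distance(ss, target)
        moves = [(m, s) for m, s in moves if ss_distance(s, target) < d0]
    return moves


def _internal_matchings(src_kinds: list[str], dst_kinds: list[str]):
    """All injective, type- and order-preserving partial matchings."""
    ns, nd = len(src_kinds), len(dst_kinds)

    def rec(i: int, j_min: int):
        if i == ns:
            yield ()
            return
        # source element i unmatched
        yield from rec(i + 1, j_min)
        for j in range(j_min, nd):
            if src_kinds[i] == dst_kinds[j]:
                for rest in rec(i + 1, j + 1):
                    yield ((i, j),) + rest

    return list(rec(0, 0))


def enumerate_pathways(src: str, dst: str) -> list[ElementMapping]:
    """Parsimonious element correspondences between two endpoints.

    The first and last strand of the source stay the first and last strand
    of the target; every injective, type-preserving, order-preserving
    partial matching of the remaining internal elements is one pathway.
    """
    es, ed = parse_elements(src), parse_elements(dst)
    for name, els in (("source", es), ("destination", ed)):
        if len(els) < 2 or els[0].kind != "E" or els[-1].kind != "E":
            raise ValueError(f"{name} endpoint lacks terminal beta strands")
    src_internal = [el.kind for el in es[1:-1]]
    dst_internal = [el.kind for el in ed[1:-1]]
    terminals = ((0, 0), (len(es) - 1, len(ed) - 1))
    mappings = []
    for match in _internal_matchings(src_internal, dst_internal):
        pairs = tuple((i + 1, j + 1) for i, j in match)  # full-element indices
        mappings.append(ElementMapping(pairs=pairs, fixed_terminals=terminals))
    return mappings


def build_path(
    src: str,
    dst: str,
    mapping: ElementMapping | None = None,
    rng_seed: int = 0,
) -> SSPath:
    """Greedy seeded walk from ``src`` to ``dst`` through legal moves.

    Each step applies one uniformly random choice among the moves that
    strictly decrease the mismatch distance to the destination; the walk
    therefore terminates in at most ``ss_distance(src, dst)`` moves or
    raises :class:`PathDeadEndError`.
    """
    for name, s in (("source", src), ("destination", dst)):
        report = validate(s)
        if report:
            raise ValueError(f"invalid {name} string: " + "; ".join(map(str, report)))
    rng = np.random.default_rng(rng_seed)
    states = [src]
    moves: list[Move] = []
    distances = [ss_distance(src, dst)]
    current = src
    while current != dst:
        options = enumerate_moves(current, target=dst)
        if not options:
            raise PathDeadEndError(current, dst)
        move, nxt = options[rng.integers(len(options))]
        moves.append(move)
        states.append(nxt)
        distances.append(ss_distance(nxt, dst))
        current = nxt
    return SSPath(states=states, moves=moves, mapping=mapping, distances=distances)
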