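"""KEGG MODULE definition grammar: parsing and alternative enumeration.

A KEGG module is a functional unit of enzymes described by a logical
DEFINITION expression over KEGG ORTHOLOGY (KO) terms.  Four couplings occur
in such expressions:

* whitespace between top-level terms separates *steps* of the pathway
  (logical AND);
* ``+`` joins required components of a molecular complex (AND);
* ``,`` separates alternative ways to perform the same step (OR);
* ``-`` marks the following component as optional.

An *alternative* is a minimal KO set that realizes every step of the module
in exactly one way.  A genome has a *complete* module iff it carries all KOs
of at least one alternative.

Operator precedence, loosest to tightest: space (step AND), comma (OR),
``+``/``-`` (complex).  ``A B,C`` therefore reads "A and then (B or C)".
The gap token ``--`` denotes an uncharacterized step; it is satisfied by any
genome and contributes no KOs.  Optional (``-``-marked) components are never
required and never counted as missing.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ModuleDefinition",
    "Alternative",
    "ModuleParseError",
    "AlternativeExplosionError",
    "parse_module_definition",
    "enumerate_alternatives",
    "completed_alternatives",
    "is_complete",
    "DEFAULT_ALTERNATIVE_CAP",
]

#: Largest number of alternatives enumerated before raising; the biggest
#: module observed in practice (glycolysis) has 13,440, so 50,000 leaves
#: headroom while still catching pathological expressions.
DEFAULT_ALTERNATIVE_CAP = 50_000

_KO_RE = re.compile(r"K\d{5}$")
GAP_TOKEN = "--"


class ModuleParseError(ValueError):
    """Raised when a module definition string cannot be parsed."""


class AlternativeExplosionError(RuntimeError):
    """Raised when the projected alternative count exceeds the cap."""


# ---------------------------------------------------------------------------
# expression tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Expr:
    """Base node of a parsed definition expression."""

    def options(self) -> tuple[frozenset[str], ...]:
        """All distinct KO sets realizing this expression one way."""
        raise NotImplementedError

    def kos(self) -> frozenset[str]:
        """Every KO mentioned in the subtree, optional ones included."""
        raise NotImplementedError


@dataclass(frozen=True)
class Leaf(Expr):
    ko: str

    def options(self) -> tuple[frozenset[str], ...]:
        if self.ko == GAP_TOKEN:
            return (frozenset(),)
        return (frozenset({self.ko}),)

    def kos(self) -> frozenset[str]:
        return frozenset() if self.ko == GAP_TOKEN else frozenset({self.ko})

    def __str__(self) -> str:
        return self.ko


@dataclass(frozen=True)
class Optional_(Expr):
    """A ``-``-marked component: allowed but never required."""

    inner: Expr

    def options(self) -> tuple[frozenset[str], ...]:
        return (frozenset(),)

    def kos(self) -> frozenset[str]:
        return self.inner.kos()

    def __str__(self) -> str:
        inner = str(self.inner)
        if isinstance(self.inner, (And, Or, Complex)):
            inner = f"({inner})"
        return f"-{inner}"


def _product_options(parts: Sequence[Expr]) -> tuple[frozenset[str], ...]:
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    for combo in itertools.product(*(p.options() for p in parts)):
        merged = frozenset().union(*combo)
        if merged not in seen:
            seen.add(merged)
            out.append(merged)
    return tuple(out)


@dataclass(frozen=True)
class And(Expr):
    """Space-joined sub-steps that must all be realized."""

    parts: tuple[Expr, ...]

    def options(self) -> tuple[frozenset[str], ...]:
        return _product_options(self.parts)

    def kos(self) -> frozenset[str]:
        return frozenset().union(*(p.kos() for p in self.parts))

    def __str__(self) -> str:
        return " ".join(_paren(p, for_and=True) for p in self.parts)


@dataclass(frozen=True)
class Or(Expr):
    """Comma-separated alternative ways to perform one step."""

    parts: tuple[Expr, ...]

    def options(self) -> tuple[frozenset[str], ...]:
        seen: set[frozenset[str]] = set()
        out: list[frozenset[str]] = []
        for p in self.parts:
            for opt in p.options():
                if opt not in seen:
                    seen.add(opt)
                    out.append(opt)
        return tuple(out)

    def kos(self) -> frozenset[str]:
        return frozenset().union(*(p.kos() for p in self.parts))

    def __str__(self) -> str:
        return ",".join(_paren(p, for_and=False) for p in self.parts)


@dataclass(frozen=True)
class Complex(Expr):
    """``+``-joined complex whose required members are all needed."""

    parts: tuple[Expr, ...]

    def options(self) -> tuple[frozenset[str], ...]:
        return _product_options(self.parts)

    def kos(self) -> frozenset[str]:
        return frozenset().union(*(p.kos() for p in self.parts))

    def __str__(self) -> str:
        out = []
        for i, p in enumerate(self.parts):
            if isinstance(p, Optional_):
                out.append(str(p))  # '-' already acts as the separator
            elif i == 0:
                out.append(_paren(p, complex_member=True))
            else:
                out.append("+" + _paren(p, complex_member=True))
        return "".join(out)


def _paren(p: Expr, for_and: bool = False, complex_member: bool = False) -> str:
    """Parenthesize a child only where precedence demands it."""
    s = str(p)
    if complex_member and isinstance(p, (And, Or)):
        return f"({s})"
    if isinstance(p, And) and not for_and:
        return f"({s})"
    if isinstance(p, Or):
        return f"({s})"
    return s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleDefinition:
    """A parsed module definition.

    ``steps`` are the top-level AND components of the expression, in order.
    """

    module_id: str
    raw: str
    steps: tuple[Expr, ...]
    name: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ModuleParseError(f"{self.module_id}: definition has no steps")

    def normalized(self) -> str:
        return " ".join(_paren(s, for_and=True) for s in self.steps)

    def kos(self) -> frozenset[str]:
        return frozenset().union(*(s.kos() for s in self.steps))

    def step_options(self) -> tuple[tuple[frozenset[str], ...], ...]:
        return tuple(s.options() for s in self.steps)


@dataclass(frozen=True)
class Alternative:
    """One minimal KO set realizing every step of a module one way.

    ``step_choices`` records the per-step option index used (provenance).
    """

    module_id: str
    ko_set: frozenset[str]
    step_choices: tuple[int, ...] = field(default=(), compare=False)


# ---------------------------------------------------------------------------
# parser (recursive descent on a token stream)
# ---------------------------------------------------------------------------


def _tokenize(raw: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(raw)
    while i < n:
        c = raw[i]
        if c.isspace():
            j = i
            while j < n and raw[j].isspace():
                j += 1
            tokens.append((" ", i))
            i = j
        elif c in "(),+":
            tokens.append((c, i))
            i += 1
        elif c == "-":
            if raw[i : i + 2] == GAP_TOKEN and (
                i + 2 >= n or not raw[i + 2].isalnum()
            ):
                tokens.append((GAP_TOKEN, i))
                i += 2
            else:
                tokens.append(("-", i))
                i += 1
        else:
            j = i
            while j < n and (raw[j].isalnum() or raw[j] in "._:"):
                j += 1
            tokens.append((raw[i:j], i))
            i = j
    return tokens


class _Parser:
    def __init__(self, module_id: str, raw: str) -> None:
        self.module_id = module_id
        self.raw = raw
        self.toks = _tokenize(raw)
        self.pos = 0

    def error(self, msg: str, at: int | None = None) -> ModuleParseError:
        where = self.toks[self.pos][1] if at is None and self.pos < len(self.toks) else at
        return ModuleParseError(
            f"{self.module_id}: {msg} at position {where if where is not None else len(self.raw)}"
        )

    def peek(self) -> str | None:
        return self.toks[self.pos][0] if self.pos < len(self.toks) else None

    def take(self) -> str:
        tok = self.toks[self.pos][0]
        self.pos += 1
        return tok

    # grammar:  expr := and_seq ;  and_seq := or_seq (SPACE or_seq)* ;
    #           or_seq := cplx (',' cplx)* ;
    #           cplx := unit (('+'|'-') unit)* | '-' unit ... ;
    #           unit := KO | '--' | '(' expr ')'
    def parse(self) -> Expr:
        self._skip_space()
        node = self.parse_and()
        self._skip_space()
        if self.peek() is not None:
            if self.peek() == ")":
                raise self.error("unbalanced parentheses: unexpected ')'")
            raise self.error(f"unexpected token {self.peek()!r}")
        return node

    def _skip_space(self) -> None:
        while self.peek() == " ":
            self.pos += 1

    def parse_and(self) -> Expr:
        parts = [self.parse_or()]
        while True:
            save = self.pos
            if self.peek() != " ":
                break
            self._skip_space()
            if self.peek() is None or self.peek() == ")":
                self.pos = save
                break
            parts.append(self.parse_or())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_or(self) -> Expr:
        parts = [self.parse_complex()]
        while self.peek() == ",":
            self.take()
            self._skip_space()
            parts.append(self.parse_complex())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_complex(self) -> Expr:
        parts: list[Expr] = []
        if self.peek() == "-":  # leading optional member
            self.take()
            parts.append(Optional_(self.parse_unit()))
        else:
            parts.append(self.parse_unit())
        while self.peek() in ("+", "-"):
            op = self.take()
            unit = self.parse_unit()
            parts.append(Optional_(unit) if op == "-" else unit)
        return parts[0] if len(parts) == 1 else Complex(tuple(parts))

    def parse_unit(self) -> Expr:
        tok = self.peek()
        if tok is None:
            raise self.error("unexpected end of definition", at=len(self.raw))
        if tok == "(":
            at = self.toks[self.pos][1]
            self.take()
            self._skip_space()
            node = self.parse_and()
            self._skip_space()
            if self.peek() != ")":
                raise self.error("unbalanced parentheses: missing ')'", at=at)
            self.take()
            return node
        tok = self.take()
        if tok == GAP_TOKEN:
            return Leaf(GAP_TOKEN)
        if _KO_RE.match(tok):
            return Leaf(tok)
        raise self.error(f"token {tok!r} is not a KO identifier or gap token")


def parse_module_definition(
    module_id: str, raw: str, *, name: str = "", category: str = ""
) -> ModuleDefinition:
    """Parse a module DEFINITION string into its step expressions.

    Definitions spanning several DEFINITION lines should be joined with a
    single space before calling (see :func:`crossnet.io.read_module_table`).

    Raises
    ------
    ModuleParseError
        On empty input, unbalanced parentheses, or tokens that are neither
        KO identifiers (``K`` + 5 digits) nor the gap token ``--``.
    """
    if not raw or not raw.strip():
        raise ModuleParseError(f"{module_id}: empty definition")
    tree = _Parser(module_id, raw.strip()).parse()
    steps = tree.parts if isinstance(tree, And) else (tree,)
    return ModuleDefinition(
        module_id=module_id, raw=raw, steps=steps, name=name, category=category
    )


# ---------------------------------------------------------------------------
# enumeration and completion
# ---------------------------------------------------------------------------


def projected_alternative_count(definition: ModuleDefinition) -> int:
    """Upper bound on the alternative count: product of per-step option counts."""
    n = 1
    for opts in definition.step_options():
        n *= len(opts)
    return n


def enumerate_alternatives(
    definition: ModuleDefinition, cap: int = DEFAULT_ALTERNATIVE_CAP
) -> tuple[Alternative, ...]:
    """Enumerate every alternative (minimal one-way-per-step KO set).

    The Cartesian product over per-step options is taken; within an option,
    complex members are all required and optional members are dropped.
    Alternatives with identical KO sets are collapsed (the first step-choice
    tuple encountered is kept as provenance).

    Raises
    ------
    AlternativeExplosionError
        If the projected count (product of per-step option counts) exceeds
        ``cap``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    projected = projected_alternative_count(definition)
    if projected > cap:
        raise AlternativeExplosionError(
            f"{definition.module_id}: projected {projected} alternatives "
            f"exceeds cap {cap}"
        )
    per_step = definition.step_options()
    seen: dict[frozenset[str], tuple[int, ...]] = {}
    for choices in itertools.product(*(range(len(o)) for o in per_step)):
        ko_set = frozenset().union(
            *(per_step[i][c] for i, c in enumerate(choices))
        )
        if ko_set not in seen:
            seen[ko_set] = choices
    return tuple(
        Alternative(definition.module_id, ko_set, choices)
        for ko_set, choices in seen.items()
    )


def completed_alternatives(
    genome_kos: Iterable[str], alternatives: Iterable[Alternative]
) -> list[Alternative]:
    """Alternatives whose KO set is fully contained in ``genome_kos``.

    The module is *complete* for the genome iff the result is nonempty.
    """
    kos = frozenset(genome_kos)
    return [alt for alt in alternatives if alt.ko_set <= kos]


def is_complete(genome_kos: Iterable[str], alternatives: Iterable[Alternative]) -> bool:
    kos = frozenset(genome_kos)
    return any(alt.ko_set <= kos for alt in alternatives)
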