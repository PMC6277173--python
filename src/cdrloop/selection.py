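"""Atom-selection expressions.

A small declarative grammar resolves to an ordered atom-index set on a
topology.  It is deliberately minimal — enough to express the selections the
analyses need, e.g. the CDRh3 loop (``"chain H and resi 95-102"``) or a
framework backbone fit region (``"(resi 90-94 or resi 103-107) and name
N,CA,C"``).

EBNF (also documented in the README)::

    selection := or_expr
    or_expr   := and_expr { "or" and_expr }
    and_expr  := unary { "and" unary }
    unary     := "not" unary | "(" selection ")" | term
    term      := "all" | "none"
               | "chain" idlist
               | "resi"  rangelist
               | "resn"  idlist
               | "name"  idlist
    idlist    := ID { "," ID }
    rangelist := resrange { "," resrange }
    resrange  := RESID [ "-" RESID ]
    RESID     := INT [ ICODE ]          (e.g. 102, 100a)

Residue identifiers with insertion codes compare as ``(number, code)`` pairs
with the blank code sorting before ``a`` (Kabat convention: 100 < 100a <
100b < 101); ranges are inclusive at both ends.  ``resn`` and ``name``
match case-insensitively; ``chain`` matches exactly.  Resolution is
deterministic and returns indices in topology order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Atom, SelectionError

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_RESID_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")

_KEYWORDS = {"and", "or", "not", "chain", "resi", "resn", "name", "all", "none"}


@dataclass(frozen=True)
class Selection:
    """A resolved selection: the expression plus ordered topology indices."""

    expression: str
    indices: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "indices", np.asarray(self.indices, dtype=np.intp)
        )


def _parse_resid(token: str, pos: int) -> tuple[int, str]:
    m = _RESID_RE.match(token)
    if not m:
        raise SelectionError(
            f"invalid residue identifier {token!r} at position {pos}"
        )
    return int(m.group(1)), m.group(2).lower()


class _Parser:
    """Recursive-descent parser producing a boolean mask over the topology."""

    def __init__(self, expression: str, topology: list[Atom]):
        self.expression = expression
        self.topology = topology
        self.tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]
        self.i = 0
        # per-atom lookup columns
        self.chains = np.array([a.chain_id for a in topology])
        self.resnames = np.array([a.residue_name.upper() for a in topology])
        self.names = np.array([a.atom_name.upper() for a in topology])
        self.resids = [(a.residue_number, a.insertion_code.lower()) for a in topology]

    # -- token helpers -------------------------------------------------
    def _peek(self) -> tuple[str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        tok = self._peek()
        if tok is None:
            raise SelectionError(
                f"unexpected end of selection expression {self.expression!r}"
            )
        self.i += 1
        return tok

    # -- grammar -------------------------------------------------------
    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression")
        mask = self._or_expr()
        if self._peek() is not None:
            tok, pos = self._peek()
            raise SelectionError(
                f"unexpected token {tok!r} at position {pos} in {self.expression!r}"
            )
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek() is not None and self._peek()[0].lower() == "or":
            self._next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._unary()
        while self._peek() is not None and self._peek()[0].lower() == "and":
            self._next()
            mask = mask & self._unary()
        return mask

    def _unary(self) -> np.ndarray:
        tok = self._peek()
        if tok is None:
            raise SelectionError(
                f"unexpected end of selection expression {self.expression!r}"
            )
        word, pos = tok
        low = word.lower()
        if low == "not":
            self._next()
            return ~self._unary()
        if word == "(":
            self._next()
            mask = self._or_expr()
            closing = self._peek()
            if closing is None or closing[0] != ")":
                raise SelectionError(
                    f"missing ')' for '(' at position {pos} in {self.expression!r}"
                )
            self._next()
            return mask
        return self._term()

    def _term(self) -> np.ndarray:
        word, pos = self._next()
        low = word.lower()
        n = len(self.topology)
        if low == "all":
            return np.ones(n, dtype=bool)
        if low == "none":
            return np.zeros(n, dtype=bool)
        if low in ("chain", "resn", "name", "resi"):
            arg_tok = self._peek()
            if arg_tok is None or arg_tok[0].lower() in _KEYWORDS or arg_tok[0] in "()":
                raise SelectionError(
                    f"keyword {word!r} at position {pos} needs an argument list"
                )
            arg, arg_pos = self._next()
            if low == "chain":
                values = set(arg.split(","))
                return np.isin(self.chains, sorted(values))
            if low == "resn":
                values = {v.upper() for v in arg.split(",")}
                return np.isin(self.resnames, sorted(values))
            if low == "name":
                values = {v.upper() for v in arg.split(",")}
                return np.isin(self.names, sorted(values))
            # resi: comma list of single ids or inclusive ranges
            mask = np.zeros(n, dtype=bool)
            for part in arg.split(","):
                if "-" in part[1:]:  # allow a leading minus sign
                    split_at = part.index("-", 1)
                    lo = _parse_resid(part[:split_at], arg_pos)
                    hi = _parse_resid(part[split_at + 1 :], arg_pos)
                else:
                    lo = hi = _parse_resid(part, arg_pos)
                if lo > hi:
                    raise SelectionError(
                        f"empty residue range {part!r} at position {arg_pos}"
                    )
                for i, rid in enumerate(self.resids):
                    if lo <= rid <= hi:
                        mask[i] = True
            return mask
        raise SelectionError(
            f"unexpected token {word!r} at position {pos} in {self.expression!r}"
        )


def resolve_selection(
    expression: str,
    topology: list[Atom],
    *,
    allow_empty: bool = True,
) -> Selection:
    """Resolve ``expression`` to an ordered index set on ``topology``.

    Resolution is idempotent and order-stable: indices come out in topology
    order.  An empty result triggers a warning (or, with
    ``allow_empty=False``, a :class:`SelectionError`) — a chain or residue
    absent from the topology is not a syntax error.
    """
    mask = _Parser(expression, topology).parse()
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        if not allow_empty:
            raise SelectionError(f"selection {expression!r} matched no atoms")
        warnings.warn(
            f"selection {expression!r} matched no atoms", stacklevel=2
        )
    return Selection(expression=expression, indices=indices)
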