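"""Expression trees for continuous and discretized model equations.

Every later stage of the code generator manipulates these trees: the model
parser produces continuous equations over bare variable references and
partial-derivative operators; the discretizer rewrites them into indexed
discrete terms such as ``V[n+1, j-1]``; instantiation replaces symbolic
spatial indices with concrete node coordinates.

Trees are immutable (frozen dataclasses), so structural equality and hashing
come for free and substitution never mutates its input.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Tuple, Union


class ExpressionError(ValueError):
    """Malformed expression source or ill-formed tree."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Expr:
    """Base class for all expression nodes."""

    def children(self) -> Tuple["Expr", ...]:
        return ()


@dataclass(frozen=True)
class Num(Expr):
    value: float

    def __post_init__(self):
        object.__setattr__(self, "value", float(self.value))


@dataclass(frozen=True)
class Idx:
    """A symbolic index expression ``base + offset`` (e.g. ``n+1``, ``j-1``).

    ``base`` names an index variable.  Concrete (instantiated) indices are
    stored as plain ``int`` entries in ``Var.indices`` instead of ``Idx``.
    """

    base: str
    offset: int = 0


IndexEntry = Union[Idx, int]


@dataclass(frozen=True)
class Var(Expr):
    """A variable reference, optionally indexed.

    ``indices is None`` for continuous (undiscretized) references.  After
    discretization the tuple holds one entry per dimension, time first.
    Distributed parameters carry spatial indices only.
    """

    name: str
    indices: Optional[Tuple[IndexEntry, ...]] = None


@dataclass(frozen=True)
class BinOp(Expr):
    op: str  # one of + - * / ^
    left: Expr
    right: Expr

    def children(self):
        return (self.left, self.right)


@dataclass(frozen=True)
class Neg(Expr):
    operand: Expr

    def children(self):
        return (self.operand,)


@dataclass(frozen=True)
class Deriv(Expr):
    """Partial-derivative operator ∂^k(arg)/∂dim^k.

    ``direction`` is an optional one-sided tag ('-' or '+') used only in
    boundary-condition templates (a left or right one-sided derivative).
    """

    arg: Expr
    dim: str
    order: int = 1
    direction: Optional[str] = None

    def __post_init__(self):
        if self.order < 1:
            raise ExpressionError(f"derivative order must be >= 1, got {self.order}")
        if self.direction not in (None, "-", "+"):
            raise ExpressionError(f"bad derivative direction {self.direction!r}")

    def children(self):
        return (self.arg,)


@dataclass(frozen=True)
class Compare(Expr):
    op: str  # < <= > >= ==
    left: Expr
    right: Expr

    def children(self):
        return (self.left, self.right)


@dataclass(frozen=True)
class And(Expr):
    left: Expr
    right: Expr

    def children(self):
        return (self.left, self.right)


@dataclass(frozen=True)
class Piecewise(Expr):
    """Conditional expression: ordered (condition, value) branches plus default."""

    branches: Tuple[Tuple[Expr, Expr], ...]
    default: Expr

    def children(self):
        out = []
        for cond, val in self.branches:
            out.extend((cond, val))
        out.append(self.default)
        return tuple(out)


# ---------------------------------------------------------------------------
# tree utilities
# ---------------------------------------------------------------------------

def walk(e: Expr) -> Iterator[Expr]:
    """Pre-order traversal of every node in the tree."""
    yield e
    for c in e.children():
        yield from walk(c)


def map_children(e: Expr, f) -> Expr:
    """Rebuild ``e`` with ``f`` applied to each child; returns ``e`` itself
    when nothing changed (preserves sharing)."""
    if isinstance(e, BinOp):
        l, r = f(e.left), f(e.right)
        return e if (l is e.left and r is e.right) else BinOp(e.op, l, r)
    if isinstance(e, Neg):
        o = f(e.operand)
        return e if o is e.operand else Neg(o)
    if isinstance(e, Deriv):
        a = f(e.arg)
        return e if a is e.arg else Deriv(a, e.dim, e.order, e.direction)
    if isinstance(e, Compare):
        l, r = f(e.left), f(e.right)
        return e if (l is e.left and r is e.right) else Compare(e.op, l, r)
    if isinstance(e, And):
        l, r = f(e.left), f(e.right)
        return e if (l is e.left and r is e.right) else And(l, r)
    if isinstance(e, Piecewise):
        branches = tuple((f(c), f(v)) for c, v in e.branches)
        default = f(e.default)
        if default is e.default and all(
            b[0] is c and b[1] is v for b, (c, v) in zip(branches, e.branches)
        ):
            return e
        return Piecewise(branches, default)
    return e


def free_variables(e: Expr) -> set:
    """Names referenced anywhere in the tree.

    Includes derivative dimension symbols and symbolic index bases, since both
    are names the surrounding context must declare.
    """
    names = set()
    for node in walk(e):
        if isinstance(node, Var):
            names.add(node.name)
            if node.indices:
                for ix in node.indices:
                    if isinstance(ix, Idx):
                        names.add(ix.base)
        elif isinstance(node, Deriv):
            names.add(node.dim)
    return names


def substitute(e: Expr, pattern: Expr, replacement: Expr) -> Expr:
    """Replace every subtree structurally equal to ``pattern``.

    Non-matching subtrees are returned untouched; the input is never mutated.
    """
    if e == pattern:
        return replacement
    return map_children(e, lambda c: substitute(c, pattern, replacement))


def substitute_many(e: Expr, mapping: Mapping[Expr, Expr]) -> Expr:
    """Simultaneous substitution: each subtree is matched against all patterns
    once, so replacements are never re-examined against the other patterns."""
    if e in mapping:
        return mapping[e]
    return map_children(e, lambda c: substitute_many(c, mapping))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?"
    r"|\d+[eE][+-]?\d+|\d+)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|==|[-+*/^()\[\],:=<>]))"
)

_RELOPS = ("<", "<=", ">", ">=", "==")


def tokenize(text: str, line: Optional[int] = None):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise ExpressionError(f"unexpected character {text[pos]!r}", line)
            break
        if m.lastgroup == "num":
            tokens.append(("num", m.group("num")))
        elif m.lastgroup == "name":
            tokens.append(("name", m.group("name")))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    return tokens


_DERIV_NAME = re.compile(r"^d(\d*)$")


class Parser:
    """Recursive-descent / precedence-climbing parser for the compact dialect."""

    def __init__(self, tokens, line: Optional[int] = None):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    # -- token helpers ----------------------------------------------------
    def peek(self, k=0):
        i = self.pos + k
        return self.tokens[i] if i < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, kind, value=None):
        tk, tv = self.next()
        if tk != kind or (value is not None and tv != value):
            raise ExpressionError(
                f"expected {value or kind}, got {tv!r}", self.line
            )
        return tv

    def at_op(self, *ops):
        tk, tv = self.peek()
        return tk == "op" and tv in ops

    def fail(self, msg):
        raise ExpressionError(msg, self.line)

    # -- grammar ----------------------------------------------------------
    def parse_expression(self) -> Expr:
        e = self.additive()
        return e

    def additive(self) -> Expr:
        e = self.multiplicative()
        while self.at_op("+", "-"):
            op = self.next()[1]
            e = BinOp(op, e, self.multiplicative())
        return e

    def multiplicative(self) -> Expr:
        e = self.unary()
        while self.at_op("*", "/"):
            op = self.next()[1]
            e = BinOp(op, e, self.unary())
        return e

    def unary(self) -> Expr:
        if self.at_op("-"):
            self.next()
            return Neg(self.unary())
        if self.at_op("+"):
            self.next()
            return self.unary()
        return self.power()

    def power(self) -> Expr:
        base = self.atom()
        if self.at_op("^"):
            self.next()
            return BinOp("^", base, self.unary())
        return base

    def atom(self) -> Expr:
        tk, tv = self.peek()
        if tk == "num":
            self.next()
            return Num(float(tv))
        if tk == "op" and tv == "(":
            self.next()
            e = self.parse_expression()
            self.expect("op", ")")
            return e
        if tk == "name":
            m = _DERIV_NAME.match(tv)
            if m and self.peek(1) == ("op", "("):
                return self.derivative(int(m.group(1) or "1"))
            if tv == "piecewise" and self.peek(1) == ("op", "("):
                return self.piecewise()
            return self.variable()
        self.fail(f"unexpected token {tv!r}")

    def variable(self) -> Expr:
        name = self.expect("name")
        if not self.at_op("["):
            return Var(name)
        self.next()
        indices = [self.index_entry()]
        while self.at_op(","):
            self.next()
            indices.append(self.index_entry())
        self.expect("op", "]")
        return Var(name, tuple(indices))

    def index_entry(self) -> IndexEntry:
        tk, tv = self.peek()
        neg = False
        if tk == "op" and tv == "-":
            self.next()
            neg = True
            tk, tv = self.peek()
        if tk == "num":
            self.next()
            v = int(tv)
            return -v if neg else v
        if tk == "name" and not neg:
            self.next()
            off = 0
            if self.at_op("+", "-"):
                sign = 1 if self.next()[1] == "+" else -1
                off = sign * int(self.expect("num"))
            return Idx(tv, off)
        self.fail(f"bad index entry near {tv!r}")

    def derivative(self, order: int) -> Expr:
        self.next()  # the 'd'/'dk' name
        self.expect("op", "(")
        arg = self.parse_expression()
        direction = None
        if self.at_op(","):
            self.next()
            tk, tv = self.next()
            if tk != "op" or tv not in ("-", "+"):
                self.fail("derivative direction must be '-' or '+'")
            direction = tv
        self.expect("op", ")")
        self.expect("op", "/")
        dname = self.expect("name")
        if not _DERIV_NAME.match(dname):
            self.fail(f"expected 'd(dim)' denominator, got {dname!r}")
        self.expect("op", "(")
        dim = self.expect("name")
        self.expect("op", ")")
        # optional trailing order digit, as in d2(V)/d(x)2
        tk, tv = self.peek()
        if tk == "num":
            self.next()
            if int(tv) != order:
                self.fail(f"derivative order mismatch: d{order} vs exponent {tv}")
        return Deriv(arg, dim, order, direction)

    def piecewise(self) -> Expr:
        self.next()  # 'piecewise'
        self.expect("op", "(")
        branches = []
        default = None
        while True:
            tk, tv = self.peek()
            if tk == "name" and tv == "otherwise":
                self.next()
                self.expect("op", ":")
                default = self.parse_expression()
                break
            cond = self.condition()
            self.expect("op", ":")
            branches.append((cond, self.parse_expression()))
            if self.at_op(","):
                self.next()
                continue
            break
        if default is None:
            self.fail("piecewise requires an 'otherwise' branch")
        self.expect("op", ")")
        return Piecewise(tuple(branches), default)

    def condition(self) -> Expr:
        """A single comparison or a chained one (``0 <= t <= 10``)."""
        operands = [self.additive()]
        ops = []
        while self.at_op(*_RELOPS):
            ops.append(self.next()[1])
            operands.append(self.additive())
        if not ops:
            self.fail("expected a comparison in piecewise condition")
        cond = Compare(ops[0], operands[0], operands[1])
        for i in range(1, len(ops)):
            cond = And(cond, Compare(ops[i], operands[i], operands[i + 1]))
        return cond


def parse_expression(text: str, line: Optional[int] = None) -> Expr:
    p = Parser(tokenize(text, line), line)
    e = p.parse_expression()
    if p.pos != len(p.tokens):
        p.fail(f"trailing input after expression: {p.peek()[1]!r}")
    return e


def parse_condition(text: str, line: Optional[int] = None) -> Expr:
    p = Parser(tokenize(text, line), line)
    e = p.condition()
    if p.pos != len(p.tokens):
        p.fail("trailing input after condition")
    return e


# ---------------------------------------------------------------------------
# serialization (canonical form; parse(to_text(e)) == e)
# ---------------------------------------------------------------------------

_PREC = {"+": 1, "-": 1, "*": 2, "/": 2, "^": 4}


def _num_text(v: float) -> str:
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def _index_text(ix: IndexEntry) -> str:
    if isinstance(ix, int):
        return str(ix)
    if ix.offset == 0:
        return ix.base
    return f"{ix.base}{'+' if ix.offset > 0 else '-'}{abs(ix.offset)}"


def to_text(e: Expr, _parent_prec: int = 0) -> str:
    if isinstance(e, Num):
        s = _num_text(e.value)
        return f"({s})" if e.value < 0 and _parent_prec > 0 else s
    if isinstance(e, Var):
        if e.indices is None:
            return e.name
        return f"{e.name}[{', '.join(_index_text(i) for i in e.indices)}]"
    if isinstance(e, Neg):
        s = f"-{to_text(e.operand, 3)}"
        return f"({s})" if _parent_prec >= 2 else s
    if isinstance(e, BinOp):
        prec = _PREC[e.op]
        left = to_text(e.left, prec if e.op != "^" else prec + 1)
        # - and / are left-associative: right operand binds one level tighter
        rprec = prec + (1 if e.op in ("-", "/") else 0)
        right = to_text(e.right, rprec if e.op != "^" else prec)
        s = f"{left}{e.op}{right}" if e.op == "^" else f"{left} {e.op} {right}"
        return f"({s})" if prec < _parent_prec else s
    if isinstance(e, Deriv):
        tag = f", {e.direction}" if e.direction else ""
        k = "" if e.order == 1 else str(e.order)
        ksuf = "" if e.order == 1 else str(e.order)
        return f"d{k}({to_text(e.arg)}{tag})/d({e.dim}){ksuf}"
    if isinstance(e, Compare):
        return f"{to_text(e.left, 1)} {e.op} {to_text(e.right, 1)}"
    if isinstance(e, And):
        # re-chain: And(Compare(a,b), Compare(b,c)) -> "a op b op c"
        left, right = e.left, e.right
        if (
            isinstance(left, Compare)
            and isinstance(right, Compare)
            and left.right == right.left
        ):
            return (
                f"{to_text(left.left, 1)} {left.op} {to_text(left.right, 1)} "
                f"{right.op} {to_text(right.right, 1)}"
            )
        chained = to_text(left)
        if isinstance(right, Compare) and chained.endswith(to_text(right.left, 1)):
            return f"{chained} {right.op} {to_text(right.right, 1)}"
        raise ExpressionError("cannot serialize non-chained conjunction")
    if isinstance(e, Piecewise):
        parts = [f"{to_text(c)}: {to_text(v)}" for c, v in e.branches]
        parts.append(f"otherwise: {to_text(e.default)}")
        return f"piecewise({', '.join(parts)})"
    raise ExpressionError(f"cannot serialize node {e!r}")


# convenience constructors used throughout the package ----------------------

def add(*terms: Expr) -> Expr:
    out = terms[0]
    for t in terms[1:]:
        out = BinOp("+", out, t)
    return out


def sub(a: Expr, b: Expr) -> Expr:
    return BinOp("-", a, b)


def mul(*factors: Expr) -> Expr:
    out = factors[0]
    for f in factors[1:]:
        out = BinOp("*", out, f)
    return out


def div(a: Expr, b: Expr) -> Expr:
    return BinOp("/", a, b)
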