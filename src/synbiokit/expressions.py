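"""Arithmetic expression trees for ODE right-hand sides.

Grammar (whitespace-insensitive)::

    expr   := term (('+'|'-') term)*
    term   := unary (('*'|'/') unary)*
    unary  := '-' unary | power
    power  := atom ('^' unary)?          (right-associative)
    atom   := NUMBER | IDENT | IDENT '(' expr (',' expr)* ')' | '(' expr ')'

Known functions: ``exp``, ``log`` (natural), ``pow(x, y)`` and the Hill
function ``hill(x, K, n) = x^n / (K^n + x^n)``.  Identifiers are validated
against a declared set so a typo is reported with its character position
rather than surfacing as a NameError mid-integration.

Trees evaluate against a name->value environment and serialize to SBML
content MathML; ``hill`` is expanded to its rational form on emission so
the SBML stays within the standard operator set.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from lxml import etree

from synbiokit.errors import SynbioParseError

MATHML_NS = "http://www.w3.org/1998/Math/MathML"

KNOWN_FUNCTIONS = {"exp": 1, "log": 1, "pow": 2, "hill": 3}

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<ident>[A-Za-z_]\w*)"
    r"|(?P<op>[-+*/^(),]))"
)


class Node:
    def eval(self, env: dict[str, float]) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def identifiers(self) -> set[str]:
        return set()


@dataclass(frozen=True)
class Num(Node):
    value: float

    def eval(self, env):
        return self.value


@dataclass(frozen=True)
class Sym(Node):
    name: str

    def eval(self, env):
        return env[self.name]

    def identifiers(self):
        return {self.name}


@dataclass(frozen=True)
class Neg(Node):
    arg: Node

    def eval(self, env):
        return -self.arg.eval(env)

    def identifiers(self):
        return self.arg.identifiers()


@dataclass(frozen=True)
class Bin(Node):
    op: str
    left: Node
    right: Node

    def eval(self, env):
        a, b = self.left.eval(env), self.right.eval(env)
        if self.op == "+":
            return a + b
        if self.op == "-":
            return a - b
        if self.op == "*":
            return a * b
        if self.op == "/":
            return a / b
        return a**b  # '^'

    def identifiers(self):
        return self.left.identifiers() | self.right.identifiers()


@dataclass(frozen=True)
class Call(Node):
    fn: str
    args: tuple[Node, ...]

    def eval(self, env):
        vals = [a.eval(env) for a in self.args]
        if self.fn == "exp":
            return math.exp(vals[0])
        if self.fn == "log":
            return math.log(vals[0])
        if self.fn == "pow":
            return vals[0] ** vals[1]
        # hill(x, K, n) = x^n / (K^n + x^n)
        x, k, n = vals
        xn = x**n
        return xn / (k**n + xn)

    def identifiers(self):
        out: set[str] = set()
        for a in self.args:
            out |= a.identifiers()
        return out


class _Parser:
    def __init__(self, text: str, allowed: set[str] | None):
        self.text = text
        self.allowed = allowed
        self.tokens: list[tuple[str, str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m or m.end() == pos:
                if text[pos:].strip():
                    raise SynbioParseError(
                        f"unexpected character {text[pos:].strip()[0]!r}", column=pos
                    )
                break
            for kind in ("num", "ident", "op"):
                if m.group(kind) is not None:
                    self.tokens.append((kind, m.group(kind), m.start(kind)))
                    break
            pos = m.end()
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else ("eof", "", len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, val, col = self.next()
        if val != value:
            raise SynbioParseError(f"expected {value!r}, found {val or 'end of input'!r}", column=col)

    def parse(self) -> Node:
        node = self.expr()
        kind, val, col = self.peek()
        if kind != "eof":
            raise SynbioParseError(f"trailing input starting at {val!r}", column=col)
        return node

    def expr(self) -> Node:
        node = self.term()
        while self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            node = Bin(op, node, self.term())
        return node

    def term(self) -> Node:
        node = self.unary()
        while self.peek()[1] in ("*", "/"):
            op = self.next()[1]
            node = Bin(op, node, self.unary())
        return node

    def unary(self) -> Node:
        if self.peek()[1] == "-":
            self.next()
            return Neg(self.unary())
        return self.power()

    def power(self) -> Node:
        base = self.atom()
        if self.peek()[1] == "^":
            self.next()
            return Bin("^", base, self.unary())
        return base

    def atom(self) -> Node:
        kind, val, col = self.next()
        if kind == "num":
            return Num(float(val))
        if kind == "ident":
            if self.peek()[1] == "(":
                if val not in KNOWN_FUNCTIONS:
                    raise SynbioParseError(f"unknown function {val!r}", column=col)
                self.next()
                args = [self.expr()]
                while self.peek()[1] == ",":
                    self.next()
                    args.append(self.expr())
                self.expect(")")
                if len(args) != KNOWN_FUNCTIONS[val]:
                    raise SynbioParseError(
                        f"{val} takes {KNOWN_FUNCTIONS[val]} argument(s), got {len(args)}",
                        column=col,
                    )
                return Call(val, tuple(args))
            if self.allowed is not None and val not in self.allowed:
                raise SynbioParseError(f"unknown identifier {val!r}", column=col)
            return Sym(val)
        if val == "(":
            node = self.expr()
            self.expect(")")
            return node
        raise SynbioParseError(f"unexpected token {val or 'end of input'!r}", column=col)


def parse_expression(expr: str, allowed: set[str] | None = None) -> Node:
    """Parse an RHS string; ``allowed`` is the set of legal identifiers
    (variables, parameters and ``t``).  Unknown names raise a parse error
    naming the identifier and its character position."""
    return _Parser(expr, allowed).parse()


# ---------------------------------------------------------------------------
# infix rendering (used when an SBML document is read back into text form)

_PREC = {"+": 1, "-": 1, "*": 2, "/": 2, "^": 3}


def to_infix(node: Node, parent_prec: int = 0) -> str:
    if isinstance(node, Num):
        v = node.value
        return repr(int(v)) if v == int(v) and abs(v) < 1e15 else repr(v)
    if isinstance(node, Sym):
        return node.name
    if isinstance(node, Neg):
        inner = to_infix(node.arg, 4)
        return f"-{inner}" if parent_prec < 2 else f"(-{inner})"
    if isinstance(node, Call):
        return f"{node.fn}({', '.join(to_infix(a) for a in node.args)})"
    assert isinstance(node, Bin)
    p = _PREC[node.op]
    left = to_infix(node.left, p)
    right = to_infix(node.right, p + 1)  # non-associative on the right
    s = f"{left} {node.op} {right}" if node.op != "^" else f"{left}^{right}"
    return f"({s})" if p < parent_prec else s


# ---------------------------------------------------------------------------
# content MathML


def _mm(tag: str, *children, text: str | None = None) -> etree._Element:
    el = etree.Element(f"{{{MATHML_NS}}}{tag}")
    if text is not None:
        el.text = text
    for ch in children:
        el.append(ch)
    return el


def to_mathml(node: Node) -> etree._Element:
    """Content-MathML ``<math>`` element; ``hill`` is expanded to
    ``x^n / (K^n + x^n)`` so only standard operators are emitted."""
    root = _mm("math")
    root.append(_node_to_mathml(node))
    return root


def _node_to_mathml(node: Node) -> etree._Element:
    if isinstance(node, Num):
        v = node.value
        if v == int(v) and abs(v) < 1e15:
            return _mm("cn", text=str(int(v)))
        return _mm("cn", text=repr(v))
    if isinstance(node, Sym):
        return _mm("ci", text=f" {node.name} ")
    if isinstance(node, Neg):
        return _mm("apply", _mm("minus"), _node_to_mathml(node.arg))
    if isinstance(node, Call):
        if node.fn == "hill":
            x, k, n = node.args
            return _node_to_mathml(
                Bin("/", Bin("^", x, n), Bin("+", Bin("^", k, n), Bin("^", x, n)))
            )
        if node.fn == "pow":
            return _mm("apply", _mm("power"), *[_node_to_mathml(a) for a in node.args])
        op = "exp" if node.fn == "exp" else "ln"
        return _mm("apply", _mm(op), _node_to_mathml(node.args[0]))
    assert isinstance(node, Bin)
    opname = {"+": "plus", "-": "minus", "*": "times", "/": "divide", "^": "power"}[node.op]
    return _mm("apply", _mm(opname), _node_to_mathml(node.left), _node_to_mathml(node.right))


def from_mathml(math_el: etree._Element) -> Node:
    """Parse a content-MathML ``<math>`` (or operand) element back to a tree."""
    tag = etree.QName(math_el).localname
    if tag == "math":
        children = [c for c in math_el if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SynbioParseError("<math> must contain exactly one expression")
        return from_mathml(children[0])
    if tag == "cn":
        return Num(float(math_el.text.strip()))
    if tag == "ci":
        return Sym(math_el.text.strip())
    if tag == "apply":
        children = [c for c in math_el if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [from_mathml(c) for c in children[1:]]
        if op == "plus":
            return _fold("+", args) if args else Num(0.0)
        if op == "times":
            return _fold("*", args)
        if op == "minus":
            return Neg(args[0]) if len(args) == 1 else Bin("-", args[0], args[1])
        if op == "divide":
            return Bin("/", args[0], args[1])
        if op == "power":
            return Bin("^", args[0], args[1])
        if op == "exp":
            return Call("exp", (args[0],))
        if op == "ln" or op == "log":
            return Call("log", (args[-1],))
        raise SynbioParseError(f"unsupported MathML operator <{op}>")
    raise SynbioParseError(f"unsupported MathML element <{tag}>")


def _fold(op: str, args: list[Node]) -> Node:
    node = args[0]
    for a in args[1:]:
        node = Bin(op, node, a)
    return node
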