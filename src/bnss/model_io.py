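"""Definition, parsing, validation and serialization of Boolean networks.

A network is declared in a small line-oriented rule language::

    # comment
    A = NOT B
    B = A OR (C AND NOT A)
    C = RANDOM            # free node: fresh Bernoulli(1/2) value each update
    clamp A = True        # hold A at True for the whole simulation

Operator precedence is ``NOT > AND > OR`` (left-associative); operator and
constant keywords are case-insensitive; node identifiers are case-sensitive
and may contain letters, digits, ``_``, ``+`` and ``-`` (so names like
``Ca2+_c`` are legal).  Declaration order of the rules defines node order.
A BoolNet-style ``targets, factors`` dialect (operators ``&``, ``|``, ``!``)
is supported for interoperability, as is a JSON serialization.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

from .errors import (
    ParseError,
    UnknownNodeError,
    UnresolvedVariableError,
    UnsupportedFeatureError,
    ValidationError,
)

__all__ = [
    "Op",
    "RuleExpr",
    "FREE",
    "BooleanNetwork",
    "NetworkState",
    "parse_network",
    "write_network",
    "evaluate_rule",
    "apply_clamp",
    "parse_boolnet",
    "write_boolnet",
    "network_to_json",
    "network_from_json",
]


class Op(str, Enum):
    """Node kinds of a rule expression tree."""

    AND = "AND"
    OR = "OR"
    NOT = "NOT"
    VAR = "VAR"
    CONST = "CONST"


@dataclass(frozen=True)
class RuleExpr:
    """Immutable Boolean expression tree.

    ``NOT`` has exactly one child, ``AND``/``OR`` at least two; ``VAR``
    carries a node name and ``CONST`` a Boolean value.
    """

    op: Op
    children: tuple["RuleExpr", ...] = ()
    name: str | None = None
    value: bool | None = None

    def __post_init__(self) -> None:
        if self.op is Op.VAR:
            if not self.name or self.children:
                raise ValidationError("VAR requires a name and no children")
        elif self.op is Op.CONST:
            if self.value is None or self.children:
                raise ValidationError("CONST requires a value and no children")
        elif self.op is Op.NOT:
            if len(self.children) != 1:
                raise ValidationError("NOT takes exactly one argument")
        elif len(self.children) < 2:
            raise ValidationError(f"{self.op.value} takes at least two arguments")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def var(name: str) -> "RuleExpr":
        return RuleExpr(Op.VAR, name=name)

    @staticmethod
    def const(value: bool) -> "RuleExpr":
        return RuleExpr(Op.CONST, value=bool(value))

    @staticmethod
    def not_(child: "RuleExpr") -> "RuleExpr":
        return RuleExpr(Op.NOT, (child,))

    @staticmethod
    def and_(*children: "RuleExpr") -> "RuleExpr":
        return RuleExpr(Op.AND, tuple(children))

    @staticmethod
    def or_(*children: "RuleExpr") -> "RuleExpr":
        return RuleExpr(Op.OR, tuple(children))

    def variables(self) -> set[str]:
        """Names of all variables referenced in the tree."""
        if self.op is Op.VAR:
            return {self.name}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.variables()
        return out

    def unparse(self, dialect: str = "native") -> str:
        """Render the tree back to rule-language text."""
        return _unparse(self, dialect, parent_prec=0)


class _Free:
    """Singleton marker for free (randomly updated) nodes."""

    _instance: "_Free | None" = None

    def __new__(cls) -> "_Free":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "FREE"


FREE = _Free()


@dataclass(frozen=True)
class BooleanNetwork:
    """A validated Boolean network.

    Attributes
    ----------
    nodes:
        Ordered unique node identifiers; order is declaration order and
        fixes the layout of every state vector.
    rules:
        Mapping node -> :class:`RuleExpr` or the :data:`FREE` marker.
    clamps:
        Mapping node -> Boolean for nodes held fixed.  A clamp takes
        precedence over both the node's rule and FREE status at every
        update, including t = 0.
    """

    nodes: tuple[str, ...]
    rules: Mapping[str, RuleExpr | _Free]
    clamps: Mapping[str, bool] = field(default_factory=dict)
    name: str = "network"

    def __post_init__(self) -> None:
        validate_network(self)

    # -- conveniences ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def free_nodes(self) -> tuple[str, ...]:
        """Free nodes in declaration order (clamped-free nodes included)."""
        return tuple(v for v in self.nodes if self.rules[v] is FREE)

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise UnknownNodeError(f"unknown node {node!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and dict(self.rules) == dict(other.rules)
            and dict(self.clamps) == dict(other.clamps)
        )

    def __hash__(self) -> int:  # rules dict is not hashable; identity is fine
        return id(self)


@dataclass(frozen=True)
class NetworkState:
    """An ordered Boolean vector aligned to ``BooleanNetwork.nodes``."""

    values: tuple[bool, ...]
    t: int = 0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError("update index t must be >= 0")

    def as_mapping(self, network: BooleanNetwork) -> dict[str, bool]:
        if len(self.values) != network.n:
            raise ValidationError("state length does not match network size")
        return dict(zip(network.nodes, self.values))


def validate_network(net: BooleanNetwork) -> None:
    """Raise :class:`ValidationError` unless ``net`` is well formed."""
    if len(net.nodes) == 0:
        raise ValidationError("empty network")
    if len(set(net.nodes)) != len(net.nodes):
        raise ValidationError("duplicate node identifiers")
    if set(net.rules) != set(net.nodes):
        missing = set(net.nodes) ^ set(net.rules)
        raise ValidationError(f"rules do not cover exactly the declared nodes: {sorted(missing)}")
    declared = set(net.nodes)
    for node, rule in net.rules.items():
        if rule is FREE:
            continue
        undefined = rule.variables() - declared
        if undefined:
            raise ValidationError(
                f"rule for {node!r} references undefined node(s) {sorted(undefined)}"
            )
    for node in net.clamps:
        if node not in declared:
            raise ValidationError(f"clamp on undeclared node {node!r}")


# ---------------------------------------------------------------------------
# tokenizer / parser for the native dialect
# ---------------------------------------------------------------------------

_IDENT_RE = re.compile(r"[A-Za-z0-9_+\-]+")
_KEYWORDS = {"AND", "OR", "NOT", "TRUE", "FALSE", "RANDOM"}


def _tokenize(text: str, line_no: int, dialect: str = "native") -> list[str]:
    """Split an expression into identifier / operator / paren tokens."""
    tokens: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(ch)
            i += 1
            continue
        if dialect == "boolnet" and ch in "&|!":
            tokens.append({"&": "AND", "|": "OR", "!": "NOT"}[ch])
            i += 1
            continue
        m = _IDENT_RE.match(text, i)
        if not m:
            raise ParseError(f"unexpected character {ch!r}", line_no)
        tok = m.group(0)
        if dialect == "native" and tok.upper() in _KEYWORDS:
            tok = tok.upper()
        elif dialect == "boolnet" and tok in ("0", "1"):
            tok = {"0": "FALSE", "1": "TRUE"}[tok]
        tokens.append(tok)
        i = m.end()
    return tokens


class _ExprParser:
    """Recursive-descent parser: OR < AND < NOT < atom."""

    def __init__(self, tokens: list[str], line_no: int):
        self.tokens = tokens
        self.pos = 0
        self.line = line_no

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of expression", self.line)
        self.pos += 1
        return tok

    def parse(self) -> RuleExpr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise ParseError(f"trailing tokens starting at {self.peek()!r}", self.line)
        return expr

    def parse_or(self) -> RuleExpr:
        terms = [self.parse_and()]
        while self.peek() == "OR":
            self.take()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else RuleExpr(Op.OR, tuple(terms))

    def parse_and(self) -> RuleExpr:
        terms = [self.parse_not()]
        while self.peek() == "AND":
            self.take()
            terms.append(self.parse_not())
        return terms[0] if len(terms) == 1 else RuleExpr(Op.AND, tuple(terms))

    def parse_not(self) -> RuleExpr:
        if self.peek() == "NOT":
            self.take()
            return RuleExpr.not_(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> RuleExpr:
        tok = self.take()
        if tok == "(":
            inner = self.parse_or()
            if self.take() != ")":
                raise ParseError("missing closing parenthesis", self.line)
            return inner
        if tok == ")":
            raise ParseError("unbalanced ')'", self.line)
        if tok == "TRUE":
            return RuleExpr.const(True)
        if tok == "FALSE":
            return RuleExpr.const(False)
        if tok in ("AND", "OR", "NOT", "RANDOM"):
            raise ParseError(f"misplaced keyword {tok}", self.line)
        return RuleExpr.var(tok)


def _parse_expression(text: str, line_no: int, dialect: str = "native") -> RuleExpr:
    tokens = _tokenize(text, line_no, dialect)
    if not tokens:
        raise ParseError("empty expression", line_no)
    return _ExprParser(tokens, line_no).parse()


def _strip_comment(line: str) -> str:
    idx = line.find("#")
    return line if idx < 0 else line[:idx]


def parse_network(text: str, name: str = "network") -> BooleanNetwork:
    """Parse native rule-file content into a :class:`BooleanNetwork`.

    Declaration order of rules defines node order.  Raises
    :class:`ParseError` on malformed lines and :class:`ValidationError`
    on undefined references, duplicate nodes, or an empty file.
    """
    nodes: list[str] = []
    rules: dict[str, RuleExpr | _Free] = {}
    clamps: dict[str, bool] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError("expected 'Name = expression'", line_no)
        lhs, rhs = line.split("=", 1)
        lhs_tokens = lhs.split()
        rhs = rhs.strip()
        if len(lhs_tokens) == 2 and lhs_tokens[0].lower() == "clamp":
            node = lhs_tokens[1]
            if not _IDENT_RE.fullmatch(node):
                raise ParseError(f"bad node identifier {node!r}", line_no)
            if rhs.upper() not in ("TRUE", "FALSE"):
                raise ParseError("clamp value must be True or False", line_no)
            if node in clamps:
                raise ValidationError(f"line {line_no}: duplicate clamp for {node!r}")
            clamps[node] = rhs.upper() == "TRUE"
            continue
        if len(lhs_tokens) != 1:
            raise ParseError(f"bad left-hand side {lhs.strip()!r}", line_no)
        node = lhs_tokens[0]
        if not _IDENT_RE.fullmatch(node) or node.upper() in _KEYWORDS:
            raise ParseError(f"bad node identifier {node!r}", line_no)
        if node in rules:
            raise ValidationError(f"line {line_no}: duplicate definition of node {node!r}")
        nodes.append(node)
        if rhs.upper() == "RANDOM":
            rules[node] = FREE
        else:
            rules[node] = _parse_expression(rhs, line_no)
    if not nodes:
        raise ValidationError("empty network: no rules defined")
    return BooleanNetwork(tuple(nodes), rules, clamps, name=name)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_PREC = {Op.OR: 1, Op.AND: 2, Op.NOT: 3, Op.VAR: 4, Op.CONST: 4}


def _unparse(expr: RuleExpr, dialect: str, parent_prec: int) -> str:
    ops = (
        {"AND": " AND ", "OR": " OR ", "NOT": "NOT "}
        if dialect == "native"
        else {"AND": " & ", "OR": " | ", "NOT": "!"}
    )
    prec = _PREC[expr.op]
    if expr.op is Op.VAR:
        s = expr.name or ""
    elif expr.op is Op.CONST:
        if dialect == "native":
            s = "True" if expr.value else "False"
        else:
            s = "1" if expr.value else "0"
    elif expr.op is Op.NOT:
        s = ops["NOT"] + _unparse(expr.children[0], dialect, prec)
    else:
        joiner = ops[expr.op.value]
        s = joiner.join(_unparse(c, dialect, prec) for c in expr.children)
    # parenthesize at equal precedence too, so nested same-operator trees
    # survive the structural round-trip instead of flattening
    if prec <= parent_prec and expr.op not in (Op.VAR, Op.CONST):
        s = "(" + s + ")"
    return s


def write_network(network: BooleanNetwork) -> str:
    """Serialize to native rule-file text; ``parse_network`` round-trips it."""
    lines = [f"# {network.name}"]
    for node in network.nodes:
        rule = network.rules[node]
        rhs = "RANDOM" if rule is FREE else rule.unparse("native")
        lines.append(f"{node} = {rhs}")
    for node, value in network.clamps.items():
        lines.append(f"clamp {node} = {'True' if value else 'False'}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# semantics
# ---------------------------------------------------------------------------


def evaluate_rule(rule: RuleExpr, assignment: Mapping[str, bool]) -> bool:
    """Evaluate a rule under a name -> Boolean assignment.

    Standard Boolean semantics, fully deterministic.  Raises
    :class:`UnresolvedVariableError` for variables missing from
    ``assignment``.
    """
    op = rule.op
    if op is Op.VAR:
        try:
            return bool(assignment[rule.name])  # type: ignore[index]
        except KeyError:
            raise UnresolvedVariableError(f"variable {rule.name!r} not in assignment") from None
    if op is Op.CONST:
        return bool(rule.value)
    if op is Op.NOT:
        return not evaluate_rule(rule.children[0], assignment)
    if op is Op.AND:
        return all(evaluate_rule(c, assignment) for c in rule.children)
    return any(evaluate_rule(c, assignment) for c in rule.children)


def compile_rule(rule: RuleExpr, node_index: Mapping[str, int]):
    """Compile a rule to a fast ``f(values_sequence) -> bool`` closure."""
    op = rule.op
    if op is Op.VAR:
        i = node_index[rule.name]  # type: ignore[index]
        return lambda v: bool(v[i])
    if op is Op.CONST:
        val = bool(rule.value)
        return lambda v: val
    kids = tuple(compile_rule(c, node_index) for c in rule.children)
    if op is Op.NOT:
        (k,) = kids
        return lambda v: not k(v)
    if op is Op.AND:
        return lambda v: all(k(v) for k in kids)
    return lambda v: any(k(v) for k in kids)


def apply_clamp(network: BooleanNetwork, node: str, value: bool) -> BooleanNetwork:
    """Return a copy of ``network`` with ``node`` held at ``value``.

    The original network is unmodified; clamping is idempotent.  Raises
    :class:`UnknownNodeError` for undeclared nodes.
    """
    if node not in network.nodes:
        raise UnknownNodeError(f"unknown node {node!r}")
    clamps = dict(network.clamps)
    clamps[node] = bool(value)
    return BooleanNetwork(network.nodes, dict(network.rules), clamps, name=network.name)


# ---------------------------------------------------------------------------
# BoolNet-style dialect
# ---------------------------------------------------------------------------


def parse_boolnet(text: str, name: str = "network") -> BooleanNetwork:
    """Parse a BoolNet-style ``targets, factors`` rule table.

    Operators ``&``, ``|``, ``!``; constants ``0``/``1``.  No free-node or
    clamp syntax exists in this dialect.
    """
    nodes: list[str] = []
    rules: dict[str, RuleExpr | _Free] = {}
    header_seen = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        if not header_seen:
            head = [p.strip().lower() for p in line.split(",")]
            if head[:2] != ["targets", "factors"]:
                raise ParseError("expected 'targets, factors' header", line_no)
            header_seen = True
            continue
        if "," not in line:
            raise ParseError("expected 'target, factors'", line_no)
        node, expr_text = line.split(",", 1)
        node = node.strip()
        if not _IDENT_RE.fullmatch(node):
            raise ParseError(f"bad node identifier {node!r}", line_no)
        if node in rules:
            raise ValidationError(f"line {line_no}: duplicate definition of node {node!r}")
        nodes.append(node)
        rules[node] = _parse_expression(expr_text, line_no, dialect="boolnet")
    if not nodes:
        raise ValidationError("empty network: no rules defined")
    return BooleanNetwork(tuple(nodes), rules, {}, name=name)


def write_boolnet(network: BooleanNetwork) -> str:
    """Serialize to the BoolNet dialect.

    Raises :class:`UnsupportedFeatureError` if the network has free nodes
    or clamps, which the dialect cannot express.
    """
    if network.free_nodes:
        raise UnsupportedFeatureError("BoolNet dialect cannot express free (RANDOM) nodes")
    if network.clamps:
        raise UnsupportedFeatureError("BoolNet dialect cannot express clamp directives")
    lines = ["targets, factors"]
    for node in network.nodes:
        rule = network.rules[node]
        assert isinstance(rule, RuleExpr)
        lines.append(f"{node}, {rule.unparse('boolnet')}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def _expr_to_obj(expr: RuleExpr) -> dict:
    if expr.op is Op.VAR:
        return {"op": "VAR", "name": expr.name}
    if expr.op is Op.CONST:
        return {"op": "CONST", "value": expr.value}
    return {"op": expr.op.value, "children": [_expr_to_obj(c) for c in expr.children]}


def _expr_from_obj(obj: dict) -> RuleExpr:
    op = Op(obj["op"])
    if op is Op.VAR:
        return RuleExpr.var(obj["name"])
    if op is Op.CONST:
        return RuleExpr.const(obj["value"])
    return RuleExpr(op, tuple(_expr_from_obj(c) for c in obj["children"]))


def network_to_json(network: BooleanNetwork) -> str:
    """Machine round-trip serialization of the full network."""
    obj = {
        "name": network.name,
        "nodes": list(network.nodes),
        "rules": {
            node: ("FREE" if rule is FREE else _expr_to_obj(rule))
            for node, rule in network.rules.items()
        },
        "clamps": {node: bool(v) for node, v in network.clamps.items()},
    }
    return json.dumps(obj, indent=1)


def network_from_json(text: str) -> BooleanNetwork:
    obj = json.loads(text)
    rules: dict[str, RuleExpr | _Free] = {
        node: (FREE if spec == "FREE" else _expr_from_obj(spec))
        for node, spec in obj["rules"].items()
    }
    return BooleanNetwork(
        tuple(obj["nodes"]), rules, {k: bool(v) for k, v in obj["clamps"].items()},
        name=obj.get("name", "network"),
    )
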