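"""Reading and writing of rule files, scenario files and export dialects.

Native rule files contain one rule per line::

    Proliferation* = CYCLIND1 and not P21
    NFKB* = not IKB          # comments start with '#'

Keywords ``and``/``or``/``not`` are case-insensitive and ``&``/``|``/``!`` are
accepted as synonyms; ``TRUE``/``FALSE`` constants are permitted.  Operator
precedence is ``not`` > ``and`` > ``or``.  Nodes that appear only as
regulators are auto-declared as self-maintaining inputs (``X* = X``): such
nodes behave as environmental switches toggled by scenarios rather than as
errors.
"""

from __future__ import annotations

import re

from . import expr as E
from .model import BooleanModel, Scenario

_KEYWORDS = {"and": "AND", "or": "OR", "not": "NOT", "true": "TRUE", "false": "FALSE"}
_TOKEN_RE = re.compile(r"\s*(?:(?P<ident>[A-Za-z][A-Za-z0-9_]*)|(?P<op>[&|!()]))")
_SYMBOLS = {"&": "AND", "|": "OR", "!": "NOT", "(": "LP", ")": "RP"}


class ParseError(ValueError):
    """Syntax error in a rule or scenario file; message names the line."""


def _tokenize(text: str, lineno: int) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ParseError(f"line {lineno}: unexpected character "
                                 f"{text[pos:].strip()[0]!r}")
            break
        if m.group("ident"):
            word = m.group("ident")
            kind = _KEYWORDS.get(word.lower(), "IDENT")
            tokens.append((kind, word))
        else:
            tokens.append((_SYMBOLS[m.group("op")], m.group("op")))
        pos = m.end()
    return tokens


class _ExprParser:
    """Recursive-descent parser with precedence NOT > AND > OR."""

    def __init__(self, tokens: list[tuple[str, str]], lineno: int) -> None:
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def fail(self, msg: str):
        raise ParseError(f"line {self.lineno}: {msg}")

    def parse(self) -> E.Expr:
        if not self.tokens:
            self.fail("empty expression")
        e = self.or_expr()
        if self.peek() is not None:
            kind, text = self.tokens[self.pos]
            if kind == "RP":
                self.fail("unbalanced parentheses")
            self.fail(f"unexpected token {text!r}")
        return e

    def or_expr(self) -> E.Expr:
        terms = [self.and_expr()]
        while self.peek() == "OR":
            self.take()
            terms.append(self.and_expr())
        return E.disj(terms)

    def and_expr(self) -> E.Expr:
        terms = [self.not_expr()]
        while self.peek() == "AND":
            self.take()
            terms.append(self.not_expr())
        return E.conj(terms)

    def not_expr(self) -> E.Expr:
        if self.peek() == "NOT":
            self.take()
            return E.Not(self.not_expr())
        return self.atom()

    def atom(self) -> E.Expr:
        kind = self.peek()
        if kind is None:
            self.fail("expression ended unexpectedly")
        k, text = self.take()
        if k == "IDENT":
            return E.Var(text)
        if k == "TRUE":
            return E.TRUE
        if k == "FALSE":
            return E.FALSE
        if k == "LP":
            e = self.or_expr()
            if self.peek() != "RP":
                self.fail("unbalanced parentheses")
            self.take()
            return e
        self.fail(f"unexpected token {text!r}")
        raise AssertionError  # unreachable


def parse_expression(text: str, lineno: int = 0) -> E.Expr:
    """Parse a single rule expression."""
    return _ExprParser(_tokenize(text, lineno), lineno).parse()


_RULE_RE = re.compile(
    r"^\s*(?P<name>[A-Za-z][A-Za-z0-9_]*)\s*\*\s*=\s*(?P<expr>.*)$")


def parse_model(text: str, roles: dict[str, str] | None = None) -> BooleanModel:
    """Parse a native rule file into a validated :class:`BooleanModel`.

    Accepts both ``Name* = expr`` and ``Name *= expr`` spellings.  Nodes that
    are referenced but never given a rule are auto-declared with the
    self-maintenance rule ``X* = X`` and flagged as inputs.
    """
    if not text.strip():
        raise ParseError("empty rule file")
    rules: dict[str, E.Expr] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _RULE_RE.match(line)
        if m is None:
            raise ParseError(f"line {lineno}: expected '<name>* = <expr>', got {raw!r}")
        name = m.group("name")
        if name in rules:
            raise ParseError(f"line {lineno}: duplicate rule for node {name!r}")
        body = m.group("expr").strip()
        if not body:
            raise ParseError(f"line {lineno}: empty expression for node {name!r}")
        rules[name] = parse_expression(body, lineno)
        order.append(name)
    referenced: set[str] = set()
    for rule in rules.values():
        referenced |= rule.variables()
    for name in sorted(referenced - set(order)):
        rules[name] = E.Var(name)
        order.append(name)
    return BooleanModel(nodes=tuple(order), rules=rules, roles=roles or {})


def export_model(model: BooleanModel, dialect: str = "native") -> str:
    """Serialise a model as ``native`` rules, BoolNet-style ``bnet`` CSV, or
    a signed-interaction ``sif`` table."""
    if dialect == "native":
        lines = [f"{n}* = {E.to_native(model.rules[n])}" for n in model.nodes]
        return "\n".join(lines) + "\n"
    if dialect == "bnet":
        lines = ["targets, factors"]
        lines += [f"{n}, {E.to_bnet(model.rules[n])}" for n in model.nodes]
        return "\n".join(lines) + "\n"
    if dialect == "sif":
        from .model import model_edges
        rows = sorted(model_edges(model))
        return "".join(f"{reg}\t{sign}\t{tgt}\n" for reg, tgt, sign in rows)
    raise ValueError(f"unknown dialect {dialect!r}")


_SECTION_RE = re.compile(r"^\[(?P<name>[a-z_]+)\]$")
_ONOFF = {"on": True, "off": False, "1": True, "0": False}


def parse_scenario(text: str) -> Scenario:
    """Parse a scenario file with ``[fixed]`` / ``[initial]`` sections of
    ``NODE = ON|OFF`` lines plus an optional ``default_initial`` key."""
    fixed: dict[str, bool] = {}
    initial: dict[str, bool] = {}
    default_initial = "uniform_random"
    section: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _SECTION_RE.match(line)
        if m:
            section = m.group("name")
            if section not in ("fixed", "initial"):
                raise ParseError(f"line {lineno}: unknown section [{section}]")
            continue
        if "=" not in line:
            raise ParseError(f"line {lineno}: expected 'key = value'")
        key, _, value = (part.strip() for part in line.partition("="))
        if key == "default_initial":
            default_initial = value
            continue
        if section is None:
            raise ParseError(f"line {lineno}: directive outside a section")
        try:
            state = _ONOFF[value.lower()]
        except KeyError:
            raise ParseError(f"line {lineno}: state must be ON or OFF, got {value!r}")
        (fixed if section == "fixed" else initial)[key] = state
    return Scenario(fixed=fixed, initial=initial, default_initial=default_initial)


def export_scenario(scenario: Scenario) -> str:
    lines = [f"default_initial = {scenario.default_initial}", "", "[fixed]"]
    lines += [f"{n} = {'ON' if v else 'OFF'}" for n, v in scenario.fixed.items()]
    lines += ["", "[initial]"]
    lines += [f"{n} = {'ON' if v else 'OFF'}" for n, v in scenario.initial.items()]
    return "\n".join(lines) + "\n"
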