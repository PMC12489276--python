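"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers with AND/OR
connectives, e.g. ``"g1 and (g2 or g3)"``.  AND encodes an enzyme complex
(all subunits required), OR encodes isozymes (any one suffices).  Rules are
used to evaluate knockouts, to collect the gene support of a reaction, and to
expand reactions into isozyme modules for enzyme-constrained models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterator


class GPRParseError(ValueError):
    """Raised for malformed rule text (e.g. unbalanced parentheses)."""


@dataclass(frozen=True)
class GPRNode:
    """Internal node ('and' | 'or') or leaf (op='gene', name set)."""

    op: str
    children: tuple["GPRNode", ...] = ()
    name: str | None = None

    def evaluate(self, knocked_out: frozenset[str]) -> bool:
        if self.op == "gene":
            return self.name not in knocked_out
        if self.op == "and":
            return all(c.evaluate(knocked_out) for c in self.children)
        return any(c.evaluate(knocked_out) for c in self.children)

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.name])
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.genes()
        return out


@dataclass(frozen=True)
class GPRRule:
    """Boolean rule over genes; ``root is None`` means the empty rule.

    The empty rule evaluates to True under any knockout (the reaction is not
    gene-associated, so it can never be disabled by a gene deletion).
    """

    root: GPRNode | None = None
    text: str = ""

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        return frozenset() if self.root is None else self.root.genes()

    def evaluate(self, knocked_out=()) -> bool:
        if self.root is None:
            return True
        return self.root.evaluate(frozenset(knocked_out))

    def isozyme_modules(self, max_modules: int = 64) -> list[frozenset[str]]:
        """Expand the rule to disjunctive normal form.

        Returns one gene set per isozyme module: the rule is satisfied iff all
        genes of at least one module are present.  Duplicate and superset
        modules are dropped.
        """
        if self.root is None:
            return []

        def dnf(node: GPRNode) -> list[frozenset[str]]:
            if node.op == "gene":
                return [frozenset([node.name])]
            if node.op == "or":
                out: list[frozenset[str]] = []
                for c in node.children:
                    out.extend(dnf(c))
                return out
            # and: cross product of child modules
            parts = [dnf(c) for c in node.children]
            out = []
            for combo in product(*parts):
                merged = frozenset().union(*combo)
                out.append(merged)
                if len(out) > max_modules:
                    raise GPRParseError(
                        f"GPR rule expands to more than {max_modules} isozyme modules"
                    )
            return out

        modules = dnf(self.root)
        minimal: list[frozenset[str]] = []
        for m in sorted(set(modules), key=lambda s: (len(s), sorted(s))):
            if not any(kept <= m for kept in minimal):
                minimal.append(m)
        return minimal

    def __str__(self) -> str:  # round-trippable text
        return self.text


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule_text: str) -> GPRRule:
    """Parse GPR text with ``and``/``or`` (case-insensitive) and parentheses.

    Empty or whitespace-only text yields the empty rule.  ``or`` binds looser
    than ``and``, following the COBRA convention.
    """
    text = (rule_text or "").strip()
    if not text:
        return GPRRule()
    tokens = _TOKEN.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GPRNode("or", tuple(terms))

    def parse_and() -> GPRNode:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else GPRNode("and", tuple(terms))

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule: {rule_text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in rule: {rule_text!r}")
            take()
            return node
        if tok == ")":
            raise GPRParseError(f"unbalanced parentheses in rule: {rule_text!r}")
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"misplaced operator {tok!r} in rule: {rule_text!r}")
        return GPRNode("gene", name=take())

    root = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in rule: {rule_text!r}")
    return GPRRule(root=root, text=text)
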