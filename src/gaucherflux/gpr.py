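"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers with AND/OR
connectives.  AND encodes an enzyme complex (all subunits required), OR
encodes isozymes (any one suffices).  An empty rule marks a spontaneous or
non-enzymatic reaction, which is always available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class GPRRule:
    """Boolean expression tree over gene identifiers.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"`` or ``"empty"``.  For a
    leaf, ``gene`` holds the identifier; for internal nodes ``children``
    holds two or more sub-rules.
    """

    op: str = "empty"
    gene: str | None = None
    children: tuple["GPRRule", ...] = field(default_factory=tuple)

    def genes(self) -> set[str]:
        """All gene identifiers appearing in the rule."""
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def is_empty(self) -> bool:
        return self.op == "empty"

    def evaluate(self, gene_states: dict[str, bool]) -> bool:
        """Evaluate the rule; True means the reaction is available.

        ``gene_states`` maps gene id -> active flag and must cover every
        leaf gene.
        """
        if self.op == "empty":
            return True
        if self.op == "gene":
            try:
                return bool(gene_states[self.gene])
            except KeyError:
                raise KeyError(
                    f"gene {self.gene!r} in GPR has no state assigned"
                ) from None
        values = (c.evaluate(gene_states) for c in self.children)
        if self.op == "and":
            return all(values)
        if self.op == "or":
            return any(values)
        raise GPRParseError(f"malformed GPR node op={self.op!r}")

    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.op in ("and", "or") and child.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _tokenize(text: str) -> Iterator[str]:
    token = []
    for ch in text:
        if ch in "()":
            if token:
                yield "".join(token)
                token = []
            yield ch
        elif ch.isspace():
            if token:
                yield "".join(token)
                token = []
        else:
            token.append(ch)
    if token:
        yield "".join(token)


def parse_gpr(text: str | None) -> GPRRule:
    """Parse a GPR string such as ``"(HEXA and HEXB) or GBA1"``.

    The grammar is the conventional one used by SBML-FBC and model JSON
    dialects: ``or`` binds weaker than ``and``; parentheses group.  The
    keywords are case-insensitive.  An empty or whitespace-only string
    yields the empty (always-active) rule.
    """
    if text is None or not text.strip():
        return GPRRule()
    tokens = list(_tokenize(text))
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRRule:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GPRRule(op="or", children=tuple(terms))

    def parse_and() -> GPRRule:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        if len(terms) == 1:
            return terms[0]
        return GPRRule(op="and", children=tuple(terms))

    def parse_atom() -> GPRRule:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR: {text!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return GPRRule(op="gene", gene=take())

    rule = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR: {text!r}")
    return rule


def evaluate_gpr(rule: GPRRule, gene_states: dict[str, bool]) -> bool:
    """Functional wrapper over :meth:`GPRRule.evaluate`."""
    return rule.evaluate(gene_states)
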