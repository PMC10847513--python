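"""Diagnostic motif patterns and their text syntax.

Grammar::

    pattern  := element+
    element  := literal | '[' literal+ ']' | wildcard
    literal  := one of the 20 amino-acid letters
    wildcard := 'x' ( '{' n ( ',' m )? '}' )?

``x{4}`` is a run of four unscored wildcard positions; ``x{1,2}`` is a
bounded variable-length run.  Literals and alternative sets are "scored"
positions; wildcards carry no score mass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import PatternSyntaxError
from .seqio import AMINO_ACIDS

__all__ = ["PatternElement", "ConsensusPattern", "parse_pattern"]


@dataclass(frozen=True)
class PatternElement:
    """One position (or wildcard run) of a consensus pattern."""

    kind: str  # 'literal' | 'set' | 'wild'
    residues: frozenset[str] = frozenset()
    min_run: int = 1
    max_run: int = 1
    low_confidence: bool = False
    display: str = ""  # written residue order, preserved through round trips

    @property
    def scored(self) -> bool:
        return self.kind != "wild"

    def matches(self, ch: str) -> bool:
        if self.kind == "wild":
            return True
        if ch == "X":  # unknown residue satisfies any element
            return True
        return ch in self.residues

    def to_text(self) -> str:
        if self.kind == "wild":
            if self.min_run == self.max_run:
                return "x" if self.min_run == 1 else f"x{{{self.min_run}}}"
            return f"x{{{self.min_run},{self.max_run}}}"
        body = self.display or "".join(sorted(self.residues))
        if self.kind == "literal":
            return body
        return "[" + body + "]"


@dataclass(frozen=True)
class ConsensusPattern:
    """Ordered motif pattern with a name and optional source span."""

    name: str
    elements: tuple[PatternElement, ...]
    source_columns: tuple[int, int] | None = None
    dropped_columns: tuple[int, ...] = ()

    @property
    def min_length(self) -> int:
        return sum(e.min_run if e.kind == "wild" else 1 for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_run if e.kind == "wild" else 1 for e in self.elements)

    @property
    def n_scored(self) -> int:
        return sum(1 for e in self.elements if e.scored)

    def expansions(self) -> list[tuple[PatternElement, ...]]:
        """All fixed-length position lists (wildcard runs expanded)."""
        WILD = PatternElement("wild")
        choices: list[list[tuple[PatternElement, ...]]] = []
        for e in self.elements:
            if e.kind == "wild":
                choices.append(
                    [
                        tuple([WILD] * n)
                        for n in range(e.min_run, e.max_run + 1)
                    ]
                )
            else:
                choices.append([(e,)])
        out = []
        for combo in itertools.product(*choices):
            out.append(tuple(itertools.chain.from_iterable(combo)))
        return out

    def to_text(self) -> str:
        return "".join(e.to_text() for e in self.elements)

    def __str__(self) -> str:
        return self.to_text()


def parse_pattern(text: str, name: str = "pattern") -> ConsensusPattern:
    """Parse motif pattern text into a :class:`ConsensusPattern`."""
    if not text:
        raise PatternSyntaxError("empty pattern")
    elements: list[PatternElement] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in AMINO_ACIDS:
            elements.append(PatternElement("literal", frozenset(ch), display=ch))
            i += 1
        elif ch == "[":
            j = text.find("]", i + 1)
            if j < 0:
                raise PatternSyntaxError("unterminated '['", offset=i)
            body = text[i + 1 : j]
            if not body:
                raise PatternSyntaxError("empty alternative set", offset=i)
            bad = set(body) - AMINO_ACIDS
            if bad:
                raise PatternSyntaxError(
                    f"non-amino-acid {sorted(bad)[0]!r} in alternative set", offset=i
                )
            kind = "literal" if len(set(body)) == 1 else "set"
            dedup = "".join(dict.fromkeys(body))
            elements.append(PatternElement(kind, frozenset(body), display=dedup))
            i = j + 1
        elif ch in ("x", "X"):
            lo = hi = 1
            i += 1
            if i < n and text[i] == "{":
                j = text.find("}", i + 1)
                if j < 0:
                    raise PatternSyntaxError("unterminated '{'", offset=i)
                body = text[i + 1 : j]
                try:
                    if "," in body:
                        lo_s, hi_s = body.split(",", 1)
                        lo, hi = int(lo_s), int(hi_s)
                    else:
                        lo = hi = int(body)
                except ValueError as exc:
                    raise PatternSyntaxError(
                        f"bad wildcard run {body!r}", offset=i
                    ) from exc
                if lo < 0 or hi < lo:
                    raise PatternSyntaxError(
                        f"bad wildcard bounds {lo},{hi}", offset=i
                    )
                i = j + 1
            if hi > 0:
                elements.append(PatternElement("wild", min_run=lo, max_run=hi))
        else:
            raise PatternSyntaxError(f"unknown character {ch!r}", offset=i)
    if not elements:
        raise PatternSyntaxError("pattern has no elements")
    return ConsensusPattern(name=name, elements=tuple(elements))
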