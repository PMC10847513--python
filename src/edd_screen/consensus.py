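"""Per-column similarity classification and consensus-pattern derivation.

Columns of a one-class alignment are shaded ``dark`` or ``light`` when the
best-covered residue or similarity group reaches the 0.80 / 0.60 cutoffs
(gaps excluded from the denominator); runs of unconserved columns collapse
into wildcard elements of the derived pattern.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import ConfigurationError, SpanError, UndefinedColumnError
from .motifs import ConsensusPattern, PatternElement
from .seqio import AMINO_ACIDS, GAP, AlignmentBlock

DEFAULT_CUTOFFS = (0.60, 0.80)

#: Dayhoff-like similarity grouping used when no scheme is supplied.
DEFAULT_GROUPS = ("AG", "ILMV", "FWY", "HKR", "DE", "NQ", "ST", "C", "P")

__all__ = [
    "SimilarityScheme",
    "ColumnClass",
    "classify_column",
    "derive_consensus",
    "DEFAULT_CUTOFFS",
]


class SimilarityScheme:
    """A named partition of the 20 amino acids into similarity classes."""

    def __init__(self, groups=DEFAULT_GROUPS):
        self.groups: dict[str, frozenset[str]] = {}
        seen: set[str] = set()
        for g in groups:
            members = frozenset(g)
            name = "".join(sorted(members))
            if members & seen:
                raise ConfigurationError(
                    f"amino acids {sorted(members & seen)} appear in two groups"
                )
            seen |= members
            self.groups[name] = members
        missing = AMINO_ACIDS - seen
        if missing:
            raise ConfigurationError(
                f"amino acids {sorted(missing)} missing from similarity scheme"
            )
        extra = seen - AMINO_ACIDS
        if extra:
            raise ConfigurationError(f"unknown symbols {sorted(extra)} in scheme")

    def group_of(self, residue: str) -> tuple[str, frozenset[str]]:
        for name, members in self.groups.items():
            if residue in members:
                return name, members
        raise KeyError(residue)

    @classmethod
    def from_tsv(cls, path) -> "SimilarityScheme":
        """Read one group per line (residue letters, tab/space separated or joined)."""
        groups = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                groups.append("".join(line.split()))
        return cls(groups)


@dataclass(frozen=True)
class ColumnClass:
    column: int  # 1-based alignment column
    shade: str  # 'dark' | 'light' | 'none'
    dominant_set: frozenset[str]
    dominant_name: str
    fraction: float


def classify_column(
    residues,
    scheme: SimilarityScheme | None = None,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    column: int = 0,
) -> ColumnClass:
    """Classify one alignment column by best residue/group coverage.

    ``residues`` is the column's character multiset; gaps are excluded from
    the denominator.  The dominant set is the single residue or similarity
    group with maximal coverage (ties broken by lexicographically smallest
    candidate name).  Unknown residues ('X') count toward any candidate.
    """
    scheme = scheme or SimilarityScheme()
    light_cut, dark_cut = cutoffs
    if not 0 < light_cut < dark_cut <= 1:
        raise ConfigurationError(f"bad cutoffs {cutoffs}: need 0 < light < dark <= 1")
    counts = Counter(ch for ch in residues if ch != GAP)
    n = sum(counts.values())
    if n == 0:
        raise UndefinedColumnError(f"column {column} holds only gaps")
    n_x = counts.pop("X", 0)

    candidates: dict[str, frozenset[str]] = {aa: frozenset(aa) for aa in counts}
    for name, members in scheme.groups.items():
        if any(aa in counts for aa in members):
            candidates[name] = members
    if not candidates:  # column is all X
        candidates = {"A": frozenset("A")}

    # ties: prefer the smaller candidate set (a single invariant residue
    # beats its containing group), then the lexicographically smaller name
    best_name, best_frac = None, -1.0
    for name in sorted(candidates, key=lambda k: (len(candidates[k]), k)):
        cov = (sum(counts[aa] for aa in candidates[name]) + n_x) / n
        if cov > best_frac + 1e-12:
            best_name, best_frac = name, cov
    shade = "dark" if best_frac >= dark_cut else (
        "light" if best_frac >= light_cut else "none"
    )
    return ColumnClass(
        column=column,
        shade=shade,
        dominant_set=candidates[best_name],
        dominant_name=best_name,
        fraction=best_frac,
    )


def derive_consensus(
    block: AlignmentBlock,
    span: tuple[int, int],
    scheme: SimilarityScheme | None = None,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    name: str = "consensus",
    max_gap_fraction: float = 0.5,
) -> ConsensusPattern:
    """Derive a consensus motif pattern over an inclusive 1-based column span.

    Dark columns become literals (or alternative sets when a group
    dominates); light columns become low-confidence alternative sets;
    unconserved columns merge into wildcard runs.  Majority-gap columns are
    dropped from the pattern and reported via ``dropped_columns``.
    """
    start, end = span
    if start < 1 or end > block.length or start > end:
        raise SpanError(f"span {span} outside alignment columns 1..{block.length}")
    scheme = scheme or SimilarityScheme()

    elements: list[PatternElement] = []
    dropped: list[int] = []
    for col in range(start, end + 1):
        chars = block.column(col)
        gap_frac = sum(1 for c in chars if c == GAP) / len(chars)
        if gap_frac > max_gap_fraction:
            dropped.append(col)
            continue
        cc = classify_column(chars, scheme, cutoffs, column=col)
        if cc.shade == "none":
            if elements and elements[-1].kind == "wild":
                prev = elements[-1]
                elements[-1] = PatternElement(
                    "wild", min_run=prev.min_run + 1, max_run=prev.max_run + 1
                )
            else:
                elements.append(PatternElement("wild"))
        elif len(cc.dominant_set) == 1 and cc.shade == "dark":
            elements.append(PatternElement("literal", cc.dominant_set))
        else:
            kind = "literal" if len(cc.dominant_set) == 1 else "set"
            elements.append(
                PatternElement(
                    kind, cc.dominant_set, low_confidence=(cc.shade == "light")
                )
            )
    if not elements:
        raise SpanError(f"all columns in span {span} were majority-gap")
    return ConsensusPattern(
        name=name,
        elements=tuple(elements),
        source_columns=(start, end),
        dropped_columns=tuple(dropped),
    )
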