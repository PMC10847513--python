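"""Motif scanning and EDD/DHAD dehydratase calling.

Approximate matching with a mismatch budget is used instead of exact
regular-expression matching: the built-in patterns are multi-species
consensus motifs and need not match any single sequence exactly.  A
pattern's score at a window is (matched scored positions) / (total scored
positions); wildcards carry no score mass.  DHAD is never called from a
positive motif — only by similarity to a supplied reference set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .motifs import ConsensusPattern, parse_pattern
from .seqio import ProteinRecord

#: class tags a library pattern may carry
EDD_DIAGNOSTIC = "EDD-diagnostic"
AUXILIARY_EDD = "auxiliary-EDD"

DEFAULT_EDD_THRESHOLD = 0.8
DEFAULT_IDENTITY_THRESHOLD = 0.35

__all__ = [
    "MotifMatch",
    "LibraryEntry",
    "MotifLibrary",
    "DehydrataseCall",
    "scan_sequence",
    "classify_dehydratase",
    "default_library",
    "ungapped_identity",
]


@dataclass(frozen=True)
class MotifMatch:
    """Best (or admissible) window of a pattern on a protein."""

    pattern_name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    matched_literals: int
    max_literals: int
    sub_threshold: bool = False

    @property
    def score(self) -> float:
        return self.matched_literals / self.max_literals

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LibraryEntry:
    pattern: ConsensusPattern
    class_tag: str = EDD_DIAGNOSTIC
    weight: float = 1.0


@dataclass
class MotifLibrary:
    """Named set of diagnostic patterns with class tags and weights."""

    entries: list[LibraryEntry] = field(default_factory=list)

    def __post_init__(self):
        names = [e.pattern.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate pattern names in library")
        for e in self.entries:
            if e.pattern.n_scored == 0:
                raise ConfigurationError(
                    f"pattern {e.pattern.name!r} has no scored positions"
                )
            if e.weight <= 0:
                raise ConfigurationError(
                    f"pattern {e.pattern.name!r} has non-positive weight"
                )

    def diagnostic(self) -> list[LibraryEntry]:
        return [
            e for e in self.entries if e.class_tag in (EDD_DIAGNOSTIC, AUXILIARY_EDD)
        ]

    @classmethod
    def from_tsv(cls, path) -> "MotifLibrary":
        """Load a library from TSV columns: name, class, weight, pattern."""
        entries = []
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                entries.append(
                    LibraryEntry(
                        pattern=parse_pattern(row["pattern"], name=row["name"]),
                        class_tag=row.get("class", EDD_DIAGNOSTIC),
                        weight=float(row.get("weight", 1.0)),
                    )
                )
        return cls(entries)


def default_library() -> MotifLibrary:
    """The two built-in EDD-diagnostic consensus patterns.

    domain1 is the N-terminal 16-residue motif; domain2 is the basic,
    lid-forming motif.  Auxiliary short motifs (2-4 residues) may be added
    by the user at weight 0.25.
    """
    return MotifLibrary(
        [
            LibraryEntry(parse_pattern("LAHGFAAx{4}[DE]Kx{3}", name="domain1")),
            LibraryEntry(parse_pattern("KxK[VI]RQLYAx{2}K", name="domain2")),
        ]
    )


@dataclass(frozen=True)
class DehydrataseCall:
    protein_id: str
    label: str  # 'EDD' | 'DHAD' | 'unknown'
    evidence: tuple[MotifMatch, ...]
    edd_score: float
    reference_identity: float | None = None
    nearest_reference: str | None = None


def _score_window(seq: str, positions, start0: int) -> int:
    matched = 0
    for off, elem in enumerate(positions):
        if elem.kind == "wild":
            continue
        if elem.matches(seq[start0 + off]):
            matched += 1
    return matched


def scan_sequence(
    protein: ProteinRecord,
    pattern: ConsensusPattern,
    max_mismatch: int = 0,
) -> list[MotifMatch]:
    """Slide a pattern over all windows of a protein.

    Returns all windows with at most ``max_mismatch`` scored-position
    mismatches, plus always the single best-scoring window (flagged
    ``sub_threshold`` when it misses the budget).  Ties on score go to the
    smallest start, then the shortest window.  A pattern longer than the
    sequence yields an empty list.
    """
    seq = protein.residues
    n_scored = pattern.n_scored
    best: MotifMatch | None = None
    hits: list[MotifMatch] = []
    for positions in pattern.expansions():
        w = len(positions)
        if w > len(seq):
            continue
        for start0 in range(len(seq) - w + 1):
            matched = _score_window(seq, positions, start0)
            m = MotifMatch(
                pattern_name=pattern.name,
                start=start0 + 1,
                end=start0 + w,
                matched_literals=matched,
                max_literals=n_scored,
            )
            if n_scored - matched <= max_mismatch:
                hits.append(m)
            if (
                best is None
                or matched > best.matched_literals
                or (
                    matched == best.matched_literals
                    and (m.start, m.length) < (best.start, best.length)
                )
            ):
                best = m
    if best is None:  # no window fits
        return []
    hits.sort(key=lambda m: (m.start, m.length))
    if not any(
        m.start == best.start and m.end == best.end for m in hits
    ):
        hits.append(
            MotifMatch(
                pattern_name=best.pattern_name,
                start=best.start,
                end=best.end,
                matched_literals=best.matched_literals,
                max_literals=best.max_literals,
                sub_threshold=True,
            )
        )
    return hits


def ungapped_identity(
    query: str, reference: str, min_overlap_frac: float = 0.5
) -> float:
    """Best ungapped (diagonal) percent identity between two sequences.

    Every relative offset of the two sequences is scored as
    matches / overlap length; only overlaps covering at least
    ``min_overlap_frac`` of the shorter sequence count.  Unrelated
    sequences score near the random baseline (~0.05); homologs score near
    their alignment identity.
    """
    nq, nr = len(query), len(reference)
    if nq == 0 or nr == 0:
        return 0.0
    min_overlap = max(1, int(min_overlap_frac * min(nq, nr)))
    best = 0.0
    for shift in range(-(nr - min_overlap), nq - min_overlap + 1):
        q_start = max(0, shift)
        r_start = max(0, -shift)
        overlap = min(nq - q_start, nr - r_start)
        if overlap < min_overlap:
            continue
        matches = sum(
            1
            for a, b in zip(
                query[q_start : q_start + overlap],
                reference[r_start : r_start + overlap],
            )
            if a == b
        )
        best = max(best, matches / overlap)
    return best


def classify_dehydratase(
    protein: ProteinRecord,
    library: MotifLibrary | None = None,
    references: list[ProteinRecord] | None = None,
    t_edd: float = DEFAULT_EDD_THRESHOLD,
    t_id: float = DEFAULT_IDENTITY_THRESHOLD,
    max_mismatch: int = 2,
) -> DehydrataseCall:
    """Call a protein EDD / DHAD / unknown.

    ``edd_score`` is the weighted mean of best-window scores over the
    library's EDD-diagnostic patterns.  When the motif call fails and
    references are given (their ``group_label`` carrying the class, e.g.
    'EDD' or 'DHAD'), the nearest reference by ungapped diagonal identity
    decides the label when identity >= ``t_id``.
    """
    library = library or default_library()
    diagnostic = library.diagnostic()
    if not diagnostic:
        raise ConfigurationError("library holds no EDD-diagnostic pattern")

    evidence: list[MotifMatch] = []
    num = den = 0.0
    for entry in diagnostic:
        matches = scan_sequence(protein, entry.pattern, max_mismatch=max_mismatch)
        best = max(matches, key=lambda m: m.score, default=None)
        score = best.score if best else 0.0
        if best:
            evidence.append(best)
        num += entry.weight * score
        den += entry.weight
    edd_score = num / den

    ref_identity = None
    nearest = None
    if references:
        scored = [
            (ungapped_identity(protein.residues, ref.residues), ref)
            for ref in references
        ]
        ref_identity, nearest = max(scored, key=lambda t: t[0])

    if edd_score >= t_edd:
        label = "EDD"
    elif nearest is not None and ref_identity >= t_id:
        label = nearest.group_label or "unknown"
    else:
        label = "unknown"

    return DehydrataseCall(
        protein_id=protein.id,
        label=label,
        evidence=tuple(sorted(evidence, key=lambda m: -m.score)),
        edd_score=edd_score,
        reference_identity=ref_identity,
        nearest_reference=nearest.id if nearest else None,
    )
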