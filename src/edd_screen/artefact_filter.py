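"""Bacterial-artefact screening of putative eukaryotic EDD genes.

Four criteria are combined under a quorum rule: codon usage more bacterial
than host-like (positive log-likelihood ratio), absence of introns
(single-exon gene), absence of a transit peptide, and nesting inside a
bacterial clade of the gene tree.  A gene is called an artefact only when
at least 3 of 4 observable criteria agree (>= 2 when only 2-3 criteria
have data; never from a single criterion).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .errors import AlphabetError, EddScreenError, FrameError
from .genome_survey import GeneRecord

#: codon -> amino acid for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_SYNONYMS: dict[str, tuple[str, ...]] = {}
_by_aa: dict[str, list[str]] = defaultdict(list)
for _codon, _aa in CODON_TO_AA.items():
    _by_aa[_aa].append(_codon)
for _aa, _codons in _by_aa.items():
    _SYNONYMS[_aa] = tuple(sorted(_codons))

DEFAULT_PSEUDOCOUNT = 0.5

__all__ = [
    "CodonUsageTable",
    "ArtefactVerdict",
    "codon_counts",
    "rscu",
    "codon_llr",
    "rscu_distance",
    "artefact_verdict",
    "transit_peptide_heuristic",
]


def _validate_cds(cds: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    for i, ch in enumerate(cds, start=1):
        if ch not in "ACGT":
            raise AlphabetError(ch, i, context="CDS")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for j, codon in enumerate(codons):
        if codon in STOP_CODONS and j != len(codons) - 1:
            raise FrameError(f"internal stop codon {codon} at codon {j + 1}")
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def codon_counts(cds: str) -> dict[str, int]:
    """Sense-codon counts of a CDS (terminal stop allowed and dropped)."""
    counts = {c: 0 for c in SENSE_CODONS}
    for codon in _validate_cds(cds):
        counts[codon] += 1
    return counts


@dataclass
class CodonUsageTable:
    """Raw sense-codon counts plus per-amino-acid synonymous frequencies."""

    counts: dict[str, int]
    frequencies: dict[str, float] = field(init=False)

    def __post_init__(self):
        unknown = set(self.counts) - set(SENSE_CODONS)
        if unknown:
            raise EddScreenError(f"unknown codons {sorted(unknown)[:3]}")
        self.counts = {c: int(self.counts.get(c, 0)) for c in SENSE_CODONS}
        if any(v < 0 for v in self.counts.values()):
            raise EddScreenError("negative codon count")
        self.frequencies = {}
        for aa, codons in _SYNONYMS.items():
            total = sum(self.counts[c] for c in codons)
            for c in codons:
                self.frequencies[c] = self.counts[c] / total if total else float("nan")

    def conditional(self, codon: str, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
        """Pseudocounted probability of a codon given its amino acid."""
        aa = CODON_TO_AA[codon]
        codons = _SYNONYMS[aa]
        total = sum(self.counts[c] for c in codons)
        return (self.counts[codon] + pseudocount) / (total + pseudocount * len(codons))

    @classmethod
    def from_cds(cls, cds: str) -> "CodonUsageTable":
        return cls(codon_counts(cds))

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        """Read a codon/count TSV (64 or 61 rows; stop codons ignored)."""
        table = pd.read_csv(path, sep="\t", dtype={"codon": str})
        counts = {
            str(row["codon"]).upper(): int(row["count"])
            for _, row in table.iterrows()
            if str(row["codon"]).upper() in CODON_TO_AA
        }
        return cls(counts)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"codon": SENSE_CODONS, "count": [self.counts[c] for c in SENSE_CODONS]}
        ).to_csv(path, sep="\t", index=False)


def rscu(cds: str) -> dict[str, float]:
    """Relative synonymous codon usage of a CDS.

    RSCU_c = observed_c * n_synonyms / total_for_amino_acid.  Codons of
    unobserved amino acids are excluded (undefined).
    """
    counts = codon_counts(cds)
    out: dict[str, float] = {}
    for aa, codons in _SYNONYMS.items():
        total = sum(counts[c] for c in codons)
        if total == 0:
            continue
        for c in codons:
            out[c] = counts[c] * len(codons) / total
    return out


def rscu_distance(a: dict[str, float], b: dict[str, float]) -> float:
    """Euclidean distance over RSCU entries defined in both tables."""
    shared = sorted(set(a) & set(b))
    return math.sqrt(sum((a[c] - b[c]) ** 2 for c in shared))


def codon_llr(
    cds: str,
    host: CodonUsageTable,
    bacterial: CodonUsageTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Per-amino-acid-conditioned log-likelihood ratio, in nats.

    Positive values favor a bacterial origin of the CDS; the statistic is
    antisymmetric in the two tables and extensive in CDS length.
    """
    total = 0.0
    for codon in _validate_cds(cds):
        if codon in STOP_CODONS:
            continue
        p_b = bacterial.conditional(codon, pseudocount)
        p_h = host.conditional(codon, pseudocount)
        total += math.log(p_b / p_h)
    return total


@dataclass(frozen=True)
class ArtefactVerdict:
    gene_id: str
    codon_llr: float | None
    rscu_distance_host: float | None
    rscu_distance_bacterial: float | None
    has_introns: bool | None
    has_transit_peptide: bool | None
    nested_in_bacterial_clade: bool | None
    criteria_met: int
    criteria_observable: int
    missing_criteria: tuple[str, ...]
    verdict: str  # 'artefact' | 'genuine' | 'indeterminate'


def _quorum(observable: int) -> int:
    # >=3 of 4 when all observable, >=2 of 2-3, never a single criterion
    if observable >= 4:
        return 3
    if observable >= 2:
        return 2
    return math.inf  # unreachable with one criterion


def artefact_verdict(
    gene: GeneRecord,
    host: CodonUsageTable | None = None,
    bacterial: CodonUsageTable | None = None,
    nested_in_bacterial_clade: bool | None = None,
) -> ArtefactVerdict:
    """Score one gene against the four artefact criteria.

    Criteria with no data shrink the observable denominator and are listed
    in ``missing_criteria``.  The call is symmetric: ``genuine`` needs as
    many clean criteria as ``artefact`` needs dirty ones.
    """
    llr = None
    d_host = d_bact = None
    if gene.cds is not None and host is not None and bacterial is not None:
        llr = codon_llr(gene.cds, host, bacterial)
        gene_rscu = rscu(gene.cds)
        host_rscu = {
            c: host.frequencies[c] * len(_SYNONYMS[CODON_TO_AA[c]])
            for c in SENSE_CODONS
            if host.frequencies[c] == host.frequencies[c]  # not NaN
        }
        bact_rscu = {
            c: bacterial.frequencies[c] * len(_SYNONYMS[CODON_TO_AA[c]])
            for c in SENSE_CODONS
            if bacterial.frequencies[c] == bacterial.frequencies[c]
        }
        d_host = rscu_distance(gene_rscu, host_rscu)
        d_bact = rscu_distance(gene_rscu, bact_rscu)

    has_introns = None if gene.exon_count is None else gene.exon_count > 1
    has_ctp = gene.transit_peptide

    criteria: dict[str, bool | None] = {
        "codon_usage_bacterial": None if llr is None else llr > 0,
        "no_introns": None if has_introns is None else not has_introns,
        "no_transit_peptide": None if has_ctp is None else not has_ctp,
        "nested_in_bacterial_clade": nested_in_bacterial_clade,
    }
    observable = sum(1 for v in criteria.values() if v is not None)
    met = sum(1 for v in criteria.values() if v is True)
    missing = tuple(k for k, v in criteria.items() if v is None)

    if observable == 0:
        raise EddScreenError(
            f"no artefact criteria computable for gene {gene.protein.id!r}"
        )
    quorum = _quorum(observable)
    if met >= quorum:
        verdict = "artefact"
    elif (observable - met) >= quorum:
        verdict = "genuine"
    else:
        verdict = "indeterminate"

    return ArtefactVerdict(
        gene_id=gene.protein.id,
        codon_llr=llr,
        rscu_distance_host=d_host,
        rscu_distance_bacterial=d_bact,
        has_introns=has_introns,
        has_transit_peptide=has_ctp,
        nested_in_bacterial_clade=nested_in_bacterial_clade,
        criteria_met=met,
        criteria_observable=observable,
        missing_criteria=missing,
        verdict=verdict,
    )


def transit_peptide_heuristic(residues: str, window: int = 60) -> bool:
    """Naive N-terminal transit-peptide guess; never applied silently.

    True when the first ``window`` residues are serine/threonine-rich
    (>= 20%) and acidic-poor (aspartate+glutamate <= 8%).
    """
    head = residues[:window]
    if not head:
        return False
    st = sum(head.count(c) for c in "ST")
    de = sum(head.count(c) for c in "DE")
    return st / len(head) >= 0.20 and de / len(head) <= 0.08
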