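"""Per-genome ED-pathway completeness calling and survey tables.

A complete (phosphorylated) ED pathway requires both an EDD and an EDA
gene; KDPG is predicted detectable exactly in complete genomes.  Genes
flagged as bacterial artefacts are excluded from presence calls but kept
in reports with their verdict.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .errors import DuplicateIdError, EddScreenError
from .seqio import ProteinRecord

GENE_CLASSES = ("EDD", "EDA", "DHAD", "other")

__all__ = [
    "GeneRecord",
    "PathwayStatus",
    "call_pathway_status",
    "survey_table",
    "load_accession_table",
    "accession_table_path",
]


@dataclass
class GeneRecord:
    """One gene of a genome inventory."""

    gene_class: str
    protein: ProteinRecord
    cds: str | None = None
    exon_count: int | None = None
    transit_peptide: bool | None = None
    is_artefact: bool | None = None  # verdict from the artefact filter

    def __post_init__(self):
        if self.gene_class not in GENE_CLASSES:
            raise EddScreenError(
                f"unknown gene class {self.gene_class!r}; expected one of {GENE_CLASSES}"
            )
        if self.cds is not None and len(self.cds) % 3 != 0:
            raise EddScreenError(
                f"CDS length {len(self.cds)} of {self.protein.id!r} not divisible by 3"
            )
        if self.exon_count is not None and self.exon_count < 1:
            raise EddScreenError(f"exon_count must be >= 1, got {self.exon_count}")


@dataclass(frozen=True)
class PathwayStatus:
    taxon: str
    has_edd: bool
    has_eda: bool
    has_dhad: bool
    ed_status: str  # 'complete' | 'eda_only' | 'edd_only' | 'absent'
    kdpg_predicted: bool


def _ed_status(has_edd: bool, has_eda: bool) -> str:
    if has_edd and has_eda:
        return "complete"
    if has_eda:
        return "eda_only"
    if has_edd:
        return "edd_only"
    return "absent"


def call_pathway_status(inventory, taxon: str) -> PathwayStatus:
    """Gene co-occurrence rule for one genome (empty inventory -> absent)."""

    def present(cls: str) -> bool:
        return any(
            g.gene_class == cls and not g.is_artefact for g in inventory
        )

    has_edd, has_eda, has_dhad = present("EDD"), present("EDA"), present("DHAD")
    status = _ed_status(has_edd, has_eda)
    return PathwayStatus(
        taxon=taxon,
        has_edd=has_edd,
        has_eda=has_eda,
        has_dhad=has_dhad,
        ed_status=status,
        kdpg_predicted=(status == "complete"),
    )


def survey_table(
    inventories: dict[str, list[GeneRecord]],
    groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the co-occurrence rule across taxa.

    Returns a per-taxon table (taxon, group, has_edd, has_eda, has_dhad,
    ed_status, kdpg_predicted) and per-group summary counts of
    EDD/EDA-positive and ED-complete taxa.
    """
    groups = groups or {}
    taxa = list(inventories)
    if len(taxa) != len(set(taxa)):
        raise DuplicateIdError("duplicate taxon in inventories")
    rows = []
    for taxon in taxa:
        st = call_pathway_status(inventories[taxon], taxon)
        rows.append(
            {
                "taxon": taxon,
                "group": groups.get(taxon, "unassigned"),
                "has_edd": st.has_edd,
                "has_eda": st.has_eda,
                "has_dhad": st.has_dhad,
                "ed_status": st.ed_status,
                "kdpg_predicted": st.kdpg_predicted,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "taxon", "group", "has_edd", "has_eda", "has_dhad",
            "ed_status", "kdpg_predicted",
        ],
    )
    if table.empty:
        summary = pd.DataFrame(
            columns=["group", "n_taxa", "edd_positive", "eda_positive", "ed_complete"]
        )
    else:
        summary = (
            table.groupby("group", sort=True)
            .agg(
                n_taxa=("taxon", "size"),
                edd_positive=("has_edd", "sum"),
                eda_positive=("has_eda", "sum"),
                ed_complete=("kdpg_predicted", "sum"),
            )
            .reset_index()
        )
    return table, summary


# ---------------------------------------------------------------------------
# curated dehydratase accession table
# ---------------------------------------------------------------------------

ACCESSION_COLUMNS = ["accession", "taxon", "group", "gene_class"]


def accession_table_path():
    """Path to the packaged curated EDD/DHAD accession table."""
    return importlib.resources.files("edd_screen") / "data" / "accession_table.tsv"


def load_accession_table(path=None) -> pd.DataFrame:
    """Load and validate a curated dehydratase accession table (TSV).

    Required columns: accession, taxon, group, gene_class.  Accessions must
    be unique and gene_class one of EDD/DHAD.
    """
    path = path or accession_table_path()
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ACCESSION_COLUMNS if c not in table.columns]
    if missing:
        raise EddScreenError(f"accession table missing columns {missing}")
    if table["accession"].duplicated().any():
        dupes = table.loc[table["accession"].duplicated(), "accession"].tolist()
        raise DuplicateIdError(f"duplicate accessions {dupes[:5]}")
    bad = ~table["gene_class"].isin(["EDD", "DHAD"])
    if bad.any():
        raise EddScreenError(
            f"unexpected gene_class values {sorted(table.loc[bad, 'gene_class'].unique())}"
        )
    if table[ACCESSION_COLUMNS].isna().any().any():
        raise EddScreenError("accession table contains empty cells")
    return table
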