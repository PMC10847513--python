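"""Readers/writers for FASTA, aligned FASTA, Newick, and header-TSV tables.

Coordinate convention: residue coordinates are 1-based and inclusive
everywhere in this package, counting from the initiator methionine.
FASTA headers carry optional metadata as whitespace-separated fields:
``>id [taxon] [group_label]``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    DuplicateIdError,
    FastaFormatError,
    NewickParseError,
)
from .tree import PhyloTree, TreeNode

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
GAP = "-"

__all__ = [
    "AMINO_ACIDS",
    "PROTEIN_ALPHABET",
    "ProteinRecord",
    "AlignedRow",
    "AlignmentBlock",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_newick",
    "write_newick",
]


@dataclass(frozen=True)
class ProteinRecord:
    """An ungapped protein sequence with optional taxon/group metadata."""

    id: str
    residues: str
    taxon: str | None = None
    group_label: str | None = None

    def __post_init__(self):
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in PROTEIN_ALPHABET:
                raise AlphabetError(ch, i, context=f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedRow:
    """One row of a multiple alignment; gaps ('-') allowed."""

    id: str
    residues: str
    taxon: str | None = None
    group_label: str | None = None

    def __post_init__(self):
        if not self.residues.replace(GAP, ""):
            raise AlignmentShapeError(f"row {self.id!r} is all gaps")
        for i, ch in enumerate(self.residues, start=1):
            if ch != GAP and ch not in PROTEIN_ALPHABET:
                raise AlphabetError(ch, i, context=f"row {self.id!r}")

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class AlignmentBlock:
    """A multiple sequence alignment with residue/column coordinate maps."""

    rows: list[AlignedRow]
    _col_maps: list[list[int]] = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.rows) < 2:
            raise AlignmentShapeError("an alignment requires at least 2 rows")
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"ragged alignment rows: lengths {sorted(lengths)}")
        seen: set[str] = set()
        for r in self.rows:
            if r.id in seen:
                raise DuplicateIdError(f"duplicate row id {r.id!r}")
            seen.add(r.id)
        # 1-based column of the k-th non-gap residue, per row
        self._col_maps = [
            [col for col, ch in enumerate(r.residues, start=1) if ch != GAP]
            for r in self.rows
        ]

    @property
    def length(self) -> int:
        return len(self.rows[0].residues)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, col: int) -> list[str]:
        """Residues (including gaps) of a 1-based column."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        return [r.residues[col - 1] for r in self.rows]

    def residue_to_column(self, row: int, k: int) -> int:
        """Column (1-based) holding the k-th (1-based) residue of a row."""
        return self._col_maps[row][k - 1]

    def column_to_residue(self, row: int, col: int) -> int | None:
        """Ungapped residue index at a column, or None on a gap."""
        ch = self.rows[row].residues[col - 1]
        if ch == GAP:
            return None
        return self.rows[row].residues[: col].replace(GAP, "").__len__()


def _parse_header(description: str) -> tuple[str, str | None, str | None]:
    fields = description.split()
    rec_id = fields[0]
    taxon = fields[1] if len(fields) > 1 else None
    group = fields[2] if len(fields) > 2 else None
    return rec_id, taxon, group


def _iter_fasta(path) -> list:
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def read_fasta(path) -> list[ProteinRecord]:
    """Read an ungapped protein FASTA file.

    Raises :class:`DuplicateIdError` on repeated ids and
    :class:`AlphabetError` on characters outside the 20 amino acids plus X.
    """
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in _iter_fasta(path):
        rec_id, taxon, group = _parse_header(rec.description)
        if rec_id in seen:
            raise DuplicateIdError(f"duplicate record id {rec_id!r} in {path}")
        seen.add(rec_id)
        out.append(
            ProteinRecord(
                id=rec_id,
                residues=str(rec.seq).upper(),
                taxon=taxon,
                group_label=group,
            )
        )
    return out


def write_fasta(records, path, width: int = 60) -> None:
    """Write protein records (or aligned rows) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            header_fields = [rec.id]
            if rec.taxon:
                header_fields.append(rec.taxon)
            if rec.group_label:
                header_fields.append(rec.group_label)
            fh.write(">" + " ".join(header_fields) + "\n")
            seq = rec.residues
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path) -> AlignmentBlock:
    """Read an aligned FASTA file into an :class:`AlignmentBlock`."""
    rows: list[AlignedRow] = []
    for rec in _iter_fasta(path):
        rec_id, taxon, group = _parse_header(rec.description)
        rows.append(
            AlignedRow(
                id=rec_id,
                residues=str(rec.seq).upper(),
                taxon=taxon,
                group_label=group,
            )
        )
    return AlignmentBlock(rows)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _check_balanced(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
    if depth != 0:
        raise NewickParseError("unbalanced '(': missing closing parenthesis",
                               offset=len(text) - 1)


def _convert_skbio(node, is_root: bool) -> TreeNode:
    children = [_convert_skbio(c, False) for c in node.children]
    name = node.name
    support = None
    if children and name is not None:
        # numeric internal labels are bootstrap supports
        try:
            support = float(name)
            name = None
        except ValueError:
            pass
    return TreeNode(
        name=name,
        length=None if is_root else node.length,
        support=support,
        children=children,
    )


def read_newick(source) -> PhyloTree:
    """Parse a Newick string or file into a :class:`PhyloTree`.

    Numeric internal-node labels are interpreted as bootstrap supports.
    """
    import skbio  # deferred: slow import

    if isinstance(source, str) and "(" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    text = text.strip()
    _check_balanced(text)
    try:
        sk_tree = skbio.TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises several format error types
        raise NewickParseError(str(exc)) from exc
    return PhyloTree(_convert_skbio(sk_tree, is_root=True))


def _fmt_len(x: float | None) -> str:
    return "" if x is None else ":" + format(float(x), ".6g")


def _write_node(node: TreeNode, canonical: bool) -> str:
    if node.is_leaf:
        return (node.name or "") + _fmt_len(node.length)
    children = node.children
    if canonical:
        children = sorted(children, key=lambda c: min(c.leaf_names()))
    inner = ",".join(_write_node(c, canonical) for c in children)
    label = ""
    if node.support is not None:
        label = format(node.support, ".6g")
    elif node.name:
        label = node.name
    return f"({inner}){label}" + _fmt_len(node.length)


def write_newick(tree: PhyloTree, canonical: bool = True) -> str:
    """Serialise a tree to Newick.

    With ``canonical=True`` children are ordered by their smallest leaf
    label so that parse-write round trips are stable.
    """
    return _write_node(tree.root, canonical) + ";"
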