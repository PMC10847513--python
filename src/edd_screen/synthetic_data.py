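"""Seeded generators for every input the pipeline consumes.

All generators are deterministic for a given spec + seed, and every
generated object carries its planted ground truth so end-to-end accuracy
is computable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artefact_filter import CODON_TO_AA, _SYNONYMS, CodonUsageTable
from .errors import EddScreenError
from .genome_survey import GeneRecord
from .kinetics import CalibrationSeries, KineticDataset
from .seqio import AlignedRow, AlignmentBlock, ProteinRecord
from .tree import PhyloTree, TreeNode

_AA = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "FamilySpec",
    "ContaminantSpec",
    "make_family",
    "make_cds",
    "make_kinetic_data",
    "make_standard_addition_series",
    "make_codon_table",
    "random_protein",
    "interspersion_fixture",
]


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA), size=length))


# ---------------------------------------------------------------------------
# protein families with planted motifs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for a dehydratase-like family diverged from a seed sequence."""

    seed_sequence: str
    n_members: int
    p_sub: float  # expected root-to-tip per-site substitution probability
    protected_columns: frozenset[int] = frozenset()  # 1-based, motif sites
    motifs_intact: bool = True  # False: randomize protected columns instead
    group_label: str = "family"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_sub < 1:
            raise EddScreenError("p_sub must be in [0, 1)")
        bad = [c for c in self.protected_columns
               if not 1 <= c <= len(self.seed_sequence)]
        if bad:
            raise EddScreenError(f"protected columns {bad[:5]} outside sequence")
        if self.n_members < 1:
            raise EddScreenError("n_members must be >= 1")


@dataclass
class Family:
    records: list[ProteinRecord]
    alignment: AlignmentBlock | None
    tree: PhyloTree | None
    spec: FamilySpec


def _random_bifurcating(names: list[str], rng: np.random.Generator) -> TreeNode:
    nodes = [TreeNode(name=n, length=float(rng.exponential(1.0)) + 0.05)
             for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode(
            children=[a, b], length=float(rng.exponential(1.0)) + 0.05
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def _max_root_tip(node: TreeNode) -> float:
    own = node.length or 0.0
    if node.is_leaf:
        return own
    return own + max(_max_root_tip(c) for c in node.children)


def make_family(spec: FamilySpec) -> Family:
    """Evolve a family along a random bifurcating tree.

    Unprotected sites substitute per branch with probability
    1-(1-p_sub)^(branch length) after normalising the deepest root-to-tip
    path to 1, so overall divergence from the seed is about ``p_sub`` per
    site.  Protected columns never mutate when ``motifs_intact``; when
    ablated they are fully randomised per member.  Because no indels are
    simulated, the true alignment equals the sequence stack.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"{spec.group_label}_{i + 1:02d}" for i in range(spec.n_members)]

    if spec.n_members == 1:
        tree = None
        tip_seqs = {names[0]: _evolve_once(spec, rng, spec.seed_sequence, 1.0)}
    else:
        root = _random_bifurcating(names, rng)
        depth = _max_root_tip(root)
        scale = 1.0 / depth if depth > 0 else 1.0

        tip_seqs: dict[str, str] = {}

        def descend(node: TreeNode, seq: str):
            frac = (node.length or 0.0) * scale
            seq = _evolve_once(spec, rng, seq, frac)
            if node.is_leaf:
                tip_seqs[node.name] = seq
            else:
                for c in node.children:
                    descend(c, seq)

        descend(root, spec.seed_sequence)
        tree = PhyloTree(root)

    records = []
    for n in names:
        seq = tip_seqs[n]
        if not spec.motifs_intact and spec.protected_columns:
            chars = list(seq)
            for col in spec.protected_columns:
                chars[col - 1] = _AA[rng.integers(0, 20)]
            seq = "".join(chars)
        records.append(
            ProteinRecord(id=n, residues=seq, group_label=spec.group_label)
        )

    alignment = None
    if len(records) >= 2:
        alignment = AlignmentBlock(
            [AlignedRow(id=r.id, residues=r.residues,
                        group_label=r.group_label) for r in records]
        )
    return Family(records=records, alignment=alignment, tree=tree, spec=spec)


def _evolve_once(
    spec: FamilySpec, rng: np.random.Generator, seq: str, branch_frac: float
) -> str:
    p_edge = 1.0 - (1.0 - spec.p_sub) ** branch_frac if spec.p_sub else 0.0
    if p_edge <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if (i + 1) in spec.protected_columns:
            continue  # motif sites mutate only via explicit ablation
        if rng.random() < p_edge:
            current = chars[i]
            choices = [a for a in _AA if a != current]
            chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# coding sequences from codon-usage tables
# ---------------------------------------------------------------------------


def make_codon_table(gc3: float, weight: float = 1000.0) -> CodonUsageTable:
    """Synthetic codon-usage table biased by third-position GC content."""
    if not 0 < gc3 < 1:
        raise EddScreenError("gc3 must be in (0, 1)")
    counts = {}
    for codon in CODON_TO_AA:
        p3 = gc3 if codon[2] in "GC" else 1.0 - gc3
        counts[codon] = max(1, round(weight * p3))
    return CodonUsageTable(counts)


@dataclass(frozen=True)
class ContaminantSpec:
    """Recipe for a CDS with a planted origin (host vs bacterial)."""

    protein: ProteinRecord
    origin: str  # 'host' | 'bacterial' — hidden truth label
    host_table: CodonUsageTable = field(compare=False, default=None)
    bacterial_table: CodonUsageTable = field(compare=False, default=None)
    intron_count: int = 0
    transit_peptide: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.origin not in ("host", "bacterial"):
            raise EddScreenError(f"origin must be host|bacterial, got {self.origin!r}")
        if self.intron_count < 0:
            raise EddScreenError("intron_count must be >= 0")


def make_cds(spec: ContaminantSpec) -> tuple[GeneRecord, str]:
    """Reverse-translate a protein sampling synonymous codons.

    Returns the gene record and its hidden origin label.
    """
    host = spec.host_table or make_codon_table(0.4)
    bact = spec.bacterial_table or make_codon_table(0.7)
    table = bact if spec.origin == "bacterial" else host
    rng = np.random.default_rng(spec.seed)
    codons = []
    for aa in spec.protein.residues:
        if aa == "X":
            aa = "A"  # unknown residues encoded arbitrarily
        syn = _SYNONYMS[aa]
        probs = np.array([table.conditional(c, 0.0) for c in syn])
        probs = probs / probs.sum()
        codons.append(syn[rng.choice(len(syn), p=probs)])
    gene = GeneRecord(
        gene_class="EDD",
        protein=spec.protein,
        cds="".join(codons),
        exon_count=spec.intron_count + 1,
        transit_peptide=spec.transit_peptide,
    )
    return gene, spec.origin


# ---------------------------------------------------------------------------
# kinetics and calibration
# ---------------------------------------------------------------------------


def make_kinetic_data(
    km: float,
    vmax: float,
    design,
    noise_cv: float = 0.0,
    replicates: int = 1,
    seed: int | None = None,
) -> KineticDataset:
    """Michaelis-Menten rates with multiplicative lognormal noise.

    ``noise_cv`` is the coefficient of variation of the mean-1 lognormal
    noise factor; 0 gives rates exactly on the curve.
    """
    if km <= 0 or vmax <= 0:
        raise EddScreenError("km and vmax must be > 0")
    if noise_cv < 0 or replicates < 1:
        raise EddScreenError("bad noise_cv or replicates")
    rng = np.random.default_rng(seed)
    s = np.tile(np.asarray(design, dtype=float), replicates)
    rep = np.repeat(np.arange(1, replicates + 1), len(design))
    v = vmax * s / (km + s)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        mu = -0.5 * sigma**2
        v = v * rng.lognormal(mean=mu, sigma=sigma, size=s.shape)
    return KineticDataset(substrate=s, rate=v, replicate=rep)


def make_standard_addition_series(
    endogenous: float,
    slope: float,
    spikes,
    noise_sd: float = 0.0,
    rel_noise: float = 0.0,
    blank_sd: float = 0.0,
    seed: int | None = None,
) -> CalibrationSeries:
    """Linear spike-response series with Gaussian baseline noise.

    ``noise_sd`` adds homoscedastic Gaussian noise to the responses;
    ``rel_noise`` instead scales each response by (1 + rel_noise * N(0,1)).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(spikes, dtype=float)
    y = slope * (endogenous + x)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(size=x.shape)
    if rel_noise > 0:
        y = y * (1.0 + rel_noise * rng.standard_normal(size=x.shape))
    return CalibrationSeries(amount=x, response=y, blank_sd=blank_sd,
                             design="standard_addition")


# ---------------------------------------------------------------------------
# phylogenetic fixtures
# ---------------------------------------------------------------------------


def interspersion_fixture() -> tuple[PhyloTree, dict[str, str]]:
    """Gene tree with 4 in-group leaves scattered across 3 donor clades.

    Mimics the observed placement of the rare cyanobacterial EDD sequences
    inside proteobacterial/archaeal diversity: the in-group is not
    monophyletic and the parsimony interspersion index is 3.
    """

    def leaf(n):
        return TreeNode(name=n, length=1.0)

    def clade(*children):
        return TreeNode(children=list(children), length=1.0)

    # donor clade 1 harbours cyano_1 and cyano_2; clades 2 and 3 one each
    c1 = clade(clade(leaf("cyano_1"), leaf("cyano_2")),
               clade(leaf("proteo_1"), leaf("proteo_2")))
    c2 = clade(leaf("cyano_3"), clade(leaf("proteo_3"), leaf("proteo_4")))
    c3 = clade(leaf("cyano_4"), clade(leaf("archaea_1"), leaf("archaea_2")))
    root = TreeNode(children=[c1, c2, c3])
    tree = PhyloTree(root)
    labels = {
        name: ("in" if name.startswith("cyano") else "out")
        for name in tree.leaf_names
    }
    return tree, labels
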