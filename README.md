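# edd-screen

Toolkit for deciding whether a genome encodes a genuine 6-phosphogluconate
dehydratase (EDD) — and hence a complete Entner–Doudoroff (ED) pathway —
rather than its look-alike paralog, dihydroxy-acid dehydratase (DHAD).
It bundles the complete desk-scale analysis chain:

- **`seqio`** — FASTA / aligned-FASTA / Newick / TSV readers and writers
  with strict validation and 1-based residue↔column coordinate maps.
- **`consensus`** — per-column similarity shading (0.60 / 0.80 cutoffs,
  configurable Dayhoff-like grouping) and consensus motif derivation.
- **`motifs` / `classifier`** — motif pattern syntax
  (`LAHGFAAx{4}[DE]Kx{3}`, `KxK[VI]RQLYAx{2}K` built in), approximate
  best-window scanning with a mismatch budget, and EDD/DHAD/unknown calls
  (DHAD is only ever called by reference similarity, never by motif).
- **`genome_survey`** — ED-pathway completeness per genome (complete ⇔
  EDD ∧ EDA), KDPG-detectability prediction, survey tables, and a curated
  155-record dehydratase accession table.
- **`artefact_filter`** — bacterial-contaminant screening of putative
  eukaryotic EDD genes: per-amino-acid codon-usage log-likelihood ratio,
  RSCU distances, intron / transit-peptide / phylogenetic-placement
  criteria under a ≥3-of-4 quorum rule.
- **`phylo`** — Poisson-corrected protein distances, neighbor joining
  (exact on additive matrices), column-bootstrap supports, monophyly
  testing, and a Fitch/Hartigan parsimony interspersion index for
  lateral-gene-transfer signal.
- **`kinetics`** — Lineweaver–Burk and nonlinear Michaelis–Menten fits,
  standard-addition quantification with error propagation, 3σ/10σ
  LOD/LOQ, and equimolar-stoichiometry checks.
- **`synthetic_data`** — seeded generators (motif-planted protein
  families with true tree/alignment, codon-usage-biased CDSs, kinetic and
  calibration series) so every stage is testable offline with planted
  ground truth.

Residue coordinates are 1-based and inclusive throughout, counting the
initiator methionine; packaged coordinates refer to UniProt P0ADF6.

## Test

```bash
python -m pytest -q tests/
```

The suite contains unit tests per module, property tests for the spec
invariants (hypothesis where useful), and `tests/test_acceptance.py` with
one test per acceptance criterion. One acceptance test
(`TestMotifAnchoring`) intentionally encodes the literature's printed
42–57 window and fails against the genuine P0ADF6 sequence, where the
motif instance starts at residue 45 (see the test docstring).

## CLI

```bash
edd-screen validate  --fasta proteins.fa
edd-screen classify  --fasta proteins.fa --refs refs.fa --out calls.tsv
edd-screen consensus --msa aln.afa --span 40:60 --cutoffs 0.6,0.8
edd-screen survey    --inventory inventory.tsv --out survey.tsv
edd-screen artefact  --cds cds.fa --exons meta.tsv --out verdicts.tsv
edd-screen phylo     --msa all.afa --bootstrap 1000 --seed 42 \
                     --group-file groups.tsv --test-monophyly cyanobacteria
edd-screen kinetics fit   --data rates.tsv --method both
edd-screen kinetics quant --data series.tsv --blank-sd 0.3
edd-screen kinetics lod   --slope 1.0 --blank-sd 0.83
edd-screen simulate family   --members 10 --p-sub 0.2 --out family.fa
edd-screen simulate kinetics --km 0.31 --vmax 5 --out rates.tsv
```

## Packaged data (`src/edd_screen/data/`)

- `P0ADF6.fasta` — E. coli EDD protein (from a curated SwissProt bundle).
- `dehydratase_refs.fasta` — EDD/DHAD reference proteins; the third
  header field carries the class label used by `classify --refs`.
- `accession_table.tsv` — 155-record curated EDD/DHAD survey table
  (4 cyanobacterial EDD entries); placeholder accessions are clearly
  marked (`EDD_PRO_0001`-style).
- `host_codon_usage.tsv`, `bacterial_codon_usage.tsv` — GC3-divergent
  codon-usage tables (0.4 vs 0.7) for artefact screening defaults.
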