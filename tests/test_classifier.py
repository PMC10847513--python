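"""Motif scanning and dehydratase calling, checked against a brute-force
window-enumeration oracle and planted-truth simulations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edd_screen.classifier import (
    classify_dehydratase,
    default_library,
    scan_sequence,
    ungapped_identity,
)
from edd_screen.errors import ConfigurationError
from edd_screen.motifs import parse_pattern
from edd_screen.seqio import ProteinRecord
from edd_screen.synthetic_data import FamilySpec, make_family, random_protein

AA = "ACDEFGHIKLMNPQRSTVWY"

DOMAIN1 = parse_pattern("LAHGFAAx{4}[DE]Kx{3}", name="domain1")
DOMAIN2 = parse_pattern("KxK[VI]RQLYAx{2}K", name="domain2")

# a seed EDD-like protein with both motifs planted at known positions
SEED_LEN = 160
D1_START, D2_START = 42, 100  # 1-based


def planted_seed(rng):
    seq = list(random_protein(SEED_LEN, rng))
    seq[D1_START - 1 : D1_START + 15] = "LAHGFAAQRSTDKAAA"
    seq[D2_START - 1 : D2_START + 11] = "KAKVRQLYAGGK"
    return "".join(seq)


def motif_columns():
    cols = set(range(D1_START, D1_START + 16)) | set(
        range(D2_START, D2_START + 12)
    )
    return frozenset(cols)


def oracle_scan(seq: str, pattern_text: str):
    """Independent per-window scorer (fixed-length patterns only)."""
    pat = []
    i = 0
    while i < len(pattern_text):
        ch = pattern_text[i]
        if ch == "[":
            j = pattern_text.index("]", i)
            pat.append(set(pattern_text[i + 1 : j]))
            i = j + 1
        elif ch == "x":
            if i + 1 < len(pattern_text) and pattern_text[i + 1] == "{":
                j = pattern_text.index("}", i)
                pat.extend([None] * int(pattern_text[i + 2 : j]))
                i = j + 1
            else:
                pat.append(None)
                i += 1
        else:
            pat.append({ch})
            i += 1
    out = []
    for start in range(len(seq) - len(pat) + 1):
        matched = 0
        for off, elem in enumerate(pat):
            if elem is None:
                continue
            c = seq[start + off]
            if c == "X" or c in elem:
                matched += 1
        out.append((start + 1, matched))
    return out


class TestScanSequence:
    def test_planted_domain1_found_exactly(self, rng):
        seq = planted_seed(rng)
        protein = ProteinRecord(id="p", residues=seq)
        matches = scan_sequence(protein, DOMAIN1, max_mismatch=0)
        best = max(matches, key=lambda m: m.score)
        assert (best.start, best.end, best.score) == (D1_START, D1_START + 15, 1.0)

    def test_literal_substring_start_42(self):
        # exact instance 'LAHGFAAQRST DK AAA' placed so the window is 42-57
        seq = "M" * 41 + "LAHGFAAQRSTDKAAA" + "M" * 30
        matches = scan_sequence(ProteinRecord(id="p", residues=seq), DOMAIN1)
        best = max(matches, key=lambda m: m.score)
        assert (best.start, best.end, best.score) == (42, 57, 1.0)

    def test_aa_on_aaa_two_windows(self):
        pat = parse_pattern("AA")
        matches = scan_sequence(ProteinRecord(id="p", residues="AAA"), pat)
        assert [(m.start, m.end) for m in matches] == [(1, 2), (2, 3)]
        assert all(m.score == 1.0 for m in matches)

    def test_pattern_longer_than_sequence(self):
        assert scan_sequence(ProteinRecord(id="p", residues="MK"), DOMAIN1) == []

    def test_x_in_sequence_matches_any(self):
        pat = parse_pattern("AKW")
        matches = scan_sequence(ProteinRecord(id="p", residues="XXX"), pat)
        assert matches[0].score == 1.0

    def test_best_window_reported_even_below_budget(self, rng):
        protein = ProteinRecord(id="p", residues=random_protein(80, rng))
        matches = scan_sequence(protein, DOMAIN1, max_mismatch=0)
        assert matches  # the flagged best window is always present
        best = max(matches, key=lambda m: m.score)
        if best.score < 1.0:
            assert best.sub_threshold

    def test_agrees_with_oracle_on_random_sequences(self, rng):
        for _ in range(25):
            seq = random_protein(int(rng.integers(20, 200)), rng)
            for pat_text, pat in (
                ("LAHGFAAx{4}[DE]Kx{3}", DOMAIN1),
                ("KxK[VI]RQLYAx{2}K", DOMAIN2),
            ):
                oracle = dict(oracle_scan(seq, pat_text))
                got = scan_sequence(
                    ProteinRecord(id="p", residues=seq), pat,
                    max_mismatch=pat.n_scored,  # keep every window
                )
                got_scores = {
                    m.start: m.matched_literals for m in got if not m.sub_threshold
                }
                assert got_scores == oracle

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet=AA + "X", min_size=12, max_size=500))
    def test_oracle_property(self, seq):
        oracle = dict(oracle_scan(seq, "KxK[VI]RQLYAx{2}K"))
        got = {
            m.start: m.matched_literals
            for m in scan_sequence(
                ProteinRecord(id="p", residues=seq), DOMAIN2, max_mismatch=9
            )
            if not m.sub_threshold
        }
        assert got == oracle


class TestClassify:
    def test_both_motifs_intact_is_edd(self, rng):
        protein = ProteinRecord(id="p", residues=planted_seed(rng))
        call = classify_dehydratase(protein)
        assert call.label == "EDD"
        assert call.edd_score == 1.0

    def test_empty_library_rejected(self, rng):
        from edd_screen.classifier import MotifLibrary

        protein = ProteinRecord(id="p", residues=planted_seed(rng))
        with pytest.raises(ConfigurationError):
            classify_dehydratase(protein, MotifLibrary([]))

    def test_randomized_motifs_fall_back_to_reference(self, rng):
        seed = planted_seed(rng)
        spec = FamilySpec(
            seed_sequence=seed,
            n_members=1,
            p_sub=0.0,
            protected_columns=motif_columns(),
            motifs_intact=False,
            seed=7,
        )
        (member,) = make_family(spec).records
        # a DHAD reference at ~90% identity to the ablated protein
        ref_seq = list(member.residues)
        for pos in rng.choice(len(ref_seq), size=len(ref_seq) // 10, replace=False):
            ref_seq[pos] = AA[int(rng.integers(0, 20))]
        ref = ProteinRecord(id="dhad_ref", residues="".join(ref_seq),
                            group_label="DHAD")
        call = classify_dehydratase(member, references=[ref])
        assert call.edd_score < 0.8
        assert call.label == "DHAD"
        assert call.nearest_reference == "dhad_ref"

    def test_library_order_irrelevant(self, rng):
        from edd_screen.classifier import MotifLibrary

        protein = ProteinRecord(id="p", residues=random_protein(120, rng))
        lib = default_library()
        flipped = MotifLibrary(list(reversed(lib.entries)))
        a = classify_dehydratase(protein, lib)
        b = classify_dehydratase(protein, flipped)
        assert a.label == b.label
        assert a.edd_score == pytest.approx(b.edd_score)


class TestSeparation:
    """Planted-truth end-to-end accuracy at generator defaults."""

    def _families(self, intact, seed):
        # distinct backbones: the two paralog families do not share a seed
        rng = np.random.default_rng(99 if intact else 100)
        spec = FamilySpec(
            seed_sequence=planted_seed(rng),
            n_members=10,
            p_sub=0.2,
            protected_columns=motif_columns(),
            motifs_intact=intact,
            group_label="EDDfam" if intact else "DHADfam",
            seed=seed,
        )
        return make_family(spec)

    def test_intact_family_all_edd(self):
        fam = self._families(True, 11)
        calls = [classify_dehydratase(r) for r in fam.records]
        assert all(c.label == "EDD" for c in calls)
        assert all(c.edd_score == 1.0 for c in calls)

    def test_ablated_family_low_scores(self):
        fam = self._families(False, 12)
        calls = [classify_dehydratase(r) for r in fam.records]
        assert all(c.edd_score < 0.5 for c in calls)
        assert all(c.label != "EDD" for c in calls)

    def test_full_separation_with_references(self, reference_set):
        edd_fam = self._families(True, 13)
        dhad_fam = self._families(False, 14)
        # references: one intact member and one ablated member (held out)
        refs = [
            ProteinRecord(id="edd_ref",
                          residues=edd_fam.records[0].residues,
                          group_label="EDD"),
            ProteinRecord(id="dhad_ref",
                          residues=dhad_fam.records[0].residues,
                          group_label="DHAD"),
        ]
        correct = 0
        total = 0
        for rec in edd_fam.records[1:]:
            total += 1
            correct += classify_dehydratase(rec, references=refs).label == "EDD"
        for rec in dhad_fam.records[1:]:
            total += 1
            correct += classify_dehydratase(rec, references=refs).label == "DHAD"
        assert correct == total  # 100% accuracy at generator defaults

    def test_degrading_motifs_monotonically_lowers_score(self, rng):
        seed = planted_seed(rng)
        cols = sorted(motif_columns())
        scores = []
        for n_broken in (0, 5, 10, 10 + 8, len(cols)):
            chars = list(seed)
            for col in cols[:n_broken]:
                # substitute with a residue outside every element at that slot
                chars[col - 1] = "W" if chars[col - 1] != "W" else "C"
            call = classify_dehydratase(
                ProteinRecord(id=f"b{n_broken}", residues="".join(chars))
            )
            scores.append(call.edd_score)
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert scores[0] == 1.0 and scores[-1] < 0.6


class TestRealSequences:
    def test_ecoli_edd_called_edd(self, ecoli_edd, reference_set):
        refs = [r for r in reference_set if r.id != "P0ADF6"]
        call = classify_dehydratase(ecoli_edd, references=refs)
        assert call.label == "EDD"
        assert call.edd_score >= 0.9

    def test_ecoli_dhad_called_dhad(self, reference_set):
        dhad = next(r for r in reference_set if r.id == "P05791")
        refs = [r for r in reference_set if r.id != "P05791"]
        call = classify_dehydratase(dhad, references=refs)
        assert call.label == "DHAD"
        assert call.edd_score < 0.8

    def test_identity_bounds(self, ecoli_edd, rng):
        assert ungapped_identity(ecoli_edd.residues, ecoli_edd.residues) == 1.0
        assert ungapped_identity("MKVLL", "WWWWW") == 0.0
        a = random_protein(300, rng)
        b = random_protein(300, rng)
        assert ungapped_identity(a, b) < 0.2  # near the random baseline
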