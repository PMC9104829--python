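"""Multiple alignment, consensus profiling and isoform feature detection."""

import re

import numpy as np
import pytest

from phocomp.protprof import (MSA, build_consensus, detect_insertion,
                              find_pest, progressive_msa, similarity_profile)
from phocomp.sequtils import random_protein


class TestProgressiveMSA:
    def test_identical_sequences_gapless(self):
        seqs = [(f"s{i}", "MKVLATTWQRPDEG") for i in range(4)]
        msa = progressive_msa(seqs)
        assert all(row == "MKVLATTWQRPDEG" for row in msa.rows)

    def test_single_insertion_one_gap_block(self, rng):
        base = random_protein(60, rng)
        longer = base[:30] + "WWW" + base[30:]
        msa = progressive_msa([("a", base), ("b", longer), ("c", base)])
        for lab in ("a", "c"):
            row = msa.row(lab)
            blocks = re.findall(r"-+", row)
            assert blocks == ["---"]
        assert "-" not in msa.row("b")

    def test_degapping_recovers_inputs(self, rng):
        seqs = [(f"s{i}", random_protein(40 + i, rng)) for i in range(5)]
        msa = progressive_msa(seqs)
        for lab, seq in seqs:
            assert msa.degapped(lab) == seq

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([("a", "MKV"), ("a", "MKL")])

    def test_family_insertion_appears_as_gap_block(self, small_panel):
        # plastidial-family rows carry the mid-insertion; cytosolic rows
        # show a contiguous ~80-column gap against them
        p1 = small_panel.record("Mon1", "PHO1").protein
        p2 = small_panel.record("Mon1", "PHO2").protein
        msa = progressive_msa([("pho1", p1), ("pho2", p2)])
        longest_gap = max(len(b) for b in re.findall(r"-+", msa.row("pho2")))
        assert 70 <= longest_gap <= 90


class TestConsensus:
    def test_all_identical_returns_input(self):
        msa = MSA(labels=("a", "b", "c"), rows=("MKV", "MKV", "MKV"))
        assert build_consensus(msa, "a") == "MKV"

    def test_reference_wins_on_disagreement(self):
        msa = MSA(labels=("x", "y", "ref"), rows=("MAV", "MAV", "MSV"))
        # column 1 reads {A, A, S}: the reference residue S is kept
        assert build_consensus(msa, "ref") == "MSV"

    def test_reference_absent_rejected(self):
        msa = MSA(labels=("a", "b"), rows=("MK", "MK"))
        with pytest.raises(ValueError):
            build_consensus(msa, "zz")

    def test_consensus_idempotent(self, rng):
        seq = random_protein(50, rng)
        msa = MSA(labels=("a", "b", "c"), rows=(seq, seq, seq))
        cons = build_consensus(msa, "a")
        msa2 = MSA(labels=("p", "q"), rows=(cons, cons))
        assert build_consensus(msa2, "p") == cons


class TestSimilarityProfile:
    def _msa(self, rows):
        labels = tuple(f"m{i}" for i in range(len(rows)))
        return MSA(labels=labels, rows=tuple(rows))

    def test_unanimous_column_scores_five_in_both_clades(self):
        msa = MSA(labels=("m1", "m2", "d1", "d2"),
                  rows=("MK", "MK", "MK", "MK"))
        clades = {"m1": "monocot", "m2": "monocot", "d1": "dicot", "d2": "dicot"}
        prof = similarity_profile(msa, clades, "m1")
        assert all(v == 5 for v in prof.monocot_index)
        assert all(v == 5 for v in prof.dicot_index)

    def test_zero_matches_scores_zero(self):
        msa = MSA(labels=("m1", "m2", "d1", "d2"),
                  rows=("MA", "MA", "MC", "MD"))
        clades = {"m1": "monocot", "m2": "monocot", "d1": "dicot", "d2": "dicot"}
        prof = similarity_profile(msa, clades, "m1")
        # consensus col 1 is the reference's A; no dicot matches it
        assert prof.dicot_index[1] == 0

    def test_half_matches_round_half_away_from_zero(self):
        # 4 of 8 monocots matching: 5*4/8 = 2.5 rounds away from zero to 3
        rows = tuple(["MA"] * 4 + ["MC"] * 4 + ["MA", "MA"])
        labels = tuple(f"m{i}" for i in range(8)) + ("d1", "d2")
        clades = {f"m{i}": "monocot" for i in range(8)}
        clades.update({"d1": "dicot", "d2": "dicot"})
        prof = similarity_profile(MSA(labels=labels, rows=rows), clades, "m0")
        assert prof.monocot_index[1] == 3

    def test_permutation_invariant_within_clade(self, rng):
        seqs = [random_protein(30, rng) for _ in range(4)]
        labels = ("a", "b", "c", "d")
        clades = {"a": "monocot", "b": "monocot", "c": "dicot", "d": "dicot"}
        msa1 = progressive_msa(list(zip(labels, seqs)))
        prof1 = similarity_profile(msa1, clades, "a")
        swapped = [("b", seqs[1]), ("a", seqs[0]), ("c", seqs[2]), ("d", seqs[3])]
        msa2 = progressive_msa(swapped)
        prof2 = similarity_profile(msa2, clades, "a")
        assert prof1.monocot_index == prof2.monocot_index

    def test_empty_clade_rejected(self):
        msa = MSA(labels=("a", "b"), rows=("MK", "MK"))
        with pytest.raises(ValueError):
            similarity_profile(msa, {"a": "monocot", "b": "monocot"}, "a")


class TestDetectInsertion:
    def test_mid_insertion_exact(self, rng):
        base = random_protein(900, rng)
        ins = random_protein(80, rng)
        pho1 = base[:450] + ins + base[450:]
        feats = detect_insertion(pho1, base)
        l80 = [f for f in feats if f.kind == "L80"]
        assert len(l80) == 1
        assert (l80[0].start, l80[0].end, l80[0].length) == (450, 530, 80)

    def test_n_terminal_extension_with_histidines(self, rng):
        base = random_protein(800, rng)
        ext = list(random_protein(40, rng).replace("H", "A"))
        for i in (2, 5, 9, 14, 20, 26, 31, 37):
            ext[i] = "H"
        pho1 = "".join(ext) + base
        feats = detect_insertion(pho1, base)
        tp = [f for f in feats if f.kind == "transit_peptide"]
        assert len(tp) == 1
        assert (tp[0].start, tp[0].end, tp[0].his_count) == (0, 40, 8)

    def test_self_comparison_empty(self, rng):
        p = random_protein(500, rng)
        assert detect_insertion(p, p) == []

    def test_panel_features_recovered(self, full_panel):
        for sp in ("Mon1", "Mon5", "Dic2"):
            rec1 = full_panel.record(sp, "PHO1")
            rec2 = full_panel.record(sp, "PHO2")
            feats = detect_insertion(rec1.protein, rec2.protein)
            kinds = {f.kind for f in feats}
            assert kinds == {"L80", "transit_peptide"}
            l80 = next(f for f in feats if f.kind == "L80")
            true_iv = rec1.insertion_interval
            assert abs(l80.start - true_iv[0]) <= 8
            assert 78 <= l80.length <= 82
            tp = next(f for f in feats if f.kind == "transit_peptide")
            assert tp.length == 45
            # histidine enrichment persists; exact count only where no
            # divergence has eroded the planted residues
            assert tp.his_count == 8 if sp == "Mon1" else tp.his_count >= 3


def pest_oracle(protein, min_fraction):
    """Independent regex-based PEST search."""
    out = []
    for m in re.finditer(r"[^KRH]+", protein.upper()):
        seg = m.group()
        if len(seg) < 12:
            continue
        frac = sum(c in "PEST" for c in seg) / len(seg)
        if frac >= min_fraction and "P" in seg and any(c in seg for c in "EST"):
            out.append((m.start(), m.end(), round(frac, 9)))
    return out


class TestFindPest:
    def test_pure_pest_block(self):
        regions = find_pest("K" + "PESTPESTPEST" + "R")
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.pest_fraction) == (1, 13, 1.0)
        assert r.flanks == ("K", "R")

    def test_poly_alanine_has_no_region(self):
        assert find_pest("K" + "A" * 30 + "R") == []

    def test_terminal_regions_allowed(self):
        regions = find_pest("PESTPESTPEST")
        assert regions and regions[0].flanks == ("^", "$")

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            # bias composition toward P/E/S/T so regions occur
            pool = np.array(list("PESTPESTACDFGKRHLMNQVWY"))
            protein = "".join(pool[rng.integers(0, len(pool), 500)])
            got = [(r.start, r.end, round(r.pest_fraction, 9))
                   for r in find_pest(protein, 0.5)]
            assert got == pest_oracle(protein, 0.5)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            find_pest("KPESTPESTPESTR", min_fraction=0.0)

    def test_planted_panel_pest_inside_insertion(self, small_panel):
        rec = small_panel.record("Mon1", "PHO1")
        iv = rec.insertion_interval
        segment = rec.protein[iv[0]:iv[1]]
        regions = find_pest(segment)
        assert any(r.pest_fraction >= 0.9 for r in regions)
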