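"""Protein-level profiling of the two phosphorylase families.

Covers progressive multiple alignment, consensus construction under a
reference-wins rule, the clade-scaled per-column similarity index, and the
features that distinguish the plastidial isoform: the ~80-residue
mid-sequence (L80) insertion, the N-terminal transit peptide, and PEST-like
regions.

Consensus rule: a column where every row carries the same symbol keeps that
symbol; any disagreement falls back to the reference (maize-role) row, so
reference insertions are retained in the consensus.  The similarity index
of a clade at a column is round(5*k/m) with k members matching the
consensus out of m, rounded half away from zero; dicot values are
sign-flipped in tabular output purely as a plotting convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from . import phylo
from ._profile_align import align_profiles
from .seqsim import global_align

_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(_AA_ORDER)}
_B62 = np.array([[float(_BLOSUM[a][b]) for b in _AA_ORDER] for a in _AA_ORDER])

GAP_OPEN = -11.0
GAP_EXTEND = -1.0

BASIC = set("KRH")
PEST_AA = set("PEST")
MIN_PEST_LEN = 12
_MERGE_GAP = 10   # matched columns tolerated inside one indel event


@dataclass(frozen=True)
class MSA:
    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def degapped(self, label: str) -> str:
        return self.row(label).replace("-", "")

    def to_fasta(self) -> str:
        return "".join(f">{lab}\n{row}\n" for lab, row in zip(self.labels, self.rows))


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 24) residue-frequency profile; gaps contribute zero mass."""
    arr = np.zeros((len(rows[0]), len(_AA_ORDER)))
    for row in rows:
        for i, ch in enumerate(row):
            if ch != "-":
                arr[i, _AA_INDEX[ch]] += 1
    return arr / len(rows)


def _merge(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = pa @ _B62 @ pb.T
    _, ops = align_profiles(S, GAP_OPEN, GAP_EXTEND)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        if op == 0:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
            i += 1
            j += 1
        elif op == 1:  # gap in B
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            i += 1
        else:          # gap in A
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
            j += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(seqs: list[tuple[str, str]]) -> MSA:
    """Progressive multiple alignment of (label, protein) pairs.

    Guide tree: neighbor joining on p-distances taken from pairwise global
    alignments; profile-profile merges in the tree's postorder.  The result
    is deterministic for a fixed input order.
    """
    labels = [lab for lab, _ in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    seqd = dict(seqs)
    if len(seqs) == 2:
        aln = global_align(seqs[0][1], seqs[1][1])
        return MSA(labels=tuple(labels), rows=(aln.aligned_a, aln.aligned_b))

    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i][1], seqs[j][1])
            d[i, j] = d[j, i] = 1.0 - aln.identity / 100.0
    guide = phylo.nj(phylo.DistanceMatrix(labels=tuple(labels), matrix=d))

    def align_node(node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.label], [seqd[node.label]]
        labs, rows = align_node(node.children[0])
        for child in node.children[1:]:
            labs_b, rows_b = align_node(child)
            rows, rows_b = _merge(rows, rows_b)
            labs, rows = labs + labs_b, rows + rows_b
        return labs, rows

    labs, rows = align_node(guide.root)
    order = sorted(range(len(labs)), key=lambda k: labels.index(labs[k]))
    return MSA(labels=tuple(labs[k] for k in order),
               rows=tuple(rows[k] for k in order))


@dataclass(frozen=True)
class ConsensusProfile:
    consensus: str                      # gapped, one symbol per MSA column
    monocot_index: tuple[int, ...]      # 0..5
    dicot_index: tuple[int, ...]        # 0..5 (sign-flipped only for output)

    @property
    def consensus_sequence(self) -> str:
        return self.consensus.replace("-", "")

    def to_tsv(self) -> str:
        lines = ["column\tconsensus\tmonocot_index\tdicot_index"]
        for i, (c, m, d) in enumerate(zip(self.consensus, self.monocot_index,
                                          self.dicot_index)):
            lines.append(f"{i}\t{c}\t{m}\t{-d}")
        lines.append("# similarity index = round(5*k/m), half away from zero; "
                     "dicot values sign-flipped for plotting")
        return "\n".join(lines) + "\n"


def build_consensus(msa: MSA, reference_label: str) -> str:
    """Per-column consensus: unanimous symbol, else the reference symbol."""
    if reference_label not in msa.labels:
        raise ValueError(f"reference {reference_label!r} absent from MSA")
    ref_row = msa.row(reference_label)
    cols = []
    for i in range(msa.n_columns):
        symbols = {row[i] for row in msa.rows}
        cols.append(symbols.pop() if len(symbols) == 1 else ref_row[i])
    return "".join(cols)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def similarity_profile(msa: MSA, clade_assignment: dict[str, str],
                       reference_label: str) -> ConsensusProfile:
    """Clade-scaled per-column similarity to the consensus (0-5 scale)."""
    for lab in msa.labels:
        if lab not in clade_assignment:
            raise ValueError(f"label {lab!r} has no clade assignment")
    consensus = build_consensus(msa, reference_label)
    clades = {"monocot": [], "dicot": []}
    for lab in msa.labels:
        clade = clade_assignment[lab]
        if clade not in clades:
            raise ValueError(f"unknown clade {clade!r} for {lab!r}")
        clades[clade].append(msa.row(lab))
    for clade, rows in clades.items():
        if not rows:
            raise ValueError(f"empty clade {clade!r}")
    indices = {}
    for clade, rows in clades.items():
        m = len(rows)
        vals = []
        for i, c in enumerate(consensus):
            k = sum(row[i] == c for row in rows)
            vals.append(_round_half_away(5.0 * k / m))
        indices[clade] = tuple(vals)
    return ConsensusProfile(consensus=consensus,
                            monocot_index=indices["monocot"],
                            dicot_index=indices["dicot"])


@dataclass(frozen=True)
class InsertionFeature:
    kind: str           # "L80" or "transit_peptide"
    start: int          # reference (first sequence) coordinates, half-open
    end: int
    length: int
    his_count: int | None = None


def detect_insertion(pho1: str, pho2: str) -> list[InsertionFeature]:
    """Find the L80 mid-insertion and N-terminal transit peptide of the
    plastidial isoform by pairwise alignment against the cytosolic one.

    Maximal gap blocks in the aligned cytosolic row are classified: a block
    of 78-82 residues whose midpoint falls in the middle third of the
    plastidial sequence is the L80 insertion; a block anchored at the
    N-terminus of length <= 50 is the transit peptide (with its histidine
    tally).  Intervals are reported in plastidial-sequence coordinates.
    """
    aln = global_align(pho1, pho2)
    row1, row2 = aln.aligned_a, aln.aligned_b
    ref_len = len(pho1)
    # raw maximal gap blocks in the cytosolic row, reference coordinates
    blocks: list[tuple[int, int]] = []
    ref_pos = 0
    col = 0
    ncol = len(row2)
    while col < ncol:
        if row2[col] == "-" and row1[col] != "-":
            start_ref = ref_pos
            while col < ncol and row2[col] == "-" and row1[col] != "-":
                ref_pos += 1
                col += 1
            blocks.append((start_ref, ref_pos))
        else:
            if row1[col] != "-":
                ref_pos += 1
            col += 1
    # merge blocks separated by short matched islands (alignment wander
    # inside a long insertion fragments the gap at higher divergence)
    merged: list[list[tuple[int, int]]] = []
    for b in blocks:
        if merged and b[0] - merged[-1][-1][1] <= _MERGE_GAP:
            merged[-1].append(b)
        else:
            merged.append([b])
    features: list[InsertionFeature] = []
    for group in merged:
        start_ref, end_ref = group[0][0], group[-1][1]
        gap_len = sum(e - s for s, e in group)
        mid = (start_ref + end_ref) / 2.0
        if 78 <= gap_len <= 82 and ref_len / 3.0 <= mid <= 2 * ref_len / 3.0:
            features.append(InsertionFeature("L80", start_ref, end_ref, gap_len))
        elif gap_len <= 50 and start_ref <= 50 and mid < ref_len / 3.0:
            segment = pho1[start_ref:end_ref]
            features.append(InsertionFeature("transit_peptide", start_ref,
                                             end_ref, gap_len,
                                             his_count=segment.count("H")))
    return features


@dataclass(frozen=True)
class PESTRegion:
    start: int
    end: int            # half-open
    pest_fraction: float
    flanks: tuple[str, str]   # boundary residues, "^"/"$" at termini


def find_pest(protein: str, min_fraction: float = 0.5) -> list[PESTRegion]:
    """PEST-like regions: K/R/H-free stretches of >= 12 residues flanked by
    basic residues (or the sequence termini) whose P/E/S/T content meets the
    threshold and which contain at least one P and one of E/S/T.

    This is a composition rule; the classic hydrophobicity-weighted PEST
    score is intentionally not reproduced.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must be in (0, 1]")
    s = protein.upper()
    regions: list[PESTRegion] = []
    start = 0
    n = len(s)
    for i in range(n + 1):
        if i == n or s[i] in BASIC:
            seg = s[start:i]
            if len(seg) >= MIN_PEST_LEN:
                frac = sum(c in PEST_AA for c in seg) / len(seg)
                if (frac >= min_fraction and "P" in seg
                        and any(c in seg for c in "EST")):
                    left = s[start - 1] if start > 0 else "^"
                    right = s[i] if i < n else "$"
                    regions.append(PESTRegion(start=start, end=i,
                                              pest_fraction=frac,
                                              flanks=(left, right)))
            start = i + 1
    return regions


def features_to_tsv(features: list[InsertionFeature],
                    pest: list[PESTRegion]) -> str:
    lines = ["kind\tstart\tend\tlength\this_count\tpest_fraction"]
    for f in features:
        his = "" if f.his_count is None else str(f.his_count)
        lines.append(f"{f.kind}\t{f.start}\t{f.end}\t{f.length}\t{his}\t")
    for r in pest:
        lines.append(f"PEST\t{r.start}\t{r.end}\t{r.end - r.start}\t\t"
                     f"{r.pest_fraction:.3f}")
    return "\n".join(lines) + "\n"
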