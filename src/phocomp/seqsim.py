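"""Pairwise global alignment, identity/coverage statistics and the
"true ortholog" acceptance rule.

Identity is defined as matches / alignment columns x 100 (gap columns count
in the denominator); an alternative denominator (the shorter sequence
length) is available via ``identity_mode="shorter"``.  Ortholog acceptance
follows clade-specific identity thresholds (candidates must exceed 80%
identity in monocots, 70% in dicots), a minimum coverage of the reference
protein, presence of every reference domain, and conservation of the
spacing between consecutive domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .genestruct import GeneModel

_NUC_CHARS = set("ACGTUN")

#: default scoring, fully overridable per call
NUC_SCORING = dict(match=2, mismatch=-3, open=-5, extend=-2)
PROT_SCORING = dict(matrix="BLOSUM62", open=-11, extend=-1)


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    identity: float       # percent
    coverage: float       # percent of query residues paired with target residues
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


@dataclass(frozen=True)
class OrthologVerdict:
    accepted: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.accepted != (len(self.reasons) == 0):
            raise ValueError("accepted must be equivalent to an empty reason list")


def _alphabet(seq: str) -> str:
    return "nuc" if set(seq.upper()) <= _NUC_CHARS else "prot"


def _make_aligner(kind: str, scoring: dict | None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    params = dict(NUC_SCORING if kind == "nuc" else PROT_SCORING)
    if scoring:
        params.update(scoring)
    if "matrix" in params:
        aligner.substitution_matrix = substitution_matrices.load(params["matrix"])
    else:
        aligner.match_score = params["match"]
        aligner.mismatch_score = params["mismatch"]
    aligner.open_gap_score = params["open"]
    aligner.extend_gap_score = params["extend"]
    return aligner


def global_align(a: str, b: str, scoring: dict | None = None,
                 identity_mode: str = "columns") -> AlignmentResult:
    """Optimal global (Needleman-Wunsch, affine gaps) alignment of two sequences."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    ka, kb = _alphabet(a), _alphabet(b)
    if ka != kb:
        raise ValueError(f"mixed alphabets: {ka} vs {kb}")
    aligner = _make_aligner(ka, scoring)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(x == y for x, y in zip(row_a, row_b) if x != "-" and y != "-")
    paired = sum(x != "-" and y != "-" for x, y in zip(row_a, row_b))
    if identity_mode == "columns":
        denom = len(row_a)
    elif identity_mode == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown identity_mode {identity_mode!r}")
    return AlignmentResult(aligned_a=row_a, aligned_b=row_b,
                           identity=100.0 * matches / denom,
                           coverage=100.0 * paired / len(a),
                           score=aln.score)


@dataclass(frozen=True)
class SegmentIdentity:
    """Per-ordinal exon and intron identities of one gene pair."""

    exon_identity: tuple[float, ...]
    intron_identity: tuple[float, ...]
    excess_exons_a: int
    excess_exons_b: int

    @property
    def mean_exon_identity(self) -> float:
        return sum(self.exon_identity) / len(self.exon_identity)

    @property
    def mean_intron_identity(self) -> float:
        if not self.intron_identity:
            return float("nan")
        return sum(self.intron_identity) / len(self.intron_identity)


def segment_identity(model_a: GeneModel, model_b: GeneModel,
                     genomic_a: str, genomic_b: str,
                     scoring: dict | None = None) -> SegmentIdentity:
    """Exon-wise and intron-wise percent identity, paired by ordinal.

    Segments are compared up to the smaller exon/intron count; the excess on
    the longer model is flagged in the report rather than silently dropped.
    """
    ex_a = [genomic_a[s:e] for s, e in model_a.exons]
    ex_b = [genomic_b[s:e] for s, e in model_b.exons]
    in_a = [genomic_a[s:e] for s, e in model_a.introns]
    in_b = [genomic_b[s:e] for s, e in model_b.introns]
    exon_id = tuple(global_align(x, y, scoring).identity
                    for x, y in zip(ex_a, ex_b))
    intron_id = tuple(global_align(x, y, scoring).identity
                      for x, y in zip(in_a, in_b))
    return SegmentIdentity(exon_identity=exon_id, intron_identity=intron_id,
                           excess_exons_a=len(ex_a) - len(exon_id),
                           excess_exons_b=len(ex_b) - len(exon_id))


#: identity must be strictly above these percentages ("more than")
CLADE_IDENTITY_THRESHOLD = {"monocot": 80.0, "dicot": 70.0}
MIN_COVERAGE = 80.0            # percent of reference protein length
INTERVAL_TOLERANCE = 0.15      # fraction of the reference inter-domain distance


@dataclass(frozen=True)
class OrthologCandidate:
    identity: float                                  # percent vs reference protein
    coverage: float                                  # percent of reference aligned
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)


def classify_ortholog(candidate: OrthologCandidate, clade: str,
                      reference_domains: dict[str, tuple[int, int]],
                      identity_thresholds: dict[str, float] | None = None,
                      min_coverage: float = MIN_COVERAGE,
                      interval_tolerance: float = INTERVAL_TOLERANCE) -> OrthologVerdict:
    """Accept a candidate as a true ortholog of the reference protein.

    Rejection reasons are collected (not short-circuited):
    ``identity_below_threshold``, ``coverage_below_threshold``,
    ``missing_domain``, ``interval_shift``.
    """
    thresholds = identity_thresholds or CLADE_IDENTITY_THRESHOLD
    if clade not in thresholds:
        raise ValueError(f"unknown clade {clade!r}")
    reasons: list[str] = []
    if not candidate.identity > thresholds[clade]:
        reasons.append("identity_below_threshold")
    if candidate.coverage < min_coverage:
        reasons.append("coverage_below_threshold")
    missing = [d for d in reference_domains if d not in candidate.domains]
    if missing:
        reasons.append("missing_domain")
    else:
        names = sorted(reference_domains, key=lambda d: reference_domains[d][0])
        for d1, d2 in zip(names, names[1:]):
            ref_gap = reference_domains[d2][0] - reference_domains[d1][1]
            cand_gap = candidate.domains[d2][0] - candidate.domains[d1][1]
            allowed = max(abs(ref_gap) * interval_tolerance, 5.0)
            if abs(cand_gap - ref_gap) > allowed:
                reasons.append("interval_shift")
                break
    return OrthologVerdict(accepted=not reasons, reasons=tuple(reasons))
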