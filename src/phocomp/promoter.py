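"""Cis-regulatory element scanning of ~1 kb upstream promoter regions.

Two motif model classes are supported: position weight matrices scored as
log2-odds against a background base composition (default uniform), and
IUPAC consensus strings scored as the count of matching positions.  Both
strands are scanned; a hit requires a score strictly above the motif's
threshold (default 5 for PWMs, echoing the common "matrix value > 5"
acceptance rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .sequtils import revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_PWM_THRESHOLD = 5.0


@dataclass(frozen=True)
class MotifDef:
    name: str
    kind: str                         # "pwm" or "iupac"
    threshold: float
    consensus: str | None = None      # iupac model
    pwm: np.ndarray | None = None     # (L, 4) probabilities, columns sum to 1
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.kind == "pwm":
            if self.pwm is None:
                raise ValueError(f"{self.name}: pwm model missing matrix")
            p = np.asarray(self.pwm, dtype=float)
            if p.ndim != 2 or p.shape[1] != 4:
                raise ValueError(f"{self.name}: PWM must be (L, 4)")
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"{self.name}: PWM columns must sum to 1")
            object.__setattr__(self, "pwm", p)
        elif self.kind == "iupac":
            if not self.consensus:
                raise ValueError(f"{self.name}: iupac model missing consensus")
            bad = set(self.consensus.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"{self.name}: invalid IUPAC codes {bad}")
        else:
            raise ValueError(f"{self.name}: unknown motif kind {self.kind!r}")
        if not math.isfinite(self.threshold):
            raise ValueError(f"{self.name}: threshold must be finite")

    def __len__(self) -> int:
        return len(self.consensus) if self.kind == "iupac" else self.pwm.shape[0]

    @property
    def logodds(self) -> np.ndarray:
        """(L, 4) log2-odds score table (PWM motifs only); pseudo-floor 1e-6."""
        p = np.maximum(self.pwm, 1e-6)
        bg = np.asarray(self.background)
        return np.log2(p / bg)

    def score(self, window: str) -> float:
        window = window.upper()
        if len(window) != len(self):
            raise ValueError("window length mismatch")
        if self.kind == "iupac":
            return float(sum(b in IUPAC_SETS[c]
                             for b, c in zip(window, self.consensus.upper())))
        lo = self.logodds
        total = 0.0
        for i, b in enumerate(window):
            if b not in _BASE_INDEX:
                return -math.inf  # ambiguous base: window cannot be scored
            total += lo[i, _BASE_INDEX[b]]
        return total


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int       # 0-based offset on the forward strand
    strand: str         # "+" or "-"
    score: float


def scan(upstream: str, motifs: list[MotifDef]) -> list[MotifHit]:
    """Score every window of every motif on both strands.

    Reverse-strand hits are reported in forward coordinates (the offset of
    the leftmost base the motif covers).  Hits require score strictly above
    the motif's threshold and are returned sorted by position.
    """
    if not motifs:
        raise ValueError("no motifs supplied")
    seq = upstream.upper()
    L = len(seq)
    longest = max(len(m) for m in motifs)
    if L < longest:
        raise ValueError(f"sequence length {L} shorter than the longest "
                         f"motif ({longest} bp)")
    rc = revcomp(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        w = len(motif)
        for i in range(L - w + 1):
            s = motif.score(seq[i:i + w])
            if s > motif.threshold:
                hits.append(MotifHit(motif.name, i, "+", s))
            s = motif.score(rc[i:i + w])
            if s > motif.threshold:
                hits.append(MotifHit(motif.name, L - i - w, "-", s))
    hits.sort(key=lambda h: (h.position, h.motif, h.strand))
    return hits


def summarize_hits(hits: list[MotifHit]) -> dict[str, int]:
    """Per-element hit counts (the per-gene summary behind element figures)."""
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.motif] = counts.get(h.motif, 0) + 1
    return dict(sorted(counts.items()))


def pwm_from_consensus(consensus: str, certainty: float = 0.91) -> np.ndarray:
    """Sharp PWM around an unambiguous consensus (off-bases share 1-certainty)."""
    p = np.full((len(consensus), 4), (1.0 - certainty) / 3.0)
    for i, b in enumerate(consensus.upper()):
        p[i, _BASE_INDEX[b]] = certainty
    return p


def parse_motif_table(text: str) -> list[MotifDef]:
    """Parse a motif TSV: columns name, type, model, threshold.

    ``model`` is an IUPAC string for type=iupac; for type=pwm it is either a
    plain consensus (expanded via :func:`pwm_from_consensus`) or
    semicolon-separated per-position A,C,G,T probability quadruples.
    """
    motifs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "name":
            continue
        name, kind, model, thr = fields[:4]
        threshold = float(thr)
        if kind == "iupac":
            motifs.append(MotifDef(name=name, kind="iupac", threshold=threshold,
                                   consensus=model))
        else:
            if ";" in model or "," in model:
                rows = [[float(x) for x in col.split(",")]
                        for col in model.split(";")]
                pwm = np.array(rows)
            else:
                pwm = pwm_from_consensus(model)
            motifs.append(MotifDef(name=name, kind="pwm", threshold=threshold,
                                   pwm=pwm))
    return motifs


def load_default_motifs() -> list[MotifDef]:
    """Packaged motif fixture: literature consensus strings for the element
    classes commonly reported in starch-gene promoters (ABA response, MYB
    binding, core promoter, endosperm expression, light response).  This is
    a curated synthetic fixture, not a database export."""
    text = (resources.files("phocomp") / "data" / "motifs.tsv").read_text()
    return parse_motif_table(text)


def hits_to_tsv(hits: list[MotifHit]) -> str:
    lines = ["motif\tposition\tstrand\tscore"]
    for h in hits:
        lines.append(f"{h.motif}\t{h.position}\t{h.strand}\t{h.score:.3f}")
    return "\n".join(lines) + "\n"
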