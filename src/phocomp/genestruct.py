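"""Exon-intron architecture from CDS-to-genome mapping.

The gene span is taken to run from the translation start to the translation
stop, so mapping the CDS back onto its own genomic span partitions the span
into exons (coding segments) and introns (the gaps between them).  Intron
phase follows the standard convention: phase = cumulative coding length
upstream of the intron modulo 3, i.e. phase 0 between codons, phase 1 after
the first base of a codon, phase 2 after the second.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequtils import truncate2

MIN_INTRON = 4  # room for GT...AG
_ANCHOR = 12    # bases of downstream CDS that must match at a candidate acceptor


class MappingError(ValueError):
    """CDS cannot be spliced out of the genomic sequence."""

    def __init__(self, offset: int):
        self.offset = offset
        super().__init__(f"CDS is not spliceable from the genomic sequence; "
                         f"first unmatchable CDS offset: {offset}")


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon intervals on a genomic span (0-based, half-open)."""

    gene_id: str
    genomic_len: int
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end <= self.genomic_len):
                raise ValueError(f"exon [{start},{end}) outside genomic span")
            if start <= prev_end:
                raise ValueError("exons must be non-overlapping and strictly increasing")
            prev_end = end

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    def spliced(self, genomic: str) -> str:
        """Concatenated exon substrings (the CDS for a complete model)."""
        return "".join(genomic[s:e] for s, e in self.exons)


@dataclass(frozen=True)
class IntronRecord:
    index: int            # 1-based ordinal
    length: int
    phase: int            # 0/1/2
    gc: float | None = None
    donor: str | None = None
    acceptor: str | None = None


@dataclass(frozen=True)
class SSRHit:
    unit: str             # lexicographically smallest rotation
    copies: int
    start: int
    end: int              # half-open

    def __post_init__(self):
        assert self.end - self.start == len(self.unit) * self.copies


def map_cds(genomic: str, cds: str, gene_id: str = "gene") -> GeneModel:
    """Derive the exon chain by exact spliced matching of the CDS onto the genome.

    Exact matching is justified because the CDS is genome-derived.  Among
    ambiguous chainings the search returns the chain with the fewest
    non-canonical (not GT...AG) introns, preferring longer exons and then
    leftmost placement on ties.

    Raises :class:`MappingError` (carrying the first unmatchable CDS offset)
    when no chain exists.
    """
    genomic = genomic.upper()
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    n, m = len(genomic), len(cds)
    best_c = 0  # deepest CDS offset reached, for error reporting

    def common_prefix(g: int, c: int) -> int:
        k = 0
        while g + k < n and c + k < m and genomic[g + k] == cds[c + k]:
            k += 1
        return k

    def attempt(anchor_len: int):
        """Chaining search with a fixed acceptor-anchor length.

        Returns the chain minimizing the number of non-canonical (not
        GT...AG) introns; ties go to longer exons, then leftmost acceptors.
        Memoized per (genomic, CDS) offset pair.
        """
        nonlocal best_c
        memo: dict[tuple[int, int], tuple[int, list[tuple[int, int]]] | None] = {}

        def solve(g: int, c: int):
            nonlocal best_c
            if (g, c) in memo:
                return memo[(g, c)]
            k = common_prefix(g, c)
            best_c = max(best_c, c + k)
            best: tuple[int, list[tuple[int, int]]] | None = None
            if c + k == m and g + k == n:
                best = (0, [(g, n)])
            else:
                candidates: list[tuple[int, int, int, int, int]] = []
                for e in range(k, 0, -1):
                    anchor = cds[c + e:c + e + anchor_len]
                    donor_ok = genomic[g + e:g + e + 2] == "GT"
                    j = genomic.find(anchor, g + e + MIN_INTRON)
                    while j != -1:
                        canonical = donor_ok and genomic[j - 2:j] == "AG"
                        candidates.append((0 if canonical else 1, -e, j, e, j))
                        j = genomic.find(anchor, j + 1)
                for penalty, _, _, e, j in sorted(candidates):
                    sub = solve(j, c + e)
                    if sub is None:
                        continue
                    bad = sub[0] + penalty
                    if best is None or bad < best[0]:
                        best = (bad, [(g, g + e)] + sub[1])
                    if best[0] == 0:
                        break  # first all-canonical chain in preference order
            memo[(g, c)] = best
            return best

        return solve(0, 0)

    # A long anchor keeps the search near-linear, but an exon shorter than
    # the anchor hides its true acceptor; retry with shorter anchors until a
    # fully canonical chain appears, keeping the best chain seen overall.
    best_chain = None
    best_bad = None
    for anchor_len in (_ANCHOR, 6, 3):
        result = attempt(anchor_len)
        if result is not None:
            bad, chain = result
            if best_bad is None or bad < best_bad:
                best_chain, best_bad = chain, bad
            if best_bad == 0:
                break
    if best_chain is None:
        raise MappingError(best_c)
    return GeneModel(gene_id=gene_id, genomic_len=n, exons=tuple(best_chain))


def intron_phases(model: GeneModel, genomic: str | None = None) -> list[IntronRecord]:
    """One record per exon gap; phase = cumulative coding length mod 3.

    With the genomic sequence supplied, each record also carries the intron
    GC fraction and its donor/acceptor dinucleotides.
    """
    records = []
    cum = 0
    lengths = model.exon_lengths
    for i, (istart, iend) in enumerate(model.introns):
        cum += lengths[i]
        gc = donor = acceptor = None
        if genomic is not None:
            intron = genomic[istart:iend].upper()
            gc = gc_content(intron)
            donor, acceptor = intron[:2], intron[-2:]
        records.append(IntronRecord(index=i + 1, length=iend - istart,
                                    phase=cum % 3, gc=gc,
                                    donor=donor, acceptor=acceptor))
    return records


def phase_share(records: list[IntronRecord], phase: int = 0) -> float:
    """Percent of introns with the given phase, two-decimal truncated."""
    if not records:
        raise ValueError("no introns")
    k = sum(1 for r in records if r.phase == phase)
    return truncate2(100.0 * k / len(records))


def total_intron_bp(gene_len: int, cdna_len: int) -> int:
    """Total intron content of the transcribed span: gene length minus cDNA length."""
    if gene_len < cdna_len:
        raise ValueError(f"gene length {gene_len} < cDNA length {cdna_len}")
    if cdna_len < 0:
        raise ValueError("negative cDNA length")
    return gene_len - cdna_len


def gc_content(seq: str) -> float:
    """(#G + #C) / #unambiguous bases, case-insensitive; N/IUPAC codes excluded."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


DEFAULT_MIN_COPIES = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


def _is_primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def _smallest_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def find_ssrs(seq: str,
              min_copies: dict[int, int] | None = None) -> list[SSRHit]:
    """All maximal perfect tandem repeats with a primitive 1-6 bp unit.

    A hit spans complete copies only and is maximal: it cannot be extended by
    a full unit in either direction.  Unit rotations are collapsed to the
    lexicographically smallest rotation.  Overlapping hits with different
    unit lengths are all reported.
    """
    if min_copies is None:
        min_copies = DEFAULT_MIN_COPIES
    if any(v <= 0 for v in min_copies.values()):
        raise ValueError("copy thresholds must be positive")
    s = seq.upper()
    n = len(s)
    hits: list[SSRHit] = []
    for u in sorted(min_copies):
        if u < 1 or u > 6:
            raise ValueError("SSR unit length must be 1-6 bp")
        thr = min_copies[u]
        # maximal stretches where s has period u; one hit per stretch
        i = 0
        while i + u < n:
            if s[i] != s[i + u]:
                i += 1
                continue
            a = i
            while i + u < n and s[i] == s[i + u]:
                i += 1
            copies = (i - a + u) // u  # complete copies from the left edge
            unit = s[a:a + u]
            if copies >= thr and _is_primitive(unit):
                hits.append(SSRHit(unit=_smallest_rotation(unit),
                                   copies=copies, start=a,
                                   end=a + copies * u))
    hits.sort(key=lambda h: (h.start, len(h.unit)))
    return hits


def model_to_gff3(model: GeneModel, seqid: str) -> str:
    """GFF3 rendering (1-based closed intervals) with gene/exon/CDS features."""
    lines = [f"{seqid}\tphocomp\tgene\t1\t{model.genomic_len}\t.\t{model.strand}\t."
             f"\tID={model.gene_id}"]
    for k, (s, e) in enumerate(model.exons, 1):
        attrs = f"ID={model.gene_id}.exon{k};Parent={model.gene_id}"
        lines.append(f"{seqid}\tphocomp\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t{attrs}")
    cum = 0
    for k, (s, e) in enumerate(model.exons, 1):
        frame = (3 - cum % 3) % 3
        cum += e - s
        attrs = f"ID={model.gene_id}.cds{k};Parent={model.gene_id}"
        lines.append(f"{seqid}\tphocomp\tCDS\t{s + 1}\t{e}\t.\t{model.strand}\t{frame}\t{attrs}")
    return "\n".join(lines) + "\n"
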