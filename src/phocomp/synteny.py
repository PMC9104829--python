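"""Microsynteny around an anchor gene: shared gene content and collinearity
of a 31-gene window (15 flanking genes on either side of the anchor)
against a target genome's gene-order tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_FLANK = 15


class GeneOrderTable:
    """Ordered gene identifiers per chromosome; ranks consecutive from 1."""

    def __init__(self, chromosomes: dict[str, list[str]]):
        seen: set[str] = set()
        for chrom, genes in chromosomes.items():
            for g in genes:
                if g in seen:
                    raise ValueError(f"duplicate gene id {g!r}")
                seen.add(g)
        self.chromosomes = {c: list(g) for c, g in chromosomes.items()}
        self._locate = {g: (c, r) for c, genes in self.chromosomes.items()
                        for r, g in enumerate(genes, start=1)}

    def locate(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, 1-based rank) of a gene."""
        if gene_id not in self._locate:
            raise KeyError(f"gene {gene_id!r} not in table")
        return self._locate[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._locate

    @classmethod
    def from_tsv(cls, text: str) -> "GeneOrderTable":
        df = pd.read_csv(_as_buffer(text), sep="\t", comment="#")
        chroms: dict[str, list[str]] = {}
        for chrom, sub in df.groupby("chromosome", sort=True):
            sub = sub.sort_values("rank")
            ranks = list(sub["rank"])
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValueError(f"ranks on {chrom} not consecutive from 1")
            chroms[str(chrom)] = [str(g) for g in sub["gene_id"]]
        return cls(chroms)

    def to_tsv(self) -> str:
        lines = ["chromosome\trank\tgene_id"]
        for chrom in sorted(self.chromosomes):
            for r, g in enumerate(self.chromosomes[chrom], start=1):
                lines.append(f"{chrom}\t{r}\t{g}")
        return "\n".join(lines) + "\n"


def _as_buffer(text: str):
    import io
    return io.StringIO(text)


@dataclass(frozen=True)
class SyntenyReport:
    anchor: str
    target_chromosome: str | None
    window_size: int
    shared: int          # flanking genes with an ortholog on the best chromosome
    collinear: int       # longest order-preserving run (either orientation)
    truncated: bool      # window clipped at a chromosome end

    def __post_init__(self):
        if not (self.collinear <= self.shared <= self.window_size - 1):
            raise ValueError("need collinear <= shared <= window - 1")

    def phrase(self) -> str:
        return (f"{self.shared} of the {self.window_size - 1} genes flanking "
                f"{self.anchor} shared on {self.target_chromosome}")


def extract_window(table: GeneOrderTable, anchor: str,
                   flank: int = DEFAULT_FLANK) -> tuple[list[str], bool]:
    """Up to 2*flank+1 genes centred on the anchor; the flag marks windows
    truncated by a chromosome end."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    chrom, rank = table.locate(anchor)
    genes = table.chromosomes[chrom]
    lo = max(0, rank - 1 - flank)
    hi = min(len(genes), rank + flank)
    window = genes[lo:hi]
    truncated = len(window) < 2 * flank + 1
    return window, truncated


def _lcs_length(a: list[int], b: list[int]) -> int:
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[m]


def count_shared(window: list[str], anchor: str, target: GeneOrderTable,
                 orthomap: dict[str, list[str]],
                 truncated: bool = False) -> SyntenyReport:
    """Shared/collinear counts of a source window against a target genome.

    ``shared`` counts flanking genes (anchor excluded) having at least one
    ortholog on the single target chromosome that maximizes the count (ties
    resolved to the lexicographically lowest chromosome label).
    ``collinear`` is the length of the longest common subsequence between
    the window order and the target rank order, computed in both
    orientations (inversions count).  Many-to-many ortholog entries are
    resolved greedily to the nearest-rank target copy.
    """
    if not any(target.chromosomes.values()):
        raise ValueError("empty target table")
    flanking = [g for g in window if g != anchor]
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for idx, gene in enumerate(flanking):
        for tgt in orthomap.get(gene, []):
            if tgt in target:
                chrom, rank = target.locate(tgt)
                per_chrom.setdefault(chrom, []).append((idx, rank))
    if not per_chrom:
        return SyntenyReport(anchor=anchor, target_chromosome=None,
                             window_size=len(window), shared=0, collinear=0,
                             truncated=truncated)
    best_chrom = max(per_chrom,
                     key=lambda c: (len({i for i, _ in per_chrom[c]}), ),
                     default=None)
    # ties to the lowest chromosome label
    best_count = len({i for i, _ in per_chrom[best_chrom]})
    for c in sorted(per_chrom):
        if len({i for i, _ in per_chrom[c]}) == best_count:
            best_chrom = c
            break
    pairs = per_chrom[best_chrom]
    shared_idx = sorted({i for i, _ in pairs})
    shared = len(shared_idx)
    # greedy nearest-rank resolution of many-to-many entries, in window order
    chosen: list[int] = []
    prev_rank: int | None = None
    by_idx: dict[int, list[int]] = {}
    for i, r in pairs:
        by_idx.setdefault(i, []).append(r)
    for i in shared_idx:
        ranks = sorted(by_idx[i])
        if prev_rank is None:
            pick = ranks[0]
        else:
            pick = min(ranks, key=lambda r: (abs(r - prev_rank), r))
        chosen.append(pick)
        prev_rank = pick
    order = list(range(len(chosen)))
    fwd = _lcs_length(order, sorted(order, key=lambda k: chosen[k]))
    rev = _lcs_length(order, sorted(order, key=lambda k: -chosen[k]))
    collinear = max(fwd, rev)
    return SyntenyReport(anchor=anchor, target_chromosome=best_chrom,
                         window_size=len(window), shared=shared,
                         collinear=collinear, truncated=truncated)


def parse_orthomap(text: str) -> dict[str, list[str]]:
    """Orthomap TSV (source_id, target_id) to a one-to-many mapping."""
    mapping: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("source_id"):
            continue
        src, tgt = line.split("\t")[:2]
        mapping.setdefault(src, []).append(tgt)
    return mapping


def report_to_tsv(reports: list[SyntenyReport]) -> str:
    lines = ["anchor\ttarget_chromosome\twindow_size\tshared\tcollinear\ttruncated"]
    for r in reports:
        lines.append(f"{r.anchor}\t{r.target_chromosome or 'NA'}\t{r.window_size}"
                     f"\t{r.shared}\t{r.collinear}\t{r.truncated}")
    return "\n".join(lines) + "\n"
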