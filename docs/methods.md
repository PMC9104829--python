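# Methods

`phocomp` re-implements, as a tested pipeline, the comparative
characterization workflow applied to the two starch phosphorylase families
of flowering plants: the plastidial isoform (PHO1-type, EC 2.4.1.1, carrying
an N-terminal transit peptide and a ~80-residue mid-sequence insertion) and
the cytosolic isoform (PHO2-type, carrying neither). The pipeline covers
ortholog acceptance, exon–intron architecture and intron phases, identity
profiling against a reference species, consensus conservation scoring,
promoter element scanning, SSR detection, neighbor-joining phylogeny with
bootstrap, and flanking-gene microsynteny. Because the underlying study
deposits no dataset, a fully seeded synthetic-panel generator stands in for
database retrieval and carries complete ground truth.

## Gene structure from CDS-to-genome mapping

The gene span is taken as translation start → stop, so mapping the CDS back
onto its own genomic span partitions it into exons and introns. Matching is
exact (the CDS is genome-derived): `map_cds` is a memoized chaining search
over (genomic offset, CDS offset) states. Candidate splice points are found
by locating an acceptor *anchor* — the next 12 bp of CDS — downstream of
each possible exon end; the search returns the chain minimizing the number
of non-canonical (not GT…AG) introns, breaking ties by longer exons and
then leftmost acceptors. Two non-obvious cases drove this design:

* an exon shorter than the anchor hides its own acceptor (the anchor spans
  a junction), so the anchor length escalates 12 → 6 → 3 bp until a fully
  canonical chain is found;
* a coincidental `AG` inside an intron can offer a locally canonical but
  globally wrong boundary whose acceptance forces a later non-canonical
  intron, which is why chain quality is minimized globally rather than
  greedily.

Intron phase is the cumulative coding length upstream of the intron mod 3
(0 between codons, 1 after the first base, 2 after the second). Percent
shares of the dominant phase are reported with two-decimal *truncation*
(floor), which is how 10/14 and 11/14 print as 71.42 and 78.57. Total
intron content of a transcribed span is gene length − cDNA length; records
where this is impossible (gene < cDNA, or cDNA = gene despite annotated
introns) are flagged, never silently corrected.

SSRs are maximal perfect tandem repeats of a primitive 1–6 bp unit,
reported as complete copies from the left edge of each period-maximal
stretch, with units collapsed to their lexicographically smallest rotation.
Default minimum copies: mono ≥ 10, di ≥ 6, tri–hexa ≥ 5 (RepeatMasker-like;
configurable). The finder is validated against an independent brute-force
oracle on 2 kb sequences.

## Alignment and identity

Pairwise global alignment uses affine gaps (Needleman–Wunsch/Gotoh, via
Biopython's C aligner). Defaults: nucleotide match 2 / mismatch −3 / gap
open −5 / extend −2; protein BLOSUM62 with open −11 / extend −1. Identity
is matches / alignment columns × 100 (gap columns in the denominator); an
alternative matches / shorter-length definition sits behind
`identity_mode="shorter"`, since the original study's alignment tool does
not publish its metric. Scores are verified against an exhaustive DP oracle
on all test pairs ≤ 30 symbols.

Ortholog acceptance follows the published rule: identity strictly above 80%
(monocots) or 70% (dicots) versus the reference protein, plus minimum
coverage (default 80% of the reference length — the study names no number),
presence of every reference domain (domain coordinates are supplied as
configuration, not recomputed), and conservation of inter-domain spacing
(default tolerance ±15% of the reference distance, floor 5 aa). All failing
reasons are reported, not just the first.

## Consensus and similarity profile

The multiple alignment is progressive: a guide tree by neighbor joining on
p-distances from pairwise global alignments, then profile–profile merges in
postorder with a numba DP kernel (sum-of-pairs BLOSUM62 column scores over
residue-frequency profiles; gaps carry zero mass; constant affine
penalties; tie-break diagonal > up > left keeps output deterministic for a
fixed input order).

The consensus keeps the column symbol when all rows agree and otherwise
falls back to the reference (maize-role) row, so reference insertions
persist in the consensus. The per-column clade similarity index is
round(5·k/m), half away from zero, where k of m clade members match the
consensus; dicot values are sign-flipped (0…−5) in tabular output purely as
the plotting convention.

Isoform features: the plastidial-vs-cytosolic pairwise alignment yields gap
blocks in the cytosolic row; blocks of 78–82 summed gap residues with
midpoints in the middle third are the L80 insertion, N-proximal blocks ≤ 50
residues the transit peptide (histidine tally attached). Blocks separated
by ≤ 10 matched columns are merged first, because at dicot-level divergence
the optimal alignment threads short spurious matches through a long
insertion. PEST-like regions are K/R/H-free stretches ≥ 12 aa flanked by
basic residues or termini with ≥ 50% P/E/S/T content, at least one P and
one of E/S/T — a composition rule; the classic hydrophobicity-weighted PEST
score is deliberately out of scope.

## Promoter scanning

1 kb upstream regions are scanned on both strands. PWM motifs score as
log2-odds against a configurable background (default uniform); hits require
a score strictly above the motif threshold (default 5, echoing the
"matrix value > 5" acceptance rule, whose original normalization is not
published). IUPAC consensus motifs (TATA/CAAT class) score as the count of
matching positions with per-motif thresholds. Reverse-strand hits map to
forward coordinates by p → L − p − len. The packaged motif table is a
curated fixture of literature consensus strings (ABRE, MBS, G-box,
GCN4/endosperm, TATA, CAAT, Box4), not a database export. The false-positive
behaviour of a sharp PWM matches its exactly enumerated per-window hit
probability within 3 sd over 200 random promoters.

## Phylogeny

p-distances use pairwise deletion of gapped columns. Neighbor joining
follows the Saitou–Nei Q-criterion with deterministic tie-breaks by label
order; negative branch lengths are clamped to zero for display with the raw
value retained on the node; the unrooted tree is serialized with a
trifurcating root at the final join. The nonparametric bootstrap resamples
alignment columns with replacement (default 1000 replicates) and annotates
each internal bipartition with its replicate count. NJ recovers additive
matrices exactly (verified on four-point-condition instances) and agrees
with an independent implementation on random matrices.

## Microsynteny

Windows of 31 genes (15 flanking each side of the anchor; truncated windows
flagged) are compared against a target genome's gene-order tables:
`shared` counts flanking genes with ≥ 1 ortholog on the single best target
chromosome (ties to the lowest label), `collinear` is the longest common
subsequence of rank orders computed in both orientations (inversions
count). Many-to-many ortholog entries resolve greedily to the nearest-rank
copy. Reciprocal-best filtering is off by default.

## The synthetic panel generator

The generator emulates the study's data conditions, not real genome
complexity. Defaults (chosen once, as the study conditions):

* 8 monocots + 4 dicots; the first monocot is the zero-divergence
  reference. Root divergences 0–0.08 substitutions/site (monocots) and
  0.10–0.13 (dicots) put protein identity to the reference in the published
  bands (monocots > 80%, dicots ≈ 70–77%); the two families derive from a
  shared 840-aa core split at 0.175 subs/site per side.
* 15-exon gene models; intron lengths uniform 80–600 bp (plastidial) /
  80–900 bp (cytosolic) with GT…AG written at every boundary; planted
  intron-phase vectors give 11 of 14 phase-0 introns in both families
  (the printed 78.57% share), with all three phases in the plastidial
  family and only 0/2 in the cytosolic one.
* the plastidial protein adds a 45-aa transit peptide (8 planted
  histidines) and an 80-aa insertion carrying a PEST-rich stretch flanked
  by K/R; 1 kb promoters carry planted elements on both strands; one SSR is
  planted mid-intron with guard bases so the planted run is exactly
  maximal.
* evolution walks a fixed caterpillar guide tree per clade: CDS mutation is
  substitution-only (start/stop fixed, internal stops reverted), introns
  mutate at twice the coding rate with small indels (splice dinucleotides
  shielded), promoters at the coding rate with planted motifs re-stamped.
  All randomness flows from explicit seeds; zero divergence reproduces the
  ancestor byte for byte.
* gene-order tables retain 10–25 of the 30 flanking orthologs per species,
  order-preserved in monocots and shuffled in dicots, with filler genes
  interspersed — giving known `shared` counts and a known
  collinear-equals-shared signature for monocots.

What the generator does *not* emulate: codon-usage bias, dN/dS structure,
rate heterogeneity across sites, UTRs (the simulated span has none, so
cDNA = CDS in synthetic summaries), repeat landscapes beyond the planted
SSRs, and segmental duplications. Passing recovery tests therefore
demonstrate algorithmic correctness under clean, canonical-splice,
exact-substring conditions — not robustness to annotation noise in real
genomes.

## Problem sizes and numerics

Multi-panel sweeps (the 100-panel truth round-trip and the acceptance
script's recovery rates) use a 3-species panel with a compact family
variant (300-aa core, 60–200 bp introns; structure otherwise identical),
while bootstrap and feature checks run on the full 12-species panel — sizes
chosen to keep a full run in the minutes range on one core. Seeds are
explicit everywhere; derived seeds stay below 2^31. Alignment ties resolve
deterministically (first-optimal in the C aligner; diagonal-first in the
profile kernel; label order in NJ). Stage timings are logged separately
from the manifest so a reseeded rerun is byte-identical.

## Known limitations

* The identity metric of the original study's tools (and PlantCARE's
  "matrix value" scale) are unpublished; both are configurable here and the
  defaults are documented, but published cross-species identity percentages
  are not reproducible at desk scale and are not targets.
* `map_cds` assumes the CDS is an exact spliced substring of the genomic
  span; sequencing error or trans-splicing are out of scope.
* The PEST rule is compositional only.
* Domain presence for ortholog classification comes from user-supplied
  coordinates, not from an HMM/CDD scan.
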