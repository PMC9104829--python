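# phocomp

Comparative characterization of the two starch phosphorylase gene families
of flowering plants — the plastidial isoform (PHO1-type; N-terminal transit
peptide plus a ~80-residue "L80" mid-sequence insertion) and the cytosolic
isoform (PHO2-type; neither) — across panels of monocot and dicot species.
It is written for molecular evolution / comparative genomics work where the
same battery of questions recurs for any gene family: which candidates are
true orthologs, how conserved are exons versus introns, where do the
isoform-specific features sit, what do the promoters carry, and does the
genomic neighbourhood persist across species.

The pipeline covers, per species and family:

* **Gene structure** — exon–intron architecture derived by exact spliced
  matching of the CDS onto its genomic span (`map_cds`), intron phases
  (cumulative coding length mod 3), GC content, total intron content
  (gene − cDNA), and maximal perfect SSRs (primitive 1–6 bp units).
* **Identity profiling** — affine-gap global alignment (nucleotide 2/−3,
  gaps −5/−2; protein BLOSUM62, gaps −11/−1), identity = matches /
  alignment columns × 100, per-exon and per-intron identity versus the
  reference species, and the true-ortholog rule (identity > 80% in
  monocots / > 70% in dicots, coverage, domain presence, inter-domain
  spacing).
* **Consensus conservation** — progressive MSA (NJ guide tree,
  profile–profile merges), a reference-wins consensus, and the 0–5
  clade-scaled similarity index round(5·k/m) per column (dicots plotted
  0…−5).
* **Isoform features** — L80 insertion and transit peptide from gap blocks
  of the plastidial/cytosolic alignment; PEST-like regions (K/R/H-free,
  ≥12 aa, ≥50% P/E/S/T).
* **Promoters** — both-strand scans of 1 kb upstream regions with log2-odds
  PWMs (hits strictly above threshold, default 5) and IUPAC consensus
  motifs; a packaged fixture covers ABRE, MBS, G-box, GCN4/endosperm,
  TATA and CAAT classes.
* **Phylogeny** — p-distance (pairwise deletion), Saitou–Nei neighbor
  joining with deterministic tie-breaks, 1000-replicate column bootstrap,
  newick output with supports.
* **Microsynteny** — 31-gene windows (15 flanking genes per side), shared
  ortholog counts on the best target chromosome, collinearity as an
  orientation-agnostic longest common subsequence.

Because the original analyses of this kind depend on database downloads, a
first-class synthetic-panel generator (`phocomp.syndata`) emulates the
study conditions — 8 monocots + 4 dicots, 15-exon genes, planted insertion/
transit peptide, planted promoter elements and SSRs, shuffled or conserved
flanking-gene windows, a known true tree — with complete ground truth, so
every stage is testable offline. `phocomp.tables` ships the published
per-species length/identity table and reproduces its arithmetic
(e.g. intron totals 1.828–5.499 Kb for the plastidial family).

## Worked example

```sh
phocomp all --seed 1 --out run1
```

generates the default 12-species panel and writes the full report bundle.
`run1/structure/summary.tsv` begins:

```text
species	family	cdna_bp	cds_bp	gene_bp	protein_aa	n_exons	n_introns	intron_total_bp	phase0_pct
Dic1	PHO1	2901	2901	7743	966	15	14	4842	78.57
Dic1	PHO2	2526	2526	8391	841	15	14	5865	78.57
```

Each gene has 15 exons and 14 introns; the plastidial protein is 966 aa
(shared core + 80-aa insertion + 45-aa transit peptide) versus 841 aa for
the cytosolic isoform; 11 of 14 introns sit between codons, hence the
phase-0 share of 78.57%. The simulated span carries no UTRs, so cDNA = CDS
and `intron_total_bp` is exactly gene − cDNA. `run1/identity/identity.tsv`
shows the conservation gradient (CDS > gene) against the reference Mon1:

```text
species	family	cds_pct	gene_pct	protein_pct
Dic1	PHO1	90.3	83.1	78.0
Dic1	PHO2	90.5	82.6	78.5
```

`run1/phylo/tree.nwk` holds the bootstrapped NJ tree of all 24 proteins —
two family clades, each split into a monocot and a dicot cluster, e.g.
`(Dic3_PHO1:0.114,Dic4_PHO1:0.133)918:...` (918/1000 support on that
internal edge). `run1/synteny/report.tsv` gives the per-species shared and
collinear counts around each anchor:

```text
species	family	anchor	target_chromosome	window_size	shared	collinear	truncated
Dic1	PHO1	Mon1_PHO1_anchor	chr3	31	16	8	False
```

— 16 of the 30 flanking genes retained on the best target chromosome, with
a longest order-preserving run of 8 (dicot targets are shuffled by
construction; monocot targets keep their order, so there
collinear = shared).

Stage verbs (`phocomp simulate|structure|identity|consensus|promoter|phylo|synteny`)
rerun single stages; everything is deterministic per seed, and a rerun of
the same seed is byte-identical (timings live in a separate log).

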