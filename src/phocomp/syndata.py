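"""Synthetic species panels with full ground truth.

The generator emulates the data a comparative starch-phosphorylase study
retrieves from sequence databases: for each species and each of two
paralogous gene families — a plastidial-type family (N-terminal transit
peptide plus a 78-82 aa mid-sequence insertion) and a cytosolic-type family
(neither) — it emits a genomic span (translation start to stop), CDS,
protein and 1 kb promoter, plus gene-order tables around each anchor and
the true tree, so every downstream stage can be tested against known truth.

Evolution model: the family's ancestral CDS is mutated along a fixed
caterpillar guide tree (uniform substitutions, frame-preserving, internal
stop codons reverted); introns evolve faster and may take indels; planted
promoter motifs and SSRs are protected and re-stamped per species so their
coordinates stay known.  Everything is driven by explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genestruct import GeneModel, SSRHit
from .promoter import IUPAC_SETS, MotifDef, load_default_motifs
from .sequtils import AA20, DNA, back_translate, random_dna, revcomp, translate

INDEL_P = 0.5        # geometric length parameter for indels
INDEL_MAX = 10
INTRON_RATE_FACTOR = 2.0   # introns evolve this much faster than coding sequence
PROMOTER_LEN = 1000


class SpecError(ValueError):
    """A generator spec field is infeasible; the message names the field."""


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    clade: str                  # "monocot" | "dicot"
    divergence: float = 0.0     # substitutions/site from the panel root

    def __post_init__(self):
        if self.clade not in ("monocot", "dicot"):
            raise SpecError(f"clade: unknown clade {self.clade!r}")
        if not (0.0 <= self.divergence < 0.75):
            raise SpecError(f"divergence: {self.divergence} outside [0, 0.75)")


@dataclass(frozen=True)
class MotifPlant:
    name: str
    offset: int      # 0-based offset in the promoter
    strand: str = "+"


@dataclass(frozen=True)
class SSRPlant:
    unit: str
    copies: int
    offset: int      # 0-based offset in the genomic span (must fall in an intron)


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    seed: int
    n_exons: int = 15
    core_len: int = 840                     # aa, shared protein core
    insertion_len: int | None = None        # 78-82 aa mid-insertion, or None
    transit_len: int = 0                    # 0-50 aa after the initiator Met
    transit_his: int = 8                    # histidines planted in the transit peptide
    intron_len_range: tuple[int, int] = (80, 600)
    exon_len_range: tuple[int, int] = (60, 480)
    phases: tuple[int, ...] | None = None   # planted intron phases
    n_flank_genes: int = 15
    motif_plants: tuple[MotifPlant, ...] = ()
    ssr_plants: tuple[SSRPlant, ...] = ()

    def __post_init__(self):
        if self.n_exons < 2:
            raise SpecError("n_exons: need at least 2 exons")
        if self.insertion_len is not None and not (78 <= self.insertion_len <= 82):
            raise SpecError(f"insertion_len: {self.insertion_len} outside [78, 82]")
        if not (0 <= self.transit_len <= 50):
            raise SpecError(f"transit_len: {self.transit_len} outside [0, 50]")
        if self.intron_len_range[0] < 4:
            raise SpecError("intron_len_range: introns need >= 4 bp (GT...AG)")
        if self.exon_len_range[0] < 3:
            raise SpecError("exon_len_range: exons need >= 3 bp")
        if self.phases is not None:
            if len(self.phases) != self.n_exons - 1:
                raise SpecError("phases: need n_exons - 1 entries")
            if any(p not in (0, 1, 2) for p in self.phases):
                raise SpecError("phases: entries must be 0, 1 or 2")

    @property
    def protein_len(self) -> int:
        extra = (self.insertion_len or 0) + self.transit_len
        return 1 + self.core_len + extra   # initiator Met included

    @property
    def cds_len(self) -> int:
        return 3 * self.protein_len + 3    # stop codon included


def mutate(seq: str, sub_rate: float, indel_rate: float,
           seed: int | None = None, rng: np.random.Generator | None = None,
           protected: np.ndarray | None = None,
           protect_splice: bool = False) -> str:
    """Uniform substitutions and geometric-length indels (p=0.5, max 10).

    Deterministic for a fixed seed.  ``protected`` is a boolean mask of
    positions immune to substitution, deletion and interior insertion;
    ``protect_splice`` additionally shields the first and last two bases
    (splice dinucleotides of an intron).
    """
    if not (0.0 <= sub_rate < 1.0) or not (0.0 <= indel_rate < 1.0):
        raise SpecError("rates: sub_rate and indel_rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(seq)
    if n == 0:
        return seq
    alphabet = DNA if set(seq.upper()) <= set(DNA + "N") else AA20
    k = len(alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    arr = np.array([idx.get(c, 0) for c in seq.upper()], dtype=np.int64)
    prot = np.zeros(n, dtype=bool) if protected is None else protected.copy()
    if protect_splice and n >= 4:
        prot[:2] = True
        prot[-2:] = True
    # substitutions: uniform over the other k-1 symbols
    mask = (rng.random(n) < sub_rate) & ~prot
    shifts = rng.integers(1, k, size=n)
    arr[mask] = (arr[mask] + shifts[mask]) % k
    chars = [alphabet[i] for i in arr]
    if indel_rate == 0.0:
        return "".join(chars)
    # indel events resolved on original coordinates, then applied in one pass
    pos = np.nonzero((rng.random(n) < indel_rate) & ~prot)[0]
    deleted = np.zeros(n, dtype=bool)
    insertions: dict[int, str] = {}
    for p in pos:
        length = min(int(rng.geometric(INDEL_P)), INDEL_MAX)
        if rng.random() < 0.5:  # insertion before p
            ins = "".join(alphabet[i] for i in rng.integers(0, k, size=length))
            insertions[p] = insertions.get(p, "") + ins
        else:                   # deletion of up to `length` unprotected chars
            stop = p
            while stop < n and stop - p < length and not prot[stop]:
                stop += 1
            deleted[p:stop] = True
    out = []
    for i in range(n):
        if i in insertions:
            out.append(insertions[i])
        if not deleted[i]:
            out.append(chars[i])
    return "".join(out)


def _mutate_intron(seq: str, rate: float, rng: np.random.Generator,
                   indel_rate: float = 0.01) -> str:
    """Intron evolution: faster substitutions, small indels, splice sites
    shielded; a zero rate leaves the intron untouched."""
    capped = min(INTRON_RATE_FACTOR * rate, 0.6)
    return mutate(seq, capped, indel_rate if rate > 0 else 0.0,
                  rng=rng, protect_splice=True)


def _mutate_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Frame-preserving CDS evolution: substitutions only, start and stop
    codons fixed, codons that become internal stops reverted."""
    n = len(cds)
    prot = np.zeros(n, dtype=bool)
    prot[:3] = True
    prot[-3:] = True
    out = mutate(cds, rate, 0.0, rng=rng, protected=prot)
    out = list(out)
    for i in range(3, n - 3, 3):
        if "".join(out[i:i + 3]) in ("TAA", "TAG", "TGA"):
            out[i:i + 3] = cds[i:i + 3]
    return "".join(out)


def _plant_phased_cuts(L: int, phases: tuple[int, ...],
                       rng: np.random.Generator) -> list[int]:
    """Cumulative coding lengths (exon boundaries in CDS space) realizing
    the requested intron phases."""
    n = len(phases) + 1
    cuts = []
    prev = 0
    for i, p in enumerate(phases, start=1):
        target = round(i * L / n) + int(rng.integers(-30, 31))
        target = max(prev + 9, min(target, L - 9 * (n - i)))
        # shift to the required residue class mod 3
        target += (p - target) % 3
        if target <= prev:
            target += 3
        cuts.append(target)
        prev = target
    return cuts


@dataclass
class SpeciesGeneTruth:
    """Ground truth for one species x family record."""

    species: str
    family: str
    model: GeneModel
    genomic: str
    cds: str
    protein: str
    promoter: str
    phases: tuple[int, ...]
    motif_plants: tuple[tuple[str, int, str], ...]   # (name, offset, strand)
    ssr_hits: tuple[SSRHit, ...]                     # genomic coordinates
    insertion_interval: tuple[int, int] | None       # protein coords of L80
    transit_interval: tuple[int, int] | None


@dataclass
class SyntenyTruth:
    species: str
    family: str
    target_chromosome: str
    shared: int
    order_preserved: bool


@dataclass
class TruthBundle:
    genes: dict[tuple[str, str], SpeciesGeneTruth]
    synteny: dict[tuple[str, str], SyntenyTruth]
    true_tree: str            # parenthesized, tips "<species>_<family>"
    source_tables: dict[str, "object"]
    target_tables: dict[tuple[str, str], "object"]
    orthomaps: dict[tuple[str, str], dict[str, list[str]]]


@dataclass
class Panel:
    species: tuple[SpeciesSpec, ...]
    families: tuple[FamilySpec, ...]
    truth: TruthBundle

    @property
    def reference(self) -> str:
        return self.species[0].name

    def record(self, species: str, family: str) -> SpeciesGeneTruth:
        return self.truth.genes[(species, family)]

    def clade_assignment(self) -> dict[str, str]:
        return {sp.name: sp.clade for sp in self.species}


def _build_ancestral_protein(spec: FamilySpec, rng: np.random.Generator,
                             core: str) -> tuple[str, tuple[int, int] | None,
                                                 tuple[int, int] | None]:
    """Assemble Met + transit + core-with-insertion; return protein and the
    protein-coordinate intervals of the insertion and transit peptide."""
    parts = ["M"]
    transit_iv = None
    if spec.transit_len > 0:
        no_h = [c for c in AA20 if c != "H"]
        aa = [no_h[i] for i in rng.integers(0, len(no_h), size=spec.transit_len)]
        n_his = min(spec.transit_his, spec.transit_len)
        his_pos = rng.choice(spec.transit_len, size=n_his, replace=False)
        for hp in his_pos:
            aa[hp] = "H"
        # keep the transit stretch clear of basic flanks confusion is fine;
        # anchor it right after the initiator Met
        parts.append("".join(aa))
        transit_iv = (1, 1 + spec.transit_len)
    ins_iv = None
    if spec.insertion_len is not None:
        mid = len(core) // 2
        ins = _pest_bearing_insert(spec.insertion_len, rng)
        start = 1 + spec.transit_len + mid
        parts.append(core[:mid])
        parts.append(ins)
        parts.append(core[mid:])
        ins_iv = (start, start + spec.insertion_len)
    else:
        parts.append(core)
    return "".join(parts), ins_iv, transit_iv


def _pest_bearing_insert(length: int, rng: np.random.Generator) -> str:
    """The mid-sequence insertion, carrying a PEST-like stretch flanked by
    basic residues (as the plastidial isoform's insertion does)."""
    pest_len = 30
    pad = length - pest_len - 2
    left = pad // 2
    right = pad - left
    non_basic = [c for c in AA20 if c not in "KRH"]
    def rand_nb(n):
        return "".join(non_basic[i] for i in rng.integers(0, len(non_basic), size=n))
    pest_pool = "PEST"
    pest = "P" + "".join(pest_pool[i] for i in rng.integers(0, 4, size=pest_len - 2)) + "E"
    return rand_nb(left) + "K" + pest + "R" + rand_nb(right)


def _plant_ssr(genomic: list[str], plant: SSRPlant,
               model: GeneModel) -> SSRHit:
    start, end = plant.offset, plant.offset + len(plant.unit) * plant.copies
    in_intron = any(s + 2 <= start and end <= e - 2 for s, e in model.introns)
    if not in_intron:
        raise SpecError(f"ssr_plants: offset {plant.offset} does not fall "
                        f"inside an intron (2 bp clear of splice sites)")
    genomic[start:end] = list(plant.unit * plant.copies)
    # guard bases so the planted run is maximal exactly as specified
    unit = plant.unit
    genomic[start - 1] = _breaker(unit[-1])
    if end < len(genomic):
        genomic[end] = _breaker(unit[0])
    return SSRHit(unit=min(unit[i:] + unit[:i] for i in range(len(unit))),
                  copies=plant.copies, start=start, end=end)


def _breaker(avoid: str) -> str:
    """A base that cannot extend a repeat whose adjacent unit base is `avoid`."""
    return "C" if avoid != "C" else "G"


def _plant_motifs(promoter: list[str], plants: tuple[MotifPlant, ...],
                  motif_defs: dict[str, MotifDef]) -> list[tuple[str, int, str]]:
    placed = []
    for p in plants:
        if p.name not in motif_defs:
            raise SpecError(f"motif_plants: unknown motif {p.name!r}")
        m = motif_defs[p.name]
        if m.kind == "iupac":
            site = "".join(IUPAC_SETS[c][0] for c in m.consensus.upper())
        else:
            site = _pwm_consensus(m)
        if p.strand == "-":
            site = revcomp(site)
        if p.offset < 0 or p.offset + len(site) > len(promoter):
            raise SpecError(f"motif_plants: offset {p.offset} beyond promoter "
                            f"length {len(promoter)}")
        promoter[p.offset:p.offset + len(site)] = list(site)
        placed.append((p.name, p.offset, p.strand))
    return placed


def _pwm_consensus(m: MotifDef) -> str:
    return "".join("ACGT"[i] for i in np.argmax(m.pwm, axis=1))


def default_families(seed: int) -> tuple[FamilySpec, FamilySpec]:
    """The two study families: plastidial-type (insertion + transit) and
    cytosolic-type (neither), with planted phases, motifs and SSRs."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(x) for x in ss.generate_state(2) % (2**31))
    pho1 = FamilySpec(
        family_id="PHO1", seed=s1, n_exons=15, core_len=840,
        insertion_len=80, transit_len=45, intron_len_range=(80, 600),
        phases=(0, 0, 0, 0, 1, 0, 0, 0, 2, 0, 0, 0, 0, 2),
        motif_plants=(MotifPlant("ABRE", 300, "+"),
                      MotifPlant("MBS", 600, "-"),
                      MotifPlant("TATA-box", 950, "+"),
                      MotifPlant("GCN4-endosperm", 450, "+")),
        ssr_plants=(SSRPlant("AT", 8, 0),),   # offset resolved per model below
    )
    pho2 = FamilySpec(
        family_id="PHO2", seed=s2, n_exons=15, core_len=840,
        insertion_len=None, transit_len=0, intron_len_range=(80, 900),
        phases=(0, 0, 0, 2, 0, 0, 0, 2, 0, 0, 0, 0, 2, 0),
        motif_plants=(MotifPlant("ABRE", 250, "+"),
                      MotifPlant("CAAT-box", 700, "+"),
                      MotifPlant("TATA-box", 955, "+")),
        ssr_plants=(SSRPlant("AAG", 6, 0),),
    )
    return pho1, pho2


def default_species() -> tuple[SpeciesSpec, ...]:
    """Eight monocots and four dicots; the first species is the reference
    (zero divergence), dicots are a deeper clade."""
    mono = [SpeciesSpec(f"Mon{i+1}", "monocot", d)
            for i, d in enumerate([0.0, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08])]
    dic = [SpeciesSpec(f"Dic{i+1}", "dicot", d)
           for i, d in enumerate([0.10, 0.11, 0.12, 0.13])]
    return tuple(mono + dic)


FAMILY_SPLIT_DIV = 0.175     # CDS divergence from the shared core to each family
BACKBONE_FRACTION = 0.5      # share of per-species divergence spent on the backbone


def generate_panel(species: list[SpeciesSpec] | tuple[SpeciesSpec, ...],
                   families: list[FamilySpec] | tuple[FamilySpec, ...]) -> Panel:
    """Generate a full panel with ground truth; deterministic per family seed."""
    names = [sp.name for sp in species]
    if len(set(names)) != len(names):
        raise SpecError("species: names must be unique within a panel")
    species = tuple(species)
    families = tuple(families)

    motif_defs = {m.name: m for m in load_default_motifs()}
    genes: dict[tuple[str, str], SpeciesGeneTruth] = {}
    synteny_truth: dict[tuple[str, str], SyntenyTruth] = {}
    source_tables = {}
    target_tables = {}
    orthomaps = {}
    family_trees = []

    # the shared ancestral core ties the two families into known paralogs
    core_rng = np.random.default_rng(
        int(np.random.SeedSequence([f.seed for f in families]).generate_state(1)[0]
            % (2**31)))
    core_len = families[0].core_len
    core = "".join(AA20[i] for i in core_rng.integers(0, 20, size=core_len))

    for fam in families:
        if fam.core_len != core_len:
            raise SpecError("core_len: all families must share the core length")
        rng = np.random.default_rng(fam.seed)
        fam_core = mutate(core, FAMILY_SPLIT_DIV, 0.0, rng=rng)
        protein, ins_iv, transit_iv = _build_ancestral_protein(fam, rng, fam_core)
        anc_cds = back_translate(protein, rng)
        phases = fam.phases or tuple(int(p) for p in rng.integers(0, 3,
                                                                  size=fam.n_exons - 1))
        cuts = _plant_phased_cuts(len(anc_cds), phases, rng)
        lo, hi = fam.intron_len_range
        anc_introns = [("GT" + random_dna(int(rng.integers(lo, hi + 1)) - 4, rng)
                        + "AG") for _ in range(fam.n_exons - 1)]
        anc_promoter = random_dna(PROMOTER_LEN, rng)

        # per-clade evolution along a caterpillar
        clade_members = {"monocot": [sp for sp in species if sp.clade == "monocot"],
                         "dicot": [sp for sp in species if sp.clade == "dicot"]}
        tips: dict[str, tuple[str, list[str], str]] = {}
        for clade, members in clade_members.items():
            if not members:
                continue
            if clade == "monocot":
                depth = 0.0
                cds_b, introns_b, prom_b = anc_cds, list(anc_introns), anc_promoter
            else:
                depth = BACKBONE_FRACTION * min(sp.divergence for sp in members)
                cds_b = _mutate_cds(anc_cds, depth, rng)
                introns_b = [_mutate_intron(i, depth, rng) for i in anc_introns]
                prom_b = mutate(anc_promoter, depth, 0.0, rng=rng)
            consumed = depth
            for sp in members:
                pendant = max(sp.divergence - consumed, 0.0)
                cds_t = _mutate_cds(cds_b, pendant, rng)
                introns_t = [_mutate_intron(i, pendant, rng) for i in introns_b]
                prom_t = mutate(prom_b, pendant, 0.0, rng=rng)
                tips[sp.name] = (cds_t, introns_t, prom_t)
                step = BACKBONE_FRACTION * max(
                    (members[members.index(sp) + 1].divergence - sp.divergence)
                    if members.index(sp) + 1 < len(members) else 0.0, 0.0)
                if step > 0:
                    cds_b = _mutate_cds(cds_b, step, rng)
                    introns_b = [_mutate_intron(i, step, rng) for i in introns_b]
                    prom_b = mutate(prom_b, step, 0.0, rng=rng)
                    consumed += step

        # assemble per-species records
        for sp in species:
            cds_t, introns_t, prom_t = tips[sp.name]
            exon_seqs = []
            prev = 0
            for c in cuts + [len(cds_t)]:
                exon_seqs.append(cds_t[prev:c])
                prev = c
            coords = []
            pos = 0
            pieces = []
            for i, ex in enumerate(exon_seqs):
                pieces.append(ex)
                coords.append((pos, pos + len(ex)))
                pos += len(ex)
                if i < len(introns_t):
                    pieces.append(introns_t[i])
                    pos += len(introns_t[i])
            genomic = list("".join(pieces))
            model = GeneModel(gene_id=f"{sp.name}_{fam.family_id}",
                              genomic_len=len(genomic), exons=tuple(coords))
            ssr_hits = []
            for plant in fam.ssr_plants:
                resolved = plant
                if plant.offset == 0:   # auto-place in the midpoint of intron 1
                    istart, iend = model.introns[0]
                    width = len(plant.unit) * plant.copies
                    off = istart + (iend - istart - width) // 2
                    resolved = replace(plant, offset=off)
                ssr_hits.append(_plant_ssr(genomic, resolved, model))
            prom_list = list(prom_t)
            placed = _plant_motifs(prom_list, fam.motif_plants, motif_defs)
            genomic_s = "".join(genomic)
            cds_final = model.spliced(genomic_s)
            prot_final = translate(cds_final)
            genes[(sp.name, fam.family_id)] = SpeciesGeneTruth(
                species=sp.name, family=fam.family_id, model=model,
                genomic=genomic_s, cds=cds_final, protein=prot_final,
                promoter="".join(prom_list), phases=phases,
                motif_plants=tuple(placed), ssr_hits=tuple(ssr_hits),
                insertion_interval=ins_iv, transit_interval=transit_iv)

        # gene-order tables and synteny truth
        src_tab, tgt_tabs, omap, struth = _make_synteny(fam, species, rng)
        source_tables[fam.family_id] = src_tab
        for spname, tab in tgt_tabs.items():
            target_tables[(spname, fam.family_id)] = tab
        for spname, m in omap.items():
            orthomaps[(spname, fam.family_id)] = m
        synteny_truth.update({(s.species, fam.family_id): s for s in struth})

        family_trees.append(_clade_newick(fam.family_id, clade_members))

    truth = TruthBundle(genes=genes, synteny=synteny_truth,
                        true_tree=f"({family_trees[0]},{family_trees[1]});"
                        if len(family_trees) == 2 else f"({family_trees[0]});",
                        source_tables=source_tables,
                        target_tables=target_tables, orthomaps=orthomaps)
    return Panel(species=species, families=families, truth=truth)


def _clade_newick(family_id: str, clade_members: dict) -> str:
    def nest(members):
        tips = [f"{sp.name}_{family_id}" for sp in members]
        out = tips[-1]
        for t in reversed(tips[:-1]):
            out = f"({t},{out})"
        return out
    parts = [nest(m) for m in clade_members.values() if m]
    return f"({','.join(parts)})" if len(parts) > 1 else parts[0]


def _make_synteny(fam: FamilySpec, species: tuple[SpeciesSpec, ...],
                  rng: np.random.Generator):
    from .synteny import GeneOrderTable
    ref = species[0].name
    flank = fam.n_flank_genes
    anchor = f"{ref}_{fam.family_id}_anchor"
    left = [f"{fam.family_id}_L{i:02d}" for i in range(flank, 0, -1)]
    right = [f"{fam.family_id}_R{i:02d}" for i in range(1, flank + 1)]
    window = left + [anchor] + right
    src_chrom = "chr3" if fam.family_id.endswith("1") else "chr1"
    src_tab = GeneOrderTable({src_chrom: window})
    tgt_tabs = {}
    omaps = {}
    struths = []
    flanking = left + right
    for sp in species[1:]:
        n_retain = int(rng.integers(10, 26))
        keep_idx = sorted(rng.choice(len(flanking), size=n_retain, replace=False))
        preserved = sp.clade == "monocot"
        order = list(keep_idx)
        if not preserved:
            order = list(rng.permutation(keep_idx))
        tgt_genes = []
        omap = {}
        for j, ki in enumerate(order):
            tgt_id = f"{sp.name}_{fam.family_id}_t{j:02d}"
            tgt_genes.append(tgt_id)
            omap[flanking[ki]] = [tgt_id]
        # interleave unrelated filler genes
        fillers = [f"{sp.name}_{fam.family_id}_x{j:02d}"
                   for j in range(int(rng.integers(3, 8)))]
        for f in fillers:
            tgt_genes.insert(int(rng.integers(0, len(tgt_genes) + 1)), f)
        chrom = f"chr{int(rng.integers(1, 11))}"
        tgt_tabs[sp.name] = GeneOrderTable({chrom: tgt_genes})
        omaps[sp.name] = omap
        struths.append(SyntenyTruth(species=sp.name, family=fam.family_id,
                                    target_chromosome=chrom, shared=n_retain,
                                    order_preserved=preserved))
    return src_tab, tgt_tabs, omaps, struths
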