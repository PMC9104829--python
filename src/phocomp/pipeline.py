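"""End-to-end orchestration: synthetic panel in, report bundle out.

Stages mirror the analysis a comparative gene-family study runs: simulate
(or load) a panel, derive exon-intron structure, profile identity against
the reference species, build the consensus/similarity profile, scan
promoters, build the bootstrapped NJ tree, and count microsynteny.  Every
stage writes plain-text outputs into its own subdirectory and the manifest
records seeds, thresholds and timings; a fixed seed reproduces the bundle
byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .genestruct import (find_ssrs, intron_phases, map_cds, model_to_gff3,
                         phase_share, total_intron_bp)
from .phylo import bootstrap, distance_to_tsv, p_distance
from .promoter import load_default_motifs, scan, summarize_hits
from .protprof import (detect_insertion, features_to_tsv, find_pest,
                       progressive_msa, similarity_profile)
from .seqsim import global_align, segment_identity
from .syndata import (FamilySpec, Panel, SpeciesSpec, default_families,
                      default_species, generate_panel)
from .synteny import count_shared, extract_window


@dataclass
class RunConfig:
    seed: int = 1
    outdir: Path = Path("phocomp_out")
    species: tuple[SpeciesSpec, ...] | None = None   # default: 8 monocots + 4 dicots
    families: tuple[FamilySpec, ...] | None = None
    reference: str | None = None                     # default: first species
    bootstrap_replicates: int = 1000
    stages: tuple[str, ...] = ("simulate", "structure", "identity", "consensus",
                               "promoter", "phylo", "synteny")

    def resolve(self) -> "RunConfig":
        sp = self.species or default_species()
        fam = self.families or default_families(self.seed)
        ref = self.reference or sp[0].name
        if ref not in {s.name for s in sp}:
            raise ValueError(f"reference {ref!r} not in the panel")
        return RunConfig(seed=self.seed, outdir=Path(self.outdir), species=sp,
                         families=fam, reference=ref,
                         bootstrap_replicates=self.bootstrap_replicates,
                         stages=self.stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        species = raw.get("species")
        if species:
            species = tuple(SpeciesSpec(**s) for s in species)
        cfg = cls(seed=raw.get("seed", 1),
                  outdir=Path(raw.get("outdir", "phocomp_out")),
                  species=species,
                  reference=raw.get("reference"),
                  bootstrap_replicates=raw.get("bootstrap_replicates", 1000))
        return cfg


def _write(path: Path, text: str):
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def _fasta(records: list[tuple[str, str]]) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in records)


def run(config: RunConfig) -> dict:
    """Run the configured stages; returns the in-memory results bundle."""
    cfg = config.resolve()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": cfg.seed,
                "reference": cfg.reference,
                "bootstrap_replicates": cfg.bootstrap_replicates,
                "species": [s.name for s in cfg.species],
                "families": [f.family_id for f in cfg.families],
                "stages": list(cfg.stages)}
    timings: dict[str, float] = {}
    results: dict = {}
    panel = generate_panel(cfg.species, cfg.families)
    results["panel"] = panel

    def stage(name):
        return name in cfg.stages

    t0 = time.perf_counter()
    if stage("simulate"):
        emit_panel(panel, out / "sequences")
        timings["simulate"] = round(time.perf_counter() - t0, 3)

    keys = sorted(panel.truth.genes)
    ref = cfg.reference

    if stage("structure"):
        t0 = time.perf_counter()
        gff, intron_rows, ssr_rows, summary_rows = [], [], [], []
        models = {}
        for sp, fam in keys:
            rec = panel.truth.genes[(sp, fam)]
            model = map_cds(rec.genomic, rec.cds, gene_id=f"{sp}_{fam}")
            models[(sp, fam)] = model
            gff.append(model_to_gff3(model, seqid=f"{sp}_{fam}"))
            recs = intron_phases(model, rec.genomic)
            for r in recs:
                intron_rows.append(f"{sp}_{fam}\t{r.index}\t{r.length}\t{r.phase}"
                                   f"\t{r.gc:.4f}")
            for h in find_ssrs(rec.genomic):
                ssr_rows.append(f"{sp}_{fam}\t{h.start}\t{h.end}\t{h.unit}\t{h.copies}")
            gene_len = model.genomic_len
            cdna_len = len(rec.cds)   # the simulated span carries no UTRs
            summary_rows.append(
                f"{sp}\t{fam}\t{cdna_len}\t{len(rec.cds)}\t{gene_len}\t"
                f"{len(rec.protein)}\t{len(model.exons)}\t{len(model.introns)}\t"
                f"{total_intron_bp(gene_len, cdna_len)}\t"
                f"{phase_share(recs):.2f}")
        _write(out / "structure" / "models.gff3", "##gff-version 3\n" + "".join(gff))
        _write(out / "structure" / "introns.tsv",
               "gene\tintron_index\tlength_bp\tphase\tgc\n" + "\n".join(intron_rows) + "\n")
        _write(out / "structure" / "ssr.bed",
               "\n".join(ssr_rows) + ("\n" if ssr_rows else ""))
        _write(out / "structure" / "summary.tsv",
               "species\tfamily\tcdna_bp\tcds_bp\tgene_bp\tprotein_aa\t"
               "n_exons\tn_introns\tintron_total_bp\tphase0_pct\n"
               + "\n".join(summary_rows) + "\n")
        results["models"] = models
        timings["structure"] = round(time.perf_counter() - t0, 3)

    if stage("identity"):
        t0 = time.perf_counter()
        rows = []
        seg_rows = []
        idmat = {}
        for sp, fam in keys:
            rec = panel.truth.genes[(sp, fam)]
            refrec = panel.truth.genes[(ref, fam)]
            vals = {}
            for label, a, b in (("cds", rec.cds, refrec.cds),
                                ("gene", rec.genomic, refrec.genomic),
                                ("protein", rec.protein, refrec.protein)):
                vals[label] = global_align(a, b).identity
            idmat[(sp, fam)] = vals
            rows.append(f"{sp}\t{fam}\t{vals['cds']:.1f}\t{vals['gene']:.1f}"
                        f"\t{vals['protein']:.1f}")
            model_a = results.get("models", {}).get((sp, fam)) or rec.model
            model_b = results.get("models", {}).get((ref, fam)) or refrec.model
            seg = segment_identity(model_a, model_b, rec.genomic, refrec.genomic)
            for i, v in enumerate(seg.exon_identity, 1):
                seg_rows.append(f"{sp}\t{fam}\texon\t{i}\t{v:.1f}")
            for i, v in enumerate(seg.intron_identity, 1):
                seg_rows.append(f"{sp}\t{fam}\tintron\t{i}\t{v:.1f}")
        _write(out / "identity" / "identity.tsv",
               "species\tfamily\tcds_pct\tgene_pct\tprotein_pct\n"
               + "\n".join(rows) + "\n")
        _write(out / "identity" / "segments.tsv",
               "species\tfamily\tsegment\tordinal\tidentity_pct\n"
               + "\n".join(seg_rows) + "\n")
        results["identity"] = idmat
        timings["identity"] = round(time.perf_counter() - t0, 3)

    if stage("consensus"):
        t0 = time.perf_counter()
        clades = panel.clade_assignment()
        for fam in sorted({f for _, f in keys}):
            seqs = [(sp, panel.truth.genes[(sp, fam)].protein)
                    for sp, f in keys if f == fam]
            msa = progressive_msa(seqs)
            profile = similarity_profile(msa, clades, ref)
            _write(out / "consensus" / f"{fam}_msa.fasta", msa.to_fasta())
            _write(out / "consensus" / f"{fam}_profile.tsv", profile.to_tsv())
            results.setdefault("msa", {})[fam] = msa
            results.setdefault("profiles", {})[fam] = profile
        fams = sorted({f for _, f in keys})
        if len(fams) == 2:
            feat_rows = []
            for sp in sorted({s for s, _ in keys}):
                p1 = panel.truth.genes[(sp, fams[0])].protein
                p2 = panel.truth.genes[(sp, fams[1])].protein
                feats = detect_insertion(p1, p2)
                pest = [r for f in feats if f.kind == "L80"
                        for r in find_pest(p1[f.start:f.end])]
                feat_rows.append((sp, feats, pest))
            text = "".join(f"# {sp}\n" + features_to_tsv(f, p)
                           for sp, f, p in feat_rows)
            _write(out / "consensus" / "features.tsv", text)
            results["features"] = feat_rows
        timings["consensus"] = round(time.perf_counter() - t0, 3)

    if stage("promoter"):
        t0 = time.perf_counter()
        motifs = load_default_motifs()
        all_rows = []
        summaries = []
        for sp, fam in keys:
            rec = panel.truth.genes[(sp, fam)]
            hits = scan(rec.promoter, motifs)
            results.setdefault("promoter", {})[(sp, fam)] = hits
            for h in hits:
                all_rows.append(f"{sp}_{fam}\t{h.motif}\t{h.position}\t{h.strand}"
                                f"\t{h.score:.3f}")
            counts = summarize_hits(hits)
            summaries.append(f"{sp}_{fam}\t" + ",".join(f"{k}:{v}"
                                                        for k, v in counts.items()))
        _write(out / "promoter" / "hits.tsv",
               "gene\tmotif\tposition\tstrand\tscore\n" + "\n".join(all_rows) + "\n")
        _write(out / "promoter" / "summary.tsv",
               "gene\telement_counts\n" + "\n".join(summaries) + "\n")
        timings["promoter"] = round(time.perf_counter() - t0, 3)

    if stage("phylo"):
        t0 = time.perf_counter()
        seqs = [(f"{sp}_{fam}", panel.truth.genes[(sp, fam)].protein)
                for sp, fam in keys]
        msa = progressive_msa(seqs)
        dist = p_distance(msa)
        tree = bootstrap(msa, n=cfg.bootstrap_replicates, seed=cfg.seed)
        _write(out / "phylo" / "combined_msa.fasta", msa.to_fasta())
        _write(out / "phylo" / "distances.tsv", distance_to_tsv(dist))
        _write(out / "phylo" / "tree.nwk", tree.newick(supports=True) + "\n")
        results["tree"] = tree
        timings["phylo"] = round(time.perf_counter() - t0, 3)

    if stage("synteny"):
        t0 = time.perf_counter()
        reports = []
        lines = ["species\tfamily\tanchor\ttarget_chromosome\twindow_size"
                 "\tshared\tcollinear\ttruncated"]
        for fam in sorted({f for _, f in keys}):
            src = panel.truth.source_tables[fam]
            anchor = f"{ref}_{fam}_anchor"
            window, truncated = extract_window(src, anchor)
            for sp in sorted({s for s, _ in keys} - {ref}):
                tgt = panel.truth.target_tables[(sp, fam)]
                omap = panel.truth.orthomaps[(sp, fam)]
                rep = count_shared(window, anchor, tgt, omap, truncated)
                reports.append((sp, fam, rep))
                lines.append(f"{sp}\t{fam}\t{rep.anchor}\t{rep.target_chromosome}"
                             f"\t{rep.window_size}\t{rep.shared}\t{rep.collinear}"
                             f"\t{rep.truncated}")
        _write(out / "synteny" / "report.tsv", "\n".join(lines) + "\n")
        results["synteny"] = reports
        timings["synteny"] = round(time.perf_counter() - t0, 3)

    _write(out / "manifest.json", json.dumps(manifest, indent=2) + "\n")
    # wall-clock timings kept out of the manifest so a reseeded rerun is
    # byte-identical; they land in a separate plain-text log
    _write(out / "timings.log",
           "".join(f"{k}\t{v:.3f}s\n" for k, v in timings.items()))
    results["manifest"] = manifest
    results["timings"] = timings
    return results


def emit_panel(panel: Panel, outdir: Path):
    """Write a panel's sequences, truth models and tables as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    keys = sorted(panel.truth.genes)
    for kind in ("genomic", "cds", "protein", "promoter"):
        recs = [(f"{sp}_{fam}", getattr(panel.truth.genes[(sp, fam)], kind))
                for sp, fam in keys]
        _write(outdir / f"{kind}.fasta", _fasta(recs))
    gff = "".join(model_to_gff3(panel.truth.genes[k].model, seqid=f"{k[0]}_{k[1]}")
                  for k in keys)
    _write(outdir / "truth_models.gff3", "##gff-version 3\n" + gff)
    for fam, tab in panel.truth.source_tables.items():
        _write(outdir / f"gene_order_{panel.reference}_{fam}.tsv", tab.to_tsv())
    for (sp, fam), tab in sorted(panel.truth.target_tables.items()):
        _write(outdir / f"gene_order_{sp}_{fam}.tsv", tab.to_tsv())
    omap_lines = ["source_id\ttarget_id"]
    for (sp, fam), omap in sorted(panel.truth.orthomaps.items()):
        for src, tgts in sorted(omap.items()):
            for t in tgts:
                omap_lines.append(f"{src}\t{t}")
    _write(outdir / "orthomap.tsv", "\n".join(omap_lines) + "\n")
    _write(outdir / "true_tree.nwk", panel.truth.true_tree + "\n")
    spec = {"species": [{"name": s.name, "clade": s.clade,
                         "divergence": s.divergence} for s in panel.species],
            "families": [{"family_id": f.family_id, "seed": f.seed,
                          "n_exons": f.n_exons,
                          "insertion_len": f.insertion_len,
                          "transit_len": f.transit_len}
                         for f in panel.families]}
    _write(outdir / "panel.yaml", yaml.safe_dump(spec, sort_keys=False))
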