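"""End-to-end orchestration: configuration, logging, and the staged pipeline
binding catalog -> pangenome -> phylogenomics -> profiling -> enrichment.

Given a simulated (or externally supplied) genome catalog with gene calls,
per-sample alignments, annotations and module definitions, ``run_pipeline``
produces, in order: the selected and dereplicated reference set, the
gene-cluster matrix and genome dendrogram, the single-copy-core supermatrix
and tree with the tree/dendrogram comparison, per-sample detection and
abundance tables rolled up to species and sites, and the module-completeness
and enrichment tables.  All outputs are plain text and reproducible from the
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd
import yaml

from . import catalog as cat
from . import enrichment as enr
from . import io as mio
from . import pangenome as pan
from . import phylo
from . import profiler as prof
from .profiler import ORAL_SITES, SampleRecord
from .simulate import SimulationConfig, simulate_annotations, simulate_catalog, simulate_metagenomes

logger = logging.getLogger("metapan")
if not logger.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_sample_manifest"]


@dataclass
class PipelineConfig:
    """All stage thresholds plus run-level settings; defaults are the
    pipeline's canonical values."""

    outdir: str = "metapan_out"
    seed: int = 1
    min_contig_len: int = 300
    min_completeness: float = 90.0
    max_contamination: float = 5.0
    derep_ani: float = 0.98
    minbit: float = 0.5
    mcl_inflation: float = 10.0
    genome_breadth_min: float = 0.5
    gene_breadth_min: float = 0.9
    module_completeness: float = 0.75
    q_threshold: float = 0.01
    max_gap_frac: float = 0.5
    abundance_denominator: str = "all"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def selection(self) -> cat.SelectionConfig:
        return cat.SelectionConfig(
            min_contig_len=self.min_contig_len,
            min_completeness=self.min_completeness,
            max_contamination=self.max_contamination,
            derep_ani=self.derep_ani,
        )

    def detection(self) -> prof.DetectionConfig:
        return prof.DetectionConfig(
            genome_breadth_min=self.genome_breadth_min,
            gene_breadth_min=self.gene_breadth_min,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    stage_counts: Dict[str, int] = field(default_factory=dict)


def load_sample_manifest(
    path: str | Path,
) -> Tuple[List[SampleRecord], Dict[str, int], int]:
    """Read the sample manifest and tally samples per oral site.

    Returns (records, per-site counts, grand total).  Unknown site labels and
    duplicate sample ids raise; samples with zero mapped reads are warned
    about, not dropped — the smallest sites must survive aggregation.
    """
    records = mio.read_sample_manifest(path)
    tallies = {site: 0 for site in ORAL_SITES}
    for r in records:
        tallies[r.oral_site] += 1
        if r.total_reads and r.mapped_reads == 0:
            logger.warning("sample %s has zero mapped reads", r.sample_id)
    return records, tallies, len(records)


def run_pipeline(
    cfg: PipelineConfig,
    sim: SimulationConfig | None = None,
    *,
    stages: Sequence[str] = ("catalog", "pangenome", "phylo", "profile", "enrich"),
) -> Dict[str, object]:
    """Run the staged pipeline on a simulated dataset and write every stage's
    plain-text outputs under ``cfg.outdir``.  Returns the in-memory bundle.

    The simulation stands in for external inputs; each stage consumes only the
    previous stage's artifacts, so externally supplied files in the same
    formats drop in unchanged.
    """
    logger.setLevel(cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = sim or SimulationConfig(seed=cfg.seed)
    bundle: Dict[str, object] = {}

    genomes, gene_calls, truth = simulate_catalog(sim)
    bundle["truth"] = truth

    # --- stage 1: catalog ------------------------------------------------
    sel_cfg = cfg.selection()
    cleaned = [cat.clean_contigs(g, sel_cfg) for g in genomes]
    selected = cat.select_genomes(cleaned, sel_cfg)
    ani = cat.ani_matrix(selected, sel_cfg)
    reps = cat.dereplicate(selected, ani, sel_cfg)
    rep_ids = {g.genome_id for g in reps}
    mio.write_manifest(selected, out / "catalog_selected.tsv")
    mio.write_ani_matrix([g.genome_id for g in selected], ani, out / "ani_matrix.tsv")
    mio.write_manifest(reps, out / "catalog_representatives.tsv")
    logger.info("catalog: %d selected, %d representatives", len(selected), len(reps))
    bundle.update(selected=selected, ani=ani, representatives=reps)
    if "pangenome" not in stages:
        return bundle

    # --- stage 2: pangenome ----------------------------------------------
    rep_genes = [g for g in gene_calls if g.genome_id in rep_ids]
    clusters, matrix = pan.build_pangenome(
        rep_genes, minbit=cfg.minbit, inflation=cfg.mcl_inflation
    )
    counts = pan.classify_clusters(matrix)
    _, dendro_newick = pan.genome_dendrogram(matrix)
    mio.write_cluster_membership(clusters, out / "gene_clusters.tsv")
    mio.write_matrix(matrix, out / "pangenome_matrix.tsv")
    (out / "pangenome_dendrogram.nwk").write_text(dendro_newick + "\n")
    logger.info("pangenome: %(total)d clusters (%(core)d core / %(accessory)d "
                "accessory / %(singleton)d singleton)", counts)
    bundle.update(clusters=clusters, matrix=matrix, cluster_counts=counts,
                  dendrogram=dendro_newick, gene_calls=rep_genes)
    if "phylo" not in stages:
        return bundle

    # --- stage 3: phylogenomics -------------------------------------------
    scg = phylo.extract_scg(matrix)
    protein_of = {g.gene_id: g.protein for g in rep_genes}
    genome_of = {g.gene_id: g.genome_id for g in rep_genes}
    alignments = {}
    for c in clusters:
        if c.cluster_id in scg.clusters:
            members = {genome_of[m]: protein_of[m] for m in c.members}
            alignments[c.cluster_id] = phylo.align_cluster(members)
    tree = None
    rf = None
    if len(scg.clusters) >= 1 and matrix.shape[0] >= 3:
        sm = phylo.concatenate_and_trim(alignments, cfg.max_gap_frac)
        tree = phylo.build_tree(sm)
        tree.write(str(out / "scg_tree.nwk"))
        from skbio import TreeNode
        dendro_tree = TreeNode.read([dendro_newick], convert_underscores=False)
        _, rf = phylo.compare_trees(tree, dendro_tree)
        with open(out / "tree_vs_dendrogram.txt", "w") as fh:
            fh.write(f"robinson_foulds\t{rf}\n")
    logger.info("phylo: %d single-copy core clusters, RF(tree, dendrogram)=%s",
                len(scg.clusters), rf)
    bundle.update(scg=scg, tree=tree, rf_distance=rf)
    if "profile" not in stages:
        return bundle

    # --- stage 4: metagenome profiling -------------------------------------
    reads_dir = out / "reads"
    samples = simulate_metagenomes(sim, reps, truth, reads_dir)
    det_cfg = cfg.detection()
    abundance_rows = []
    detection = {}
    for s in samples:
        profiles = prof.coverage_from_alignments(
            str(reads_dir / f"{s.sample_id}.sam"), reps, s.sample_id
        )
        table = prof.relative_abundance(
            profiles, det_cfg, denominator=cfg.abundance_denominator
        )
        abundance_rows.append(table)
        detection[s.sample_id] = dict(zip(table["genome_id"], table["detected"]))
    abundance = pd.concat(abundance_rows, ignore_index=True)
    species_map = {g.genome_id: truth.species_of[g.genome_id] for g in reps}
    species_table = prof.species_rollup(abundance, species_map)
    det_matrix = pd.DataFrame(detection).fillna(False).astype(int)
    mio.write_matrix(det_matrix, out / "detection_matrix.tsv")
    abundance.to_csv(out / "abundance.tsv", sep="\t", index=False)
    species_table.to_csv(out / "species_abundance.tsv", sep="\t", index=False)
    logger.info("profile: %d samples, %d detections", len(samples),
                int(det_matrix.to_numpy().sum()))
    bundle.update(samples=samples, abundance=abundance,
                  species_abundance=species_table, detection=det_matrix)
    if "enrich" not in stages:
        return bundle

    # --- stage 5: functional enrichment ------------------------------------
    annotations, modules, truth = simulate_annotations(sim, reps, rep_genes, truth)
    group_map = species_map  # site-preference groups coincide with species here
    comp = enr.completeness_matrix(annotations, modules, cfg.module_completeness)
    results = enr.enriched_modules(
        annotations, modules, group_map,
        completeness_threshold=cfg.module_completeness,
        q_threshold=cfg.q_threshold,
    )
    frame = enr.results_frame(results)
    mio.write_matrix(comp, out / "module_completeness.tsv")
    frame.to_csv(out / "module_enrichment.tsv", sep="\t", index=False)
    mio.write_modules(modules, out / "modules.json")
    annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    logger.info("enrich: %d modules tested, %d enriched calls",
                len(modules), int(frame["enriched"].sum()))
    bundle.update(annotations=annotations, modules=modules,
                  completeness=comp, enrichment=frame)

    manifest = RunManifest("0.1.0", cfg.config_hash(),
                           {"selected": len(selected), "representatives": len(reps),
                            "clusters": counts["total"], "samples": len(samples),
                            "modules": len(modules)})
    (out / "run_manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=1)
    )
    return bundle
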