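"""Synthetic genus catalog, metagenome, and annotation simulator.

The simulator builds the kind of data the pipeline consumes, with ground truth
recorded for every planted signal so each stage can be checked by parameter
recovery:

* a genome catalog with species-level clade structure (within-species ANI
  above, between-species ANI below, configurable targets) generated from an
  ancestral gene repertoire with core, species-specific accessory, and
  per-genome singleton gene families, mutated by i.i.d. substitutions whose
  per-branch rates are solved analytically from the ANI targets;
* site-structured metagenomes: error-free reads drawn uniformly from each
  genome at a per-site depth set by the species' site tropism, emitted as
  plain SAM against the source genome (idealised competitive mapping);
* annotation tables and metabolic-module definitions in which a configurable
  number of modules are complete only in designated species groups while the
  rest are complete uniformly at random.

Everything is deterministic under the seed.  Stop codons arising from
substitutions are masked to X at translation time, so the nucleotide process
stays exactly i.i.d. and realised identity tracks the analytic target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .catalog import GenomeRecord
from .pangenome import GeneCall
from .profiler import ORAL_SITES, SampleRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_catalog",
    "simulate_metagenomes",
    "simulate_annotations",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genus.

    Defaults emulate the desk-scale structure the pipeline is tested against:
    three species-level clades of four genomes each, within-species ANI 0.98
    and between-species 0.85 (clearly across the 95% species boundary), a
    50/30/20 core/accessory/singleton split, four oral sites with one tropic
    site per species, 50x per-site depth and 100-nt reads, and 50 modules of
    which 2 are planted as group-specific.
    """

    seed: int = 1
    n_species: int = 3
    genomes_per_species: int = 4
    genome_len: int = 12_000
    within_species_ani: float = 0.98
    between_species_ani: float = 0.85
    core_frac: float = 0.5
    accessory_frac: float = 0.3
    singleton_frac: float = 0.2
    sites: Tuple[str, ...] = ("SUPP", "TD", "KG", "BM")
    samples_per_site: int = 3
    tropism: Mapping[str, Tuple[str, ...]] | None = None  # species -> sites
    depth_per_site: float = 50.0
    read_len: int = 100
    genus_fraction: float = 0.065  # mapped / total reads, emulating genus abundance
    genome_weights: Mapping[str, float] | None = None  # genome -> depth multiplier
    gene_len: int = 300
    spacer_len: int = 60
    n_modules: int = 50
    n_planted_enriched: int = 2
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        fracs = (self.core_frac, self.accessory_frac, self.singleton_frac)
        if any(not (0 <= f <= 1) for f in fracs) or abs(sum(fracs) - 1) > 1e-9:
            raise ValueError("core/accessory/singleton fractions must sum to 1")
        if not self.within_species_ani > self.between_species_ani:
            raise ValueError("within-species ANI must exceed between-species ANI")
        unknown = set(self.sites) - set(ORAL_SITES)
        if unknown:
            raise ValueError(f"unknown oral sites {sorted(unknown)}")
        if self.n_planted_enriched > self.n_modules:
            raise ValueError("cannot plant more enriched modules than modules")

    def species_sites(self, species: str, index: int) -> Tuple[str, ...]:
        """Default tropism: sites dealt round-robin over species, so every
        site recruits at least one species and every species has >= 1 site."""
        if self.tropism and species in self.tropism:
            return tuple(self.tropism[species])
        return tuple(
            site for j, site in enumerate(self.sites) if j % self.n_species == index
        )


@dataclass
class GroundTruth:
    species_of: Dict[str, str]  # genome_id -> species
    family_of_gene: Dict[str, str]  # gene_id -> family id
    family_category: Dict[str, str]  # family id -> core/accessory/singleton
    site_abundance: Dict[str, Dict[str, float]]  # genome -> site -> expected depth
    planted_modules: List[str]
    planted_groups: Dict[str, str]  # module_id -> species group carrying it

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _branch_rate(target_identity: float) -> float:
    """Per-lineage substitution probability d such that two sequences mutated
    independently from an ancestor match at the target rate:
    (1-d)^2 + d^2/3 = target (substitutions uniform over the 3 other bases).
    """
    a, b, c = 4.0 / 3.0, -2.0, 1.0 - target_identity
    return (-b - math.sqrt(b * b - 4 * a * c)) / (2 * a)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitutions at the given per-site rate, uniform over the three
    alternative bases, with the count conditioned on its expectation
    (``round(rate * L)`` sites drawn without replacement) so realised identity
    tracks the analytic target tightly.  Stop codons arising in coding
    sequence are masked to X at translation time."""
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    n_hits = int(round(rate * arr.size))
    hits = rng.choice(arr.size, size=min(n_hits, arr.size), replace=False)
    for i in hits:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons))


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def simulate_catalog(
    cfg: SimulationConfig,
) -> Tuple[List[GenomeRecord], List[GeneCall], GroundTruth]:
    """Generate the genome catalog with planted clade and gene-family
    structure.  Genome ids are ``S{s}_G{g}``, species ``sp{s}``, families
    ``FAM_core_i`` / ``FAM_acc_sp{s}_i`` / ``FAM_sing_{genome}_i``.
    """
    rng = np.random.default_rng(cfg.seed)
    slot = cfg.gene_len + cfg.spacer_len
    n_genes = max(2, cfg.genome_len // slot)
    n_core = max(1, round(cfg.core_frac * n_genes))
    n_acc = round(cfg.accessory_frac * n_genes)
    n_sing = n_genes - n_core - n_acc
    if n_sing < 0:
        raise ValueError("infeasible core/accessory fractions for this genome length")

    d_within = _branch_rate(cfg.within_species_ani)
    pair_m = _branch_rate(cfg.between_species_ani)  # total per-lineage divergence
    # composing two uniform-substitution steps p1 then p2 gives an effective
    # rate p1 + p2 - (4/3) p1 p2; invert for the species-branch rate
    d_species = (pair_m - d_within) / (1.0 - 4.0 / 3.0 * d_within)
    if d_species < 0:
        raise ValueError("ANI targets imply negative species-branch length")

    n_codons = cfg.gene_len // 3
    root_core = [_random_cds(n_codons, rng) for _ in range(n_core)]
    root_spacers = [_random_nt(cfg.spacer_len, rng) for _ in range(n_core + n_acc + n_sing)]

    genomes: List[GenomeRecord] = []
    gene_calls: List[GeneCall] = []
    truth = GroundTruth({}, {}, {}, {}, [], {})

    for fam_i in range(n_core):
        truth.family_category[f"FAM_core_{fam_i}"] = "core"

    for s in range(cfg.n_species):
        species = f"sp{s}"
        species_core = [_mutate(g, d_species, rng) for g in root_core]
        species_spacers = [_mutate(sp, d_species, rng) for sp in root_spacers]
        species_acc = [_random_cds(n_codons, rng) for _ in range(n_acc)]
        for fam_i in range(n_acc):
            cat = "accessory" if cfg.n_species > 1 else "core"
            truth.family_category[f"FAM_acc_{species}_{fam_i}"] = cat
        for g in range(cfg.genomes_per_species):
            gid = f"S{s}_G{g}"
            truth.species_of[gid] = species
            parts: List[str] = []
            calls: List[Tuple[str, str, int, int]] = []  # gene_id, family, start, stop
            pos = 0

            def _add(gene_seq: str, spacer: str, gene_id: str, family: str) -> None:
                nonlocal pos
                parts.append(spacer)
                pos += len(spacer)
                parts.append(gene_seq)
                calls.append((gene_id, family, pos, pos + len(gene_seq)))
                pos += len(gene_seq)

            for i, anc in enumerate(species_core):
                _add(
                    _mutate(anc, d_within, rng),
                    _mutate(species_spacers[i], d_within, rng),
                    f"{gid}_core_{i}",
                    f"FAM_core_{i}",
                )
            for i, anc in enumerate(species_acc):
                _add(
                    _mutate(anc, d_within, rng),
                    _mutate(species_spacers[n_core + i], d_within, rng),
                    f"{gid}_acc_{i}",
                    f"FAM_acc_{species}_{i}",
                )
            for i in range(n_sing):
                fam = f"FAM_sing_{gid}_{i}"
                truth.family_category[fam] = (
                    "singleton" if cfg.genomes_per_species * cfg.n_species > 1 else "core"
                )
                _add(
                    _random_cds(n_codons, rng),
                    _mutate(species_spacers[n_core + n_acc + i], d_within, rng),
                    f"{gid}_sing_{i}",
                    fam,
                )
            contig_id = f"{gid}_c0"
            genome = GenomeRecord(
                genome_id=gid,
                contigs=((contig_id, "".join(parts)),),
                species_label=species,
                host="human",
                oral=True,
                completeness=round(float(rng.uniform(92, 99.5)), 2),
                contamination=round(float(rng.uniform(0, 2)), 2),
            )
            genomes.append(genome)
            seq = genome.contigs[0][1]
            for gene_id, family, start, stop in calls:
                protein = str(Seq(seq[start:stop]).translate()).replace("*", "X")
                gene_calls.append(
                    GeneCall(gene_id, gid, contig_id, start, stop, "+", protein)
                )
                truth.family_of_gene[gene_id] = family
    return genomes, gene_calls, truth


# --- metagenomes ----------------------------------------------------------


def _genome_site_depths(
    cfg: SimulationConfig, genomes: Sequence[GenomeRecord], truth: GroundTruth
) -> None:
    species_list = sorted({truth.species_of[g.genome_id] for g in genomes})
    for g in genomes:
        sp = truth.species_of[g.genome_id]
        tropic = cfg.species_sites(sp, species_list.index(sp))
        weight = 1.0
        if cfg.genome_weights and g.genome_id in cfg.genome_weights:
            weight = float(cfg.genome_weights[g.genome_id])
        truth.site_abundance[g.genome_id] = {
            site: (cfg.depth_per_site * weight if site in tropic else 0.0)
            for site in cfg.sites
        }


def simulate_metagenomes(
    cfg: SimulationConfig,
    genomes: Sequence[GenomeRecord],
    truth: GroundTruth,
    outdir: str | Path,
) -> List[SampleRecord]:
    """Write one plain SAM per sample plus ``samples.tsv``; reads are drawn
    uniformly from each genome at that genome's expected site depth.  Returns
    the sample records.  A site whose every genome weight is zero is an error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 7919)
    if not truth.site_abundance:
        _genome_site_depths(cfg, genomes, truth)
    header_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for g in genomes:
        for cid, seq in g.contigs:
            header_lines.append(f"@SQ\tSN:{cid}\tLN:{len(seq)}")
    samples: List[SampleRecord] = []
    manifest_rows = []
    for site in cfg.sites:
        site_total = sum(truth.site_abundance[g.genome_id][site] for g in genomes)
        if cfg.depth_per_site > 0 and site_total == 0:
            raise ValueError(f"site {site}: all genome weights are zero")
        for j in range(cfg.samples_per_site):
            sample_id = f"{site}_{j}"
            lines = list(header_lines)
            n_mapped = 0
            ridx = 0
            for g in genomes:
                depth = truth.site_abundance[g.genome_id][site]
                if depth <= 0:
                    continue
                for cid, seq in g.contigs:
                    span = len(seq) - cfg.read_len
                    if span <= 0:
                        continue
                    # read count fixed at its expectation; start positions
                    # random, so depth is still locally stochastic
                    n_reads = int(round(depth * len(seq) / cfg.read_len))
                    starts = rng.integers(0, span + 1, n_reads)
                    for st in np.sort(starts):
                        read = seq[st : st + cfg.read_len]
                        if cfg.read_error_rate > 0:
                            read = _mutate(read, cfg.read_error_rate, rng)
                        lines.append(
                            "\t".join(
                                [
                                    f"{sample_id}.r{ridx}",
                                    "0",
                                    cid,
                                    str(st + 1),
                                    "60",
                                    f"{cfg.read_len}M",
                                    "*",
                                    "0",
                                    "0",
                                    read,
                                    "*",
                                ]
                            )
                        )
                        ridx += 1
                        n_mapped += 1
            path = outdir / f"{sample_id}.sam"
            path.write_text("\n".join(lines) + "\n")
            total = max(n_mapped, int(round(n_mapped / cfg.genus_fraction))) if n_mapped else 0
            samples.append(SampleRecord(sample_id, site, total, n_mapped))
            manifest_rows.append(
                f"{sample_id}\t{site}\t{total}\t{n_mapped}\t{path.name}"
            )
    (outdir / "samples.tsv").write_text(
        "sample_id\toral_site\ttotal_reads\tmapped_reads\tpath\n"
        + "\n".join(manifest_rows)
        + "\n"
    )
    return samples


# --- annotations ----------------------------------------------------------


def simulate_annotations(
    cfg: SimulationConfig,
    genomes: Sequence[GenomeRecord],
    gene_calls: Sequence[GeneCall],
    truth: GroundTruth,
    *,
    steps_per_module: int = 4,
):
    """Build an annotation table and module definitions.

    The first ``n_planted_enriched`` modules are complete (all steps) only in
    genomes of their designated species group and far below the completeness
    threshold elsewhere; the remaining modules are complete in each genome
    independently with probability 1/2.  Returns ``(annotations DataFrame,
    [ModuleDefinition], truth)`` with the planted set recorded in the truth.
    """
    import pandas as pd

    from .enrichment import ModuleDefinition

    rng = np.random.default_rng(cfg.seed + 104729)
    species_list = sorted({truth.species_of[g.genome_id] for g in genomes})
    genes_by_genome: Dict[str, List[str]] = {g.genome_id: [] for g in genomes}
    for call in gene_calls:
        genes_by_genome[call.genome_id].append(call.gene_id)

    modules: List[ModuleDefinition] = []
    rows = []
    truth.planted_modules = []
    truth.planted_groups = {}
    for m in range(cfg.n_modules):
        module_id = f"M{m + 1:05d}"
        kos = [
            frozenset({f"K{m:03d}{s:02d}a", f"K{m:03d}{s:02d}b"})
            for s in range(steps_per_module)
        ]
        modules.append(ModuleDefinition(module_id, f"synthetic module {m}", tuple(kos)))
        planted = m < cfg.n_planted_enriched
        group = species_list[m % len(species_list)] if planted else None
        if planted:
            truth.planted_modules.append(module_id)
            truth.planted_groups[module_id] = group
        for g in genomes:
            if planted:
                complete = truth.species_of[g.genome_id] == group
            else:
                complete = bool(rng.random() < 0.5)
            if complete:
                step_ids = range(steps_per_module)
            else:
                # strictly below the 0.75 completeness threshold
                n_have = int(rng.integers(0, max(1, int(0.75 * steps_per_module))))
                step_ids = rng.choice(steps_per_module, size=n_have, replace=False)
            gene_pool = genes_by_genome[g.genome_id]
            for s in step_ids:
                ko = sorted(kos[s])[int(rng.integers(2))]
                gene = gene_pool[int(rng.integers(len(gene_pool)))]
                rows.append(
                    {
                        "genome_id": g.genome_id,
                        "gene_id": gene,
                        "source": "KEGG",
                        "accession": ko,
                        "description": f"synthetic KO for {module_id}",
                    }
                )
    annotations = pd.DataFrame(rows)
    return annotations, modules, truth
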