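"""Metagenomic read-recruitment profiling.

Alignments of one metagenome against the reference genome set (each read
already assigned to a single genome by the competitive mapper) are turned into
per-nucleotide depth vectors.  From those, the stage applies the detection
rules — a genome is detected when at least 50% of its nucleotides have >= 1x
coverage, a gene when at least 90% do — and computes the robust abundance
statistic: the mean depth over the interquartile positions (depths ranked,
middle half averaged), normalised per sample across the reference set.
Species abundance is the sum over member genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .catalog import GenomeRecord
from .pangenome import GeneCall

__all__ = [
    "ORAL_SITES",
    "SampleRecord",
    "CoverageProfile",
    "DetectionConfig",
    "coverage_from_alignments",
    "coverage_from_depth_table",
    "breadth",
    "detect_genome",
    "detect_gene",
    "q2q3_mean",
    "relative_abundance",
    "species_rollup",
]

#: The nine oral sites: supra-/subgingival plaque, keratinized gingiva, tongue
#: dorsum, palatine tonsil, throat, saliva, hard palate, buccal mucosa.
ORAL_SITES = ("SUPP", "SUBP", "KG", "TD", "PT", "TH", "SV", "HP", "BM")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    oral_site: str
    total_reads: int
    mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.oral_site not in ORAL_SITES:
            raise ValueError(
                f"sample {self.sample_id}: unknown oral site {self.oral_site!r}; "
                f"expected one of {ORAL_SITES}"
            )
        if self.mapped_reads > self.total_reads:
            raise ValueError(f"sample {self.sample_id}: mapped_reads > total_reads")


@dataclass
class CoverageProfile:
    """Per-nucleotide depth over one genome's concatenated contigs."""

    genome_id: str
    sample_id: str
    depth: np.ndarray
    contig_offsets: Mapping[str, Tuple[int, int]]  # contig -> [start, end)

    def contig_depth(self, contig_id: str) -> np.ndarray:
        start, end = self.contig_offsets[contig_id]
        return self.depth[start:end]


@dataclass(frozen=True)
class DetectionConfig:
    genome_breadth_min: float = 0.5
    gene_breadth_min: float = 0.9
    min_depth: int = 1

    def __post_init__(self) -> None:
        for v in (self.genome_breadth_min, self.gene_breadth_min):
            if not (0.0 < v <= 1.0):
                raise ValueError("breadth thresholds must lie in (0, 1]")


def _empty_profiles(
    genomes: Sequence[GenomeRecord], sample_id: str
) -> Dict[str, CoverageProfile]:
    profiles = {}
    for g in genomes:
        offsets = {}
        pos = 0
        for cid, seq in g.contigs:
            offsets[cid] = (pos, pos + len(seq))
            pos += len(seq)
        profiles[g.genome_id] = CoverageProfile(
            g.genome_id, sample_id, np.zeros(pos, dtype=np.int32), offsets
        )
    return profiles


def coverage_from_alignments(
    sam_path: str,
    genomes: Sequence[GenomeRecord],
    sample_id: str = "",
) -> Dict[str, CoverageProfile]:
    """Accumulate per-base depth from a SAM file.

    Reference-consuming aligned blocks (CIGAR M/=/X) add depth; deletions (D)
    consume reference without depth; insertions and clips do not touch the
    reference.  SAM's 1-based coordinates are handled by pysam; internally
    everything is 0-based half-open.  Unknown reference contigs are an error.
    """
    profiles = _empty_profiles(genomes, sample_id)
    contig_home = {
        cid: g.genome_id for g in genomes for cid, _ in g.contigs
    }
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            contig = aln.reference_name
            if contig not in contig_home:
                raise ValueError(f"alignment references unknown contig {contig!r}")
            prof = profiles[contig_home[contig]]
            start, _ = prof.contig_offsets[contig]
            for bstart, bend in aln.get_blocks():
                prof.depth[start + bstart : start + bend] += 1
    return profiles


def coverage_from_depth_table(
    table: pd.DataFrame,
    genomes: Sequence[GenomeRecord],
    sample_id: str = "",
) -> Dict[str, CoverageProfile]:
    """Build profiles from a (contig, pos, depth) table — the plain-text depth
    dialect.  Positions are 0-based; omitted positions have depth 0.
    """
    profiles = _empty_profiles(genomes, sample_id)
    contig_home = {cid: g.genome_id for g in genomes for cid, _ in g.contigs}
    for contig, pos, depth in table[["contig", "pos", "depth"]].itertuples(index=False):
        if contig not in contig_home:
            raise ValueError(f"depth table references unknown contig {contig!r}")
        prof = profiles[contig_home[contig]]
        start, end = prof.contig_offsets[contig]
        if not (0 <= pos < end - start):
            raise ValueError(f"position {pos} outside contig {contig!r}")
        prof.depth[start + pos] = depth
    return profiles


def breadth(profile: CoverageProfile, min_depth: int = 1) -> float:
    """Fraction of positions covered at >= ``min_depth``."""
    if profile.depth.size == 0:
        raise ValueError(f"empty profile for genome {profile.genome_id}")
    return float(np.mean(profile.depth >= min_depth))


def detect_genome(profile: CoverageProfile, cfg: DetectionConfig | None = None) -> bool:
    """Genome detected iff breadth >= 50% (inclusive)."""
    cfg = cfg or DetectionConfig()
    return breadth(profile, cfg.min_depth) >= cfg.genome_breadth_min


def detect_gene(
    profile: CoverageProfile, gene: GeneCall, cfg: DetectionConfig | None = None
) -> bool:
    """Gene detected iff >= 90% of its nucleotides have >= 1x coverage."""
    cfg = cfg or DetectionConfig()
    if gene.contig_id not in profile.contig_offsets:
        raise ValueError(f"gene {gene.gene_id}: contig {gene.contig_id!r} not in profile")
    cstart, cend = profile.contig_offsets[gene.contig_id]
    if gene.stop > cend - cstart or gene.start < 0:
        raise ValueError(f"gene {gene.gene_id}: coordinates outside contig bounds")
    window = profile.depth[cstart + gene.start : cstart + gene.stop]
    return float(np.mean(window >= cfg.min_depth)) >= cfg.gene_breadth_min


def q2q3_mean(profile: CoverageProfile | np.ndarray) -> float:
    """Mean depth over interquartile positions: sort depths ascending and
    average indices ``floor(L/4) <= i < ceil(3L/4)`` — exactly the middle half
    when L is divisible by 4, at least half otherwise.
    """
    depth = profile.depth if isinstance(profile, CoverageProfile) else np.asarray(profile)
    length = depth.size
    if length < 4:
        raise ValueError("q2q3_mean needs a profile of length >= 4")
    lo = length // 4
    hi = -(-3 * length // 4)  # ceil(3L/4)
    middle = np.sort(depth)[lo:hi]
    return float(middle.mean())


def relative_abundance(
    profiles: Mapping[str, CoverageProfile],
    cfg: DetectionConfig | None = None,
    *,
    denominator: str = "all",
) -> pd.DataFrame:
    """Per-genome relative abundance within one sample.

    Each genome's Q2Q3 mean coverage is divided by the summed Q2Q3 mean over
    the denominator set — every reference genome by default, or only the
    detected ones with ``denominator='detected'``.  Undetected genomes are
    reported (detected = False) and, in the default mode, still contribute to
    the denominator.  A sample where the denominator is zero gets all-zero
    abundances and ``flagged = True``.
    """
    if denominator not in ("all", "detected"):
        raise ValueError("denominator must be 'all' or 'detected'")
    cfg = cfg or DetectionConfig()
    rows = []
    for gid, prof in profiles.items():
        rows.append(
            {
                "sample_id": prof.sample_id,
                "genome_id": gid,
                "detected": detect_genome(prof, cfg),
                "q2q3_mean": q2q3_mean(prof),
            }
        )
    table = pd.DataFrame(rows)
    mask = table["detected"] if denominator == "detected" else np.ones(len(table), bool)
    denom = table.loc[mask, "q2q3_mean"].sum()
    if denom > 0:
        table["rel_abundance"] = np.where(mask, table["q2q3_mean"] / denom, 0.0)
        table["flagged"] = False
    else:
        table["rel_abundance"] = 0.0
        table["flagged"] = True
    return table


def species_rollup(
    table: pd.DataFrame, species_map: Mapping[str, str]
) -> pd.DataFrame:
    """Aggregate a per-(sample, genome) abundance table to species: species
    abundance is the sum of member-genome abundances; a species is detected
    when any member is.  Only samples where at least one genome was detected
    are emitted.
    """
    unmapped = set(table["genome_id"]) - set(species_map)
    if unmapped:
        raise ValueError(f"genomes missing from species map: {sorted(unmapped)}")
    tab = table.copy()
    tab["species"] = tab["genome_id"].map(species_map)
    keep = tab.groupby("sample_id")["detected"].transform("any")
    tab = tab[keep]
    out = (
        tab.groupby(["sample_id", "species"], sort=True)
        .agg(detected=("detected", "any"), rel_abundance=("rel_abundance", "sum"))
        .reset_index()
    )
    return out
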