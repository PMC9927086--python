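"""Reference genome catalog: quality selection, contig cleaning, fragment ANI,
and ANI-threshold dereplication.

The catalog stage turns a raw set of isolate genome assemblies plus a metadata
manifest into the non-redundant reference set the rest of the pipeline uses.
Genomes are kept when they come from a human host, are not flagged as duplicate
strains, and pass CheckM-style quality bounds (completeness >= 90%,
contamination < 5%).  Average nucleotide identity (ANI) between cleaned genomes
is estimated by the fragment convention: the query genome is cut into
non-overlapping 1,020-nt windows, each window is located in the subject genome
and scored with an affine-gap local alignment, and the mean identity over
accepted fragments (coverage >= 0.7, identity >= 0.3) is reported.  Directed
estimates for the two orientations of a pair are averaged.  Dereplication then
removes genomes that share more than 98% ANI with a better-quality
representative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import edlib
import numpy as np
from Bio import Align

__all__ = [
    "GenomeRecord",
    "SelectionConfig",
    "AniResult",
    "clean_contigs",
    "select_genomes",
    "compute_ani",
    "ani_matrix",
    "dereplicate",
    "species_groups",
]

_CANONICAL = re.compile(r"[^ACGT]")
_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomeRecord:
    """One isolate genome assembly with its manifest metadata."""

    genome_id: str
    contigs: Tuple[Tuple[str, str], ...]
    species_label: str = "unassigned"
    host: str = "human"
    oral: bool = True
    completeness: float = 100.0
    contamination: float = 0.0
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError(f"{self.genome_id}: completeness outside [0, 100]")
        if not (0.0 <= self.contamination <= 100.0):
            raise ValueError(f"{self.genome_id}: contamination outside [0, 100]")

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def sequence(self) -> str:
        """Concatenated contig sequence (contig order preserved)."""
        return "".join(s for _, s in self.contigs)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for genome selection, cleaning and dereplication."""

    min_contig_len: int = 300
    min_completeness: float = 90.0
    max_contamination: float = 5.0
    derep_ani: float = 0.98
    ani_fragment_len: int = 1020
    ani_min_fragment_identity: float = 0.3
    ani_min_fragment_coverage: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 < self.derep_ani < 1.0):
            raise ValueError("derep_ani must lie in (0, 1)")
        if self.ani_fragment_len <= 0:
            raise ValueError("ani_fragment_len must be positive")


@dataclass(frozen=True)
class AniResult:
    """Symmetric ANI estimate for one genome pair (mean of the two directions)."""

    genome_a: str
    genome_b: str
    ani: float
    aligned_fraction: float


class EmptyGenomeError(ValueError):
    pass


def clean_contigs(genome: GenomeRecord, cfg: SelectionConfig | None = None) -> GenomeRecord:
    """Drop contigs shorter than ``min_contig_len`` and mask non-canonical
    letters (anything outside A/C/G/T) with N.

    Raises :class:`EmptyGenomeError` if no contig survives.
    """
    cfg = cfg or SelectionConfig()
    if not genome.contigs:
        raise EmptyGenomeError(f"genome {genome.genome_id} has no contigs")
    kept = []
    for cid, seq in genome.contigs:
        seq = seq.upper()
        if len(seq) < cfg.min_contig_len:
            continue
        kept.append((cid, _CANONICAL.sub("N", seq)))
    if not kept:
        raise EmptyGenomeError(
            f"genome {genome.genome_id}: all contigs shorter than "
            f"{cfg.min_contig_len} nt"
        )
    return replace(genome, contigs=tuple(kept))


def select_genomes(
    catalog: Sequence[GenomeRecord], cfg: SelectionConfig | None = None
) -> List[GenomeRecord]:
    """Apply the manifest filters: human host, not a duplicate strain,
    completeness >= ``min_completeness`` and contamination strictly below
    ``max_contamination``.  Input order is preserved; the filter is idempotent.
    """
    cfg = cfg or SelectionConfig()
    for g in catalog:
        for fld in ("host", "completeness", "contamination"):
            if getattr(g, fld, None) is None:
                raise ValueError(f"genome {g.genome_id}: manifest field {fld!r} missing")
    return [
        g
        for g in catalog
        if g.host == "human"
        and g.duplicate_of is None
        and g.completeness >= cfg.min_completeness
        and g.contamination < cfg.max_contamination
    ]


# --- fragment ANI ---------------------------------------------------------

# affine gaps in the blast convention: existence 5, extension 2, so a gap of
# length k costs 5 + 2k and the first gapped position scores -(5 + 2)
_LOCAL = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-7,
    extend_gap_score=-2,
)


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _fragment_hit(frag: str, target: str, pad: int = 40) -> Tuple[float, float]:
    """Best local-alignment (identity, query coverage) of one fragment against
    a genome, trying both strands.

    The candidate window on each strand is found with a fast infix edit-distance
    search; the window (padded) is then re-aligned with the affine-gap local
    scorer (+1 match / -1 mismatch / gap existence 5 / extension 2) to measure
    identity over aligned columns and the fraction of the fragment covered.
    """
    best = None
    for query in (frag, _revcomp(frag)):
        hit = edlib.align(query, target, mode="HW", task="locations")
        if hit["editDistance"] < 0 or not hit["locations"]:
            continue
        if best is None or hit["editDistance"] < best[0]:
            loc = hit["locations"][0]
            best = (hit["editDistance"], query, loc)
    if best is None:
        return 0.0, 0.0
    _, query, (start, end) = best
    window = target[max(0, start - pad) : min(len(target), end + 1 + pad)]
    alns = _LOCAL.align(query, window)
    if len(alns) == 0:
        return 0.0, 0.0
    aln = alns[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, 0.0
    identity = counts.identities / columns
    qspan = int(aln.coordinates[0, -1] - aln.coordinates[0, 0])
    return identity, qspan / len(frag)


def _directed_ani(a_seq: str, b_seq: str, cfg: SelectionConfig) -> Tuple[float, float]:
    flen = cfg.ani_fragment_len
    frags = [a_seq[i : i + flen] for i in range(0, len(a_seq) - flen + 1, flen)]
    tail = len(a_seq) % flen
    if not frags:  # genome shorter than one fragment: use it whole
        frags = [a_seq]
    elif tail >= flen // 2:
        frags.append(a_seq[-tail:])
    identities = []
    for frag in frags:
        ident, cov = _fragment_hit(frag, b_seq)
        if cov >= cfg.ani_min_fragment_coverage and ident >= cfg.ani_min_fragment_identity:
            identities.append(ident)
    if not identities:
        return 0.0, 0.0
    return float(np.mean(identities)), len(identities) / len(frags)


def compute_ani(
    a: GenomeRecord, b: GenomeRecord, cfg: SelectionConfig | None = None
) -> AniResult:
    """Fragment-based ANI between two cleaned genomes.

    Both directed estimates (a vs b and b vs a) are computed and averaged; a
    pair with no accepted fragment yields ``AniResult(ani=0, aligned_fraction=0)``
    rather than an error.
    """
    cfg = cfg or SelectionConfig()
    ani_ab, af_ab = _directed_ani(a.sequence(), b.sequence(), cfg)
    ani_ba, af_ba = _directed_ani(b.sequence(), a.sequence(), cfg)
    return AniResult(a.genome_id, b.genome_id, (ani_ab + ani_ba) / 2, (af_ab + af_ba) / 2)


def ani_matrix(
    catalog: Sequence[GenomeRecord], cfg: SelectionConfig | None = None
) -> Dict[Tuple[str, str], AniResult]:
    """All-pairs ANI, keyed by unordered pair (both orders present)."""
    cfg = cfg or SelectionConfig()
    out: Dict[Tuple[str, str], AniResult] = {}
    for i, a in enumerate(catalog):
        for b in catalog[i + 1 :]:
            res = compute_ani(a, b, cfg)
            out[(a.genome_id, b.genome_id)] = res
            out[(b.genome_id, a.genome_id)] = res
    return out


def _pair_ani(ani: Mapping[Tuple[str, str], AniResult | float], a: str, b: str) -> float:
    key = (a, b) if (a, b) in ani else (b, a)
    if key not in ani:
        raise ValueError(f"ANI matrix is missing pair ({a}, {b})")
    val = ani[key]
    return val.ani if isinstance(val, AniResult) else float(val)


def dereplicate(
    catalog: Sequence[GenomeRecord],
    ani: Mapping[Tuple[str, str], AniResult | float],
    cfg: SelectionConfig | None = None,
) -> List[GenomeRecord]:
    """Greedy dereplication so that no two retained genomes share ANI above
    ``derep_ani``.

    Candidates are ranked by (completeness desc, total length desc, genome_id
    asc); the best unclaimed genome becomes a representative and claims every
    genome it exceeds the threshold with.  Deterministic, idempotent, and
    biased toward the most complete assemblies.
    """
    cfg = cfg or SelectionConfig()
    order = sorted(catalog, key=lambda g: (-g.completeness, -g.length, g.genome_id))
    claimed: set[str] = set()
    reps: List[GenomeRecord] = []
    for g in order:
        if g.genome_id in claimed:
            continue
        reps.append(g)
        claimed.add(g.genome_id)
        for h in order:
            if h.genome_id in claimed:
                continue
            if _pair_ani(ani, g.genome_id, h.genome_id) > cfg.derep_ani:
                claimed.add(h.genome_id)
    id_order = {g.genome_id: i for i, g in enumerate(catalog)}
    reps.sort(key=lambda g: id_order[g.genome_id])
    return reps


def species_groups(
    genome_ids: Sequence[str],
    ani: Mapping[Tuple[str, str], AniResult | float],
    threshold: float = 0.95,
) -> List[List[str]]:
    """Single-linkage species-level grouping: connected components of the graph
    whose edges are pairs with ANI > ``threshold`` (95% is the conventional
    species boundary).
    """
    parent = {g: g for g in genome_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(genome_ids):
        for b in genome_ids[i + 1 :]:
            if _pair_ani(ani, a, b) > threshold:
                parent[find(a)] = find(b)
    groups: Dict[str, List[str]] = {}
    for g in genome_ids:
        groups.setdefault(find(g), []).append(g)
    return sorted((sorted(v) for v in groups.values()), key=lambda v: v[0])
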