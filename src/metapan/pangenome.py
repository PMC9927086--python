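"""Pangenome construction: all-vs-all protein similarity, minbit pruning,
Markov clustering into gene clusters, core/accessory/singleton partition, the
gene-cluster frequency matrix, and the Ward genome dendrogram.

Similarity is Smith-Waterman with BLOSUM62 and affine gaps (existence 11 /
extension 1), converted to a bitscore with the gapped Karlin-Altschul constants
(lambda = 0.267, K = 0.041).  A pair's minbit is its cross score divided by the
smaller of the two self scores; edges below 0.5 are discarded before MCL.  Only
score ratios enter minbit, so a raw-score mode is available and gives identical
filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "GeneCall",
    "SimilarityEdge",
    "GeneCluster",
    "pairwise_scores",
    "minbit_filter",
    "mcl_cluster",
    "build_pangenome_matrix",
    "classify_clusters",
    "genome_dendrogram",
    "build_pangenome",
]

_KA_LAMBDA = 0.267  # gapped BLOSUM62
_KA_K = 0.041


@dataclass(frozen=True)
class GeneCall:
    """One ORF: coordinates on its contig plus the translated protein."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 0-based inclusive
    stop: int  # 0-based exclusive
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise ValueError(f"{self.gene_id}: start must be < stop")
        if not self.protein:
            raise ValueError(f"{self.gene_id}: empty protein")


@dataclass(frozen=True)
class SimilarityEdge:
    gene_a: str
    gene_b: str
    score: float  # bitscore-like units
    minbit: float


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    members: Tuple[str, ...]  # gene_ids
    frequency: Mapping[str, int]  # genome_id -> copy count
    category: str  # core | accessory | singleton


def _aligner() -> Align.PairwiseAligner:
    # blastp-default gap costs: existence 11, extension 1 — a gap of length k
    # costs 11 + k, so the first gapped position scores -(11 + 1)
    aligner = Align.PairwiseAligner(
        mode="local", open_gap_score=-12, extend_gap_score=-1
    )
    mat = substitution_matrices.load("BLOSUM62").copy()
    # X is an ambiguous residue: contribute nothing either way
    if "X" in mat.alphabet:
        xi = mat.alphabet.index("X")
        mat[xi, :] = 0.0
        mat[:, xi] = 0.0
    aligner.substitution_matrix = mat
    return aligner


def _bitscore(raw: float) -> float:
    return (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2)


def pairwise_scores(
    genes: Sequence[GeneCall], *, raw_scores: bool = False
) -> List[SimilarityEdge]:
    """All-vs-all local alignment scores, including self edges (the self score
    is the minbit denominator).  Edges whose raw alignment score is <= 0 are
    dropped.  ``raw_scores=True`` skips the Karlin-Altschul bit conversion;
    minbit values are score ratios either way.
    """
    aligner = _aligner()
    for g in genes:
        if not g.protein:
            raise ValueError(f"gene {g.gene_id}: empty protein")
    seqs = [g.protein.upper() for g in genes]
    convert = (lambda s: s) if raw_scores else _bitscore
    self_raw = [aligner.score(s, s) for s in seqs]
    edges: List[SimilarityEdge] = []
    for i, gi in enumerate(genes):
        si = convert(self_raw[i])
        edges.append(SimilarityEdge(gi.gene_id, gi.gene_id, si, 1.0))
        for j in range(i + 1, len(genes)):
            raw = aligner.score(seqs[i], seqs[j])
            if raw <= 0:
                continue
            score = convert(raw)
            denom = min(convert(self_raw[i]), convert(self_raw[j]))
            minbit = score / denom if denom > 0 else 0.0
            edges.append(SimilarityEdge(gi.gene_id, genes[j].gene_id, score, minbit))
    return edges


def minbit_filter(
    edges: Iterable[SimilarityEdge], threshold: float = 0.5
) -> List[SimilarityEdge]:
    """Keep cross edges with minbit >= threshold (boundary inclusive); self
    edges are removed from the output graph.  Each surviving unordered pair
    keeps its maximum score.
    """
    self_scores: Dict[str, float] = {}
    cross: Dict[Tuple[str, str], SimilarityEdge] = {}
    for e in edges:
        if e.gene_a == e.gene_b:
            self_scores[e.gene_a] = e.score
            continue
        key = (min(e.gene_a, e.gene_b), max(e.gene_a, e.gene_b))
        if key not in cross or e.score > cross[key].score:
            cross[key] = e
    out = []
    for (a, b), e in sorted(cross.items()):
        for gid in (a, b):
            if gid not in self_scores:
                raise ValueError(f"missing self score for gene {gid}")
        if e.minbit >= threshold:
            out.append(e)
    return out


def mcl_cluster(
    nodes: Sequence[str],
    edges: Iterable[SimilarityEdge],
    inflation: float = 10.0,
    *,
    prune: float = 1e-8,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> List[List[str]]:
    """Markov clustering of the weighted gene graph.

    The transition matrix is column-stochastic over minbit weights with a
    self-loop per node equal to its maximum incident weight (1 for isolated
    nodes).  Iterations alternate expansion (matrix square) and inflation
    (entrywise power followed by column renormalisation), pruning entries below
    ``prune``, until the largest entry change is below ``tol`` or ``max_iter``
    rounds.  Clusters are read off attractor rows; attractors sharing a node
    are merged, and output order is by smallest member gene_id.
    """
    nodes = list(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return []
    w = np.zeros((n, n))
    for e in edges:
        if e.gene_a == e.gene_b:
            continue
        if not (math.isfinite(e.minbit) and e.minbit >= 0):
            raise ValueError(f"non-finite or negative weight on ({e.gene_a}, {e.gene_b})")
        i, j = idx[e.gene_a], idx[e.gene_b]
        w[i, j] = w[j, i] = max(w[i, j], e.minbit)
    loops = w.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(w, loops)
    m = w / w.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = m @ m  # expansion
        m = np.power(m, inflation)  # inflation
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        m[m < prune] = 0.0  # prune the normalised matrix
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if prev.shape == m.shape and np.max(np.abs(m - prev)) < tol:
            break
    # attractors: rows with mass on the diagonal
    clusters: List[set] = []
    for i in range(n):
        if m[i, i] > prune:
            members = set(np.nonzero(m[i, :] > prune)[0])
            members.add(i)
            clusters.append(members)
    # every node must land somewhere; unattached nodes follow their column mass
    assigned = set().union(*clusters) if clusters else set()
    for j in range(n):
        if j not in assigned:
            i = int(np.argmax(m[:, j]))
            target = next((c for c in clusters if i in c), None)
            if target is None:
                clusters.append({j})
            else:
                target.add(j)
    # merge overlapping attractor sets
    merged: List[set] = []
    for c in clusters:
        hits = [mset for mset in merged if mset & c]
        for h in hits:
            merged.remove(h)
            c = c | h
        merged.append(c)
    out = [sorted(nodes[i] for i in c) for c in merged]
    return sorted(out, key=lambda c: c[0])


def build_pangenome_matrix(
    clusters: Sequence[Sequence[str]], genes: Sequence[GeneCall]
) -> pd.DataFrame:
    """Genome x cluster copy-count matrix.  Cluster ids are GC_00001... in the
    given cluster order; rows are genomes in first-seen order.
    """
    genome_of = {g.gene_id: g.genome_id for g in genes}
    genomes = list(dict.fromkeys(g.genome_id for g in genes))
    ids = [f"GC_{i + 1:05d}" for i in range(len(clusters))]
    mat = pd.DataFrame(0, index=genomes, columns=ids, dtype=int)
    for cid, members in zip(ids, clusters):
        for gid in members:
            mat.loc[genome_of[gid], cid] += 1
    return mat


def classify_clusters(matrix: pd.DataFrame) -> Dict[str, int]:
    """Partition clusters into core (every genome), singleton (exactly one
    genome) and accessory (the rest); returns the counts plus the total.
    """
    if matrix.empty:
        raise ValueError("empty pangenome matrix")
    occupancy = (matrix > 0).sum(axis=0)
    n_genomes = matrix.shape[0]
    core = int((occupancy == n_genomes).sum())
    singleton = int((occupancy == 1).sum()) if n_genomes > 1 else 0
    if n_genomes == 1:
        # with one genome every cluster is core by definition
        core, singleton = int((occupancy == 1).sum()), 0
    total = matrix.shape[1]
    return {
        "core": core,
        "singleton": singleton,
        "accessory": total - core - singleton,
        "total": total,
    }


def cluster_categories(matrix: pd.DataFrame) -> pd.Series:
    """Per-cluster category label (core/accessory/singleton)."""
    occupancy = (matrix > 0).sum(axis=0)
    n = matrix.shape[0]
    labels = pd.Series("accessory", index=matrix.columns)
    labels[occupancy == n] = "core"
    if n > 1:
        labels[occupancy == 1] = "singleton"
    return labels


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    nodes = {i: (labels[i], 0.0) for i in range(n)}  # (newick, height)
    for k, (a, b, height, _) in enumerate(link):
        na, ha = nodes.pop(int(a))
        nb, hb = nodes.pop(int(b))
        node = f"({na}:{height / 2 - ha / 2:.6g},{nb}:{height / 2 - hb / 2:.6g})"
        nodes[n + k] = (node, height)
    (tree, _) = next(iter(nodes.values()))
    return tree + ";"


def genome_dendrogram(matrix: pd.DataFrame) -> Tuple[np.ndarray, str]:
    """Hierarchically cluster genomes on gene-cluster frequencies with
    Euclidean distance and Ward linkage.  Returns the scipy linkage matrix and
    an ultrametric Newick string (merge heights halved onto each child branch).
    """
    if matrix.shape[0] < 2:
        raise ValueError("dendrogram needs at least 2 genomes")
    link = hierarchy.ward(pdist(matrix.to_numpy(dtype=float)))
    return link, _linkage_to_newick(link, list(matrix.index))


def build_pangenome(
    genes: Sequence[GeneCall],
    *,
    minbit: float = 0.5,
    inflation: float = 10.0,
) -> Tuple[List[GeneCluster], pd.DataFrame]:
    """End-to-end pangenome: scores -> minbit filter -> MCL -> matrix +
    categorised clusters.
    """
    edges = pairwise_scores(genes)
    kept = minbit_filter(edges, threshold=minbit)
    raw_clusters = mcl_cluster([g.gene_id for g in genes], kept, inflation=inflation)
    matrix = build_pangenome_matrix(raw_clusters, genes)
    cats = cluster_categories(matrix)
    genome_of = {g.gene_id: g.genome_id for g in genes}
    clusters = []
    for cid, members in zip(matrix.columns, raw_clusters):
        freq: Dict[str, int] = {}
        for gid in members:
            freq[genome_of[gid]] = freq.get(genome_of[gid], 0) + 1
        clusters.append(GeneCluster(cid, tuple(members), freq, cats[cid]))
    return clusters, matrix
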