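"""Protein similarity, minbit filtering, Markov clustering, and the
pangenome matrix — each checked against an independently coded oracle."""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from metapan.pangenome import (
    GeneCall,
    SimilarityEdge,
    build_pangenome_matrix,
    classify_clusters,
    genome_dendrogram,
    mcl_cluster,
    minbit_filter,
    pairwise_scores,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _sw_oracle(a, b, gap_open=-11, gap_extend=-1):
    """Independent affine-gap Smith-Waterman (Gotoh) on BLOSUM62, pure DP."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in a
    F = np.full((n + 1, m + 1), -np.inf)  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open + gap_extend)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open + gap_extend)
            sub = H[i - 1, j - 1] + BLOSUM62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, sub, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def _gene(gene_id, genome_id, protein):
    return GeneCall(gene_id, genome_id, f"{genome_id}_c", 0, 3 * len(protein), "+", protein)


class TestPairwiseScores:
    def test_identical_proteins_minbit_one(self):
        rng = np.random.default_rng(0)
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50))
        edges = pairwise_scores([_gene("a", "g1", prot), _gene("b", "g2", prot)])
        cross = [e for e in edges if e.gene_a != e.gene_b]
        assert cross[0].minbit == pytest.approx(1.0)

    def test_minbit_definition_arithmetic(self):
        # cross 60, self 100 and 120 -> minbit 0.6
        assert 60 / min(100, 120) == pytest.approx(0.6)
        # and the implementation computes it from its own alignment scores
        edges = pairwise_scores(
            [_gene("a", "g1", "MKLVINW" * 8), _gene("b", "g2", "MKLVINW" * 8 + "AAAA")]
        )
        by_pair = {(e.gene_a, e.gene_b): e for e in edges}
        self_a = by_pair[("a", "a")].score
        self_b = by_pair[("b", "b")].score
        assert by_pair[("a", "b")].minbit == pytest.approx(
            by_pair[("a", "b")].score / min(self_a, self_b)
        )

    def test_unrelated_shuffle_below_half_minbit(self):
        rng = np.random.default_rng(1)
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
        shuffled = "".join(rng.permutation(list(prot)))
        edges = pairwise_scores([_gene("a", "g1", prot), _gene("b", "g2", shuffled)])
        cross = [e for e in edges if e.gene_a != e.gene_b]
        assert all(e.minbit < 0.5 for e in cross)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            _gene("a", "g1", "")

    def test_toy_set_matches_brute_force_oracle(self):
        """Minbit values on a 6-gene set agree with an independent pure-python
        Gotoh Smith-Waterman over all 15 pairs (raw-score mode: minbit is a
        score ratio, invariant to the bitscore transform)."""
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(aas, 60))
        prots = {
            "p0": base,
            "p1": base[:50] + "".join(rng.choice(aas, 10)),
            "p2": "".join(rng.choice(aas, 60)),
            "p3": "".join(rng.choice(aas, 45)),
            "p4": base[10:55],
            "p5": "".join(rng.choice(aas, 70)),
        }
        genes = [_gene(k, f"g_{k}", v) for k, v in sorted(prots.items())]
        edges = pairwise_scores(genes, raw_scores=True)
        got = {(e.gene_a, e.gene_b): e.minbit for e in edges if e.gene_a != e.gene_b}
        names = sorted(prots)
        selfs = {k: _sw_oracle(prots[k], prots[k]) for k in names}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                raw = _sw_oracle(prots[a], prots[b])
                if raw <= 0:
                    assert (a, b) not in got
                    continue
                expected = raw / min(selfs[a], selfs[b])
                assert got[(a, b)] == pytest.approx(expected, abs=1e-9)

    def test_minbit_symmetric(self):
        rng = np.random.default_rng(9)
        prots = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40)) for _ in range(4)]
        genes = [_gene(f"p{i}", f"g{i}", p) for i, p in enumerate(prots)]
        edges = pairwise_scores(genes)
        seen = {}
        for e in edges:
            seen[frozenset((e.gene_a, e.gene_b))] = e.minbit
        rev = pairwise_scores(list(reversed(genes)))
        for e in rev:
            assert seen[frozenset((e.gene_a, e.gene_b))] == pytest.approx(e.minbit)


class TestMinbitFilter:
    def _edges(self, minbits):
        edges = [SimilarityEdge(g, g, 100.0, 1.0) for g in "abcdef"]
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        for (x, y), mb in zip(pairs, minbits):
            edges.append(SimilarityEdge(x, y, 100 * mb, mb))
        return edges

    def test_boundary_inclusive_at_half(self):
        kept = minbit_filter(self._edges([0.49, 0.50, 0.90]))
        assert sorted(e.minbit for e in kept) == [0.50, 0.90]

    def test_empty_input(self):
        assert minbit_filter([]) == []

    def test_self_edges_removed(self):
        kept = minbit_filter(self._edges([0.9, 0.9, 0.9]))
        assert all(e.gene_a != e.gene_b for e in kept)

    def test_missing_self_score_raises(self):
        with pytest.raises(ValueError, match="zzz"):
            minbit_filter([SimilarityEdge("a", "zzz", 50.0, 0.9),
                           SimilarityEdge("a", "a", 100.0, 1.0)])


def _mcl_oracle(nodes, edges, inflation=10.0):
    """Independent textbook MCL: explicit loops, same parameterisation."""
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for e in edges:
        if e.gene_a != e.gene_b:
            i, j = idx[e.gene_a], idx[e.gene_b]
            w[i, j] = w[j, i] = max(w[i, j], e.minbit)
    for j in range(n):
        mx = w[:, j].max()
        w[j, j] = mx if mx > 0 else 1.0
    M = w / w.sum(axis=0)
    for _ in range(200):
        prev = M.copy()
        M = M.dot(M)
        M = M ** inflation
        M = M / M.sum(axis=0)
        M[M < 1e-8] = 0.0
        s = M.sum(axis=0)
        s[s == 0] = 1.0
        M = M / s
        if np.abs(M - prev).max() < 1e-6:
            break
    comp = {}
    for i in range(n):
        for j in range(n):
            if M[i, j] > 1e-8:
                comp.setdefault(i, set()).add(j)
    # union overlapping row-supports into clusters
    clusters = []
    for members in comp.values():
        hit = [c for c in clusters if c & members]
        for h in hit:
            clusters.remove(h)
            members = members | h
        clusters.append(set(members))
    covered = set().union(*clusters) if clusters else set()
    for j in range(n):
        if j not in covered:
            clusters.append({j})
    return sorted(sorted(nodes[i] for i in c) for c in clusters)


class TestMcl:
    def _clique_edges(self, groups, weight=0.9, bridges=()):
        edges = []
        for grp in groups:
            for i, a in enumerate(grp):
                for b in grp[i + 1 :]:
                    edges.append(SimilarityEdge(a, b, 100 * weight, weight))
        for a, b, w in bridges:
            edges.append(SimilarityEdge(a, b, 100 * w, w))
        return edges

    def test_disconnected_cliques_stay_separate(self):
        nodes = list("abcdef")
        edges = self._clique_edges([list("abc"), list("def")])
        assert mcl_cluster(nodes, edges) == [["a", "b", "c"], ["d", "e", "f"]]

    def test_isolated_gene_is_singleton(self):
        nodes = list("abcx")
        edges = self._clique_edges([list("abc")])
        assert ["x"] in mcl_cluster(nodes, edges)

    def test_planted_families_with_weak_bridges(self):
        """Three 4-gene families joined by minbit-0.55 bridges resolve into 3
        clusters at inflation 10; agrees with bridge-removal connected
        components and an independent textbook MCL."""
        fams = [[f"f{k}_{i}" for i in range(4)] for k in range(3)]
        nodes = [g for f in fams for g in f]
        bridges = [(fams[0][0], fams[1][0], 0.55), (fams[1][1], fams[2][0], 0.55)]
        edges = self._clique_edges(fams, weight=0.9, bridges=bridges)
        got = mcl_cluster(nodes, edges, inflation=10.0)
        # oracle 1: drop weak bridges, take connected components
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            if e.minbit > 0.55:
                g.add_edge(e.gene_a, e.gene_b)
        cc = sorted(sorted(c) for c in nx.connected_components(g))
        assert got == cc == sorted(sorted(f) for f in fams)
        # oracle 2: independent MCL implementation
        assert got == _mcl_oracle(nodes, edges, inflation=10.0)

    def test_nonfinite_weight_rejected(self):
        with pytest.raises(ValueError):
            mcl_cluster(["a", "b"], [SimilarityEdge("a", "b", 1.0, float("nan"))])

    def test_inflation_monotonicity(self):
        """Mean cluster size does not increase as inflation rises 2 -> 10."""
        rng = np.random.default_rng(11)
        nodes = [f"n{i}" for i in range(30)]
        edges = []
        for i in range(30):
            for j in range(i + 1, 30):
                if (i // 6 == j // 6 and rng.random() < 0.8) or rng.random() < 0.08:
                    mb = rng.uniform(0.5, 1.0)
                    edges.append(SimilarityEdge(nodes[i], nodes[j], 100 * mb, mb))
        sizes = []
        for infl in (2.0, 4.0, 10.0):
            clusters = mcl_cluster(nodes, edges, inflation=infl)
            sizes.append(np.mean([len(c) for c in clusters]))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_gene_conservation(self, sim_catalog, sim_pangenome):
        _, genes, _ = sim_catalog
        clusters, _ = sim_pangenome
        members = [m for c in clusters for m in c.members]
        assert len(members) == len(genes)
        assert len(set(members)) == len(members)

    def test_recovers_planted_families(self, sim_catalog, sim_pangenome):
        _, _, truth = sim_catalog
        clusters, _ = sim_pangenome
        fam = truth.family_of_gene
        for c in clusters:
            assert len({fam[m] for m in c.members}) == 1


class TestClassify:
    def _matrix(self):
        # 3 genomes x 5 clusters, hand-counted: 2 core, 1 accessory, 2 singleton
        return pd.DataFrame(
            {
                "c1": [1, 1, 1],
                "c2": [2, 1, 1],
                "c3": [1, 1, 0],
                "c4": [1, 0, 0],
                "c5": [0, 0, 3],
            },
            index=["g1", "g2", "g3"],
        )

    def test_hand_counted_toy(self):
        counts = classify_clusters(self._matrix())
        assert counts == {"core": 2, "accessory": 1, "singleton": 2, "total": 5}

    def test_partition_identity(self, sim_pangenome):
        _, matrix = sim_pangenome
        counts = classify_clusters(matrix)
        assert counts["core"] + counts["accessory"] + counts["singleton"] == counts["total"]

    def test_planted_category_counts(self, sim_catalog, sim_pangenome):
        _, _, truth = sim_catalog
        _, matrix = sim_pangenome
        import collections
        expected = collections.Counter(truth.family_category.values())
        counts = classify_clusters(matrix)
        assert counts["core"] == expected["core"]
        assert counts["accessory"] == expected["accessory"]
        assert counts["singleton"] == expected["singleton"]


def _ward_oracle(x):
    """Lance-Williams Ward agglomeration: returns merge heights in order."""
    import itertools
    clusters = {i: [i] for i in range(len(x))}
    d = {frozenset((i, j)): float(np.sum((x[i] - x[j]) ** 2)) ** 0.5
         for i, j in itertools.combinations(range(len(x)), 2)}
    sizes = {i: 1 for i in range(len(x))}
    merges = []
    nxt = len(x)
    while len(clusters) > 1:
        (a, b), h = min(((tuple(k), v) for k, v in d.items()
                         if all(i in clusters for i in k)), key=lambda kv: (kv[1], kv[0]))
        merges.append((frozenset(clusters[a] + clusters[b]), h))
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        na, nb = sizes.pop(a), sizes.pop(b)
        sizes[nxt] = na + nb
        for k in list(clusters):
            if k == nxt:
                continue
            nk = sizes[k]
            dak = d.pop(frozenset((a, k)), None)
            dbk = d.pop(frozenset((b, k)), None)
            dab = d[frozenset((a, b))]
            alpha_a = (na + nk) / (na + nb + nk)
            alpha_b = (nb + nk) / (na + nb + nk)
            beta = -nk / (na + nb + nk)
            d[frozenset((nxt, k))] = float(
                np.sqrt(alpha_a * dak ** 2 + alpha_b * dbk ** 2 + beta * dab ** 2)
            )
        del d[frozenset((a, b))]
        nxt += 1
    return merges


class TestDendrogram:
    def test_identical_genomes_merge_at_zero(self):
        m = pd.DataFrame([[1, 0, 2], [1, 0, 2], [5, 5, 5]], index=["a", "b", "c"])
        link, newick = genome_dendrogram(m)
        assert link[0, 2] == pytest.approx(0.0)
        assert newick.count("(") == 2

    def test_fewer_than_two_genomes_error(self):
        with pytest.raises(ValueError):
            genome_dendrogram(pd.DataFrame([[1, 2]], index=["a"]))

    def test_matches_lance_williams_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 4, size=(6, 20)).astype(float)
        m = pd.DataFrame(x, index=[f"g{i}" for i in range(6)])
        link, _ = genome_dendrogram(m)
        oracle = _ward_oracle(x)
        assert len(oracle) == link.shape[0]
        for (members, height), row in zip(oracle, link):
            assert height == pytest.approx(row[2], rel=1e-9)

    def test_planted_clades_recovered(self, sim_catalog, sim_pangenome):
        """Cutting the Ward dendrogram at 3 groups reproduces the planted
        species clades."""
        from scipy.cluster.hierarchy import fcluster
        _, _, truth = sim_catalog
        _, matrix = sim_pangenome
        link, _ = genome_dendrogram(matrix)
        cut = fcluster(link, t=3, criterion="maxclust")
        groups = {}
        for gid, lab in zip(matrix.index, cut):
            groups.setdefault(lab, set()).add(truth.species_of[gid])
        assert all(len(sp) == 1 for sp in groups.values())
        assert len(groups) == 3


class TestMatrix:
    def test_row_and_column_sums(self, sim_catalog, sim_pangenome):
        _, genes, _ = sim_catalog
        clusters, matrix = sim_pangenome
        per_genome = {}
        for g in genes:
            per_genome[g.genome_id] = per_genome.get(g.genome_id, 0) + 1
        for gid, total in per_genome.items():
            assert matrix.loc[gid].sum() == total
        for c in clusters:
            assert matrix[c.cluster_id].sum() == len(c.members)
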