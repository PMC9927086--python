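"""Metabolic-module completeness and group enrichment.

A module is an ordered list of steps, each satisfied by any of its alternative
orthology accessions; completeness is the fraction of satisfied steps, and a
genome carries a "complete" module when that fraction reaches 0.75.  To find
site-specialist signatures, each item (a module's complete/incomplete
indicator, or a raw function's presence/absence) is tested for association
with the genome grouping using the Rao score test of the logistic GLM
``presence ~ group`` against the intercept-only model — for a one-way
categorical design this statistic is the Pearson chi-square of the
group x presence table, referred to chi-square with (groups - 1) degrees of
freedom.  P-values are Benjamini-Hochberg adjusted within each pairwise group
comparison, and items with q <= 0.01 are flagged enriched.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModuleDefinition",
    "EnrichmentResult",
    "module_completeness",
    "completeness_matrix",
    "enrichment_test",
    "bh_adjust",
    "enriched_modules",
    "enriched_functions",
]


@dataclass(frozen=True)
class ModuleDefinition:
    """One metabolic module: ordered steps, each a set of alternative KOs."""

    module_id: str
    name: str
    steps: Tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"module {self.module_id} has no steps")
        if any(not s for s in self.steps):
            raise ValueError(f"module {self.module_id} has an empty step")


@dataclass(frozen=True)
class EnrichmentResult:
    item_id: str
    comparison: Tuple[str, str] | Tuple[str, ...]
    group_present_fractions: Mapping[str, float]
    score: float
    p: float
    q: float
    enriched: bool


def module_completeness(
    annotations: Iterable[str], module: ModuleDefinition, threshold: float = 0.75
) -> Tuple[float, bool]:
    """Fraction of module steps satisfied by the genome's accessions (a step
    is satisfied when any alternative is annotated); complete at >= threshold.
    """
    present = set(annotations)
    satisfied = sum(1 for step in module.steps if step & present)
    fraction = satisfied / len(module.steps)
    return fraction, fraction >= threshold


def completeness_matrix(
    annotations: pd.DataFrame,
    modules: Sequence[ModuleDefinition],
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Genome x module completeness fractions from a long annotation table
    with columns (genome_id, accession).
    """
    per_genome = annotations.groupby("genome_id")["accession"].apply(set)
    rows = {}
    for gid, accs in per_genome.items():
        rows[gid] = {
            m.module_id: module_completeness(accs, m, threshold)[0] for m in modules
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def enrichment_test(
    presence: Sequence[bool], groups: Sequence[str]
) -> Tuple[float, float]:
    """Rao score test of the logistic model presence ~ group vs intercept-only.

    For a categorical one-way design the score statistic reduces to the
    Pearson chi-square of the groups x presence contingency table; the p-value
    uses chi-square with (n_groups - 1) df.  Identical presence across all
    genomes gives (0, 1).
    """
    presence = np.asarray(presence, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("enrichment_test needs at least 2 groups")
    if presence.size != groups.size:
        raise ValueError("presence and groups differ in length")
    overall = presence.mean()
    if overall in (0.0, 1.0):
        return 0.0, 1.0
    score = 0.0
    for lab in labels:
        mask = groups == lab
        n_g = mask.sum()
        obs = presence[mask].sum()
        exp = n_g * overall
        # Pearson terms over both outcome cells of this group's row
        score += (obs - exp) ** 2 / exp + ((n_g - obs) - (n_g - exp)) ** 2 / (n_g - exp)
    df = labels.size - 1
    p = float(stats.chi2.sf(score, df))
    return float(score), p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _test_items(
    presence: pd.DataFrame, group_map: Mapping[str, str], q_threshold: float
) -> List[EnrichmentResult]:
    """Test every column of a genome x item boolean frame for association with
    the grouping, in every pairwise group comparison; BH within comparison.
    """
    genomes = list(presence.index)
    missing = [g for g in genomes if g not in group_map]
    if missing:
        raise ValueError(f"genomes missing from group map: {missing}")
    labels = np.array([group_map[g] for g in genomes])
    group_names = sorted(set(labels))
    if len(group_names) < 2:
        raise ValueError("need at least 2 genome groups")
    results: List[EnrichmentResult] = []
    for ga, gb in combinations(group_names, 2):
        mask = np.isin(labels, [ga, gb])
        sub = presence.loc[mask]
        sub_labels = labels[mask]
        scored = []
        for item in presence.columns:
            vals = sub[item].to_numpy(dtype=bool)
            score, p = enrichment_test(vals, sub_labels)
            fracs = {
                g: float(vals[sub_labels == g].mean()) for g in (ga, gb)
            }
            scored.append((item, score, p, fracs))
        qvals = bh_adjust([s[2] for s in scored])
        for (item, score, p, fracs), q in zip(scored, qvals):
            results.append(
                EnrichmentResult(
                    item, (ga, gb), fracs, score, p, float(q), bool(q <= q_threshold)
                )
            )
    return results


def enriched_modules(
    annotations: pd.DataFrame,
    modules: Sequence[ModuleDefinition],
    group_map: Mapping[str, str],
    *,
    completeness_threshold: float = 0.75,
    q_threshold: float = 0.01,
) -> List[EnrichmentResult]:
    """Test each module's complete/incomplete indicator for group association
    across all pairwise group comparisons.  Genomes present in the group map
    but absent from the annotation table count as carrying nothing.
    """
    comp = completeness_matrix(annotations, modules, completeness_threshold)
    comp = comp.reindex(sorted(group_map), fill_value=0.0)
    complete = comp >= completeness_threshold
    return _test_items(complete, group_map, q_threshold)


def enriched_functions(
    annotations: pd.DataFrame,
    group_map: Mapping[str, str],
    *,
    q_threshold: float = 0.01,
) -> List[EnrichmentResult]:
    """Presence/absence enrichment of individual function accessions,
    independent of module structure.
    """
    presence = (
        annotations.assign(present=True)
        .pivot_table(
            index="genome_id", columns="accession", values="present",
            aggfunc="any", fill_value=False,
        )
        .reindex(sorted(group_map), fill_value=False)
        .astype(bool)
    )
    return _test_items(presence, group_map, q_threshold)


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results, sorted by q then item."""
    rows = [
        {
            "item_id": r.item_id,
            "group_a": r.comparison[0],
            "group_b": r.comparison[1],
            "frac_a": r.group_present_fractions[r.comparison[0]],
            "frac_b": r.group_present_fractions[r.comparison[1]],
            "score": r.score,
            "p": r.p,
            "q": r.q,
            "enriched": r.enriched,
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values(["q", "item_id"]).reset_index(drop=True)
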