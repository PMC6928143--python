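"""Canonical-pathway over-representation and cross-dataset intersection.

Each dataset's network-eligible molecules are tested pathway by pathway
with the one-sided hypergeometric upper tail (Fisher's exact right tail):
given N annotated molecules in the knowledge-base universe, K of them in
the pathway and n of them in the query, the p-value is P(X >= k) for the
observed overlap k.  Benjamini-Hochberg adjustment is applied across the
pathways of one dataset, and a pathway is significant at adjusted
p < 0.05.  Pathways significant in at least two datasets form the shared
(cross-dataset) pathway table, annotated with cancer-related and panel
labels supplied as input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .knowledge_base import KnowledgeBase

__all__ = [
    "EnrichmentResult",
    "SharedPathwayRecord",
    "hypergeometric_tail",
    "benjamini_hochberg",
    "enrich_dataset",
    "shared_pathways",
    "ALPHA",
]

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    adjusted_p: float
    significant: bool
    overlap_members: frozenset[str]


@dataclass(frozen=True)
class SharedPathwayRecord:
    pathway_name: str
    dataset_serials: frozenset[int]
    n_datasets: int
    cancer_related: bool
    panel_label: Optional[str]


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the pathway size, n the query size and k the
    observed overlap.  Returns 1.0 at k = 0.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); clip away a possible negative-zero rounding
    return float(min(1.0, max(stats.hypergeom.sf(k - 1, N, K, n), 0.0)))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(q) for q in adjusted]


def enrich_dataset(
    eligible: Iterable[str],
    kb: KnowledgeBase,
    alpha: float = ALPHA,
) -> list[EnrichmentResult]:
    """Over-representation of one dataset's eligible molecules in every pathway.

    Query identifiers outside the KB universe are dropped with a warning;
    BH is applied across all pathways of this dataset; results are sorted
    by adjusted p ascending, ties by pathway name.
    """
    eligible = set(eligible)
    if not eligible:
        return []
    universe = kb.universe
    stray = eligible - universe
    if stray:
        log.warning(
            "%d eligible identifiers outside the KB universe dropped", len(stray)
        )
    query = eligible & universe
    N = len(universe)
    n = len(query)
    raw: list[tuple[str, int, int, frozenset[str], float]] = []
    for pathway in kb.pathways:
        overlap = frozenset(query & pathway.members)
        k, K = len(overlap), len(pathway.members)
        raw.append((pathway.name, k, K, overlap, hypergeometric_tail(k, K, n, N)))
    adjusted = benjamini_hochberg([r[4] for r in raw])
    results = [
        EnrichmentResult(
            pathway_name=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            adjusted_p=q,
            significant=q < alpha,
            overlap_members=overlap,
        )
        for (name, k, K, overlap, p), q in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.pathway_name))
    return results


def shared_pathways(
    per_dataset: Mapping[int, Iterable[EnrichmentResult]],
    min_datasets: int = 2,
    labels: Optional[Mapping[str, tuple[bool, Optional[str]]]] = None,
) -> list[SharedPathwayRecord]:
    """Pathways significant in at least ``min_datasets`` datasets.

    ``per_dataset`` maps dataset serial to that dataset's enrichment
    results (only significant entries are counted).  ``labels`` maps a
    pathway name to its (cancer_related, panel_label) annotation.
    Records are sorted by n_datasets descending, then name.
    """
    if min_datasets < 1:
        raise ValueError("min_datasets must be >= 1")
    labels = labels or {}
    hits: dict[str, set[int]] = {}
    for serial, results in per_dataset.items():
        for result in results:
            if result.significant:
                hits.setdefault(result.pathway_name, set()).add(serial)
    records = [
        SharedPathwayRecord(
            pathway_name=name,
            dataset_serials=frozenset(serials),
            n_datasets=len(serials),
            cancer_related=labels.get(name, (False, None))[0],
            panel_label=labels.get(name, (False, None))[1],
        )
        for name, serials in hits.items()
        if len(serials) >= min_datasets
    ]
    records.sort(key=lambda r: (-r.n_datasets, r.pathway_name))
    return records
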