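"""Cluster-level trait enrichment and depletion with BH FDR control.

Each (cluster, trait) cell is tested against the hypergeometric null: draw
``n`` annotated cluster nodes from a background of ``N`` annotated nodes of
which ``K`` are trait-positive, and observe ``k`` positives.  Enrichment
uses the upper tail ``P[X >= k]``, depletion the lower tail ``P[X <= k]``;
one-sided tails in both directions keep the direction of each finding
explicit.  All cluster × trait × direction p-values form a single
Benjamini–Hochberg family.

Nodes with an unknown call for a trait are excluded from that trait's
counts; a trait positive in zero background nodes is skipped (recorded with
a reason rather than tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotate import TraitTable

__all__ = [
    "EnrichmentResult",
    "cluster_trait_tests",
    "bh_adjust",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    cluster: str
    trait: str
    direction: str  # "enriched" | "depleted"
    k: int  # trait-positive annotated nodes in cluster
    n: int  # annotated nodes in cluster
    K: int  # trait-positive annotated nodes in background
    N: int  # annotated background nodes
    p_value: float
    q_value: float = float("nan")


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q.tolist()


def cluster_trait_tests(
    traits: TraitTable,
    clusters: Mapping[str, str],
    node_traits: Mapping[str, Mapping[str, bool | None]] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment/depletion of every trait in every cluster.

    ``clusters`` maps node → cluster label; unassigned nodes are excluded.
    By default trait calls are taken from ``traits.values`` keyed by node;
    ``node_traits`` overrides this with per-node merged vectors (e.g. from
    an annotated network).  The background is all cluster-assigned nodes
    with a known call for the trait under test.

    Returns results sorted by (cluster, trait, direction) with BH q-values
    over the full family.
    """
    calls: Mapping[str, Mapping[str, bool | None]]
    calls = node_traits if node_traits is not None else traits.values
    trait_names = traits.declared_traits()
    assigned = [n for n in clusters if n in calls]
    labels = sorted(set(clusters[n] for n in assigned))

    results: list[EnrichmentResult] = []
    for trait in trait_names:
        known = [n for n in assigned if calls[n].get(trait) is not None]
        N = len(known)
        K = sum(1 for n in known if calls[n][trait])
        if N == 0 or K == 0:
            logger.info(
                "skipping trait %r: %s",
                trait,
                "no annotated nodes" if N == 0 else "positive in zero background nodes",
            )
            continue
        for label in labels:
            members = [n for n in known if clusters[n] == label]
            n_ = len(members)
            if n_ == 0:
                continue
            k = sum(1 for n in members if calls[n][trait])
            p_enr = float(hypergeom.sf(k - 1, N, K, n_))
            p_dep = float(hypergeom.cdf(k, N, K, n_))
            results.append(
                EnrichmentResult(label, trait, "enriched", k, n_, K, N, min(p_enr, 1.0))
            )
            results.append(
                EnrichmentResult(label, trait, "depleted", k, n_, K, N, min(p_dep, 1.0))
            )
    if not results:
        return []
    q = bh_adjust([r.p_value for r in results])
    adjusted = [
        EnrichmentResult(
            r.cluster, r.trait, r.direction, r.k, r.n, r.K, r.N, r.p_value, qv
        )
        for r, qv in zip(results, q)
    ]
    adjusted.sort(key=lambda r: (r.cluster, r.trait, r.direction))
    return adjusted
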