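"""Overrepresentation of transcription-factor target sets in behavior clusters."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError
from .periodicity import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class GeneSetAnnotation:
    tf_name: str
    targets: set[str]

    def __post_init__(self):
        self.targets = set(self.targets)
        if not self.targets:
            raise InputError(f"annotation {self.tf_name!r} has no targets")


@dataclass
class EnrichmentRow:
    tf_name: str
    cluster_id: str
    k: int          # annotated genes in the cluster
    n: int          # cluster size
    K: int          # annotated genes in the universe
    N: int          # universe size
    p_value: float
    q_value: float = 1.0


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise InputError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) is the survival function at k-1, i.e. P(X >= k); computed in
    # log space internally by scipy
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def cluster_overrepresentation(clusters: dict[str, set[str]],
                               annotations: list[GeneSetAnnotation],
                               universe: set[str],
                               alpha: float = 0.05) -> list[EnrichmentRow]:
    """One-sided overrepresentation test for every (TF, cluster) pair.

    Clusters are expected to be disjoint subsets of the universe; subset
    membership is enforced, disjointness is the caller's responsibility.
    Annotation targets outside the universe are dropped (with a logged
    count).  BH q-values are computed jointly across all rows; rows sort by
    (q, p, tf, cluster).
    """
    universe = set(universe)
    for cid, genes in clusters.items():
        if not genes <= universe:
            raise InputError(f"cluster {cid!r} is not a subset of the universe")

    N = len(universe)
    rows: list[EnrichmentRow] = []
    for ann in annotations:
        targets = ann.targets & universe
        dropped = len(ann.targets) - len(targets)
        if dropped:
            logger.info("annotation %s: dropped %d targets outside the universe",
                        ann.tf_name, dropped)
        K = len(targets)
        for cid in sorted(clusters):
            genes = clusters[cid]
            n = len(genes)
            k = len(genes & targets)
            p = hypergeom_tail(k, K, n, N) if K else 1.0
            rows.append(EnrichmentRow(tf_name=ann.tf_name, cluster_id=cid,
                                      k=k, n=n, K=K, N=N, p_value=p))
    if rows:
        q = bh_fdr([r.p_value for r in rows])
        for r, qv in zip(rows, q):
            r.q_value = float(qv)
    rows.sort(key=lambda r: (r.q_value, r.p_value, r.tf_name, r.cluster_id))
    return rows
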