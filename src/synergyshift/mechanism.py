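"""Consensus mechanism clustering of R-to-S shifting compounds.

Each calling compound's experiments are reduced to ternary expression
indicators (z > 1 -> +1, z < -1 -> -1, else 0, strict thresholds) and
summed across experiments into a per-compound consensus vector.
Compounds are clustered hierarchically (Ward update on 1 - Pearson
correlation distances) and each cluster is summarized by the per-gene
median consensus value, ranked descending into a profile that is
annotated by preranked GSEA against a pathway collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .enrichment import EnrichmentResult, GeneSet, RankedProfile, prerank_gsea

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 12.0


@dataclass
class IndicatorMatrix:
    """Ternary expression indicators, genes x experiments, with the
    compound each experiment belongs to."""

    values: pd.DataFrame
    compound_of: pd.Series  # experiment_id -> compound_id

    def __post_init__(self):
        vals = self.values.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("indicator entries must be -1, 0 or +1")
        missing = set(self.values.columns) - set(self.compound_of.index)
        if missing:
            raise ValueError(f"experiments without a compound mapping: {sorted(missing)[:5]}")


@dataclass
class ConsensusVectors:
    """Per-compound integer sums of indicators (genes x compounds)."""

    values: pd.DataFrame
    n_experiments: pd.Series  # compound_id -> count

    def __post_init__(self):
        for cid in self.values.columns:
            n = int(self.n_experiments[cid])
            col = self.values[cid]
            if col.abs().max() > n:
                raise ValueError(f"consensus entries of {cid} exceed +-n_experiments")


@dataclass
class CompoundClustering:
    linkage_matrix: np.ndarray
    labels: pd.Series        # compound_id -> integer cluster label
    compounds: list[str]
    distance: str = "1 - pearson r"
    method: str = "ward-on-precomputed"


def make_indicators(
    profiles: pd.DataFrame, compound_of: pd.Series
) -> IndicatorMatrix:
    """Threshold z-score profiles into ternary indicators.

    Strict comparisons: exactly +1 or -1 maps to 0.
    """
    vals = profiles.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("profile values must be finite")
    ind = np.zeros_like(vals, dtype=np.int8)
    ind[vals > 1] = 1
    ind[vals < -1] = -1
    return IndicatorMatrix(
        pd.DataFrame(ind, index=profiles.index, columns=profiles.columns),
        compound_of.loc[profiles.columns],
    )


def consensus_vectors(indicators: IndicatorMatrix) -> ConsensusVectors:
    """Sum indicators across each compound's experiments."""
    grouped = indicators.values.T.groupby(indicators.compound_of, sort=True)
    sums = grouped.sum().T.astype(int)
    counts = grouped.size()
    return ConsensusVectors(values=sums, n_experiments=counts)


def _correlation_distance(vectors: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Pearson r between compounds (columns).

    Zero-variance vectors get r defined as 0 (distance 1), with a
    warning — correlation with a constant is otherwise undefined.
    """
    X = vectors.to_numpy(dtype=float).T  # compounds x genes
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant consensus vectors; their correlations set to 0", int(constant.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R[np.isnan(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D[D < 0] = 0.0
    return D


def cluster_compounds(
    vectors: ConsensusVectors | pd.DataFrame,
    cutoff: float | None = None,
    k: int | None = 2,
) -> CompoundClustering:
    """Hierarchical clustering of compounds on correlation distance.

    The Ward update rule is applied directly to the precomputed
    1 - Pearson r distance matrix (the "Ward on distances" convention);
    merge heights therefore live on that convention's scale, and a
    height cutoff is only meaningful relative to it.  Flat labels come
    from ``cutoff`` (merge-height threshold) when given, else from a
    ``k``-cluster cut (default 2).  Compounds are sorted by id first so
    the result is independent of input order.
    """
    df = vectors.values if isinstance(vectors, ConsensusVectors) else vectors
    df = df[sorted(df.columns)]
    if df.shape[1] < 2:
        raise ValueError("need at least 2 compounds to cluster")
    D = _correlation_distance(df)
    Z = linkage(squareform(D, checks=False), method="ward")
    heights = Z[:, 2]
    if np.any(np.diff(heights) < -1e-10):
        logger.warning("non-monotone merge heights (Ward on non-Euclidean distances)")
    if cutoff is not None:
        labels = fcluster(Z, t=cutoff, criterion="distance")
    else:
        labels = fcluster(Z, t=int(k or 2), criterion="maxclust")
    return CompoundClustering(
        linkage_matrix=Z,
        labels=pd.Series(labels, index=df.columns, name="cluster"),
        compounds=list(df.columns),
    )


@dataclass
class ClusterSignature:
    cluster_id: int
    medians: pd.Series       # per-gene median consensus value
    ranked: RankedProfile    # descending-ranked over the full universe


def cluster_signature(
    vectors: ConsensusVectors | pd.DataFrame,
    members: Sequence[str],
    cluster_id: int = 0,
) -> ClusterSignature:
    """Per-gene median consensus across cluster members, ranked descending.

    Even-sized clusters use midpoint interpolation for the median.
    """
    df = vectors.values if isinstance(vectors, ConsensusVectors) else vectors
    members = list(members)
    if len(members) == 0:
        raise ValueError("cluster has no members")
    med = df[members].median(axis=1)
    ranked = RankedProfile.from_series(med)
    return ClusterSignature(cluster_id=cluster_id, medians=med, ranked=ranked)


def annotate_cluster(
    signature: ClusterSignature,
    go_sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int | None = 0,
) -> list[EnrichmentResult]:
    """Preranked GSEA of the cluster signature against a pathway
    collection; results sorted by NES descending (undefined NES last)."""
    results = prerank_gsea(signature.ranked, go_sets, n_perm=n_perm, seed=seed)
    return sorted(
        results,
        key=lambda r: (r.nes is None, -(r.nes if r.nes is not None else 0.0)),
    )
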