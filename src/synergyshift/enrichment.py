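"""Weighted Kolmogorov–Smirnov enrichment scoring.

This module is the engine behind every enrichment quantity in the
package: the ES_R / ES_S pair that feeds the shift-ability statistic,
the preranked GSEA used to annotate compound mechanism clusters, and
the single-sample (ssGSEA) scores used for immune-class profiling of
patient cohorts.

The core statistic is the classic preranked GSEA running sum.  Given a
gene list ranked by a real-valued statistic (descending) and a gene
set S, walk down the list accumulating

* ``+|score_i|**weight / sum_{hits} |score|**weight`` at members of S
  ("hits"), and
* ``-1 / (N - N_hits)`` at non-members ("misses").

The enrichment score (ES) is the signed maximum deviation of this sum
from zero: ES near +1 means S is concentrated at the top of the list,
near -1 at the bottom.  With ``weight=0`` the statistic reduces to the
unweighted Kolmogorov–Smirnov statistic.

Conventions (documented because the literature varies):

* ES is the single two-sided extremum (not the positive/negative split
  used by some implementations); on an exact tie ``max == -min`` the
  positive extremum is reported.
* Ranking ties are broken deterministically: score descending, then
  gene id ascending (see :meth:`RankedProfile.from_unsorted`).
* Gene-set members absent from the profile are dropped before scoring
  and reflected in ``n_overlap``.
* The null model for NES / nominal p / FDR is gene-set permutation:
  random same-size sets drawn without replacement from the profile's
  genes.  Phenotype permutation is impossible on a single ranked list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "RankedProfile",
    "EnrichmentResult",
    "UnscorableSetError",
    "weighted_ks_es",
    "prerank_gsea",
    "ssgsea_score",
    "ssgsea_matrix",
]


class UnscorableSetError(ValueError):
    """Raised when a gene set has no members in the profile/sample."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers.

    Members are stored in input order (deduplication would hide input
    errors, so duplicates are rejected instead).
    """

    set_id: str
    members: tuple[str, ...]

    def __init__(self, set_id: str, members: Iterable[str]):
        members = tuple(str(m) for m in members)
        if len(members) == 0:
            raise ValueError(f"gene set {set_id!r} is empty")
        if len(set(members)) != len(members):
            raise ValueError(f"gene set {set_id!r} has duplicate members")
        object.__setattr__(self, "set_id", str(set_id))
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


@dataclass(frozen=True)
class RankedProfile:
    """A descending-ranked gene list with its ranking statistic.

    ``gene_ids[i]`` carries ``scores[i]``; scores are non-increasing,
    finite, and gene ids are unique.  All enrichment computations take
    a :class:`RankedProfile` as substrate.
    """

    gene_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        gene_ids = np.asarray(self.gene_ids, dtype=str)
        scores = np.asarray(self.scores, dtype=float)
        if gene_ids.ndim != 1 or scores.ndim != 1 or len(gene_ids) != len(scores):
            raise ValueError("gene_ids and scores must be 1-D and equal length")
        if len(gene_ids) < 2:
            raise ValueError("a ranked profile needs at least 2 genes")
        if not np.all(np.isfinite(scores)):
            raise ValueError("ranking scores must be finite")
        if len(np.unique(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids in profile")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be sorted non-increasing")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_unsorted(cls, gene_ids: Sequence[str], scores: Sequence[float]) -> "RankedProfile":
        """Build a profile from unordered (gene, score) pairs.

        Stable deterministic comparator: score descending, then gene id
        ascending.  This tie rule is load-bearing for bit-reproducible
        screens and is relied on throughout the package.
        """
        gene_ids = np.asarray(gene_ids, dtype=str)
        scores = np.asarray(scores, dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ValueError("ranking scores must be finite")
        order = np.lexsort((gene_ids, -scores))
        return cls(gene_ids[order], scores[order])

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedProfile":
        return cls.from_unsorted(s.index.to_numpy(dtype=str), s.to_numpy(dtype=float))

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.gene_ids)


@dataclass(frozen=True)
class EnrichmentResult:
    """One enrichment score, with permutation statistics when computed.

    ``nes``, ``p_nominal`` and ``fdr`` are ``None`` unless permutations
    were run; ``nes`` stays ``None`` (undefined, never fabricated) when
    no null ES of the observed sign was drawn.
    """

    set_id: str
    es: float
    n_overlap: int
    leading_edge: tuple[str, ...] = field(default_factory=tuple)
    nes: float | None = None
    p_nominal: float | None = None
    fdr: float | None = None


def _hit_mask(profile: RankedProfile, gene_set: GeneSet) -> np.ndarray:
    return np.isin(profile.gene_ids, np.asarray(gene_set.members, dtype=str))


def _running_sum(scores: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    """Running hit-minus-miss sum over positions (weighted KS walk)."""
    n = len(scores)
    n_hit = int(hit.sum())
    steps = np.empty(n, dtype=float)
    w = np.abs(scores[hit]) ** weight
    total = w.sum()
    if total > 0:
        steps[hit] = w / total
    else:
        # all-zero hit scores: fall back to uniform hit mass so the
        # statistic stays defined (documented degenerate case)
        steps[hit] = 1.0 / n_hit
    miss = 0.0 if n_hit == n else 1.0 / (n - n_hit)
    steps[~hit] = -miss
    return np.cumsum(steps)


def weighted_ks_es(
    profile: RankedProfile, gene_set: GeneSet, weight: float = 1.0
) -> EnrichmentResult:
    """Weighted-KS enrichment score of ``gene_set`` in ``profile``.

    Returns the signed maximum deviation of the running sum from zero,
    the set/profile overlap size and the leading edge (set members at
    or before the positive extremum, or at or after the negative one).

    Raises
    ------
    UnscorableSetError
        If no set member is present in the profile.
    """
    if weight < 0:
        raise ValueError("weight must be non-negative")
    hit = _hit_mask(profile, gene_set)
    n_overlap = int(hit.sum())
    if n_overlap == 0:
        raise UnscorableSetError(
            f"gene set {gene_set.set_id!r} has no members in the profile"
        )
    running = _running_sum(profile.scores, hit, weight)
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    vmax = running[imax]
    vmin = running[imin]
    # signed two-sided extremum; exact tie resolves positive
    es = vmax if vmax >= -vmin else vmin
    es = float(np.clip(es, -1.0, 1.0))
    if es > 0:
        le = profile.gene_ids[: imax + 1][hit[: imax + 1]]
    elif es < 0:
        le = profile.gene_ids[imin:][hit[imin:]]
    else:
        le = np.array([], dtype=str)
    return EnrichmentResult(
        set_id=gene_set.set_id,
        es=es,
        n_overlap=n_overlap,
        leading_edge=tuple(le.tolist()),
    )


def _es_only(scores: np.ndarray, hit: np.ndarray, weight: float) -> float:
    """ES without leading-edge bookkeeping (hot path for permutations)."""
    running = _running_sum(scores, hit, weight)
    vmax = running.max()
    vmin = running.min()
    return float(vmax if vmax >= -vmin else vmin)


def prerank_gsea(
    profile: RankedProfile,
    sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int | None = 0,
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Preranked GSEA over a collection of gene sets.

    Observed ES per set via :func:`weighted_ks_es`.  With ``n_perm > 0``
    a gene-set-permutation null is drawn per set (random same-size sets,
    without replacement, from the profile's genes), giving:

    * ``nes = es / mean(|null ES| of the same sign)``
    * ``p_nominal = (1 + #{same-sign null at least as extreme})
      / (1 + #{same-sign null})``
    * ``fdr`` by the sign-stratified ratio-of-tails procedure on the
      pooled normalized null distribution.

    Results are reproducible for a given ``seed``.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    observed = [weighted_ks_es(profile, gs, weight=weight) for gs in sets]
    if n_perm == 0:
        return observed

    rng = np.random.default_rng(seed)
    n = len(profile)
    scores = profile.scores
    null_nes_pool: list[np.ndarray] = []
    per_set_null: list[np.ndarray] = []

    for res in observed:
        k = res.n_overlap
        null = np.empty(n_perm, dtype=float)
        hit = np.zeros(n, dtype=bool)
        for b in range(n_perm):
            idx = rng.choice(n, size=k, replace=False)
            hit[:] = False
            hit[idx] = True
            null[b] = _es_only(scores, hit, weight)
        per_set_null.append(null)

    # per-set sign-conditional normalization constants
    results: list[EnrichmentResult] = []
    norm_nulls = []
    for res, null in zip(observed, per_set_null):
        pos = null[null > 0]
        neg = null[null < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        # normalized null for the FDR pool
        nn = np.where(null > 0, null / mean_pos, null / mean_neg)
        norm_nulls.append(nn[np.isfinite(nn)])

        es = res.es
        if es > 0:
            same = pos
            denom = mean_pos
        elif es < 0:
            same = np.abs(neg)
            denom = mean_neg
        else:
            same = np.array([])
            denom = np.nan
        if es == 0:
            p_nom = 1.0
            nes = 0.0
        elif same.size == 0 or not np.isfinite(denom):
            p_nom = None
            nes = None
        else:
            p_nom = float((1 + np.sum(same >= abs(es))) / (1 + same.size))
            nes = float(es / denom) if es > 0 else float(es / denom)
        results.append(
            EnrichmentResult(
                set_id=res.set_id,
                es=res.es,
                n_overlap=res.n_overlap,
                leading_edge=res.leading_edge,
                nes=nes,
                p_nominal=p_nom,
            )
        )

    pool = np.concatenate(norm_nulls) if norm_nulls else np.array([])
    obs_nes = np.array([r.nes if r.nes is not None else np.nan for r in results])
    final: list[EnrichmentResult] = []
    for r in results:
        if r.nes is None:
            final.append(r)
            continue
        nes = r.nes
        if nes > 0:
            null_tail = np.sum(pool >= nes)
            null_sign = np.sum(pool > 0)
            obs_tail = np.sum(obs_nes[np.isfinite(obs_nes)] >= nes)
            obs_sign = np.sum(obs_nes[np.isfinite(obs_nes)] > 0)
        elif nes < 0:
            null_tail = np.sum(pool <= nes)
            null_sign = np.sum(pool < 0)
            obs_tail = np.sum(obs_nes[np.isfinite(obs_nes)] <= nes)
            obs_sign = np.sum(obs_nes[np.isfinite(obs_nes)] < 0)
        else:
            final.append(
                EnrichmentResult(r.set_id, r.es, r.n_overlap, r.leading_edge, r.nes, r.p_nominal, 1.0)
            )
            continue
        if null_sign == 0 or obs_sign == 0 or obs_tail == 0:
            fdr = None
        else:
            fdr = float(min(1.0, (null_tail / null_sign) / (obs_tail / obs_sign)))
        final.append(
            EnrichmentResult(r.set_id, r.es, r.n_overlap, r.leading_edge, r.nes, r.p_nominal, fdr)
        )
    return final


def _ssgsea_from_order(
    order_values: np.ndarray, hit: np.ndarray, exponent: float
) -> float:
    """ssGSEA running sum given genes already ordered by decreasing value.

    Hit weights are the rank values ``N - position + 1`` (top gene has
    rank value N) raised to ``exponent`` and normalized over hits; miss
    steps are ``1/(N - |S|)``.  The score is the sum over all positions
    of the running hit-minus-miss difference.
    """
    n = len(hit)
    n_hit = int(hit.sum())
    rank_values = np.arange(n, 0, -1, dtype=float)  # N, N-1, ..., 1
    w = np.zeros(n)
    hw = rank_values[hit] ** exponent
    w[hit] = hw / hw.sum()
    cum_hit = np.cumsum(w)
    if n_hit == n:
        cum_miss = np.zeros(n)
    else:
        miss = np.where(hit, 0.0, 1.0 / (n - n_hit))
        cum_miss = np.cumsum(miss)
    return float(np.sum(cum_hit - cum_miss))


def ssgsea_score(
    sample_expression: Mapping[str, float] | pd.Series,
    gene_set: GeneSet,
    exponent: float = 0.25,
) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    Genes are ordered by decreasing expression (ties: gene id
    ascending).  No cross-sample normalization is applied.
    """
    if exponent < 0:
        raise ValueError("exponent must be non-negative")
    s = pd.Series(sample_expression, dtype=float)
    profile = RankedProfile.from_series(s)
    hit = _hit_mask(profile, gene_set)
    if not hit.any():
        raise UnscorableSetError(
            f"gene set {gene_set.set_id!r} has no members in the sample"
        )
    return _ssgsea_from_order(profile.scores, hit, exponent)


def ssgsea_matrix(
    expression: pd.DataFrame,
    gene_sets: Sequence[GeneSet],
    exponent: float = 0.25,
) -> pd.DataFrame:
    """ssGSEA scores for every sample (column) and gene set.

    Parameters
    ----------
    expression : DataFrame, genes x samples.
    gene_sets : sequence of GeneSet.

    Returns
    -------
    DataFrame, samples x gene sets.  Sets with no overlap anywhere are
    dropped with a warning; per-sample the overlap is identical since
    all samples share the gene space.
    """
    genes = expression.index.to_numpy(dtype=str)
    masks = {}
    for gs in gene_sets:
        m = np.isin(genes, np.asarray(gs.members, dtype=str))
        if not m.any():
            logger.warning("dropping unscorable gene set %r (no overlap)", gs.set_id)
            continue
        masks[gs.set_id] = m
    out = np.empty((expression.shape[1], len(masks)))
    vals = expression.to_numpy(dtype=float)
    for j in range(expression.shape[1]):
        col = vals[:, j]
        order = np.lexsort((genes, -col))
        ordered_vals = col[order]
        for k, (sid, m) in enumerate(masks.items()):
            out[j, k] = _ssgsea_from_order(ordered_vals, m[order], exponent)
    return pd.DataFrame(out, index=expression.columns, columns=list(masks.keys()))
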