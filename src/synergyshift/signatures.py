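"""Derivation of treatment-induced response signatures.

The immunotherapy-response signatures are built from paired tumor
transcriptomes sampled before and during anti-PD-1 therapy.  For each
patient the treatment-induced change of a gene is the log2 fold change
between on-treatment and pre-treatment expression.  A two-sided
Wilcoxon rank-sum test per gene compares these induced changes between
responders and non-responders; significant genes are split by the sign
of the responder-minus-non-responder median difference into

* S (sensitivity) signature — induced changes higher in responders,
* R (resistance) signature — induced changes higher in non-responders.

For cohorts without paired sampling, per-sample deviation from the
cohort mean ("surrogate changes") stands in for the induced change.
Classification uses signature-average scores or the first principal
component of the change matrix, evaluated by ROC AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score, roc_curve

from .enrichment import GeneSet

logger = logging.getLogger(__name__)

RESPONDER = "R"       # response label: responder
NON_RESPONDER = "NR"  # response label: non-responder


@dataclass
class PairedCohort:
    """Pre/on-treatment expression for the same patients.

    ``pre`` and ``post`` are genes x patients DataFrames with identical
    index and columns; ``response`` maps each patient to "R"
    (responder) or "NR" (non-responder).  ``scale`` declares the unit
    of the stored values ("log2" or "linear"); it is required because
    fold changes are always computed on the linear scale.
    """

    pre: pd.DataFrame
    post: pd.DataFrame
    response: pd.Series
    scale: Literal["log2", "linear"] = "log2"

    def __post_init__(self):
        if not self.pre.index.equals(self.post.index) or not self.pre.columns.equals(
            self.post.columns
        ):
            raise ValueError("pre and post must share gene and patient ordering")
        missing = set(self.pre.columns) - set(self.response.index)
        if missing:
            raise ValueError(f"response labels missing for patients {sorted(missing)[:5]}")
        self.response = self.response.loc[self.pre.columns]
        classes = set(self.response.unique())
        if not classes <= {RESPONDER, NON_RESPONDER}:
            raise ValueError(f"response labels must be in {{R, NR}}, got {classes}")
        if len(classes) < 2:
            raise ValueError("both response classes must be non-empty")
        if self.scale not in ("log2", "linear"):
            raise ValueError("scale must be 'log2' or 'linear'")


@dataclass
class InducedChangeMatrix:
    """Per-gene, per-patient log2 fold changes (or surrogate changes)."""

    values: pd.DataFrame  # genes x patients
    provenance: Literal["paired", "surrogate"]

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("induced changes must be finite")


@dataclass
class ResponseSignature:
    """The R and S gene sets with per-gene test statistics.

    ``entries`` is indexed by gene with columns ``direction`` ("S" or
    "R"), ``p_value`` and ``median_diff`` (responder median change
    minus non-responder median change).  Genes significant but with
    exactly tied medians are excluded and listed in ``excluded_ties``.
    """

    entries: pd.DataFrame
    alpha: float
    excluded_ties: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        need = {"direction", "p_value", "median_diff"}
        if not need <= set(self.entries.columns):
            raise ValueError(f"entries needs columns {need}")
        bad = self.entries[self.entries["p_value"] >= self.alpha]
        if len(bad):
            raise ValueError("signature entries must all satisfy p < alpha")
        s_wrong = (self.entries["direction"] == "S") & (self.entries["median_diff"] <= 0)
        r_wrong = (self.entries["direction"] == "R") & (self.entries["median_diff"] >= 0)
        if s_wrong.any() or r_wrong.any():
            raise ValueError("direction inconsistent with sign of median difference")

    @property
    def s_genes(self) -> list[str]:
        return self.entries.index[self.entries["direction"] == "S"].tolist()

    @property
    def r_genes(self) -> list[str]:
        return self.entries.index[self.entries["direction"] == "R"].tolist()

    def gene_set(self, part: Literal["S", "R"]) -> GeneSet:
        genes = self.s_genes if part == "S" else self.r_genes
        if not genes:
            raise ValueError(f"{part} signature is empty")
        return GeneSet(f"{part}_signature", genes)

    def to_frame(self) -> pd.DataFrame:
        return self.entries.copy()


def compute_induced_changes(
    cohort: PairedCohort, pseudocount: float = 1.0
) -> InducedChangeMatrix:
    """log2((post + c) / (pre + c)) on the linear scale, c = pseudocount."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if cohort.scale == "log2":
        pre_lin = np.exp2(cohort.pre.to_numpy(dtype=float))
        post_lin = np.exp2(cohort.post.to_numpy(dtype=float))
    else:
        pre_lin = cohort.pre.to_numpy(dtype=float)
        post_lin = cohort.post.to_numpy(dtype=float)
    if np.any(pre_lin < 0) or np.any(post_lin < 0):
        raise ValueError("linear-scale expression must be non-negative")
    if pseudocount == 0 and np.any(pre_lin == 0):
        raise ValueError(
            "zero pre-treatment expression with pseudocount 0; pass a positive pseudocount"
        )
    vals = np.log2(post_lin + pseudocount) - np.log2(pre_lin + pseudocount)
    return InducedChangeMatrix(
        pd.DataFrame(vals, index=cohort.pre.index, columns=cohort.pre.columns),
        provenance="paired",
    )


def surrogate_changes(expression: pd.DataFrame) -> InducedChangeMatrix:
    """Per-gene mean-centered expression as a stand-in for induced change.

    Used for cohorts lacking paired pre/on sampling: each sample's
    deviation from the cohort population baseline (per-gene mean,
    computed in log space) proxies the treatment-induced change.
    """
    if expression.shape[1] < 2:
        raise ValueError("surrogate changes need at least 2 samples")
    centered = expression.sub(expression.mean(axis=1), axis=0)
    return InducedChangeMatrix(centered, provenance="surrogate")


def derive_signatures(
    changes: InducedChangeMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    correct_fdr: bool = False,
) -> ResponseSignature:
    """Split genes into S/R signatures by rank-sum test on induced changes.

    Two-sided Wilcoxon rank-sum (Mann-Whitney U) per gene; exact null
    when both classes have <= 10 patients, tie-corrected normal
    approximation otherwise.  Genes with p < alpha are assigned S when
    the responder median change exceeds the non-responder median, R
    when it is lower; exact median ties are excluded and logged.

    ``correct_fdr=True`` applies Benjamini-Hochberg before the alpha
    cut (off by default; the reference procedure uses raw p-values).
    """
    labels = labels.loc[changes.values.columns]
    resp_cols = labels.index[labels == RESPONDER]
    nonresp_cols = labels.index[labels == NON_RESPONDER]
    if len(resp_cols) < 2 or len(nonresp_cols) < 2:
        raise ValueError("need >= 2 patients per response class")

    x = changes.values[resp_cols].to_numpy(dtype=float)
    y = changes.values[nonresp_cols].to_numpy(dtype=float)
    method = "exact" if max(x.shape[1], y.shape[1]) <= 10 else "asymptotic"
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided", method=method)
    p = np.asarray(res.pvalue, dtype=float)
    # constant genes (all patients identical) have a degenerate null: p = 1
    combined = np.concatenate([x, y], axis=1)
    constant = np.ptp(combined, axis=1) == 0
    p[constant] = 1.0
    p[~np.isfinite(p)] = 1.0
    if correct_fdr:
        p = stats.false_discovery_control(p, method="bh")

    med_diff = np.median(x, axis=1) - np.median(y, axis=1)
    sig = p < alpha
    tied = sig & (med_diff == 0)
    if tied.any():
        logger.info(
            "excluding %d significant genes with exactly tied medians", int(tied.sum())
        )
    keep = sig & ~tied
    genes = changes.values.index[keep]
    entries = pd.DataFrame(
        {
            "direction": np.where(med_diff[keep] > 0, "S", "R"),
            "p_value": p[keep],
            "median_diff": med_diff[keep],
        },
        index=genes,
    )
    return ResponseSignature(
        entries=entries,
        alpha=alpha,
        excluded_ties=tuple(changes.values.index[tied].tolist()),
    )


def signature_score(
    changes: InducedChangeMatrix,
    signature: ResponseSignature,
    part: Literal["S", "R", "combined"] = "combined",
) -> pd.Series:
    """Signature-average score per sample.

    S (R) mode: mean induced change over the S (R) genes present in the
    matrix.  Combined mode: mean-S minus mean-R, so that high values
    point to a sensitive (responder-like) induced state.
    """
    def _mean(genes: Sequence[str], name: str) -> pd.Series:
        present = changes.values.index.intersection(genes)
        if len(present) == 0:
            raise ValueError(
                f"no {name} signature genes present in matrix; missing: {list(genes)[:10]}"
            )
        return changes.values.loc[present].mean(axis=0)

    if part == "S":
        return _mean(signature.s_genes, "S")
    if part == "R":
        return _mean(signature.r_genes, "R")
    if part == "combined":
        return _mean(signature.s_genes, "S") - _mean(signature.r_genes, "R")
    raise ValueError("part must be 'S', 'R' or 'combined'")


def pca_response_score(
    matrix: pd.DataFrame,
    signature: ResponseSignature | None = None,
) -> pd.Series:
    """Per-sample response score: projection on the first principal axis.

    The genes x samples matrix is gene-centered (no unit-variance
    scaling).  The PC sign is arbitrary, so orientation is fixed
    deterministically: when a signature is supplied the score is made
    to correlate non-negatively with the combined signature score of
    the same matrix; otherwise the loading entry of largest magnitude
    is made positive.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(X.var(axis=0).sum(), 0):
        raise ValueError("zero-variance matrix has no principal axis")
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(X)[:, 0]
    loadings = pca.components_[0]
    flip = False
    if signature is not None:
        combined = signature_score(
            InducedChangeMatrix(matrix, provenance="surrogate"), signature, "combined"
        ).to_numpy()
        c = np.corrcoef(scores, combined)[0, 1]
        if np.isfinite(c) and c < 0:
            flip = True
    else:
        if loadings[np.argmax(np.abs(loadings))] < 0:
            flip = True
    if flip:
        scores = -scores
    return pd.Series(scores, index=matrix.columns)


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray,
            positive: str = RESPONDER) -> RocResult:
    """ROC AUC of ``scores`` against binary labels.

    Equals the fraction of (positive, negative) pairs ranked
    concordantly, ties counted 1/2.  Also returns the ROC point
    sequence.
    """
    y = np.asarray(pd.Series(labels) == positive, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr)
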