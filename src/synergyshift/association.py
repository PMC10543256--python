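"""Immune and survival association of signatures and targets in
pan-cancer patient cohorts.

Immune activation per sample is profiled by ssGSEA over a collection
of immune-response gene signatures whose scores are averaged within
immunity classes.  Gene or signature expression is then correlated
(Pearson and Spearman, per cancer type) with these class scores or
with precomputed immune-infiltration estimates.  Survival association
uses single-covariate Cox proportional-hazards fits on the
progression-free interval and a log-rank test between the top and
bottom score tertiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .enrichment import GeneSet, ssgsea_matrix

logger = logging.getLogger(__name__)

ALPHA = 0.05


def immune_class_scores(
    expression: pd.DataFrame,
    signatures: Sequence[GeneSet],
    class_of: Mapping[str, str],
    exponent: float = 0.25,
) -> pd.DataFrame:
    """Per-sample immunity-class scores.

    ssGSEA per signature and sample, then the arithmetic mean over the
    signatures belonging to each immunity class.  Signatures without
    overlap are dropped (warned) inside :func:`ssgsea_matrix`;
    signatures lacking a class label are ignored with a warning.

    Returns samples x classes DataFrame.
    """
    scores = ssgsea_matrix(expression, signatures, exponent=exponent)
    cols = {}
    for sid in scores.columns:
        cls = class_of.get(sid)
        if cls is None:
            logger.warning("signature %r has no immunity class; ignored", sid)
            continue
        cols.setdefault(cls, []).append(sid)
    out = pd.DataFrame(
        {cls: scores[sids].mean(axis=1) for cls, sids in sorted(cols.items())}
    )
    return out


def correlate_with_immunity(
    statistic: pd.Series,
    immunity: pd.DataFrame | pd.Series,
    cancer_types: pd.Series,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Correlate a per-sample statistic with immune read-outs by cancer type.

    Both Pearson (linear) and Spearman (rank) coefficients are
    reported, with flags at p < alpha.  Types with fewer than 3
    samples, or with a constant variable, are excluded with a reason.

    Returns a tidy frame: one row per (cancer_type, immune variable)
    with columns pearson_r/p, spearman_rho/p, n, significant, sign,
    excluded_reason.
    """
    if isinstance(immunity, pd.Series):
        immunity = immunity.to_frame(immunity.name or "immunity")
    rows = []
    for ct in sorted(cancer_types.unique()):
        samples = cancer_types.index[cancer_types == ct]
        x = statistic.loc[samples].to_numpy(dtype=float)
        for var in immunity.columns:
            y = immunity.loc[samples, var].to_numpy(dtype=float)
            row = {"cancer_type": ct, "variable": var, "n": len(samples)}
            if len(samples) < 3:
                row.update(excluded_reason="too_few_samples")
            elif np.ptp(x) == 0 or np.ptp(y) == 0:
                row.update(excluded_reason="constant_input")
            else:
                pr = stats.pearsonr(x, y)
                sr = stats.spearmanr(x, y)
                row.update(
                    pearson_r=pr.statistic,
                    pearson_p=pr.pvalue,
                    spearman_rho=sr.statistic,
                    spearman_p=sr.pvalue,
                    significant=pr.pvalue < alpha,
                    sign=int(np.sign(pr.statistic)),
                    excluded_reason="",
                )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SurvivalResult:
    hazard_ratio: float
    coef: float
    p: float
    n: int
    n_events: int
    converged: bool
    reason: str = ""


def survival_association(
    score: pd.Series | np.ndarray,
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
) -> SurvivalResult:
    """Single-covariate Cox proportional-hazards fit (Efron ties).

    HR = exp(coefficient) per unit of ``score``; Wald p-value.  A
    degenerate covariate, absent events, or non-convergence yields a
    flagged result (``converged=False``) with NaN estimates instead of
    a fabricated hazard ratio.
    """
    df = pd.DataFrame(
        {
            "score": np.asarray(score, dtype=float),
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
        }
    )
    n, n_events = len(df), int(df["event"].sum())
    if n_events == 0:
        return SurvivalResult(np.nan, np.nan, np.nan, n, 0, False, "no_events")
    if np.ptp(df["score"].to_numpy()) == 0:
        return SurvivalResult(np.nan, np.nan, np.nan, n, n_events, False, "constant_covariate")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as e:  # lifelines raises ConvergenceError subclasses
        return SurvivalResult(np.nan, np.nan, np.nan, n, n_events, False, f"fit_failed: {e}")
    coef = float(cph.params_["score"])
    return SurvivalResult(
        hazard_ratio=float(np.exp(coef)),
        coef=coef,
        p=float(cph.summary.loc["score", "p"]),
        n=n,
        n_events=n_events,
        converged=True,
    )


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p: float
    group_sizes: tuple[int, int, int]  # (low, mid, high)


def tertile_logrank(
    score: pd.Series | np.ndarray,
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
) -> LogrankResult:
    """Log-rank test between the top and bottom score tertiles.

    Samples are split evenly into three groups by score order (stable
    sort; tied scores fall into the lower tertile; sizes differ by at
    most one, extra samples going to the lower groups).  The middle
    tertile is not tested.  If neither extreme group has any event the
    statistic is 0 and p = 1.
    """
    s = np.asarray(score, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    n = len(s)
    if n < 6:
        raise ValueError("tertile split needs at least 6 samples")
    order = np.argsort(s, kind="stable")
    thirds = np.array_split(order, 3)
    low, _, high = thirds
    if e[low].sum() == 0 and e[high].sum() == 0:
        return LogrankResult(0.0, 1.0, tuple(len(g) for g in thirds))
    res = logrank_test(t[high], t[low], event_observed_A=e[high], event_observed_B=e[low])
    chi2 = float(res.test_statistic)
    if not np.isfinite(chi2):
        chi2 = 0.0
    return LogrankResult(
        chi_square=chi2,
        p=float(res.p_value) if np.isfinite(res.p_value) else 1.0,
        group_sizes=tuple(len(g) for g in thirds),
    )
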