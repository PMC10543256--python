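"""Shift-ability screening of perturbation transcriptomes.

Each level-5-style perturbation profile (a per-gene z-score
differential signature for one compound or shRNA experiment) is ranked
descending and scored against the resistance (R) and sensitivity (S)
signatures with the weighted-KS enrichment score at weight 1.  The
shift ability of a perturbation p is

    shift_ability(p) = ES_S - ES_R

A large positive value means p suppresses the R signature (ES_R < 0)
while inducing the S signature (ES_S > 0) — an R-to-S shift toward an
anti-PD-1-sensitive transcriptional state.  Experiments with
shift ability >= 0.7 (inclusive) are called R-to-S shifters.

Downstream, targets are prioritized by concordance: a gene counts when
some efficient shRNA knockdown of it and some compound inhibiting it
both produce R-to-S calls in the same cell line, and its tumor
expression is negatively associated with immune activation in patient
cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet, RankedProfile, UnscorableSetError, weighted_ks_es

logger = logging.getLogger(__name__)

DEFAULT_TAS_MIN = 0.4
DEFAULT_SHIFT_THRESHOLD = 0.7
DEFAULT_KNOCKDOWN_PERCENTILE = 25.0


@dataclass
class PerturbationCompendium:
    """A level-5-style z-score matrix plus per-experiment metadata.

    ``values``: genes x experiments; ``meta``: indexed by experiment id
    with columns perturbagen_id, type ("compound" | "shRNA"), target,
    cell_line, dose, time, tas (in [0, 1]).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.columns.equals(self.meta.index):
            # allow same set, different order
            if set(self.values.columns) != set(self.meta.index):
                raise ValueError("metadata must cover exactly the value columns")
            self.meta = self.meta.loc[self.values.columns]
        tas = self.meta["tas"].to_numpy(dtype=float)
        if len(tas) and (not np.all(np.isfinite(tas)) or tas.min() < 0 or tas.max() > 1):
            raise ValueError("tas must be finite in [0, 1]")
        bad = self.meta[(self.meta["type"] == "shRNA") & (self.meta["target"].isna())]
        if len(bad):
            raise ValueError("shRNA profiles must carry a target gene")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset(self, experiments: Sequence[str]) -> "PerturbationCompendium":
        return PerturbationCompendium(
            self.values[list(experiments)], self.meta.loc[list(experiments)]
        )


@dataclass(frozen=True)
class ShiftResult:
    """ES pair and shift ability for one perturbation experiment."""

    experiment_id: str
    es_r: float
    es_s: float
    shift_ability: float
    r_suppressed: bool
    s_induced: bool
    r_to_s_call: bool = False


@dataclass(frozen=True)
class KnockdownAssessment:
    experiment_id: str
    target_gene: str
    target_z: float
    efficient: bool
    reason: str = ""


@dataclass
class TargetPriority:
    target_gene: str
    cell_lines_concordant: list[str] = field(default_factory=list)
    n_types_positive: int = 0
    n_types_negative: int = 0
    prioritized: bool = False


def filter_profiles(
    compendium: PerturbationCompendium,
    tas_min: float = DEFAULT_TAS_MIN,
    gene_universe: Sequence[str] | None = None,
) -> PerturbationCompendium:
    """Retain experiments with TAS >= tas_min (boundary inclusive) and
    restrict the gene space to ``gene_universe`` when given.

    Mirrors the compendium-level quality filter: level-5 signatures
    built from poorly reproducible replicates (low transcriptional
    activity score) are discarded, and scoring is confined to the
    reliably measured/inferred gene space.
    """
    keep = compendium.meta["tas"] >= tas_min
    kept = compendium.meta.index[keep]
    logger.info("TAS filter >= %.3g: kept %d / %d experiments", tas_min, len(kept), len(keep))
    values = compendium.values[kept]
    if gene_universe is not None:
        universe = pd.Index(gene_universe)
        missing = universe.difference(compendium.genes)
        if len(missing):
            raise ValueError(f"gene_universe genes absent from compendium: {list(missing)[:5]}")
        values = values.loc[universe]
    if len(kept) == 0:
        logger.warning("TAS filter removed every experiment")
    return PerturbationCompendium(values, compendium.meta.loc[kept])


def shift_ability(
    profile: pd.Series,
    r_sig: GeneSet,
    s_sig: GeneSet,
    experiment_id: str = "",
) -> ShiftResult:
    """ES_S - ES_R on the descending-ranked profile (weight-1 KS).

    Raises :class:`UnscorableSetError` naming the offending signature
    when either gene set has no overlap with the profile.
    """
    ranked = RankedProfile.from_series(profile)
    try:
        es_r = weighted_ks_es(ranked, r_sig, weight=1.0).es
    except UnscorableSetError as e:
        raise UnscorableSetError(f"R signature unscorable: {e}") from e
    try:
        es_s = weighted_ks_es(ranked, s_sig, weight=1.0).es
    except UnscorableSetError as e:
        raise UnscorableSetError(f"S signature unscorable: {e}") from e
    delta = es_s - es_r
    return ShiftResult(
        experiment_id=experiment_id or (profile.name if profile.name else ""),
        es_r=es_r,
        es_s=es_s,
        shift_ability=delta,
        r_suppressed=es_r < 0,
        s_induced=es_s > 0,
    )


def call_r_to_s(result: ShiftResult, threshold: float = DEFAULT_SHIFT_THRESHOLD) -> bool:
    """R-to-S call: shift ability >= threshold (inclusive)."""
    return bool(result.shift_ability >= threshold)


def screen_compendium(
    compendium: PerturbationCompendium,
    r_sig: GeneSet,
    s_sig: GeneSet,
    threshold: float = DEFAULT_SHIFT_THRESHOLD,
) -> pd.DataFrame:
    """Shift-ability table for every experiment, joined with metadata.

    Columns: es_r, es_s, shift_ability, r_suppressed, s_induced,
    r_to_s_call, plus the compendium metadata.
    """
    rows = []
    for exp_id in compendium.values.columns:
        res = shift_ability(compendium.values[exp_id], r_sig, s_sig, experiment_id=exp_id)
        rows.append(
            {
                "experiment_id": exp_id,
                "es_r": res.es_r,
                "es_s": res.es_s,
                "shift_ability": res.shift_ability,
                "r_suppressed": res.r_suppressed,
                "s_induced": res.s_induced,
                "r_to_s_call": call_r_to_s(res, threshold),
            }
        )
    out = pd.DataFrame(rows).set_index("experiment_id")
    return out.join(compendium.meta)


def assess_knockdown(
    profile: pd.Series,
    target_gene: str,
    panel: pd.DataFrame,
    q: float = DEFAULT_KNOCKDOWN_PERCENTILE,
    experiment_id: str = "",
) -> KnockdownAssessment:
    """Judge knockdown efficiency of an shRNA experiment.

    The target's z-score must be negative AND at or below the q-th
    percentile (linear interpolation) of that gene's values across the
    panel (experiments sharing the cell line).  Both criteria are
    configurable; a missing target gene yields ``efficient=False`` with
    a reason code rather than an error.
    """
    exp_id = experiment_id or (profile.name if profile.name else "")
    if target_gene not in profile.index:
        return KnockdownAssessment(exp_id, target_gene, np.nan, False, "target_absent")
    z = float(profile[target_gene])
    if target_gene not in panel.index:
        return KnockdownAssessment(exp_id, target_gene, z, False, "target_absent_from_panel")
    cut = float(np.percentile(panel.loc[target_gene].to_numpy(dtype=float), q))
    efficient = (z < 0) and (z <= cut)
    return KnockdownAssessment(exp_id, target_gene, z, efficient)


def assess_knockdowns(
    compendium: PerturbationCompendium,
    q: float = DEFAULT_KNOCKDOWN_PERCENTILE,
) -> pd.DataFrame:
    """Knockdown assessment for every shRNA experiment.

    The comparison panel for an experiment is all experiments in the
    same cell line (any perturbagen type).
    """
    shrna = compendium.meta[compendium.meta["type"] == "shRNA"]
    rows = []
    for exp_id, m in shrna.iterrows():
        panel_ids = compendium.meta.index[compendium.meta["cell_line"] == m["cell_line"]]
        ka = assess_knockdown(
            compendium.values[exp_id], str(m["target"]), compendium.values[panel_ids],
            q=q, experiment_id=exp_id,
        )
        rows.append(
            {
                "experiment_id": ka.experiment_id,
                "target_gene": ka.target_gene,
                "target_z": ka.target_z,
                "efficient": ka.efficient,
                "reason": ka.reason,
            }
        )
    return pd.DataFrame(rows).set_index("experiment_id")


def aggregate_perturbagen(
    results: pd.DataFrame,
    threshold: float = DEFAULT_SHIFT_THRESHOLD,
) -> pd.DataFrame:
    """Per perturbagen x cell line summary of shift results.

    Columns: mean_shift, frac_called (fraction of experiments with
    shift ability >= threshold), any_call, n_experiments.
    """
    grouped = results.groupby(["perturbagen_id", "cell_line"], sort=True)
    out = grouped["shift_ability"].agg(
        mean_shift="mean",
        frac_called=lambda s: float(np.mean(s >= threshold)),
        n_experiments="size",
    )
    out["any_call"] = out["frac_called"] > 0
    # carry type/target through (constant within perturbagen)
    extra = grouped[["type", "target"]].first()
    return out.join(extra)


def concordant_targets(
    compound_results: pd.DataFrame,
    shrna_results: pd.DataFrame,
    knockdowns: pd.DataFrame,
    drug_target_map: Mapping[str, Sequence[str]],
) -> list[TargetPriority]:
    """Targets whose genetic and pharmacological inhibition both shift.

    A target is retained iff there exists a cell line where (a) some
    shRNA experiment against the target makes an R-to-S call with an
    efficient knockdown, and (b) some compound mapped to the target
    makes an R-to-S call.  Compounds absent from ``drug_target_map``
    are skipped (counted in the log).
    """
    sh = shrna_results.join(knockdowns[["efficient"]], how="left")
    sh["efficient"] = sh["efficient"].fillna(False)
    good_sh = sh[sh["r_to_s_call"] & sh["efficient"]]
    sh_cells: dict[str, set[str]] = {}
    for _, row in good_sh.iterrows():
        sh_cells.setdefault(str(row["target"]), set()).add(str(row["cell_line"]))

    cpd_calls = compound_results[compound_results["r_to_s_call"]]
    cpd_cells: dict[str, set[str]] = {}
    n_unmapped = 0
    for _, row in cpd_calls.iterrows():
        pid = str(row["perturbagen_id"])
        targets = drug_target_map.get(pid)
        if not targets:
            n_unmapped += 1
            continue
        for t in targets:
            cpd_cells.setdefault(str(t), set()).add(str(row["cell_line"]))
    if n_unmapped:
        logger.info("skipped %d calling compound experiments with no target mapping", n_unmapped)

    out: list[TargetPriority] = []
    for target in sorted(set(sh_cells) & set(cpd_cells)):
        both = sorted(sh_cells[target] & cpd_cells[target])
        if both:
            out.append(TargetPriority(target_gene=target, cell_lines_concordant=both))
    return out


def prioritize_targets(
    candidates: Sequence[TargetPriority],
    immune_assoc: pd.DataFrame,
    min_types: int = 1,
    alpha: float = 0.05,
) -> list[TargetPriority]:
    """Keep candidates whose expression opposes immune activation.

    ``immune_assoc`` has one row per (target, cancer_type) with columns
    ``pearson_r`` and ``pearson_p``.  A candidate is prioritized when
    its expression is significantly negatively correlated (p < alpha,
    r < 0) with immune-activation scores in >= min_types cancer types
    (inhibiting the target then aligns with immune activation).
    Candidates absent from the association table are excluded.
    """
    out: list[TargetPriority] = []
    for cand in candidates:
        sub = immune_assoc[immune_assoc["target"] == cand.target_gene]
        if len(sub) == 0:
            logger.info("candidate %s absent from association table; excluded", cand.target_gene)
            continue
        sig = sub[sub["pearson_p"] < alpha]
        if "cancer_type" in sub.columns:
            # a type counts once even if several immunity classes agree
            n_neg = int(sig.loc[sig["pearson_r"] < 0, "cancer_type"].nunique())
            n_pos = int(sig.loc[sig["pearson_r"] > 0, "cancer_type"].nunique())
        else:
            n_neg = int((sig["pearson_r"] < 0).sum())
            n_pos = int((sig["pearson_r"] > 0).sum())
        out.append(
            TargetPriority(
                target_gene=cand.target_gene,
                cell_lines_concordant=list(cand.cell_lines_concordant),
                n_types_positive=n_pos,
                n_types_negative=n_neg,
                prioritized=n_neg >= min_types,
            )
        )
    return out
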