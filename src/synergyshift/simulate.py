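"""Synthetic study generators.

Every pipeline stage can be exercised without external downloads:
these generators emit data with the statistical structure the analysis
assumes, plus the planted ground truth needed for parameter-recovery
tests.

Three generators mirror the three data tiers of the study design:

* :func:`gen_paired_cohort` — a paired pre/on-treatment patient cohort
  with responder/non-responder labels and planted differential induced
  changes (S genes up in responders, R genes up in non-responders).
* :func:`gen_perturbation_compendium` — a level-5-style z-score
  perturbation compendium with planted R-suppressing / S-inducing
  perturbagens, shRNA knockdown effects on target genes, a TAS
  distribution, target-concordance structure, and planted mechanism
  modules for clustering.
* :func:`gen_pancancer_cohort` — a multi-cancer-type cohort in which a
  latent immune factor drives immune-signature genes and infiltration
  positively and planted anti-immune targets negatively, with
  exponential survival tied to the R-signature average.

Noise is independent Gaussian per gene: the downstream analysis is
built on rank and threshold statistics, for which Gaussian noise is
the neutral choice.  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet
from .screen import PerturbationCompendium
from .signatures import PairedCohort

__all__ = [
    "SyntheticTruth",
    "gene_universe",
    "gen_paired_cohort",
    "gen_perturbation_compendium",
    "gen_pancancer_cohort",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    planted_s_genes: list[str] = field(default_factory=list)
    planted_r_genes: list[str] = field(default_factory=list)
    gamma: dict[str, float] = field(default_factory=dict)          # perturbagen -> strength
    concordant_targets: list[str] = field(default_factory=list)
    shrna_only_targets: list[str] = field(default_factory=list)
    null_targets: list[str] = field(default_factory=list)
    drug_target_map: dict[str, list[str]] = field(default_factory=dict)
    mechanism_labels: dict[str, int] = field(default_factory=dict)  # compound -> mechanism
    mechanism_modules: dict[int, list[str]] = field(default_factory=dict)
    immune_classes: dict[str, str] = field(default_factory=dict)    # signature -> class
    immune_signatures: list[GeneSet] = field(default_factory=list)
    anti_immune_targets: list[str] = field(default_factory=list)
    decoy_targets: list[str] = field(default_factory=list)
    beta_survival: float = 0.0

    def __post_init__(self):
        if set(self.planted_s_genes) & set(self.planted_r_genes):
            raise ValueError("planted S and R gene sets must be disjoint")


def gene_universe(n_genes: int) -> list[str]:
    """Deterministic synthetic gene ids G00000, G00001, ..."""
    return [f"G{i:05d}" for i in range(n_genes)]


# ------------------------------------------------------- paired cohort

def gen_paired_cohort(
    n_resp: int = 20,
    n_nonresp: int = 20,
    n_genes: int = 2000,
    n_planted_per_direction: int = 200,
    effect: float = 1.5,
    noise_sd: float = 1.0,
    baseline_mean: float = 7.0,
    seed: int = 0,
    s_genes: Sequence[str] | None = None,
    r_genes: Sequence[str] | None = None,
) -> tuple[PairedCohort, SyntheticTruth]:
    """Paired pre/on-treatment cohort with planted induced changes.

    Pre-treatment expression (log2 units) is a per-gene baseline plus
    Gaussian noise.  On-treatment expression adds a per-patient induced
    change ``delta ~ N(0, noise_sd)``, shifted by ``+effect * noise_sd``
    on planted S genes for responders and on planted R genes for
    non-responders (``effect`` is therefore in noise-SD units).
    ``s_genes`` / ``r_genes`` override the planted sets (used when the
    cohort must share planted structure with a compendium).
    """
    if n_resp < 2 or n_nonresp < 2:
        raise ValueError("need >= 2 patients per class")
    genes = gene_universe(n_genes)
    rng = np.random.default_rng(seed)
    if s_genes is None or r_genes is None:
        if 2 * n_planted_per_direction > n_genes:
            raise ValueError("planted genes exceed the gene universe")
        picked = rng.choice(n_genes, size=2 * n_planted_per_direction, replace=False)
        s_genes = [genes[i] for i in picked[:n_planted_per_direction]]
        r_genes = [genes[i] for i in picked[n_planted_per_direction:]]
    s_genes, r_genes = list(s_genes), list(r_genes)

    patients = [f"P{i:03d}" for i in range(n_resp + n_nonresp)]
    labels = pd.Series(["R"] * n_resp + ["NR"] * n_nonresp, index=patients)
    n_pat = len(patients)

    baseline = rng.normal(baseline_mean, 1.0, size=n_genes)
    pre = baseline[:, None] + rng.normal(0, noise_sd, size=(n_genes, n_pat))
    delta = rng.normal(0, noise_sd, size=(n_genes, n_pat))
    gidx = pd.Index(genes)
    s_idx = gidx.get_indexer(s_genes)
    r_idx = gidx.get_indexer(r_genes)
    resp_mask = (labels == "R").to_numpy()
    delta[np.ix_(s_idx, np.where(resp_mask)[0])] += effect * noise_sd
    delta[np.ix_(r_idx, np.where(~resp_mask)[0])] += effect * noise_sd
    post = pre + delta

    cohort = PairedCohort(
        pre=pd.DataFrame(pre, index=genes, columns=patients),
        post=pd.DataFrame(post, index=genes, columns=patients),
        response=labels,
        scale="log2",
    )
    truth = SyntheticTruth(planted_s_genes=s_genes, planted_r_genes=r_genes)
    return cohort, truth


# ------------------------------------------------ perturbation compendium

def _tas_draw(rng: np.random.Generator, n: int, active: bool,
              tas_params: tuple[float, float], tas_floor_active: float) -> np.ndarray:
    """TAS reflects replicate reproducibility: transcriptionally active
    experiments sit above the retention floor, inert ones spread low."""
    if active:
        return tas_floor_active + (1 - tas_floor_active) * rng.beta(*tas_params, size=n)
    return rng.beta(2.0, 3.0, size=n)


def gen_perturbation_compendium(
    n_genes: int = 2000,
    n_signature_genes: int = 100,
    cell_lines: Sequence[str] = ("CL01", "CL02", "CL03"),
    n_targets: int = 20,
    n_concordant: int = 5,
    n_shrna_only: int = 5,
    n_extra_compounds: int = 170,
    frac_extra_shifting: float = 0.2,
    gamma: float = 2.0,
    gamma_map: Mapping[str, float] | None = None,
    n_mechanisms: int = 2,
    mechanism_module_size: int = 100,
    mechanism_strength: float = 2.0,
    knockdown_effect: float = -3.0,
    tas_params: tuple[float, float] = (6.0, 2.0),
    tas_floor_active: float = 0.4,
    noise_sd: float = 1.0,
    seed: int = 0,
    s_genes: Sequence[str] | None = None,
    r_genes: Sequence[str] | None = None,
) -> tuple[PerturbationCompendium, SyntheticTruth]:
    """Level-5-style z-score compendium with planted structure.

    Layout per cell line: one shRNA experiment per target gene and one
    compound experiment per target, plus ``n_extra_compounds``
    untargeted compounds.  Planted roles:

    * the first ``n_concordant`` targets: shRNA and the mapped compound
      both shift (strength ``gamma``) in every cell line, with an
      efficient knockdown;
    * the next ``n_shrna_only`` targets: only the shRNA shifts;
    * remaining targets: inert decoys;
    * the first ``round(frac_extra_shifting * n_extra_compounds)``
      extra compounds shift and carry a mechanism label (round-robin
      over ``n_mechanisms``); each mechanism adds
      ``+mechanism_strength`` to a dedicated gene module.

    Shifting means ``+gamma`` on planted S genes and ``-gamma`` on
    planted R genes on top of N(0, noise_sd) profile noise.  shRNA
    profiles additionally set their target gene to ``knockdown_effect``
    (plus small noise).  ``gamma_map`` overrides per-perturbagen
    strengths by id.
    """
    if n_concordant + n_shrna_only > n_targets:
        raise ValueError("planted target roles exceed n_targets")
    genes = gene_universe(n_genes)
    rng = np.random.default_rng(seed)

    n_reserved = 2 * n_signature_genes + n_targets + n_mechanisms * mechanism_module_size
    if n_reserved > n_genes:
        raise ValueError("gene universe too small for planted structure")
    picked = rng.choice(n_genes, size=n_reserved, replace=False)
    pos = 0
    if s_genes is None or r_genes is None:
        s_genes = [genes[i] for i in picked[pos:pos + n_signature_genes]]
        pos += n_signature_genes
        r_genes = [genes[i] for i in picked[pos:pos + n_signature_genes]]
        pos += n_signature_genes
    else:
        s_genes, r_genes = list(s_genes), list(r_genes)
        pos += 2 * n_signature_genes
    target_genes = [genes[i] for i in picked[pos:pos + n_targets]]
    pos += n_targets
    modules = {}
    for m in range(n_mechanisms):
        modules[m] = [genes[i] for i in picked[pos:pos + mechanism_module_size]]
        pos += mechanism_module_size

    gidx = pd.Index(genes)
    s_idx = gidx.get_indexer(s_genes)
    r_idx = gidx.get_indexer(r_genes)

    concordant = target_genes[:n_concordant]
    shrna_only = target_genes[n_concordant:n_concordant + n_shrna_only]
    null_targets = target_genes[n_concordant + n_shrna_only:]

    # perturbagen roster: strength per perturbagen id
    pert_gamma: dict[str, float] = {}
    drug_target_map: dict[str, list[str]] = {}
    mech_labels: dict[str, int] = {}

    shrna_ids, shrna_targets = [], []
    for i, t in enumerate(target_genes):
        pid = f"SH{i:04d}"
        shrna_ids.append(pid)
        shrna_targets.append(t)
        pert_gamma[pid] = gamma if (t in concordant or t in shrna_only) else 0.0

    tcpd_ids = []
    for i, t in enumerate(target_genes):
        pid = f"TCP{i:04d}"
        tcpd_ids.append(pid)
        drug_target_map[pid] = [t]
        pert_gamma[pid] = gamma if t in concordant else 0.0

    n_shift_extra = int(round(frac_extra_shifting * n_extra_compounds))
    extra_ids = []
    for i in range(n_extra_compounds):
        pid = f"CPD{i:04d}"
        extra_ids.append(pid)
        if i < n_shift_extra:
            pert_gamma[pid] = gamma
            mech_labels[pid] = i % n_mechanisms
        else:
            pert_gamma[pid] = 0.0
    if gamma_map:
        pert_gamma.update({k: float(v) for k, v in gamma_map.items()})

    # assemble experiments: one per perturbagen per cell line
    exp_ids, columns, meta_rows = [], [], []
    for cl in cell_lines:
        for pid, ptype, target in (
            [(p, "shRNA", t) for p, t in zip(shrna_ids, shrna_targets)]
            + [(p, "compound", drug_target_map[p][0]) for p in tcpd_ids]
            + [(p, "compound", None) for p in extra_ids]
        ):
            g = pert_gamma[pid]
            profile = rng.normal(0.0, noise_sd, size=n_genes)
            if g != 0.0:
                profile[s_idx] += g
                profile[r_idx] -= g
            mech = mech_labels.get(pid)
            if mech is not None and g != 0.0:
                profile[gidx.get_indexer(modules[mech])] += mechanism_strength
            if ptype == "shRNA":
                profile[gidx.get_loc(target)] = knockdown_effect + rng.normal(0, 0.3)
            exp_id = f"{pid}:{cl}"
            exp_ids.append(exp_id)
            columns.append(profile)
            active = g != 0.0 or ptype == "shRNA"
            meta_rows.append(
                {
                    "experiment_id": exp_id,
                    "perturbagen_id": pid,
                    "type": ptype,
                    "target": target,
                    "cell_line": cl,
                    "dose": 10.0,
                    "time": "24h",
                    "tas": float(
                        _tas_draw(rng, 1, active, tas_params, tas_floor_active)[0]
                    ),
                }
            )

    values = pd.DataFrame(
        np.column_stack(columns), index=genes, columns=exp_ids
    )
    meta = pd.DataFrame(meta_rows).set_index("experiment_id")
    comp = PerturbationCompendium(values=values, meta=meta)
    truth = SyntheticTruth(
        planted_s_genes=list(s_genes),
        planted_r_genes=list(r_genes),
        gamma=pert_gamma,
        concordant_targets=concordant,
        shrna_only_targets=shrna_only,
        null_targets=null_targets,
        drug_target_map=drug_target_map,
        mechanism_labels=mech_labels,
        mechanism_modules=modules,
    )
    return comp, truth


# --------------------------------------------------- pan-cancer cohort

@dataclass
class PancancerCohort:
    """Synthetic multi-type tumor cohort.

    ``expression``: genes x samples (log2-like units);
    ``clinical``: per-sample cancer_type, pfi_time, pfi_event;
    ``infiltration``: per-sample immune cell-type fraction estimates
    (consumed as input by the association stage, the way precomputed
    deconvolution estimates are).
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    infiltration: pd.DataFrame


def gen_pancancer_cohort(
    n_types: int = 5,
    n_per_type: int = 100,
    n_genes: int = 2000,
    n_immune_classes: int = 3,
    sigs_per_class: int = 2,
    genes_per_signature: int = 30,
    n_anti_immune: int = 5,
    n_decoy_targets: int = 15,
    immune_loading: float = 0.8,
    beta_survival: float = 0.7,
    baseline_hazard: float = 0.05,
    censor_rate: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
    s_genes: Sequence[str] | None = None,
    r_genes: Sequence[str] | None = None,
    n_signature_genes: int = 100,
    anti_immune_targets: Sequence[str] | None = None,
    decoy_targets: Sequence[str] | None = None,
) -> tuple[PancancerCohort, SyntheticTruth]:
    """Pan-cancer cohort with a latent immune factor and survival.

    Each sample carries a latent immune factor z ~ N(0,1) that loads
    positively (``immune_loading``) on the immune-signature genes and
    the infiltration columns, and negatively on the planted anti-immune
    target genes.  Planted S-signature genes track z positively and
    R-signature genes negatively (immune-hot vs immune-cold axes).
    Survival: exponential times with log-hazard
    ``beta_survival * z_R`` where z_R is the standardized per-sample
    mean deviation of R-signature genes from the cohort mean (exactly
    the covariate the analysis recomputes); censoring is independent
    exponential tuned to ``censor_rate``.
    """
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    genes = gene_universe(n_genes)
    gidx = pd.Index(genes)
    rng = np.random.default_rng(seed)

    n_needed = (
        n_immune_classes * sigs_per_class * genes_per_signature
        + (n_anti_immune if anti_immune_targets is None else 0)
        + (n_decoy_targets if decoy_targets is None else 0)
        + (0 if s_genes is not None else 2 * n_signature_genes)
    )
    if n_needed > n_genes:
        raise ValueError("gene universe too small for planted structure")
    picked = list(rng.choice(n_genes, size=n_needed, replace=False))
    pos = 0

    immune_sigs: list[GeneSet] = []
    class_of: dict[str, str] = {}
    for c in range(n_immune_classes):
        for s in range(sigs_per_class):
            sid = f"IMM_C{c}_S{s}"
            members = [genes[i] for i in picked[pos:pos + genes_per_signature]]
            pos += genes_per_signature
            immune_sigs.append(GeneSet(sid, members))
            class_of[sid] = f"class{c}"
    if anti_immune_targets is None:
        anti_immune = [genes[i] for i in picked[pos:pos + n_anti_immune]]
        pos += n_anti_immune
    else:
        anti_immune = list(anti_immune_targets)
    if decoy_targets is None:
        decoys = [genes[i] for i in picked[pos:pos + n_decoy_targets]]
        pos += n_decoy_targets
    else:
        decoys = list(decoy_targets)
    if s_genes is None or r_genes is None:
        s_genes = [genes[i] for i in picked[pos:pos + n_signature_genes]]
        pos += n_signature_genes
        r_genes = [genes[i] for i in picked[pos:pos + n_signature_genes]]
        pos += n_signature_genes
    s_genes, r_genes = list(s_genes), list(r_genes)

    samples, types = [], []
    for t in range(n_types):
        for i in range(n_per_type):
            samples.append(f"T{t:02d}S{i:04d}")
            types.append(f"CT{t:02d}")
    n_samp = len(samples)
    cancer_type = pd.Series(types, index=samples, name="cancer_type")

    z = rng.normal(0, 1, size=n_samp)  # latent immune factor
    baseline = rng.normal(7.0, 1.0, size=n_genes)
    expr = baseline[:, None] + rng.normal(0, noise_sd, size=(n_genes, n_samp))
    imm_gene_idx = gidx.get_indexer([m for gs in immune_sigs for m in gs.members])
    expr[imm_gene_idx, :] += immune_loading * z
    expr[gidx.get_indexer(anti_immune), :] -= immune_loading * z
    expr[gidx.get_indexer(s_genes), :] += 0.6 * immune_loading * z
    u = rng.normal(0, 1, size=n_samp)  # R axis partially opposed to immunity
    expr[gidx.get_indexer(r_genes), :] += -0.4 * immune_loading * z + 0.6 * u

    cell_types = ["cd8_t", "cd4_t", "dendritic", "macrophage", "nk"]
    infil = np.clip(
        0.2 + 0.08 * z[:, None] + rng.normal(0, 0.05, size=(n_samp, len(cell_types))),
        0.0, None,
    )
    infiltration = pd.DataFrame(infil, index=samples, columns=cell_types)

    expression = pd.DataFrame(expr, index=genes, columns=samples)

    # survival tied to the standardized mean R-gene deviation
    r_dev = (
        expression.loc[r_genes].sub(expression.loc[r_genes].mean(axis=1), axis=0).mean(axis=0)
    )
    z_r = (r_dev - r_dev.mean()) / r_dev.std(ddof=0)
    rate = baseline_hazard * np.exp(beta_survival * z_r.to_numpy())
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n_samp)
    else:
        t_cens = np.full(n_samp, np.inf)
    pfi_time = np.minimum(t_event, t_cens)
    pfi_event = (t_event <= t_cens).astype(int)
    clinical = pd.DataFrame(
        {"cancer_type": types, "pfi_time": pfi_time, "pfi_event": pfi_event},
        index=samples,
    )

    cohort = PancancerCohort(expression=expression, clinical=clinical, infiltration=infiltration)
    truth = SyntheticTruth(
        planted_s_genes=s_genes,
        planted_r_genes=r_genes,
        immune_classes=class_of,
        immune_signatures=immune_sigs,
        anti_immune_targets=anti_immune,
        decoy_targets=decoys,
        beta_survival=beta_survival,
    )
    return cohort, truth
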