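"""Config-driven orchestration of the full synthetic-study pipeline.

Stages run in method order: simulate inputs -> derive R/S signatures
from the paired cohort -> TAS-filter and shift-screen the perturbation
compendium -> knockdown assessment, target concordance and immune
prioritization -> consensus mechanism clustering and annotation ->
cohort immune/survival association.  Every numeric output file carries
a header with the config hash and seed; identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    correlate_with_immunity,
    immune_class_scores,
    survival_association,
    tertile_logrank,
)
from .enrichment import GeneSet
from .io import META_COLUMNS, write_gct, write_gmt, write_gctx, write_perturbation_meta
from .mechanism import (
    annotate_cluster,
    cluster_compounds,
    cluster_signature,
    consensus_vectors,
    make_indicators,
)
from .screen import (
    aggregate_perturbagen,
    assess_knockdowns,
    concordant_targets,
    filter_profiles,
    prioritize_targets,
    screen_compendium,
)
from .signatures import (
    compute_induced_changes,
    derive_signatures,
    pca_response_score,
    roc_auc,
    signature_score,
    surrogate_changes,
)
from .simulate import gen_paired_cohort, gen_pancancer_cohort, gen_perturbation_compendium

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with reference defaults.

    Thresholds carry the reference procedure's values: alpha 0.05 for
    the signature split, TAS >= 0.4 retention, R-to-S call at shift
    ability >= 0.7, +-1 indicator thresholds (fixed), and a 2-cluster
    mechanism cut (the dendrogram-height alternative is exposed via
    ``cluster_cutoff``).
    """

    seed: int = 0
    out_dir: str = "synergyshift_out"
    # signature derivation
    alpha: float = 0.05
    pseudocount: float = 1.0
    # screen
    tas_min: float = 0.4
    shift_threshold: float = 0.7
    knockdown_percentile: float = 25.0
    min_types: int = 1
    # clustering / annotation
    cluster_k: int = 2
    cluster_cutoff: float | None = None
    n_perm_annotation: int = 250
    ssgsea_exponent: float = 0.25
    # synthetic scale
    n_genes: int = 2000
    n_resp: int = 20
    n_nonresp: int = 20
    n_planted_per_direction: int = 200
    paired_effect: float = 1.5
    n_signature_genes_compendium: int = 100
    n_targets: int = 20
    n_concordant: int = 5
    n_shrna_only: int = 5
    n_extra_compounds: int = 170
    frac_extra_shifting: float = 0.2
    gamma: float = 2.0
    n_types: int = 5
    n_per_type: int = 100
    beta_survival: float = 0.7
    censor_rate: float = 0.3
    write_inputs: bool = True

    def validate(self) -> None:
        checks = [
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (self.pseudocount >= 0, "pseudocount must be >= 0"),
            (0 <= self.tas_min <= 1, "tas_min must be in [0, 1]"),
            (-2 <= self.shift_threshold <= 2, "shift_threshold must be in [-2, 2]"),
            (0 <= self.knockdown_percentile <= 100, "knockdown_percentile in [0, 100]"),
            (self.min_types >= 1, "min_types must be >= 1"),
            (self.cluster_k >= 2, "cluster_k must be >= 2"),
            (self.n_perm_annotation >= 0, "n_perm_annotation must be >= 0"),
            (self.ssgsea_exponent >= 0, "ssgsea_exponent must be >= 0"),
            (0 <= self.censor_rate < 1, "censor_rate must be in [0, 1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        """Hash over the scientific parameters (out_dir excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# synergyshift v{__version__}\n")
        fh.write(f"# config_sha256={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study; returns the machine-readable report.

    Any stage failure is re-raised annotated with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "config_sha256": config.hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        seed = int(config.seed)
        paired, paired_truth = gen_paired_cohort(
            n_resp=config.n_resp,
            n_nonresp=config.n_nonresp,
            n_genes=config.n_genes,
            n_planted_per_direction=config.n_planted_per_direction,
            effect=config.paired_effect,
            seed=seed,
        )
        comp, comp_truth = gen_perturbation_compendium(
            n_genes=config.n_genes,
            n_signature_genes=config.n_signature_genes_compendium,
            n_targets=config.n_targets,
            n_concordant=config.n_concordant,
            n_shrna_only=config.n_shrna_only,
            n_extra_compounds=config.n_extra_compounds,
            frac_extra_shifting=config.frac_extra_shifting,
            gamma=config.gamma,
            seed=seed + 1,
            s_genes=paired_truth.planted_s_genes[: config.n_signature_genes_compendium],
            r_genes=paired_truth.planted_r_genes[: config.n_signature_genes_compendium],
        )
        pancancer, pc_truth = gen_pancancer_cohort(
            n_types=config.n_types,
            n_per_type=config.n_per_type,
            n_genes=config.n_genes,
            beta_survival=config.beta_survival,
            censor_rate=config.censor_rate,
            seed=seed + 2,
            s_genes=paired_truth.planted_s_genes,
            r_genes=paired_truth.planted_r_genes,
            # the screen's planted concordant targets are immune-suppressive
            # in patient tumors; decoy targets carry no immune loading
            anti_immune_targets=comp_truth.concordant_targets,
            decoy_targets=comp_truth.shrna_only_targets + comp_truth.null_targets,
        )
        report["stages"]["simulate"] = {
            "n_genes": config.n_genes,
            "n_patients": config.n_resp + config.n_nonresp,
            "n_experiments": int(comp.values.shape[1]),
            "n_tumor_samples": int(pancancer.expression.shape[1]),
        }
        if config.write_inputs:
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            write_gct(paired.pre, inputs / "paired_pre.gct")
            write_gct(paired.post, inputs / "paired_post.gct")
            write_gctx(comp.values, inputs / "compendium.gctx")
            write_perturbation_meta(comp.meta, inputs / "compendium_meta.tsv")
            write_gmt(pc_truth.immune_signatures, inputs / "immune_signatures.gmt")

        stage = "derive_signatures"
        changes = compute_induced_changes(paired, pseudocount=config.pseudocount)
        signature = derive_signatures(changes, paired.response, alpha=config.alpha)
        _write_table(signature.to_frame(), out / "signature.tsv", config)
        recovered_s = set(signature.s_genes) & set(paired_truth.planted_s_genes)
        recovered_r = set(signature.r_genes) & set(paired_truth.planted_r_genes)
        auc_induced = roc_auc(pca_response_score(changes.values, signature), paired.response).auc
        auc_naive = roc_auc(pca_response_score(paired.pre, signature), paired.response).auc
        report["stages"]["derive_signatures"] = {
            "n_s_genes": len(signature.s_genes),
            "n_r_genes": len(signature.r_genes),
            "planted_s_recovered": len(recovered_s),
            "planted_r_recovered": len(recovered_r),
            "auc_induced_pca": auc_induced,
            "auc_naive_pca": auc_naive,
        }

        stage = "screen"
        r_set = signature.gene_set("R")
        s_set = signature.gene_set("S")
        filtered = filter_profiles(comp, tas_min=config.tas_min)
        results = screen_compendium(filtered, r_set, s_set, threshold=config.shift_threshold)
        _write_table(results, out / "shift_results.tsv", config)
        kd = assess_knockdowns(filtered, q=config.knockdown_percentile)
        _write_table(kd, out / "knockdown_assessment.tsv", config)
        agg = aggregate_perturbagen(results, threshold=config.shift_threshold)
        _write_table(agg, out / "perturbagen_summary.tsv", config)
        report["stages"]["screen"] = {
            "n_experiments_kept": int(filtered.values.shape[1]),
            "n_experiments_dropped": int(comp.values.shape[1] - filtered.values.shape[1]),
            "n_r_to_s_calls": int(results["r_to_s_call"].sum()),
            "n_shifting_compounds": int(
                results.loc[
                    (results["type"] == "compound") & results["r_to_s_call"], "perturbagen_id"
                ].nunique()
            ),
        }

        stage = "prioritize"
        cpd_results = results[results["type"] == "compound"]
        sh_results = results[results["type"] == "shRNA"]
        candidates = concordant_targets(cpd_results, sh_results, kd, comp_truth.drug_target_map)
        class_scores = immune_class_scores(
            pancancer.expression,
            pc_truth.immune_signatures,
            pc_truth.immune_classes,
            exponent=config.ssgsea_exponent,
        )
        surrogate = surrogate_changes(pancancer.expression)
        assoc_frames = []
        for cand in candidates:
            if cand.target_gene not in surrogate.values.index:
                continue
            assoc = correlate_with_immunity(
                surrogate.values.loc[cand.target_gene],
                class_scores,
                pancancer.clinical["cancer_type"],
            )
            assoc.insert(0, "target", cand.target_gene)
            assoc_frames.append(assoc)
        immune_assoc = (
            pd.concat(assoc_frames, ignore_index=True)
            if assoc_frames
            else pd.DataFrame(columns=["target", "cancer_type", "pearson_r", "pearson_p"])
        )
        _write_table(immune_assoc, out / "target_immune_association.tsv", config, index=False)
        prioritized = prioritize_targets(candidates, immune_assoc, min_types=config.min_types)
        prio_df = pd.DataFrame(
            [
                {
                    "target_gene": p.target_gene,
                    "cell_lines_concordant": ",".join(p.cell_lines_concordant),
                    "n_types_positive": p.n_types_positive,
                    "n_types_negative": p.n_types_negative,
                    "prioritized": p.prioritized,
                }
                for p in prioritized
            ]
        )
        _write_table(prio_df, out / "prioritized_targets.tsv", config, index=False)
        report["stages"]["prioritize"] = {
            "n_concordant": len(candidates),
            "planted_concordant_recovered": len(
                {c.target_gene for c in candidates} & set(comp_truth.concordant_targets)
            ),
            "n_prioritized": int(prio_df["prioritized"].sum()) if len(prio_df) else 0,
            "planted_prioritized_recovered": len(
                {p.target_gene for p in prioritized if p.prioritized}
                & set(pc_truth.anti_immune_targets)
            ),
        }

        stage = "cluster"
        shifting = results[(results["type"] == "compound") & results["r_to_s_call"]]
        mech_report = {"n_shifting_experiments": int(len(shifting))}
        if shifting["perturbagen_id"].nunique() >= 2:
            profiles = filtered.values[shifting.index]
            indicators = make_indicators(profiles, shifting["perturbagen_id"])
            consensus = consensus_vectors(indicators)
            clustering = cluster_compounds(
                consensus, cutoff=config.cluster_cutoff, k=config.cluster_k
            )
            _write_table(clustering.labels.to_frame(), out / "cluster_labels.tsv", config)
            linkage_df = pd.DataFrame(
                clustering.linkage_matrix, columns=["left", "right", "height", "size"]
            )
            _write_table(linkage_df, out / "cluster_linkage.tsv", config, index=False)
            go_like = [
                GeneSet(f"MODULE_{m}", genes)
                for m, genes in comp_truth.mechanism_modules.items()
            ] + [GeneSet("IMMUNE_S_SIG", comp_truth.planted_s_genes)]
            annotations = []
            for cl in sorted(clustering.labels.unique()):
                members = clustering.labels.index[clustering.labels == cl]
                sig = cluster_signature(consensus, members, cluster_id=int(cl))
                _write_table(
                    sig.ranked.to_series().to_frame("consensus_median"),
                    out / f"cluster_{cl}_signature.tsv",
                    config,
                )
                for res in annotate_cluster(
                    sig, go_like, n_perm=config.n_perm_annotation, seed=config.seed + 10 + int(cl)
                ):
                    annotations.append(
                        {
                            "cluster": int(cl),
                            "set_id": res.set_id,
                            "es": res.es,
                            "nes": res.nes,
                            "p_nominal": res.p_nominal,
                            "fdr": res.fdr,
                        }
                    )
            _write_table(
                pd.DataFrame(annotations), out / "cluster_annotation.tsv", config, index=False
            )
            mech_report["n_clusters"] = int(clustering.labels.nunique())
        else:
            logger.warning("fewer than 2 shifting compounds; clustering skipped")
            mech_report["n_clusters"] = 0
        report["stages"]["cluster"] = mech_report

        stage = "associate"
        r_score = signature_score(surrogate, signature, "R")
        s_score = signature_score(surrogate, signature, "S")
        assoc_rows = []
        for name, sc in (("R_signature", r_score), ("S_signature", s_score)):
            assoc = correlate_with_immunity(
                sc,
                pd.concat([class_scores, pancancer.infiltration], axis=1),
                pancancer.clinical["cancer_type"],
            )
            assoc.insert(0, "score", name)
            assoc_rows.append(assoc)
        _write_table(
            pd.concat(assoc_rows, ignore_index=True),
            out / "signature_immune_association.tsv",
            config,
            index=False,
        )
        surv_rows = []
        for name, sc in (("R_signature", r_score), ("S_signature", s_score)):
            sr = survival_association(
                sc, pancancer.clinical["pfi_time"], pancancer.clinical["pfi_event"]
            )
            lr = tertile_logrank(
                sc, pancancer.clinical["pfi_time"], pancancer.clinical["pfi_event"]
            )
            surv_rows.append(
                {
                    "score": name,
                    "hazard_ratio": sr.hazard_ratio,
                    "coef": sr.coef,
                    "cox_p": sr.p,
                    "converged": sr.converged,
                    "logrank_chi2": lr.chi_square,
                    "logrank_p": lr.p,
                }
            )
        _write_table(pd.DataFrame(surv_rows), out / "survival_association.tsv", config, index=False)
        report["stages"]["associate"] = {
            "r_signature_hr": surv_rows[0]["hazard_ratio"],
            "s_signature_hr": surv_rows[1]["hazard_ratio"],
        }
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def validate_formats(paths: list[str | Path]) -> list[dict]:
    """Diagnostic format conformity checks; returns a list of findings.

    Each finding: {"path", "level" ("error" | "warning"), "message"}.
    An empty list means every file conformed.
    """
    findings: list[dict] = []

    def flag(path, msg, level="error"):
        findings.append({"path": str(path), "level": level, "message": msg})

    for p in paths:
        p = Path(p)
        if not p.exists():
            flag(p, "file does not exist")
            continue
        suffix = p.suffix.lower()
        try:
            if suffix == ".gct":
                with open(p) as fh:
                    first = fh.readline().strip()
                    if first not in ("#1.2", "#1.3"):
                        flag(p, f"missing GCT version line (got {first!r})")
                        continue
                    dims = fh.readline().split()
                    want = 2 if first == "#1.2" else 4
                    if len(dims) < want or not all(d.isdigit() for d in dims[:want]):
                        flag(p, "malformed GCT dimension line")
            elif suffix == ".gctx":
                with h5py.File(p, "r") as f:
                    for ds in ("0/DATA/0/matrix", "0/META/ROW/id", "0/META/COL/id"):
                        if ds not in f:
                            flag(p, f"GCTX missing dataset {ds}")
            elif suffix == ".gmt":
                with open(p) as fh:
                    for ln, line in enumerate(fh, 1):
                        if line.strip() and len(line.rstrip("\n").split("\t")) < 3:
                            flag(p, f"line {ln}: GMT needs >= 3 tab-separated fields")
                            break
            elif suffix in (".tsv", ".txt"):
                header = pd.read_csv(p, sep="\t", nrows=0, comment="#")
                if "experiment_id" in header.columns or "tas" in header.columns:
                    missing = set(META_COLUMNS) - set(header.columns)
                    if missing:
                        flag(p, f"metadata TSV lacks columns {sorted(missing)}")
            else:
                flag(p, f"unrecognized extension {suffix!r}", level="warning")
        except Exception as e:
            flag(p, f"unreadable: {e}")
    return findings
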