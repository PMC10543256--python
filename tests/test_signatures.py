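"""Signature derivation: fold changes, the rank-sum split, scoring and
classification arithmetic."""

import numpy as np
import pandas as pd
import pytest

from synergyshift import (
    InducedChangeMatrix,
    PairedCohort,
    ResponseSignature,
    compute_induced_changes,
    derive_signatures,
    gen_paired_cohort,
    pca_response_score,
    roc_auc,
    signature_score,
    surrogate_changes,
)

from oracles import pair_count_auc


def _cohort(pre, post, labels, scale="linear"):
    genes = [f"g{i}" for i in range(pre.shape[0])]
    patients = [f"p{i}" for i in range(pre.shape[1])]
    return PairedCohort(
        pre=pd.DataFrame(pre, index=genes, columns=patients),
        post=pd.DataFrame(post, index=genes, columns=patients),
        response=pd.Series(labels, index=patients),
        scale=scale,
    )


class TestInducedChanges:
    def test_identity_gives_zero(self):
        pre = np.full((3, 4), 5.0)
        c = _cohort(pre, pre.copy(), ["R", "R", "NR", "NR"])
        out = compute_induced_changes(c, pseudocount=0.0)
        assert np.allclose(out.values.to_numpy(), 0.0)
        assert out.provenance == "paired"

    def test_linear_fold_change(self):
        pre = np.full((2, 4), 4.0)
        post = np.full((2, 4), 16.0)
        c = _cohort(pre, post, ["R", "R", "NR", "NR"])
        out = compute_induced_changes(c, pseudocount=0.0)
        assert np.allclose(out.values.to_numpy(), 2.0)

    def test_pseudocount_rescues_zero(self):
        pre = np.full((2, 4), 0.0)
        post = np.full((2, 4), 3.0)
        c = _cohort(pre, post, ["R", "R", "NR", "NR"])
        out = compute_induced_changes(c, pseudocount=1.0)
        assert np.allclose(out.values.to_numpy(), 2.0)  # log2(4/1)
        with pytest.raises(ValueError, match="pseudocount"):
            compute_induced_changes(c, pseudocount=0.0)

    def test_log2_scale_exponentiated_first(self):
        pre = np.full((2, 4), 2.0)   # linear 4
        post = np.full((2, 4), 4.0)  # linear 16
        c = _cohort(pre, post, ["R", "R", "NR", "NR"], scale="log2")
        out = compute_induced_changes(c, pseudocount=0.0)
        assert np.allclose(out.values.to_numpy(), 2.0)


class TestDeriveSignatures:
    def test_no_separation_gives_empty_signature(self):
        rng = np.random.default_rng(0)
        patients = [f"p{i}" for i in range(12)]
        # identical change distribution in both classes, gene by gene
        half = rng.normal(0, 1, size=(30, 6))
        vals = np.concatenate([half, half], axis=1)
        changes = InducedChangeMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(30)], columns=patients),
            "paired",
        )
        labels = pd.Series(["R"] * 6 + ["NR"] * 6, index=patients)
        sig = derive_signatures(changes, labels)
        assert len(sig.entries) == 0

    def test_complete_separation_exact_p(self, tiny_changes):
        changes, labels = tiny_changes
        sig = derive_signatures(changes, labels)
        assert "gA" in sig.s_genes
        assert sig.entries.loc["gA", "p_value"] == pytest.approx(2 / 252, abs=1e-12)

    def test_label_symmetry_swaps_s_and_r(self):
        rng = np.random.default_rng(3)
        patients = [f"p{i}" for i in range(12)]
        vals = rng.normal(0, 1, size=(80, 12))
        vals[:10, :6] += 2.0  # planted separation
        changes = InducedChangeMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(80)], columns=patients),
            "paired",
        )
        labels = pd.Series(["R"] * 6 + ["NR"] * 6, index=patients)
        swapped = labels.map({"R": "NR", "NR": "R"})
        sig = derive_signatures(changes, labels)
        sig_sw = derive_signatures(changes, swapped)
        assert set(sig.s_genes) == set(sig_sw.r_genes)
        assert set(sig.r_genes) == set(sig_sw.s_genes)

    def test_constant_gene_never_selected(self):
        patients = [f"p{i}" for i in range(8)]
        vals = np.vstack([np.zeros(8), np.r_[np.ones(4) * 3, np.zeros(4)]])
        changes = InducedChangeMatrix(
            pd.DataFrame(vals, index=["const", "sep"], columns=patients), "paired"
        )
        labels = pd.Series(["R"] * 4 + ["NR"] * 4, index=patients)
        sig = derive_signatures(changes, labels)
        assert "const" not in sig.entries.index
        assert "sep" in sig.s_genes

    def test_small_class_errors(self, tiny_changes):
        changes, labels = tiny_changes
        labels = labels.copy()
        labels[:] = "NR"
        labels.iloc[0] = "R"
        with pytest.raises(ValueError, match=">= 2"):
            derive_signatures(changes, labels)

    def test_planted_recovery_at_moderate_effect(self):
        cohort, truth = gen_paired_cohort(
            n_resp=20, n_nonresp=20, n_genes=2000, n_planted_per_direction=200,
            effect=1.5, seed=123,
        )
        changes = compute_induced_changes(cohort)
        sig = derive_signatures(changes, cohort.response)
        rec_s = set(sig.s_genes) & set(truth.planted_s_genes)
        rec_r = set(sig.r_genes) & set(truth.planted_r_genes)
        recovered = (len(rec_s) + len(rec_r)) / 400
        assert recovered >= 0.8
        # every recovered planted gene carries the planted direction
        assert not (set(sig.r_genes) & set(truth.planted_s_genes))
        assert not (set(sig.s_genes) & set(truth.planted_r_genes))


class TestSurrogateChanges:
    def test_mean_centering_example(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = surrogate_changes(expr)
        assert out.values.loc["g"].tolist() == [-1.0, 0.0, 1.0]
        assert out.provenance == "surrogate"

    def test_rows_are_mean_zero(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(5, 2, (40, 9)))
        out = surrogate_changes(expr)
        assert np.all(np.abs(out.values.mean(axis=1)) < 1e-9)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            surrogate_changes(pd.DataFrame([[1.0]], index=["g"], columns=["a"]))


def _toy_signature(s_genes, r_genes):
    entries = pd.DataFrame(
        {
            "direction": ["S"] * len(s_genes) + ["R"] * len(r_genes),
            "p_value": 0.01,
            "median_diff": [1.0] * len(s_genes) + [-1.0] * len(r_genes),
        },
        index=list(s_genes) + list(r_genes),
    )
    return ResponseSignature(entries=entries, alpha=0.05)


class TestSignatureScore:
    def test_worked_arithmetic(self):
        changes = InducedChangeMatrix(
            pd.DataFrame({"x": [1.0, 3.0, 2.0]}, index=["s1", "s2", "r1"]), "paired"
        )
        sig = _toy_signature(["s1", "s2"], ["r1"])
        assert signature_score(changes, sig, "S")["x"] == pytest.approx(2.0)
        assert signature_score(changes, sig, "R")["x"] == pytest.approx(2.0)
        assert signature_score(changes, sig, "combined")["x"] == pytest.approx(0.0)

    def test_all_zero_changes_score_zero(self):
        changes = InducedChangeMatrix(
            pd.DataFrame(np.zeros((4, 3)), index=["s1", "s2", "r1", "r2"]), "paired"
        )
        sig = _toy_signature(["s1", "s2"], ["r1", "r2"])
        for part in ("S", "R", "combined"):
            assert np.allclose(signature_score(changes, sig, part), 0.0)

    def test_combined_antisymmetric_under_set_swap(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(10)]
        changes = InducedChangeMatrix(
            pd.DataFrame(rng.normal(0, 1, (10, 6)), index=genes), "paired"
        )
        a = _toy_signature(genes[:4], genes[4:8])
        b = _toy_signature(genes[4:8], genes[:4])
        np.testing.assert_allclose(
            signature_score(changes, a, "combined"),
            -signature_score(changes, b, "combined"),
        )

    def test_missing_genes_error(self):
        changes = InducedChangeMatrix(pd.DataFrame({"x": [1.0, 1.0]}, index=["a", "b"]), "paired")
        sig = _toy_signature(["zz"], ["a"])
        with pytest.raises(ValueError, match="missing"):
            signature_score(changes, sig, "S")


class TestPcaResponseScore:
    def test_rank_one_matrix_recovers_factor(self):
        rng = np.random.default_rng(2)
        factor = rng.normal(0, 2, 8)
        loading = rng.normal(0, 1, 30)
        mat = pd.DataFrame(np.outer(loading, factor))
        scores = pca_response_score(mat)
        r = np.corrcoef(scores, factor)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_samples_get_identical_scores(self):
        rng = np.random.default_rng(4)
        col = rng.normal(0, 1, 20)
        other = rng.normal(0, 1, 20)
        mat = pd.DataFrame({"a": col, "b": col, "c": other})
        scores = pca_response_score(mat)
        assert scores["a"] == pytest.approx(scores["b"], abs=1e-10)

    def test_projection_variance_is_leading_eigenvalue(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.normal(0, 1, (15, 10)))
        scores = pca_response_score(mat)
        cov = np.cov(mat.to_numpy().T, rowvar=False)
        top = np.linalg.eigvalsh(cov)[-1]
        assert np.var(scores, ddof=1) == pytest.approx(top, abs=1e-9)

    def test_zero_variance_errors(self):
        mat = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValueError, match="variance"):
            pca_response_score(mat)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([3.0, 2.0, 1.0, 0.0], ["R", "R", "NR", "NR"])
        assert res.auc == pytest.approx(1.0)

    def test_all_ties_is_half(self):
        res = roc_auc([1.0, 1.0, 1.0, 1.0], ["R", "NR", "R", "NR"])
        assert res.auc == pytest.approx(0.5)

    def test_worked_example(self):
        res = roc_auc([0.9, 0.8, 0.4, 0.3], ["R", "NR", "R", "NR"])
        assert res.auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.1, 0.25, 0.5, 0.8, 1.3], size=n)  # forces ties
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            labels = np.where(y == 1, "R", "NR")
            assert roc_auc(scores, labels).auc == pytest.approx(
                pair_count_auc(scores, y == 1), abs=1e-12
            )

    def test_complement_property_without_ties(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(0, 1, 20)
        labels = np.where(rng.integers(0, 2, 20) == 1, "R", "NR")
        if (labels == "R").all() or (labels == "NR").all():
            labels[0] = "R"
            labels[1] = "NR"
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], ["R", "R"])
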