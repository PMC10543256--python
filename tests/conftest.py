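import numpy as np
import pandas as pd
import pytest

from synergyshift import GeneSet, RankedProfile


@pytest.fixture
def simple_profile():
    """Five genes with scores 5..1 — the worked-example substrate."""
    return RankedProfile.from_unsorted(
        ["g1", "g2", "g3", "g4", "g5"], [5.0, 4.0, 3.0, 2.0, 1.0]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_profile(rng, n):
    genes = [f"g{i}" for i in range(n)]
    scores = rng.normal(0, 1, size=n)
    return RankedProfile.from_unsorted(genes, scores)


def random_gene_set(rng, profile, size, set_id="S"):
    members = rng.choice(profile.gene_ids, size=size, replace=False)
    return GeneSet(set_id, members.tolist())


@pytest.fixture
def tiny_changes():
    """3 genes x 10 patients induced-change matrix with one planted
    fully-separated gene (gA higher in the 5 responders)."""
    from synergyshift import InducedChangeMatrix

    patients = [f"p{i}" for i in range(10)]
    labels = pd.Series(["R"] * 5 + ["NR"] * 5, index=patients)
    rng = np.random.default_rng(7)
    vals = rng.normal(0, 1, size=(3, 10))
    vals[0, :5] = [2.0, 2.5, 3.0, 2.2, 2.8]   # responders
    vals[0, 5:] = [0.1, -0.3, 0.5, 0.0, -0.1]  # non-responders
    changes = InducedChangeMatrix(
        pd.DataFrame(vals, index=["gA", "gB", "gC"], columns=patients), "paired"
    )
    return changes, labels
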