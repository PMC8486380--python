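import logging

import dendropy
import numpy as np
import pytest

from lewontin import phylo_comparative as pc
from lewontin import synthetic_data as sd

logging.getLogger("lewontin").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def three_tip_tree() -> dendropy.Tree:
    """((A:1,B:1):1,C:2); — covariance computable by hand."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture(scope="session")
def medium_tree() -> dendropy.Tree:
    return sd.simulate_tree(50, birth_rate=0.1, seed=42)


@pytest.fixture(scope="session")
def small_dataset() -> sd.SyntheticDataset:
    return sd.simulate_dataset(sd.SimConfig(n_taxa=60, seed=7))


def make_mixed_model_data(tree, beta, lam, total_sd, seed, intercept=-2.7):
    """Draw (y, x, C) from the mixed model itself (exact MVN phylo effect)."""
    cov = pc.phylo_covariance(sd.scale_tree_to_unit_height(tree))
    n = len(cov.labels)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov.matrix + 1e-10 * np.eye(n))
    u = np.sqrt(lam) * total_sd * (chol @ rng.standard_normal(n))
    e = np.sqrt(1.0 - lam) * total_sd * rng.standard_normal(n)
    x = rng.uniform(4.0, 14.0, n)
    y = intercept + beta * x + u + e
    return y, x, cov
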