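import numpy as np
import pandas as pd
import pytest

import imodkit as ik
from imodkit.io import ExpressionMatrix, center_to_reference


@pytest.fixture(scope="session")
def small_truth():
    """5 planted components in 500 genes, 10 members each."""
    return ik.generate_truth(
        n_genes=500, n_components=5, members_per_component=10,
        member_weight=1.0, background_sigma=0.05, noise_sigma=0.05, seed=7,
    )


@pytest.fixture(scope="session")
def small_design():
    return ik.default_design(n_conditions=10, replicates_per_condition=2)


@pytest.fixture(scope="session")
def small_compendium(small_truth, small_design):
    """Centered noisy compendium over the small truth; activities attached."""
    rng = np.random.default_rng(7)
    effects = {
        c: rng.normal(0, 8, small_truth.n_components)
        for c in small_design.conditions
    }
    A = ik.generate_activities(
        small_truth, small_design, effects, replicate_sigma=1.0, seed=8
    )
    X = ik.synthesize_compendium(small_truth, A, small_design, seed=9)
    Xc = center_to_reference(
        ExpressionMatrix(X), small_design.reference_samples()
    )
    return Xc


@pytest.fixture(scope="session")
def small_decomposition(small_compendium):
    cfg = ik.IcaConfig(n_runs=10, fixed_dim=5, base_seed=0)
    return ik.decompose(small_compendium, cfg)


def greedy_match(true_M: np.ndarray, est_M: np.ndarray):
    """Greedy bijective matching of components by |Pearson|; returns the
    list of matched correlations, one per true component."""
    k, m = true_M.shape[1], est_M.shape[1]
    C = np.abs(
        np.array(
            [
                [np.corrcoef(true_M[:, i], est_M[:, j])[0, 1] for j in range(m)]
                for i in range(k)
            ]
        )
    )
    matches = []
    used_i, used_j = set(), set()
    for _ in range(min(k, m)):
        best = -1.0
        bi = bj = -1
        for i in range(k):
            if i in used_i:
                continue
            for j in range(m):
                if j in used_j:
                    continue
                if C[i, j] > best:
                    best, bi, bj = C[i, j], i, j
        used_i.add(bi)
        used_j.add(bj)
        matches.append(best)
    return matches
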