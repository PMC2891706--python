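import numpy as np
import pytest

from placa.expression_data import (ConditionSummary, ExpressionDataset,
                                   PerturbationPanel)


def dataset_from_means(A, G, logA=None, logG=None, dA=None, dG=None,
                       signs=None, n_rep=3):
    """Build a small ExpressionDataset directly from summary arrays."""
    A = np.asarray(A, dtype=float)
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    logA = np.log(A) if logA is None else np.asarray(logA, dtype=float)
    logG = np.log(G) if logG is None else np.asarray(logG, dtype=float)
    dA = np.full(m, 0.1) if dA is None else np.asarray(dA, dtype=float)
    dG = np.full((n, m), 0.1) if dG is None else np.asarray(dG, dtype=float)
    signs = (-1,) * n if signs is None else tuple(signs)
    panel = PerturbationPanel(components=tuple(f"C{j+1}" for j in range(n)),
                              signs=signs)
    nr = np.full(m, float(n_rep))
    return ExpressionDataset(
        genes=tuple(f"g{k+1}" for k in range(m)),
        baseline=ConditionSummary(A, logA, dA, nr),
        perturbed=tuple(ConditionSummary(G[j], logG[j], dG[j], nr)
                        for j in range(n)),
        panel=panel,
    )


@pytest.fixture
def toy_dataset():
    """3 genes x 2 perturbations, each gene a clean reporter of one component."""
    A = np.array([2.0, 1.0, 4.0])
    G = np.array([[1.0, 1.0, 4.0],
                  [2.0, 0.5, 4.0]])
    return dataset_from_means(A, G)


@pytest.fixture
def rich_dataset():
    """6 genes x 3 perturbations with distinct responses; invertible system."""
    rng = np.random.default_rng(42)
    A = rng.uniform(1.0, 5.0, size=6)
    resp = np.eye(3).repeat(2, axis=1) * 0.6  # two clean reporters/component
    resp += rng.uniform(-0.05, 0.05, size=(3, 6))
    G = A[None, :] * (1.0 - resp)
    return dataset_from_means(A, G)
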