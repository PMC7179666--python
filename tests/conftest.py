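import numpy as np
import pytest

from tritask.data_io import AssociationMatrices
from tritask.model import Hyperparams, ModelState


@pytest.fixture
def tiny_association_file(tmp_path):
    path = tmp_path / "assoc.tsv"
    path.write_text(
        "# comment line\n"
        "r1\td1\ttherapeutic\n"
        "r1\td2\tmarker/mechanism\n"
        "r2\td1\ttherapeutic\n"
    )
    return path


@pytest.fixture
def tiny_matrices():
    return AssociationMatrices(
        A_p=np.array([[1.0, 0.0], [1.0, 0.0]]),
        A_n=np.array([[0.0, 1.0], [0.0, 0.0]]),
        drug_index=["r1", "r2"],
        disease_index=["d1", "d2"],
    )


def random_state(rng, m, n, k, rho=1.0):
    """Random but shape-consistent optimizer state for update/objective tests."""
    return ModelState(
        U=rng.normal(size=(m, k)),
        V=rng.normal(size=(n, k)),
        R_p=rng.normal(size=(k, k)),
        R_n=rng.normal(size=(k, k)),
        J=rng.normal(size=(n, k)),
        W=rng.normal(size=(m, k)),
        Y=rng.normal(size=(n, k)),
        Z=rng.normal(size=(m, k)),
        rho1=rho,
        rho2=rho,
    )


def random_laplacian(rng, n):
    W = rng.uniform(0, 1, size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 1.0)
    return np.diag(W.sum(axis=1)) - W


@pytest.fixture
def small_problem():
    """5x4 instance with k=2: matrices, Laplacians and hyperparameters."""
    rng = np.random.default_rng(7)
    m, n, k = 5, 4, 2
    A_p = (rng.random((m, n)) < 0.4).astype(float)
    A_n = ((rng.random((m, n)) < 0.4) & (A_p == 0)).astype(float)
    L_U = random_laplacian(rng, m)
    L_V = random_laplacian(rng, n)
    hyper = Hyperparams(k=k, alpha=0.7, beta=1.3, lam=0.5, seed=7)
    state = random_state(rng, m, n, k, rho=1.5)
    return A_p, A_n, L_U, L_V, hyper, state
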