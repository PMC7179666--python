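"""Offline synthetic instances with planted shared low-rank structure.

Both binary matrices derive from ONE pair of nonnegative entity factors with
type-specific coefficient matrices, so the two link types genuinely share
latent structure; link-type exclusivity is enforced by assigning each cell to
the type with the higher planted score.  Similarity matrices are built from
the same planted factors (plus optional perturbation) so the Laplacian
regularizers carry real signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from tritask.data_io import AssociationMatrices
from tritask.similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Generation settings; see :func:`generate`."""

    m: int = 150
    n: int = 200
    k_true: int = 5
    density_p: float = 0.02
    density_n: float = 0.04
    noise: float = 0.0
    sim_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 2:
            raise ValueError("need at least 2 entities per side")
        if not (0 < self.k_true < min(self.m, self.n)):
            raise ValueError(f"k_true={self.k_true} must be in (0, min(m, n))")
        if min(self.density_p, self.density_n) <= 0:
            raise ValueError("densities must be positive")
        if self.density_p + self.density_n > 1:
            raise ValueError("density_p + density_n must not exceed 1 (exclusivity)")
        if not (0 <= self.noise < 0.5):
            raise ValueError("noise must be in [0, 0.5)")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be nonnegative")


@dataclass
class SyntheticInstance:
    """Generated dataset plus the planted ground truth."""

    matrices: AssociationMatrices
    W_r: SimilarityMatrix
    W_d: SimilarityMatrix
    U_true: np.ndarray
    V_true: np.ndarray
    R_p_true: np.ndarray
    R_n_true: np.ndarray
    scores_p: np.ndarray
    scores_n: np.ndarray


def _cosine_similarity(F: np.ndarray, rng: np.random.Generator, sim_noise: float) -> np.ndarray:
    """Cosine similarity of nonnegative factor rows, optionally perturbed."""
    norms = np.linalg.norm(F, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    S = (F @ F.T) / np.outer(norms, norms)
    if sim_noise > 0:
        E = rng.normal(0.0, sim_noise, size=S.shape)
        S = S + (E + E.T) / 2
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S


def generate(spec: SyntheticSpec) -> SyntheticInstance:
    """Draw one synthetic instance from the planted-factor model.

    Cells are assigned to the link type with the larger planted score; within
    each type's cells the top ``density * m * n`` scores become 1-entries.
    ``noise`` flips each 1 off with that probability and re-lights a matched
    number of dark cells (dark in BOTH matrices, so exclusivity survives).
    """
    rng = np.random.default_rng(spec.seed)
    m, n, k = spec.m, spec.n, spec.k_true
    U = rng.uniform(0.0, 1.0, size=(m, k))
    V = rng.uniform(0.0, 1.0, size=(n, k))
    R_p = rng.uniform(0.0, 1.0, size=(k, k))
    R_n = rng.uniform(0.0, 1.0, size=(k, k))
    S_p = U @ R_p @ V.T
    S_n = U @ R_n @ V.T

    # compare within-type percentile ranks: raw scores of the two types have
    # arbitrary relative scale, which would hand every cell to one type
    P_p = rankdata(S_p.ravel()).reshape(m, n)
    P_n = rankdata(S_n.ravel()).reshape(m, n)
    prefer_p = P_p >= P_n
    A_p = np.zeros((m, n))
    A_n = np.zeros((m, n))
    for A, S, prefer, density, name in (
        (A_p, S_p, prefer_p, spec.density_p, "p"),
        (A_n, S_n, ~prefer_p, spec.density_n, "n"),
    ):
        want = int(round(density * m * n))
        cells = np.argwhere(prefer)
        if len(cells) < want:
            raise ValueError(
                f"type {name}: only {len(cells)} cells prefer it but density asks for {want}"
            )
        vals = S[prefer]
        top = np.argsort(-vals, kind="stable")[:want]
        for i, j in cells[top]:
            A[i, j] = 1.0

    if spec.noise > 0:
        for A in (A_p, A_n):
            ones = np.argwhere(A == 1)
            flip = rng.random(len(ones)) < spec.noise
            for i, j in ones[flip]:
                A[i, j] = 0.0
            dark = np.argwhere((A_p == 0) & (A_n == 0))
            n_add = int(flip.sum())
            picks = rng.choice(len(dark), size=n_add, replace=False)
            for i, j in dark[picks]:
                A[i, j] = 1.0

    W_r = SimilarityMatrix(values=_cosine_similarity(U, rng, spec.sim_noise), ids=[f"r{i:04d}" for i in range(m)])
    W_d = SimilarityMatrix(values=_cosine_similarity(V, rng, spec.sim_noise), ids=[f"d{j:04d}" for j in range(n)])
    matrices = AssociationMatrices(A_p=A_p, A_n=A_n, drug_index=W_r.ids, disease_index=W_d.ids)
    logger.info(
        "generated %dx%d instance: %d / %d positives (densities %.4f / %.4f)",
        m, n, int(A_p.sum()), int(A_n.sum()), A_p.mean(), A_n.mean(),
    )
    return SyntheticInstance(
        matrices=matrices, W_r=W_r, W_d=W_d,
        U_true=U, V_true=V, R_p_true=R_p, R_n_true=R_n,
        scores_p=S_p, scores_n=S_n,
    )


def default_benchmark_scale_spec(seed: int = 2020) -> SyntheticSpec:
    """Spec emulating the benchmark scale: 269 x 598 with two link types.

    Densities 0.0388 / 0.0757 put the expected positive counts near 6,244
    and 12,172.
    """
    return SyntheticSpec(
        m=269, n=598, k_true=30,
        density_p=0.0388, density_n=0.0757,
        noise=0.05, sim_noise=0.0, seed=seed,
    )
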