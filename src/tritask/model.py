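"""Collective matrix tri-factorization with ADMM optimization.

Two binary relation matrices ``A_p`` and ``A_n`` (same row/column entities,
mutually exclusive link types) are approximated as ``U R_p V^T`` and
``U R_n V^T`` with SHARED entity factors ``U`` (m x k) and ``V`` (n x k) and
type-specific coefficient matrices ``R_p``, ``R_n`` (k x k).  The loss

    1/2 (||A_p - U R_p V^T||_F^2 + ||A_n - U R_n V^T||_F^2)
    + alpha/2 tr(U^T L_U U) + beta/2 tr(V^T L_V V)
    + lam/2 (||U||^2 + ||V||^2 + ||R_p||^2 + ||R_n||^2)

is minimized by ADMM after splitting the Laplacian terms onto auxiliary
copies ``W = U`` and ``J = V``.  Each outer iteration solves the two
coefficient subproblems by conjugate gradients on a k^2-dimensional linear
operator, applies the four closed-form primal updates in sequence, and then
performs a dual ascent step with geometric penalty growth (capped).

Single-task reductions (``single_task_p`` / ``single_task_n``) drop the other
type's reconstruction and coefficient terms but keep identical machinery.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse.linalg as spla

from tritask.similarity import SimilarityMatrix, graph_laplacian

logger = logging.getLogger(__name__)

MODES = ("multi_task", "single_task_p", "single_task_n")


@dataclass
class Hyperparams:
    """Model and optimizer settings.

    Defaults follow the reference configuration: latent dimensionality 30,
    Laplacian weights ``alpha = beta = 8``, ridge weight ``lam = 4``, penalty
    growth ``mu = 1.1`` starting from ``rho_init = 1``.
    """

    k: int = 30
    alpha: float = 8.0
    beta: float = 8.0
    lam: float = 4.0
    mu: float = 1.1
    rho_init: float = 1.0
    rho_cap: float = 1e6
    max_iter: int = 500
    tol: float = 1e-4
    obj_tol: float = 1e-6
    obj_window: int = 5
    cg_max_iter: int = 200
    cg_tol: float = 1e-8
    seed: int = 0
    mode: str = "multi_task"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.mu <= 1:
            raise ValueError(f"mu must exceed 1, got {self.mu}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.alpha < 0 or self.beta < 0 or self.lam < 0:
            raise ValueError("alpha, beta, lam must be nonnegative")
        if self.rho_init <= 0 or self.rho_cap <= 0:
            raise ValueError("penalties must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def use_p(self) -> bool:
        return self.mode in ("multi_task", "single_task_p")

    @property
    def use_n(self) -> bool:
        return self.mode in ("multi_task", "single_task_n")


@dataclass
class ModelState:
    """All optimizer variables plus the per-iteration history."""

    U: np.ndarray
    V: np.ndarray
    R_p: np.ndarray
    R_n: np.ndarray
    J: np.ndarray
    W: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    rho1: float
    rho2: float
    iteration: int = 0
    history: dict[str, list[float]] = field(
        default_factory=lambda: {"objective": [], "res_J": [], "res_W": [], "rho1": [], "rho2": []}
    )


@dataclass
class PredictionScores:
    """Dense score matrices ``S_p = U R_p V^T`` and ``S_n = U R_n V^T``."""

    S_p: np.ndarray
    S_n: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.S_p).all() and np.isfinite(self.S_n).all()):
            raise ValueError("prediction scores contain non-finite entries")


def _as_array(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    return S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)


def objective_value(
    state: ModelState,
    A_p: np.ndarray,
    A_n: np.ndarray,
    L_U: np.ndarray,
    L_V: np.ndarray,
    hyper: Hyperparams,
) -> float:
    """Regularized reconstruction loss at the current factors."""
    U, V = state.U, state.V
    val = 0.0
    if hyper.use_p:
        val += 0.5 * np.linalg.norm(A_p - U @ state.R_p @ V.T) ** 2
        val += 0.5 * hyper.lam * np.linalg.norm(state.R_p) ** 2
    if hyper.use_n:
        val += 0.5 * np.linalg.norm(A_n - U @ state.R_n @ V.T) ** 2
        val += 0.5 * hyper.lam * np.linalg.norm(state.R_n) ** 2
    val += 0.5 * hyper.alpha * np.trace(U.T @ L_U @ U)
    val += 0.5 * hyper.beta * np.trace(V.T @ L_V @ V)
    val += 0.5 * hyper.lam * (np.linalg.norm(U) ** 2 + np.linalg.norm(V) ** 2)
    return float(val)


def augmented_lagrangian(
    state: ModelState,
    A_p: np.ndarray,
    A_n: np.ndarray,
    L_U: np.ndarray,
    L_V: np.ndarray,
    hyper: Hyperparams,
) -> float:
    """Augmented Lagrangian of the split problem (Laplacians act on W, J)."""
    U, V, J, W = state.U, state.V, state.J, state.W
    val = 0.0
    if hyper.use_p:
        val += 0.5 * np.linalg.norm(A_p - U @ state.R_p @ V.T) ** 2
        val += 0.5 * hyper.lam * np.linalg.norm(state.R_p) ** 2
    if hyper.use_n:
        val += 0.5 * np.linalg.norm(A_n - U @ state.R_n @ V.T) ** 2
        val += 0.5 * hyper.lam * np.linalg.norm(state.R_n) ** 2
    val += 0.5 * hyper.alpha * np.trace(W.T @ L_U @ W)
    val += 0.5 * hyper.beta * np.trace(J.T @ L_V @ J)
    val += 0.5 * hyper.lam * (np.linalg.norm(U) ** 2 + np.linalg.norm(V) ** 2)
    val += float(np.trace(state.Z.T @ (W - U))) + 0.5 * state.rho1 * np.linalg.norm(W - U) ** 2
    val += float(np.trace(state.Y.T @ (J - V))) + 0.5 * state.rho2 * np.linalg.norm(J - V) ** 2
    return float(val)


def solve_coefficient(
    A: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    lam: float,
    x0: np.ndarray | None = None,
    cg_max_iter: int = 200,
    cg_tol: float = 1e-8,
) -> np.ndarray:
    """Ridge coefficient solve ``min_R 1/2 ||A - U R V^T||^2 + lam/2 ||R||^2``.

    The normal equation ``(U^T U) R (V^T V) + lam R = U^T A V`` is solved by
    conjugate gradients on the k^2-dimensional operator
    ``R -> (U^T U) R (V^T V) + lam R`` — the Kronecker system is never
    materialized, so each CG step costs two k x k multiplications.
    """
    k = U.shape[1]
    G_u = U.T @ U
    G_v = V.T @ V
    B = U.T @ A @ V

    def matvec(r: np.ndarray) -> np.ndarray:
        R = r.reshape(k, k, order="F")
        return (G_u @ R @ G_v + lam * R).reshape(-1, order="F")

    op = spla.LinearOperator((k * k, k * k), matvec=matvec, dtype=float)
    b = B.reshape(-1, order="F")
    x0v = None if x0 is None else np.asarray(x0, dtype=float).reshape(-1, order="F")
    x, info = spla.cg(op, b, x0=x0v, rtol=cg_tol, atol=0.0, maxiter=cg_max_iter)
    if info > 0:
        warnings.warn(
            f"coefficient CG did not reach tolerance in {cg_max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return x.reshape(k, k, order="F")


# --- closed-form primal updates (each zeroes its own partial derivative of
# the augmented Lagrangian, given the variables current at call time) ---

def _update_J(V: np.ndarray, Y: np.ndarray, L_V: np.ndarray, beta: float, rho2: float) -> np.ndarray:
    return np.linalg.solve(beta * L_V + rho2 * np.eye(L_V.shape[0]), rho2 * V - Y)


def _update_W(U: np.ndarray, Z: np.ndarray, L_U: np.ndarray, alpha: float, rho1: float) -> np.ndarray:
    return np.linalg.solve(alpha * L_U + rho1 * np.eye(L_U.shape[0]), rho1 * U - Z)


def _update_U(
    A_p: np.ndarray,
    A_n: np.ndarray,
    V: np.ndarray,
    R_p: np.ndarray,
    R_n: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
    hyper: Hyperparams,
    rho1: float,
) -> np.ndarray:
    k = R_p.shape[0]
    VtV = V.T @ V
    G = (hyper.lam + rho1) * np.eye(k)
    rhs = Z + rho1 * W
    if hyper.use_p:
        G = G + R_p @ VtV @ R_p.T
        rhs = rhs + A_p @ V @ R_p.T
    if hyper.use_n:
        G = G + R_n @ VtV @ R_n.T
        rhs = rhs + A_n @ V @ R_n.T
    return np.linalg.solve(G.T, rhs.T).T  # U = rhs @ G^{-1}; G symmetric


def _update_V(
    A_p: np.ndarray,
    A_n: np.ndarray,
    U: np.ndarray,
    R_p: np.ndarray,
    R_n: np.ndarray,
    Y: np.ndarray,
    J: np.ndarray,
    hyper: Hyperparams,
    rho2: float,
) -> np.ndarray:
    k = R_p.shape[0]
    G = (hyper.lam + rho2) * np.eye(k)
    rhs = Y + rho2 * J
    if hyper.use_p:
        UR = U @ R_p
        G = G + UR.T @ UR
        rhs = rhs + A_p.T @ UR
    if hyper.use_n:
        UR = U @ R_n
        G = G + UR.T @ UR
        rhs = rhs + A_n.T @ UR
    return np.linalg.solve(G.T, rhs.T).T


def update_primal(
    state: ModelState,
    A_p: np.ndarray,
    A_n: np.ndarray,
    L_U: np.ndarray,
    L_V: np.ndarray,
    hyper: Hyperparams,
) -> ModelState:
    """One sequential sweep of the closed-form updates: J, W, U, V."""
    state.J = _update_J(state.V, state.Y, L_V, hyper.beta, state.rho2)
    state.W = _update_W(state.U, state.Z, L_U, hyper.alpha, state.rho1)
    state.U = _update_U(A_p, A_n, state.V, state.R_p, state.R_n, state.Z, state.W, hyper, state.rho1)
    state.V = _update_V(A_p, A_n, state.U, state.R_p, state.R_n, state.Y, state.J, hyper, state.rho2)
    return state


def update_multipliers(state: ModelState, hyper: Hyperparams) -> ModelState:
    """Dual ascent and geometric penalty growth (capped at ``rho_cap``)."""
    state.Y = state.Y + state.rho2 * (state.J - state.V)
    state.Z = state.Z + state.rho1 * (state.W - state.U)
    state.rho1 = min(hyper.mu * state.rho1, hyper.rho_cap)
    state.rho2 = min(hyper.mu * state.rho2, hyper.rho_cap)
    return state


def _residuals(state: ModelState) -> tuple[float, float]:
    res_J = np.linalg.norm(state.J - state.V) / max(1.0, np.linalg.norm(state.V))
    res_W = np.linalg.norm(state.W - state.U) / max(1.0, np.linalg.norm(state.U))
    return float(res_J), float(res_W)


def fit(
    A_p: np.ndarray,
    A_n: np.ndarray,
    W_r: SimilarityMatrix | np.ndarray,
    W_d: SimilarityMatrix | np.ndarray,
    hyper: Hyperparams,
    init_U: np.ndarray | None = None,
    init_V: np.ndarray | None = None,
) -> tuple[ModelState, PredictionScores]:
    """Run the full ADMM loop and return the state plus score matrices.

    Factors are initialized uniformly in [0, 1] from ``hyper.seed`` (or taken
    from ``init_U`` / ``init_V`` when supplied, e.g. for equivariance checks);
    multipliers start at zero and both penalties at ``rho_init``.  The loop
    stops when both relative primal residuals drop below ``tol``, when the
    relative objective change stays below ``obj_tol`` over ``obj_window``
    iterations, or at ``max_iter``.
    """
    A_p = np.asarray(A_p, dtype=float)
    A_n = np.asarray(A_n, dtype=float)
    m, n = A_p.shape
    if A_n.shape != (m, n):
        raise ValueError(f"A_p {A_p.shape} and A_n {A_n.shape} differ in shape")
    if not (0 < hyper.k < min(m, n)):
        raise ValueError(f"k={hyper.k} must satisfy 0 < k < min(m, n)={min(m, n)}")
    L_U = graph_laplacian(_as_array(W_r))
    L_V = graph_laplacian(_as_array(W_d))
    if L_U.shape[0] != m or L_V.shape[0] != n:
        raise ValueError("similarity matrices do not match association shape")

    rng = np.random.default_rng(hyper.seed)
    k = hyper.k
    U0 = rng.uniform(0.0, 1.0, size=(m, k)) if init_U is None else np.array(init_U, dtype=float)
    V0 = rng.uniform(0.0, 1.0, size=(n, k)) if init_V is None else np.array(init_V, dtype=float)
    if U0.shape != (m, k) or V0.shape != (n, k):
        raise ValueError("initial factors have wrong shape")
    state = ModelState(
        U=U0,
        V=V0,
        R_p=np.zeros((k, k)),
        R_n=np.zeros((k, k)),
        J=np.zeros((n, k)),
        W=np.zeros((m, k)),
        Y=np.zeros((n, k)),
        Z=np.zeros((m, k)),
        rho1=hyper.rho_init,
        rho2=hyper.rho_init,
    )
    state.J = state.V.copy()
    state.W = state.U.copy()

    hist = state.history
    for it in range(hyper.max_iter):
        if hyper.use_p:
            state.R_p = solve_coefficient(
                A_p, state.U, state.V, hyper.lam,
                x0=state.R_p, cg_max_iter=hyper.cg_max_iter, cg_tol=hyper.cg_tol,
            )
        if hyper.use_n:
            state.R_n = solve_coefficient(
                A_n, state.U, state.V, hyper.lam,
                x0=state.R_n, cg_max_iter=hyper.cg_max_iter, cg_tol=hyper.cg_tol,
            )
        update_primal(state, A_p, A_n, L_U, L_V, hyper)

        res_J, res_W = _residuals(state)
        obj = objective_value(state, A_p, A_n, L_U, L_V, hyper)
        hist["objective"].append(obj)
        hist["res_J"].append(res_J)
        hist["res_W"].append(res_W)
        hist["rho1"].append(state.rho1)
        hist["rho2"].append(state.rho2)

        update_multipliers(state, hyper)
        state.iteration = it + 1

        if (it + 1) % 10 == 0 or it + 1 == hyper.max_iter:
            if not (np.isfinite(state.U).all() and np.isfinite(state.V).all()
                    and np.isfinite(state.R_p).all() and np.isfinite(state.R_n).all()):
                raise FloatingPointError(
                    f"non-finite values in factors at iteration {it + 1}; "
                    "try smaller alpha/beta or larger lam"
                )
        if res_J <= hyper.tol and res_W <= hyper.tol:
            logger.info("converged at iteration %d (primal residuals below tol)", it + 1)
            break
        w = hyper.obj_window
        if len(hist["objective"]) > w:
            prev, cur = hist["objective"][-w - 1], obj
            if abs(prev - cur) <= hyper.obj_tol * max(1.0, abs(prev)):
                logger.info("converged at iteration %d (objective plateau)", it + 1)
                break

    scores = PredictionScores(
        S_p=state.U @ state.R_p @ state.V.T,
        S_n=state.U @ state.R_n @ state.V.T,
    )
    return state, scores


def fit_single_task(
    A: np.ndarray,
    W_r: SimilarityMatrix | np.ndarray,
    W_d: SimilarityMatrix | np.ndarray,
    hyper: Hyperparams,
    task: str = "p",
) -> tuple[ModelState, np.ndarray]:
    """Single-task reduction: factorize one relation matrix only.

    Identical machinery and parameters with the other task's reconstruction
    and coefficient terms removed.  Returns the state and that task's score
    matrix.
    """
    if task not in ("p", "n"):
        raise ValueError(f"task must be 'p' or 'n', got {task!r}")
    mode = f"single_task_{task}"
    hp = Hyperparams(**{**asdict(hyper), "mode": mode})
    zeros = np.zeros_like(np.asarray(A, dtype=float))
    if task == "p":
        state, scores = fit(A, zeros, W_r, W_d, hp)
        return state, scores.S_p
    state, scores = fit(zeros, A, W_r, W_d, hp)
    return state, scores.S_n


def save_checkpoint(
    state: ModelState,
    hyper: Hyperparams,
    path: str | Path,
    drug_index: list[str] | None = None,
    disease_index: list[str] | None = None,
) -> None:
    """Serialize factors, hyperparameters and history to one ``.npz`` archive."""
    meta = {
        "hyper": asdict(hyper),
        "iteration": state.iteration,
        "history": state.history,
        "drug_index": drug_index,
        "disease_index": disease_index,
    }
    np.savez(
        path,
        U=state.U, V=state.V, R_p=state.R_p, R_n=state.R_n,
        J=state.J, W=state.W, Y=state.Y, Z=state.Z,
        rho=np.array([state.rho1, state.rho2]),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_checkpoint(path: str | Path) -> tuple[ModelState, Hyperparams, dict]:
    """Inverse of :func:`save_checkpoint` (bit-exact round trip)."""
    with np.load(path) as arc:
        meta = json.loads(arc["meta"].tobytes().decode())
        state = ModelState(
            U=arc["U"], V=arc["V"], R_p=arc["R_p"], R_n=arc["R_n"],
            J=arc["J"], W=arc["W"], Y=arc["Y"], Z=arc["Z"],
            rho1=float(arc["rho"][0]), rho2=float(arc["rho"][1]),
            iteration=int(meta["iteration"]),
            history=meta["history"],
        )
    hyper = Hyperparams(**meta["hyper"])
    extra = {"drug_index": meta.get("drug_index"), "disease_index": meta.get("disease_index")}
    return state, hyper, extra
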