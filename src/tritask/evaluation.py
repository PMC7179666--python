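"""Cross-validated evaluation: fold planning, masking, and metrics.

Known positives of each link type are split into folds independently; per
fold, BOTH types' held-out positives are removed from the same training
matrices (the shared factors would otherwise leak test links), a single model
is fitted, and each task is scored on its own matrix.

The evaluation universe of a task is every (row, column) cell that is not one
of that task's TRAINING positives; cells positive in the other task count as
negatives unless ``exclude_cross_type`` is set.  Threshold metrics are
reported at the F-maximizing cutoff (prediction positive iff score >=
threshold, ties toward the higher threshold); ranking metrics are
tie-corrected AUC and step-wise AUPR.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from tritask.data_io import AssociationMatrices
from tritask.model import Hyperparams, fit
from tritask.similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

Coord = tuple[int, int]

DEFAULT_TOP_NS = tuple(range(10, 1001, 10))


@dataclass
class FoldPlan:
    """Random partition of each task's positives into ``n_folds`` groups."""

    n_folds: int
    fold_of_p: dict[Coord, int]
    fold_of_n: dict[Coord, int]
    seed: int

    def __post_init__(self) -> None:
        for mapping in (self.fold_of_p, self.fold_of_n):
            counts = np.bincount(list(mapping.values()), minlength=self.n_folds)
            if mapping and counts.max() - counts.min() > 1:
                raise ValueError("fold sizes within a task must differ by at most 1")


@dataclass
class MetricReport:
    """Mean cross-validated metrics of one task plus per-fold detail."""

    task: str
    aupr: float
    auc: float
    se: float
    sp: float
    pre: float
    acc: float
    f: float
    threshold: float
    topn: list[tuple[int, float, float]]
    per_fold: list[dict[str, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def make_folds(matrices: AssociationMatrices, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Uniform random fold assignment per task, deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    plan: dict[str, dict[Coord, int]] = {}
    for name, A in (("p", matrices.A_p), ("n", matrices.A_n)):
        coords = [tuple(c) for c in np.argwhere(A == 1)]
        if len(coords) < n_folds:
            raise ValueError(f"task {name} has {len(coords)} positives < {n_folds} folds")
        order = rng.permutation(len(coords))
        assignment: dict[Coord, int] = {}
        for rank, idx in enumerate(order):
            assignment[coords[idx]] = rank % n_folds
        plan[name] = assignment
    return FoldPlan(n_folds=n_folds, fold_of_p=plan["p"], fold_of_n=plan["n"], seed=seed)


def mask_fold(
    matrices: AssociationMatrices, plan: FoldPlan, fold: int
) -> tuple[AssociationMatrices, set[Coord], set[Coord]]:
    """Zero one fold's positives (both tasks) and return the held-out coords."""
    if not (0 <= fold < plan.n_folds):
        raise ValueError(f"fold {fold} out of range [0, {plan.n_folds})")
    train = matrices.copy()
    test_p = {c for c, f in plan.fold_of_p.items() if f == fold}
    test_n = {c for c, f in plan.fold_of_n.items() if f == fold}
    for i, j in test_p:
        train.A_p[i, j] = 0.0
    for i, j in test_n:
        train.A_n[i, j] = 0.0
    if not test_p or not test_n:
        logger.warning("fold %d has an empty test set (p=%d, n=%d)", fold, len(test_p), len(test_n))
    return train, test_p, test_n


def _flatten(scores: np.ndarray, test_pos: set[Coord], eval_mask: set[Coord]):
    if not test_pos <= eval_mask:
        raise ValueError("test positives must be a subset of the evaluation mask")
    coords = sorted(eval_mask)
    s = np.array([scores[c] for c in coords], dtype=float)
    y = np.array([1 if c in test_pos else 0 for c in coords], dtype=int)
    return coords, s, y


def threshold_metrics(
    scores: np.ndarray, test_pos: set[Coord], eval_mask: set[Coord]
) -> tuple[float, float, float, float, float, float]:
    """Confusion metrics at the F-maximizing threshold.

    Sweeps every distinct score in the evaluation universe as a candidate
    cutoff (positive iff score >= cutoff); returns
    ``(se, sp, pre, acc, f, threshold)``.  F ties break toward the higher
    threshold (fewer predicted positives).
    """
    if not test_pos:
        raise ValueError("metrics undefined with no test positives")
    _, s, y = _flatten(scores, test_pos, eval_mask)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    # last index of each distinct score value (predicting >= that value)
    boundary = np.nonzero(np.diff(s_sorted, append=-np.inf) != 0)[0]
    P = int(y.sum())
    N = len(y) - P
    best = None
    for idx in boundary:  # descending thresholds
        tp, fp = int(tp_cum[idx]), int(fp_cum[idx])
        fn, tn = P - tp, N - fp
        pre = tp / (tp + fp) if tp + fp else 0.0
        se = tp / P
        f = 2 * pre * se / (pre + se) if pre + se > 0 else 0.0
        if best is None or f > best[0]:  # strict: first (highest) threshold wins ties
            sp = tn / N if N else 0.0
            acc = (tp + tn) / (P + N)
            best = (f, se, sp, pre, acc, float(s_sorted[idx]))
    f, se, sp, pre, acc, thr = best
    return se, sp, pre, acc, f, thr


def ranking_metrics(
    scores: np.ndarray, test_pos: set[Coord], eval_mask: set[Coord]
) -> tuple[float, float]:
    """(AUC, AUPR) over the evaluation universe.

    AUC is the tie-corrected Mann-Whitney statistic.  AUPR is the step-wise
    average of precision at the rank of each positive, with ties broken by
    coordinate order for reproducibility.
    """
    if not test_pos:
        raise ValueError("metrics undefined with no test positives")
    _, s, y = _flatten(scores, test_pos, eval_mask)
    P = int(y.sum())
    N = len(y) - P
    if N == 0:
        raise ValueError("no negatives in the evaluation universe")
    ranks = rankdata(s)  # midranks for ties
    auc = (ranks[y == 1].sum() - P * (P + 1) / 2) / (P * N)

    order = np.argsort(-s, kind="stable")  # coordinate order breaks ties (coords sorted)
    y_sorted = y[order]
    pos_ranks = np.nonzero(y_sorted)[0] + 1
    hits = np.arange(1, P + 1)
    aupr = float(np.mean(hits / pos_ranks))
    return float(auc), aupr


def topn_curves(
    scores: np.ndarray,
    test_pos: set[Coord],
    eval_mask: set[Coord],
    Ns: tuple[int, ...] = DEFAULT_TOP_NS,
) -> list[tuple[int, float, float]]:
    """Recall/precision among the N top-scored cells for each N."""
    _, s, y = _flatten(scores, test_pos, eval_mask)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    cum = np.cumsum(y_sorted)
    out = []
    for N in Ns:
        if N <= 0 or N > len(y):
            raise ValueError(f"top-N value {N} outside [1, {len(y)}]")
        hits = int(cum[N - 1])
        out.append((N, hits / max(1, len(test_pos)), hits / N))
    return out


def _eval_universe(
    train: AssociationMatrices, task: str, exclude_cross_type: bool
) -> set[Coord]:
    m, n = train.shape
    own = train.A_p if task == "p" else train.A_n
    other = train.A_n if task == "p" else train.A_p
    blocked = own == 1
    if exclude_cross_type:
        blocked = blocked | (other == 1)
    return {(int(i), int(j)) for i, j in np.argwhere(~blocked)}


def cross_validate(
    matrices: AssociationMatrices,
    W_r: SimilarityMatrix | np.ndarray,
    W_d: SimilarityMatrix | np.ndarray,
    hyper: Hyperparams,
    plan: FoldPlan,
    Ns: tuple[int, ...] | None = None,
    exclude_cross_type: bool = False,
) -> tuple[MetricReport, MetricReport]:
    """Fit once per fold and average per-task metrics across folds."""
    metric_names = ("aupr", "auc", "se", "sp", "pre", "acc", "f", "threshold")
    per_fold: dict[str, list[dict[str, float]]] = {"p": [], "n": []}
    topn_acc: dict[str, list[np.ndarray]] = {"p": [], "n": []}
    used_Ns: dict[str, tuple[int, ...]] = {}

    for fold in range(plan.n_folds):
        train, test_p, test_n = mask_fold(matrices, plan, fold)
        fold_hyper = Hyperparams(**{**asdict(hyper), "seed": hyper.seed + fold})
        _, scores = fit(train.A_p, train.A_n, W_r, W_d, fold_hyper)
        for task, S, test_pos in (("p", scores.S_p, test_p), ("n", scores.S_n, test_n)):
            universe = _eval_universe(train, task, exclude_cross_type)
            # the universe must never contain a training positive of this task
            train_pos_matrix = train.A_p if task == "p" else train.A_n
            assert all(train_pos_matrix[c] == 0 for c in list(universe)[:100])
            auc, aupr = ranking_metrics(S, test_pos, universe)
            se, sp, pre, acc, f, thr = threshold_metrics(S, test_pos, universe)
            row = dict(zip(metric_names, (aupr, auc, se, sp, pre, acc, f, thr)))
            row["fold"] = float(fold)
            per_fold[task].append(row)
            ns = Ns if Ns is not None else tuple(N for N in DEFAULT_TOP_NS if N <= len(universe))
            used_Ns[task] = ns
            curve = topn_curves(S, test_pos, universe, ns)
            topn_acc[task].append(np.array([(r, p) for _, r, p in curve]))
        logger.info(
            "fold %d: task1 auc=%.4f aupr=%.4f | task2 auc=%.4f aupr=%.4f",
            fold, per_fold["p"][-1]["auc"], per_fold["p"][-1]["aupr"],
            per_fold["n"][-1]["auc"], per_fold["n"][-1]["aupr"],
        )

    reports = []
    for task, name in (("p", "task1"), ("n", "task2")):
        rows = per_fold[task]
        means = {k: float(np.mean([r[k] for r in rows])) for k in metric_names}
        curves = np.mean(topn_acc[task], axis=0)
        topn = [(int(N), float(r), float(p)) for N, (r, p) in zip(used_Ns[task], curves)]
        reports.append(
            MetricReport(
                task=name,
                aupr=means["aupr"], auc=means["auc"], se=means["se"], sp=means["sp"],
                pre=means["pre"], acc=means["acc"], f=means["f"],
                threshold=means["threshold"], topn=topn, per_fold=rows,
            )
        )
    return reports[0], reports[1]


def write_report_tsv(reports: tuple[MetricReport, MetricReport], path: str | Path) -> None:
    """One row per task per fold plus a mean row, as TSV."""
    cols = ("aupr", "auc", "se", "sp", "pre", "acc", "f", "threshold")
    with open(path, "w") as fh:
        fh.write("task\tfold\t" + "\t".join(cols) + "\n")
        for rep in reports:
            for row in rep.per_fold:
                fh.write(
                    rep.task + "\t" + str(int(row["fold"])) + "\t"
                    + "\t".join(f"{row[c]:.6f}" for c in cols) + "\n"
                )
            fh.write(
                rep.task + "\tmean\t" + "\t".join(f"{getattr(rep, c):.6f}" for c in cols) + "\n"
            )


def write_topn_tsv(report: MetricReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("N\trecall\tprecision\n")
        for N, rec, pre in report.topn:
            fh.write(f"{N}\t{rec:.6f}\t{pre:.6f}\n")
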