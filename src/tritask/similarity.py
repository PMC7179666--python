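"""Entity similarity matrices and their graph Laplacians.

Drug-drug similarity is the Jaccard (Tanimoto) index over binary descriptor
sets.  Disease-disease similarity is a DAG-based semantic measure: each
disease's hierarchical tree numbers expand into an ancestor DAG by dot-prefix,
every node receives a semantic contribution decaying by a factor per level
away from the disease's own node(s), and similarity of two diseases is the
shared contribution mass normalized by their total semantic values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tritask.data_io import FeatureProfiles, MeshTreeTable

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 0.5


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1].

    The diagonal is 1 for entities with a non-empty representation;
    entities loaded with empty profiles/DAGs may carry an all-zero row.
    """

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity shape {self.values.shape} does not match {n} ids")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("similarity matrix must be exactly symmetric")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("similarity entries must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(i) for i in df.index]
        if ids != [str(c) for c in df.columns]:
            raise ValueError(f"{path}: row and column ids differ")
        values = df.to_numpy(dtype=float)
        # guard against asymmetric round-trips
        values = np.where(np.abs(values - values.T) < 1e-12, (values + values.T) / 2, values)
        return cls(values=values, ids=ids)


@dataclass
class DiseaseDAG:
    """Ancestor DAG of one disease built from its hierarchical tree numbers.

    ``nodes`` holds every dot-prefix of every tree number; ``own`` the full
    tree numbers themselves.  ``sc``/``sv`` are filled by
    :func:`semantic_contribution` / :func:`semantic_value`.
    """

    disease_id: str
    nodes: frozenset[str]
    children: dict[str, frozenset[str]]
    own: frozenset[str]
    sc: dict[str, float] = field(default_factory=dict)
    sv: float | None = None
    delta: float | None = None


def build_disease_dag(disease_id: str, tree_numbers: frozenset[str] | set[str]) -> DiseaseDAG:
    """Expand tree numbers into the ancestor DAG of one disease.

    Each tree number contributes a node for every dot-prefix; edges run from
    a prefix to its one-segment extension.  Node identity is the tree-number
    string, so diseases share ancestors exactly when they share prefixes.
    """
    if not tree_numbers:
        raise ValueError(f"disease {disease_id!r} has no tree numbers")
    nodes: set[str] = set()
    children: dict[str, set[str]] = {}
    for number in tree_numbers:
        segments = number.split(".")
        if not all(segments):
            raise ValueError(f"malformed tree number {number!r}")
        prefixes = [".".join(segments[: i + 1]) for i in range(len(segments))]
        nodes.update(prefixes)
        for parent, child in zip(prefixes, prefixes[1:]):
            children.setdefault(parent, set()).add(child)
    return DiseaseDAG(
        disease_id=disease_id,
        nodes=frozenset(nodes),
        children={p: frozenset(c) for p, c in children.items()},
        own=frozenset(tree_numbers),
    )


def semantic_contribution(dag: DiseaseDAG, delta: float = DEFAULT_DELTA) -> DiseaseDAG:
    """Fill per-node semantic contributions, decaying by ``delta`` per level.

    The disease's own node(s) contribute 1; every other node contributes
    ``max(delta * sc(child))`` over its children.  Prefix DAGs are acyclic by
    construction (children are strictly longer strings), so processing nodes
    by decreasing depth is a reverse-topological order.
    """
    if not (0 < delta < 1):
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    sc: dict[str, float] = {}
    for node in sorted(dag.nodes, key=lambda t: -t.count(".")):
        if node in dag.own:
            sc[node] = 1.0
        else:
            kids = dag.children.get(node, frozenset())
            if not kids:
                raise ValueError(f"non-own leaf node {node!r} in DAG of {dag.disease_id!r}")
            sc[node] = max(delta * sc[child] for child in kids)
    dag.sc = sc
    dag.delta = delta
    dag.sv = None
    return dag


def semantic_value(dag: DiseaseDAG) -> float:
    """Total semantic value: sum of contributions over all DAG nodes."""
    if not dag.sc:
        raise ValueError(f"semantic contributions not computed for {dag.disease_id!r}")
    dag.sv = float(sum(dag.sc.values()))
    return dag.sv


def disease_similarity_matrix(
    dags: dict[str, DiseaseDAG], delta: float = DEFAULT_DELTA
) -> SimilarityMatrix:
    """Pairwise semantic similarity over a collection of disease DAGs.

    ``S[i, j] = sum_{t in V_i & V_j} (SC_i(t) + SC_j(t)) / (SV_i + SV_j)``.
    All DAGs must carry contributions computed with the same ``delta``.
    A ``None`` entry stands for a disease without tree numbers; it gets an
    all-zero row (including the diagonal) with a warning.
    """
    ids = sorted(dags)
    for disease in ids:
        dag = dags[disease]
        if dag is None:
            continue
        if dag.delta != delta:
            raise ValueError(
                f"DAG of {disease!r} computed with delta={dag.delta}, expected {delta}"
            )
        if dag.sv is None:
            semantic_value(dag)
    empties = [d for d in ids if dags[d] is None]
    if empties:
        logger.warning("diseases without DAG representation get zero similarity: %s", empties)

    n = len(ids)
    S = np.zeros((n, n))
    for a in range(n):
        da = dags[ids[a]]
        if da is None:
            continue
        S[a, a] = 1.0
        for b in range(a + 1, n):
            db = dags[ids[b]]
            if db is None:
                continue
            shared = da.nodes & db.nodes
            if not shared:
                continue
            num = sum(da.sc[t] + db.sc[t] for t in shared)
            S[a, b] = S[b, a] = num / (da.sv + db.sv)
    return SimilarityMatrix(values=S, ids=ids)


def mesh_similarity_matrix(table: MeshTreeTable, delta: float = DEFAULT_DELTA) -> SimilarityMatrix:
    """Convenience: MeshTreeTable -> disease similarity in one call."""
    dags: dict[str, DiseaseDAG | None] = {}
    for disease, numbers in table.trees.items():
        if numbers:
            dag = build_disease_dag(disease, numbers)
            semantic_contribution(dag, delta)
            semantic_value(dag)
            dags[disease] = dag
        else:
            dags[disease] = None
    return disease_similarity_matrix(dags, delta)


def jaccard_similarity_matrix(profiles: FeatureProfiles, ids: list[str] | None = None) -> SimilarityMatrix:
    """Pairwise Jaccard (Tanimoto) similarity over descriptor sets.

    ``S[i, j] = |P_i & P_j| / (|P_i| + |P_j| - |P_i & P_j|)``; pairs where
    both profiles are empty score 0 (the empty-profile diagonal too, logged).
    """
    ids = sorted(profiles.profiles) if ids is None else list(ids)
    if not ids:
        raise ValueError("no drugs to compare")
    missing = [d for d in ids if d not in profiles.profiles]
    if missing:
        raise KeyError(f"no feature profile for drugs: {missing}")

    universe = profiles.universe
    col = {d: i for i, d in enumerate(universe)}
    X = np.zeros((len(ids), len(universe)))
    for r, drug in enumerate(ids):
        for desc in profiles.profiles[drug]:
            X[r, col[desc]] = 1.0

    inter = X @ X.T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    empty = [ids[i] for i in range(len(ids)) if sizes[i] == 0]
    if empty:
        logger.warning("drugs with empty profiles get zero similarity (even to self): %s", empty)
    S = (S + S.T) / 2  # exact symmetry despite float noise
    return SimilarityMatrix(values=S, ids=ids)


def graph_laplacian(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Unnormalized graph Laplacian ``L = D - S`` (D = diagonal of row sums)."""
    W = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"expected a square matrix, got {W.shape}")
    if not np.allclose(W, W.T):
        raise ValueError("similarity matrix must be symmetric")
    if W.min() < 0:
        raise ValueError("similarity entries must be nonnegative")
    return np.diag(W.sum(axis=1)) - W
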