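"""Parsing of association triples, feature profiles and MeSH tree tables.

All on-disk formats are plain tab-separated text:

* association TSV: ``drug_id<TAB>disease_id<TAB>type``
* feature TSV:     ``drug_id<TAB>descriptor`` or ``drug_id<TAB>a,b,c``
* MeSH TSV:        ``disease_id<TAB>tree_number``

Lines starting with ``#`` and blank lines are ignored everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

THERAPEUTIC = "therapeutic"
NON_THERAPEUTIC = "non_therapeutic"

#: recognized type tokens (matched case-insensitively)
_TYPE_TOKENS = {
    "therapeutic": THERAPEUTIC,
    "1": THERAPEUTIC,
    "marker/mechanism": NON_THERAPEUTIC,
    "non-therapeutic": NON_THERAPEUTIC,
    "non_therapeutic": NON_THERAPEUTIC,
    "-1": NON_THERAPEUTIC,
}

CONFLICT_POLICIES = ("therapeutic_wins", "non_therapeutic_wins", "drop")


class AssociationParseError(ValueError):
    """Raised for malformed association input (carries the line number)."""


@dataclass
class AssociationTable:
    """Deduplicated (drug, disease, type) triples after conflict resolution.

    ``n_conflicts`` counts pairs that appeared with both types in the raw
    input; how they were resolved depends on the policy used at load time.
    """

    records: list[tuple[str, str, str]]
    n_conflicts: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            drug, disease, typ = rec
            if not drug or not disease:
                raise ValueError(f"empty id in record {rec!r}")
            if typ not in (THERAPEUTIC, NON_THERAPEUTIC):
                raise ValueError(f"unknown association type {typ!r}")
            if rec in seen:
                raise ValueError(f"duplicate record {rec!r}")
            seen.add(rec)

    @property
    def drugs(self) -> list[str]:
        return sorted({r[0] for r in self.records})

    @property
    def diseases(self) -> list[str]:
        return sorted({r[1] for r in self.records})


@dataclass
class AssociationMatrices:
    """Paired binary matrices (drugs x diseases), one per link type.

    Rows map to ``drug_index``, columns to ``disease_index``, identically in
    both matrices.  The two types are mutually exclusive: ``A_p * A_n == 0``
    elementwise.
    """

    A_p: np.ndarray
    A_n: np.ndarray
    drug_index: list[str]
    disease_index: list[str]

    def __post_init__(self) -> None:
        self.A_p = np.asarray(self.A_p, dtype=float)
        self.A_n = np.asarray(self.A_n, dtype=float)
        m, n = len(self.drug_index), len(self.disease_index)
        if self.A_p.shape != (m, n) or self.A_n.shape != (m, n):
            raise ValueError(
                f"matrix shapes {self.A_p.shape}/{self.A_n.shape} inconsistent "
                f"with {m} drugs x {n} diseases"
            )
        for A, name in ((self.A_p, "A_p"), (self.A_n, "A_n")):
            if not np.isin(A, (0.0, 1.0)).all():
                raise ValueError(f"{name} entries must be binary")
        if (self.A_p * self.A_n).any():
            raise ValueError("A_p and A_n must be elementwise exclusive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.A_p.shape

    def copy(self) -> "AssociationMatrices":
        return AssociationMatrices(
            self.A_p.copy(), self.A_n.copy(), list(self.drug_index), list(self.disease_index)
        )


@dataclass
class FeatureProfiles:
    """Per-drug descriptor sets plus the ordered descriptor universe."""

    profiles: dict[str, frozenset[str]]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = sorted(set().union(*self.profiles.values(), set()))
        uni = set(self.universe)
        for drug, prof in self.profiles.items():
            if not prof <= uni:
                raise ValueError(f"profile of {drug!r} contains descriptors outside the universe")

    def encode(self, drug_id: str) -> np.ndarray:
        """Binary indicator vector of the drug's profile over the universe."""
        prof = self.profiles[drug_id]
        return np.array([1.0 if d in prof else 0.0 for d in self.universe])


@dataclass
class MeshTreeTable:
    """Disease id -> set of dot-delimited hierarchical tree numbers."""

    trees: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for disease, numbers in self.trees.items():
            for t in numbers:
                if not t or any(seg == "" for seg in t.split(".")):
                    raise ValueError(f"malformed tree number {t!r} for {disease!r}")


def _data_lines(path: str | Path, header: bool = False):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    with open(path) as fh:
        first_data = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header and first_data:
                first_data = False
                continue
            first_data = False
            yield lineno, line


def load_associations(
    path: str | Path,
    conflict_policy: str = "therapeutic_wins",
    header: bool = False,
) -> AssociationTable:
    """Load (drug, disease, type) triples from a TSV file.

    Exact duplicate triples collapse.  Pairs annotated with BOTH types are
    resolved per ``conflict_policy``: ``therapeutic_wins`` (default, mirrors
    keeping the extreme cases as therapeutic), ``non_therapeutic_wins`` or
    ``drop``.  Records are returned in sorted order, so the result is
    invariant under permutation of input lines.
    """
    if conflict_policy not in CONFLICT_POLICIES:
        raise ValueError(f"unknown conflict policy {conflict_policy!r}; use one of {CONFLICT_POLICIES}")

    triples: set[tuple[str, str, str]] = set()
    for lineno, line in _data_lines(path, header=header):
        fields = line.split("\t")
        if len(fields) < 3:
            raise AssociationParseError(
                f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            )
        drug, disease, token = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if not drug or not disease:
            raise AssociationParseError(f"{path}:{lineno}: empty drug or disease id")
        typ = _TYPE_TOKENS.get(token.lower())
        if typ is None:
            raise AssociationParseError(f"{path}:{lineno}: unknown type token {token!r}")
        triples.add((drug, disease, typ))

    if not triples:
        raise ValueError(f"no associations in {path}")

    pairs_p = {(d, s) for d, s, t in triples if t == THERAPEUTIC}
    pairs_n = {(d, s) for d, s, t in triples if t == NON_THERAPEUTIC}
    conflicts = pairs_p & pairs_n
    if conflicts:
        logger.warning(
            "%d drug-disease pair(s) annotated with both types; resolving with policy %r",
            len(conflicts), conflict_policy,
        )
    if conflict_policy == "therapeutic_wins":
        pairs_n -= conflicts
    elif conflict_policy == "non_therapeutic_wins":
        pairs_p -= conflicts
    else:  # drop
        pairs_p -= conflicts
        pairs_n -= conflicts

    records = sorted(
        [(d, s, THERAPEUTIC) for d, s in pairs_p] + [(d, s, NON_THERAPEUTIC) for d, s in pairs_n]
    )
    return AssociationTable(records=records, n_conflicts=len(conflicts))


def build_matrices(
    table: AssociationTable,
    drug_order: list[str] | None = None,
    disease_order: list[str] | None = None,
) -> AssociationMatrices:
    """Materialize the paired binary matrices from an association table.

    Default ordering is lexicographic by id so matrices are reproducible
    across runs; supplied orders must cover every id in the table.
    """
    drugs = list(drug_order) if drug_order is not None else table.drugs
    diseases = list(disease_order) if disease_order is not None else table.diseases
    di = {d: i for i, d in enumerate(drugs)}
    si = {s: j for j, s in enumerate(diseases)}
    missing = [r for r, _, _ in table.records if r not in di]
    missing += [s for _, s, _ in table.records if s not in si]
    if missing:
        raise ValueError(f"ids in table missing from supplied order: {sorted(set(missing))}")

    A_p = np.zeros((len(drugs), len(diseases)))
    A_n = np.zeros_like(A_p)
    for drug, disease, typ in table.records:
        (A_p if typ == THERAPEUTIC else A_n)[di[drug], si[disease]] = 1.0
    return AssociationMatrices(A_p=A_p, A_n=A_n, drug_index=drugs, disease_index=diseases)


def load_features(path: str | Path, allow_empty: bool = False, header: bool = False) -> FeatureProfiles:
    """Load drug -> descriptor-set profiles.

    Two dialects are auto-detected per line: one descriptor per line, or a
    single comma-joined descriptor list.  Duplicate (drug, descriptor) pairs
    are harmless (set semantics).
    """
    profiles: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path, header=header):
        fields = line.split("\t")
        if len(fields) < 2:
            raise AssociationParseError(f"{path}:{lineno}: expected drug_id<TAB>descriptor(s)")
        drug = fields[0].strip()
        if not drug:
            raise AssociationParseError(f"{path}:{lineno}: empty drug id")
        raw = fields[1].strip()
        descriptors = [d.strip() for d in raw.split(",")] if "," in raw else [raw]
        descriptors = [d for d in descriptors if d]
        bucket = profiles.setdefault(drug, set())
        bucket.update(descriptors)

    if not profiles:
        raise ValueError(f"no feature profiles in {path}")
    empty = sorted(d for d, p in profiles.items() if not p)
    if empty and not allow_empty:
        raise ValueError(f"drugs with zero descriptors: {empty} (pass allow_empty to keep them)")
    if empty:
        logger.warning("drugs with empty feature profiles: %s", empty)
    return FeatureProfiles(profiles={d: frozenset(p) for d, p in profiles.items()})


def load_mesh_trees(path: str | Path, header: bool = False) -> MeshTreeTable:
    """Load disease -> MeSH tree-number sets from a two-column TSV."""
    trees: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path, header=header):
        fields = line.split("\t")
        if len(fields) < 2:
            raise AssociationParseError(f"{path}:{lineno}: expected disease_id<TAB>tree_number")
        disease, number = fields[0].strip(), fields[1].strip()
        if not disease or not number:
            raise AssociationParseError(f"{path}:{lineno}: empty field")
        trees.setdefault(disease, set()).add(number)
    if not trees:
        raise ValueError(f"no tree numbers in {path}")
    return MeshTreeTable(trees={d: frozenset(t) for d, t in trees.items()})


def write_predictions(
    scores_p: np.ndarray,
    scores_n: np.ndarray,
    matrices: AssociationMatrices,
    path: str | Path,
    top_k: int = 100,
) -> None:
    """Write the top-ranked novel (drug, disease, type) triples as TSV.

    Entries already known in the corresponding matrix are masked out; the two
    types compete in a single merged ranking.  Ties are broken by
    (drug_id, disease_id, type) for determinism.
    """
    scores_p = np.asarray(scores_p, dtype=float)
    scores_n = np.asarray(scores_n, dtype=float)
    if scores_p.shape != matrices.shape or scores_n.shape != matrices.shape:
        raise ValueError(
            f"score shapes {scores_p.shape}/{scores_n.shape} do not match data {matrices.shape}"
        )
    candidates: list[tuple[float, str, str, str]] = []
    for scores, A, typ in (
        (scores_p, matrices.A_p, THERAPEUTIC),
        (scores_n, matrices.A_n, NON_THERAPEUTIC),
    ):
        for i, j in zip(*np.nonzero(A == 0)):
            candidates.append(
                (float(scores[i, j]), matrices.drug_index[i], matrices.disease_index[j], typ)
            )
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    with open(path, "w") as fh:
        fh.write("rank\tdrug_id\tdisease_id\ttype\tscore\n")
        for rank, (score, drug, disease, typ) in enumerate(candidates[:top_k], start=1):
            fh.write(f"{rank}\t{drug}\t{disease}\t{typ}\t{score:.10g}\n")
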