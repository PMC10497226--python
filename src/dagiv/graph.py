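"""Graph types and deterministic graph algorithms.

The model distinguishes *primary* variables Y_1..Y_p (e.g. gene expression
levels) whose mutual directed relations are the inference target, and
*intervention* variables X_1..X_q (e.g. SNP genotypes) that may act on
primary variables with unknown targets.  A directed edge (k, j) always means
"k points to j"; all indices in this module are 1-based, matching the usual
notation Y_k -> Y_j and X_l -> Y_j.

Two graph containers are provided:

* :class:`InterventionDAG` -- the full DAG with primary edges (Y -> Y) and
  intervention edges (X -> Y).  Edges from Y to X are unrepresentable.
* :class:`AncestralRelationGraph` -- the transitive-closure view of a DAG:
  ancestral pairs among Y, plus candidate intervention edges pointing at a
  node or any of its ancestors.  This is the object the peeling algorithm
  estimates, and the topological-order information inference runs on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "InterventionDAG",
    "AncestralRelationGraph",
    "HypothesisSpec",
    "HypothesisClassification",
    "InterventionClassification",
    "is_acyclic",
    "topological_order",
    "transitive_closure",
    "arg_of_dag",
    "classify_interventions",
    "classify_hypothesis",
    "read_edge_tsv",
    "write_edge_tsv",
]

Edge = tuple[int, int]


def _check_indices(edges: Iterable[Edge], p: int, *, what: str = "edge") -> None:
    for k, j in edges:
        if not (1 <= k <= p and 1 <= j <= p):
            raise IndexError(f"{what} ({k}, {j}) out of range 1..{p}")


def topological_order(edges: Iterable[Edge], p: int) -> list[int] | None:
    """Kahn topological sort with deterministic ascending tie-break.

    Returns the order as a list of 1-based node indices, or ``None`` if the
    graph contains a directed cycle.
    """
    edges = set(edges)
    _check_indices(edges, p)
    children: dict[int, list[int]] = {v: [] for v in range(1, p + 1)}
    indeg = {v: 0 for v in range(1, p + 1)}
    for k, j in sorted(edges):
        children[k].append(j)
        indeg[j] += 1
    # ascending-index frontier for reproducible orders and error messages
    frontier = sorted(v for v in indeg if indeg[v] == 0)
    order: list[int] = []
    while frontier:
        v = frontier.pop(0)
        order.append(v)
        changed = False
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                frontier.append(c)
                changed = True
        if changed:
            frontier.sort()
    return order if len(order) == p else None


def is_acyclic(edges: Iterable[Edge], p: int) -> bool:
    """True iff the directed graph on nodes 1..p has no directed cycle."""
    return topological_order(edges, p) is not None


def transitive_closure(edges: Iterable[Edge], p: int) -> set[Edge]:
    """All pairs (k, j) such that a directed path k -> ... -> j exists.

    The input must be acyclic; nodes are processed in topological order so
    each node's ancestor set is the union of its parents' ancestor sets.
    """
    edges = set(edges)
    order = topological_order(edges, p)
    if order is None:
        raise ValueError("transitive_closure requires an acyclic edge set")
    parents: dict[int, list[int]] = {v: [] for v in range(1, p + 1)}
    for k, j in edges:
        parents[j].append(k)
    ancestors: dict[int, set[int]] = {}
    for v in order:
        anc: set[int] = set()
        for u in parents[v]:
            anc.add(u)
            anc |= ancestors[u]
        ancestors[v] = anc
    return {(k, j) for j, anc in ancestors.items() for k in anc}


@dataclass(frozen=True)
class InterventionDAG:
    """DAG over p primary and q intervention variables.

    ``primary_edges`` holds pairs (k, j) meaning Y_k -> Y_j and must be
    acyclic; ``intervention_edges`` holds pairs (l, j) meaning X_l -> Y_j.
    """

    p: int
    q: int
    primary_edges: frozenset[Edge] = frozenset()
    intervention_edges: frozenset[Edge] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "primary_edges", frozenset(self.primary_edges))
        object.__setattr__(self, "intervention_edges", frozenset(self.intervention_edges))
        if self.p < 1 or self.q < 0:
            raise ValueError("need p >= 1 and q >= 0")
        for k, j in self.primary_edges:
            if k == j:
                raise ValueError(f"self-loop ({k}, {j}) in primary edges")
        _check_indices(self.primary_edges, self.p, what="primary edge")
        for l, j in self.intervention_edges:
            if not (1 <= l <= self.q):
                raise IndexError(f"intervention source {l} out of range 1..{self.q}")
            if not (1 <= j <= self.p):
                raise IndexError(f"intervention target {j} out of range 1..{self.p}")
        if not is_acyclic(self.primary_edges, self.p):
            raise ValueError("primary edges contain a directed cycle")

    def parents(self, j: int) -> set[int]:
        return {k for k, jj in self.primary_edges if jj == j}

    def interventions_on(self, j: int) -> set[int]:
        return {l for l, jj in self.intervention_edges if jj == j}


@dataclass(frozen=True)
class AncestralRelationGraph:
    """Ancestral relations among Y plus candidate intervention edges.

    ``ancestral_edges`` must be acyclic and transitively closed;
    ``candidate_intervention_edges`` holds (l, j) pairs meaning X_l is a
    candidate intervention for Y_j or one of its ancestors.
    """

    p: int
    q: int
    ancestral_edges: frozenset[Edge] = frozenset()
    candidate_intervention_edges: frozenset[Edge] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ancestral_edges", frozenset(self.ancestral_edges))
        object.__setattr__(
            self, "candidate_intervention_edges", frozenset(self.candidate_intervention_edges)
        )
        _check_indices(self.ancestral_edges, self.p, what="ancestral edge")
        if not is_acyclic(self.ancestral_edges, self.p):
            raise ValueError("ancestral edges contain a directed cycle")
        if transitive_closure(self.ancestral_edges, self.p) != set(self.ancestral_edges):
            raise ValueError("ancestral edges are not transitively closed")
        for l, j in self.candidate_intervention_edges:
            if not (1 <= l <= self.q and 1 <= j <= self.p):
                raise IndexError(f"candidate intervention edge ({l}, {j}) out of range")

    def ancestors(self, j: int) -> set[int]:
        return {k for k, jj in self.ancestral_edges if jj == j}

    def candidate_interventions(self, j: int) -> set[int]:
        return {l for l, jj in self.candidate_intervention_edges if jj == j}

    def is_superset_of(self, other: "AncestralRelationGraph") -> bool:
        """Superset in both the ancestral and the intervention edge sets."""
        return self.ancestral_edges >= other.ancestral_edges and (
            self.candidate_intervention_edges >= other.candidate_intervention_edges
        )


def arg_of_dag(g: InterventionDAG) -> AncestralRelationGraph:
    """Ancestral relation graph of a DAG.

    Ancestral edges are the transitive closure of the primary edges; the
    candidate intervention set attaches X_l to Y_j whenever X_l intervenes
    on Y_j itself or on any ancestor of Y_j.
    """
    closure = transitive_closure(g.primary_edges, g.p)
    anc = {j: {k for k, jj in closure if jj == j} for j in range(1, g.p + 1)}
    cand: set[Edge] = set()
    for j in range(1, g.p + 1):
        for k in anc[j] | {j}:
            for l in g.interventions_on(k):
                cand.add((l, j))
    return AncestralRelationGraph(g.p, g.q, frozenset(closure), frozenset(cand))


@dataclass(frozen=True)
class InterventionClassification:
    """Role of each intervention variable plus the everyone-instrumented flag.

    An *instrument* targets exactly one primary variable; an invalid
    instrument targets two or more; an inactive intervention targets none.
    ``all_primary_instrumented`` records whether every primary variable has
    at least one instrument -- the condition under which peeling recovers
    the ancestral relations exactly.
    """

    roles: Mapping[int, str]
    all_primary_instrumented: bool


def classify_interventions(g: InterventionDAG) -> InterventionClassification:
    targets: dict[int, set[int]] = {l: set() for l in range(1, g.q + 1)}
    for l, j in g.intervention_edges:
        targets[l].add(j)
    roles: dict[int, str] = {}
    instrumented: set[int] = set()
    for l in range(1, g.q + 1):
        if len(targets[l]) == 0:
            roles[l] = "inactive"
        elif len(targets[l]) == 1:
            roles[l] = "instrument"
            instrumented |= targets[l]
        else:
            roles[l] = "invalid_instrument"
    return InterventionClassification(
        roles=roles,
        all_primary_instrumented=instrumented == set(range(1, g.p + 1)),
    )


@dataclass(frozen=True)
class HypothesisSpec:
    """A set of hypothesized directed edges among primary variables.

    ``mode`` is ``"edge"`` (null: all hypothesized coefficients are zero)
    or ``"pathway"`` (null: at least one is zero).  Order is preserved so
    pathway sub-hypotheses enumerate deterministically.
    """

    edges: tuple[Edge, ...]
    mode: str = "edge"

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        if self.mode not in ("edge", "pathway"):
            raise ValueError(f"unknown hypothesis mode {self.mode!r}")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in hypothesis")
        for k, j in self.edges:
            if k == j:
                raise ValueError(f"self-loop ({k}, {j}) in hypothesis")

    @classmethod
    def from_path(cls, nodes: Iterable[int]) -> "HypothesisSpec":
        """Pathway a -> b -> c ... expanded to its consecutive edge pairs."""
        nodes = list(nodes)
        if len(nodes) < 2:
            raise ValueError("a pathway needs at least two nodes")
        return cls(tuple(zip(nodes[:-1], nodes[1:])), mode="pathway")


@dataclass(frozen=True)
class HypothesisClassification:
    """Nondegenerate subset of a hypothesis and its regularity status.

    An edge is *nondegenerate* when adding it to the (estimated) ancestral
    edges creates no directed cycle; the hypothesis is *regular* when all
    nondegenerate edges can be added jointly without creating a cycle.
    Degenerate hypotheses receive p-value 1 by definition.
    """

    nondegenerate_edges: tuple[Edge, ...]
    degenerate: bool
    regular: bool

    def __post_init__(self) -> None:
        if self.degenerate != (len(self.nondegenerate_edges) == 0):
            raise ValueError("degenerate flag inconsistent with nondegenerate set")
        if self.degenerate and not self.regular:
            raise ValueError("an empty nondegenerate set cannot be irregular")


def classify_hypothesis(
    h: HypothesisSpec, arg: AncestralRelationGraph
) -> HypothesisClassification:
    """Split a hypothesis into nondegenerate edges and check regularity.

    With a transitively closed ancestral set, edge (k, j) is nondegenerate
    iff (j, k) is not an ancestral pair (and k != j); regularity additionally
    requires the nondegenerate edges plus the ancestral edges to be jointly
    acyclic.
    """
    _check_indices(h.edges, arg.p, what="hypothesis edge")
    nondeg = tuple(
        (k, j) for k, j in h.edges if (j, k) not in arg.ancestral_edges and k != j
    )
    degenerate = len(nondeg) == 0
    if degenerate:
        regular = True
    else:
        regular = is_acyclic(set(nondeg) | set(arg.ancestral_edges), arg.p)
    return HypothesisClassification(nondeg, degenerate, regular)


# -- edge-list serialization -------------------------------------------------
# TSV columns: src_kind (Y|X), src_index, dst_index; indices are 1-based.


def write_edge_tsv(
    path: str | Path,
    primary_edges: Iterable[Edge] = (),
    intervention_edges: Iterable[Edge] = (),
) -> None:
    lines = ["src_kind\tsrc_index\tdst_index"]
    for k, j in sorted(set(primary_edges)):
        lines.append(f"Y\t{k}\t{j}")
    for l, j in sorted(set(intervention_edges)):
        lines.append(f"X\t{l}\t{j}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_tsv(path: str | Path) -> tuple[set[Edge], set[Edge]]:
    primary: set[Edge] = set()
    interv: set[Edge] = set()
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["src_kind", "src_index", "dst_index"]:
        raise ValueError(f"{path}: expected header 'src_kind\\tsrc_index\\tdst_index'")
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        kind, src, dst = line.split("\t")
        if kind == "Y":
            primary.add((int(src), int(dst)))
        elif kind == "X":
            interv.add((int(src), int(dst)))
        else:
            raise ValueError(f"{path}:{ln}: unknown src_kind {kind!r}")
    return primary, interv
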