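"""Discrete Bayesian-network structures and learning.

Implements the model family of the analysis:

* naive Bayes (NB): the class node is the sole parent of every feature, so
  features are conditionally independent given the class;
* tree-augmented naive Bayes (TAN): on top of the class edges, the features
  form a tree of pairwise dependencies.  The tree is the maximum-weight
  spanning tree of the class-conditional mutual information

      I(Xi; Xj | C) = sum_{xi,xj,c} p(xi,xj,c) log[ p(xi,xj|c)
                                                    / (p(xi|c) p(xj|c)) ],

  oriented outward from a randomly chosen root (Chow–Liu construction
  conditioned on the class);
* general DAGs found by score-based greedy hill-climbing (used for arc
  strength model averaging), scored by BIC.

Conditional probability tables are multinomial with a Laplace pseudocount
(default 1) so that every entry is strictly positive, which logic/rejection
sampling relies on.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import CLASS_VAR, CohortTable, FeatureSpec

__all__ = [
    "DAGStructure",
    "CPTSet",
    "FittedClassifier",
    "conditional_mutual_information",
    "cmi_weight_matrix",
    "maximum_weight_spanning_tree",
    "build_nb_structure",
    "learn_tan_structure",
    "tan_root",
    "fit_cpts",
    "bic_score",
    "BICScorer",
    "hill_climb",
    "ancestral_sample",
]


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DAGStructure:
    """A directed acyclic graph over named nodes."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        node_set = set(self.nodes)
        seen = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add((u, v))
        self.topological_order()  # raises on cycles

    # -- queries ------------------------------------------------------------

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(u for u, v in self.edges if v == node)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(v for u, v in self.edges if u == node)

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in set(self.edges)

    def undirected_pairs(self) -> set[tuple[str, str]]:
        """Edge set with orientation erased; pairs sorted lexicographically."""
        return {tuple(sorted((u, v))) for u, v in self.edges}

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; raises ValueError if the graph has a cycle."""
        indeg = {n: 0 for n in self.nodes}
        adj: dict[str, list[str]] = {n: [] for n in self.nodes}
        for u, v in self.edges:
            indeg[v] += 1
            adj[u].append(v)
        queue = [n for n in self.nodes if indeg[n] == 0]
        order: list[str] = []
        while queue:
            n = queue.pop()
            order.append(n)
            for m in adj[n]:
                indeg[m] -= 1
                if indeg[m] == 0:
                    queue.append(m)
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return order

    def is_tan(self, class_var: str = CLASS_VAR) -> bool:
        """Check the TAN structural constraint.

        Every feature has the class as a parent and at most one other
        parent, and the feature–feature (augmenting) edges form a spanning
        tree of the features when there are two or more.
        """
        features = [n for n in self.nodes if n != class_var]
        edge_set = set(self.edges)
        aug = []
        for u, v in self.edges:
            if class_var in (u, v):
                if u != class_var:
                    return False  # class may not have parents
            else:
                aug.append((u, v))
        for f in features:
            if (class_var, f) not in edge_set:
                return False
            non_class = [u for u, v in aug if v == f]
            if len(non_class) > 1:
                return False
        if len(features) >= 2:
            if len(aug) != len(features) - 1:
                return False
            # connectivity of the undirected augmenting graph
            parent = {f: f for f in features}

            def find(x: str) -> str:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for u, v in aug:
                parent[find(u)] = find(v)
            if len({find(f) for f in features}) != 1:
                return False
        return True

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes), "edges": [list(e) for e in self.edges]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DAGStructure":
        return cls(tuple(d["nodes"]), tuple((u, v) for u, v in d["edges"]))


def build_nb_structure(spec: FeatureSpec) -> DAGStructure:
    """Naive Bayes: the class points at every feature; nothing else."""
    if len(spec.feature_names) < 1:
        raise ValueError("need at least one feature")
    nodes = (spec.class_var,) + spec.feature_names
    edges = tuple((spec.class_var, f) for f in spec.feature_names)
    return DAGStructure(nodes, edges)


# ---------------------------------------------------------------------------
# Encoding helpers
# ---------------------------------------------------------------------------


def _as_frame_and_spec(data: CohortTable | pd.DataFrame,
                       spec: FeatureSpec | None) -> tuple[pd.DataFrame, FeatureSpec]:
    if isinstance(data, CohortTable):
        return data.data, data.spec
    if spec is None:
        raise ValueError("a FeatureSpec is required with a bare DataFrame")
    return data, spec


def encode_columns(df: pd.DataFrame, domains: Mapping[str, Sequence[str]],
                   columns: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode selected columns; missing values become -1.

    Returns (codes[n, k], cards[k]) with codes following declared domain
    order, which fixes CPT row indexing everywhere.
    """
    n = len(df)
    codes = np.empty((n, len(columns)), dtype=np.int32)
    cards = np.empty(len(columns), dtype=np.int64)
    for k, col in enumerate(columns):
        dom = list(domains[col])
        cards[k] = len(dom)
        mapping = {v: i for i, v in enumerate(dom)}
        codes[:, k] = df[col].map(mapping).fillna(-1).astype(np.int32).values
    return codes, cards


# ---------------------------------------------------------------------------
# Conditional mutual information and TAN learning
# ---------------------------------------------------------------------------


def conditional_mutual_information(
    data: CohortTable | pd.DataFrame,
    xi: str,
    xj: str,
    class_var: str = CLASS_VAR,
    spec: FeatureSpec | None = None,
) -> float:
    """Plug-in class-conditional mutual information I(xi; xj | class), nats.

    Uses rows complete over {xi, xj, class}; empirical (unsmoothed)
    probabilities; 0·log 0 = 0.  A variable with a single observed state
    contributes zero information.
    """
    df, fspec = _as_frame_and_spec(data, spec)
    domains = fspec.node_domains()
    codes, cards = encode_columns(df, domains, [xi, xj, class_var])
    complete = (codes >= 0).all(axis=1)
    codes = codes[complete]
    n = len(codes)
    if n == 0:
        raise ValueError(f"no complete rows over ({xi!r}, {xj!r}, {class_var!r})")
    ci, cj, cc = (int(c) for c in cards)
    joint = np.bincount(
        (codes[:, 0] * cj + codes[:, 1]) * cc + codes[:, 2], minlength=ci * cj * cc
    ).reshape(ci, cj, cc).astype(float) / n
    p_c = joint.sum(axis=(0, 1))            # p(c)
    p_ic = joint.sum(axis=1)                # p(xi, c)
    p_jc = joint.sum(axis=0)                # p(xj, c)
    total = 0.0
    for a in range(ci):
        for b in range(cj):
            for c in range(cc):
                p = joint[a, b, c]
                if p <= 0.0:
                    continue
                total += p * np.log(p * p_c[c] / (p_ic[a, c] * p_jc[b, c]))
    return float(total)


def cmi_weight_matrix(
    data: CohortTable | pd.DataFrame,
    features: Sequence[str],
    class_var: str = CLASS_VAR,
    spec: FeatureSpec | None = None,
    missing: str = "pairwise",
) -> pd.DataFrame:
    """Symmetric matrix of class-conditional mutual information weights.

    ``missing='pairwise'`` uses complete cases per feature pair (default);
    ``'listwise'`` first drops rows missing any feature or the class.
    """
    df, fspec = _as_frame_and_spec(data, spec)
    if missing == "listwise":
        df = df.dropna(subset=[*features, class_var])
    elif missing != "pairwise":
        raise ValueError("missing must be 'pairwise' or 'listwise'")
    w = pd.DataFrame(0.0, index=list(features), columns=list(features))
    for xi, xj in itertools.combinations(features, 2):
        val = conditional_mutual_information(df, xi, xj, class_var, fspec)
        w.loc[xi, xj] = w.loc[xj, xi] = val
    return w


def maximum_weight_spanning_tree(
    weights: pd.DataFrame,
) -> list[tuple[str, str]]:
    """Kruskal maximum-weight spanning tree over a symmetric weight matrix.

    Ties are broken by lexicographic node-pair order, making the result
    deterministic.  Returned edges are sorted pairs.
    """
    names = list(weights.index)
    if len(names) < 2:
        return []
    edges = sorted(
        ((u, v) for u, v in itertools.combinations(sorted(names), 2)),
        key=lambda e: (-float(weights.loc[e[0], e[1]]), e[0], e[1]),
    )
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[tuple[str, str]] = []
    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v))
            if len(tree) == len(names) - 1:
                break
    return tree


def learn_tan_structure(
    train: CohortTable | pd.DataFrame,
    spec: FeatureSpec | None = None,
    seed: int = 0,
    missing: str = "pairwise",
) -> DAGStructure:
    """Learn a TAN structure from data.

    Steps: class-conditional mutual information per feature pair, maximum
    weight spanning tree over the features, root feature chosen uniformly
    at random (seeded) with edges oriented outward from it, and class
    edges to every feature.
    """
    df, fspec = _as_frame_and_spec(train, spec)
    if len(df) == 0:
        raise ValueError("training data is empty")
    features = fspec.feature_names
    if len(features) < 1:
        raise ValueError("need at least one feature")
    nodes = (fspec.class_var,) + features
    class_edges = tuple((fspec.class_var, f) for f in features)
    if len(features) == 1:
        warnings.warn("single feature: TAN reduces to naive Bayes")
        return DAGStructure(nodes, class_edges)

    weights = cmi_weight_matrix(df, features, fspec.class_var, fspec, missing)
    tree = maximum_weight_spanning_tree(weights)

    rng = np.random.default_rng(seed)
    root = features[int(rng.integers(len(features)))]

    # Orient the tree outward from the root by BFS.
    adjacency: dict[str, list[str]] = {f: [] for f in features}
    for u, v in tree:
        adjacency[u].append(v)
        adjacency[v].append(u)
    oriented: list[tuple[str, str]] = []
    visited = {root}
    frontier = [root]
    while frontier:
        nxt: list[str] = []
        for u in frontier:
            for v in sorted(adjacency[u]):
                if v not in visited:
                    visited.add(v)
                    oriented.append((u, v))
                    nxt.append(v)
        frontier = nxt
    structure = DAGStructure(nodes, class_edges + tuple(oriented))
    assert structure.is_tan(fspec.class_var)
    return structure


def tan_root(structure: DAGStructure, class_var: str = CLASS_VAR) -> str | None:
    """The feature from which the augmenting tree is oriented outward."""
    features = [n for n in structure.nodes if n != class_var]
    roots = [
        f for f in features
        if all(p == class_var for p in structure.parents(f))
    ]
    if len(features) >= 2 and len(roots) == 1:
        return roots[0]
    return None


# ---------------------------------------------------------------------------
# Conditional probability tables
# ---------------------------------------------------------------------------


@dataclass
class CPTSet:
    """Per-node conditional probability tables.

    ``tables[node]`` has shape (n_parent_configs, cardinality); the parent
    configuration index is mixed-radix over the node's parents in stored
    order (first parent most significant), with each parent coded in its
    declared domain order.
    """

    tables: dict[str, np.ndarray]
    parents: dict[str, tuple[str, ...]]
    domains: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for node, table in self.tables.items():
            card = len(self.domains[node])
            n_cfg = int(np.prod([len(self.domains[p]) for p in self.parents[node]])) \
                if self.parents[node] else 1
            if table.shape != (n_cfg, card):
                raise ValueError(
                    f"CPT for {node!r} has shape {table.shape}, expected {(n_cfg, card)}"
                )
            if (table < 0).any():
                raise ValueError(f"negative probability in CPT for {node!r}")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {node!r} do not sum to 1")

    def config_index(self, node: str, assignment: Mapping[str, str]) -> int:
        idx = 0
        for p in self.parents[node]:
            idx = idx * len(self.domains[p]) + self.domains[p].index(assignment[p])
        return idx

    def dist(self, node: str, assignment: Mapping[str, str]) -> np.ndarray:
        """p(node | parent values taken from ``assignment``)."""
        return self.tables[node][self.config_index(node, assignment)]


@dataclass
class FittedClassifier:
    """A structure plus fitted CPTs: everything needed for inference."""

    structure: DAGStructure
    cpts: CPTSet
    spec: FeatureSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.structure.nodes:
            if node not in self.cpts.tables:
                raise ValueError(f"node {node!r} has no CPT")
        kind = self.meta.get("model_kind")
        if kind == "nb":
            nb = build_nb_structure(self.spec)
            if set(self.structure.edges) != set(nb.edges):
                raise ValueError("structure is not naive Bayes")
        elif kind == "tan":
            if not self.structure.is_tan(self.spec.class_var):
                raise ValueError("structure violates the TAN constraint")

    @property
    def class_var(self) -> str:
        return self.spec.class_var

    @property
    def class_domain(self) -> tuple[str, ...]:
        return self.spec.class_domain

    def class_prior(self) -> np.ndarray:
        return self.cpts.tables[self.class_var][0]

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "structure": self.structure.to_dict(),
            "domains": {k: list(v) for k, v in self.cpts.domains.items()},
            "cpts": {
                node: {
                    "parents": list(self.cpts.parents[node]),
                    "table": self.cpts.tables[node].tolist(),
                }
                for node in self.structure.nodes
            },
            "spec": {
                "class_var": self.spec.class_var,
                "class_domain": list(self.spec.class_domain),
                "features": [[n, list(d)] for n, d in self.spec.features],
                "geneset_mode": self.spec.geneset_mode,
            },
            "meta": self.meta,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedClassifier":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        spec = FeatureSpec(
            features=tuple((n, tuple(d)) for n, d in doc["spec"]["features"]),
            class_var=doc["spec"]["class_var"],
            class_domain=tuple(doc["spec"]["class_domain"]),
            geneset_mode=doc["spec"]["geneset_mode"],
        )
        structure = DAGStructure.from_dict(doc["structure"])
        domains = {k: tuple(v) for k, v in doc["domains"].items()}
        cpts = CPTSet(
            tables={k: np.asarray(v["table"], dtype=float) for k, v in doc["cpts"].items()},
            parents={k: tuple(v["parents"]) for k, v in doc["cpts"].items()},
            domains=domains,
        )
        return cls(structure, cpts, spec, dict(doc.get("meta", {})))


def fit_cpts(
    structure: DAGStructure,
    train: CohortTable | pd.DataFrame,
    pseudocount: float = 1.0,
    spec: FeatureSpec | None = None,
    meta: dict | None = None,
) -> FittedClassifier:
    """Estimate CPTs by (smoothed) maximum likelihood.

    p(v | pa) = (count(v, pa) + a) / (count(pa) + a * |domain|).  Each
    node's counts use rows complete over its family.  With a > 0 an
    unobserved parent configuration yields the uniform distribution; with
    a = 0 it is an error.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    df, fspec = _as_frame_and_spec(train, spec)
    domains = fspec.node_domains()
    node_order = {n: i for i, n in enumerate(structure.nodes)}
    tables: dict[str, np.ndarray] = {}
    parents_map: dict[str, tuple[str, ...]] = {}
    for node in structure.nodes:
        parents = tuple(sorted(structure.parents(node), key=node_order.__getitem__))
        parents_map[node] = parents
        cols = [*parents, node]
        codes, cards = encode_columns(df, domains, cols)
        complete = (codes >= 0).all(axis=1)
        codes = codes[complete]
        card = int(cards[-1])
        n_cfg = int(np.prod(cards[:-1])) if parents else 1
        idx = np.zeros(len(codes), dtype=np.int64)
        for k in range(len(cols)):
            idx = idx * cards[k] + codes[:, k]
        counts = np.bincount(idx, minlength=n_cfg * card).reshape(n_cfg, card).astype(float)
        if pseudocount == 0 and (counts.sum(axis=1) == 0).any():
            raise ValueError(
                f"node {node!r}: unobserved parent configuration with "
                "pseudocount 0; use a positive pseudocount (Laplace smoothing)"
            )
        counts += pseudocount
        tables[node] = counts / counts.sum(axis=1, keepdims=True)
    cpts = CPTSet(tables=tables, parents=parents_map,
                  domains={n: tuple(domains[n]) for n in structure.nodes})
    return FittedClassifier(structure, cpts, fspec, dict(meta or {}))


# ---------------------------------------------------------------------------
# BIC scoring and hill-climbing
# ---------------------------------------------------------------------------


class BICScorer:
    """Decomposable BIC score with per-family caching.

    family(child, parents) = max log-likelihood - (log N / 2) * free params,
    computed on rows complete over the family.  Higher is better.
    """

    def __init__(self, data: CohortTable | pd.DataFrame,
                 spec: FeatureSpec | None = None):
        df, fspec = _as_frame_and_spec(data, spec)
        self.nodes = (fspec.class_var,) + fspec.feature_names
        domains = fspec.node_domains()
        self.codes, self.cards = encode_columns(df, domains, self.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family(self, child: str, parents: Iterable[str]) -> float:
        ci = self.index[child]
        pidx = tuple(sorted(self.index[p] for p in parents))
        key = (ci, pidx)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        cols = [*pidx, ci]
        sub = self.codes[:, cols]
        sub = sub[(sub >= 0).all(axis=1)]
        n = len(sub)
        card = int(self.cards[ci])
        n_cfg = int(np.prod(self.cards[list(pidx)])) if pidx else 1
        if n == 0:
            self._cache[key] = 0.0
            return 0.0
        idx = np.zeros(n, dtype=np.int64)
        for k, col in enumerate(cols):
            idx = idx * self.cards[col] + sub[:, k]
        counts = np.bincount(idx, minlength=n_cfg * card).reshape(n_cfg, card)
        row_tot = counts.sum(axis=1)
        nz = counts > 0
        ll = float((counts[nz] * np.log(counts[nz])).sum())
        rnz = row_tot > 0
        ll -= float((row_tot[rnz] * np.log(row_tot[rnz])).sum())
        penalty = 0.5 * np.log(n) * (card - 1) * n_cfg
        score = ll - penalty
        self._cache[key] = score
        return score

    def structure(self, structure: DAGStructure) -> float:
        return sum(self.family(n, structure.parents(n)) for n in structure.nodes)


def bic_score(structure: DAGStructure, data: CohortTable | pd.DataFrame,
              spec: FeatureSpec | None = None) -> float:
    """BIC of a DAG on data: sum of per-node family scores (higher wins)."""
    return BICScorer(data, spec).structure(structure)


def _closure(adj: np.ndarray) -> np.ndarray:
    """Boolean reachability matrix (does a directed path u -> v exist)."""
    reach = adj.copy()
    v = adj.shape[0]
    np.fill_diagonal(reach, True)
    steps = max(1, int(np.ceil(np.log2(max(v, 2)))))
    for _ in range(steps):
        reach = reach | (reach @ reach)
    np.fill_diagonal(reach, False)
    return reach


def _path_avoiding_edge(adj: np.ndarray, src: int, dst: int,
                        drop: tuple[int, int]) -> bool:
    """Is there a path src -> dst after deleting one edge? (small-graph BFS)"""
    a = adj.copy()
    a[drop] = False
    frontier = [src]
    seen = {src}
    while frontier:
        u = frontier.pop()
        for w in np.flatnonzero(a[u]):
            if w == dst:
                return True
            if w not in seen:
                seen.add(int(w))
                frontier.append(int(w))
    return False


def dag_moves(adj: np.ndarray) -> list[tuple[str, int, int]]:
    """All acyclicity-preserving single-edge moves from a DAG (adjacency)."""
    v = adj.shape[0]
    reach = _closure(adj)
    moves: list[tuple[str, int, int]] = []
    for i in range(v):
        for j in range(v):
            if i == j:
                continue
            if adj[i, j]:
                moves.append(("del", i, j))
                if not _path_avoiding_edge(adj, i, j, (i, j)):
                    moves.append(("rev", i, j))
            elif not adj[j, i] and not reach[j, i]:
                moves.append(("add", i, j))
    return moves


def apply_dag_move(adj: np.ndarray, move: tuple[str, int, int]) -> None:
    op, i, j = move
    if op == "add":
        adj[i, j] = True
    elif op == "del":
        adj[i, j] = False
    else:
        adj[i, j] = False
        adj[j, i] = True


def hill_climb(
    data: CohortTable | pd.DataFrame,
    start: DAGStructure,
    scorer: BICScorer | None = None,
    spec: FeatureSpec | None = None,
    max_iter: int | None = None,
    max_parents: int | None = None,
    restarts: int = 0,
    perturb_moves: int = 8,
    seed: int = 0,
) -> DAGStructure:
    """Greedy best-improvement structure search.

    Moves are single-edge additions, deletions and reversals that keep the
    graph acyclic; the search stops at a local optimum (no move improves
    the score) or after ``max_iter`` applied moves.  The returned score is
    never below the starting score.

    With ``restarts`` > 0 the search becomes an iterated local search:
    after converging, the current optimum is perturbed by ``perturb_moves``
    random valid moves and re-climbed, and the best-scoring optimum over
    all rounds is returned.  This costs a constant factor but escapes the
    orientation traps that single-move greedy search falls into when
    started from a dense random graph.
    """
    if scorer is None:
        scorer = BICScorer(data, spec)
    if restarts > 0:
        rng = np.random.default_rng(seed)
        best = hill_climb(data, start, scorer=scorer, max_iter=max_iter,
                          max_parents=max_parents)
        best_score = scorer.structure(best)
        nodes = best.nodes
        index = {n: i for i, n in enumerate(nodes)}
        current = best
        for _ in range(restarts):
            adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
            for u, w in current.edges:
                adj[index[u], index[w]] = True
            for _ in range(perturb_moves):
                moves = dag_moves(adj)
                apply_dag_move(adj, moves[int(rng.integers(len(moves)))])
            perturbed = DAGStructure(
                nodes,
                tuple((nodes[i], nodes[j]) for i, j in zip(*np.nonzero(adj))),
            )
            current = hill_climb(data, perturbed, scorer=scorer,
                                 max_iter=max_iter, max_parents=max_parents)
            score = scorer.structure(current)
            if score > best_score:
                best, best_score = current, score
        return best
    nodes = list(start.nodes)
    if list(scorer.nodes) != nodes:
        # Allow any node order as long as the sets agree.
        if set(scorer.nodes) != set(nodes):
            raise ValueError("start structure nodes do not match the data")
        nodes = list(scorer.nodes)
    v = len(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    if max_iter is None:
        max_iter = 100 * v * v

    adj = np.zeros((v, v), dtype=bool)
    parents: list[set[int]] = [set() for _ in range(v)]
    for u_name, w_name in start.edges:
        u, w = idx[u_name], idx[w_name]
        adj[u, w] = True
        parents[w].add(u)

    def fam(child: int, ps: set[int]) -> float:
        return scorer.family(nodes[child], tuple(nodes[p] for p in ps))

    fam_scores = [fam(j, parents[j]) for j in range(v)]

    for _ in range(max_iter):
        reach = _closure(adj)
        best_delta = 1e-10
        best_move = None
        for i in range(v):
            for j in range(v):
                if i == j:
                    continue
                if adj[i, j]:
                    # delete i -> j
                    delta = fam(j, parents[j] - {i}) - fam_scores[j]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("del", i, j)
                    # reverse i -> j (requires no alternative path i ~> j)
                    if max_parents is None or len(parents[i]) < max_parents:
                        if not _path_avoiding_edge(adj, i, j, (i, j)):
                            delta = (
                                fam(j, parents[j] - {i}) - fam_scores[j]
                                + fam(i, parents[i] | {j}) - fam_scores[i]
                            )
                            if delta > best_delta:
                                best_delta, best_move = delta, ("rev", i, j)
                elif not adj[j, i] and not reach[j, i]:
                    # add i -> j
                    if max_parents is not None and len(parents[j]) >= max_parents:
                        continue
                    delta = fam(j, parents[j] | {i}) - fam_scores[j]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", i, j)
        if best_move is None:
            break
        op, i, j = best_move
        if op == "add":
            adj[i, j] = True
            parents[j].add(i)
        elif op == "del":
            adj[i, j] = False
            parents[j].remove(i)
        else:
            adj[i, j] = False
            parents[j].remove(i)
            adj[j, i] = True
            parents[i].add(j)
        fam_scores[j] = fam(j, parents[j])
        fam_scores[i] = fam(i, parents[i])

    edges = tuple(
        (nodes[i], nodes[j]) for i, j in sorted(zip(*np.nonzero(adj)))
    )
    return DAGStructure(tuple(nodes), tuple((u, w) for u, w in edges))


# ---------------------------------------------------------------------------
# Ancestral sampling (shared by the synthetic generator and inference)
# ---------------------------------------------------------------------------


def ancestral_sample(
    structure: DAGStructure,
    cpts: CPTSet,
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw n joint samples in topological order; returns integer codes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out: dict[str, np.ndarray] = {}
    for node in structure.topological_order():
        table = cpts.tables[node]
        parents = cpts.parents[node]
        if parents:
            cfg = np.zeros(n, dtype=np.int64)
            for p in parents:
                cfg = cfg * len(cpts.domains[p]) + out[p]
            probs = table[cfg]
        else:
            probs = np.broadcast_to(table[0], (n, table.shape[1]))
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        code = (u[:, None] > cum).sum(axis=1).astype(np.int64)
        out[node] = np.minimum(code, table.shape[1] - 1)  # guard cumsum rounding
    return out
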