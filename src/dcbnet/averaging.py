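"""Arc-strength estimation by model averaging.

The confidence in an individual edge of a learned network ("arc
strength") is the relative frequency with which the edge appears across
many independently learned graphs.  Two generators of graph ensembles are
provided:

* nonparametric bootstrap: resample the rows with replacement, learn a
  structure by hill-climbing on each resample;
* MCMC over DAG space: a Metropolis chain whose stationary distribution
  is uniform over DAGs supplies random starting graphs (one kept every
  ``thin`` steps); each kept graph seeds a hill-climb on the data.

Strengths above 0.85 are conventionally deemed strong; significant pairs
are compared against a reference TAN structure to produce a concordance
table (the edge is either confirmed by the TAN or flagged as found only
by averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import CohortTable
from .models import (
    BICScorer,
    DAGStructure,
    apply_dag_move,
    build_nb_structure,
    dag_moves,
    hill_climb,
)

__all__ = [
    "ArcStrengthTable",
    "ConcordanceTable",
    "bootstrap_arc_strength",
    "mcmc_arc_strength",
    "significant_arcs",
    "concordance_with_tan",
    "STRONG_ARC_THRESHOLD",
]

STRONG_ARC_THRESHOLD = 0.85


@dataclass
class ArcStrengthTable:
    """Model-averaged confidence per undirected node pair."""

    strengths: dict[tuple[str, str], float]
    method: str
    B: int
    seed: int | None = None
    weighted: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("replicate count B must be >= 1")
        for pair, s in self.strengths.items():
            if tuple(sorted(pair)) != tuple(pair):
                raise ValueError(f"pair {pair} is not sorted")
            if not -1e-12 <= s <= 1 + 1e-12:
                raise ValueError(f"strength {s} for {pair} outside [0, 1]")

    def entries(self) -> list[tuple[tuple[str, str], float]]:
        return sorted(self.strengths.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [("-".join(pair), s) for pair, s in self.entries()],
            columns=["pair", "strength"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ConcordanceTable:
    """Significant pairs annotated with membership in a reference TAN."""

    rows: list[dict]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["pair", "strength", "significant", "in_tan"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _count_pairs(graphs: Sequence[DAGStructure],
                 weights: np.ndarray | None = None) -> dict[tuple[str, str], float]:
    strengths: dict[tuple[str, str], float] = {}
    if weights is None:
        weights = np.full(len(graphs), 1.0 / len(graphs))
    for g, w in zip(graphs, weights):
        for pair in g.undirected_pairs():
            strengths[pair] = strengths.get(pair, 0.0) + float(w)
    return {p: min(s, 1.0) for p, s in strengths.items()}


def bootstrap_arc_strength(
    data: CohortTable,
    B: int = 500,
    seed: int = 0,
    max_parents: int | None = None,
) -> ArcStrengthTable:
    """Nonparametric-bootstrap arc strengths.

    For each of B replicates, resample n rows with replacement and learn a
    structure by BIC hill-climbing from the empty graph; the strength of a
    pair is the fraction of replicates whose graph contains it in either
    orientation.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(data) == 0:
        raise ValueError("data is empty")
    rng = np.random.default_rng(seed)
    nodes = (data.spec.class_var,) + data.spec.feature_names
    empty = DAGStructure(nodes, ())
    graphs = []
    n = len(data)
    for _ in range(B):
        rows = rng.integers(0, n, size=n)
        resample = CohortTable(
            data.data.iloc[rows].set_axis(range(n)), data.spec
        )
        graphs.append(
            hill_climb(resample, empty, max_parents=max_parents)
        )
    return ArcStrengthTable(
        strengths=_count_pairs(graphs), method="bootstrap", B=B, seed=seed
    )


# ---------------------------------------------------------------------------
# Uniform-DAG MCMC
# ---------------------------------------------------------------------------


def sample_uniform_dags(
    nodes: Sequence[str],
    n_keep: int,
    thin: int = 50,
    seed: int = 0,
    burn_in: int | None = None,
) -> list[DAGStructure]:
    """Approximately uniform DAG samples via a Metropolis edge-move chain.

    Proposals pick uniformly among the valid add/delete/reverse moves of
    the current graph; the acceptance ratio |moves(g)| / |moves(g')|
    balances the differing neighbourhood sizes so the stationary
    distribution is uniform over DAGs.
    """
    if n_keep < 1 or thin < 1:
        raise ValueError("n_keep and thin must be >= 1")
    rng = np.random.default_rng(seed)
    v = len(nodes)
    if burn_in is None:
        burn_in = 10 * v * v
    adj = np.zeros((v, v), dtype=bool)
    moves = dag_moves(adj)
    kept: list[DAGStructure] = []
    step = 0
    total_steps = burn_in + n_keep * thin
    while step < total_steps:
        proposal = moves[int(rng.integers(len(moves)))]
        new_adj = adj.copy()
        apply_dag_move(new_adj, proposal)
        new_moves = dag_moves(new_adj)
        if rng.random() < len(moves) / len(new_moves):
            adj, moves = new_adj, new_moves
        step += 1
        if step > burn_in and (step - burn_in) % thin == 0:
            edges = tuple(
                (nodes[i], nodes[j]) for i, j in zip(*np.nonzero(adj))
            )
            kept.append(DAGStructure(tuple(nodes), edges))
    return kept


def mcmc_arc_strength(
    data: CohortTable,
    n_keep: int = 500,
    thin: int = 50,
    seed: int = 0,
    weighting: bool = False,
    resample: bool = False,
    max_parents: int | None = None,
    burn_in: int | None = None,
    restarts: int = 10,
) -> ArcStrengthTable:
    """Arc strengths from MCMC-sampled random starting graphs.

    Uniformly random DAGs (one kept per ``thin`` chain steps) each seed a
    BIC hill-climb on the data; pair strength is the (optionally
    score-weighted) frequency of the pair among the resulting graphs.
    ``weighting=True`` weights each graph by its normalized
    exp(BIC) posterior-score weight instead of uniformly.
    ``resample=True`` additionally bootstraps the data per kept graph.
    """
    if len(data) == 0:
        raise ValueError("data is empty")
    nodes = (data.spec.class_var,) + data.spec.feature_names
    starts = sample_uniform_dags(nodes, n_keep, thin, seed, burn_in)
    rng = np.random.default_rng(seed + 1)
    n = len(data)
    scorer = None if resample else BICScorer(data)
    graphs: list[DAGStructure] = []
    scores = np.empty(len(starts))
    for k, start in enumerate(starts):
        if resample:
            rows = rng.integers(0, n, size=n)
            d = CohortTable(data.data.iloc[rows].set_axis(range(n)), data.spec)
            s = BICScorer(d)
        else:
            s = scorer
        g = hill_climb(data, start, scorer=s, max_parents=max_parents,
                       restarts=restarts, seed=int(rng.integers(2**31)))
        graphs.append(g)
        scores[k] = s.structure(g)
    if weighting:
        w = np.exp(scores - scores.max())
        w /= w.sum()
    else:
        w = None
    return ArcStrengthTable(
        strengths=_count_pairs(graphs, w),
        method="mcmc",
        B=len(graphs),
        seed=seed,
        weighted=weighting,
    )


def significant_arcs(
    table: ArcStrengthTable, threshold: float = STRONG_ARC_THRESHOLD
) -> list[tuple[str, str]]:
    """Pairs with strength strictly above threshold, strongest first."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return [pair for pair, s in table.entries() if s > threshold]


def concordance_with_tan(
    table: ArcStrengthTable,
    tan: DAGStructure,
    threshold: float = STRONG_ARC_THRESHOLD,
    class_var: str = "dcb",
) -> ConcordanceTable:
    """Mark each significant pair as present or absent in a reference TAN.

    A pair is ``in_tan`` iff it is a class edge or an augmenting edge of
    the TAN, orientation ignored.
    """
    if not tan.is_tan(class_var):
        raise ValueError("reference structure violates the TAN constraint")
    tan_pairs = tan.undirected_pairs()
    rows = []
    for pair, s in table.entries():
        if s > threshold:
            rows.append(
                {
                    "pair": "-".join(pair),
                    "strength": s,
                    "significant": True,
                    "in_tan": pair in tan_pairs,
                }
            )
    return ConcordanceTable(rows=rows, threshold=threshold)
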