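"""Posterior computation on fitted networks.

Three routes, all over the same fitted classifier:

* :func:`posterior_class` — the exact class posterior under full evidence,
  p(C | x1..xn) ∝ p(C) · Π p(xk | parents(xk), C), which is the closed
  form both NB and TAN share;
* :func:`exact_query` — exact conditional marginals by enumerating the
  whole joint state space (feasible at this problem's scale, and the
  oracle for the sampler);
* :func:`rejection_sample_query` — logic (rejection) sampling: ancestral
  samples of the full network, keeping only draws that match the
  evidence.  This is what makes prediction under partial evidence
  possible, e.g. scoring a patient from gene variants alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .models import DAGStructure, FittedClassifier, ancestral_sample

__all__ = [
    "EvidenceQuery",
    "PosteriorReport",
    "LowAcceptanceError",
    "posterior_class",
    "exact_query",
    "rejection_sample_query",
    "predict_label",
    "predict_proba",
]


class LowAcceptanceError(RuntimeError):
    """Raised when rejection sampling keeps too few draws to trust."""


@dataclass(frozen=True)
class EvidenceQuery:
    """A partial assignment of observed variables."""

    assignments: tuple[tuple[str, str], ...]

    def __init__(self, assignments: Mapping[str, str]):
        object.__setattr__(self, "assignments", tuple(sorted(assignments.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.assignments)

    def validate(self, model: FittedClassifier, class_is_query: bool = True) -> None:
        domains = model.cpts.domains
        for var, val in self.assignments:
            if var not in domains:
                raise ValueError(f"unknown evidence variable {var!r}")
            if val not in domains[var]:
                raise ValueError(
                    f"value {val!r} not in domain of {var!r}: {domains[var]}"
                )
            if class_is_query and var == model.class_var:
                raise ValueError("the class variable cannot be evidence here")


@dataclass
class PosteriorReport:
    """Class posterior plus marginals for every unobserved variable."""

    class_posterior: dict[str, float]
    hidden_marginals: dict[str, dict[str, float]]
    n_draws: int
    n_accepted: int
    seed: int | None = None
    method: str = "exact"

    def __post_init__(self) -> None:
        if self.n_accepted > self.n_draws:
            raise ValueError("n_accepted cannot exceed n_draws")
        for name, dist in [("class", self.class_posterior),
                           *self.hidden_marginals.items()]:
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"distribution for {name!r} sums to {total}")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "class_posterior": self.class_posterior,
            "hidden_marginals": self.hidden_marginals,
            "n_draws": self.n_draws,
            "n_accepted": self.n_accepted,
            "seed": self.seed,
            "method": self.method,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _normalize_evidence(evidence) -> dict[str, str]:
    if isinstance(evidence, EvidenceQuery):
        return evidence.as_dict()
    return dict(evidence)


def posterior_class(
    model: FittedClassifier, evidence: Mapping[str, str] | EvidenceQuery
) -> dict[str, float]:
    """Exact class posterior when every feature is observed.

    Computes p(C=c) · Π p(xk | parents(xk)) per class state in log space
    and normalizes; deterministic and order-invariant.
    """
    ev = _normalize_evidence(evidence)
    features = model.spec.feature_names
    missing = [f for f in features if f not in ev or ev[f] is None]
    if missing:
        raise ValueError(
            f"features {missing} unobserved; use exact_query or "
            "rejection_sample_query for partial evidence"
        )
    EvidenceQuery({k: v for k, v in ev.items() if k in features}).validate(model)
    cvar, cdom = model.class_var, model.class_domain
    log_post = np.zeros(len(cdom))
    prior = model.class_prior()
    for ci, cval in enumerate(cdom):
        assignment = {**ev, cvar: cval}
        logp = np.log(prior[ci])
        for f in features:
            dist = model.cpts.dist(f, assignment)
            logp += np.log(dist[model.cpts.domains[f].index(ev[f])])
        log_post[ci] = logp
    log_post -= log_post.max()
    p = np.exp(log_post)
    p /= p.sum()
    return {cval: float(p[ci]) for ci, cval in enumerate(cdom)}


def exact_query(
    model: FittedClassifier,
    evidence: Mapping[str, str] | EvidenceQuery,
    max_states: int = 10**7,
) -> PosteriorReport:
    """Exact conditional marginals by full joint enumeration.

    Builds the joint probability tensor from the factorization and
    conditions on the evidence; errors out beyond ``max_states`` states.
    """
    ev = _normalize_evidence(evidence)
    EvidenceQuery(ev).validate(model, class_is_query=False)
    nodes = list(model.structure.topological_order())
    domains = model.cpts.domains
    cards = [len(domains[n]) for n in nodes]
    n_states = int(np.prod(cards))
    if n_states > max_states:
        raise ValueError(
            f"joint state space has {n_states} states (> {max_states}); "
            "use rejection_sample_query"
        )
    axis = {n: i for i, n in enumerate(nodes)}
    joint = np.ones(cards)
    for node in nodes:
        parents = model.cpts.parents[node]
        table = model.cpts.tables[node]
        # factor with axes (parents..., node), broadcast into the joint
        shape = [len(domains[p]) for p in parents] + [len(domains[node])]
        factor = table.reshape(shape)
        order = [*[axis[p] for p in parents], axis[node]]
        # permute factor dims into increasing joint-axis order, then reshape
        # with singleton axes elsewhere so it broadcasts into the joint
        factor_sorted = np.transpose(factor, np.argsort(order))
        expand = [1] * len(nodes)
        for a in order:
            expand[a] = cards[a]
        joint = joint * factor_sorted.reshape(expand)
    # condition on evidence by zeroing non-matching slices
    for var, val in ev.items():
        k = domains[var].index(val)
        sl = [slice(None)] * len(nodes)
        mask = np.zeros(len(domains[var]))
        mask[k] = 1.0
        shape = [1] * len(nodes)
        shape[axis[var]] = len(domains[var])
        joint = joint * mask.reshape(shape)
    total = joint.sum()
    if total <= 0:
        raise ValueError("evidence has zero probability under the model")
    joint = joint / total

    def marginal(var: str) -> dict[str, float]:
        axes = tuple(i for i in range(len(nodes)) if i != axis[var])
        m = joint.sum(axis=axes)
        return {v: float(m[k]) for k, v in enumerate(domains[var])}

    hidden = [n for n in nodes if n not in ev and n != model.class_var]
    return PosteriorReport(
        class_posterior=marginal(model.class_var),
        hidden_marginals={h: marginal(h) for h in hidden},
        n_draws=0,
        n_accepted=0,
        method="exact",
    )


def rejection_sample_query(
    model: FittedClassifier,
    evidence: Mapping[str, str] | EvidenceQuery,
    n_draws: int = 10**6,
    seed: int = 0,
    min_accept: int = 100,
    batch_size: int = 250_000,
) -> PosteriorReport:
    """Logic-sampling posterior under partial evidence.

    Ancestral-samples the full network ``n_draws`` times, keeps draws
    matching the evidence, and reports the empirical class posterior and
    hidden-variable marginals over the accepted draws.  Raises
    :class:`LowAcceptanceError` when fewer than ``min_accept`` draws are
    kept — a noisy estimate is worse than an explicit failure.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    ev = _normalize_evidence(evidence)
    EvidenceQuery(ev).validate(model, class_is_query=False)
    domains = model.cpts.domains
    ev_codes = {var: domains[var].index(val) for var, val in ev.items()}
    rng = np.random.default_rng(seed)
    nodes = list(model.structure.nodes)
    report_vars = [n for n in nodes if n not in ev]
    counts = {n: np.zeros(len(domains[n]), dtype=np.int64) for n in report_vars}
    accepted = 0
    remaining = n_draws
    while remaining > 0:
        m = min(batch_size, remaining)
        remaining -= m
        draws = ancestral_sample(model.structure, model.cpts, m, rng)
        keep = np.ones(m, dtype=bool)
        for var, code in ev_codes.items():
            keep &= draws[var] == code
        accepted += int(keep.sum())
        for var in report_vars:
            counts[var] += np.bincount(draws[var][keep], minlength=len(domains[var]))
    if accepted < min_accept:
        raise LowAcceptanceError(
            f"only {accepted} of {n_draws} draws matched the evidence "
            f"(acceptance rate {accepted / n_draws:.2e}); "
            "need at least "
            f"{min_accept} — consider exact_query or more draws"
        )

    def dist(var: str) -> dict[str, float]:
        p = counts[var] / accepted
        return {v: float(p[k]) for k, v in enumerate(domains[var])}

    hidden = [n for n in report_vars if n != model.class_var]
    return PosteriorReport(
        class_posterior=dist(model.class_var),
        hidden_marginals={h: dist(h) for h in hidden},
        n_draws=n_draws,
        n_accepted=accepted,
        seed=seed,
        method="rejection",
    )


def predict_label(
    class_posterior: Mapping[str, float] | float,
    threshold: float = 0.5,
    positive: str = "benefit",
    negative: str = "no_benefit",
) -> str:
    """Binary DCB call: 'benefit' iff p(benefit) >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    p = class_posterior if isinstance(class_posterior, float) \
        else float(class_posterior[positive])
    return positive if p >= threshold else negative


def predict_proba(model: FittedClassifier, cohort, positive: str = "benefit",
                  max_states: int = 10**7) -> np.ndarray:
    """P(benefit) per patient; exact enumeration for rows with missing data."""
    from .cohort_io import CohortTable  # local import to avoid cycles

    df = cohort.data if isinstance(cohort, CohortTable) else cohort
    features = model.spec.feature_names
    out = np.empty(len(df))
    for k, (_, row) in enumerate(df.iterrows()):
        ev = {f: row[f] for f in features if isinstance(row[f], str)}
        if len(ev) == len(features):
            post = posterior_class(model, ev)
        else:
            post = exact_query(model, ev, max_states=max_states).class_posterior
        out[k] = post[positive]
    return out
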