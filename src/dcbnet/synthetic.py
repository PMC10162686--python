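"""Synthetic NSCLC immunotherapy cohorts with a known ground truth.

The generator draws cohorts from a fixed tree-augmented naive Bayes model
over the study's variables — a binary DCB class, four clinical features
(sex, dichotomized age, smoking status, three-level histology) and seven
binary gene-variant indicators — plus DCB-dependent right-censored
progression-free survival.  Because the generative structure and CPTs are
known exactly, every downstream stage (structure learning, CPT recovery,
inference, arc-strength averaging, survival stratification) can be tested
offline against the truth.

The augmenting tree mirrors dependency patterns reported for this disease
setting: smoking with KRAS and KMT2C variants, KRAS with TP53 and with
histology, STK11 with KEAP1 co-variation, and demographic coupling
(smoking with age, age with sex).  Conditional probabilities are chosen to
give every edge a strong signal (per-parent probability shifts of roughly
0.15–0.35) so that recovery experiments are well posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    CLASS_VAR,
    CohortTable,
    FeatureSpec,
)
from .models import CPTSet, DAGStructure, FittedClassifier, ancestral_sample

__all__ = [
    "SurvivalParams",
    "GroundTruthModel",
    "default_ground_truth",
    "sample_cohort",
    "sample_survival",
    "write_cohort_tables",
]

FREQUENCY_GENES = ("TP53", "KRAS", "TTN", "KMT2C", "SMARCA4", "STK11", "KEAP1")

#: Augmenting tree (oriented outward from the smoker root).
_TREE_EDGES = (
    ("smoker", "age"),
    ("age", "sex"),
    ("smoker", "KRAS"),
    ("smoker", "KMT2C"),
    ("KRAS", "TP53"),
    ("KRAS", "histology"),
    ("histology", "TTN"),
    ("TTN", "SMARCA4"),
    ("TP53", "STK11"),
    ("STK11", "KEAP1"),
)


@dataclass(frozen=True)
class SurvivalParams:
    """Exponential proportional-hazards survival with uniform censoring.

    ``baseline_rate`` is the event rate (events/month) for non-DCB
    patients; DCB patients progress at ``baseline_rate * hazard_ratio``
    (ratio < 1 means DCB confers longer progression-free survival);
    censoring times are uniform on (0, ``censor_horizon``) months.
    """

    baseline_rate: float = 0.15
    hazard_ratio: float = 0.35
    censor_horizon: float = 30.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be > 0")


@dataclass
class GroundTruthModel:
    """A fully specified TAN + survival model used as the simulation truth."""

    structure: DAGStructure
    cpts: CPTSet
    spec: FeatureSpec
    survival: SurvivalParams = field(default_factory=SurvivalParams)

    def __post_init__(self) -> None:
        if not self.structure.is_tan(self.spec.class_var):
            raise ValueError("ground-truth structure must satisfy the TAN constraint")
        for node, table in self.cpts.tables.items():
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows for {node!r} must sum to 1 within 1e-12")
            if (table <= 0).any() or (table >= 1).any():
                raise ValueError(f"CPT entries for {node!r} must lie strictly in (0,1)")

    @property
    def class_prior(self) -> float:
        """P(benefit) under the truth."""
        k = self.spec.class_domain.index("benefit")
        return float(self.cpts.tables[self.spec.class_var][0, k])

    def as_classifier(self) -> FittedClassifier:
        return FittedClassifier(self.structure, self.cpts, self.spec,
                                meta={"model_kind": "tan", "source": "ground_truth"})

    def augmenting_skeleton(self) -> set[tuple[str, str]]:
        """Undirected feature–feature edges of the truth."""
        return {
            tuple(sorted(e)) for e in self.structure.edges
            if self.spec.class_var not in e
        }

    def skeleton(self) -> set[tuple[str, str]]:
        """All undirected edges (class edges + augmenting tree)."""
        return self.structure.undirected_pairs()

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "classifier": json.loads(self.as_classifier().to_json()),
            "survival": {
                "baseline_rate": self.survival.baseline_rate,
                "hazard_ratio": self.survival.hazard_ratio,
                "censor_horizon": self.survival.censor_horizon,
            },
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruthModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        clf = FittedClassifier.from_json(json.dumps(doc["classifier"]))
        return cls(clf.structure, clf.cpts, clf.spec,
                   SurvivalParams(**doc["survival"]))


def _binary(rows: Sequence[float]) -> np.ndarray:
    """CPT for a binary child from P(level 1) per parent configuration."""
    p = np.asarray(rows, dtype=float)
    return np.column_stack([1.0 - p, p])


def default_ground_truth(
    class_prior: float = 0.35,
    survival: SurvivalParams | None = None,
) -> GroundTruthModel:
    """The default 12-node ground truth (DCB class + 11 features).

    ``class_prior`` is the marginal probability of durable clinical
    benefit; the cohorts this emulates do not report it, so it is a free
    parameter of the simulation.
    """
    if not 0 < class_prior < 1:
        raise ValueError("class_prior must lie in (0, 1)")
    spec = FeatureSpec.with_genes(FREQUENCY_GENES, "frequency")
    nodes = (spec.class_var,) + spec.feature_names
    class_edges = tuple((spec.class_var, f) for f in spec.feature_names)
    structure = DAGStructure(nodes, class_edges + _TREE_EDGES)

    domains = spec.node_domains()
    node_order = {n: i for i, n in enumerate(nodes)}
    parents = {
        n: tuple(sorted(structure.parents(n), key=node_order.__getitem__))
        for n in nodes
    }

    # Parent configuration rows are enumerated with the first parent most
    # significant; parents are (dcb, tree-parent) ordered by node position,
    # so rows run (no_benefit, p0), (no_benefit, p1), (benefit, p0), ...
    tables: dict[str, np.ndarray] = {
        CLASS_VAR: np.array([[1.0 - class_prior, class_prior]]),
        # P(male | dcb, age{<65,>=65})
        "sex": _binary([0.40, 0.65, 0.60, 0.80]),
        # P(>=65 | dcb, smoker{never,ever})
        "age": _binary([0.45, 0.65, 0.30, 0.50]),
        # P(ever | dcb)
        "smoker": _binary([0.50, 0.88]),
        # P(adeno, squamous, other | dcb, KRAS{wt,variant})
        "histology": np.array(
            [
                [0.58, 0.30, 0.12],
                [0.82, 0.11, 0.07],
                [0.20, 0.62, 0.18],
                [0.48, 0.42, 0.10],
            ]
        ),
        # P(variant | dcb, KRAS{wt,variant})
        "TP53": _binary([0.35, 0.65, 0.55, 0.85]),
        # P(variant | dcb, smoker{never,ever})
        "KRAS": _binary([0.06, 0.30, 0.22, 0.68]),
        # P(variant | dcb, histology{adeno,squamous,other})
        "TTN": _binary([0.22, 0.52, 0.38, 0.55, 0.85, 0.70]),
        # P(variant | dcb, smoker{never,ever})
        "KMT2C": _binary([0.10, 0.32, 0.30, 0.62]),
        # P(variant | dcb, TTN{wt,variant}); class effect reverses with
        # TTN status (effect modification NB cannot represent)
        "SMARCA4": _binary([0.10, 0.65, 0.45, 0.10]),
        # P(variant | dcb, TP53{wt,variant})
        "STK11": _binary([0.30, 0.62, 0.04, 0.18]),
        # P(variant | dcb, STK11{wt,variant}); STK11/KEAP1 co-variation is
        # concentrated in non-benefit patients (effect modification)
        "KEAP1": _binary([0.15, 0.80, 0.35, 0.08]),
    }
    cpts = CPTSet(
        tables=tables,
        parents=parents,
        domains={n: tuple(domains[n]) for n in nodes},
    )
    return GroundTruthModel(structure, cpts, spec,
                            survival or SurvivalParams())


def sample_survival(
    dcb: Sequence[str] | np.ndarray,
    params: SurvivalParams,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Progression times and event flags given per-patient DCB labels.

    Event times are exponential with rate ``baseline_rate`` (non-DCB) or
    ``baseline_rate * hazard_ratio`` (DCB); censoring is uniform on
    (0, horizon); the observation is the minimum with an event flag.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    dcb = np.asarray(dcb)
    is_benefit = dcb == "benefit"
    rates = np.where(is_benefit, params.baseline_rate * params.hazard_ratio,
                     params.baseline_rate)
    event_times = rng.exponential(1.0 / rates)
    censor_times = rng.uniform(0.0, params.censor_horizon, size=len(dcb))
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(float)
    return times, events


def sample_cohort(
    model: GroundTruthModel,
    n: int = 290,
    seed: int = 0,
    cohort_label: str = "synthetic",
) -> CohortTable:
    """Draw an n-patient cohort by ancestral sampling plus survival times."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    codes = ancestral_sample(model.structure, model.cpts, n, rng)
    domains = model.cpts.domains
    df = pd.DataFrame(index=pd.Index(
        [f"SYN-{i:05d}" for i in range(n)], name="patient_id"))
    for node in (model.spec.class_var,) + model.spec.feature_names:
        dom = np.asarray(domains[node], dtype=object)
        df[node] = dom[codes[node]]
    times, events = sample_survival(df[CLASS_VAR].values, model.survival, rng)
    df["pfs_months"] = times
    df["pfs_event"] = events
    df["cohort"] = cohort_label
    return CohortTable(df, model.spec)


# ---------------------------------------------------------------------------
# Round-trip table writers (same dialect cohort_io reads)
# ---------------------------------------------------------------------------

_RAW_HISTOLOGY = {
    "adenocarcinoma": "Lung Adenocarcinoma",
    "squamous": "Lung Squamous Cell Carcinoma",
    "other": "Large Cell Carcinoma",
}
_QUALIFYING_MAF = (
    "Missense_Mutation",
    "Frame_Shift_Del",
    "In_Frame_Del",
    "Splice_Site",
)


def write_cohort_tables(
    cohort: CohortTable,
    clinical_path: str | Path,
    mutation_path: str | Path,
    seed: int = 0,
    silent_rate: float = 0.05,
) -> None:
    """Emit the cohort as the clinical + mutation CSV dialect cohort_io reads.

    Categorical age is realised as a numeric age consistent with the <65
    dichotomy; variant indicators become MAF-style mutation rows with a
    qualifying variant class; a sprinkling of non-qualifying 'Silent'
    records exercises the category filter.  Reading the two files back and
    rebuilding the feature table reproduces the cohort exactly.
    """
    rng = np.random.default_rng(seed)
    df = cohort.data
    n = len(df)
    age_num = np.where(
        df["age"] == "<65",
        rng.integers(40, 65, size=n),
        rng.integers(65, 85, size=n),
    ).astype(object)
    age_num[df["age"].isna().values] = ""
    clinical = pd.DataFrame(
        {
            "patient_id": df.index,
            "age": age_num,
            "sex": df["sex"].fillna(""),
            "smoker": df["smoker"].fillna(""),
            "histology": df["histology"].map(_RAW_HISTOLOGY).fillna(""),
            "dcb": df[CLASS_VAR].fillna(""),
            "pfs_months": df["pfs_months"],
            "pfs_event": df["pfs_event"],
            "cohort": df["cohort"],
        }
    )
    clinical.to_csv(clinical_path, index=False)

    rows = []
    for pid, row in df.iterrows():
        for gene in cohort.spec.gene_names:
            if row[gene] == "variant":
                vclass = _QUALIFYING_MAF[int(rng.integers(len(_QUALIFYING_MAF)))]
                rows.append((pid, gene, vclass))
            elif rng.random() < silent_rate:
                rows.append((pid, gene, "Silent"))
    pd.DataFrame(rows, columns=["Tumor_Sample_Barcode", "Hugo_Symbol",
                                "Variant_Classification"]) \
        .to_csv(mutation_path, index=False)
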