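"""Reading and curating clinical + mutation tables into analysis-ready cohorts.

The analysis works on a per-patient table of finite categorical features
(sex, dichotomized age, smoking status, histopathology and a handful of
binary gene-variant indicators), a binary class variable DCB (durable
clinical benefit: partial response or stable disease lasting more than six
months under RECIST v1.1), and a right-censored progression-free-survival
endpoint.  This module turns raw delimited-text clinical and mutation
tables (cBioPortal/MAF-style dialects) into that form and applies the
curation rules of the study design: qualifying variant categories,
histology exclusions, frequency- or evidence-based gene selection, and a
seeded 2:1 train/test split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Domains and fixed vocabulary
# ---------------------------------------------------------------------------

CLASS_VAR = "dcb"
CLASS_DOMAIN = ("no_benefit", "benefit")
BENEFIT = "benefit"
NO_BENEFIT = "no_benefit"

GENE_DOMAIN = ("wt", "variant")

#: Clinical features shared by every model variant, with their domains.
CLINICAL_FEATURES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("sex", ("female", "male")),
    ("age", ("<65", ">=65")),
    ("smoker", ("never", "ever")),
    ("histology", ("adenocarcinoma", "squamous", "other")),
)

#: Literature-derived geneset: genes with reported associations between
#: variants and ICI response/prognosis in NSCLC.
EVIDENCE_GENESET = ("KRAS", "STK11", "TP53", "EGFR", "ALK", "ROS1")

#: Variant classes counted as function-impairing "genetic variants".
QUALIFYING_CATEGORIES = frozenset(
    {
        "deletion",
        "in frame deletion",
        "frameshift deletion",
        "splice variant",
        "missense",
    }
)

# MAF-style and free-text synonyms, keyed by normalized form.
_VARIANT_SYNONYMS = {
    "missense mutation": "missense",
    "missense variant": "missense",
    "frame shift del": "frameshift deletion",
    "frameshift del": "frameshift deletion",
    "frame shift deletion": "frameshift deletion",
    "in frame del": "in frame deletion",
    "inframe deletion": "in frame deletion",
    "in frame deletion": "in frame deletion",
    "splice site": "splice variant",
    "splice site variant": "splice variant",
    "del": "deletion",
}

_SEX_MAP = {"f": "female", "female": "female", "m": "male", "male": "male"}
_SMOKER_MAP = {
    "never": "never",
    "no": "never",
    "nonsmoker": "never",
    "non smoker": "never",
    "ever": "ever",
    "yes": "ever",
    "current": "ever",
    "former": "ever",
    "smoker": "ever",
    "current/former": "ever",
}
_DCB_MAP = {
    "benefit": BENEFIT,
    "dcb": BENEFIT,
    "durable clinical benefit": BENEFIT,
    "1": BENEFIT,
    "yes": BENEFIT,
    "true": BENEFIT,
    "no_benefit": NO_BENEFIT,
    "no benefit": NO_BENEFIT,
    "ndb": NO_BENEFIT,
    "no durable benefit": NO_BENEFIT,
    "0": NO_BENEFIT,
    "no": NO_BENEFIT,
    "false": NO_BENEFIT,
}

_HISTOLOGY_ADENO = {"adenocarcinoma", "lung adenocarcinoma", "luad", "adeno"}
_HISTOLOGY_SQUAMOUS = {
    "squamous",
    "squamous cell carcinoma",
    "lung squamous cell carcinoma",
    "lusc",
}
# Labels carrying no usable subtype information; treated as missing.
_HISTOLOGY_UNSPECIFIED = {
    "",
    "na",
    "nan",
    "unknown",
    "nsclc",
    "non small cell lung cancer",
    "nsclc not otherwise specified",
    "nsclc nos",
    "not otherwise specified",
}

#: Histologies removed during curation by default (rare subtypes).
DEFAULT_EXCLUDED_HISTOLOGIES = frozenset({"large cell neuroendocrine carcinoma"})


def _normalize(text: object) -> str:
    """Lower-case, separator-insensitive normal form of a free-text label."""
    s = str(text).strip().lower()
    for ch in "_-,/":
        s = s.replace(ch, " ")
    return " ".join(s.split())


def normalize_variant_class(variant_class: str) -> str:
    """Canonical form of a variant-classification string."""
    norm = _normalize(variant_class)
    return _VARIANT_SYNONYMS.get(norm, norm)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One mutation-table row: a variant call for one gene in one patient."""

    patient_id: str
    gene: str
    variant_class: str

    def __post_init__(self) -> None:
        if not str(self.patient_id).strip():
            raise ValueError("VariantRecord.patient_id must be nonempty")
        if not str(self.gene).strip():
            raise ValueError("VariantRecord.gene must be nonempty")

    @property
    def qualifies(self) -> bool:
        return normalize_variant_class(self.variant_class) in QUALIFYING_CATEGORIES


@dataclass(frozen=True)
class FeatureSpec:
    """Declares the class variable and the ordered categorical feature set."""

    features: tuple[tuple[str, tuple[str, ...]], ...]
    class_var: str = CLASS_VAR
    class_domain: tuple[str, ...] = CLASS_DOMAIN
    geneset_mode: str = "frequency"

    def __post_init__(self) -> None:
        names = [name for name, _ in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if self.class_var in names:
            raise ValueError("class variable may not appear among features")
        for name, domain in self.features:
            if len(domain) == 0:
                raise ValueError(f"feature {name!r} has an empty domain")
        if self.geneset_mode not in {"frequency", "evidence"}:
            raise ValueError("geneset_mode must be 'frequency' or 'evidence'")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.features)

    @property
    def gene_names(self) -> tuple[str, ...]:
        clinical = {name for name, _ in CLINICAL_FEATURES}
        return tuple(n for n in self.feature_names if n not in clinical)

    def domain(self, name: str) -> tuple[str, ...]:
        if name == self.class_var:
            return self.class_domain
        for fname, dom in self.features:
            if fname == name:
                return dom
        raise KeyError(name)

    def node_domains(self) -> dict[str, tuple[str, ...]]:
        """Domains for every network node (class first)."""
        out = {self.class_var: self.class_domain}
        out.update({name: dom for name, dom in self.features})
        return out

    @classmethod
    def with_genes(cls, genes: Sequence[str], geneset_mode: str = "frequency") -> "FeatureSpec":
        features = CLINICAL_FEATURES + tuple((g, GENE_DOMAIN) for g in genes)
        return cls(features=features, geneset_mode=geneset_mode)


#: Columns beyond the features that a cohort table carries.
_EXTRA_COLUMNS = (CLASS_VAR, "pfs_months", "pfs_event", "cohort")


@dataclass
class CohortTable:
    """Per-patient feature table plus class label and survival endpoint.

    ``data`` is indexed by patient id and holds one column per declared
    feature (categorical strings, NaN for missing), the class column
    ``dcb`` in {'benefit', 'no_benefit', NaN}, ``pfs_months`` (float >= 0
    or NaN), ``pfs_event`` (1.0 event / 0.0 censored / NaN), and a
    ``cohort`` label.  An optional ``raw_histology`` column preserves the
    source label for exclusion rules.
    """

    data: pd.DataFrame
    spec: FeatureSpec

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate patient ids: {dupes}")
        for col in self.spec.feature_names + _EXTRA_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        for name in self.spec.feature_names:
            dom = set(self.spec.domain(name))
            vals = self.data[name].dropna()
            bad = vals[~vals.isin(dom)]
            if len(bad):
                raise ValueError(
                    f"feature {name!r} has values outside its domain: "
                    f"{sorted(set(bad))} (rows {bad.index.tolist()[:5]})"
                )
        dcb_vals = self.data[CLASS_VAR].dropna()
        bad = dcb_vals[~dcb_vals.isin(set(self.spec.class_domain))]
        if len(bad):
            raise ValueError(f"dcb values outside domain: {sorted(set(bad))}")
        times = self.data["pfs_months"].dropna()
        if (times < 0).any():
            raise ValueError("pfs_months must be >= 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def features(self) -> pd.DataFrame:
        return self.data[list(self.spec.feature_names)]

    def labelled(self) -> "CohortTable":
        """Rows with an observed DCB label (used for supervised fitting)."""
        return CohortTable(self.data[self.data[CLASS_VAR].notna()].copy(), self.spec)

    def subset(self, ids: Sequence[str]) -> "CohortTable":
        return CohortTable(self.data.loc[list(ids)].copy(), self.spec)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_CLINICAL_ALIASES = {
    "patient_id": ("patient_id", "patient", "sample_id", "tumor_sample_barcode"),
    "age": ("age", "age_at_diagnosis"),
    "sex": ("sex", "gender"),
    "smoker": ("smoker", "smoking_status", "smoking"),
    "histology": ("histology", "histopathology", "cancer_type_detailed"),
    "dcb": ("dcb", "durable_clinical_benefit", "benefit"),
    "pfs_months": ("pfs_months", "pfs", "pfs_time"),
    "pfs_event": ("pfs_event", "pfs_status", "progression"),
    "cohort": ("cohort", "study", "cohort_label"),
}

_MUTATION_ALIASES = {
    "patient_id": ("patient_id", "tumor_sample_barcode", "sample_id", "patient"),
    "gene": ("gene", "hugo_symbol", "gene_symbol"),
    "variant_class": ("variant_class", "variant_classification", "mutation_type"),
}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def _canonicalize_columns(df: pd.DataFrame, aliases: Mapping[str, tuple[str, ...]],
                          required: Iterable[str]) -> pd.DataFrame:
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canon, names in aliases.items():
        for name in names:
            if name in lower:
                rename[lower[name]] = canon
                break
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"input table missing required columns: {missing}")
    return df


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a clinical CSV/TSV into canonical columns (strings, unparsed)."""
    df = _read_delimited(path)
    df = _canonicalize_columns(df, _CLINICAL_ALIASES, _CLINICAL_ALIASES.keys())
    return df


def read_mutation_table(path: str | Path) -> list[VariantRecord]:
    """Read a mutation CSV/TSV (MAF-compatible column aliases) into records."""
    df = _read_delimited(path)
    df = _canonicalize_columns(df, _MUTATION_ALIASES, _MUTATION_ALIASES.keys())
    return [
        VariantRecord(str(r.patient_id), str(r.gene), str(r.variant_class))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Curation operations
# ---------------------------------------------------------------------------


def binarize_variants(
    records: Sequence[VariantRecord],
    patients: Sequence[str],
    genes: Sequence[str],
    qualifying: frozenset[str] | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-patient, per-gene binary variant indicators.

    A cell is 1 iff the patient has at least one record for the gene whose
    variant class falls in the qualifying category set; duplicated records
    are harmless.  Patients with no records are wild type throughout
    (cBioPortal-style exports list only altered samples); ``strict=True``
    instead requires every patient to appear in ``records``.
    """
    qualifying = QUALIFYING_CATEGORIES if qualifying is None else qualifying
    patients = [str(p) for p in patients]
    known = set(patients)
    unknown = sorted({r.patient_id for r in records if r.patient_id not in known})
    if unknown:
        raise ValueError(f"mutation records reference unknown patient ids: {unknown}")
    table = pd.DataFrame(0, index=pd.Index(patients, name="patient_id"),
                         columns=list(genes), dtype=np.int8)
    gene_set = set(genes)
    seen = set()
    for rec in records:
        seen.add(rec.patient_id)
        if rec.gene not in gene_set:
            continue
        if normalize_variant_class(rec.variant_class) in qualifying:
            table.loc[rec.patient_id, rec.gene] = 1
    if strict:
        absent = sorted(known - seen)
        if absent:
            raise ValueError(
                f"strict mode: patients with no mutation records: {absent}"
            )
    return table


def observed_genes(records: Sequence[VariantRecord]) -> list[str]:
    """All gene symbols appearing in the mutation records, sorted."""
    return sorted({r.gene for r in records})


def select_frequency_geneset(
    indicators: pd.DataFrame, threshold: float = 0.10
) -> list[str]:
    """Genes whose variant fraction strictly exceeds ``threshold``.

    Ordered by descending frequency with alphabetical tie-break.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if len(indicators) == 0:
        raise ValueError("need at least one patient")
    freq = indicators.mean(axis=0)
    chosen = freq[freq > threshold]
    return sorted(chosen.index, key=lambda g: (-chosen[g], g))


def _map_value(raw: object, mapping: Mapping[str, str], feature: str, row: object):
    if pd.isna(raw) or _normalize(raw) in {"", "na", "nan", "unknown"}:
        return np.nan
    key = _normalize(raw)
    if key not in mapping:
        raise ValueError(f"row {row!r}: value {raw!r} outside domain of {feature!r}")
    return mapping[key]


def _map_histology(raw: object) -> object:
    if pd.isna(raw):
        return np.nan
    norm = _normalize(raw)
    if norm in _HISTOLOGY_UNSPECIFIED:
        return np.nan
    if norm in _HISTOLOGY_ADENO:
        return "adenocarcinoma"
    if norm in _HISTOLOGY_SQUAMOUS:
        return "squamous"
    return "other"


def build_feature_table(
    clinical: pd.DataFrame,
    indicators: pd.DataFrame,
    spec: FeatureSpec,
) -> CohortTable:
    """Assemble the analysis table from canonical clinical rows + indicators.

    Age is dichotomized at 65 years; sex/smoker/histology are normalized to
    their declared domains (missing stays missing); the selected gene
    indicators are attached as {'wt', 'variant'}; DCB maps to
    {'benefit', 'no_benefit'}.
    """
    clinical = clinical.copy()
    clinical["patient_id"] = clinical["patient_id"].astype(str)
    if clinical["patient_id"].duplicated().any():
        dupes = clinical.loc[clinical["patient_id"].duplicated(), "patient_id"]
        raise ValueError(f"duplicate patient ids in clinical table: {list(dupes)}")
    idx = pd.Index(clinical["patient_id"], name="patient_id")

    age_raw = pd.to_numeric(clinical["age"], errors="coerce")
    out = pd.DataFrame(index=idx)
    age_cat = np.where(age_raw < 65, "<65", ">=65").astype(object)
    age_cat[age_raw.isna().values] = np.nan
    out["age"] = age_cat
    out["sex"] = [
        _map_value(v, _SEX_MAP, "sex", pid)
        for v, pid in zip(clinical["sex"], clinical["patient_id"])
    ]
    out["smoker"] = [
        _map_value(v, _SMOKER_MAP, "smoker", pid)
        for v, pid in zip(clinical["smoker"], clinical["patient_id"])
    ]
    out["raw_histology"] = list(clinical["histology"])
    out["histology"] = [_map_histology(v) for v in clinical["histology"]]
    out[CLASS_VAR] = [
        _map_value(v, _DCB_MAP, CLASS_VAR, pid)
        for v, pid in zip(clinical["dcb"], clinical["patient_id"])
    ]
    out["pfs_months"] = pd.to_numeric(clinical["pfs_months"], errors="coerce").values
    event = pd.to_numeric(clinical["pfs_event"], errors="coerce").values
    out["pfs_event"] = event
    out["cohort"] = clinical["cohort"].values

    for gene in spec.gene_names:
        if gene in indicators.columns:
            col = indicators.reindex(out.index)[gene]
            vals = np.where(col.fillna(0).astype(int) == 1, "variant", "wt") \
                .astype(object)
            vals[col.isna().values] = np.nan
            out[gene] = vals
        else:
            out[gene] = "wt"
    return CohortTable(out, spec)


def apply_exclusions(
    cohort: CohortTable,
    excluded_histologies: frozenset[str] | set[str] = DEFAULT_EXCLUDED_HISTOLOGIES,
) -> CohortTable:
    """Drop rows with missing/unspecified histology or an excluded subtype.

    Exclusion labels are matched against the preserved raw histology string
    (normalized), so rare subtypes like large-cell neuroendocrine carcinoma
    can be removed even though they map to the generic 'other' level.
    """
    if "histology" not in cohort.spec.feature_names:
        raise ValueError("histology is not a declared feature")
    excluded = {_normalize(h) for h in excluded_histologies}
    df = cohort.data
    drop = df["histology"].isna()
    if "raw_histology" in df.columns and excluded:
        raw_norm = df["raw_histology"].map(lambda v: _normalize(v) if pd.notna(v) else "")
        drop |= raw_norm.isin(excluded)
    kept = df[~drop].copy()
    n_removed = int(drop.sum())
    logger.info("apply_exclusions: removed %d of %d rows", n_removed, len(df))
    if len(kept) == 0:
        raise ValueError("exclusion rules removed every row")
    return CohortTable(kept, cohort.spec)


def split_train_test(
    cohort: CohortTable, seed: int, ratio: tuple[int, int] = (2, 1)
) -> tuple[CohortTable, CohortTable]:
    """Seeded random partition into train/test at the given integer ratio.

    For the study's 2:1 ratio the test set has floor(n/3) rows.  Row order
    within each part follows the original table.
    """
    n = len(cohort)
    if n < sum(ratio):
        raise ValueError(f"cannot split {n} rows at ratio {ratio}")
    n_test = math.floor(n * ratio[1] / sum(ratio))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_pos = np.sort(perm[:n_test])
    train_pos = np.sort(perm[n_test:])
    df = cohort.data
    return (
        CohortTable(df.iloc[train_pos].copy(), cohort.spec),
        CohortTable(df.iloc[test_pos].copy(), cohort.spec),
    )


def split_by_cohort(
    cohort: CohortTable, train_label: str, eval_label: str
) -> tuple[CohortTable, CohortTable]:
    """Route rows into train/evaluation sets by their cohort label."""
    if train_label == eval_label:
        raise ValueError("train and evaluation cohort labels must differ")
    labels = set(cohort.data["cohort"].dropna())
    for lab in (train_label, eval_label):
        if lab not in labels:
            raise ValueError(f"unknown cohort label {lab!r}; present: {sorted(labels)}")
    df = cohort.data
    return (
        CohortTable(df[df["cohort"] == train_label].copy(), cohort.spec),
        CohortTable(df[df["cohort"] == eval_label].copy(), cohort.spec),
    )


def curate(
    clinical: pd.DataFrame,
    records: Sequence[VariantRecord],
    geneset_mode: str = "frequency",
    frequency_threshold: float = 0.10,
    excluded_histologies: frozenset[str] | set[str] = DEFAULT_EXCLUDED_HISTOLOGIES,
    frequency_before_exclusion: bool = False,
) -> CohortTable:
    """Full curation: exclusions, gene selection, final feature table.

    By default the >threshold variant-frequency geneset is computed after
    the histology exclusions (configurable).
    """
    patients = [str(p) for p in clinical["patient_id"]]
    all_genes = observed_genes(records)
    indicators = binarize_variants(records, patients, all_genes)

    # Preliminary table with no genes, used only to apply exclusions.
    base_spec = FeatureSpec(features=CLINICAL_FEATURES, geneset_mode=geneset_mode)
    base = build_feature_table(clinical, indicators.iloc[:, :0], base_spec)
    base = apply_exclusions(base, excluded_histologies)
    kept_ids = base.patient_ids

    if geneset_mode == "evidence":
        genes = list(EVIDENCE_GENESET)
    else:
        pool = indicators if frequency_before_exclusion else indicators.loc[kept_ids]
        genes = select_frequency_geneset(pool, frequency_threshold)
        if not genes:
            raise ValueError("no gene exceeded the variant-frequency threshold")
    spec = FeatureSpec.with_genes(genes, geneset_mode)
    table = build_feature_table(
        clinical[clinical["patient_id"].astype(str).isin(kept_ids)],
        indicators.loc[kept_ids, [g for g in genes if g in indicators.columns]],
        spec,
    )
    return table
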