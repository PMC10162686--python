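"""End-to-end workflow: curate -> split -> fit NB/TAN -> evaluate -> average -> stratify.

One global seed fans out into stage-specific derived seeds (split, TAN
root choice, bootstrap, MCMC, sampling) so each stage is independently
reproducible; the whole run is a pure function of the configuration and
the input files and writes a machine-readable JSON report alongside the
artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_io
from .averaging import (
    bootstrap_arc_strength,
    concordance_with_tan,
    mcmc_arc_strength,
    significant_arcs,
)
from .cohort_io import CohortTable, split_by_cohort, split_train_test
from .evaluation import roc_curve, stratify_by_prediction
from .inference import predict_proba
from .models import build_nb_structure, fit_cpts, learn_tan_structure, tan_root
from .synthetic import default_ground_truth, sample_cohort, write_cohort_tables

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "split", "tan_root", "bootstrap", "mcmc", "inference")


@dataclass
class RunConfig:
    """Tunable knobs of the workflow with the study's defaults."""

    seed: int = 0
    geneset_mode: str = "frequency"
    pseudocount: float = 1.0
    frequency_threshold: float = 0.10
    arc_threshold: float = 0.85
    class_threshold: float = 0.5
    split_ratio: tuple[int, int] = (2, 1)
    train_cohort: str | None = None   # set both to use cohort-label routing
    eval_cohort: str | None = None
    bootstrap_B: int = 500
    mcmc_n_keep: int = 500
    mcmc_thin: int = 50
    simulate_n: int = 290
    class_prior: float = 0.35
    outdir: str = "dcbnet_run"

    def __post_init__(self) -> None:
        for name in ("frequency_threshold", "arc_threshold", "class_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES))
        return {s: int(v % (2**31)) for s, v in zip(_STAGES, state)}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key=value (or JSON) config file."""
        text = Path(path).read_text()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        kwargs = {}
        for f_name, f_type in cls.__dataclass_fields__.items():
            if f_name not in raw:
                continue
            v = raw[f_name]
            default = getattr(cls(), f_name)
            if f_name == "split_ratio":
                if isinstance(v, str):
                    v = tuple(int(x) for x in v.split(":"))
                kwargs[f_name] = tuple(v)
            elif isinstance(default, bool):
                kwargs[f_name] = str(v).lower() in {"1", "true", "yes"}
            elif isinstance(default, int):
                kwargs[f_name] = int(v)
            elif isinstance(default, float):
                kwargs[f_name] = float(v)
            else:
                kwargs[f_name] = v if v not in ("", "none", "None") else None
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_and_score(kind: str, train: CohortTable, test: CohortTable,
                   config: RunConfig, seeds: dict[str, int]):
    train_sup = train.labelled()
    if kind == "nb":
        structure = build_nb_structure(train.spec)
        meta = {"model_kind": "nb", "pseudocount": config.pseudocount}
    else:
        structure = learn_tan_structure(train_sup, seed=seeds["tan_root"])
        meta = {
            "model_kind": "tan",
            "pseudocount": config.pseudocount,
            "root": tan_root(structure, train.spec.class_var),
            "seed": seeds["tan_root"],
        }
    model = fit_cpts(structure, train_sup, config.pseudocount, meta=meta)

    def auc_on(part: CohortTable) -> float:
        sup = part.labelled()
        scores = predict_proba(model, sup)
        return roc_curve(scores, sup.data[cohort_io.CLASS_VAR].values).auc

    return model, {"train_auc": auc_on(train), "test_auc": auc_on(test)}


def run_pipeline(
    config: RunConfig,
    clinical_path: str | Path | None = None,
    mutation_path: str | Path | None = None,
    simulate: bool = False,
) -> dict:
    """Execute the full workflow and write artifacts + report to outdir.

    In simulate mode the cohort is drawn from the default ground-truth
    model (and the truth is dumped next to the artifacts); otherwise the
    clinical and mutation tables are read and curated.  Returns the run
    report (also written as ``report.json``).
    """
    if not simulate and (clinical_path is None or mutation_path is None):
        raise ValueError("provide input tables or set simulate=True")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    report: dict = {"config": {**asdict(config),
                               "split_ratio": list(config.split_ratio)},
                    "stage_seeds": seeds, "simulate": simulate}

    # --- curation ---------------------------------------------------------
    stage = "curation"
    try:
        if simulate:
            truth = default_ground_truth(class_prior=config.class_prior)
            cohort = sample_cohort(truth, config.simulate_n, seeds["simulate"])
            truth.to_json(outdir / "ground_truth.json")
            write_cohort_tables(cohort, outdir / "clinical.csv",
                                outdir / "mutations.csv", seed=seeds["simulate"])
            if config.geneset_mode == "evidence":
                raise ValueError(
                    "simulate mode generates the frequency geneset only"
                )
        else:
            clinical = cohort_io.read_clinical_table(clinical_path)
            records = cohort_io.read_mutation_table(mutation_path)
            cohort = cohort_io.curate(
                clinical, records,
                geneset_mode=config.geneset_mode,
                frequency_threshold=config.frequency_threshold,
            )
        report["n_patients"] = len(cohort)
        report["genes"] = list(cohort.spec.gene_names)

        # --- split ----------------------------------------------------------
        stage = "split"
        if config.train_cohort and config.eval_cohort:
            train, test = split_by_cohort(cohort, config.train_cohort,
                                          config.eval_cohort)
        else:
            train, test = split_train_test(cohort, seeds["split"],
                                           config.split_ratio)
        report["n_train"], report["n_test"] = len(train), len(test)

        # --- models ---------------------------------------------------------
        stage = "fit"
        nb_model, nb_auc = _fit_and_score("nb", train, test, config, seeds)
        tan_model, tan_auc = _fit_and_score("tan", train, test, config, seeds)
        nb_model.to_json(outdir / "model_nb.json")
        tan_model.to_json(outdir / "model_tan.json")
        report["nb"] = nb_auc
        report["tan"] = {**tan_auc, "root": tan_model.meta["root"],
                         "edges": [list(e) for e in tan_model.structure.edges]}
        for kind, model in (("nb", nb_model), ("tan", tan_model)):
            sup = test.labelled()
            roc = roc_curve(predict_proba(model, sup),
                            sup.data[cohort_io.CLASS_VAR].values)
            roc.to_tsv(outdir / f"roc_{kind}_test.tsv")

        # --- arc strengths ----------------------------------------------------
        stage = "model_averaging"
        train_sup = train.labelled()
        boot = bootstrap_arc_strength(train_sup, config.bootstrap_B,
                                      seeds["bootstrap"])
        mcmc = mcmc_arc_strength(train_sup, config.mcmc_n_keep,
                                 config.mcmc_thin, seeds["mcmc"])
        boot.to_tsv(outdir / "arcs_bootstrap.tsv")
        mcmc.to_tsv(outdir / "arcs_mcmc.tsv")
        report["arc_strength"] = {}
        for name, table in (("bootstrap", boot), ("mcmc", mcmc)):
            conc = concordance_with_tan(table, tan_model.structure,
                                        config.arc_threshold)
            conc.to_tsv(outdir / f"concordance_{name}.tsv")
            sig = significant_arcs(table, config.arc_threshold)
            report["arc_strength"][name] = {
                "significant": ["-".join(p) for p in sig],
                "in_tan": [row["pair"] for row in conc.rows if row["in_tan"]],
            }

        # --- survival stratification -----------------------------------------
        stage = "stratification"
        strat = stratify_by_prediction(tan_model, cohort, config.class_threshold)
        pd.DataFrame({"group": strat.groups}).to_csv(outdir / "groups.tsv", sep="\t")
        for g, curve in strat.curves.items():
            curve.to_frame().to_csv(outdir / f"km_{g}.tsv", sep="\t", index=False)
        report["stratification"] = {
            "group_sizes": strat.groups.value_counts().to_dict(),
            "logrank_chi_square": None if strat.logrank is None
            else strat.logrank.chi_square,
            "logrank_p": None if strat.logrank is None else strat.logrank.p_value,
        }
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    # --- report -----------------------------------------------------------
    artifacts = sorted(p for p in outdir.iterdir()
                       if p.is_file() and p.name != "report.json")
    report["artifacts"] = {p.name: _sha256(p) for p in artifacts}
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
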