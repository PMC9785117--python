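"""End-to-end orchestration: generate -> featureqc -> preprocess -> screen ->
enrich -> model -> breakpoint, with persisted stage outputs and a
deterministic machine-readable summary.

Every stage consumes the previous stage's persisted TSV/JSON outputs from the
run directory, so stages are independently re-runnable; toggling a stage off
and running a downstream stage raises a missing-input error naming the file.
Running the pipeline twice with the same configuration and seed produces
byte-identical summaries (the run log carries timestamps, the summary does
not).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .association import screen_cohort, select_covariates
from .breakpoint import align_signs, detect_breakpoint, fit_pca
from .enrichment import ora_test, read_gmt, toy_library
from .errors import ConfigurationError, MissingInputError
from .featureqc import apply_filter, filter_features, loess_normalize
from .preprocess import ImputationSpec, fit_transform_cohort, impute
from .stepwise import evaluate_on_test, forward_stepwise
from .synthdata import GeneratorConfig, generate_cohort, generate_feature_table, split_cohort

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger("metaboaging")

ALL_STAGES = ("generate", "featureqc", "preprocess", "screen", "enrich", "model", "breakpoint")


@dataclass
class RunConfig:
    """Parameters of one pipeline run; defaults follow the study's choices.

    Feature-QC thresholds 5% blank / 20% CV / 10% missing; Box-Cox lambda on
    a [-10, 10] grid; BH FDR q = 0.2 with nominal alpha = 0.05; forward
    stepwise entry p = 0.05; train fraction 105/138; breakpoint minimum
    segment one third of the sample.
    """

    seed: int
    outdir: str | Path = "metaboaging_run"
    stages: tuple[str, ...] = ALL_STAGES
    generator: GeneratorConfig | None = None
    # feature-table generation
    n_features: int = 128
    n_feature_samples: int = 105
    n_blanks: int = 3
    n_qc_groups: int = 8
    drift_amplitude: float = 0.15
    # featureqc
    blank_threshold: float = 0.05
    cv_threshold: float = 20.0
    missing_threshold: float = 0.10
    loess_span: float = 0.75
    # preprocess
    train_fraction: float = 105.0 / 138.0
    n_imputations: int = 5
    grid_step: float = 0.1
    # screen
    fdr_q: float = 0.2
    alpha: float = 0.05
    # enrich
    gmt_path: str | None = None
    min_pathway_hits: int = 2
    # model
    p_enter: float = 0.05
    # breakpoint
    min_segment: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigurationError("seed: mandatory in the run configuration file")
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            if "age_range" in gen:
                gen["age_range"] = tuple(gen["age_range"])
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def stage_params(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("generator", None)
        d.pop("outdir", None)  # a result summary should not embed its location
        d["stages"] = list(self.stages)
        return d


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingInputError(
            f"stage '{stage}': required input {path.name} is missing; "
            "run the upstream stage first"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return the summary dictionary.

    Outputs are persisted under ``config.outdir``; the consolidated
    ``summary.json`` is written last and is byte-identical across runs with
    the same configuration and seed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"stages: unknown stage(s) {sorted(unknown)}")

    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "parameters": config.stage_params()}
    try:
        logger.info("run started; parameters: %s", summary["parameters"])
        for stage in ALL_STAGES:
            if stage not in config.stages:
                logger.info("stage %s: skipped", stage)
                continue
            logger.info("stage %s: starting", stage)
            try:
                _STAGES[stage](config, out, summary)
            except Exception as exc:
                logger.error("stage %s: failed: %s", stage, exc)
                io.write_json(summary, out / "summary_partial.json")
                raise
        io.write_json(summary, out / "summary.json")
        logger.info("run finished")
    finally:
        logger.removeHandler(fh)
        fh.close()
    return summary


def _stage_generate(config: RunConfig, out: Path, summary: dict) -> None:
    gen = config.generator if config.generator is not None else GeneratorConfig(seed=config.seed)
    cohort = generate_cohort(gen)
    io.write_cohort(cohort, out / "cohort.tsv", out / "cohort_meta.tsv")
    features = generate_feature_table(
        config.n_features,
        config.n_feature_samples,
        config.n_blanks,
        config.n_qc_groups,
        config.drift_amplitude,
        seed=config.seed + 1,
    )
    io.write_feature_table(features, out / "features.tsv", out / "features_meta.tsv")
    summary["generate"] = {
        "n_subjects": int(len(cohort.data)),
        "n_variables": int(len(cohort.variables("clinical", "metabolite"))),
        "n_features": int(config.n_features),
        "missing_fraction": float(
            cohort.data[cohort.variables("clinical", "metabolite")].isna().mean().mean()
        ),
    }
    logger.info("generated cohort n=%d", len(cohort.data))


def _stage_featureqc(config: RunConfig, out: Path, summary: dict) -> None:
    features = io.read_feature_table(
        _require(out / "features.tsv", "featureqc"),
        _require(out / "features_meta.tsv", "featureqc"),
    )
    logger.info(
        "featureqc thresholds: blank=%g cv=%g%% missing=%g span=%g",
        config.blank_threshold,
        config.cv_threshold,
        config.missing_threshold,
        config.loess_span,
    )
    report = filter_features(
        features,
        blank_threshold=config.blank_threshold,
        cv_threshold=config.cv_threshold,
        missing_threshold=config.missing_threshold,
    )
    report.to_csv(out / "featureqc_report.tsv", sep="\t", float_format="%.10g")
    retained = apply_filter(features, report)
    normalized, warn = loess_normalize(retained, span=config.loess_span)
    io.write_feature_table(
        normalized, out / "features_normalized.tsv", out / "features_normalized_meta.tsv"
    )
    summary["featureqc"] = {
        "n_input": int(len(features.intensities)),
        "n_retained": int(report["retained"].sum()),
        "n_loess_warnings": len(warn),
    }


def _stage_preprocess(config: RunConfig, out: Path, summary: dict) -> None:
    cohort = io.read_cohort(
        _require(out / "cohort.tsv", "preprocess"),
        _require(out / "cohort_meta.tsv", "preprocess"),
    )
    cohort = split_cohort(cohort, config.train_fraction, seed=config.seed + 2)
    cohort = impute(cohort, ImputationSpec(n_imputations=config.n_imputations, seed=config.seed + 3))
    transformed, specs, normality = fit_transform_cohort(cohort, grid_step=config.grid_step)
    io.write_cohort(transformed, out / "cohort_transformed.tsv", out / "cohort_transformed_meta.tsv")
    io.write_boxcox_specs(specs, out / "boxcox_specs.tsv")
    normality.to_csv(out / "normality_report.tsv", sep="\t", float_format="%.10g")
    summary["preprocess"] = {
        "n_train": int((transformed.split == "train").sum()),
        "n_test": int((transformed.split == "test").sum()),
        "n_transformed_variables": len(specs),
    }
    logger.info(
        "preprocess: %d train / %d test, lambda grid step %g",
        summary["preprocess"]["n_train"],
        summary["preprocess"]["n_test"],
        config.grid_step,
    )


def _stage_screen(config: RunConfig, out: Path, summary: dict) -> None:
    cohort = io.read_cohort(
        _require(out / "cohort_transformed.tsv", "screen"),
        _require(out / "cohort_transformed_meta.tsv", "screen"),
    )
    train = cohort.arm("train")
    covariates = select_covariates(train)
    logger.info("screen: covariates retained: %s (q=%g, alpha=%g)", covariates, config.fdr_q, config.alpha)
    records, corr = screen_cohort(train, covariates, q=config.fdr_q, alpha=config.alpha)
    records.to_csv(out / "associations.tsv", sep="\t", float_format="%.10g")
    corr.to_csv(out / "correlation_matrix.tsv", sep="\t", float_format="%.10g")
    sig = records.index[records["significant"]].tolist()
    summary["screen"] = {
        "covariates": covariates,
        "n_tested": int(len(records)),
        "n_significant": len(sig),
        "significant": {v: float(records.loc[v, "partial_r"]) for v in sig},
    }


def _stage_enrich(config: RunConfig, out: Path, summary: dict) -> None:
    records = pd.read_csv(_require(out / "associations.tsv", "enrich"), sep="\t", index_col=0)
    query = records.index[records["significant"]].tolist()
    library = read_gmt(config.gmt_path) if config.gmt_path else toy_library()
    logger.info("enrich: query size %d against %d pathways", len(query), library.n_pathways)
    enr, n_dropped = ora_test(query, library)
    enr.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.10g")
    enriched = enr.index[
        (enr["hits"] >= config.min_pathway_hits) & (enr["enrichment_ratio"] > 1.0)
    ].tolist()
    summary["enrich"] = {
        "n_query": len(query),
        "n_unmapped": n_dropped,
        "enriched_pathways": enriched,
        "top_pathway": enr.index[0],
        "top_enrichment_ratio": float(enr["enrichment_ratio"].iloc[0]),
    }


def _stage_model(config: RunConfig, out: Path, summary: dict) -> None:
    cohort = io.read_cohort(
        _require(out / "cohort_transformed.tsv", "model"),
        _require(out / "cohort_transformed_meta.tsv", "model"),
    )
    records = pd.read_csv(_require(out / "associations.tsv", "model"), sep="\t", index_col=0)
    enr = pd.read_csv(_require(out / "enrichment.tsv", "model"), sep="\t", index_col=0)
    candidates = _panel_from_enrichment(config, records, enr)
    logger.info("model: %d candidates, p_enter=%g", len(candidates), config.p_enter)
    train, test = cohort.arm("train"), cohort.arm("test")
    model = forward_stepwise(
        train, candidates, target="age_years", forced=("bmi",), p_enter=config.p_enter
    )
    r_test = evaluate_on_test(model, test, target="age_years") if model.selected else float("nan")
    payload = {
        "selected": model.selected,
        "forced": model.forced,
        "coefficients": model.coefficients,
        "intercept": model.intercept,
        "r_multiple": model.r_multiple,
        "r2": model.r2,
        "r2_adjusted": model.r2_adjusted,
        "vif": model.vif,
        "entry_p": model.entry_p,
        "r_multiple_test": r_test,
        "warnings": model.warnings,
    }
    io.write_json(payload, out / "model.json")
    summary["model"] = payload


def _panel_from_enrichment(config: RunConfig, records, enr) -> list[str]:
    """Metabolites retained by both screening and enrichment.

    The aging panel is the set of significant variables that are members of
    an enriched pathway (at least ``min_pathway_hits`` hits and enrichment
    ratio above 1); when no pathway qualifies, all significant variables are
    used so downstream stages stay runnable.
    """
    sig = set(records.index[records["significant"]])
    library = read_gmt(config.gmt_path) if config.gmt_path else toy_library()
    enriched = enr.index[
        (enr["hits"] >= config.min_pathway_hits) & (enr["enrichment_ratio"] > 1.0)
    ].tolist()
    members: set[str] = set()
    for p in enriched:
        members |= library.pathways.get(p, frozenset())
    panel = sorted(sig & members)
    return panel if panel else sorted(sig)


def _stage_breakpoint(config: RunConfig, out: Path, summary: dict) -> None:
    cohort = io.read_cohort(
        _require(out / "cohort_transformed.tsv", "breakpoint"),
        _require(out / "cohort_transformed_meta.tsv", "breakpoint"),
    )
    records = pd.read_csv(_require(out / "associations.tsv", "breakpoint"), sep="\t", index_col=0)
    enr = pd.read_csv(_require(out / "enrichment.tsv", "breakpoint"), sep="\t", index_col=0)
    panel = _panel_from_enrichment(config, records, enr)
    variables = panel + ["bmi"]
    train, test = cohort.arm("train"), cohort.arm("test")
    pca_train = fit_pca(train, variables, n_components=min(2, len(variables)))
    pca_test = align_signs(fit_pca(test, variables, n_components=min(2, len(variables))), pca_train)
    pca_train.loadings.to_csv(out / "pca_loadings_train.tsv", sep="\t", float_format="%.10g")
    pca_test.loadings.to_csv(out / "pca_loadings_test.tsv", sep="\t", float_format="%.10g")
    pca_train.scores.to_csv(out / "pca_scores_train.tsv", sep="\t", float_format="%.10g")
    pca_test.scores.to_csv(out / "pca_scores_test.tsv", sep="\t", float_format="%.10g")

    res = detect_breakpoint(
        train.data["age"].to_numpy(),
        pca_train.scores["PC1"].to_numpy(),
        min_segment=config.min_segment,
        subject_ids=train.data.index.to_numpy(),
    )
    logger.info(
        "breakpoint: split %d, intersection %.2f years (r2 product %.4f)",
        res.split_index,
        res.intersection_age,
        res.r2_product,
    )
    payload = {
        "panel": panel,
        "split_index": res.split_index,
        "line1": {"slope": res.slope1, "intercept": res.intercept1, "r2": res.r2_first},
        "line2": {"slope": res.slope2, "intercept": res.intercept2, "r2": res.r2_second},
        "r2_product": res.r2_product,
        "intersection_age": res.intersection_age,
        "no_intersection": res.no_intersection,
        "extrapolated": res.extrapolated,
        "pc1_explained_train": float(pca_train.explained_variance_ratio[0]),
        "pc1_explained_test": float(pca_test.explained_variance_ratio[0]),
        "search_trace": {
            "split_index": res.search_trace["split_index"].tolist(),
            "r2_product": [
                None if not np.isfinite(v) else float(v)
                for v in res.search_trace["r2_product"]
            ],
        },
    }
    io.write_json(payload, out / "breakpoint.json")
    summary["breakpoint"] = {k: payload[k] for k in payload if k != "search_trace"}


_STAGES = {
    "generate": _stage_generate,
    "featureqc": _stage_featureqc,
    "preprocess": _stage_preprocess,
    "screen": _stage_screen,
    "enrich": _stage_enrich,
    "model": _stage_model,
    "breakpoint": _stage_breakpoint,
}
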