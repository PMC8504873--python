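"""End-to-end comparison of the two color-image preprocessing arms.

``run_comparison`` runs the whole experiment once: simulate (or load) a
labelled cohort of color elastograms, convert every image both ways
(direct luminance vs. R/G/B channel split), extract the same feature
bank from each arm, split once into training and validation cohorts,
oversample / select / fit the four classifiers per arm, and score the
comparison statistics on the identical validation lesions.

Both arms see the same lesions, the same split and the same seeds —
the conversion method is the only varying factor.  All child seeds are
derived deterministically from one master seed and recorded in the run
manifest, so reruns with the same config agree exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ElastomicsError
from .evaluation import (ComparisonReport, EvalReport, compare_models,
                         evaluate_model, write_report)
from .features import FeatureBankConfig, FeatureTable, build_feature_table
from .modeling import (ClassifierSpec, LassoResult, SplitSpec, choose_cutoff,
                       lasso_select, predict_scores, smote_oversample,
                       stratified_split, train_score)
from .synthetic import SyntheticConfig, generate_cohort, write_cohort

log = logging.getLogger("elastomics")

ARMS = ("direct", "rgb3")


@dataclass
class RunConfig:
    """One experiment: cohort, bank, split, classifiers, one master seed."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_benign: int = 40
    n_malignant: int = 90
    bank: FeatureBankConfig = field(default_factory=FeatureBankConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    classifiers: tuple[str, ...] = ("RF", "SVM", "AdaBoost", "LR")
    smote_k: int = 5
    lasso_folds: int = 5
    master_seed: int = 0
    output_dir: Path | None = None
    write_images: bool = False


@dataclass
class ArmResult:
    """Everything one conversion arm produced."""

    arm: str
    lasso: LassoResult
    cutoffs: dict[str, float]
    train_scores: dict[str, np.ndarray]
    valid_scores: dict[str, np.ndarray]
    reports: dict[str, EvalReport]


@dataclass
class ComparisonOutcome:
    """Both arms plus their paired comparison, per classifier."""

    config: RunConfig
    seeds: dict[str, int]
    train_labels: np.ndarray
    valid_labels: np.ndarray
    arms: dict[str, ArmResult]
    comparisons: dict[str, ComparisonReport]


def _spawn_seeds(master_seed: int) -> dict[str, int]:
    """Derive named child seeds (< 2**31) from the master seed."""
    names = ("cohort", "split", "smote", "lasso", "rf", "svm", "adaboost", "lr")
    root = np.random.SeedSequence(master_seed)
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, root.spawn(len(names)))}


def _classifier_seed(seeds: dict[str, int], kind: str) -> int:
    return seeds[kind.lower()]


def _run_arm(arm: str, train: FeatureTable, valid: FeatureTable,
             config: RunConfig, seeds: dict[str, int]) -> ArmResult:
    balanced = smote_oversample(train, k_neighbors=config.smote_k,
                                seed=seeds["smote"])
    log.info("[%s] SMOTE: %d -> %d training lesions", arm, train.n, balanced.n)
    lasso = lasso_select(balanced, folds=config.lasso_folds, seed=seeds["lasso"])
    selected = lasso.selected or list(balanced.feature_names)
    if not lasso.selected:
        log.warning("[%s] LASSO selected nothing; falling back to all "
                    "%d features", arm, len(selected))
    log.info("[%s] LASSO: %d features at lambda=%.4g", arm, len(selected),
             lasso.chosen_lambda)
    cutoffs: dict[str, float] = {}
    train_scores: dict[str, np.ndarray] = {}
    valid_scores: dict[str, np.ndarray] = {}
    reports: dict[str, EvalReport] = {}
    for kind in config.classifiers:
        spec = ClassifierSpec(kind=kind, seed=_classifier_seed(seeds, kind))
        model = train_score(balanced.select(selected), spec)
        # operating point from the raw (pre-SMOTE) training scores
        tr = predict_scores(model, train, cohort="train").scores
        va = predict_scores(model, valid, cohort="validation").scores
        cut = choose_cutoff(tr, train.labels)
        cutoffs[kind] = cut
        train_scores[kind] = tr
        valid_scores[kind] = va
        reports[kind] = evaluate_model(f"{arm}-{kind}", "validation", va,
                                       valid.labels, cut)
        log.info("[%s] %s: validation AUC %.3f (cutoff %.3f)", arm, kind,
                 reports[kind].auc.auc, cut)
    return ArmResult(arm=arm, lasso=lasso, cutoffs=cutoffs,
                     train_scores=train_scores, valid_scores=valid_scores,
                     reports=reports)


def run_comparison(config: RunConfig) -> ComparisonOutcome:
    """Run both conversion arms on one cohort and compare them."""
    seeds = _spawn_seeds(config.master_seed)
    try:
        items = generate_cohort(config.synthetic, config.n_benign,
                                config.n_malignant, seeds["cohort"])
    except ElastomicsError as err:
        raise ElastomicsError(f"stage=simulate: {err}") from err
    log.info("cohort: %d lesions (%d benign / %d malignant), mode=%s",
             len(items), config.n_benign, config.n_malignant,
             config.synthetic.mode)
    if config.output_dir is not None and config.write_images:
        write_cohort(items, Path(config.output_dir) / "cohort")

    tables: dict[str, FeatureTable] = {}
    for arm in ARMS:
        try:
            tables[arm] = build_feature_table(items, config.bank, method=arm)
        except ElastomicsError as err:
            raise ElastomicsError(f"stage=extract arm={arm}: {err}") from err
        log.info("[%s] extracted %d features x %d lesions", arm,
                 len(tables[arm].feature_names), tables[arm].n)

    # one split, shared by both arms
    train_d, valid_d = stratified_split(
        tables["direct"],
        SplitSpec(config.split.train_fraction, config.split.stratified,
                  seeds["split"]),
    )
    train_ids = set(train_d.ids)
    arms: dict[str, ArmResult] = {}
    for arm in ARMS:
        tbl = tables[arm]
        tr_idx = np.asarray([i for i, id_ in enumerate(tbl.ids) if id_ in train_ids])
        va_idx = np.asarray([i for i, id_ in enumerate(tbl.ids) if id_ not in train_ids])
        try:
            arms[arm] = _run_arm(arm, tbl.subset(tr_idx), tbl.subset(va_idx),
                                 config, seeds)
        except ElastomicsError as err:
            raise ElastomicsError(f"stage=model arm={arm}: {err}") from err

    comparisons: dict[str, ComparisonReport] = {}
    valid_labels = tables["direct"].subset(
        np.asarray([i for i, id_ in enumerate(tables["direct"].ids)
                    if id_ not in train_ids])).labels
    for kind in config.classifiers:
        comparisons[kind] = compare_models(
            f"rgb3-{kind}", f"direct-{kind}",
            arms["rgb3"].valid_scores[kind], arms["direct"].valid_scores[kind],
            valid_labels,
            arms["rgb3"].cutoffs[kind], arms["direct"].cutoffs[kind],
        )
        log.info("%s: dAUC=%.3f (p=%.3g), NRI=%.3f", kind,
                 comparisons[kind].delta_auc, comparisons[kind].delong_p,
                 comparisons[kind].nri.nri_total)

    outcome = ComparisonOutcome(
        config=config, seeds=seeds, train_labels=train_d.labels,
        valid_labels=valid_labels, arms=arms, comparisons=comparisons,
    )
    if config.output_dir is not None:
        _write_outputs(outcome, tables, train_ids, Path(config.output_dir))
    return outcome


def _write_outputs(outcome: ComparisonOutcome, tables: dict[str, FeatureTable],
                   train_ids: set[str], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seeds": outcome.seeds,
        "n_benign": outcome.config.n_benign,
        "n_malignant": outcome.config.n_malignant,
        "mode": outcome.config.synthetic.mode,
        "classifiers": list(outcome.config.classifiers),
        "arms": {
            arm: {
                "chosen_lambda": res.lasso.chosen_lambda,
                "selected_features": res.lasso.selected,
                "cutoffs": res.cutoffs,
            } for arm, res in outcome.arms.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    for arm, tbl in tables.items():
        tbl.to_csv(out / f"features_{arm}.csv")
    rows = []
    for arm, res in outcome.arms.items():
        for kind in outcome.config.classifiers:
            tbl = tables[arm]
            for cohort, scores, ids in (
                ("train", res.train_scores[kind],
                 [i for i in tbl.ids if i in train_ids]),
                ("validation", res.valid_scores[kind],
                 [i for i in tbl.ids if i not in train_ids]),
            ):
                labels = {i: l for i, l in zip(tbl.ids, tbl.labels)}
                for id_, s in zip(ids, scores):
                    rows.append({"id": id_, "label": labels[id_],
                                 "score": float(s), "model": f"{arm}-{kind}",
                                 "cohort": cohort})
    pd.DataFrame(rows).to_csv(out / "scores.csv", index=False)
    for arm, res in outcome.arms.items():
        for kind, report in res.reports.items():
            write_report(report, out / f"report_{arm}_{kind}.json")
    for kind, cmp in outcome.comparisons.items():
        write_report(cmp, out / f"comparison_{kind}.json")
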