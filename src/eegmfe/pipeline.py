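"""End-to-end driver: cohort -> features per condition -> evaluation.

Ties the stages together while keeping each testable in isolation. The
same subject-level split plan is reused for every amplitude condition
and classifier, so the per-condition accuracies are paired and can be
compared subject-by-subject.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import classify
from .entropy import MFEParams, extract_features, mfe_matrix
from .preprocess import PreprocConfig, epoch, preprocess
from .recording import Recording
from .transforms import TransformSpec, apply_condition

logger = logging.getLogger(__name__)

__all__ = ["condition_features", "run_conditions", "reports_to_frame"]


def condition_features(
    cohort: list[Recording],
    spec: TransformSpec,
    preproc: PreprocConfig = PreprocConfig(),
    mfe_params: MFEParams = MFEParams(),
    preprocessed: bool = False,
) -> pd.DataFrame:
    """Feature table (epochs x channels) for one amplitude condition.

    Per subject: preprocess (unless ``preprocessed``), fit and apply the
    amplitude transform on the continuous post-filter recording, epoch,
    compute the entropy curves and average the long-scale values.
    """
    mats = []
    for rec in cohort:
        pre = rec if preprocessed else preprocess(rec, preproc)
        transformed, _ = apply_condition(pre, spec)
        tensor = epoch(transformed, preproc.epoch_len)
        mats.append(mfe_matrix(tensor, mfe_params))
    return extract_features(mats)


def run_conditions(
    cohort: list[Recording],
    conditions: list[str] | None = None,
    grids: dict[str, classify.GridSpec] | None = None,
    seed: int = 0,
    preproc: PreprocConfig = PreprocConfig(),
    mfe_params: MFEParams = MFEParams(),
    test_fraction: float = 30 / 104,
    split: classify.SplitPlan | None = None,
) -> dict:
    """Evaluate every (condition, classifier) cell on one shared split.

    Returns ``{"split": SplitPlan, "features": {condition: table},
    "reports": {(condition, family): EvalReport}}``.
    """
    if conditions is None:
        conditions = ["reference", "single_stand", "single_norm",
                      "global_stand", "global_norm"]
    if grids is None:
        grids = classify.default_grids()

    logger.info("preprocessing %d subjects", len(cohort))
    pre = [preprocess(rec, preproc) for rec in cohort]
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in pre],
            "group": [r.group for r in pre],
            "dataset_id": [r.dataset_id for r in pre],
        }
    )
    if split is None:
        split = classify.make_split(meta, test_fraction=test_fraction, seed=seed)

    features: dict[str, pd.DataFrame] = {}
    reports: dict[tuple, classify.EvalReport] = {}
    for cond in conditions:
        logger.info("condition %s: extracting features", cond)
        table = condition_features(
            pre, TransformSpec(cond), preproc, mfe_params, preprocessed=True
        )
        features[cond] = table
        train = table[table["subject_id"].isin(split.train_subjects)]
        test = table[table["subject_id"].isin(split.test_subjects)]
        for family, grid in grids.items():
            chosen = classify.loso_select(train, grid, seed=seed)
            reports[(cond, family)] = classify.fit_evaluate(
                train, test, family, chosen, seed=seed, condition=cond
            )
    return {"split": split, "features": features, "reports": reports}


def reports_to_frame(reports: dict) -> pd.DataFrame:
    """Summary table: one row per (condition, classifier)."""
    rows = []
    for (cond, family), rep in reports.items():
        rows.append(
            {
                "condition": cond,
                "classifier": family,
                "mean_accuracy": rep.mean_accuracy,
                "expanded_uncertainty": rep.expanded_uncertainty,
                "mcc": rep.mcc,
                "tp": rep.tp, "tn": rep.tn, "fp": rep.fp, "fn": rep.fn,
                "chosen_params": str(rep.chosen_params),
            }
        )
    return pd.DataFrame(rows)
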