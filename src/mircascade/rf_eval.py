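"""Random-forest evaluation of filter stages.

Each filter stage yields a transcript set; the sets are compared by how well
a random forest, trained on the samples-x-subset expression matrix with the
differentiation day as the class label, discriminates the days under
stratified k-fold cross-validation (tenfold by default).  Discrimination is
summarized as a single macro-averaged one-vs-rest ROC AUC, computed from the
pooled out-of-fold class probabilities, so successive stages can be ranked
as "does the smaller signature classify maturation stage at least as well".
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import label_binarize

from .datasets import ExpressionDataset

__all__ = ["StageEval", "evaluate_stage", "compare_stages"]

logger = logging.getLogger(__name__)


@dataclass
class StageEval:
    """Cross-validated discrimination summary for one filter stage's transcript set."""

    stage_name: str
    n_observations: int  # samples retained x transcripts, for funnel bookkeeping
    auc: float
    roc_points: list[tuple[float, float]]
    n_folds: int = 10
    seed: int = 0


def _macro_roc(y_bin: np.ndarray, proba: np.ndarray) -> list[tuple[float, float]]:
    """Macro-average per-class ROC curves on a common FPR grid."""
    grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    for k in range(y_bin.shape[1]):
        if y_bin[:, k].sum() in (0, y_bin.shape[0]):
            continue
        fpr, tpr, _ = roc_curve(y_bin[:, k], proba[:, k])
        tprs.append(np.interp(grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0] = 0.0
    mean_tpr[-1] = 1.0
    mean_tpr = np.maximum.accumulate(mean_tpr)
    return list(zip(grid.tolist(), mean_tpr.tolist()))


def evaluate_stage(
    ds: ExpressionDataset,
    transcript_ids: Iterable[str],
    stage_name: str = "stage",
    n_folds: int = 10,
    n_trees: int = 500,
    seed: int = 0,
) -> StageEval:
    """Cross-validated day classification on one transcript subset.

    Folds are stratified by day and seeded, so results are reproducible for
    a fixed seed.  If the rarest day has fewer samples than ``n_folds`` the
    fold count is reduced to that size with a logged warning.  The AUC is
    the macro-averaged one-vs-rest ROC AUC over the pooled out-of-fold
    probabilities.
    """
    ids = list(transcript_ids)
    if not ids:
        raise ValueError("transcript subset is empty")
    sub = ds.subset(ids)
    x = sub.values.T  # samples x transcripts
    y = sub.sample_days
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("day classification needs >= 2 distinct days")
    min_class = min(Counter(y).values())
    if min_class < 2:
        raise ValueError("every day needs >= 2 samples for stratified cross-validation")
    eff_folds = n_folds
    if min_class < n_folds:
        eff_folds = min_class
        logger.warning(
            "stage %s: smallest day class has %d samples; folds reduced %d -> %d",
            stage_name, min_class, n_folds, eff_folds,
        )

    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    proba = np.zeros((x.shape[0], classes.size))
    for train, test in skf.split(x, y):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(x[train], y[train])
        p = clf.predict_proba(x[test])
        # align fold-local classes onto the global class order
        for j, cls in enumerate(clf.classes_):
            proba[test, np.searchsorted(classes, cls)] = p[:, j]

    y_bin = label_binarize(y, classes=classes)
    if classes.size == 2:
        y_bin = np.column_stack([1 - y_bin[:, 0], y_bin[:, 0]])
    auc = float(roc_auc_score(y_bin, proba, average="macro"))
    return StageEval(
        stage_name=stage_name,
        n_observations=x.shape[0] * len(ids),
        auc=auc,
        roc_points=_macro_roc(y_bin, proba),
        n_folds=eff_folds,
        seed=seed,
    )


def compare_stages(evals: list[StageEval]) -> pd.DataFrame:
    """Rank stage evaluations by AUC (descending, stable ties) with deltas
    against the first-listed stage."""
    if len(evals) < 2:
        raise ValueError("stage comparison needs >= 2 evaluations")
    baseline = evals[0].auc
    df = pd.DataFrame(
        {
            "stage_name": [e.stage_name for e in evals],
            "n_observations": [e.n_observations for e in evals],
            "auc": [e.auc for e in evals],
            "delta_vs_first": [e.auc - baseline for e in evals],
        }
    )
    return df.sort_values("auc", ascending=False, kind="stable").reset_index(drop=True)
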