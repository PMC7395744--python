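"""Five-fold patient-level cross-validation and multi-horizon ranking metrics.

Patients are shuffled once and divided into five portions of 20%.  In each of
the five rotations, four portions train the model and the held-out portion is
split in half into validation (early stopping) and test.  All windows of a
patient stay on one side of every split, so no patient leaks across folds.

Discrimination is summarized by AUROC (Mann-Whitney, ties counted one half)
and AUPRC (step-wise average precision), with per-horizon means and normal-
approximation 95% confidence intervals across the five fold values.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .baselines import GBVital, gb_vital_features, mews_predictor, sofa_predictor
from .ehr import Preprocessor
from .tcn import TCN, TCNConfig, TrainConfig, build_network, make_samples, train

MODEL_KINDS = ("tcn", "mews", "sofa", "gb_vital", "random")


@dataclasses.dataclass(frozen=True)
class FoldSplit:
    fold: int
    train_patients: frozenset
    val_patients: frozenset
    test_patients: frozenset


@dataclasses.dataclass(frozen=True)
class FoldResult:
    illness: str
    horizon_hours: int
    fold: int
    auroc: float
    auprc: float
    n_test: int


def make_folds(patient_ids: Sequence[str], seed: int = 0) -> list[FoldSplit]:
    """Five patient-level splits: 80% train / 10% validation / 10% test."""
    ids = sorted(set(patient_ids))
    if len(ids) < 10:
        raise ValueError("need at least 10 patients for five-fold cross-validation")
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    portions = [shuffled[i::5] for i in range(5)]
    folds = []
    for f in range(5):
        held = portions[f]
        half = len(held) // 2
        folds.append(
            FoldSplit(
                fold=f + 1,
                train_patients=frozenset(p for g in range(5) if g != f for p in portions[g]),
                val_patients=frozenset(held[:half]),
                test_patients=frozenset(held[half:]),
            )
        )
    return folds


def auroc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under precision-recall via step-wise average-precision summation."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("AUPRC undefined with zero positives")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# model scoring backends
# ---------------------------------------------------------------------------

def _fit_and_score_tcn(train_s, val_s, test_s, parameters, seed, tcn_config, train_config):
    """Fit the TCN (optionally an average over independently initialized
    members) on one fold and score the test samples."""
    pre = Preprocessor(parameters).fit([s.matrix for s in train_s])
    as_x = lambda ss: np.stack([pre.transform(s.matrix) for s in ss])
    config = tcn_config or TCNConfig(
        n_features=len(parameters), window_hours=train_s[0].matrix.n_bins
    )
    tcfg = train_config or TrainConfig()
    X_tr, y_tr = as_x(train_s), np.array([s.label for s in train_s])
    X_va = as_x(val_s) if val_s else None
    y_va = np.array([s.label for s in val_s]) if val_s else None
    X_te = as_x(test_s)
    nets, scores = [], []
    for member in range(max(tcfg.n_ensemble, 1)):
        member_seed = seed + 1000 * member
        net = build_network(config, seed=member_seed)
        train(net, X_tr, y_tr, X_va, y_va, dataclasses.replace(tcfg, seed=member_seed))
        nets.append(net)
        scores.append(net.predict(X_te))
    return np.mean(scores, axis=0), (nets, pre)


def _score_gb_vital(train_s, test_s, timelines_by_id, seed):
    feats = lambda ss: np.stack(
        [gb_vital_features(timelines_by_id[s.admission_id], s.prediction_time) for s in ss]
    )
    model = GBVital(seed=seed).fit(feats(train_s), np.array([s.label for s in train_s]))
    return model.predict_proba(feats(test_s)), model


def evaluate(
    model_kind: str,
    timelines,
    labels: pd.DataFrame,
    illness: str,
    horizons: Sequence[int] = (0, 3, 6, 12, 24),
    parameters: Sequence[str] | None = None,
    seed: int = 0,
    tcn_config: TCNConfig | None = None,
    train_config: TrainConfig | None = None,
    return_models: bool = False,
):
    """Cross-validate one model kind over the cohort at the given horizons.

    Returns ``(fold_results, summary)`` DataFrames; with ``return_models=True``
    also a dict mapping ``(fold, horizon)`` to the fitted artifacts (TCN:
    ``(network, preprocessor)``; GB-Vital: the fitted classifier; score-based
    baselines have no fitted state).
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    timelines = list(timelines)
    timelines_by_id = {tl.admission_id: tl for tl in timelines}
    from .parameters import parameter_names as _names

    parameters = _names() if parameters is None else list(parameters)
    folds = make_folds([tl.patient_id for tl in timelines], seed=seed)
    rng = np.random.default_rng(seed)

    samples = {
        h: make_samples(timelines, labels, illness, h, parameters, seed=seed) for h in horizons
    }
    results: list[FoldResult] = []
    models: dict = {}
    for fold in folds:
        for h in horizons:
            pick = lambda pats: [s for s in samples[h] if s.patient_id in pats]
            train_s = pick(fold.train_patients)
            val_s = pick(fold.val_patients)
            test_s = pick(fold.test_patients)
            test_y = np.array([s.label for s in test_s])
            if len(test_s) == 0 or len(np.unique(test_y)) < 2:
                warnings.warn(
                    f"fold {fold.fold}, horizon {h}: test set lacks both classes; skipped"
                )
                continue
            fitted = None
            if model_kind == "tcn":
                scores, fitted = _fit_and_score_tcn(
                    train_s, val_s, test_s, parameters, seed + fold.fold, tcn_config, train_config
                )
            elif model_kind == "gb_vital":
                scores, fitted = _score_gb_vital(
                    train_s, test_s, timelines_by_id, seed + fold.fold
                )
            elif model_kind == "mews":
                scores = np.array(
                    [mews_predictor(timelines_by_id[s.admission_id], s.prediction_time)
                     for s in test_s]
                )
            elif model_kind == "sofa":
                scores = np.array(
                    [sofa_predictor(timelines_by_id[s.admission_id], s.prediction_time)
                     for s in test_s]
                )
            else:  # random: the null reference
                scores = rng.uniform(size=len(test_s))
            results.append(
                FoldResult(
                    illness=illness,
                    horizon_hours=h,
                    fold=fold.fold,
                    auroc=auroc(scores, test_y),
                    auprc=auprc(scores, test_y),
                    n_test=len(test_s),
                )
            )
            if return_models and fitted is not None:
                models[(fold.fold, h)] = fitted

    frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
    summary = summarize(frame, model_kind)
    if return_models:
        return frame, summary, models
    return frame, summary


def summarize(fold_results: pd.DataFrame, model_kind: str) -> pd.DataFrame:
    """Per-horizon mean and normal-approximation 95% CI across fold metrics."""
    rows = []
    for (illness, h), grp in fold_results.groupby(["illness", "horizon_hours"]):
        row = {"illness": illness, "horizon_hours": h, "model": model_kind, "n_folds": len(grp)}
        for metric in ("auroc", "auprc"):
            vals = grp[metric].to_numpy()
            mean = vals.mean()
            half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            row[f"mean_{metric}"] = mean
            row[f"{metric}_ci_lo"] = mean - half
            row[f"{metric}_ci_hi"] = mean + half
        rows.append(row)
    return pd.DataFrame(rows)
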