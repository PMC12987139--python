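"""Stratified evaluation protocol and ablation/baseline harness.

The protocol mirrors a common screening-study design: 20% of each label
stratum is sealed off as a test set (per-stratum counts rounded half-up,
so strata of 56 and 78 give 11 + 16 = 27 test drivers), the remaining
drivers are split into five stratified cross-validation folds, a screening
model is calibrated on each fold's training part and evaluated on its
validation part, fold metrics are macro-averaged, and the sealed test set
is touched exactly once by the final model.  The same split machinery
drives any classifier implementing fit/predict, enabling baseline and
feature-ablation comparisons in one report schema.

The positive class for precision/recall/F1 is D2 (perceivers).  Test-set
metrics carry Wilson 95% confidence intervals; each metric is treated as
the proportion its definition expresses (for F1, 2*TP out of
2*TP + FP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint

from omenscreen.cohort import CohortTable, FEATURES
from omenscreen.sem import calibrate, screen_cohort, standardize_features

__all__ = [
    "EvalReport",
    "FEATURE_SUBSETS",
    "ProtocolReport",
    "baseline_run",
    "classification_metrics",
    "run_protocol",
    "stratified_holdout",
    "stratified_kfold",
]

FEATURE_SUBSETS = {
    "all": FEATURES,
    "eeg": ("alpha", "beta", "theta", "delta", "gamma"),
    "ecg": ("ecg",),
    "eye": ("gv", "lpd", "rpd"),
    "ecg+eye": ("ecg", "gv", "lpd", "rpd"),
}

METRICS = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class EvalReport:
    """Metrics and 2x2 confusion matrix (rows true D1/D2, cols predicted)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: tuple  # ((tn, fp), (fn, tp)) with D2 positive
    n: int
    positive_class: str = "D2"
    degenerate: bool = False
    ci: dict = field(default_factory=dict)  # metric -> (lower, upper)

    def metric(self, name: str) -> float:
        return getattr(self, name)


def stratified_holdout(cohort: CohortTable, fraction: float = 0.2, seed: int = 0):
    """Per-stratum random hold-out.

    The test count per stratum is the half-up rounding of
    ``fraction * stratum size`` — a deterministic function of the sizes;
    only the membership depends on the seed.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    labels = np.array(cohort.labels())
    rng = np.random.default_rng(seed)
    test_idx: list = []
    for stratum in sorted(set(labels)):
        members = np.flatnonzero(labels == stratum)
        n_test = int(np.floor(fraction * members.size + 0.5))
        if n_test < 1 or n_test >= members.size:
            raise ValueError(
                f"stratum {stratum} of size {members.size} cannot yield a "
                f"{fraction:.0%} hold-out"
            )
        test_idx.extend(rng.choice(members, size=n_test, replace=False))
    test_set = set(test_idx)
    train = cohort.subset(i for i in range(len(cohort)) if i not in test_set)
    test = cohort.subset(sorted(test_set))
    return train, test


def stratified_kfold(cohort: CohortTable, k: int = 5, seed: int = 0):
    """k mutually exclusive, exhaustive, label-stratified folds.

    Returns a list of ``(train, validation)`` cohort pairs; per-fold class
    counts differ from exact proportionality by at most one driver.
    """
    labels = cohort.labels()
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = {c: labels.count(c) for c in set(labels)}
    small = [c for c, n in counts.items() if n < k]
    if small:
        raise ValueError(f"classes smaller than k={k}: {small}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (cohort.subset(tr), cohort.subset(va))
        for tr, va in splitter.split(np.zeros(len(labels)), labels)
    ]


def classification_metrics(truth, predictions, with_ci: bool = False) -> EvalReport:
    """Accuracy, precision, recall, F1 and the confusion matrix (D2 positive).

    Zero-denominator precision or recall is reported as 0 with the
    ``degenerate`` flag set.  ``with_ci=True`` adds Wilson 95% intervals.
    """
    t = list(truth)
    p = list(predictions)
    if len(t) != len(p):
        raise ValueError("truth and predictions must have equal length")
    bad = [x for x in t + p if x not in ("D1", "D2")]
    if bad:
        raise ValueError(f"labels outside {{D1, D2}}: {sorted(set(bad))}")
    tp = sum(1 for a, b in zip(t, p) if a == "D2" and b == "D2")
    tn = sum(1 for a, b in zip(t, p) if a == "D1" and b == "D1")
    fp = sum(1 for a, b in zip(t, p) if a == "D1" and b == "D2")
    fn = sum(1 for a, b in zip(t, p) if a == "D2" and b == "D1")
    n = len(t)
    accuracy = (tp + tn) / n
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    ci = {}
    if with_ci:
        pairs = {
            "accuracy": (tp + tn, n),
            "precision": (tp, tp + fp),
            "recall": (tp, tp + fn),
            "f1": (2 * tp, 2 * tp + fp + fn),
        }
        for name, (count, nobs) in pairs.items():
            if nobs > 0:
                lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
                ci[name] = (float(lo), float(hi))
    return EvalReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        confusion=((tn, fp), (fn, tp)), n=n, degenerate=degenerate, ci=ci,
    )


@dataclass(frozen=True)
class ProtocolReport:
    cv_mean: dict  # metric -> mean over folds
    cv_sd: dict  # metric -> SD over folds (ddof=1)
    folds: tuple  # per-fold EvalReport
    test: EvalReport
    mode: str
    subset: str
    seed: int
    n_test_evaluations: int = 1


def _evaluate_model(model, cohort: CohortTable, with_ci: bool = False) -> EvalReport:
    results = screen_cohort(cohort, model)
    return classification_metrics(
        cohort.labels(), [r.predicted for r in results], with_ci=with_ci
    )


def _summarize(fold_reports):
    cv_mean = {m: float(np.mean([r.metric(m) for r in fold_reports])) for m in METRICS}
    cv_sd = {
        m: float(np.std([r.metric(m) for r in fold_reports], ddof=1))
        for m in METRICS
    }
    return cv_mean, cv_sd


def run_protocol(
    cohort: CohortTable,
    mode: str = "refit",
    subset: str = "all",
    k: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> ProtocolReport:
    """Full evaluation: hold-out, k-fold calibration/validation, sealed test.

    ``subset`` names a feature ablation (see :data:`FEATURE_SUBSETS`); the
    latent structure degrades gracefully for single-feature subsets.  The
    test set is evaluated exactly once, by the model calibrated on the
    full training portion.
    """
    if subset not in FEATURE_SUBSETS:
        raise ValueError(
            f"unknown subset {subset!r}; expected one of {sorted(FEATURE_SUBSETS)}"
        )
    features = FEATURE_SUBSETS[subset]
    train, test = stratified_holdout(cohort, fraction=test_fraction, seed=seed)
    fold_reports = []
    for fold_train, fold_val in stratified_kfold(train, k=k, seed=seed):
        model = calibrate(fold_train, mode=mode, features=features)
        fold_reports.append(_evaluate_model(model, fold_val))
    cv_mean, cv_sd = _summarize(fold_reports)
    final_model = calibrate(train, mode=mode, features=features)
    test_report = _evaluate_model(final_model, test, with_ci=True)
    return ProtocolReport(
        cv_mean=cv_mean, cv_sd=cv_sd, folds=tuple(fold_reports),
        test=test_report, mode=mode, subset=subset, seed=seed,
        n_test_evaluations=1,
    )


def baseline_run(
    cohort: CohortTable,
    classifier_factory,
    seed: int = 0,
    k: int = 5,
    test_fraction: float = 0.2,
    features=FEATURES,
) -> ProtocolReport:
    """Run any fit/predict classifier through the identical split machinery.

    ``classifier_factory`` is a zero-argument callable returning a fresh
    estimator with ``fit(X, y)`` and ``predict(X)``; features are
    standardized on each training portion before fitting.
    """
    def fit_and_predict(train_cohort, eval_cohort):
        clf = classifier_factory()
        if not (hasattr(clf, "fit") and hasattr(clf, "predict")):
            raise TypeError("classifier must implement fit(X, y) and predict(X)")
        z_train, params = standardize_features(train_cohort, features=features)
        clf.fit(z_train.to_numpy(), train_cohort.labels())
        frame = eval_cohort.to_frame()
        z_eval = np.column_stack(
            [
                (frame[f].to_numpy(dtype=float) - params[f][0]) / params[f][1]
                for f in features
            ]
        )
        return list(clf.predict(z_eval))

    train, test = stratified_holdout(cohort, fraction=test_fraction, seed=seed)
    fold_reports = []
    for fold_train, fold_val in stratified_kfold(train, k=k, seed=seed):
        preds = fit_and_predict(fold_train, fold_val)
        fold_reports.append(classification_metrics(fold_val.labels(), preds))
    cv_mean, cv_sd = _summarize(fold_reports)
    test_report = classification_metrics(
        test.labels(), fit_and_predict(train, test), with_ci=True
    )
    return ProtocolReport(
        cv_mean=cv_mean, cv_sd=cv_sd, folds=tuple(fold_reports),
        test=test_report, mode="baseline", subset="all", seed=seed,
        n_test_evaluations=1,
    )
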