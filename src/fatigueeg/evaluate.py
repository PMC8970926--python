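"""Leave-one-subject-out (LOSO) experiment harness.

Every subject in turn supplies the test epochs while the remaining subjects
train each classifier; the report carries the per-(classifier, subject)
accuracy grid, the row means, and paired t-tests of a reference classifier
against every other.  LOSO prevents subject leakage: a classifier scored on
a subject it never saw must rely on state differences, not subject identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from . import classify
from .errors import ParameterError
from .features import FeatureMatrix, extract_features
from .preprocess import preprocess_recording
from .recording import EpochSet, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "TTestRow",
    "EvalReport",
    "loso_splits",
    "accuracy",
    "paired_t_test",
    "run_experiment",
    "CLASSIFIERS",
]


@dataclass
class SplitPlan:
    """One LOSO fold: a held-out test subject and the training remainder."""

    test_subject: str
    train_ids: list[str]
    test_rows: np.ndarray  # boolean mask over FeatureMatrix rows
    train_rows: np.ndarray


def loso_splits(fm: FeatureMatrix) -> list[SplitPlan]:
    """One plan per subject; test folds partition the rows exactly."""
    subjects = sorted(set(np.asarray(fm.subject_ids).tolist()))
    if len(subjects) < 2:
        raise ParameterError("leave-one-subject-out needs at least 2 subjects")
    plans = []
    sid = np.asarray(fm.subject_ids)
    for s in subjects:
        test = sid == s
        plans.append(
            SplitPlan(
                test_subject=s,
                train_ids=[t for t in subjects if t != s],
                test_rows=test,
                train_rows=~test,
            )
        )
    return plans


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percent agreement between predicted and true labels."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape or pred.size == 0:
        raise ParameterError("pred and truth must be non-empty and equal length")
    return float(100.0 * np.mean(pred == truth))


@dataclass
class TTestRow:
    """Paired-difference statistics in the usual report layout."""

    pair: str
    mean: float
    sd: float
    se: float
    ci95: tuple[float, float]
    t: float | None
    df: int
    p: float | None
    degenerate: bool = False
    p_holm: float | None = None


def paired_t_test(a: np.ndarray, b: np.ndarray, pair: str = "a-b") -> TTestRow:
    """Two-sided paired t-test of accuracies ``a`` against ``b``.

    Zero-variance differences are flagged degenerate (t and p omitted)
    rather than producing a division by zero.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ParameterError("need two equal-length vectors with n >= 2")
    d = a - b
    n = len(d)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        return TTestRow(
            pair=pair, mean=mean, sd=0.0, se=0.0, ci95=(mean, mean),
            t=None, df=df, p=None, degenerate=True,
        )
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, df)
    tval = mean / se
    p = float(2.0 * stats.t.sf(abs(tval), df))
    return TTestRow(
        pair=pair, mean=mean, sd=sd, se=float(se),
        ci95=(mean - tcrit * se, mean + tcrit * se),
        t=float(tval), df=df, p=p,
    )


@dataclass
class EvalReport:
    """Accuracy grid, averages and paired t-tests of one LOSO experiment."""

    per_cell: pd.DataFrame  # classifiers x subjects, accuracy in percent
    averages: pd.Series
    ttests: list[TTestRow] = field(default_factory=list)
    n_missing: int = 0

    def summary(self) -> str:
        lines = ["Per-subject accuracy (%)", self.per_cell.round(2).to_string(), ""]
        lines += ["Average accuracy (%)", self.averages.round(2).to_string(), ""]
        if self.ttests:
            rows = []
            for r in self.ttests:
                rows.append(
                    {
                        "pair": r.pair,
                        "mean": round(r.mean, 3),
                        "sd": round(r.sd, 3),
                        "se": round(r.se, 3),
                        "ci95_lo": round(r.ci95[0], 3),
                        "ci95_hi": round(r.ci95[1], 3),
                        "t": None if r.t is None else round(r.t, 3),
                        "df": r.df,
                        "p": None if r.p is None else round(r.p, 4),
                    }
                )
            lines += ["Paired t-tests", pd.DataFrame(rows).to_string(index=False)]
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "per_cell": self.per_cell.to_dict(),
            "averages": self.averages.to_dict(),
            "ttests": [
                {
                    "pair": r.pair, "mean": r.mean, "sd": r.sd, "se": r.se,
                    "ci95": list(r.ci95), "t": r.t, "df": r.df, "p": r.p,
                    "p_holm": r.p_holm, "degenerate": r.degenerate,
                }
                for r in self.ttests
            ],
            "n_missing": self.n_missing,
        }


#: name -> train(X: FeatureMatrix-slice, y, seed) factory for run_experiment
CLASSIFIERS: dict[str, Callable] = {
    "knn": lambda X, y, seed: classify.knn_train(X, y),
    "svm": lambda X, y, seed: classify.svm_train(X, y),
    "elm": lambda X, y, seed: classify.elm_train(X, y, seed=seed),
    "helm": lambda X, y, seed: classify.helm_train(X, y, seed=seed),
    "pso_helm": None,  # handled specially (needs a PSOConfig)
}


def holm_adjust(pvals: list[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def evaluate_features(
    fm: FeatureMatrix,
    classifiers: list[str],
    seed: int = 0,
    pso_config: "classify.PSOConfig | None" = None,
    ttest_reference: str | None = None,
    holm: bool = False,
) -> EvalReport:
    """LOSO-evaluate named classifiers on an existing feature matrix."""
    plans = loso_splits(fm)
    subjects = [p.test_subject for p in plans]
    grid = pd.DataFrame(index=classifiers, columns=subjects, dtype=float)
    n_missing = 0
    for plan in plans:
        train = fm.subset(plan.train_rows)
        test = fm.subset(plan.test_rows)
        for name in classifiers:
            try:
                if name == "pso_helm":
                    cfg = pso_config or classify.PSOConfig(
                        bounds=list(classify.DEFAULT_PSO_BOUNDS), seed=seed
                    )
                    model, _ = classify.pso_helm_train(train, cfg=cfg)
                elif name in CLASSIFIERS:
                    model = CLASSIFIERS[name](train.values, train.labels, seed)
                else:
                    raise ParameterError(f"unknown classifier {name!r}")
            except ParameterError:
                raise
            except Exception as exc:  # classifier failure: missing cell, not fatal
                logger.warning(
                    "classifier %s failed on test subject %s: %s",
                    name, plan.test_subject, exc,
                )
                n_missing += 1
                continue
            pred = classify.predict(model, test.values)
            grid.loc[name, plan.test_subject] = accuracy(pred, test.labels)
    averages = grid.mean(axis=1, skipna=True)
    ttests = []
    ref = ttest_reference
    if ref is None and "pso_helm" in classifiers:
        ref = "pso_helm"
    if ref is not None and ref in grid.index:
        for name in classifiers:
            if name == ref:
                continue
            a, b = grid.loc[ref].to_numpy(float), grid.loc[name].to_numpy(float)
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() >= 2:
                ttests.append(paired_t_test(a[ok], b[ok], pair=f"{ref}-{name}"))
    if holm:
        with_p = [r for r in ttests if r.p is not None]
        for r, adj in zip(with_p, holm_adjust([r.p for r in with_p])):
            r.p_holm = adj
    return EvalReport(
        per_cell=grid, averages=averages, ttests=ttests, n_missing=n_missing
    )


def run_experiment(
    dataset: list[Recording],
    feature_method: str = "emd",
    classifiers: list[str] | None = None,
    seed: int = 0,
    target_rate: float | None = 200.0,
    band: tuple[float, float] | None = (0.1, 50.0),
    epoch_duration: float = 10.0,
    pso_config: "classify.PSOConfig | None" = None,
    feature_kwargs: dict | None = None,
) -> EvalReport:
    """Full pipeline: preprocess every recording, extract features, LOSO-evaluate.

    Deterministic under ``seed``: the only randomness is in the classifiers,
    which all derive from it.
    """
    if not dataset:
        raise ParameterError("dataset is empty")
    classifiers = classifiers or ["knn", "svm", "elm", "helm"]
    states = {r.state for r in dataset}
    subjects = {r.subject_id for r in dataset}
    if len(states) < 2 or len(subjects) < 2:
        raise ParameterError("dataset must span both states and >= 2 subjects")
    epochs = EpochSet()
    for rec in dataset:
        epochs = epochs.extend(
            preprocess_recording(
                rec, target_rate=target_rate, band=band,
                epoch_duration=epoch_duration,
            )
        )
    fm = extract_features(epochs, method=feature_method, **(feature_kwargs or {}))
    return evaluate_features(
        fm, classifiers, seed=seed, pso_config=pso_config
    )
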