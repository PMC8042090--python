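"""The two contrasted experimental protocols over repeated stratified k-fold CV.

``run_outside_cv_protocol`` reproduces the leaky design: features are z-scored
and the vote selector is run once on ALL samples, and the resulting fixed
feature sets are then "evaluated" by CV.  Every test sample has already
influenced which features the classifier sees, so the estimate is inflated by
selection bias.

``run_within_cv_protocol`` is the nested (correct) design: inside every CV
loop, standardization statistics, vote counts and the classifier are computed
from the training folds only and applied to the untouched test fold.

``run_feature_count_sweep`` evaluates both designs as a function of the number
of top-voted features k = 1..k_max, which exposes the curse of dimensionality
in the nested protocol and the saturation of the leaky one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .classifiers import ClassifierSpec, accuracy, predict, train
from .datatypes import FeatureMatrix
from .selection import (
    VoteParams,
    VoteTable,
    _vote_count_arrays,
    rank_features,
    select_by_threshold,
)
from .synthetic import _zscore_apply, _zscore_fit

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (50, 60, 70, 80, 90)


@dataclass
class CVPlan:
    """Fold assignments for repeated (stratified) k-fold cross-validation.

    ``fold_of[r, i]`` is the test-fold id of sample i in repetition r; within
    each repetition every sample sits in exactly one test fold.
    """

    fold_of: np.ndarray  # (n_repetitions, n_samples) int
    n_folds: int
    n_repetitions: int
    stratified: bool = True
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.fold_of.shape[1]

    @property
    def n_loops(self) -> int:
        return self.n_repetitions * self.n_folds

    def loops(self) -> Iterator[tuple[int, int, np.ndarray, np.ndarray]]:
        """Yield (repetition, fold, train_indices, test_indices) per CV loop."""
        for r in range(self.n_repetitions):
            for f in range(self.n_folds):
                test = np.flatnonzero(self.fold_of[r] == f)
                trainset = np.flatnonzero(self.fold_of[r] != f)
                yield r, f, trainset, test


def make_cv_plan(
    labels: Sequence[int],
    n_folds: int = 10,
    n_repetitions: int = 10,
    seed: int | None = None,
    stratified: bool = True,
) -> CVPlan:
    """Build a repeated (stratified) k-fold plan, reshuffled per repetition.

    Stratification keeps per-fold class counts within one of proportionality;
    each class must have at least ``n_folds`` samples.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    for c in np.unique(labels):
        if (labels == c).sum() < n_folds:
            raise ValueError(f"class {c} has fewer samples than n_folds={n_folds}")
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_repetitions) % (2**31)
    fold_of = np.empty((n_repetitions, n), dtype=int)
    for r in range(n_repetitions):
        splitter_cls = StratifiedKFold if stratified else KFold
        splitter = splitter_cls(n_splits=n_folds, shuffle=True, random_state=int(rep_seeds[r]))
        for f, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), labels)):
            fold_of[r, test_idx] = f
    return CVPlan(fold_of, n_folds, n_repetitions, stratified, seed)


@dataclass
class ProtocolResult:
    """Per-threshold, per-classifier accuracies under one protocol.

    ``fold_acc[(threshold, kind)]`` holds the accuracy (fraction) of every CV
    loop; ``n_selected[threshold]`` is a fixed integer for the leaky protocol
    and a (min, max) range over loops for the nested one.
    """

    protocol: str  # "outside_cv" | "within_cv"
    thresholds: list[int]
    classifier_kinds: list[str]
    fold_acc: dict[tuple[int, str], np.ndarray]
    n_selected: dict[int, int | tuple[int, int]]
    per_loop_selected: dict[int, list[list[str]]] | None = None
    fallback_counts: dict[int, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    models: dict[tuple[int, str], list] | None = None  # per-loop TrainedModels

    def mean_accuracy(self, threshold: int, kind: str) -> float:
        """Mean accuracy over all CV loops, in percent."""
        return float(self.fold_acc[(threshold, kind)].mean() * 100.0)

    def sd_accuracy(self, threshold: int, kind: str) -> float:
        """Sample SD of the loop accuracies, in percentage points."""
        return float(self.fold_acc[(threshold, kind)].std(ddof=1) * 100.0)

    def threshold_mean(self, kind: str) -> float:
        """Mean over thresholds of the per-threshold mean accuracies (percent)."""
        return float(np.mean([self.mean_accuracy(t, kind) for t in self.thresholds]))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.thresholds:
            n_sel = self.n_selected[t]
            row: dict = {
                "threshold": t,
                "n_selected": n_sel if isinstance(n_sel, int) else f"{n_sel[0]}-{n_sel[1]}",
            }
            for kind in self.classifier_kinds:
                row[kind] = self.mean_accuracy(t, kind)
                row[f"{kind}_sd"] = self.sd_accuracy(t, kind)
            rows.append(row)
        return pd.DataFrame(rows)


def _evaluate_fixed_features(
    Z: np.ndarray,
    labels: np.ndarray,
    cols: np.ndarray,
    specs: Sequence[ClassifierSpec],
    trainset: np.ndarray,
    test: np.ndarray,
) -> dict[str, float]:
    out = {}
    for spec in specs:
        model = train(spec, Z[np.ix_(trainset, cols)], labels[trainset])
        out[spec.kind] = accuracy(predict(model, Z[np.ix_(test, cols)]), labels[test])
    return out


def run_outside_cv_protocol(
    data: FeatureMatrix,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    specs: Sequence[ClassifierSpec] = (ClassifierSpec("svm"), ClassifierSpec("rlda")),
    plan: CVPlan | None = None,
    vote_params: VoteParams | None = None,
) -> ProtocolResult:
    """Leaky protocol: select features once on all samples, then CV.

    Standardization statistics and vote counts both use every sample, so each
    threshold yields one fixed feature set; CV then only estimates the
    accuracy of classifiers restricted to that (already biased) set.
    Thresholds whose selection is empty are reported as absent with a warning.
    """
    vote_params = vote_params or VoteParams()
    plan = plan if plan is not None else make_cv_plan(data.labels)
    if plan.n_samples != data.n_samples:
        raise ValueError("CV plan does not match the data's sample count")

    Z = _zscore_apply(data.values, _zscore_fit(data.values), warn=False)
    rng = np.random.default_rng(vote_params.seed)
    votes_arr, mean_p = _vote_count_arrays(Z, data.labels, vote_params, rng)
    table = VoteTable(list(data.feature_ids), votes_arr, mean_p, vote_params)

    kept_thresholds: list[int] = []
    col_sets: dict[int, np.ndarray] = {}
    n_selected: dict[int, int | tuple[int, int]] = {}
    for t in thresholds:
        sel = select_by_threshold(table, t)
        if sel.is_empty:
            logger.warning("threshold >= %d selects no features; reported as absent", t)
            continue
        kept_thresholds.append(t)
        col_sets[t] = data.column_index(sel.feature_ids)
        n_selected[t] = sel.n_selected

    kinds = [s.kind for s in specs]
    fold_acc = {(t, k): np.empty(plan.n_loops) for t in kept_thresholds for k in kinds}
    for loop, (_, _, trainset, test) in enumerate(plan.loops()):
        for t in kept_thresholds:
            accs = _evaluate_fixed_features(Z, data.labels, col_sets[t], specs, trainset, test)
            for k, a in accs.items():
                fold_acc[(t, k)][loop] = a

    return ProtocolResult(
        protocol="outside_cv",
        thresholds=kept_thresholds,
        classifier_kinds=kinds,
        fold_acc=fold_acc,
        n_selected=n_selected,
        config={"vote_params": vars(vote_params), "n_folds": plan.n_folds,
                "n_repetitions": plan.n_repetitions, "plan_seed": plan.seed},
    )


def _loop_vote_seeds(vote_params: VoteParams, n_loops: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(vote_params.seed).spawn(n_loops)
    return [np.random.default_rng(c) for c in children]


def run_within_cv_protocol(
    data: FeatureMatrix,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    specs: Sequence[ClassifierSpec] = (ClassifierSpec("svm"), ClassifierSpec("rlda")),
    plan: CVPlan | None = None,
    vote_params: VoteParams | None = None,
    standardize: str = "train",
    keep_models: bool = False,
) -> ProtocolResult:
    """Nested protocol: feature selection repeated inside every CV loop.

    Per loop, z-score statistics come from the training folds and are applied
    to the test fold; the vote selector sees training folds only; the
    classifier is trained on the selected training features and scored on the
    corresponding test features.  ``standardize='global'`` switches to
    whole-dataset z-scoring (a deliberate leakage channel kept for strict
    replication of the leaky pipeline's preprocessing).  An empty selection
    in a loop falls back to the single top-voted feature (counted and
    logged).
    """
    if standardize not in ("train", "global"):
        raise ValueError("standardize must be 'train' or 'global'")
    vote_params = vote_params or VoteParams()
    plan = plan if plan is not None else make_cv_plan(data.labels)
    if plan.n_samples != data.n_samples:
        raise ValueError("CV plan does not match the data's sample count")

    thresholds = list(thresholds)
    kinds = [s.kind for s in specs]
    fold_acc = {(t, k): np.empty(plan.n_loops) for t in thresholds for k in kinds}
    per_loop_selected: dict[int, list[list[str]]] = {t: [] for t in thresholds}
    per_loop_counts: dict[int, list[int]] = {t: [] for t in thresholds}
    fallback_counts: dict[int, int] = {t: 0 for t in thresholds}
    models: dict[tuple[int, str], list] = {(t, k): [] for t in thresholds for k in kinds}

    rngs = _loop_vote_seeds(vote_params, plan.n_loops)
    global_stats = _zscore_fit(data.values) if standardize == "global" else None

    for loop, (_, _, trainset, test) in enumerate(plan.loops()):
        stats = global_stats if global_stats is not None else _zscore_fit(data.values[trainset])
        Ztr = _zscore_apply(data.values[trainset], stats, warn=False)
        Zte = _zscore_apply(data.values[test], stats, warn=False)
        ytr, yte = data.labels[trainset], data.labels[test]

        votes_arr, mean_p = _vote_count_arrays(Ztr, ytr, vote_params, rngs[loop])
        table = VoteTable(list(data.feature_ids), votes_arr, mean_p, vote_params)

        for t in thresholds:
            sel = select_by_threshold(table, t)
            ids = sel.feature_ids
            if not ids:
                ids = rank_features(table, 1)
                fallback_counts[t] += 1
            cols = data.column_index(ids)
            per_loop_selected[t].append(list(ids))
            per_loop_counts[t].append(len(ids))
            for spec in specs:
                model = train(spec, Ztr[:, cols], ytr, feature_ids=ids)
                fold_acc[(t, spec.kind)][loop] = accuracy(predict(model, Zte[:, cols]), yte)
                if keep_models:
                    models[(t, spec.kind)].append(model)

    for t, n in fallback_counts.items():
        if n:
            logger.info("threshold >= %d: top-1 fallback used in %d of %d loops",
                        t, n, plan.n_loops)

    n_selected = {
        t: (int(min(c)), int(max(c))) for t, c in per_loop_counts.items()
    }
    return ProtocolResult(
        protocol="within_cv",
        thresholds=thresholds,
        classifier_kinds=kinds,
        fold_acc=fold_acc,
        n_selected=n_selected,
        per_loop_selected=per_loop_selected,
        fallback_counts=fallback_counts,
        models=models if keep_models else None,
        config={"vote_params": vars(vote_params), "n_folds": plan.n_folds,
                "n_repetitions": plan.n_repetitions, "plan_seed": plan.seed,
                "standardize": standardize},
    )


@dataclass
class SweepResult:
    """Mean accuracy (percent) per feature count k, per classifier, one protocol."""

    protocol: str
    ks: list[int]
    classifier_kinds: list[str]
    fold_acc: dict[tuple[int, str], np.ndarray]

    def mean_accuracy(self, k: int, kind: str) -> float:
        return float(self.fold_acc[(k, kind)].mean() * 100.0)

    def curve(self, kind: str) -> np.ndarray:
        return np.array([self.mean_accuracy(k, kind) for k in self.ks])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"k": k, "protocol": self.protocol, "classifier": kind,
             "accuracy": self.mean_accuracy(k, kind)}
            for k in self.ks
            for kind in self.classifier_kinds
        ]
        return pd.DataFrame(rows)


def run_feature_count_sweep(
    data: FeatureMatrix,
    protocol: str,
    specs: Sequence[ClassifierSpec] = (ClassifierSpec("svm"), ClassifierSpec("rlda")),
    plan: CVPlan | None = None,
    vote_params: VoteParams | None = None,
    k_max: int = 40,
) -> SweepResult:
    """Accuracy as a function of the number of top-voted features, k = 1..k_max.

    The leaky protocol ranks features once by their global vote totals (fixed
    top-k); the nested protocol re-ranks within every CV loop from training
    folds only.  Accuracies are averaged over all loops for each k.
    """
    if protocol not in ("outside_cv", "within_cv"):
        raise ValueError("protocol must be 'outside_cv' or 'within_cv'")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > data.n_features:
        raise ValueError("k_max exceeds the number of features")
    vote_params = vote_params or VoteParams()
    plan = plan if plan is not None else make_cv_plan(data.labels)

    ks = list(range(1, k_max + 1))
    kinds = [s.kind for s in specs]
    fold_acc = {(k, kind): np.empty(plan.n_loops) for k in ks for kind in kinds}

    if protocol == "outside_cv":
        Z = _zscore_apply(data.values, _zscore_fit(data.values), warn=False)
        rng = np.random.default_rng(vote_params.seed)
        votes_arr, mean_p = _vote_count_arrays(Z, data.labels, vote_params, rng)
        table = VoteTable(list(data.feature_ids), votes_arr, mean_p, vote_params)
        ranked_cols = data.column_index(rank_features(table, k_max))
        for loop, (_, _, trainset, test) in enumerate(plan.loops()):
            for k in ks:
                cols = ranked_cols[:k]
                accs = _evaluate_fixed_features(Z, data.labels, cols, specs, trainset, test)
                for kind, a in accs.items():
                    fold_acc[(k, kind)][loop] = a
    else:
        rngs = _loop_vote_seeds(vote_params, plan.n_loops)
        for loop, (_, _, trainset, test) in enumerate(plan.loops()):
            stats = _zscore_fit(data.values[trainset])
            Ztr = _zscore_apply(data.values[trainset], stats, warn=False)
            Zte = _zscore_apply(data.values[test], stats, warn=False)
            ytr, yte = data.labels[trainset], data.labels[test]
            votes_arr, mean_p = _vote_count_arrays(Ztr, ytr, vote_params, rngs[loop])
            table = VoteTable(list(data.feature_ids), votes_arr, mean_p, vote_params)
            ranked_cols = data.column_index(rank_features(table, k_max))
            for k in ks:
                cols = ranked_cols[:k]
                for spec in specs:
                    model = train(spec, Ztr[:, cols], ytr)
                    fold_acc[(k, spec.kind)][loop] = accuracy(
                        predict(model, Zte[:, cols]), yte
                    )

    return SweepResult(protocol=protocol, ks=ks, classifier_kinds=kinds, fold_acc=fold_acc)
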