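"""Leakage-controlled cross-validated comparison of raw vs network features.

Two scenarios are compared under a shared stratified 10-fold partition:

* **raw** — linear-SVM classification on the raw biomarker columns;
* **enhanced** — the same candidates plus the two network features
  (link density, Information Content).

When network features are in play, every fold recomputes the pairwise
baseline on the *training* fold's survivors only, and both training and test
subjects' networks are built from that per-fold baseline — no test subject
ever touches baseline fitting, standardization statistics, or SVM training.
Greedy forward selection (stop on small gain or a feature cap) mirrors how
compact clinical models are built and keeps the comparison about features,
not model capacity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import sklearn
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .cohort import Cohort
from .netfeatures import features_from_zscores
from .networks import fit_baseline

NETWORK_FEATURES = ("link_density", "information_content")


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings for the SVM / cross-validation / selection machinery.

    The kernel is fixed linear; ``regularization`` is the SVM C parameter
    (no tuning — the comparison is about features, not hyperparameters).
    ``selection_tolerance`` is the absolute accuracy gain below which greedy
    forward selection stops; ``network_threshold`` is the |w| cut used when
    binarizing per-fold networks.
    """

    kernel: str = "linear"
    regularization: float = 1.0
    standardize: bool = True
    seed: int = 0
    n_folds: int = 10
    selection_tolerance: float = 0.005
    max_features: int = 5
    network_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.network_threshold < 0:
            raise ValueError("network threshold must be non-negative")


@dataclass
class CVReport:
    """Fold-wise scores plus the feature-selection trace for one scenario."""

    scenario: str
    fold_scores: list[float]
    selected_features: list[str]
    selection_trace: list[dict[str, float]] = field(default_factory=list)

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def error(self) -> float:
        return 1.0 - self.mean_score

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "fold_scores": [float(s) for s in self.fold_scores],
            "mean_score": self.mean_score,
            "error": self.error,
            "selected_features": list(self.selected_features),
            "selection_trace": self.selection_trace,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


@dataclass
class ComparisonReport:
    raw: CVReport
    enhanced: CVReport

    @property
    def relative_error_reduction(self) -> float:
        """1 - err_enhanced / err_raw (positive when networks help)."""
        if self.raw.error == 0:
            return 0.0
        return 1.0 - self.enhanced.error / self.raw.error

    def to_dict(self) -> dict:
        return {
            "raw": self.raw.to_dict(),
            "enhanced": self.enhanced.to_dict(),
            "relative_error_reduction": self.relative_error_reduction,
        }


def make_folds(cohort: Cohort, config: ClassifierConfig) -> np.ndarray:
    """Stratified fold id per subject; seeded, per-class sizes differ <= 1."""
    y = cohort.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"need >= {config.n_folds} subjects per class, got {counts.min()}")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    folds = np.empty(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros_like(y), y)):
        folds[test_idx] = i
    return folds


@dataclass
class _FoldState:
    """Everything one fold exposes to candidate evaluation (train stats only)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    X_train: np.ndarray  # standardized, columns = `columns`
    X_test: np.ndarray
    columns: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    baseline: object | None = None  # fitted per-fold BaselineModel, if networks


def _prepare_folds(cohort: Cohort, config: ClassifierConfig,
                   folds: np.ndarray | None,
                   with_networks: bool) -> list[_FoldState]:
    """Per-fold standardized design matrices (and per-fold network features).

    Built once and shared across all candidate-set evaluations — selecting a
    feature subset is then a column slice, with identical results to
    re-standardizing the subset from scratch.
    """
    if folds is None:
        folds = make_folds(cohort, config)
    y = cohort.labels
    raw_names = cohort.feature_names
    X_raw = cohort.feature_matrix()
    states = []
    for f in range(config.n_folds):
        test_idx = np.where(folds == f)[0]
        train_idx = np.where(folds != f)[0]
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError(f"fold {f} is degenerate (single class)")
        columns = list(raw_names)
        Xtr, Xte = X_raw[train_idx], X_raw[test_idx]
        baseline = None
        if with_networks:
            survivors = train_idx[y[train_idx] == 0]
            if len(survivors) < 3:
                raise ValueError(
                    f"fold {f}: fewer than 3 surviving training subjects")
            baseline = fit_baseline(
                cohort.frame.iloc[survivors][raw_names])
            net_tr = features_from_zscores(
                baseline.zscores(Xtr), baseline.degenerate,
                len(raw_names), config.network_threshold)
            net_te = features_from_zscores(
                baseline.zscores(Xte), baseline.degenerate,
                len(raw_names), config.network_threshold)
            Xtr = np.column_stack([Xtr, net_tr])
            Xte = np.column_stack([Xte, net_te])
            columns += list(NETWORK_FEATURES)
        if config.standardize:
            mean = Xtr.mean(axis=0)
            scale = Xtr.std(axis=0)
            scale[scale == 0] = 1.0
        else:
            mean = np.zeros(Xtr.shape[1])
            scale = np.ones(Xtr.shape[1])
        states.append(_FoldState(
            train_idx=train_idx, test_idx=test_idx,
            X_train=(Xtr - mean) / scale, X_test=(Xte - mean) / scale,
            columns=columns, scaler_mean=mean, scaler_scale=scale,
            baseline=baseline))
    return states


def _score_columns(states: list[_FoldState], y: np.ndarray,
                   features: list[str], config: ClassifierConfig,
                   memo: dict | None = None) -> list[float]:
    # Standardization is per column, so a given feature tuple scores
    # identically whichever scenario evaluates it; memo is shared between
    # the raw and enhanced greedy runs over one fold partition.
    key = tuple(features)
    if memo is not None and key in memo:
        return memo[key]
    scores = []
    with sklearn.config_context(assume_finite=True):
        for st in states:
            cols = [st.columns.index(f) for f in features]
            clf = LinearSVC(C=config.regularization, dual=False, tol=1e-4)
            clf.fit(st.X_train[:, cols], y[st.train_idx])
            scores.append(float(clf.score(st.X_test[:, cols], y[st.test_idx])))
    if memo is not None:
        memo[key] = scores
    return scores


def cross_validate(cohort: Cohort, features: list[str],
                   config: ClassifierConfig,
                   use_network_features: bool = False,
                   folds: np.ndarray | None = None,
                   _states: list[_FoldState] | None = None,
                   return_states: bool = False):
    """Stratified k-fold accuracy of a linear SVM on the given features.

    With ``use_network_features``, each fold refits the pairwise baseline on
    its training survivors and derives link density / Information Content
    for train and test subjects from that fold-local baseline.
    """
    if not features:
        raise ValueError("feature list is empty")
    if _states is None:
        _states = _prepare_folds(cohort, config, folds, use_network_features)
    for f in features:
        if f not in _states[0].columns:
            raise KeyError(f"unknown feature {f!r}")
    scenario = "enhanced" if use_network_features else "raw"
    scores = _score_columns(_states, cohort.labels, list(features), config)
    report = CVReport(scenario=scenario, fold_scores=scores,
                      selected_features=list(features))
    if return_states:
        return report, _states
    return report


def greedy_select(cohort: Cohort, candidates: list[str],
                  config: ClassifierConfig,
                  use_network_features: bool = False,
                  folds: np.ndarray | None = None,
                  _states: list[_FoldState] | None = None,
                  _memo: dict | None = None) -> CVReport:
    """Forward feature selection under a fixed fold partition.

    Starts empty and repeatedly adds the candidate with the highest
    cross-validated mean accuracy (ties: candidate order); stops when the
    best gain drops below ``selection_tolerance`` or ``max_features`` is
    reached. Returns the final CVReport with the full selection trace.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if _states is None:
        _states = _prepare_folds(cohort, config, folds, use_network_features)
    y = cohort.labels
    selected: list[str] = []
    trace: list[dict[str, float]] = []
    best_score = 0.0
    best_fold_scores: list[float] = []
    while len(selected) < config.max_features:
        step: dict[str, float] = {}
        step_best = None
        for cand in candidates:
            if cand in selected:
                continue
            scores = _score_columns(_states, y, selected + [cand], config, _memo)
            mean = float(np.mean(scores))
            step[cand] = mean
            if step_best is None or mean > step_best[1]:
                step_best = (cand, mean, scores)
        if step_best is None:
            break
        trace.append(step)
        cand, mean, scores = step_best
        gain = mean - best_score
        if selected and gain < config.selection_tolerance:
            trace.pop()  # step rejected; keep the trace consistent with selection
            break
        selected.append(cand)
        best_score = mean
        best_fold_scores = scores
    scenario = "enhanced" if use_network_features else "raw"
    return CVReport(scenario=scenario, fold_scores=best_fold_scores,
                    selected_features=selected, selection_trace=trace)


def run_comparison(cohort: Cohort, config: ClassifierConfig) -> ComparisonReport:
    """Raw vs network-enhanced scenario comparison on one fold partition.

    Both scenarios share the same stratified folds; the enhanced scenario's
    candidate list appends link density and Information Content to the raw
    features (per-fold recomputed, leakage-free).
    """
    folds = make_folds(cohort, config)
    raw_candidates = cohort.feature_names
    memo: dict = {}
    raw_states = _prepare_folds(cohort, config, folds, with_networks=False)
    raw_report = greedy_select(cohort, raw_candidates, config,
                               use_network_features=False, _states=raw_states,
                               _memo=memo)
    enh_states = _prepare_folds(cohort, config, folds, with_networks=True)
    enh_candidates = raw_candidates + list(NETWORK_FEATURES)
    enh_report = greedy_select(cohort, enh_candidates, config,
                               use_network_features=True, _states=enh_states,
                               _memo=memo)
    return ComparisonReport(raw=raw_report, enhanced=enh_report)
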