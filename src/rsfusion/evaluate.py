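"""Cross-validation orchestration, metrics and the statistics battery.

Implements the study protocol around the classifiers: repeated nested
stratified cross-validation in which an inner CV chooses only the number of
ranked features, confusion-count metrics with Wilson 95% intervals, the
5x2-CV paired t-test for comparing two classifiers, vertically averaged ROC
curves, voxel-wise two-sample t discriminative mapping with
Benjamini-Hochberg FDR control, and the Rician-noise robustness protocol in
which only test-fold volumes are corrupted and already-trained models are
re-applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .classify import LinearModel, feature_fusion, majority_vote, predict, train_linear
from .measures import ActivityMap
from .preprocess import BrainMask
from .selection import (
    FeatureMatrix,
    FsvParams,
    rank_fsv,
    rank_l0,
    rank_relief,
    rank_wilcoxon,
    sequential_forward_select,
)
from .synthetic import CONTROL, PATIENT, add_rician_noise

__all__ = [
    "Metrics",
    "FoldResult",
    "CvConfig",
    "Scheme",
    "CvReport",
    "RocCurve",
    "FiveByTwoScores",
    "compute_metrics",
    "wilson_interval",
    "nested_cv",
    "make_scheme_evaluator",
    "five_by_two_test",
    "five_by_two_critical_value",
    "roc_from_scores",
    "roc_vertical_average",
    "discriminative_map",
    "fdr_reject",
    "rician_robustness",
]

FIVE_BY_TWO_DF = 5


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class Metrics:
    """Accuracy / sensitivity / specificity; None where the denominator is 0."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    """Confusion-count metrics with patients as the positive class.

    accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
    A metric whose denominator is zero is reported as None, not 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return Metrics(acc, sens, spec)


def wilson_interval(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1 or not (0 <= successes <= n):
        raise ValueError("invalid counts")
    low, high = proportion_confint(successes, n, alpha=1.0 - conf, method="wilson")
    # The Wilson bounds are exactly 0/1 at the boundaries; remove round-off.
    if successes == 0:
        low = 0.0
    if successes == n:
        high = 1.0
    return float(low), float(high)


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocCurve:
    """Ordered (FPR, TPR) points from sweeping a decision threshold."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if fpr.size == 0 or fpr.shape != tpr.shape:
            raise ValueError("curve must have matched, nonempty coordinates")
        if fpr[0] != 0 or tpr[0] != 0 or fpr[-1] != 1 or tpr[-1] != 1:
            raise ValueError("curve must run from (0,0) to (1,1)")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("curve coordinates must be non-decreasing")
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)


def roc_from_scores(decision_values, labels) -> RocCurve:
    """ROC curve of decision values against true labels (patient positive)."""
    from sklearn.metrics import roc_curve as _sk_roc

    y = np.where(np.asarray(labels) == PATIENT, 1, 0)
    if y.min() == y.max():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc(y, np.asarray(decision_values, float))
    if fpr[0] != 0 or tpr[0] != 0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    return RocCurve(fpr, tpr)


def roc_vertical_average(
    curves: list[RocCurve], fpr_grid: np.ndarray | None = None
) -> tuple[RocCurve, float]:
    """Average TPR across curves at fixed FPR values; AUC by trapezoid rule."""
    if not curves:
        raise ValueError("need at least one curve")
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    fpr_grid = np.asarray(fpr_grid, dtype=float)
    if np.any(np.diff(fpr_grid) <= 0) or fpr_grid[0] < 0 or fpr_grid[-1] > 1:
        raise ValueError("fpr_grid must be ascending within [0, 1]")
    tprs = np.vstack([np.interp(fpr_grid, c.fpr, c.tpr) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    # Pin the endpoints so the averaged curve is itself a valid ROC curve
    # (a perfect fold contributes a vertical segment at FPR = 0).
    grid = np.concatenate([[0.0], fpr_grid, [1.0]])
    mean_tpr = np.concatenate([[0.0], mean_tpr, [1.0]])
    mean_tpr = np.maximum.accumulate(np.clip(mean_tpr, 0.0, 1.0))
    auc = float(np.trapezoid(mean_tpr, grid))
    return RocCurve(grid, mean_tpr), auc


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass(frozen=True)
class Scheme:
    """What is being classified: one measure, a majority vote of three
    single-measure classifiers, or a concatenation of measures."""

    kind: str
    measures: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("single", "decision_fusion", "feature_fusion"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        measures = tuple(self.measures)
        if self.kind == "single" and len(measures) != 1:
            raise ValueError("single scheme takes exactly one measure")
        if self.kind == "decision_fusion" and len(measures) != 3:
            raise ValueError("decision fusion takes exactly three measures")
        if self.kind == "feature_fusion" and len(measures) < 2:
            raise ValueError("feature fusion takes at least two measures")
        object.__setattr__(self, "measures", measures)

    @classmethod
    def single(cls, measure: str) -> "Scheme":
        return cls("single", (measure,))

    @classmethod
    def decision_fusion(cls, measures=("falff", "reho", "vmhc")) -> "Scheme":
        return cls("decision_fusion", tuple(measures))

    @classmethod
    def feature_fusion(cls, measures) -> "Scheme":
        return cls("feature_fusion", tuple(measures))

    def describe(self) -> str:
        return f"{self.kind}:{'+'.join(self.measures)}"


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation settings.

    The defaults mirror the study protocol (5 repetitions of nested 10-fold
    CV, soft margin C = 10, FSV ranking); fold counts are capped at the
    minority-class size of the split being made, so small cohorts degrade
    gracefully instead of failing stratification.
    """

    n_repetitions: int = 5
    n_outer_folds: int = 10
    n_inner_folds: int = 10
    k_max: int = 200
    C: float = 10.0
    ranker: str = "fsv"
    fsv_params: FsvParams = field(default_factory=FsvParams)
    n_prescreen: int | None = None
    seed: int = 0
    store_models: bool = False


@dataclass
class FoldResult:
    """Outcome of one outer test fold."""

    tp: int
    fp: int
    tn: int
    fn: int
    selected_k: int
    selected_features: tuple
    decision_values: np.ndarray
    test_idx: np.ndarray
    true_labels: np.ndarray
    pred_labels: np.ndarray
    models: dict[str, LinearModel] | None = None

    def __post_init__(self) -> None:
        if self.tp + self.fp + self.tn + self.fn != len(self.test_idx):
            raise ValueError("confusion counts must sum to the test-fold size")

    def metrics(self) -> Metrics:
        return compute_metrics(self.tp, self.fp, self.tn, self.fn)


@dataclass
class CvReport:
    """All fold results of a repeated nested-CV run plus aggregates."""

    scheme: Scheme
    config: CvConfig
    folds: list[list[FoldResult]]  # [repetition][outer fold]

    def all_folds(self) -> list[FoldResult]:
        return [fr for rep in self.folds for fr in rep]

    def pooled_counts(self) -> tuple[int, int, int, int]:
        frs = self.all_folds()
        return (
            sum(f.tp for f in frs),
            sum(f.fp for f in frs),
            sum(f.tn for f in frs),
            sum(f.fn for f in frs),
        )

    def pooled_metrics(self) -> Metrics:
        return compute_metrics(*self.pooled_counts())

    def repetition_metrics(self) -> list[Metrics]:
        out = []
        for rep in self.folds:
            tp = sum(f.tp for f in rep)
            fp = sum(f.fp for f in rep)
            tn = sum(f.tn for f in rep)
            fn = sum(f.fn for f in rep)
            out.append(compute_metrics(tp, fp, tn, fn))
        return out

    @property
    def accuracy(self) -> float:
        """Mean over repetitions of within-repetition pooled accuracy."""
        return float(np.mean([m.accuracy for m in self.repetition_metrics()]))

    @property
    def accuracy_sd(self) -> float:
        """Across-fold standard deviation of per-fold accuracy."""
        return float(np.std([f.metrics().accuracy for f in self.all_folds()]))

    def wilson_intervals(self, conf: float = 0.95) -> dict[str, tuple[float, float]]:
        tp, fp, tn, fn = self.pooled_counts()
        out = {"accuracy": wilson_interval(tp + tn, tp + fp + tn + fn, conf)}
        if tp + fn > 0:
            out["sensitivity"] = wilson_interval(tp, tp + fn, conf)
        if tn + fp > 0:
            out["specificity"] = wilson_interval(tn, tn + fp, conf)
        return out

    def mean_selected_k(self) -> float:
        return float(np.mean([f.selected_k for f in self.all_folds()]))

    def roc(self, fpr_grid: np.ndarray | None = None) -> tuple[RocCurve, float]:
        curves = []
        for f in self.all_folds():
            try:
                curves.append(roc_from_scores(f.decision_values, f.true_labels))
            except ValueError:
                continue  # single-class test fold: no curve
        return roc_vertical_average(curves, fpr_grid)

    def summary(self) -> dict:
        m = self.pooled_metrics()
        _, auc = self.roc()
        return {
            "scheme": self.scheme.describe(),
            "seed": self.config.seed,
            "accuracy": self.accuracy,
            "accuracy_sd": self.accuracy_sd,
            "pooled": {
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
            },
            "wilson_95": {k: list(v) for k, v in self.wilson_intervals().items()},
            "mean_selected_k": self.mean_selected_k(),
            "auc": auc,
        }


def _rank(X: FeatureMatrix, config: CvConfig):
    if config.ranker == "fsv":
        return rank_fsv(X, config.fsv_params)
    if config.ranker == "l0":
        return rank_l0(X, C=config.C)
    if config.ranker == "relief":
        return rank_relief(X)
    if config.ranker == "wilcoxon":
        return rank_wilcoxon(X)
    raise ValueError(f"unknown ranker {config.ranker!r}")


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    y = np.where(labels == PATIENT, 1, 0)
    n_min = min(int(y.sum()), int((1 - y).sum()))
    if n_min < 2:
        raise ValueError("need at least 2 subjects per class for stratified folds")
    n_splits = min(n_folds, n_min)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=seed % 2**31)
    return list(skf.split(np.zeros(len(y)), y))


def _fit_single_path(
    X: FeatureMatrix, train_idx: np.ndarray, config: CvConfig, inner_seed: int
) -> tuple[np.ndarray, LinearModel, int]:
    """Rank on the outer-training set, choose k by inner CV, train the model.

    Returns (global feature indices, trained model, k*). The inner CV sees
    only outer-training subjects, so test subjects never influence feature
    selection or standardization.
    """
    Xtr = X.subset(subjects=train_idx)
    if config.n_prescreen is not None and config.n_prescreen < Xtr.n_features:
        # Mass-univariate screen on |t|: a continuous score, so chance
        # perfect separators do not tie with strong-contrast voxels the way
        # they do under a rank-test screen at small n.
        ytr = Xtr.y
        with np.errstate(invalid="ignore", divide="ignore"):
            t_scores, _ = stats.ttest_ind(
                Xtr.values[ytr == 1], Xtr.values[ytr == -1], axis=0, equal_var=True
            )
        t_scores = np.where(np.isfinite(t_scores), np.abs(t_scores), 0.0)
        pre = np.sort(np.argsort(-t_scores, kind="stable")[: config.n_prescreen])
    else:
        pre = np.arange(Xtr.n_features)
    Xp = Xtr.subset(features=pre)
    ranked = _rank(Xp, config)
    k_max = min(config.k_max, Xp.n_features)
    splits = _stratified_folds(Xp.labels, config.n_inner_folds, inner_seed)

    def evaluator(k: int) -> float:
        feats = ranked.top(k)
        correct = total = 0
        for tr, va in splits:
            model = train_linear(Xp.subset(subjects=tr, features=feats), config.C)
            preds = predict(model, Xp.subset(subjects=va, features=feats))
            truth = Xp.labels[va]
            correct += sum(p.label == t for p, t in zip(preds, truth))
            total += len(va)
        return correct / total

    k_star = sequential_forward_select(ranked, evaluator, k_max)
    sel_global = pre[ranked.top(k_star)]
    model = train_linear(X.subset(subjects=train_idx, features=sel_global), config.C)
    return sel_global, model, k_star


def _confusion(true_labels, pred_labels) -> tuple[int, int, int, int]:
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, pred_labels):
        if t == PATIENT:
            if p == PATIENT:
                tp += 1
            else:
                fn += 1
        else:
            if p == PATIENT:
                fp += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def nested_cv(
    features: dict[str, FeatureMatrix], scheme: Scheme, config: CvConfig | None = None
) -> CvReport:
    """Repeated nested stratified cross-validation of a classification scheme.

    Per repetition, subjects are split into stratified outer folds; per outer
    fold, feature ranking and the inner CV (which only picks the number of
    features) run on the outer-training subjects, the final model is trained
    on them, and the held-out fold is scored. Decision fusion trains one
    classifier per measure on identical folds and fuses labels by majority
    vote; its reported decision value is the mean of the three classifier
    decision values. Feature fusion concatenates the measures' matrices
    before selection.
    """
    config = config or CvConfig()
    for m in scheme.measures:
        if m not in features:
            raise ValueError(f"missing feature matrix for measure {m!r}")
    if scheme.kind == "feature_fusion":
        single_X = feature_fusion([features[m] for m in scheme.measures])
    elif scheme.kind == "single":
        single_X = features[scheme.measures[0]]
    else:
        single_X = None
    labels = features[scheme.measures[0]].labels

    folds: list[list[FoldResult]] = []
    for rep in range(config.n_repetitions):
        rep_seed = (config.seed * 1009 + rep) % 2**31
        rep_results: list[FoldResult] = []
        for fold_i, (train_idx, test_idx) in enumerate(
            _stratified_folds(labels, config.n_outer_folds, rep_seed)
        ):
            inner_seed = (rep_seed * 101 + fold_i) % 2**31
            true_lab = labels[test_idx]
            if scheme.kind in ("single", "feature_fusion"):
                sel, model, k_star = _fit_single_path(
                    single_X, train_idx, config, inner_seed
                )
                Xte = single_X.subset(subjects=test_idx, features=sel)
                preds = predict(model, Xte)
                pred_lab = np.array([p.label for p in preds])
                dvals = np.array([p.decision_value for p in preds])
                sel_features = tuple(single_X.provenance[int(j)] for j in sel)
                models = {scheme.describe(): model} if config.store_models else None
            else:  # decision fusion
                votes = []
                dval_parts = []
                sel_features_all = []
                k_star = 0
                models = {} if config.store_models else None
                for m in scheme.measures:
                    Xm = features[m]
                    sel, model, k_m = _fit_single_path(
                        Xm, train_idx, config, inner_seed
                    )
                    k_star += k_m
                    preds = predict(model, Xm.subset(subjects=test_idx, features=sel))
                    votes.append([p.label for p in preds])
                    dval_parts.append([p.decision_value for p in preds])
                    sel_features_all.extend(Xm.provenance[int(j)] for j in sel)
                    if models is not None:
                        models[m] = model
                pred_lab = np.array(majority_vote(list(zip(*votes))))
                dvals = np.mean(dval_parts, axis=0)
                sel_features = tuple(sel_features_all)
            tp, fp, tn, fn = _confusion(true_lab, pred_lab)
            rep_results.append(
                FoldResult(tp, fp, tn, fn, k_star, sel_features, dvals,
                           np.asarray(test_idx), true_lab, pred_lab, models)
            )
        folds.append(rep_results)
    return CvReport(scheme, config, folds)


# ---------------------------------------------------------------------------
# 5x2-CV paired t-test


@dataclass(frozen=True)
class FiveByTwoScores:
    """Accuracy differences p_i^(j) over 5 repetitions x 2 folds."""

    diffs: np.ndarray

    def __post_init__(self) -> None:
        diffs = np.asarray(self.diffs, dtype=float)
        if diffs.shape != (5, 2):
            raise ValueError("diffs must be 5x2")
        object.__setattr__(self, "diffs", diffs)

    def rep_means(self) -> np.ndarray:
        return self.diffs.mean(axis=1)

    def rep_variances(self) -> np.ndarray:
        pbar = self.rep_means()[:, None]
        return ((self.diffs - pbar) ** 2).sum(axis=1)

    def t_statistic(self) -> float:
        """t = p_1^(1) / sqrt(mean of the five repetition variances)."""
        s2 = self.rep_variances()
        denom = math.sqrt(s2.mean() / 1.0) if s2.mean() > 0 else 0.0
        p11 = float(self.diffs[0, 0])
        if denom == 0.0:
            if p11 == 0.0:
                return 0.0
            warnings.warn("zero variance with nonzero difference: t is infinite",
                          stacklevel=2)
            return math.inf if p11 > 0 else -math.inf
        return p11 / math.sqrt(s2.mean())


def five_by_two_critical_value(alpha: float = 0.05) -> float:
    """Two-sided critical t at ``alpha`` with 5 degrees of freedom (~2.57)."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, FIVE_BY_TWO_DF))


def make_scheme_evaluator(
    features: dict[str, FeatureMatrix], scheme: Scheme, config: CvConfig
):
    """Build an (train_idx, test_idx) -> accuracy evaluator for a scheme."""

    def evaluator(train_idx, test_idx) -> float:
        sub_config = replace(config, n_repetitions=1, n_outer_folds=2)
        labels = features[scheme.measures[0]].labels
        if scheme.kind == "feature_fusion":
            X = feature_fusion([features[m] for m in scheme.measures])
            schemes_X = [("fused", X)]
        elif scheme.kind == "single":
            schemes_X = [("single", features[scheme.measures[0]])]
        else:
            schemes_X = [(m, features[m]) for m in scheme.measures]
        votes = []
        for _, X in schemes_X:
            sel, model, _ = _fit_single_path(
                X, np.asarray(train_idx), sub_config, sub_config.seed
            )
            preds = predict(model, X.subset(subjects=test_idx, features=sel))
            votes.append([p.label for p in preds])
        if scheme.kind == "decision_fusion":
            pred_lab = majority_vote(list(zip(*votes)))
        else:
            pred_lab = votes[0]
        truth = labels[np.asarray(test_idx)]
        return float(np.mean([p == t for p, t in zip(pred_lab, truth)]))

    return evaluator


def five_by_two_test(
    evaluator_a, evaluator_b, labels, seed: int = 0, alpha: float = 0.05
) -> tuple[float, bool, FiveByTwoScores]:
    """5x2-CV paired t-test between two classifiers.

    Runs five repetitions of stratified 2-fold CV on shared folds; per fold,
    both evaluators return an accuracy and the difference enters the
    t-statistic t = p_1^(1) / sqrt((1/5) sum_i s_i^2), compared against the
    two-sided critical value of a t distribution with 5 df.
    """
    labels = np.asarray(labels)
    diffs = np.zeros((5, 2))
    for i in range(5):
        fold_pairs = _stratified_folds(labels, 2, (seed * 7919 + i) % 2**31)
        for j, (train_idx, test_idx) in enumerate(fold_pairs):
            acc_a = evaluator_a(train_idx, test_idx)
            acc_b = evaluator_b(train_idx, test_idx)
            diffs[i, j] = acc_a - acc_b
    scores = FiveByTwoScores(diffs)
    t = scores.t_statistic()
    reject = abs(t) > five_by_two_critical_value(alpha)
    return t, reject, scores


# ---------------------------------------------------------------------------
# discriminative mapping


def fdr_reject(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level ``q``."""
    reject, _, _, _ = multipletests(np.asarray(pvals, float), alpha=q,
                                    method="fdr_bh")
    return reject


@dataclass(frozen=True)
class ClusterPeak:
    coordinate: tuple[int, int, int]
    value: float
    cluster_size: int


@dataclass(frozen=True)
class DiscriminativeMap:
    t_map: np.ndarray
    p_map: np.ndarray
    significant: np.ndarray
    peaks: tuple[ClusterPeak, ...]
    flags: np.ndarray


def discriminative_map(
    maps: list[ActivityMap],
    labels,
    q: float = 0.05,
    min_abs_t: float | None = None,
) -> DiscriminativeMap:
    """Voxel-wise two-sample t mapping with Benjamini-Hochberg FDR control.

    Per in-mask voxel, a pooled-variance two-sample t-test (patients minus
    controls) gives a signed t and two-sided p; BH at level ``q`` over the
    in-mask p-values defines the significance mask. ``min_abs_t`` optionally
    pre-thresholds the mask on |t|. Clusters are 26-connectivity components
    of the significance mask; each contributes its max-|t| voxel as a peak.
    Voxels with zero within-group variance are assigned p = 1 and flagged.
    """
    labels = np.asarray(labels)
    if len(maps) != labels.size:
        raise ValueError("one map per subject required")
    mask = maps[0].mask
    data = np.stack([m.data for m in maps])
    pat = data[labels == PATIENT]
    con = data[labels == CONTROL]
    if pat.shape[0] < 2 or con.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant voxels trigger scipy precision warnings; they are flagged
        warnings.simplefilter("ignore", RuntimeWarning)
        t_map, p_map = stats.ttest_ind(pat, con, axis=0, equal_var=True)
    flags = ~np.isfinite(t_map) & mask.data
    t_map = np.where(np.isfinite(t_map), t_map, 0.0)
    p_map = np.where(np.isfinite(p_map), p_map, 1.0)

    sig = np.zeros(mask.data.shape, dtype=bool)
    in_mask = mask.data
    sig[in_mask] = fdr_reject(p_map[in_mask], q)
    if min_abs_t is not None:
        sig &= np.abs(t_map) > min_abs_t

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n_clusters = ndimage.label(sig, structure=structure)
    peaks = []
    for c in range(1, n_clusters + 1):
        coords = np.argwhere(labeled == c)
        vals = t_map[tuple(coords.T)]
        peak_i = int(np.argmax(np.abs(vals)))
        peaks.append(
            ClusterPeak(tuple(int(x) for x in coords[peak_i]),
                        float(vals[peak_i]), len(coords))
        )
    peaks.sort(key=lambda p: -abs(p.value))
    return DiscriminativeMap(t_map, p_map, sig, tuple(peaks), flags)


# ---------------------------------------------------------------------------
# Rician robustness protocol


def rician_robustness(
    report: CvReport,
    cohort,
    mask: BrainMask,
    sigmas,
    seed: int = 0,
    band=None,
    fwhm_mm: float = 4.0,
):
    """Re-score already-trained fold models on Rician-corrupted test volumes.

    For each noise level sigma, only the volumes of subjects while they sit
    in a test fold are corrupted; features are re-extracted from the
    corrupted volumes and the stored per-fold selection and models are
    re-applied unchanged (training folds are never touched, nothing is
    retrained). sigma = 0 leaves the volumes untouched and reproduces the
    noiseless pooled metrics exactly. Returns a pandas DataFrame with one
    row per sigma.
    """
    import pandas as pd

    from .measures import extract_subject_maps

    if any(s < 0 for s in sigmas):
        raise ValueError("sigmas must be non-negative")
    if report.all_folds()[0].models is None:
        raise ValueError("report must be produced with store_models=True")
    volumes = [v for v, _ in cohort]
    labels = np.asarray([lab for _, lab in cohort])

    rows = []
    for s_i, sigma in enumerate(sorted(sigmas)):
        # One corrupted map set per subject per sigma, shared across folds.
        map_cache: dict[int, dict[str, ActivityMap]] = {}

        def subject_maps(idx: int) -> dict[str, ActivityMap]:
            if idx not in map_cache:
                noise_seed = (seed * 100003 + 31 * idx + s_i) % 2**31
                vol = add_rician_noise(volumes[idx], sigma, noise_seed)
                map_cache[idx] = extract_subject_maps(vol, mask, band, fwhm_mm)
            return map_cache[idx]

        tp = fp = tn = fn = 0
        for fr in report.all_folds():
            votes = []
            for model in fr.models.values():
                dvals = []
                for idx in fr.test_idx:
                    maps = subject_maps(int(idx))
                    row = np.array(
                        [maps[m].data.ravel()[j] for (m, j) in model.feature_ids]
                    )
                    dvals.append(float(model.decision_values(row[None, :])[0]))
                votes.append([PATIENT if d >= 0 else CONTROL for d in dvals])
            if len(votes) == 3 and report.scheme.kind == "decision_fusion":
                pred_lab = majority_vote(list(zip(*votes)))
            else:
                pred_lab = votes[0]
            dtp, dfp, dtn, dfn = _confusion(labels[fr.test_idx], pred_lab)
            tp, fp, tn, fn = tp + dtp, fp + dfp, tn + dtn, fn + dfn
        m = compute_metrics(tp, fp, tn, fn)
        rows.append(
            {"sigma": float(sigma), "accuracy": m.accuracy,
             "sensitivity": m.sensitivity, "specificity": m.specificity,
             "tp": tp, "fp": fp, "tn": tn, "fn": fn}
        )
    return pd.DataFrame(rows)
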