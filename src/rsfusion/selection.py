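"""Feature matrices and feature-ranking methods.

Voxel-wise activity maps are vectorized into a subjects x features matrix
with per-feature provenance (measure, flat voxel index). Four rankers order
features from most to least discriminative:

* FSV — feature selection via concave minimization: a sparse linear
  separation problem whose exponential concave sparsity term is minimised by
  successive linearization, each step an LP.
* L0 — iterative rescaling of a trained linear classifier's weights, an
  approximation to zero-norm minimisation.
* Relief — nearest-hit / nearest-miss feature weighting.
* Wilcoxon — per-feature two-sided rank-sum test, ranked by p-value.

All rankers break score ties by ascending feature index, so rankings are
deterministic and permutation-equivariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .measures import ActivityMap
from .preprocess import BrainMask
from .synthetic import CONTROL, PATIENT

__all__ = [
    "FeatureMatrix",
    "RankedFeatures",
    "FsvParams",
    "maps_to_feature_matrix",
    "rank_fsv",
    "rank_l0",
    "rank_relief",
    "rank_wilcoxon",
    "sequential_forward_select",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x features values with labels and per-feature provenance.

    ``provenance`` holds one ``(measure, voxel_flat_index)`` pair per column;
    fused matrices carry the blocks of their sources in order.
    """

    values: np.ndarray
    labels: np.ndarray
    provenance: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels)
        if values.ndim != 2:
            raise ValueError("values must be 2D (subjects x features)")
        if labels.shape != (values.shape[0],):
            raise ValueError("labels length must equal subject count")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains missing/non-finite values")
        bad = set(labels) - {PATIENT, CONTROL}
        if bad:
            raise ValueError(f"unknown labels {bad}")
        if len(self.provenance) != values.shape[1]:
            raise ValueError("provenance length must equal feature count")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Numeric labels: +1 patient, -1 control."""
        return np.where(self.labels == PATIENT, 1, -1)

    def require_both_classes(self, minimum: int = 2) -> None:
        n_pat = int((self.labels == PATIENT).sum())
        n_con = int((self.labels == CONTROL).sum())
        if n_pat < minimum or n_con < minimum:
            raise ValueError(
                f"need at least {minimum} subjects per class "
                f"(got {n_pat} patients, {n_con} controls)"
            )

    def subset(self, subjects=None, features=None) -> "FeatureMatrix":
        values = self.values
        labels = self.labels
        prov = self.provenance
        if subjects is not None:
            subjects = np.asarray(subjects)
            values = values[subjects]
            labels = labels[subjects]
        if features is not None:
            features = np.asarray(features)
            values = values[:, features]
            prov = tuple(prov[int(j)] for j in features)
        return FeatureMatrix(values, labels, prov)


@dataclass(frozen=True)
class RankedFeatures:
    """Feature ordering from most to least discriminative."""

    order: np.ndarray
    scores: np.ndarray
    method: str
    converged: bool = True

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=int)
        scores = np.asarray(self.scores, dtype=float)
        if sorted(order.tolist()) != list(range(order.size)):
            raise ValueError("order must be a permutation of feature indices")
        if scores.shape != order.shape or not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite, one per feature")
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "scores", scores)

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


@dataclass(frozen=True)
class FsvParams:
    """Knobs of the concave-minimization ranker.

    ``lam`` trades separation error against sparsity; ``alpha`` sets the
    sharpness of the exponential approximation to the step function. The
    defaults are the method's canonical settings.
    """

    lam: float = 0.5
    alpha: float = 5.0
    max_iters: int = 50
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.lam < 1.0):
            raise ValueError("lam must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.max_iters < 1 or self.tol < 0:
            raise ValueError("invalid max_iters/tol")


def _order_desc(scores: np.ndarray) -> np.ndarray:
    """Descending-score order with ties broken by ascending index."""
    n = scores.size
    return np.lexsort((np.arange(n), -scores))


def _standardize_columns(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mean) / sd


def maps_to_feature_matrix(
    subject_maps: list[dict[str, ActivityMap]],
    labels,
    mask: BrainMask,
    measures: tuple[str, ...],
) -> FeatureMatrix:
    """Vectorize per-subject maps into a feature matrix.

    Features are the in-mask voxels of each requested measure, concatenated
    in fixed (measure, voxel-flat-index) order. Requesting more than one
    measure is feature-level fusion.
    """
    measures = tuple(measures)
    if not measures:
        raise ValueError("measures must be nonempty")
    labels = np.asarray(labels)
    if len(subject_maps) != labels.size:
        raise ValueError("one map dict per subject required")
    flat_idx = np.flatnonzero(mask.data.ravel())
    provenance: list[tuple[str, int]] = [
        (m, int(j)) for m in measures for j in flat_idx
    ]
    rows = []
    for i, maps in enumerate(subject_maps):
        blocks = []
        for m in measures:
            if m not in maps:
                raise ValueError(f"subject {i} is missing measure {m!r}")
            amap = maps[m]
            if amap.mask.data.shape != mask.data.shape or not np.array_equal(
                amap.mask.data, mask.data
            ):
                raise ValueError(f"subject {i} map grid/mask mismatch")
            blocks.append(amap.data.ravel()[flat_idx])
        rows.append(np.concatenate(blocks))
    return FeatureMatrix(np.vstack(rows), labels, tuple(provenance))


def rank_fsv(X: FeatureMatrix, params: FsvParams | None = None) -> RankedFeatures:
    """Feature selection via concave minimization.

    Minimises ``(1-lam) * (mean slack of each class) + lam * sum_j
    (1 - exp(-alpha v_j))`` over a linear separator w, offset gamma, slack
    vectors and the envelope v >= |w|, by successive linearization: each
    iteration replaces the concave term by its tangent at the previous v and
    solves the resulting LP. Final v_j are the scores.

    The iteration starts from the slack-minimising separator (first LP with a
    negligible cost on v) rather than from v = 0: the origin is always a
    fixed point of the linearization whenever lam * alpha exceeds the
    attainable slack reduction, so starting there would select nothing.
    """
    params = params or FsvParams()
    X.require_both_classes()
    values = _standardize_columns(X.values)
    y = X.y
    A = values[y == 1]
    B = values[y == -1]
    m_a, n = A.shape
    m_b = B.shape[0]

    # Variables: [w (n), gamma (1), y_slack (m_a), z_slack (m_b), v (n)]
    n_var = n + 1 + m_a + m_b + n
    iw = slice(0, n)
    ig = n
    iy = slice(n + 1, n + 1 + m_a)
    iz = slice(n + 1 + m_a, n + 1 + m_a + m_b)
    iv = slice(n + 1 + m_a + m_b, n_var)

    rows = m_a + m_b + 2 * n
    A_ub = np.zeros((rows, n_var))
    b_ub = np.empty(rows)
    # -A w + gamma - y <= -1
    A_ub[:m_a, iw] = -A
    A_ub[:m_a, ig] = 1.0
    A_ub[np.arange(m_a), n + 1 + np.arange(m_a)] = -1.0
    b_ub[:m_a] = -1.0
    # B w - gamma - z <= -1
    A_ub[m_a : m_a + m_b, iw] = B
    A_ub[m_a : m_a + m_b, ig] = -1.0
    A_ub[m_a + np.arange(m_b), n + 1 + m_a + np.arange(m_b)] = -1.0
    b_ub[m_a : m_a + m_b] = -1.0
    # |w| <= v
    r0 = m_a + m_b
    A_ub[r0 : r0 + n, iw] = np.eye(n)
    A_ub[r0 : r0 + n, iv] = -np.eye(n)
    b_ub[r0 : r0 + n] = 0.0
    A_ub[r0 + n :, iw] = -np.eye(n)
    A_ub[r0 + n :, iv] = -np.eye(n)
    b_ub[r0 + n :] = 0.0

    bounds = (
        [(None, None)] * n + [(None, None)] + [(0, None)] * (m_a + m_b) + [(0, None)] * n
    )

    c = np.zeros(n_var)
    c[iy] = (1.0 - params.lam) / m_a
    c[iz] = (1.0 - params.lam) / m_b

    v: np.ndarray | None = None
    converged = False
    for _ in range(params.max_iters):
        if v is None:
            c[iv] = 1e-8  # init: essentially the pure error-minimising LP
        else:
            c[iv] = params.lam * params.alpha * np.exp(-params.alpha * v)
        res = optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        if not res.success:  # pragma: no cover - slack LP is always feasible
            raise RuntimeError(f"FSV LP failed: {res.message}")
        v_new = res.x[iv].copy()
        if v is not None and np.max(np.abs(v_new - v)) <= params.tol:
            v = v_new
            converged = True
            break
        v = v_new
    if not converged:
        warnings.warn("FSV successive linearization did not converge; "
                      "returning last iterate", stacklevel=2)
    return RankedFeatures(_order_desc(v), v, "fsv", converged=converged)


def rank_l0(X: FeatureMatrix, max_rounds: int = 10, C: float = 10.0) -> RankedFeatures:
    """Zero-norm approximation by iterative feature rescaling.

    Trains a soft-margin linear classifier, multiplies each feature's scale
    by |w_j|, and repeats until the (normalised) scales stabilise or
    ``max_rounds`` is reached. Accumulated scales are the scores.
    """
    from .classify import _fit_svc

    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    X.require_both_classes()
    values = _standardize_columns(X.values)
    y = X.y
    n = values.shape[1]
    scales = np.ones(n)
    first_round_w: np.ndarray | None = None
    for _ in range(max_rounds):
        w, _ = _fit_svc(values * scales, y, C)
        if first_round_w is None:
            first_round_w = np.abs(w)
        new_scales = scales * np.abs(w)
        if new_scales.max() == 0:
            # Degenerate zero-weight classifier: fall back to first-round |w|.
            return RankedFeatures(_order_desc(first_round_w), first_round_w, "l0")
        rel = np.max(
            np.abs(new_scales / new_scales.max() - scales / scales.max())
        )
        scales = new_scales
        if rel < 1e-6:
            break
    return RankedFeatures(_order_desc(scales), scales, "l0")


def rank_relief(
    X: FeatureMatrix, n_sample: int | None = None, relief_seed: int = 0
) -> RankedFeatures:
    """Classic Relief weighting for binary classes.

    Features are min-max scaled to [0, 1]; for each sampled subject the
    nearest same-class ("hit") and other-class ("miss") subjects update each
    weight by |x_j - miss_j| - |x_j - hit_j|. Scores are mean updates.
    """
    X.require_both_classes(minimum=1)
    values = X.values
    lo = values.min(axis=0)
    rng_feat = values.max(axis=0) - lo
    scaled = np.where(rng_feat > 0, (values - lo) / np.where(rng_feat > 0, rng_feat, 1.0), 0.0)
    y = X.y
    N, n = scaled.shape
    if n_sample is None or n_sample >= N:
        sample = np.arange(N)
    else:
        rng = np.random.default_rng(relief_seed)
        sample = rng.choice(N, size=n_sample, replace=False)

    weights = np.zeros(n)
    n_used = 0
    for i in sample:
        same = np.flatnonzero((y == y[i]) & (np.arange(N) != i))
        other = np.flatnonzero(y != y[i])
        if same.size == 0:
            warnings.warn(f"subject {i} has no same-class hit; skipped", stacklevel=2)
            continue
        d_same = np.linalg.norm(scaled[same] - scaled[i], axis=1)
        d_other = np.linalg.norm(scaled[other] - scaled[i], axis=1)
        hit = scaled[same[np.argmin(d_same)]]
        miss = scaled[other[np.argmin(d_other)]]
        weights += np.abs(scaled[i] - miss) - np.abs(scaled[i] - hit)
        n_used += 1
    if n_used == 0:
        raise ValueError("no subject had both a hit and a miss")
    scores = weights / n_used
    return RankedFeatures(_order_desc(scores), scores, "relief")


def rank_wilcoxon(X: FeatureMatrix) -> RankedFeatures:
    """Per-feature two-sided Wilcoxon rank-sum test, ranked by p-value.

    Uses exact enumeration when both groups have <= 10 subjects and the
    feature is tie-free, otherwise the normal approximation with tie
    correction. Constant features get p = 1.
    """
    X.require_both_classes()
    y = X.y
    a = X.values[y == 1]
    b = X.values[y == -1]
    small = a.shape[0] <= 10 and b.shape[0] <= 10
    pvals = np.empty(X.n_features)
    for j in range(X.n_features):
        aj, bj = a[:, j], b[:, j]
        if np.ptp(np.concatenate([aj, bj])) == 0:
            pvals[j] = 1.0
            continue
        tie_free = np.unique(np.concatenate([aj, bj])).size == aj.size + bj.size
        method = "exact" if (small and tie_free) else "asymptotic"
        pvals[j] = stats.mannwhitneyu(aj, bj, alternative="two-sided",
                                      method=method).pvalue
    # Ascending p == descending (1 - p); ties by index either way.
    return RankedFeatures(_order_desc(-pvals), pvals, "wilcoxon")


def sequential_forward_select(ranked: RankedFeatures, evaluator, k_max: int) -> int:
    """Smallest feature count k in 1..k_max maximising validation accuracy.

    ``evaluator(k)`` must return the validation accuracy of a model using the
    top-k ranked features and be deterministic for fixed folds.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > ranked.order.size:
        raise ValueError("k_max exceeds feature count")
    accs = [evaluator(k) for k in range(1, k_max + 1)]
    return int(np.argmax(accs)) + 1
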