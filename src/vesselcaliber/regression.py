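"""Width regression, ground-truth matching and evaluation.

The mapping from best-fit model parameters to vessel width is learned with
ensembles of bagged regression trees with random feature selection (a
random forest): each record pairs the N model parameters of a profile with
its ground-truth diameter. Evaluation follows the reference protocol:
greedy unique matching of detected to annotated center points within 5 px,
precision as the standard deviation of the point-by-point width errors
chi_i = omega_i - psi_i, success rate as the fraction of annotated profiles
measured, and validation by 10-fold cross-validation (profile level) or
leave-one-segment-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

__all__ = [
    "TrainingRecord",
    "RegressorConfig",
    "WidthRegressor",
    "Matching",
    "MatchPair",
    "EvaluationReport",
    "SegmentCorrelationReport",
    "train_width_regressor",
    "predict_width",
    "match_centers",
    "evaluate",
    "run_kfold",
    "run_loso",
    "segment_correlations",
    "bland_altman_points",
]


@dataclass(frozen=True)
class TrainingRecord:
    """One profile's model parameters paired with its ground-truth width."""

    param_vector: np.ndarray
    width_gt: float
    segment_id: int = 0
    dataset_id: int = 0
    profile_id: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "param_vector", np.asarray(self.param_vector, dtype=float)
        )
        if self.width_gt <= 0:
            raise ValueError("width_gt must be positive")


@dataclass(frozen=True)
class RegressorConfig:
    """Hyperparameters of the bagged-tree ensemble (all overridable; the
    reference values are unpublished)."""

    n_trees: int = 100
    predictors_per_split: int | None = None  # default: max(1, round(N/3))
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class WidthRegressor:
    """Trained ensemble mapping an N-dim parameter vector to width (px)."""

    forest: RandomForestRegressor
    n_features: int

    def predict(self, param_vectors: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(param_vectors, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features}-dim parameter vectors, got {X.shape[1]}"
            )
        return self.forest.predict(X)


def train_width_regressor(
    records: list[TrainingRecord], config: RegressorConfig | None = None
) -> WidthRegressor:
    """Fit a bagged regression-tree ensemble on parameter/width records.

    Bootstrap resampling with replacement; each split draws a random subset
    of predictors. Deterministic for a fixed config seed.
    """
    config = config or RegressorConfig()
    if len(records) < 2:
        raise ValueError("need at least 2 training records")
    N = len(records[0].param_vector)
    if any(len(r.param_vector) != N for r in records):
        raise ValueError("all records must have the same parameter dimension")
    X = np.vstack([r.param_vector for r in records])
    y = np.array([r.width_gt for r in records])
    mtry = config.predictors_per_split or max(1, round(N / 3))
    if not 1 <= mtry <= N:
        raise ValueError(f"predictors_per_split must be in [1, {N}]")
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=mtry,
        min_samples_leaf=config.min_leaf,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return WidthRegressor(forest=forest, n_features=N)


def predict_width(reg: WidthRegressor, param_vector: np.ndarray) -> float:
    """Estimated width omega (px) for one best-fit parameter vector."""
    return float(reg.predict(np.asarray(param_vector, dtype=float).reshape(1, -1))[0])


@dataclass(frozen=True)
class MatchPair:
    gt_index: int
    detected_index: int
    distance: float


@dataclass(frozen=True)
class Matching:
    """Unique ground-truth/detected center-point correspondence."""

    pairs: list[MatchPair]
    unmatched_gt: list[int]


def match_centers(
    gt_centers: np.ndarray, detected_centers: np.ndarray, max_dist: float = 5.0
) -> Matching:
    """Greedy unique matching of annotated to detected center points.

    Candidate pairs closer than ``max_dist`` (strict) are accepted in
    ascending distance order; each ground-truth and each detected point is
    used at most once, so at a tie for one detected point only the closer
    ground-truth point is matched.
    """
    gt = np.atleast_2d(np.asarray(gt_centers, dtype=float))
    det = np.atleast_2d(np.asarray(detected_centers, dtype=float))
    if gt.size == 0 or det.size == 0:
        return Matching(pairs=[], unmatched_gt=list(range(len(gt) if gt.size else 0)))
    d = cdist(gt, det)
    gi, di = np.nonzero(d < max_dist)
    order = np.argsort(d[gi, di], kind="stable")
    used_gt: set[int] = set()
    used_det: set[int] = set()
    pairs: list[MatchPair] = []
    for k in order:
        g, t = int(gi[k]), int(di[k])
        if g in used_gt or t in used_det:
            continue
        used_gt.add(g)
        used_det.add(t)
        pairs.append(MatchPair(gt_index=g, detected_index=t, distance=float(d[g, t])))
    unmatched = [g for g in range(len(gt)) if g not in used_gt]
    return Matching(pairs=pairs, unmatched_gt=unmatched)


@dataclass(frozen=True)
class EvaluationReport:
    """Success rate and width / width-error statistics.

    chi_i = omega_i - psi_i (estimated minus ground truth); sigma_error
    uses the n_p - 1 denominator and is the primary precision criterion.
    """

    sr: float
    mu_meas: float
    sigma_meas: float
    mu_error: float
    sigma_error: float
    n_p: int

    def as_dict(self) -> dict:
        return {
            "sr": self.sr,
            "mu_meas": self.mu_meas,
            "sigma_meas": self.sigma_meas,
            "mu_error": self.mu_error,
            "sigma_error": self.sigma_error,
            "n_p": self.n_p,
        }


def evaluate(widths_est, widths_gt, n_gt_total: int | None = None) -> EvaluationReport:
    """Width-error statistics and success rate over matched profiles."""
    est = np.asarray(widths_est, dtype=float)
    gt = np.asarray(widths_gt, dtype=float)
    if est.shape != gt.shape:
        raise ValueError("estimated and ground-truth widths must align")
    n_p = len(est)
    if n_p < 2:
        raise ValueError("need at least 2 measurements for sigma_error")
    if n_gt_total is None:
        n_gt_total = n_p
    chi = est - gt
    return EvaluationReport(
        sr=100.0 * n_p / n_gt_total,
        mu_meas=float(est.mean()),
        sigma_meas=float(est.std(ddof=1)),
        mu_error=float(chi.mean()),
        sigma_error=float(chi.std(ddof=1)),
        n_p=n_p,
    )


def _cv_predictions(
    records: list[TrainingRecord],
    splits: list[tuple[np.ndarray, np.ndarray]],
    config: RegressorConfig,
) -> np.ndarray:
    preds = np.full(len(records), np.nan)
    for train_idx, test_idx in splits:
        reg = train_width_regressor([records[i] for i in train_idx], config)
        X = np.vstack([records[i].param_vector for i in test_idx])
        preds[test_idx] = reg.predict(X)
    assert not np.isnan(preds).any()
    return preds


def run_kfold(
    records: list[TrainingRecord],
    k: int = 10,
    seed: int = 0,
    config: RegressorConfig | None = None,
    return_predictions: bool = False,
):
    """k-fold cross-validation at profile level (random partition).

    Each record is tested exactly once by the ensemble trained on the
    other k-1 folds; the report pools all out-of-fold predictions.
    """
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    config = config or RegressorConfig(seed=seed)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(kf.split(np.arange(len(records))))
    preds = _cv_predictions(records, splits, config)
    gts = np.array([r.width_gt for r in records])
    report = evaluate(preds, gts, n_gt_total=len(records))
    if return_predictions:
        return report, preds
    return report


def run_loso(
    records: list[TrainingRecord],
    config: RegressorConfig | None = None,
    return_predictions: bool = False,
):
    """Leave-one-segment-out validation.

    One iteration per (dataset, segment): all of that segment's profiles
    are withheld from training and predicted by the ensemble trained on
    the remaining segments.
    """
    config = config or RegressorConfig()
    keys = [(r.dataset_id, r.segment_id) for r in records]
    unique_keys = sorted(set(keys))
    if len(unique_keys) < 2:
        raise ValueError("leave-one-segment-out needs >= 2 distinct segments")
    splits = []
    idx = np.arange(len(records))
    for key in unique_keys:
        test = np.array([i for i, k in enumerate(keys) if k == key])
        train = np.setdiff1d(idx, test)
        splits.append((train, test))
    preds = _cv_predictions(records, splits, config)
    gts = np.array([r.width_gt for r in records])
    report = evaluate(preds, gts, n_gt_total=len(records))
    if return_predictions:
        return report, preds
    return report


@dataclass(frozen=True)
class SegmentCorrelationReport:
    """Pairwise similarity of segment mean profiles (max-aligned,
    normalized cross-correlation)."""

    mu_corr: float
    sigma_corr: float
    max_corr: float
    n_comb: int


def _aligned_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Cross-correlation of two profiles aligned at their maxima,
    normalized by the larger of the two autocorrelations (over the
    aligned overlap)."""
    shift = int(np.argmax(a)) - int(np.argmax(b))
    lo = max(0, -shift)
    hi = min(len(b), len(a) - shift)
    bb = b[lo:hi]
    aa = a[lo + shift : hi + shift]
    cross = float(np.dot(aa, bb))
    denom = max(float(np.dot(aa, aa)), float(np.dot(bb, bb)))
    if denom == 0:
        return 0.0
    return cross / denom


def segment_correlations(
    segment_mean_profiles: list[np.ndarray],
) -> SegmentCorrelationReport:
    """Correlation between every unordered pair of segment mean profiles.

    For each pair the profiles are aligned by their maximum value; the
    cross-correlation at that alignment is divided by the maximum of the
    two autocorrelations, so identical profiles (up to an integer shift)
    score exactly 1.
    """
    profiles = [np.asarray(p, dtype=float) for p in segment_mean_profiles]
    n = len(profiles)
    if n < 2:
        raise ValueError("need at least 2 segments")
    corrs = [
        _aligned_correlation(profiles[i], profiles[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    corrs = np.array(corrs)
    return SegmentCorrelationReport(
        mu_corr=float(corrs.mean()),
        sigma_corr=float(corrs.std(ddof=1)) if len(corrs) > 1 else 0.0,
        max_corr=float(corrs.max()),
        n_comb=len(corrs),
    )


def bland_altman_points(widths_est, widths_gt) -> np.ndarray:
    """Agreement-plot points (x, y - x): ground truth on x, signed error
    on y, one point per matched profile."""
    est = np.asarray(widths_est, dtype=float)
    gt = np.asarray(widths_gt, dtype=float)
    if est.shape != gt.shape:
        raise ValueError("estimated and ground-truth widths must align")
    return np.column_stack([gt, est - gt])
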