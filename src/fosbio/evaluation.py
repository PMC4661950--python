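"""Cross-validated model assessment: R values, order selection, clipping,
and statistical comparison of R values between candidate pools.

Performance is summarized by R, the Pearson correlation between actual
and predicted outcome values on held-out subjects.  By convention R is
reported on [0, 1]: negative correlations are clamped to 0 (an
anticorrelated predictor is no better than none), and a constant
prediction scores 0.  The signed raw correlation is kept for diagnostics.

Model order (number of basis functions including the constant) is chosen
by 10-fold cross-validation over orders 1..15.  Beyond the true model
size the mean held-out R typically sits on a flat plateau whose point of
maximum is decided by fold noise, so the default rule is the one-standard-
error parsimony rule: the smallest order whose mean held-out R is within
one standard error (over folds) of the best mean.  A strict argmax (ties
to the smaller order) is available as ``order_rule="max"``.  Predictions
are clipped into the valid range of the target scale (e.g. 18-126 for
FIM-Total) before scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from .basis import LOG_EPS, expand_candidates, realize
from .features_io import BiomarkerTable, NormalizationParams, TargetSpec, fit_normalization
from .fos_core import FOSModel, RankError, _ols_coefficients, fos_fit

__all__ = ["CVResult", "compute_r", "pearson_r", "clip_to_range", "cross_validate",
           "compare_r", "compare_r_from_predictions"]


def pearson_r(actual, predicted) -> float:
    """Signed Pearson correlation; 0.0 if either vector is constant."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise ValueError(f"length mismatch: {a.size} vs {p.size}")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(a) == 0 or np.ptp(p) == 0:
        return 0.0
    return float(np.corrcoef(a, p)[0, 1])


def compute_r(actual, predicted) -> float:
    """Goodness-of-fit R in [0, 1]: Pearson r clamped below at 0."""
    return max(0.0, pearson_r(actual, predicted))


def clip_to_range(pred, spec: TargetSpec):
    """Clip predictions into the valid range of the target scale."""
    clipped = np.clip(np.asarray(pred, dtype=float), spec.valid_min, spec.valid_max)
    if np.ndim(pred) == 0:
        return float(clipped)
    return clipped


@dataclass
class CVResult:
    """Outcome of a k-fold cross-validated order sweep.

    ``per_order_r[f, m]`` is the held-out R of the (m+1)-term model on
    fold f; ``mean_r[m]`` averages over folds.  ``chosen_order`` follows
    the configured ``order_rule`` ("1se" parsimony default or strict
    "max") and ``overall_r`` is the mean held-out R at that order.
    ``pooled_predictions[:, m]`` stacks each
    subject's single held-out prediction, a diagnostic for pooled-R and
    for comparing predictors on the same subjects.
    """

    target_name: str
    per_order_r: np.ndarray          # folds x max_order
    mean_r: np.ndarray               # max_order
    chosen_order: int
    overall_r: float
    fold_assignments: np.ndarray     # subject -> fold index
    seed: int
    norm_scope: str = "global"
    order_rule: str = "1se"
    pooled_predictions: np.ndarray | None = None   # subjects x max_order
    actual: np.ndarray | None = None
    per_order_raw_r: np.ndarray | None = None      # signed, unclamped

    @property
    def max_order(self) -> int:
        return self.mean_r.size

    @property
    def pooled_r(self) -> float:
        """R of the pooled held-out predictions at the chosen order."""
        return compute_r(self.actual, self.pooled_predictions[:, self.chosen_order - 1])

    def to_dict(self) -> dict:
        return {
            "target": self.target_name,
            "seed": int(self.seed),
            "norm_scope": self.norm_scope,
            "order_rule": self.order_rule,
            "chosen_order": int(self.chosen_order),
            "overall_r": float(self.overall_r),
            "pooled_r": float(self.pooled_r),
            "mean_r_per_order": [float(v) for v in self.mean_r],
            "per_fold_r": [[float(v) for v in row] for row in self.per_order_r],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _fit_max_model(design, candidates, target, max_order):
    """FOS fit at the largest achievable order <= max_order."""
    try:
        return fos_fit(design, candidates, target, max_order)
    except RankError as err:
        if err.achievable < 1:
            raise
        return fos_fit(design, candidates, target, err.achievable)


def cross_validate(
    table: BiomarkerTable,
    columns: list[str],
    target: TargetSpec,
    max_order: int = 15,
    k: int = 10,
    seed: int = 0,
    *,
    norm_scope: str = "global",
    order_rule: str = "1se",
    include_identity: bool = True,
    log_eps: float = LOG_EPS,
) -> CVResult:
    """k-fold cross-validated order sweep for one candidate pool and target.

    Subjects are partitioned into ``k`` random folds (seeded, no
    stratification).  For each fold the model is trained on the remaining
    subjects at every order 1..``max_order`` — the greedy selection path is
    nested, so one search at the maximum order yields every prefix model,
    with coefficients refit per prefix — and held-out predictions are
    clipped into the target range and scored with :func:`compute_r`.

    ``norm_scope`` controls where min-max bounds come from: ``"global"``
    (one pass over all subjects, the default) or ``"train_fold"`` (bounds
    refit inside each training fold, avoiding test-set leakage).
    ``order_rule`` is ``"1se"`` (smallest order within one fold-standard-
    error of the best mean R; exact ties also resolve to the smaller
    order) or ``"max"`` (strict argmax, ties to the smaller order).
    """
    if norm_scope not in ("global", "train_fold"):
        raise ValueError(f"norm_scope must be 'global' or 'train_fold', got {norm_scope!r}")
    if order_rule not in ("1se", "max"):
        raise ValueError(f"order_rule must be '1se' or 'max', got {order_rule!r}")
    n = table.n_subjects
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    y = np.asarray(target.values, dtype=float)
    if y.size != n:
        raise ValueError("target values must align with table rows")
    max_order = int(max_order)
    if max_order < 1:
        raise ValueError("max_order must be >= 1")

    global_params = fit_normalization(table, columns) if norm_scope == "global" else None

    per_order_r = np.zeros((k, max_order))
    per_order_raw = np.zeros((k, max_order))
    fold_of = np.empty(n, dtype=int)
    pooled = np.empty((n, max_order))

    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.arange(n))):
        fold_of[test_idx] = fold
        train_frame = table.data.iloc[train_idx]
        test_frame = table.data.iloc[test_idx]
        params = global_params if norm_scope == "global" else fit_normalization(train_frame, columns)

        z_train = params.transform(train_frame[columns])
        candidates, design = expand_candidates(
            z_train, include_identity=include_identity, log_eps=log_eps
        )
        model = _fit_max_model(design, candidates, y[train_idx], max_order)

        # realize selected candidate columns on the test fold once
        z_test = params.transform(test_frame[columns])
        sel_idx = model.selected_indices[1:]
        test_cols = np.column_stack(
            [np.ones(len(test_idx))]
            + [realize(candidates[j], z_test[candidates[j].metric].to_numpy(), log_eps=log_eps)
               for j in sel_idx]
        )
        y_train, y_test = y[train_idx], y[test_idx]
        for m in range(1, max_order + 1):
            m_eff = min(m, model.order)
            beta = _ols_coefficients(design, sel_idx[: m_eff - 1], y_train)
            pred = clip_to_range(test_cols[:, :m_eff] @ beta, target)
            raw = pearson_r(y_test, pred)
            per_order_raw[fold, m - 1] = raw
            per_order_r[fold, m - 1] = max(0.0, raw)
            pooled[test_idx, m - 1] = pred

    mean_r = per_order_r.mean(axis=0)
    best = int(np.argmax(mean_r))  # first max -> smallest order on ties
    if order_rule == "1se" and k > 1:
        se_best = float(per_order_r[:, best].std(ddof=1)) / np.sqrt(k)
        chosen = int(np.argmax(mean_r >= mean_r[best] - se_best)) + 1
    else:
        chosen = best + 1
    return CVResult(
        target_name=target.name,
        per_order_r=per_order_r,
        mean_r=mean_r,
        chosen_order=chosen,
        overall_r=float(mean_r[chosen - 1]),
        fold_assignments=fold_of,
        seed=seed,
        norm_scope=norm_scope,
        order_rule=order_rule,
        pooled_predictions=pooled,
        actual=y,
        per_order_raw_r=per_order_raw,
    )


def compare_r(
    r1: float,
    r2: float,
    n: int,
    dependency: str,
    *,
    r12: float | None = None,
    n2: int | None = None,
    alternative: str = "two-sided",
) -> float:
    """p-value for the difference between two correlation-based R values.

    ``dependency="dependent-overlapping"`` covers two predictors of the
    same outcome evaluated on the same subjects: a Steiger-type z test on
    the Fisher-transformed correlations, using the correlation ``r12``
    between the two prediction vectors to account for their dependence.
    ``dependency="independent"`` is the two-sample Fisher z test
    (``n2`` defaults to ``n``).
    """
    for label, r in (("r1", r1), ("r2", r2)):
        if not (0.0 <= r < 1.0):
            raise ValueError(f"{label} must lie in [0, 1), got {r}")
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    if dependency == "independent":
        n2 = n if n2 is None else n2
        if n2 < 10:
            raise ValueError(f"need n2 >= 10, got {n2}")
        z = (z1 - z2) / np.sqrt(1.0 / (n - 3) + 1.0 / (n2 - 3))
    elif dependency == "dependent-overlapping":
        if r12 is None:
            raise ValueError("dependent-overlapping comparison requires r12")
        rbar = 0.5 * (r1 + r2)
        # asymptotic covariance of the two Fisher z's (Steiger 1980)
        c = (r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)) / (
            (1 - rbar**2) ** 2
        )
        z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    else:
        raise ValueError(f"unknown dependency {dependency!r}")

    if alternative == "two-sided":
        return float(2.0 * stats.norm.sf(abs(z)))
    if alternative == "greater":
        return float(stats.norm.sf(z))
    return float(stats.norm.cdf(z))


def compare_r_from_predictions(
    actual,
    pred1,
    pred2,
    *,
    alternative: str = "two-sided",
) -> dict:
    """Dependent-overlapping comparison of two prediction vectors.

    Computes r1 = r(actual, pred1), r2 = r(actual, pred2) and the
    inter-prediction correlation r12, then delegates to :func:`compare_r`.
    Returns a dict with the r's, n, p-value and the method stamp.
    """
    r1 = compute_r(actual, pred1)
    r2 = compute_r(actual, pred2)
    r12 = pearson_r(pred1, pred2)
    n = np.asarray(actual).size
    p = compare_r(r1, r2, n, "dependent-overlapping", r12=r12, alternative=alternative)
    return {"r1": r1, "r2": r2, "r12": r12, "n": int(n), "p": p,
            "method": "steiger-dependent-z", "alternative": alternative}
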