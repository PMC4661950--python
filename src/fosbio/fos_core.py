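"""Fast Orthogonal Search: greedy forward selection by largest MSE reduction.

Given a pool of N candidate basis functions (N >> M), the search builds an
M-term model S = sum_m a_m p_m(n) + e(n) term by term.  The first term is
always the constant.  At every subsequent step each remaining candidate is
implicitly orthogonalized (Gram-Schmidt) against the already selected
terms, and the candidate whose orthogonal component explains the most
residual variance — i.e. yields the largest reduction in mean squared
error — is added.  The coefficients a_m are the ordinary-least-squares
solution on the selected columns, so the training MSE after each step
equals the OLS residual MSE of the corresponding prefix model.

``greedy_forward_ols`` is a deliberately naive reference: it refits a full
OLS model for every remaining candidate at every step.  It is algebraically
equivalent to the orthogonal recursion (the orthogonalized component's
explained variance equals the drop in residual sum of squares when the
candidate joins a full refit) and serves as the verification oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import CONSTANT, CandidateBasis, LOG_EPS, realize
from .features_io import BiomarkerTable, NormalizationParams

__all__ = ["FOSModel", "RankError", "fos_fit", "greedy_forward_ols", "predict",
           "COLLINEARITY_TOL", "TIE_TOL"]

#: A candidate is skipped as collinear when its orthogonalized squared norm
#: falls below this fraction of its raw squared norm.
COLLINEARITY_TOL = 1e-10

#: Reductions within this relative tolerance of the best are ties,
#: resolved toward the lowest candidate index.
TIE_TOL = 1e-12


class RankError(ValueError):
    """Requested model order exceeds the number of independent candidates."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"order {requested} not achievable; only {achievable} linearly "
            f"independent terms available"
        )


@dataclass
class FOSModel:
    """An ordered selection of basis functions with OLS coefficients.

    ``selected[0]`` is always the constant term.  ``train_mse_path[m]`` is
    the training MSE of the OLS fit on the first m+1 selected terms; it is
    non-increasing because each added term is orthogonalized against the
    span of its predecessors.
    """

    selected: list[CandidateBasis]
    coefficients: np.ndarray
    train_mse_path: np.ndarray
    target_name: str = ""
    selected_indices: list[int] = field(default_factory=list)  # pool indices, -1 = constant

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.train_mse_path = np.asarray(self.train_mse_path, dtype=float)
        if not self.selected or self.selected[0].kind != "constant":
            raise ValueError("first selected term must be the constant")
        if len(self.coefficients) != len(self.selected):
            raise ValueError("coefficients must align with selected terms")

    @property
    def order(self) -> int:
        return len(self.selected)

    @property
    def metrics(self) -> list[str]:
        """Underlying metric of each non-constant term, in selection order."""
        return [c.metric for c in self.selected if c.kind != "constant"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "target": self.target_name,
                "terms": [
                    {"kind": c.kind, "metric": c.metric, "coefficient": float(a)}
                    for c, a in zip(self.selected, self.coefficients)
                ],
                "train_mse_path": self.train_mse_path.tolist(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FOSModel":
        obj = json.loads(text)
        selected = [
            CandidateBasis(t["kind"], t.get("metric")) for t in obj["terms"]
        ]
        coefs = [t["coefficient"] for t in obj["terms"]]
        return cls(selected, np.array(coefs), np.array(obj["train_mse_path"]),
                   target_name=obj.get("target", ""))


def _validate_inputs(design: np.ndarray, candidates, target: np.ndarray, order: int):
    design = np.asarray(design, dtype=float)
    target = np.asarray(target, dtype=float).ravel()
    if design.ndim != 2 or design.shape[0] != target.size:
        raise ValueError(
            f"design rows ({design.shape[0] if design.ndim == 2 else '?'}) "
            f"must equal target length ({target.size})"
        )
    if len(candidates) != design.shape[1]:
        raise ValueError("candidate list must align with design columns")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if order > design.shape[1] + 1:
        raise RankError(order, design.shape[1] + 1)
    if target.size < order + 1:
        raise ValueError(
            f"need at least order+1 = {order + 1} observations, got {target.size}"
        )
    return design, target


def _ols_coefficients(design, selected_idx, target):
    n = target.size
    X = np.column_stack([np.ones(n)] + [design[:, j] for j in selected_idx])
    beta, *_ = np.linalg.lstsq(X, target, rcond=None)
    return beta


def fos_fit(
    design: np.ndarray,
    candidates: list[CandidateBasis],
    target: np.ndarray,
    order: int,
    *,
    target_name: str = "",
    collinearity_tol: float = COLLINEARITY_TOL,
    tie_tol: float = TIE_TOL,
) -> FOSModel:
    """Fit an ``order``-term model by fast orthogonal search.

    Maintains deflated (orthogonalized) copies of every candidate column:
    after each selection the chosen direction is projected out of the
    remaining pool and of the residual, so scoring a candidate is a single
    dot product.  Candidates whose orthogonalized squared norm drops below
    ``collinearity_tol`` times their raw squared norm are skipped; exact
    ties in MSE reduction go to the lowest candidate index.

    Raises
    ------
    RankError
        If fewer than ``order`` linearly independent terms exist; the
        exception reports the achievable order.
    """
    design, target = _validate_inputs(design, candidates, target, order)
    n, n_cand = design.shape

    Q = design.copy()
    raw_sq = np.einsum("ij,ij->j", design, design)
    raw_sq = np.where(raw_sq > 0, raw_sq, 1.0)  # all-zero column: never selectable

    # term 1: the constant (project the mean out of everything)
    q0 = np.full(n, 1.0 / np.sqrt(n))
    residual = target - q0 * (q0 @ target)
    Q -= np.outer(q0, q0 @ Q)

    mse_path = [float(residual @ residual) / n]
    selected_idx: list[int] = []
    available = np.ones(n_cand, dtype=bool)

    for _ in range(order - 1):
        qq = np.einsum("ij,ij->j", Q, Q)
        active = available & (qq >= collinearity_tol * raw_sq)
        if not active.any():
            raise RankError(order, len(selected_idx) + 1)
        proj = Q.T @ residual
        reduction = np.where(active, proj * proj / np.where(qq > 0, qq, 1.0), -np.inf)
        best = float(reduction.max())
        tied = reduction >= best - tie_tol * max(abs(best), 1.0)
        j = int(np.flatnonzero(tied & active)[0])

        q = Q[:, j] / np.sqrt(qq[j])
        residual = residual - q * (q @ residual)
        Q -= np.outer(q, q @ Q)
        available[j] = False
        selected_idx.append(j)
        mse_path.append(float(residual @ residual) / n)

    coefs = _ols_coefficients(design, selected_idx, target)
    return FOSModel(
        selected=[CONSTANT] + [candidates[j] for j in selected_idx],
        coefficients=coefs,
        train_mse_path=np.array(mse_path),
        target_name=target_name,
        selected_indices=[-1] + selected_idx,
    )


def greedy_forward_ols(
    design: np.ndarray,
    candidates: list[CandidateBasis],
    target: np.ndarray,
    order: int,
    *,
    target_name: str = "",
    collinearity_tol: float = COLLINEARITY_TOL,
    tie_tol: float = TIE_TOL,
) -> FOSModel:
    """Brute-force forward selection oracle: full OLS refit per candidate.

    At every step, every remaining candidate is appended to the selected
    set, the model is refit from scratch with ``numpy.linalg.lstsq``, and
    the candidate with the smallest residual MSE wins.  Same collinearity
    and tie rules as :func:`fos_fit`; selection sequences and MSE paths of
    the two must agree on every instance.
    """
    design, target = _validate_inputs(design, candidates, target, order)
    n, n_cand = design.shape

    raw_sq = np.einsum("ij,ij->j", design, design)
    raw_sq = np.where(raw_sq > 0, raw_sq, 1.0)

    selected_idx: list[int] = []
    mean = target.mean()
    sse_prev = float(((target - mean) ** 2).sum())
    mse_path = [sse_prev / n]

    for _ in range(order - 1):
        base = np.column_stack([np.ones(n)] + [design[:, j] for j in selected_idx])
        # collinearity screen: orthogonal component of each candidate vs span(base)
        fitted, *_ = np.linalg.lstsq(base, design, rcond=None)
        orth = design - base @ fitted
        orth_sq = np.einsum("ij,ij->j", orth, orth)

        best_j, best_red = -1, -np.inf
        for j in range(n_cand):
            if j in selected_idx or orth_sq[j] < collinearity_tol * raw_sq[j]:
                continue
            X = np.column_stack([base, design[:, j]])
            beta, *_ = np.linalg.lstsq(X, target, rcond=None)
            sse = float(((target - X @ beta) ** 2).sum())
            red = sse_prev - sse
            if best_j < 0 or red > best_red + tie_tol * max(abs(best_red), 1.0):
                best_j, best_red = j, red
        if best_j < 0:
            raise RankError(order, len(selected_idx) + 1)
        selected_idx.append(best_j)
        sse_prev = sse_prev - max(best_red, 0.0)
        mse_path.append(sse_prev / n)

    coefs = _ols_coefficients(design, selected_idx, target)
    return FOSModel(
        selected=[CONSTANT] + [candidates[j] for j in selected_idx],
        coefficients=coefs,
        train_mse_path=np.array(mse_path),
        target_name=target_name,
        selected_indices=[-1] + selected_idx,
    )


def predict(
    model: FOSModel,
    table: BiomarkerTable | pd.DataFrame,
    params: NormalizationParams,
    *,
    log_eps: float = LOG_EPS,
) -> np.ndarray:
    """Evaluate sum_m a_m p_m per subject (unclipped).

    Metrics are normalized with the stored training bounds (out-of-range
    values clip to [0, 1]); range clipping of the prediction itself is the
    evaluation module's job.
    """
    frame = table.data if isinstance(table, BiomarkerTable) else table
    needed = [c.metric for c in model.selected if c.kind != "constant"]
    missing = [m for m in needed if m not in frame.columns]
    if missing:
        raise KeyError(f"model metrics absent from table: {missing}")

    n = len(frame)
    out = np.zeros(n)
    for cand, a in zip(model.selected, model.coefficients):
        if cand.kind == "constant":
            out += a
        else:
            z = params.normalize(cand.metric, frame[cand.metric].to_numpy(dtype=float))
            out += a * realize(cand, z, log_eps=log_eps)
    return out
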