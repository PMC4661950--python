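"""Candidate basis functions over normalized biomarkers.

The model estimates an outcome S as a sparse sum of nonlinear basis
functions of individual metrics.  For each normalized metric z in [0, 1]
the candidate pool holds six univariate transforms — identity, square,
cube, sin, cos and log — in a fixed, reproducible order.  The constant
term is not part of the pool: the search injects it as the mandatory
first model term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CandidateBasis", "CONSTANT", "TRANSFORM_ORDER", "LOG_EPS", "realize", "expand_candidates"]

#: Transform order within each metric; metrics keep their table order.
TRANSFORM_ORDER = ("identity", "square", "cube", "sin", "cos", "log")

#: log is made total on [0, 1] as ln(z + eps).
LOG_EPS = 1e-6

_KINDS = ("constant",) + TRANSFORM_ORDER


@dataclass(frozen=True)
class CandidateBasis:
    """One candidate model term: a transform of a named metric, or the constant."""

    kind: str
    metric: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "constant" and self.metric is not None:
            raise ValueError("constant basis takes no metric")
        if self.kind != "constant" and not self.metric:
            raise ValueError(f"{self.kind} basis requires a metric name")

    @property
    def label(self) -> str:
        if self.kind == "constant":
            return "const"
        if self.kind == "identity":
            return self.metric
        return f"{self.kind}({self.metric})"

    def to_dict(self) -> dict:
        return {"label": self.label, "kind": self.kind, "metric": self.metric}


CONSTANT = CandidateBasis("constant")


def realize(candidate: CandidateBasis, z, log_eps: float = LOG_EPS):
    """Evaluate a candidate on normalized values z in [0, 1].

    sin/cos take the normalized value itself as the angle in radians;
    log is the natural logarithm of (z + eps) so z = 0 stays finite.
    """
    z = np.asarray(z, dtype=float)
    kind = candidate.kind
    if kind == "constant":
        return np.ones_like(z)
    if kind == "identity":
        return z
    if kind == "square":
        return z ** 2
    if kind == "cube":
        return z ** 3
    if kind == "sin":
        return np.sin(z)
    if kind == "cos":
        return np.cos(z)
    if kind == "log":
        return np.log(z + log_eps)
    raise AssertionError(kind)


def expand_candidates(
    z_frame: pd.DataFrame,
    columns: list[str] | None = None,
    *,
    include_identity: bool = True,
    log_eps: float = LOG_EPS,
) -> tuple[list[CandidateBasis], np.ndarray]:
    """Build the candidate pool and its realized design matrix.

    Parameters
    ----------
    z_frame:
        Normalized metric values, one column per metric, entries in [0, 1].
    columns:
        Metrics to expand (default: every column), kept in frame order.
    include_identity:
        Whether the untransformed metric is itself a candidate.

    Returns
    -------
    (candidates, design):
        ``candidates`` has exactly 6 entries per metric (5 without
        identity) in a deterministic order; ``design`` is the matching
        subjects x candidates matrix, all entries finite.
    """
    if columns is None:
        columns = list(z_frame.columns)
    else:
        missing = [c for c in columns if c not in z_frame.columns]
        if missing:
            raise KeyError(f"metrics not in frame: {missing}")
        order = {c: i for i, c in enumerate(z_frame.columns)}
        columns = sorted(columns, key=order.__getitem__)

    transforms = TRANSFORM_ORDER if include_identity else TRANSFORM_ORDER[1:]
    candidates: list[CandidateBasis] = []
    cols: list[np.ndarray] = []
    for metric in columns:
        z = z_frame[metric].to_numpy(dtype=float)
        if z.size and (z.min() < -1e-12 or z.max() > 1 + 1e-12):
            raise ValueError(f"metric {metric!r} is not normalized to [0, 1]")
        for kind in transforms:
            cand = CandidateBasis(kind, metric)
            candidates.append(cand)
            cols.append(realize(cand, z, log_eps=log_eps))

    design = np.column_stack(cols) if cols else np.empty((len(z_frame), 0))
    return candidates, design
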