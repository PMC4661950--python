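"""Repeat-rate stability analysis of metric selection.

A metric's importance is summarized by how often forward selection picks
it when the model is refit on random 90 % subsets of the subjects, 100
times.  Counts are collapsed over transforms — a metric "is picked"
whichever transform (square, log, ...) carried it — and tallied per rank
position, i.e. per slot in the selection order after the constant term.
Per-transform detail is kept as a diagnostic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import LOG_EPS, expand_candidates
from .evaluation import cross_validate
from .features_io import BiomarkerTable, TargetSpec, fit_normalization
from .fos_core import fos_fit

__all__ = ["RepeatRateReport", "repeat_rates"]


@dataclass
class RepeatRateReport:
    """Selection frequencies over resampled fits.

    ``by_rank[r]`` maps metric -> number of repeats (out of ``n_repeats``)
    in which that metric filled rank position r (1-based, constant term
    excluded); per rank the counts sum to exactly ``n_repeats``.
    ``counts`` aggregates over ranks.  ``detail_counts`` keeps the
    per-(metric, transform) tallies.
    """

    target_name: str
    n_repeats: int
    subsample_fraction: float
    order: int
    counts: dict[str, int]
    by_rank: dict[int, dict[str, int]]
    seed: int
    detail_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_ranks(self) -> int:
        return self.order - 1

    def top(self, rank: int, k: int = 1) -> list[tuple[str, int]]:
        """The k most frequently selected metrics at a rank position."""
        items = sorted(self.by_rank[rank].items(), key=lambda kv: (-kv[1], kv[0]))
        return items[:k]

    def to_dataframe(self, min_count: int = 0) -> pd.DataFrame:
        """Long-format table: rank, metric, count, percent.

        ``min_count`` is a display threshold only; the report itself keeps
        every pick.
        """
        rows = []
        for rank in sorted(self.by_rank):
            for metric, count in sorted(
                self.by_rank[rank].items(), key=lambda kv: (-kv[1], kv[0])
            ):
                if count >= max(min_count, 1):
                    rows.append(
                        {
                            "rank": rank,
                            "metric": metric,
                            "count": count,
                            "percent": 100.0 * count / self.n_repeats,
                        }
                    )
        return pd.DataFrame(rows, columns=["rank", "metric", "count", "percent"])


def repeat_rates(
    table: BiomarkerTable,
    columns: list[str],
    target: TargetSpec,
    order: int,
    n_repeats: int = 100,
    fraction: float = 0.9,
    seed: int = 0,
    *,
    include_identity: bool = True,
    log_eps: float = LOG_EPS,
    reselect_order: bool = False,
    cv_kwargs: dict | None = None,
) -> RepeatRateReport:
    """Tally metric selections over repeated subsampled fits.

    Each repeat draws ``floor(fraction * n)`` subjects without replacement
    (seeded), refits normalization and the forward search on that subset at
    the given ``order``, and records which metric underlies each selected
    non-constant term at each rank.  With ``reselect_order=True`` the
    cross-validated order sweep is rerun inside every repeat instead of
    reusing a fixed order.
    """
    n = table.n_subjects
    m_sub = int(np.floor(fraction * n))
    if not m_sub > order + 1:
        raise ValueError(
            f"subset size floor({fraction} * {n}) = {m_sub} must exceed order + 1 = {order + 1}"
        )
    y = np.asarray(target.values, dtype=float)

    rng = np.random.default_rng(seed)
    rank_counts: dict[int, Counter] = {}
    totals: Counter = Counter()
    detail: Counter = Counter()

    for _ in range(n_repeats):
        idx = np.sort(rng.choice(n, size=m_sub, replace=False))
        sub_frame = table.data.iloc[idx]
        sub_y = y[idx]

        fit_order = order
        if reselect_order:
            sub_table, _ = _subset_table(table, idx)
            cv = cross_validate(
                sub_table, columns, target.with_values(sub_y),
                seed=int(rng.integers(2**31 - 1)), **(cv_kwargs or {}),
            )
            fit_order = cv.chosen_order

        params = fit_normalization(sub_frame, columns)
        z = params.transform(sub_frame[columns])
        candidates, design = expand_candidates(
            z, include_identity=include_identity, log_eps=log_eps
        )
        model = fos_fit(design, candidates, sub_y, fit_order)

        for rank, cand in enumerate(model.selected[1:], start=1):
            rank_counts.setdefault(rank, Counter())[cand.metric] += 1
            totals[cand.metric] += 1
            detail[(cand.metric, cand.kind)] += 1

    return RepeatRateReport(
        target_name=target.name,
        n_repeats=n_repeats,
        subsample_fraction=fraction,
        order=order,
        counts=dict(totals),
        by_rank={r: dict(c) for r, c in sorted(rank_counts.items())},
        seed=seed,
        detail_counts=dict(detail),
    )


def _subset_table(table: BiomarkerTable, idx: np.ndarray) -> tuple[BiomarkerTable, np.ndarray]:
    sub = BiomarkerTable(
        data=table.data.iloc[idx],
        group_map=dict(table.group_map),
        dataset_unions=dict(table.dataset_unions),
        targets=None if table.targets is None else table.targets.iloc[idx],
        target_ranges=dict(table.target_ranges),
    )
    return sub, idx
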