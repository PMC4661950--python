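"""Biomarker feature tables: loading, grouping, validation and min-max normalization.

A cohort is a subjects x metrics table.  Each metric column belongs to a
named group (e.g. the reaching-task parameters of the affected arm, the
arm-position-matching parameters, the clinical scales), and named datasets
are unions of groups (``All-Robotic`` = reaching + matching + object-hit).
Outcome columns (FIM scores) ride along in the same CSV and carry a valid
score range used for prediction clipping.

All candidate metrics are rescaled to [0, 1] by their observed minimum and
maximum, ``z(x) = (x - x_min) / (x_max - x_min)``, so that the nonlinear
basis transforms (log, sin, ...) share a common bounded domain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "ParseError",
    "DegenerateMetricError",
    "TargetSpec",
    "BiomarkerTable",
    "NormalizationParams",
    "load_table",
    "load_group_config",
    "fit_normalization",
    "normalize",
    "FIM_TOTAL_RANGE",
    "FIM_MOTOR_RANGE",
    "default_target_range",
]


class ConfigurationError(ValueError):
    """A group/dataset/target configuration does not match the data."""


class ParseError(ValueError):
    """A cell in the input CSV could not be interpreted as a number."""


class DegenerateMetricError(ValueError):
    """A metric is constant and cannot be min-max normalized."""


#: Valid score ranges of the Functional Independence Measure.
#: 18 items scored 1-7 (total), of which 13 are motor items.
FIM_TOTAL_RANGE = (18.0, 126.0)
FIM_MOTOR_RANGE = (13.0, 91.0)


def default_target_range(name: str) -> tuple[float, float]:
    """Return the valid score range implied by a FIM target name."""
    if "Motor" in name:
        return FIM_MOTOR_RANGE
    return FIM_TOTAL_RANGE


@dataclass
class TargetSpec:
    """An outcome to be predicted, with its valid score range.

    Parameters
    ----------
    name:
        Outcome label, e.g. ``"FIM-Total-2w"`` or ``"FIM-Motor-3m"``.
    valid_min, valid_max:
        Bounds of the scale; predictions outside are clipped to them.
    values:
        Observed outcome per subject (aligned with the table rows), or
        ``None`` for a bare specification.
    """

    name: str
    valid_min: float
    valid_max: float
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.valid_min < self.valid_max:
            raise ConfigurationError(
                f"target {self.name!r}: valid_min ({self.valid_min}) must be "
                f"< valid_max ({self.valid_max})"
            )
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)

    def with_values(self, values: np.ndarray) -> "TargetSpec":
        return TargetSpec(self.name, self.valid_min, self.valid_max, values)


@dataclass
class BiomarkerTable:
    """Validated subjects x metrics table with group labels and outcomes.

    ``data`` holds the metric columns only (float, finite); outcome columns
    live in ``targets``.  ``group_map`` assigns each metric to a group and
    ``dataset_unions`` names the group unions used as candidate pools.
    """

    data: pd.DataFrame
    group_map: dict[str, str]
    dataset_unions: dict[str, tuple[str, ...]] = field(default_factory=dict)
    targets: pd.DataFrame | None = None
    target_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ConfigurationError(f"duplicate metric names: {dups}")
        unmapped = [c for c in self.data.columns if c not in self.group_map]
        if unmapped:
            raise ConfigurationError(f"metric columns without a group label: {unmapped}")
        if len(self.data) < 2:
            raise ConfigurationError(
                f"need at least 2 subjects, got {len(self.data)}"
            )
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ConfigurationError("non-finite metric values after missing-data handling")

    # -- basic views ------------------------------------------------------

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def metric_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def metrics_for(self, dataset: str) -> list[str]:
        """Metric names (in table order) belonging to a named dataset.

        ``dataset`` may be a configured union name or a bare group label.
        """
        if dataset in self.dataset_unions:
            groups = set(self.dataset_unions[dataset])
        elif dataset in set(self.group_map.values()):
            groups = {dataset}
        else:
            raise ConfigurationError(
                f"unknown dataset {dataset!r}; known: "
                f"{sorted(self.dataset_unions)} or group labels "
                f"{sorted(set(self.group_map.values()))}"
            )
        return [m for m in self.data.columns if self.group_map[m] in groups]

    def target_spec(self, name: str) -> TargetSpec:
        """TargetSpec (with values) for a named outcome column."""
        if self.targets is None or name not in self.targets.columns:
            raise ConfigurationError(f"unknown target {name!r}")
        lo, hi = self.target_ranges.get(name, default_target_range(name))
        return TargetSpec(name, lo, hi, self.targets[name].to_numpy(dtype=float))

    def dropna_for(self, columns: list[str], target: str | None = None) -> tuple["BiomarkerTable", int]:
        """Listwise-delete rows missing any of ``columns`` (and ``target``).

        Returns the filtered table and the number of excluded subjects.
        Used per (target, dataset) analysis so an incomplete subject only
        drops out of analyses that actually need the missing value.
        """
        mask = self.data[columns].notna().all(axis=1)
        if target is not None:
            mask &= self.targets[target].notna()
        n_dropped = int((~mask).sum())
        if n_dropped:
            log.info("listwise deletion: excluded %d subject(s) with missing values", n_dropped)
        sub = BiomarkerTable(
            data=self.data.loc[mask].astype(float),
            group_map=dict(self.group_map),
            dataset_unions=dict(self.dataset_unions),
            targets=None if self.targets is None else self.targets.loc[mask],
            target_ranges=dict(self.target_ranges),
        )
        return sub, n_dropped


def load_group_config(source) -> dict:
    """Read a group configuration from YAML/JSON path or pass a dict through.

    Expected keys: ``groups`` (metric -> group label), optional ``datasets``
    (dataset name -> list of group labels) and optional ``targets``
    (target name -> {min, max}).
    """
    if isinstance(source, dict):
        cfg = source
    else:
        text = Path(source).read_text(encoding="utf-8")
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "groups" not in cfg:
        raise ConfigurationError("group config must be a mapping with a 'groups' key")
    return cfg


def load_table(path, group_config, columns: list[str] | None = None) -> BiomarkerTable:
    """Load a cohort CSV and its group configuration.

    The CSV has a header row of metric/target names with subject ids in the
    first column.  Every column must be mapped in the config (``groups``)
    or declared as a target.  Rows with a missing value in any selected
    metric or target column are removed listwise and the count is logged.

    Parameters
    ----------
    path:
        CSV file (UTF-8, '.' decimal).
    group_config:
        Path to a YAML/JSON config, or an equivalent dict.
    columns:
        Restrict the metric columns kept (default: all mapped columns).
    """
    cfg = load_group_config(group_config)
    groups: dict[str, str] = dict(cfg["groups"])
    datasets = {k: tuple(v) for k, v in (cfg.get("datasets") or {}).items()}
    target_cfg = cfg.get("targets") or {}

    raw = pd.read_csv(path, index_col=0)
    metric_cols, target_cols = [], []
    for col in raw.columns:
        if col in groups:
            metric_cols.append(col)
        elif col in target_cfg:
            target_cols.append(col)
        else:
            raise ConfigurationError(
                f"column {col!r} in {path} is neither mapped to a group nor a declared target"
            )

    # locate non-numeric cells precisely before coercing
    numeric = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise ParseError(
                f"non-numeric value {raw.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        numeric[col] = converted
    frame = pd.DataFrame(numeric, index=raw.index)

    if columns is not None:
        missing = [c for c in columns if c not in metric_cols]
        if missing:
            raise ConfigurationError(f"requested columns not in table: {missing}")
        metric_cols = [c for c in metric_cols if c in set(columns)]

    selected = metric_cols + target_cols
    complete = frame[selected].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info(
            "listwise deletion at load: excluded %d of %d subjects with missing values",
            n_dropped, len(frame),
        )
    frame = frame.loc[complete]

    target_ranges = {}
    for name, spec in target_cfg.items():
        if isinstance(spec, dict):
            lo, hi = float(spec["min"]), float(spec["max"])
        else:
            lo, hi = map(float, spec)
        target_ranges[name] = (lo, hi)

    return BiomarkerTable(
        data=frame[metric_cols].astype(float),
        group_map={m: groups[m] for m in metric_cols},
        dataset_unions=datasets,
        targets=frame[target_cols] if target_cols else None,
        target_ranges=target_ranges,
    )


@dataclass
class NormalizationParams:
    """Per-metric min-max bounds for the z(x) = (x - min) / (max - min) map."""

    bounds: dict[str, tuple[float, float]]

    def normalize(self, metric: str, x) -> np.ndarray | float:
        """Map values of ``metric`` into [0, 1], clipping out-of-range inputs.

        Training values land exactly on 0 at the observed minimum and 1 at
        the maximum; new data beyond the training range is clipped so the
        log/sin transform domains stay valid.
        """
        lo, hi = self.bounds[metric]
        return normalize(x, lo, hi)

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Normalize every bound column present in ``frame``."""
        out = {}
        for col in frame.columns:
            if col not in self.bounds:
                raise ConfigurationError(f"no normalization bounds for metric {col!r}")
            out[col] = self.normalize(col, frame[col].to_numpy(dtype=float))
        return pd.DataFrame(out, index=frame.index)

    def to_json(self) -> str:
        return json.dumps({m: list(b) for m, b in self.bounds.items()}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NormalizationParams":
        return cls({m: (float(lo), float(hi)) for m, (lo, hi) in json.loads(text).items()})


def normalize(x, x_min: float, x_max: float):
    """Affine [x_min, x_max] -> [0, 1] map with clipping outside the range."""
    if not x_max > x_min:
        raise DegenerateMetricError(f"degenerate bounds: x_min={x_min}, x_max={x_max}")
    z = (np.asarray(x, dtype=float) - x_min) / (x_max - x_min)
    z = np.clip(z, 0.0, 1.0)
    if np.ndim(x) == 0:
        return float(z)
    return z


def fit_normalization(table: BiomarkerTable | pd.DataFrame, columns: list[str]) -> NormalizationParams:
    """Record the observed min and max of each requested metric.

    Raises
    ------
    DegenerateMetricError
        If a column is constant (max == min), naming the column.
    """
    frame = table.data if isinstance(table, BiomarkerTable) else table
    bounds = {}
    for col in columns:
        vals = frame[col].to_numpy(dtype=float)
        lo, hi = float(np.min(vals)), float(np.max(vals))
        if not hi > lo:
            raise DegenerateMetricError(f"metric {col!r} is constant (value {lo})")
        bounds[col] = (lo, hi)
    return NormalizationParams(bounds)
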