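"""Seeded synthetic stroke cohorts with known sparse nonlinear outcome models.

The study data this package is designed for — ~85 subjects assessed with
robotic reaching / arm-position-matching / object-hit tasks plus clinical
scales, with FIM outcomes — are not publicly deposited.  This module
generates cohorts with the statistical structure the analysis assumes, so
the pipeline can be exercised and validated end to end against a known
ground truth:

* a latent per-subject severity factor drives equicorrelated Gaussian
  metric blocks, one block per task group (task parameters within a group
  are mutually correlated; groups correlate more weakly through severity);
* metrics are affinely mapped to plausible measurement ranges, and
  clinical-scale columns are binned into ordinal levels (Chedoke-like
  1-7) at standard-normal cut points, preserving monotone association
  with severity;
* the outcome is a known sparse nonlinear model of a few normalized
  metrics plus Gaussian noise, affinely rescaled to the configured
  moments (FIM-Total-2w: mean ~96, sd ~24 by default) and clipped into
  the valid FIM range.

The returned ground-truth record (terms, rescaled coefficients, noise
vector, normalization bounds) reproduces the targets exactly from the
table, which parameter-recovery tests rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import CandidateBasis, LOG_EPS, realize
from .features_io import (
    BiomarkerTable,
    ConfigurationError,
    NormalizationParams,
    TargetSpec,
    default_target_range,
    fit_normalization,
)
from .evaluation import pearson_r

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_target",
    "realized_generative_r",
    "noise_sd_for_r",
    "DEFAULT_GROUPS",
    "DEFAULT_DATASETS",
]

#: Metric counts per group, mirroring the robotic task parameter inventory
#: (13 reaching parameters per arm and interlimb, 9 matching, 14 object-hit)
#: plus small affected/unaffected clinical panels.
DEFAULT_GROUPS = {"RA": 13, "RU": 13, "RI": 13, "M": 9, "OH": 14, "CA": 4, "CU": 4}

#: Named candidate pools as unions of groups.
DEFAULT_DATASETS = {
    "Reach-Affected": ("RA",),
    "Reach-Unaffected": ("RU",),
    "Reach-Interlimb": ("RI",),
    "Match": ("M",),
    "Object-Hit": ("OH",),
    "All-Robotic": ("RA", "RU", "RI", "M", "OH"),
    "Clinical-Affected": ("CA",),
    "Clinical-Unaffected": ("CU",),
    "Clinical-All": ("CA", "CU"),
}

# plausible measurement location/scale per group (reaching times ~s,
# matching errors ~m, object-hit counts, clinical scales are binned anyway)
_GROUP_LOC_SCALE = {
    "RA": (1.0, 0.5), "RU": (0.8, 0.4), "RI": (0.1, 0.3),
    "M": (0.05, 0.03), "OH": (100.0, 30.0), "CA": (0.0, 1.0), "CU": (0.0, 1.0),
}


def noise_sd_for_r(signal_sd: float, r: float) -> float:
    """Gaussian noise s.d. giving generative correlation ``r`` for a signal
    with standard deviation ``signal_sd`` (r = sd_s / sqrt(sd_s^2 + sd_n^2))."""
    if not 0.0 < r <= 1.0:
        raise ConfigurationError(f"target generative r must be in (0, 1], got {r}")
    return float(signal_sd) * np.sqrt(1.0 / r**2 - 1.0)


@dataclass
class SyntheticCohortConfig:
    """Conditions of a generated cohort.

    ``true_model`` lists (metric, transform, coefficient) terms on the
    normalized [0, 1] metric scale; an empty list yields a pure-noise
    outcome.  ``noise_sd`` is on the pre-rescaling signal scale; leave it
    ``None`` to derive it from ``target_generative_r``.  The outcome is
    rescaled to (``target_mean``, ``target_sd``) and clipped into the
    target's valid range when ``clip`` is set.
    """

    n_subjects: int = 85
    groups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    within_group_correlation: float = 0.3
    severity_loading: float = 0.7
    true_model: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("M3", "square", -1.0),
            ("M5", "identity", 0.8),
            ("OH11", "cube", -0.6),
        ]
    )
    intercept: float = 0.0
    noise_sd: float | None = None
    target_generative_r: float = 0.8
    target_name: str = "FIM-Total-2w"
    target_mean: float = 96.3
    target_sd: float = 24.3
    clip: bool = True
    ordinal_groups: tuple[str, ...] = ("CA", "CU")
    ordinal_levels: int = 7
    heavy_tailed: bool = False
    log_eps: float = LOG_EPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not 0.0 <= self.within_group_correlation < 1.0:
            raise ConfigurationError("within_group_correlation must be in [0, 1)")
        if not 0.0 <= self.severity_loading <= 1.0:
            raise ConfigurationError("severity_loading must be in [0, 1]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        names = set(self.metric_names())
        for metric, kind, _ in self.true_model:
            if metric not in names:
                raise ConfigurationError(f"true-model metric {metric!r} not generated")
            CandidateBasis(kind, metric)  # validates the transform name

    def metric_names(self) -> list[str]:
        return [f"{g}{i + 1}" for g, count in self.groups.items() for i in range(count)]


@dataclass
class GroundTruth:
    """Exact recipe of a generated target, for recovery and round-trip tests."""

    terms: list[tuple[CandidateBasis, float]]   # rescaled coefficients
    intercept: float                            # rescaled
    noise: np.ndarray                           # rescaled noise vector
    bounds: NormalizationParams                 # normalization of the true metrics
    noiseless: np.ndarray                       # rescaled signal (pre-clip)
    generative_r: float
    log_eps: float = LOG_EPS

    @property
    def metrics(self) -> list[str]:
        return [c.metric for c, _ in self.terms]

    @property
    def order(self) -> int:
        """Model order including the constant term."""
        return len(self.terms) + 1

    def recompute_targets(self, table: BiomarkerTable, spec: TargetSpec) -> np.ndarray:
        """Rebuild the target vector exactly from the metric table."""
        out = np.full(table.n_subjects, self.intercept, dtype=float)
        for cand, coef in self.terms:
            z = self.bounds.normalize(cand.metric, table.data[cand.metric].to_numpy())
            out += coef * realize(cand, z, log_eps=self.log_eps)
        out += self.noise
        return np.clip(out, spec.valid_min, spec.valid_max)

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": [
                    {"kind": c.kind, "metric": c.metric, "coefficient": coef}
                    for c, coef in self.terms
                ],
                "intercept": self.intercept,
                "noise": self.noise.tolist(),
                "bounds": {m: list(b) for m, b in self.bounds.bounds.items()},
                "noiseless": self.noiseless.tolist(),
                "generative_r": self.generative_r,
                "log_eps": self.log_eps,
            },
            sort_keys=True,
        )


def _draw(rng: np.random.Generator, shape, heavy: bool) -> np.ndarray:
    if heavy:
        df = 4.0
        return rng.standard_t(df, size=shape) / np.sqrt(df / (df - 2.0))
    return rng.standard_normal(shape)


def _ordinal_bin(g: np.ndarray, levels: int) -> np.ndarray:
    from scipy.stats import norm

    cuts = norm.ppf(np.linspace(0, 1, levels + 1)[1:-1])
    return (np.digitize(g, cuts) + 1).astype(float)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[BiomarkerTable, TargetSpec, GroundTruth]:
    """Generate a seeded cohort, its target values, and the ground truth.

    Metric structure: for group g with factor f_g = lam * s + sqrt(1-lam^2) e_g
    (s the shared severity), each metric is sqrt(rho) f_g + sqrt(1-rho) eps,
    so any two metrics in the same group correlate at exactly rho.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    rho, lam = cfg.within_group_correlation, cfg.severity_loading

    severity = rng.standard_normal(n)
    columns: dict[str, np.ndarray] = {}
    group_map: dict[str, str] = {}
    for g, count in cfg.groups.items():
        e_g = _draw(rng, n, cfg.heavy_tailed)
        factor = lam * severity + np.sqrt(1.0 - lam**2) * e_g
        loc0, scale0 = _GROUP_LOC_SCALE.get(g, (0.0, 1.0))
        for i in range(count):
            name = f"{g}{i + 1}"
            eps = _draw(rng, n, cfg.heavy_tailed)
            latent = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps
            if g in cfg.ordinal_groups:
                columns[name] = _ordinal_bin(latent, cfg.ordinal_levels)
            else:
                loc = loc0 * (1.0 + 0.1 * i)
                scale = scale0 * (1.0 + 0.05 * i)
                columns[name] = loc + scale * latent
            group_map[name] = g

    data = pd.DataFrame(columns, index=[f"S{j + 1:03d}" for j in range(n)])
    table = BiomarkerTable(
        data=data,
        group_map=group_map,
        dataset_unions={k: v for k, v in DEFAULT_DATASETS.items()
                        if set(v) <= set(cfg.groups)},
    )
    table, spec, truth = generate_target(table, cfg, rng=rng)
    return table, spec, truth


def generate_target(
    table: BiomarkerTable,
    cfg: SyntheticCohortConfig,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[BiomarkerTable, TargetSpec, GroundTruth]:
    """Attach a synthetic target built from ``cfg.true_model`` to a table.

    Useful for adding a second outcome (e.g. FIM-Motor alongside FIM-Total)
    to an existing cohort.  Returns the augmented table, the filled
    TargetSpec and the exact GroundTruth.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = table.n_subjects
    lo, hi = default_target_range(cfg.target_name)

    terms = [(CandidateBasis(kind, metric), float(coef)) for metric, kind, coef in cfg.true_model]
    if terms:
        bounds = fit_normalization(table, sorted({c.metric for c, _ in terms}))
        signal = np.full(n, float(cfg.intercept))
        for cand, coef in terms:
            z = bounds.normalize(cand.metric, table.data[cand.metric].to_numpy())
            signal += coef * realize(cand, z, log_eps=cfg.log_eps)
    else:
        bounds = NormalizationParams({})
        signal = np.full(n, float(cfg.intercept))

    if cfg.noise_sd is not None:
        noise_sd = float(cfg.noise_sd)
    elif terms:
        noise_sd = noise_sd_for_r(float(np.std(signal)), cfg.target_generative_r)
    else:
        noise_sd = 1.0  # pure-noise outcome needs some spread
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)

    raw = signal + noise
    raw_sd = float(np.std(raw))
    a = cfg.target_sd / raw_sd if raw_sd > 0 else 1.0
    b = cfg.target_mean - a * float(np.mean(raw))

    noiseless = a * signal + b
    values = a * raw + b
    if cfg.clip:
        values = np.clip(values, lo, hi)

    truth = GroundTruth(
        terms=[(c, a * coef) for c, coef in terms],
        intercept=a * float(cfg.intercept) + b,
        noise=a * noise,
        bounds=bounds,
        noiseless=noiseless,
        generative_r=pearson_r(noiseless, values) if np.ptp(noiseless) > 0 else 0.0,
        log_eps=cfg.log_eps,
    )
    spec = TargetSpec(cfg.target_name, lo, hi, values)

    targets = pd.DataFrame(index=table.data.index) if table.targets is None else table.targets.copy()
    targets[cfg.target_name] = values
    ranges = dict(table.target_ranges)
    ranges[cfg.target_name] = (lo, hi)
    augmented = BiomarkerTable(
        data=table.data,
        group_map=dict(table.group_map),
        dataset_unions=dict(table.dataset_unions),
        targets=targets,
        target_ranges=ranges,
    )
    return augmented, spec, truth


def realized_generative_r(target, truth: GroundTruth) -> float:
    """Pearson r between the noiseless model values and the final targets.

    ``target`` may be a TargetSpec with values or a plain vector.
    """
    values = target.values if isinstance(target, TargetSpec) else np.asarray(target, dtype=float)
    if np.ptp(truth.noiseless) == 0:
        return 0.0
    return pearson_r(truth.noiseless, values)


def write_cohort(
    table: BiomarkerTable,
    out_csv,
    groups_out=None,
    truth: GroundTruth | None = None,
    truth_out=None,
) -> None:
    """Write a cohort to the standard on-disk form: CSV + group map + truth."""
    import yaml

    frame = table.data.copy()
    if table.targets is not None:
        for col in table.targets.columns:
            frame[col] = table.targets[col]
    frame.index.name = "subject"
    frame.to_csv(out_csv)

    if groups_out is not None:
        cfg = {
            "groups": dict(table.group_map),
            "datasets": {k: list(v) for k, v in table.dataset_unions.items()},
            "targets": {
                name: {"min": lo, "max": hi}
                for name, (lo, hi) in table.target_ranges.items()
            },
        }
        with open(groups_out, "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)

    if truth is not None and truth_out is not None:
        with open(truth_out, "w", encoding="utf-8") as fh:
            fh.write(truth.to_json())
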