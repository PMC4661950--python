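"""End-to-end analysis orchestration.

Runs, for each (dataset, target) pair: the cross-validated order sweep,
a final full-data fit at the chosen order, and the repeat-rate stability
analysis; then compares held-out R values between candidate pools that
predict the same target on the same subjects.  Every stochastic step is
seeded and the seeds, configuration hash and method stamps are written
into a manifest so each reported number is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .basis import expand_candidates
from .evaluation import CVResult, compare_r_from_predictions, cross_validate
from .features_io import BiomarkerTable, ConfigurationError, fit_normalization, load_table
from .fos_core import FOSModel, fos_fit
from .stability import RepeatRateReport, repeat_rates

log = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis"]


@dataclass
class AnalysisConfig:
    """Settings for a full multi-dataset, multi-target analysis run."""

    table: str | Path | BiomarkerTable
    groups: str | Path | dict | None = None
    analyses: list[tuple[str, str]] = field(default_factory=list)
    folds: int = 10
    max_order: int = 15
    seed: int = 42
    norm_scope: str = "global"
    order_rule: str = "1se"
    n_repeats: int = 100
    fraction: float = 0.9
    reselect_order: bool = False
    include_identity: bool = True
    comparisons: list[tuple[str, str, str]] | None = None  # (ds1, ds2, target)
    out_dir: str | Path | None = None
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        obj = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        analyses = [tuple(a) for a in obj.get("analyses", [])]
        comparisons = obj.get("comparisons")
        if comparisons is not None:
            comparisons = [tuple(c) for c in comparisons]
        kwargs = {k: v for k, v in obj.items() if k not in ("analyses", "comparisons")}
        return cls(analyses=analyses, comparisons=comparisons, **kwargs)

    def canonical(self) -> dict:
        out = {
            "table": str(self.table) if not isinstance(self.table, BiomarkerTable) else "<in-memory>",
            "groups": str(self.groups) if isinstance(self.groups, (str, Path)) else self.groups,
            "analyses": [list(a) for a in self.analyses],
            "folds": self.folds,
            "max_order": self.max_order,
            "seed": self.seed,
            "norm_scope": self.norm_scope,
            "order_rule": self.order_rule,
            "n_repeats": self.n_repeats,
            "fraction": self.fraction,
            "reselect_order": self.reselect_order,
            "include_identity": self.include_identity,
            "comparisons": None if self.comparisons is None else [list(c) for c in self.comparisons],
        }
        return out

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class ReportBundle:
    """In-memory results of a full run, writable as CSV/JSON tables."""

    config: AnalysisConfig
    cv_results: dict[tuple[str, str], CVResult]
    models: dict[tuple[str, str], FOSModel]
    repeat_reports: dict[tuple[str, str], RepeatRateReport]
    comparisons: list[dict]
    pooled: dict[tuple[str, str], tuple[list, np.ndarray, np.ndarray]]  # ids, pred, actual
    exclusions: dict[tuple[str, str], int]
    seeds: dict[str, int]

    def r_matrix(self) -> pd.DataFrame:
        """Held-out R per dataset (rows) and target (columns)."""
        datasets = sorted({ds for ds, _ in self.cv_results})
        targets = sorted({t for _, t in self.cv_results})
        mat = pd.DataFrame(index=datasets, columns=targets, dtype=float)
        for (ds, tgt), cv in self.cv_results.items():
            mat.loc[ds, tgt] = cv.overall_r
        return mat

    def order_matrix(self) -> pd.DataFrame:
        datasets = sorted({ds for ds, _ in self.cv_results})
        targets = sorted({t for _, t in self.cv_results})
        mat = pd.DataFrame(index=datasets, columns=targets, dtype="Int64")
        for (ds, tgt), cv in self.cv_results.items():
            mat.loc[ds, tgt] = cv.chosen_order
        return mat

    def pvalue_table(self) -> pd.DataFrame:
        """Dataset-pair p-values per target (Steiger dependent z)."""
        rows = [
            {
                "dataset_1": c["dataset_1"],
                "dataset_2": c["dataset_2"],
                "target": c["target"],
                "r1": c["r1"],
                "r2": c["r2"],
                "n": c["n"],
                "p": c["p"],
                "method": c["method"],
            }
            for c in self.comparisons
        ]
        return pd.DataFrame(rows, columns=["dataset_1", "dataset_2", "target",
                                           "r1", "r2", "n", "p", "method"])

    def manifest(self) -> dict:
        return {
            "package_version": __version__,
            "config": self.config.canonical(),
            "config_sha256": self.config.sha256(),
            "seeds": self.seeds,
            "exclusions": {f"{ds}::{tgt}": n for (ds, tgt), n in self.exclusions.items()},
            "comparison_method": "steiger-dependent-z",
        }

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        (out / "cv").mkdir(parents=True, exist_ok=True)
        (out / "models").mkdir(exist_ok=True)
        (out / "repeat_rates").mkdir(exist_ok=True)

        self.r_matrix().to_csv(out / "r_matrix.csv", float_format="%.6f")
        self.order_matrix().to_csv(out / "chosen_orders.csv")
        self.pvalue_table().to_csv(out / "pvalues.csv", index=False, float_format="%.6g")
        for (ds, tgt), cv in self.cv_results.items():
            (out / "cv" / f"{ds}__{tgt}.json").write_text(cv.to_json(), encoding="utf-8")
        for (ds, tgt), model in self.models.items():
            (out / "models" / f"{ds}__{tgt}.json").write_text(model.to_json(), encoding="utf-8")
        for (ds, tgt), rep in self.repeat_reports.items():
            rep.to_dataframe().to_csv(out / "repeat_rates" / f"{ds}__{tgt}.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest(), sort_keys=True, indent=2), encoding="utf-8"
        )
        if self.config.plots:
            self._write_plots(out)
        return out

    def _write_plots(self, out: Path) -> None:
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:  # plots are an optional extra
            log.warning("matplotlib not available; skipping over-fitting plots")
            return
        plot_dir = out / "plots"
        plot_dir.mkdir(exist_ok=True)
        for (ds, tgt), cv in self.cv_results.items():
            fig, ax = plt.subplots(figsize=(5, 3.2))
            orders = np.arange(1, cv.max_order + 1)
            ax.plot(orders, cv.mean_r, marker="o", lw=1.2)
            ax.axvline(cv.chosen_order, color="crimson", ls="--", lw=0.8,
                       label=f"chosen order = {cv.chosen_order}")
            ax.set_xlabel("model order (terms incl. constant)")
            ax.set_ylabel("mean held-out R")
            ax.set_title(f"{ds} → {tgt}")
            ax.legend(frameon=False, fontsize=8)
            fig.tight_layout()
            fig.savefig(plot_dir / f"{ds}__{tgt}.png", dpi=110)
            plt.close(fig)


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute every configured (dataset, target) analysis and comparisons.

    Raises with analysis context on any failure (unknown dataset, missing
    target, rank problems); the CLI maps that to a nonzero exit.
    """
    if isinstance(config.table, BiomarkerTable):
        table = config.table
    else:
        table = load_table(config.table, config.groups)
    if not config.analyses:
        raise ConfigurationError("no (dataset, target) analyses configured")

    cv_results: dict[tuple[str, str], CVResult] = {}
    models: dict[tuple[str, str], FOSModel] = {}
    reports: dict[tuple[str, str], RepeatRateReport] = {}
    pooled: dict[tuple[str, str], tuple[list, np.ndarray, np.ndarray]] = {}
    exclusions: dict[tuple[str, str], int] = {}
    seeds = {"cv": int(config.seed), "repeats": int(config.seed) + 1}

    for ds, tgt in config.analyses:
        t0 = time.perf_counter()
        try:
            metrics = table.metrics_for(ds)
            sub, n_dropped = table.dropna_for(metrics, target=tgt)
            spec = sub.target_spec(tgt)
            cv = cross_validate(
                sub, metrics, spec,
                max_order=config.max_order, k=config.folds, seed=config.seed,
                norm_scope=config.norm_scope, order_rule=config.order_rule,
                include_identity=config.include_identity,
            )
            params = fit_normalization(sub, metrics)
            z = params.transform(sub.data[metrics])
            candidates, design = expand_candidates(
                z, include_identity=config.include_identity
            )
            model = fos_fit(design, candidates, spec.values, cv.chosen_order,
                            target_name=tgt)
            rep = repeat_rates(
                sub, metrics, spec, order=cv.chosen_order,
                n_repeats=config.n_repeats, fraction=config.fraction,
                seed=seeds["repeats"], include_identity=config.include_identity,
                reselect_order=config.reselect_order,
            )
        except Exception as err:
            raise type(err)(f"analysis ({ds}, {tgt}): {err}") from err

        key = (ds, tgt)
        cv_results[key] = cv
        models[key] = model
        reports[key] = rep
        exclusions[key] = n_dropped
        pooled[key] = (
            sub.subject_ids,
            cv.pooled_predictions[:, cv.chosen_order - 1],
            np.asarray(spec.values),
        )
        log.info(
            "analysis (%s, %s): order=%d overall_R=%.3f [%.2fs]",
            ds, tgt, cv.chosen_order, cv.overall_r, time.perf_counter() - t0,
        )

    comparisons = _run_comparisons(config, pooled)
    return ReportBundle(
        config=config,
        cv_results=cv_results,
        models=models,
        repeat_reports=reports,
        comparisons=comparisons,
        pooled=pooled,
        exclusions=exclusions,
        seeds=seeds,
    )


def _run_comparisons(config: AnalysisConfig, pooled) -> list[dict]:
    pairs = config.comparisons
    if pairs is None:
        pairs = []
        by_target: dict[str, list[str]] = {}
        for ds, tgt in config.analyses:
            by_target.setdefault(tgt, []).append(ds)
        for tgt, datasets in by_target.items():
            for i, d1 in enumerate(datasets):
                for d2 in datasets[i + 1:]:
                    pairs.append((d1, d2, tgt))

    out = []
    for d1, d2, tgt in pairs:
        k1, k2 = (d1, tgt), (d2, tgt)
        if k1 not in pooled or k2 not in pooled:
            raise ConfigurationError(
                f"comparison ({d1}, {d2}, {tgt}) references an analysis that was not run"
            )
        ids1, pred1, act1 = pooled[k1]
        ids2, pred2, act2 = pooled[k2]
        common = [s for s in ids1 if s in set(ids2)]
        if len(common) < 10:
            raise ConfigurationError(
                f"comparison ({d1}, {d2}, {tgt}): only {len(common)} shared subjects"
            )
        pos1 = {s: i for i, s in enumerate(ids1)}
        pos2 = {s: i for i, s in enumerate(ids2)}
        i1 = [pos1[s] for s in common]
        i2 = [pos2[s] for s in common]
        res = compare_r_from_predictions(act1[i1], pred1[i1], pred2[i2])
        res.update({"dataset_1": d1, "dataset_2": d2, "target": tgt})
        out.append(res)
    return out
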