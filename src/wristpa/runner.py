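"""Orchestration of the full experiment grid and its report tables.

The grid enumerates: three type targets and three intensity targets, each as
binary tasks crossed with the four learner families and four strata (young,
middle, old, all) — 48 + 48 models; the energy-expenditure regression crossed
with learners and strata — 16 models; and the 33-class individual-activity
task with gradient boosting only, per stratum — 4 models; 116 in total. The
``all`` stratum is trained on the pooled cohort. Each cell runs one grouped
nested CV; the manifest lists every model instance with its metric summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import modeling
from .evaluation import NestedCVResults, macro_f1, nested_cv, top_features
from .exceptions import EmptyDatasetError, InputError
from .labels import (
    INTENSITY_TARGETS,
    TYPE_TARGETS,
    IntensityScheme,
    build_task_dataset,
)

logger = logging.getLogger(__name__)

STRATA = ("young", "middle", "old", "all")


@dataclass
class ExperimentGrid:
    """Enumeration of every model instance in the experiment."""

    algorithms: tuple = tuple(modeling.ALGORITHMS)
    strata: tuple = STRATA
    type_targets: tuple = TYPE_TARGETS
    intensity_targets: tuple = INTENSITY_TARGETS
    multiclass_algorithm: str = "xgboost"
    k: int = 5
    seed: int = 0
    grids: dict | None = None

    def cells(self) -> list[dict]:
        out = []
        for stratum in self.strata:
            for target in self.type_targets:
                for algo in self.algorithms:
                    out.append(
                        {"kind": "type_binary", "target": target, "algorithm": algo, "stratum": stratum}
                    )
            for target in self.intensity_targets:
                for algo in self.algorithms:
                    out.append(
                        {"kind": "intensity_binary", "target": target, "algorithm": algo, "stratum": stratum}
                    )
            for algo in self.algorithms:
                out.append(
                    {"kind": "ee_regression", "target": None, "algorithm": algo, "stratum": stratum}
                )
            out.append(
                {
                    "kind": "individual_multiclass",
                    "target": None,
                    "algorithm": self.multiclass_algorithm,
                    "stratum": stratum,
                }
            )
        return out


@dataclass
class ExperimentBundle:
    """All nested-CV results of one grid run plus the model manifest."""

    results: dict[tuple, NestedCVResults]
    manifest: pd.DataFrame
    grid: ExperimentGrid


def _cell_key(cell: dict) -> tuple:
    return (cell["kind"], cell["target"], cell["algorithm"], cell["stratum"])


def run_experiment_grid(
    grid: ExperimentGrid,
    windows: pd.DataFrame,
    roster: pd.DataFrame,
    mapping: dict | None = None,
    scheme: IntensityScheme | None = None,
) -> ExperimentBundle:
    """Run one grouped nested CV per grid cell.

    Cells whose stratum yields no windows are recorded as skipped with a
    warning rather than failing the run.
    """
    results: dict[tuple, NestedCVResults] = {}
    rows = []
    cells = grid.cells()
    seeds = np.random.SeedSequence(grid.seed).generate_state(len(cells)) % (2**31)
    for cell, cell_seed in zip(cells, seeds):
        key = _cell_key(cell)
        row = {
            "task": cell["kind"],
            "target": cell["target"],
            "algorithm": cell["algorithm"],
            "stratum": cell["stratum"],
            "seed": int(cell_seed),
            "status": "ok",
        }
        try:
            dataset = build_task_dataset(
                windows,
                roster,
                cell["kind"],
                target_name=cell["target"],
                age_stratum=cell["stratum"],
                mapping=mapping,
                scheme=scheme,
            )
            res = nested_cv(
                dataset,
                cell["algorithm"],
                grids=grid.grids,
                k=grid.k,
                seed=int(cell_seed),
            )
        except (EmptyDatasetError, InputError) as err:
            # empty stratum, or one with fewer participants than folds
            logger.warning("skipped cell %s: %s", key, err)
            row["status"] = "skipped"
            row["reason"] = str(err)
            rows.append(row)
            continue
        results[key] = res
        summ = res.summary()
        row["n_windows"] = res.n_windows
        row["n_participants"] = res.n_participants
        for metric in summ.index:
            row[f"{metric}_mean"] = summ.loc[metric, "mean"]
            row[f"{metric}_sd"] = summ.loc[metric, "sd"]
        rows.append(row)
        logger.info("cell %s done (%d windows)", key, res.n_windows)
    manifest = pd.DataFrame(rows)
    return ExperimentBundle(results=results, manifest=manifest, grid=grid)


def _mean_sd_cell(res: NestedCVResults, metric: str) -> str:
    vals = res.metric_values(metric)
    if not vals:
        return ""
    mean = np.mean(vals)
    sd = np.std(vals, ddof=1) if len(vals) > 1 else float("nan")
    return f"{mean:.3f} ({sd:.3f})"


def report_tables(bundle: ExperimentBundle) -> dict[str, pd.DataFrame]:
    """Assemble the report tables of one grid run.

    Per-type and per-intensity F1 mean(sd) tables by stratum and algorithm,
    the RMSE table, the per-activity F1 table with a macro-average row, the
    top-15 feature tables and the pooled confusion matrices.
    """
    grid = bundle.grid
    tables: dict[str, pd.DataFrame] = {}

    for kind, targets, name in (
        ("type_binary", grid.type_targets, "type_f1"),
        ("intensity_binary", grid.intensity_targets, "intensity_f1"),
    ):
        rows = []
        for target in targets:
            for algo in grid.algorithms:
                row = {"target": target, "algorithm": algo}
                for stratum in grid.strata:
                    res = bundle.results.get((kind, target, algo, stratum))
                    row[stratum] = _mean_sd_cell(res, "f1") if res else ""
                rows.append(row)
        tables[name] = pd.DataFrame(rows).set_index(["target", "algorithm"])

    rows = []
    for algo in grid.algorithms:
        row = {"algorithm": algo}
        for stratum in grid.strata:
            res = bundle.results.get(("ee_regression", None, algo, stratum))
            row[stratum] = _mean_sd_cell(res, "rmse") if res else ""
        rows.append(row)
    tables["ee_rmse"] = pd.DataFrame(rows).set_index("algorithm")

    # individual activities: per-class F1 mean (sd) over folds, plus macro row
    indiv_rows: dict[str, dict] = {}
    macro_row = {}
    for stratum in grid.strata:
        res = bundle.results.get(
            ("individual_multiclass", None, grid.multiclass_algorithm, stratum)
        )
        if res is None:
            continue
        per_class: dict[str, list[float]] = {}
        for fold in res.folds:
            for cls, v in (fold.per_class_f1 or {}).items():
                per_class.setdefault(cls, []).append(v)
        class_means = {}
        for cls, vals in per_class.items():
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
            indiv_rows.setdefault(cls, {})[stratum] = f"{mean:.3f} ({sd:.3f})"
            class_means[cls] = mean
        macro_row[stratum] = f"{macro_f1(class_means.values()):.3f}"
    if indiv_rows:
        table = pd.DataFrame(indiv_rows).T.sort_index()
        table.loc["Macro average (F1 score)"] = pd.Series(macro_row)
        tables["individual_f1"] = table

    for key, res in bundle.results.items():
        if res.confusion is not None:
            tables[f"confusion__{key[0]}__{key[1]}__{key[2]}__{key[3]}"] = res.confusion
        tables[f"top15__{key[0]}__{key[1]}__{key[2]}__{key[3]}"] = top_features(res, 15).to_frame(
            "importance"
        )
    return tables


def write_report(bundle: ExperimentBundle, out_dir) -> None:
    """Write the manifest and every report table as CSV under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.manifest.to_csv(out / "manifest.csv", index=False)
    for name, table in report_tables(bundle).items():
        safe = name.replace(" ", "_")
        table.to_csv(out / f"{safe}.csv")
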