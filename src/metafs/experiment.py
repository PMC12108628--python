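"""Orchestration of the full comparison protocol.

A grid of (metaheuristic x classifier x objective) configurations is run
for a fixed number of seeded repetitions each, producing a long-format
fitness/metric table that feeds :mod:`metafs.stats_compare`, per-
configuration best/average/std aggregates, and boxplot reports.
Configuration labels follow the "<CLF>_<MH>" convention (e.g. "XGB_PSO").

Seeds enumerate deterministically as ``base_seed + run_index`` over the
grid, so any single cell can be reproduced in isolation from its manifest;
cells already on disk are skipped on re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metaheuristics import Algorithm, MetaheuristicConfig, SearchResult, run_search
from .metrics import METRIC_NAMES
from .objective import ClassifierId, ObjectiveConfig, ObjectiveId, SubsetObjective

CLF_LABEL = {
    ClassifierId.KNN: "KNN",
    ClassifierId.RANDOM_FOREST: "RF",
    ClassifierId.XGBOOST: "XGB",
}
MH_LABEL = {
    Algorithm.PSO: "PSO",
    Algorithm.GWO: "GWO",
    Algorithm.PSA: "PSA",
    Algorithm.WOA: "WOA",
}


@dataclass(frozen=True)
class ExperimentGrid:
    metaheuristics: tuple[Algorithm, ...] = tuple(Algorithm)
    classifiers: tuple[ClassifierId, ...] = tuple(ClassifierId)
    objectives: tuple[ObjectiveId, ...] = tuple(ObjectiveId)
    repetitions: int = 31
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be positive")
        if not (self.metaheuristics and self.classifiers and self.objectives):
            raise ValueError("grid must be nonempty")

    def cells(self):
        """Deterministic enumeration; seed = base_seed + running index."""
        idx = 0
        for obj in self.objectives:
            for clf in self.classifiers:
                for mh in self.metaheuristics:
                    for rep in range(self.repetitions):
                        yield obj, clf, mh, rep, self.base_seed + idx
                        idx += 1

    @property
    def n_configurations(self) -> int:
        return (len(self.metaheuristics) * len(self.classifiers)
                * len(self.objectives))


def config_label(clf: ClassifierId, mh: Algorithm) -> str:
    return f"{CLF_LABEL[ClassifierId(clf)]}_{MH_LABEL[Algorithm(mh)]}"


@dataclass
class RunResult:
    label: str
    objective_id: str
    repetition: int
    seed: int
    fitness: float
    tfs: int
    metrics: dict
    mask: np.ndarray
    trace: list[float]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "objective_id": self.objective_id,
            "repetition": self.repetition,
            "seed": self.seed,
            "fitness": self.fitness,
            "tfs": self.tfs,
            "metrics": self.metrics,
            "mask": "".join(str(int(b)) for b in self.mask),
            "trace": list(self.trace),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunResult":
        d = dict(d)
        d["mask"] = np.array([int(c) for c in d["mask"]], dtype=np.int8)
        return cls(**d)


def _manifest_hash(obj_cfg: ObjectiveConfig, mh_cfg: MetaheuristicConfig,
                   n_samples: int, n_features: int) -> str:
    payload = json.dumps({
        "objective": dataclasses.asdict(obj_cfg),
        "metaheuristic": dataclasses.asdict(mh_cfg),
        "shape": [n_samples, n_features],
    }, default=str, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_cell(X, y, obj: ObjectiveId, clf: ClassifierId, mh: Algorithm,
             seed: int, objective_defaults: ObjectiveConfig,
             mh_defaults: MetaheuristicConfig) -> SearchResult:
    obj_cfg = dataclasses.replace(objective_defaults, objective_id=obj,
                                  classifier_id=clf, seed=seed)
    mh_cfg = dataclasses.replace(mh_defaults, algorithm=mh, seed=seed)
    objective = SubsetObjective(X, y, obj_cfg)
    return run_search(objective, objective.n_features, mh_cfg)


def run_grid(
    grid: ExperimentGrid,
    X,
    y,
    objective_defaults: ObjectiveConfig | None = None,
    mh_defaults: MetaheuristicConfig | None = None,
    out_dir: str | Path | None = None,
    progress=None,
) -> list[RunResult]:
    """Execute every grid cell; resumable via per-cell JSON files.

    Failed cells are recorded (as ``<cell>.failed.json``) and skipped; the
    caller can inspect :func:`failed_cells` afterwards.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    objective_defaults = objective_defaults or ObjectiveConfig()
    mh_defaults = mh_defaults or MetaheuristicConfig()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    results: list[RunResult] = []
    for obj, clf, mh, rep, seed in grid.cells():
        label = config_label(clf, mh)
        cell_file = None
        if out_path is not None:
            obj_cfg = dataclasses.replace(objective_defaults, objective_id=obj,
                                          classifier_id=clf, seed=seed)
            mh_cfg = dataclasses.replace(mh_defaults, algorithm=mh, seed=seed)
            h = _manifest_hash(obj_cfg, mh_cfg, *X.shape)
            cell_file = out_path / f"{label}_{obj.value}_rep{rep}_{h}.json"
            if cell_file.exists():
                results.append(RunResult.from_dict(
                    json.loads(cell_file.read_text())))
                continue
        try:
            sr = run_cell(X, y, obj, clf, mh, seed,
                          objective_defaults, mh_defaults)
        except Exception as exc:  # noqa: BLE001 - cell failures are recorded
            if cell_file is not None:
                cell_file.with_suffix(".failed.json").write_text(json.dumps(
                    {"label": label, "objective": obj.value,
                     "repetition": rep, "seed": seed, "error": str(exc)}))
            continue
        rec = sr.best_record
        rr = RunResult(
            label=label, objective_id=obj.value, repetition=rep, seed=seed,
            fitness=sr.best_fitness, tfs=rec.tfs,
            metrics=rec.metrics or {}, mask=sr.best_mask, trace=sr.trace)
        if cell_file is not None:
            cell_file.write_text(json.dumps(rr.to_dict()))
        results.append(rr)
        if progress is not None:
            progress(rr)
    return results


def failed_cells(out_dir: str | Path) -> list[dict]:
    return [json.loads(p.read_text())
            for p in sorted(Path(out_dir).glob("*.failed.json"))]


def results_to_frame(results: list[RunResult]) -> pd.DataFrame:
    """Long-format table (run, configuration, objective, fitness, metrics, TFS)."""
    if not results:
        raise ValueError("no results to tabulate")
    rows = []
    for r in results:
        rows.append({"run": r.repetition, "configuration": r.label,
                     "objective": r.objective_id, "seed": r.seed,
                     "fitness": r.fitness, "TFS": r.tfs,
                     **{k: r.metrics.get(k, np.nan) for k in METRIC_NAMES}})
    return pd.DataFrame(rows)


REPORTED_COLUMNS = ("fitness", *METRIC_NAMES, "TFS")


def aggregate_results(results: list[RunResult]) -> pd.DataFrame:
    """Best / average / sample-std per configuration and metric.

    'Best' is the minimum for fitness and TFS (both minimized) and the
    maximum for the classification metrics.  Cells with a single run
    report std 0 and are flagged.
    """
    frame = results_to_frame(results)
    rows = []
    for (label, obj), g in frame.groupby(["configuration", "objective"]):
        row = {"configuration": label, "objective": obj, "runs": len(g)}
        for col in REPORTED_COLUMNS:
            vals = g[col].to_numpy(dtype=float)
            best = vals.min() if col in ("fitness", "TFS") else vals.max()
            row[f"{col}_best"] = best
            row[f"{col}_avg"] = vals.mean()
            row[f"{col}_std"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        row["single_run"] = len(g) == 1
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["objective", "configuration"]).reset_index(drop=True)


def export_report(results: list[RunResult], out_dir: str | Path) -> list[Path]:
    """Write aggregate CSVs and one boxplot per reported metric.

    Boxplots group metaheuristic-classifier pairs on the x-axis, split by
    objective.  Returns the written file paths; byte-stable for fixed
    inputs.
    """
    if not results:
        raise ValueError("refusing to report on empty results")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    frame = results_to_frame(results).sort_values(
        ["objective", "configuration", "run"]).reset_index(drop=True)
    f = out_path / "results_long.csv"
    frame.to_csv(f, index=False)
    written.append(f)
    f = out_path / "aggregates.csv"
    aggregate_results(results).to_csv(f, index=False)
    written.append(f)

    for col in REPORTED_COLUMNS:
        fig, ax = plt.subplots(figsize=(10, 4))
        sns.boxplot(data=frame, x="configuration", y=col, hue="objective",
                    ax=ax)
        ax.set_xlabel("classifier-metaheuristic pair")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        f = out_path / f"boxplot_{col}.png"
        fig.savefig(f, dpi=100)
        plt.close(fig)
        written.append(f)
    return written
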