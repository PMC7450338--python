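"""File I/O and experiment orchestration: dataset loading, the seeded
multi-run protocol, and the comparison reports."""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .binary import FeatureSelectionProblem, FitnessWeights, run_feature_selection
from .core import ConfigurationError
from .evaluation import aggregate_metrics, rank_algorithms, wilcoxon_rank_sum
from .hybrid import HybridConfig

logger = logging.getLogger("cswolf")

LABEL_COLUMN = "label"


class DataError(ValueError):
    """Raised for malformed input datasets."""


def load_dataset(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a feature-selection dataset from CSV.

    Expected layout: a header row, numeric feature columns, and a trailing
    ``label`` column with exactly two values.  Labels other than {0, 1} are
    remapped (sorted order -> 0, 1) with a warning.
    """
    df = pd.read_csv(path)
    if LABEL_COLUMN not in df.columns:
        raise DataError(f"dataset {path} lacks the required '{LABEL_COLUMN}' column")
    features = df.drop(columns=[LABEL_COLUMN])
    try:
        X = features.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric feature cells in {path}: {exc}") from exc
    if not np.isfinite(X).all():
        raise DataError(f"dataset {path} contains missing or non-finite feature values")
    raw = df[LABEL_COLUMN].to_numpy()
    classes = np.unique(raw)
    if classes.size != 2:
        raise DataError(f"dataset {path} must have exactly two classes; found {classes.tolist()}")
    if set(classes.tolist()) != {0, 1}:
        warnings.warn(
            f"labels {classes.tolist()} remapped to {{0, 1}}", UserWarning, stacklevel=2
        )
    y = (raw == classes[1]).astype(int)
    logger.info(
        "loaded %s: %d samples x %d features, class balance %.2f",
        path, X.shape[0], X.shape[1], y.mean(),
    )
    return X, y


def write_dataset(path, X: np.ndarray, y: np.ndarray) -> None:
    """Write a dataset in the CSV dialect ``load_dataset`` reads."""
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    df[LABEL_COLUMN] = y
    df.to_csv(path, index=False)


@dataclass
class ExperimentConfig:
    """Multi-run feature-selection experiment configuration.

    Defaults follow the reference protocol: population 30, budget 10000
    evaluations, 10 runs, step_max = a_o = 1, p_a = 0.25.
    """

    data: Optional[str] = None
    n_runs: int = 10
    base_seed: int = 0
    n_agents: int = 30
    fe_budget: int = 10000
    k_folds: int = 10
    alpha_w: float = 0.2
    beta_w: float = 0.8
    convention: str = "as_printed"
    out_dir: str = "results"
    estimator: object = field(default=None, repr=False)

    def run_seed(self, run: int) -> int:
        return self.base_seed + run


def run_experiment(config: ExperimentConfig, X=None, y=None) -> dict:
    """Execute the seeded multi-run protocol and write report files.

    Writes into ``config.out_dir``: ``runs.csv`` (one row per run with seed,
    accuracy, subset size, fitness and the selected 0-based feature indices,
    semicolon-separated), ``aggregate.csv`` (one row per aggregate metric),
    per-run convergence logs, and the effective configuration.  Returns the
    per-run and aggregate results in memory.
    """
    if X is None or y is None:
        if config.data is None:
            raise ConfigurationError("either a dataset path or in-memory X, y is required")
        X, y = load_dataset(config.data)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for run in range(config.n_runs):
        seed = config.run_seed(run)
        problem = FeatureSelectionProblem(
            X,
            y,
            estimator=config.estimator,
            k=config.k_folds,
            cv_seed=seed,
            weights=FitnessWeights(config.alpha_w, config.beta_w),
            convention=config.convention,
        )
        hconfig = HybridConfig(n=config.n_agents, fe_budget=config.fe_budget, seed=seed)
        result, report = run_feature_selection(problem, hconfig)
        (out / f"run_{run}_convergence.tsv").write_text(result.log_text())
        rows.append(
            {
                "run": run,
                "seed": seed,
                "avg_cross_acc": report.cv_accuracy,
                "n_selected": report.n_selected,
                "fitness": report.fitness,
                "selected_features": ";".join(map(str, report.selected.tolist())),
            }
        )
        logger.info(
            "run %d (seed %d): acc=%.4f |R|=%d fit=%.4f",
            run, seed, report.cv_accuracy, report.n_selected, report.fitness,
        )

    runs_df = pd.DataFrame(rows)
    runs_df.to_csv(out / "runs.csv", index=False, float_format="%.10g")
    metrics = aggregate_metrics(runs_df["avg_cross_acc"], runs_df["n_selected"])
    agg_df = pd.DataFrame(
        {
            "metric": ["avg_acc", "min_acc", "max_acc", "avg_nfeat", "min_nfeat", "max_nfeat"],
            "value": [
                metrics.avg_acc,
                metrics.min_acc,
                metrics.max_acc,
                metrics.avg_nfeat,
                metrics.min_nfeat,
                metrics.max_nfeat,
            ],
        }
    )
    agg_df.to_csv(out / "aggregate.csv", index=False, float_format="%.10g")
    effective = {k: v for k, v in asdict(config).items() if k != "estimator"}
    (out / "config.yaml").write_text(yaml.safe_dump(effective, sort_keys=True))
    return {"runs": runs_df, "aggregate": metrics}


MEASURES = ["max_acc", "min_acc", "avg_acc", "max_nfeat", "min_nfeat", "avg_nfeat"]
DIRECTIONS = ["higher", "higher", "higher", "lower", "lower", "lower"]


def compare_results(result_dirs: Sequence[str], names: Optional[Sequence[str]] = None,
                    out_dir: str = "comparison") -> dict:
    """Compare >= 2 experiment result directories.

    Reads each directory's ``runs.csv``, performs pairwise Wilcoxon rank-sum
    tests of per-run accuracy against the first (reference) algorithm, and
    builds the six-measure competition-ranking table.  Writes
    ``wilcoxon.csv`` and ``ranking.csv`` into ``out_dir``.
    """
    if len(result_dirs) < 2:
        raise ConfigurationError("compare mode needs at least two result directories")
    if names is None:
        names = [Path(d).name for d in result_dirs]
    runs = [pd.read_csv(Path(d) / "runs.csv") for d in result_dirs]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    wil_rows = []
    ref_acc = runs[0]["avg_cross_acc"].to_numpy()
    for name, df in zip(names[1:], runs[1:]):
        p, h, z = wilcoxon_rank_sum(df["avg_cross_acc"].to_numpy(), ref_acc)
        wil_rows.append({"pair": f"{name} vs {names[0]}", "p": p, "h": h, "z": z})
    wil_df = pd.DataFrame(wil_rows)
    wil_df.to_csv(out / "wilcoxon.csv", index=False, float_format="%.10g")

    table = np.empty((len(runs), len(MEASURES), 1))
    for i, df in enumerate(runs):
        m = aggregate_metrics(df["avg_cross_acc"], df["n_selected"])
        table[i, :, 0] = [m.max_acc, m.min_acc, m.avg_acc, m.max_nfeat, m.min_nfeat, m.avg_nfeat]
    ranking = rank_algorithms(table, DIRECTIONS)
    rank_rows = []
    for i, name in enumerate(names):
        row = {"algorithm": name}
        for j, meas in enumerate(MEASURES):
            row[f"rank_{meas}"] = ranking.rank_sums[i, j]
        row["total"] = ranking.total_sums[i]
        row["final_rank"] = ranking.final_ranks[i]
        rank_rows.append(row)
    rank_df = pd.DataFrame(rank_rows)
    rank_df.to_csv(out / "ranking.csv", index=False)
    return {"wilcoxon": wil_df, "ranking": rank_df}
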