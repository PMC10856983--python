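"""Hyperparameter grid enumeration, execution and tiered ranking.

The full grid spans six axes — wavelet family (5), sampling-frequency mode
(2), samples per window (12), overlap (4), learning rate (3), optimizer
(2) — 2,880 configurations over 28 distinct axis values.  Enumeration
iterates the axes in that order with the rightmost axis fastest, so a
budget-truncated or resumed run is reproducible.

Each configuration is evaluated by preprocessing the dataset, running
stratified k-fold cross-validation of the full training protocol, and
recording the mean metrics, the pooled mean squared error between one-hot
labels and predicted probabilities (the "L2" tiebreak), wall-clock timings
and the model's parameter count.  Ranking is tiered: mean of the four
metrics (desc), then L2 (asc), then parameter count (asc).
"""

from __future__ import annotations

import itertools
import time
import traceback
from dataclasses import dataclass, field, replace

import pandas as pd

from .model import PINConfig, count_parameters
from .preprocess import DEFAULT_N_SCALES, plan_windows, preprocess_dataset
from .signal_io import EEGRecord
from .training import TrainSpec
from .evaluation import cross_validate

FS_BONN = 173.61


@dataclass(frozen=True)
class HyperGrid:
    wavelets: tuple = ("gmw", "morlet", "bump", "cmhat", "hhhat")
    fs_options: tuple = (None, FS_BONN)
    window_sizes: tuple = (174, 347, 521, 694, 868, 1042, 1215, 1389, 1562, 1736, 1910, 2083)
    overlaps: tuple = (0.0, 0.25, 0.33, 0.50)
    learning_rates: tuple = (0.01, 0.001, 0.0001)
    optimizers: tuple = ("adam", "sgd")

    def axes(self) -> list[tuple]:
        return [
            self.wavelets,
            self.fs_options,
            self.window_sizes,
            self.overlaps,
            self.learning_rates,
            self.optimizers,
        ]

    def __post_init__(self) -> None:
        if any(len(ax) == 0 for ax in self.axes()):
            raise ValueError("every grid axis must be non-empty")


@dataclass(frozen=True)
class GridPoint:
    wavelet: str
    fs: float | None
    window_len: int
    overlap: float
    learning_rate: float
    optimizer: str


@dataclass
class SearchResult:
    config: GridPoint
    metrics: dict | None
    l2: float | None
    scalogram_time_s: float
    train_time_s: float
    n_parameters: int | None
    failed: bool = False
    error: str = ""


def enumerate_grid(grid: HyperGrid) -> list[GridPoint]:
    """Full Cartesian product; rightmost axis varies fastest."""
    return [GridPoint(*combo) for combo in itertools.product(*grid.axes())]


def count_grid_values(grid: HyperGrid) -> int:
    """Total number of distinct axis values (28 for the full grid)."""
    return sum(len(ax) for ax in grid.axes())


def run_search(
    records: list[EEGRecord],
    grid: HyperGrid,
    spec: TrainSpec,
    budget: int | None = None,
    n_scales: int = DEFAULT_N_SCALES,
    k: int = 10,
    on_result=None,
) -> list[SearchResult]:
    """Evaluate grid points in enumeration order, up to `budget` configs.

    A failing configuration is recorded as failed, never fatal.  The
    optional `on_result` callback receives each SearchResult as it is
    produced, enabling streaming/resumable output.
    """
    points = enumerate_grid(grid)
    if budget is not None:
        points = points[:budget]
    results: list[SearchResult] = []
    for point in points:
        results.append(
            _run_one(records, point, spec, n_scales=n_scales, k=k)
        )
        if on_result is not None:
            on_result(results[-1])
    return results


def _run_one(records, point: GridPoint, spec, n_scales, k) -> SearchResult:
    try:
        t0 = time.perf_counter()
        stacks = preprocess_dataset(
            records,
            window_len=point.window_len,
            overlap=point.overlap,
            wavelet=point.wavelet,
            n_scales=n_scales,
        )
        t_scal = time.perf_counter() - t0
        plan = plan_windows(len(records[0]), point.window_len, point.overlap)
        config = PINConfig(
            n_blocks=plan.n_windows,
            input_scales=n_scales,
            input_width=point.window_len,
        )
        fold_spec = replace(
            spec, optimizer=point.optimizer, learning_rate=point.learning_rate
        )
        cv = cross_validate(stacks, config, fold_spec, k=k)
        return SearchResult(
            config=point,
            metrics=cv.mean.as_dict(),
            l2=cv.l2,
            scalogram_time_s=t_scal,
            train_time_s=cv.train_time_s,
            n_parameters=count_parameters(config),
        )
    except Exception as exc:  # single-config failure is logged, not fatal
        return SearchResult(
            config=point,
            metrics=None,
            l2=None,
            scalogram_time_s=0.0,
            train_time_s=0.0,
            n_parameters=None,
            failed=True,
            error=f"{type(exc).__name__}: {exc}",
        )


def select_best(results: list[SearchResult]) -> list[SearchResult]:
    """Tiered stable ranking: mean metrics desc, L2 asc, parameters asc.

    Failed configurations sort last.
    """
    if not results:
        raise ValueError("no search results to rank")

    def key(r: SearchResult):
        if r.failed or r.metrics is None:
            return (1, 0.0, float("inf"), float("inf"))
        mean4 = sum(r.metrics.values()) / len(r.metrics)
        return (0, -mean4, r.l2, r.n_parameters)

    return sorted(results, key=key)


def results_table(results: list[SearchResult]) -> pd.DataFrame:
    """One row per attempted configuration, ready for parallel-coordinates
    plotting or delimited-text export."""
    rows = []
    for r in results:
        row = {
            "wavelet": r.config.wavelet,
            "fs": "None" if r.config.fs is None else r.config.fs,
            "window_len": r.config.window_len,
            "overlap": r.config.overlap,
            "learning_rate": r.config.learning_rate,
            "optimizer": r.config.optimizer,
            "scalogram_time_s": r.scalogram_time_s,
            "train_time_s": r.train_time_s,
            "l2": r.l2,
            "n_parameters": r.n_parameters,
            "failed": r.failed,
            "error": r.error,
        }
        if r.metrics:
            row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)
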