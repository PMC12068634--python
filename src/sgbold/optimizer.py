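"""Brute-force Savitzky-Golay parameter search with cross-run validation.

Phase one (detrending) scans (window, degree) pairs; for each pair the
observed series are denoised and SG-detrended in a GLM while the predictor
series come from a denoise-only pipeline on the *other* run, avoiding
circularity.  Phase two (cleaning) fixes the detrending filter, scans cleaning
candidates applied after the GLM, and additionally tracks how far each
candidate pushes the lag 1-4 autocorrelations away from those of the
(unfiltered) predictor series: cells whose autocorrelation RMSE exceeds a
threshold are masked out before the best mean cross-run correlation is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .dataset import Dataset, RUN_LABELS
from .filters import FilterSpec, apply_filter
from .glm import PRESETS, Pipeline, denoise_detrend
from .predictor import align_observed, build_predictor, event_average

__all__ = [
    "SearchGrid",
    "SearchResult",
    "NoAdmissibleFilterError",
    "autocorrelations",
    "rmse_autocorr",
    "crossrun_correlation",
    "detrend_search",
    "clean_search",
    "select_optimal",
]

logger = logging.getLogger(__name__)

AUTOCORR_LAGS = (1, 2, 3, 4)


class NoAdmissibleFilterError(RuntimeError):
    """Raised when the autocorrelation mask rejects every grid cell."""


@dataclass(frozen=True)
class SearchGrid:
    """The (window, degree) lattice scanned by the brute-force search.

    Defaults follow the full study grid: odd windows 3..487, degrees
    1..window-1, with ``max_degree`` capping the degree (50 in the cleaning
    phase).  ``degrees`` optionally restricts the scan to an explicit degree
    subset for desk-scale runs.
    """

    windows: tuple[int, ...] = field(
        default_factory=lambda: tuple(range(3, 488, 2))
    )
    max_degree: int | None = None
    degrees: tuple[int, ...] | None = None

    def __post_init__(self):
        wins = tuple(int(w) for w in self.windows)
        if not wins:
            raise ValueError("grid needs at least one window")
        if any(w < 3 or w % 2 == 0 for w in wins):
            raise ValueError("all windows must be odd integers >= 3")
        if list(wins) != sorted(set(wins)):
            raise ValueError("windows must be sorted and unique")
        if self.max_degree is not None and self.max_degree < 1:
            raise ValueError("max_degree must be >= 1")
        object.__setattr__(self, "windows", wins)
        if self.degrees is not None:
            degs = tuple(sorted(set(int(d) for d in self.degrees)))
            if any(d < 1 for d in degs):
                raise ValueError("degrees must be >= 1")
            object.__setattr__(self, "degrees", degs)

    def degrees_for(self, window: int) -> tuple[int, ...]:
        top = window - 1
        if self.max_degree is not None:
            top = min(top, self.max_degree)
        allowed = range(1, top + 1)
        if self.degrees is not None:
            return tuple(d for d in self.degrees if d in allowed)
        return tuple(allowed)

    def cells(self) -> Iterator[FilterSpec]:
        for w in self.windows:
            for d in self.degrees_for(w):
                yield FilterSpec(w, d)

    @property
    def n_cells(self) -> int:
        return sum(len(self.degrees_for(w)) for w in self.windows)


@dataclass
class SearchResult:
    """Per-cell search outcome.

    ``table`` columns: window, degree, mean_r, mean_rmse (clean phase only,
    NaN otherwise), n (correlations entering the mean), n_missing.
    """

    table: pd.DataFrame
    phase: str


def autocorrelations(series, lags: Iterable[int] = AUTOCORR_LAGS) -> np.ndarray:
    """Sample autocorrelations of a series at the given positive lags."""
    x = np.asarray(series, dtype=float)
    if x.size <= max(lags) + 1:
        raise ValueError("series too short for the requested lags")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("zero-variance series has no autocorrelation")
    return np.array([float(x[:-k] @ x[k:]) / denom for k in lags])


def rmse_autocorr(observed, predicted, lags: Iterable[int] = AUTOCORR_LAGS) -> float:
    """RMSE between the lag 1-4 autocorrelations of two series."""
    ao = autocorrelations(observed, lags)
    ap = autocorrelations(predicted, lags)
    return float(np.sqrt(np.mean((ao - ap) ** 2)))


def mean_correlation(values: np.ndarray, fisher_z: bool = False) -> float:
    """Mean of correlations, ignoring missing values.

    Grand means are reported on the raw Pearson scale by default;
    ``fisher_z=True`` averages variance-stabilized z-transforms instead and
    maps the result back through tanh.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return np.nan
    if fisher_z:
        z = np.arctanh(np.clip(v, -1 + 1e-12, 1 - 1e-12))
        return float(np.tanh(z.mean()))
    return float(v.mean())


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = float(a @ a), float(b @ b)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(a @ b) / np.sqrt(na * nb)


def _other(run: str) -> str:
    return RUN_LABELS[1] if run == RUN_LABELS[0] else RUN_LABELS[0]


def _predictor_bank(dataset: Dataset, pipeline: Pipeline) -> dict:
    """Predictor series per (subject index, run label, node)."""
    bank = {}
    for si, subj in enumerate(dataset.subjects):
        for lab in RUN_LABELS:
            run = subj.runs[lab]
            proc = pipeline.apply_matrix(run.matrix, run.nuisance, run.tr_seconds)
            bank[(si, lab)] = np.stack(
                [
                    build_predictor(event_average(row, run.design), run.design)
                    for row in proc
                ]
            )
    return bank


def crossrun_correlation(
    dataset: Dataset,
    pipeline_for_observed: Pipeline,
    pipeline_for_predictor: Pipeline,
) -> np.ndarray:
    """All cross-run predictor/observed Pearson correlations.

    For every subject and node the predictor built from one run is correlated
    with the aligned, filtered observed series of the other run, in both
    directions: 2 * n_nodes * n_subjects values.  Zero-variance series yield
    NaN entries (counted and logged, excluded from downstream means).
    """
    predictors = _predictor_bank(dataset, pipeline_for_predictor)
    out = []
    for si, subj in enumerate(dataset.subjects):
        observed = {}
        for lab in RUN_LABELS:
            run = subj.runs[lab]
            proc = pipeline_for_observed.apply_matrix(
                run.matrix, run.nuisance, run.tr_seconds
            )
            observed[lab] = np.stack(
                [align_observed(row, run.design) for row in proc]
            )
        for lab in RUN_LABELS:
            pred = predictors[(si, _other(lab))]
            obs = observed[lab]
            for node in range(obs.shape[0]):
                out.append(_pearson(pred[node], obs[node]))
    arr = np.array(out)
    n_missing = int(np.isnan(arr).sum())
    if n_missing:
        logger.warning("crossrun_correlation: %d missing correlations", n_missing)
    return arr


def detrend_search(
    dataset: Dataset, grid: SearchGrid, fisher_z: bool = False
) -> SearchResult:
    """Phase one: scan SG detrending parameters.

    Observed series: denoised + SG-detrended (candidate cell) in the GLM.
    Predictor series: denoise-only pipeline from the other run.
    """
    predictors = _predictor_bank(dataset, PRESETS["denoise"])
    rows = []
    for spec in grid.cells():
        rs = []
        for si, subj in enumerate(dataset.subjects):
            aligned = {}
            for lab in RUN_LABELS:
                run = subj.runs[lab]
                proc = np.stack(
                    [
                        denoise_detrend(row, run.nuisance, spec, run.tr_seconds)
                        for row in run.matrix
                    ]
                )
                aligned[lab] = np.stack(
                    [align_observed(row, run.design) for row in proc]
                )
            for lab in RUN_LABELS:
                pred = predictors[(si, _other(lab))]
                for node in range(dataset.n_nodes):
                    rs.append(_pearson(pred[node], aligned[lab][node]))
        rs = np.array(rs)
        rows.append(
            {
                "window": spec.window,
                "degree": spec.degree,
                "mean_r": mean_correlation(rs, fisher_z),
                "mean_rmse": np.nan,
                "n": int((~np.isnan(rs)).sum()),
                "n_missing": int(np.isnan(rs).sum()),
            }
        )
    logger.info("detrend_search scanned %d cells", len(rows))
    return SearchResult(pd.DataFrame(rows), phase="detrend")


def clean_search(
    dataset: Dataset,
    detrend_spec: FilterSpec,
    grid: SearchGrid,
    grand_average_autocorr: bool = True,
    fisher_z: bool = False,
) -> SearchResult:
    """Phase two: scan SG cleaning parameters under a fixed detrending filter.

    Observed series: denoised + detrended (``detrend_spec``), then cleaned
    with the candidate cell.  Predictor series: denoised + detrended, no
    cleaning.  Each cell records the mean cross-run correlation and the RMSE
    between the grand-average lag 1-4 autocorrelations of cleaned observed and
    predictor series (``grand_average_autocorr=False`` averages per-series
    RMSEs instead).
    """
    base = Pipeline("detrend_base", use_nuisance=True, detrend=detrend_spec)
    predictors = _predictor_bank(dataset, base)
    # detrended observed series are cell-independent: precompute once
    detrended = {}
    for si, subj in enumerate(dataset.subjects):
        for lab in RUN_LABELS:
            run = subj.runs[lab]
            detrended[(si, lab)] = base.apply_matrix(
                run.matrix, run.nuisance, run.tr_seconds
            )
    pred_lags = np.mean(
        [
            autocorrelations(series)
            for (si, lab), bank in predictors.items()
            for series in bank
        ],
        axis=0,
    )
    rows = []
    for spec in grid.cells():
        rs, obs_lag_list, rmse_list = [], [], []
        for si, subj in enumerate(dataset.subjects):
            for lab in RUN_LABELS:
                run = subj.runs[lab]
                pred = predictors[(si, _other(lab))]
                for node in range(dataset.n_nodes):
                    cleaned = apply_filter(
                        detrended[(si, lab)][node], spec, run.tr_seconds
                    )
                    aligned = align_observed(cleaned, run.design)
                    rs.append(_pearson(pred[node], aligned))
                    if np.ptp(aligned) > 0:
                        lags = autocorrelations(aligned)
                        obs_lag_list.append(lags)
                        rmse_list.append(
                            float(np.sqrt(np.mean((lags - pred_lags) ** 2)))
                        )
        rs = np.array(rs)
        if grand_average_autocorr:
            mean_rmse = float(
                np.sqrt(np.mean((np.mean(obs_lag_list, axis=0) - pred_lags) ** 2))
            )
        else:
            mean_rmse = float(np.mean(rmse_list))
        rows.append(
            {
                "window": spec.window,
                "degree": spec.degree,
                "mean_r": mean_correlation(rs, fisher_z),
                "mean_rmse": mean_rmse,
                "n": int((~np.isnan(rs)).sum()),
                "n_missing": int(np.isnan(rs).sum()),
            }
        )
    logger.info("clean_search scanned %d cells", len(rows))
    return SearchResult(pd.DataFrame(rows), phase="clean")


def select_optimal(result: SearchResult, rmse_mask_threshold: float = 0.1) -> FilterSpec:
    """Best admissible grid cell.

    In the clean phase only cells with mean autocorrelation RMSE strictly
    below ``rmse_mask_threshold`` are admissible.  Among admissible cells the
    one with maximal mean correlation wins; exact ties break toward the
    smaller window, then the smaller degree.
    """
    df = result.table
    if df.empty:
        raise ValueError("empty search result")
    if result.phase == "clean":
        df = df[df["mean_rmse"] < rmse_mask_threshold]
        if df.empty:
            raise NoAdmissibleFilterError(
                f"no grid cell passes the autocorrelation RMSE mask "
                f"(threshold {rmse_mask_threshold})"
            )
    df = df.dropna(subset=["mean_r"])
    if df.empty:
        raise NoAdmissibleFilterError("no cell produced a valid mean correlation")
    best = df.sort_values(
        ["mean_r", "window", "degree"], ascending=[False, True, True]
    ).iloc[0]
    return FilterSpec(int(best["window"]), int(best["degree"]))
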