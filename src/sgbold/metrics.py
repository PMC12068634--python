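"""Reliability, connectivity and detectable-connectivity metrics.

Attenuation theory bounds the correlation observable between two measured
time courses by the geometric mean of their test-retest reliabilities:

    r_AB <= sqrt(rho_A * rho_B)

Detectable connectivity caps the observed path correlation at that bound and
zeroes paths whose node reliabilities are non-positive ("corrupt").  Group
reproducibility uses the two-way random-effects, absolute-agreement,
single-measure intraclass correlation ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset, RUN_LABELS
from .glm import Pipeline

__all__ = [
    "timecourse_reliability",
    "connectivity_matrix",
    "upper_bound",
    "detectable_connectivity",
    "DetectablePath",
    "icc_2_1",
    "ReliabilityReport",
    "FeasibilitySummary",
    "summary_table",
    "feasibility",
]

RELIABILITY_CUTOFFS = (0.4, 0.6, 0.75)


def timecourse_reliability(test, retest) -> float:
    """Pearson correlation of paired test/retest series (NaN if degenerate)."""
    a = np.asarray(test, dtype=float)
    b = np.asarray(retest, dtype=float)
    if a.shape != b.shape:
        raise ValueError("test and retest series must have equal length")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = float(a @ a), float(b @ b)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(a @ b) / np.sqrt(na * nb)


def connectivity_matrix(run_matrix: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between node time courses.

    Symmetric with unit diagonal; rows/columns of zero-variance nodes are NaN.
    """
    mat = np.asarray(run_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 nodes")
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def upper_bound(rho_a: float, rho_b: float) -> float:
    """Attenuation ceiling sqrt(rho_a * rho_b); NaN marks a corrupt pair.

    A node with zero or negative test-retest reliability carries no repeatable
    signal, so no connectivity involving it is detectable.
    """
    if rho_a > 0 and rho_b > 0:
        return float(np.sqrt(rho_a * rho_b))
    return np.nan


class DetectablePath(NamedTuple):
    value: float
    corrupt: bool
    overestimated: bool


def detectable_connectivity(obs_mean_r: float, rho_a: float, rho_b: float) -> DetectablePath:
    """Cap an observed path correlation at its attenuation upper bound.

    Rules: a non-positive node reliability makes the path corrupt (value 0);
    otherwise positive observations are capped at the bound and negative ones
    at minus the bound; ``overestimated`` flags |observed| above the bound.
    """
    if not -1.0 <= obs_mean_r <= 1.0 or np.isnan(obs_mean_r):
        raise ValueError(f"observed correlation must lie in [-1, 1], got {obs_mean_r}")
    if rho_a <= 0 or rho_b <= 0 or np.isnan(rho_a) or np.isnan(rho_b):
        return DetectablePath(0.0, True, False)
    bound = upper_bound(rho_a, rho_b)
    over = bool(abs(obs_mean_r) > bound)
    if obs_mean_r > 0:
        return DetectablePath(min(obs_mean_r, bound), False, over)
    if obs_mean_r < 0:
        return DetectablePath(-min(abs(obs_mean_r), bound), False, over)
    return DetectablePath(0.0, False, False)


def icc_2_1(data: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``data`` is subjects x sessions.  Returns NaN when the between-subject
    variance vanishes (the coefficient is undefined).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 sessions")
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC input contains non-finite values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0 or (msr == 0 and mse == 0):
        return np.nan
    return (msr - mse) / denom


def _path_labels(n_nodes: int) -> list[str]:
    iu = np.triu_indices(n_nodes, k=1)
    return [f"{i}-{j}" for i, j in zip(*iu)]


@dataclass
class ReliabilityReport:
    """Per-subject node reliabilities and path-level connectivity statistics.

    Frames are indexed by subject id; path columns are "i-j" node-index pairs.
    Corrupt paths carry detectable connectivity 0 and NaN upper bound.
    """

    node_reliability: pd.DataFrame
    path_connectivity: pd.DataFrame
    path_upper_bound: pd.DataFrame
    path_detectable: pd.DataFrame
    path_corrupt: pd.DataFrame
    path_overestimated: pd.DataFrame
    icc_per_path: pd.Series
    pipeline_name: str

    @property
    def n_nodes(self) -> int:
        return self.node_reliability.shape[1]

    @property
    def n_paths(self) -> int:
        return self.path_connectivity.shape[1]

    def summary(self, cutoffs: Sequence[float] = RELIABILITY_CUTOFFS) -> dict:
        """Grand means and percentages in the style of a per-pipeline table row.

        Corrupt paths enter the detectable and upper-bound grand means as 0;
        the overestimation percentage is computed per subject among
        non-corrupt paths and then averaged.
        """
        rel = self.node_reliability.to_numpy()
        conn = self.path_connectivity.to_numpy()
        det = self.path_detectable.to_numpy()
        ub = np.nan_to_num(self.path_upper_bound.to_numpy(), nan=0.0)
        corrupt = self.path_corrupt.to_numpy()
        over = self.path_overestimated.to_numpy()
        noncorrupt_per_subj = (~corrupt).sum(axis=1)
        with np.errstate(invalid="ignore"):
            over_pct = 100.0 * over.sum(axis=1) / noncorrupt_per_subj
        pct_nodes = {
            c: float(np.nanmean(100.0 * (rel > c).mean(axis=1))) for c in cutoffs
        }
        icc_vals = self.icc_per_path.to_numpy()
        group_icc = (
            float(np.nanmean(icc_vals)) if np.any(np.isfinite(icc_vals)) else np.nan
        )
        return {
            "pipeline": self.pipeline_name,
            "group_icc_2_1": group_icc,
            "grand_mean_connectivity": float(np.nanmean(conn)),
            "connectivity_std": float(np.nanstd(conn)),
            "grand_mean_reliability": float(np.nanmean(rel)),
            "reliability_std": float(np.nanstd(rel)),
            "grand_mean_upper_bound": float(np.mean(ub)),
            "grand_mean_detectable": float(np.mean(det)),
            "pct_corrupt_paths": float(100.0 * corrupt.mean()),
            "mean_pct_overestimated_paths": float(np.nanmean(over_pct)),
            "mean_pct_nodes_detected": pct_nodes,
            "n_reliability_values": int(rel.size),
            "n_path_values": int(conn.size),
        }


def summary_table(dataset: Dataset, pipeline: Pipeline) -> ReliabilityReport:
    """Apply a pipeline to every subject/run and assemble the metric suite.

    Per subject: node test-retest reliabilities from full filtered series;
    per-path connectivity as the mean of the test and retest correlation
    matrices; attenuation upper bounds and detectable connectivity with
    corrupt/overestimated flags.  Per path: group ICC(2,1) across subjects
    over the two sessions.
    """
    n_nodes = dataset.n_nodes
    iu = np.triu_indices(n_nodes, k=1)
    subj_ids = [s.subject_id for s in dataset.subjects]
    paths = _path_labels(n_nodes)

    rel_rows, conn_rows, ub_rows, det_rows, cor_rows, over_rows = [], [], [], [], [], []
    conn_by_session = {lab: [] for lab in RUN_LABELS}
    for subj in dataset.subjects:
        proc = {}
        for lab in RUN_LABELS:
            run = subj.runs[lab]
            proc[lab] = pipeline.apply_matrix(run.matrix, run.nuisance, run.tr_seconds)
        rel = np.array(
            [
                timecourse_reliability(proc["test"][i], proc["retest"][i])
                for i in range(n_nodes)
            ]
        )
        cmats = {lab: connectivity_matrix(proc[lab]) for lab in RUN_LABELS}
        for lab in RUN_LABELS:
            conn_by_session[lab].append(cmats[lab][iu])
        mean_conn = np.nanmean(np.stack([cmats[lab] for lab in RUN_LABELS]), axis=0)[iu]
        ubs, dets, cors, overs = [], [], [], []
        for (i, j), obs in zip(zip(*iu), mean_conn):
            if np.isnan(obs):
                ubs.append(np.nan)
                dets.append(np.nan)
                cors.append(True)
                overs.append(False)
                continue
            res = detectable_connectivity(float(obs), rel[i], rel[j])
            ubs.append(upper_bound(rel[i], rel[j]))
            dets.append(res.value)
            cors.append(res.corrupt)
            overs.append(res.overestimated)
        rel_rows.append(rel)
        conn_rows.append(mean_conn)
        ub_rows.append(ubs)
        det_rows.append(dets)
        cor_rows.append(cors)
        over_rows.append(overs)

    icc_vals = []
    sessions = np.stack(
        [np.vstack(conn_by_session[lab]) for lab in RUN_LABELS], axis=2
    )  # subjects x paths x 2
    for p in range(len(paths)):
        mat = sessions[:, p, :]
        if np.all(np.isfinite(mat)) and mat.shape[0] >= 3:
            icc_vals.append(icc_2_1(mat))
        else:
            icc_vals.append(np.nan)

    def frame(rows, dtype=float):
        return pd.DataFrame(rows, index=subj_ids, columns=paths).astype(dtype)

    return ReliabilityReport(
        node_reliability=pd.DataFrame(
            rel_rows, index=subj_ids, columns=[f"node{i}" for i in range(n_nodes)]
        ),
        path_connectivity=frame(conn_rows),
        path_upper_bound=frame(ub_rows),
        path_detectable=frame(det_rows),
        path_corrupt=frame(cor_rows, dtype=bool),
        path_overestimated=frame(over_rows, dtype=bool),
        icc_per_path=pd.Series(icc_vals, index=paths),
        pipeline_name=pipeline.name,
    )


@dataclass(frozen=True)
class FeasibilitySummary:
    """Clinical feasibility screen under a Pareto-style survival rule.

    A subject "passes" at a cutoff when at least ``node_threshold`` node
    reliabilities (or ``path_threshold`` detectable connectivities) exceed it.
    """

    node_threshold: int
    path_threshold: int
    pct_subjects_nodes: dict[float, float]
    pct_subjects_paths: dict[float, float]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def feasibility(
    report: ReliabilityReport,
    pareto_fraction: float = 0.2,
    cutoffs: Sequence[float] = RELIABILITY_CUTOFFS,
) -> FeasibilitySummary:
    """Fraction of subjects whose connectome survives per-cutoff thresholds.

    Thresholds are ``round(pareto_fraction * n_nodes)`` nodes and
    ``round(pareto_fraction * n_paths)`` paths (round half away from zero:
    20% of 34 nodes -> 7, of 561 paths -> 112).
    """
    if not 0 < pareto_fraction <= 1:
        raise ValueError("pareto_fraction must lie in (0, 1]")
    node_thr = _round_half_away(pareto_fraction * report.n_nodes)
    path_thr = _round_half_away(pareto_fraction * report.n_paths)
    rel = report.node_reliability.to_numpy()
    det = report.path_detectable.to_numpy()
    pct_nodes, pct_paths = {}, {}
    for c in cutoffs:
        nodes_ok = (rel > c).sum(axis=1) >= node_thr
        paths_ok = (det > c).sum(axis=1) >= path_thr
        pct_nodes[c] = float(100.0 * nodes_ok.mean())
        pct_paths[c] = float(100.0 * paths_ok.mean())
    return FeasibilitySummary(node_thr, path_thr, pct_nodes, pct_paths)
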