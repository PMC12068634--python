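"""GLM-based denoising and detrending of grey-matter time courses.

Denoising regresses nuisance time courses (white-matter, ventricle and head
motion principal components, 12 regressors in the standard configuration) out
of each grey-matter series.  Detrending adds the slow-trend regressors — a
Savitzky-Golay trend of the series itself, or a discrete-cosine basis — to the
same design, so both are removed in a single ordinary-least-squares fit.
Cleaning (low-pass filtering of the residual) happens after the GLM.

Named pipeline presets cover the nine processing variants compared in this
framework (raw, denoise-only, DCT/SG detrending, HRF/Gaussian/SG cleaning).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .filters import (
    BaselineFilterSpec,
    FilterSpec,
    apply_filter,
    dct_detrend_basis,
    sg_smooth,
)

__all__ = [
    "NuisanceSet",
    "DesignMatrix",
    "build_nuisance_pcs",
    "denoise",
    "denoise_detrend",
    "clean_after",
    "Pipeline",
    "PRESETS",
]


@dataclass(frozen=True)
class NuisanceSet:
    """Per-run nuisance regressors: WM, ventricle (CSF) and motion PCs."""

    wm_pcs: np.ndarray
    csf_pcs: np.ndarray
    motion_pcs: np.ndarray

    def __post_init__(self):
        for name in ("wm_pcs", "csf_pcs", "motion_pcs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"{name} must be a 2-D (n_trs x k) matrix")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        n = {self.wm_pcs.shape[0], self.csf_pcs.shape[0], self.motion_pcs.shape[0]}
        if len(n) != 1:
            raise ValueError("nuisance blocks disagree on n_trs")

    @property
    def n_trs(self) -> int:
        return self.wm_pcs.shape[0]

    @property
    def n_regressors(self) -> int:
        return (
            self.wm_pcs.shape[1] + self.csf_pcs.shape[1] + self.motion_pcs.shape[1]
        )

    def columns(self) -> np.ndarray:
        return np.hstack([self.wm_pcs, self.csf_pcs, self.motion_pcs])

    def labels(self) -> list[str]:
        out = [f"wm_pc{i + 1}" for i in range(self.wm_pcs.shape[1])]
        out += [f"csf_pc{i + 1}" for i in range(self.csf_pcs.shape[1])]
        out += [f"motion_pc{i + 1}" for i in range(self.motion_pcs.shape[1])]
        return out


@dataclass(frozen=True)
class DesignMatrix:
    """GLM design with per-column role tags (intercept | nuisance | trend)."""

    columns: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        cols = np.asarray(self.columns, dtype=float)
        if cols.ndim != 2:
            raise ValueError("design columns must be 2-D")
        if cols.shape[1] != len(self.labels):
            raise ValueError("one label per design column required")
        rank = np.linalg.matrix_rank(cols)
        if rank < cols.shape[1]:
            offenders = _rank_deficient_columns(cols, self.labels)
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {cols.shape[1]}); "
                f"offending columns: {offenders}"
            )
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def has_intercept(self) -> bool:
        return any(lab.split(":")[0] == "intercept" for lab in self.labels)


def _rank_deficient_columns(cols: np.ndarray, labels: Sequence[str]) -> list[str]:
    """Name columns that do not increase the rank when added left to right."""
    offenders, kept = [], []
    for j in range(cols.shape[1]):
        trial = cols[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            offenders.append(labels[j])
    return offenders


def build_nuisance_pcs(raw_signals: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component score time courses of a raw nuisance matrix.

    The input columns are centred; returned score columns are unit-norm and
    ordered by decreasing explained variance.
    """
    raw = np.asarray(raw_signals, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw_signals must be 2-D (n_trs x q)")
    if not 1 <= k <= raw.shape[1]:
        raise ValueError(f"need 1 <= k <= {raw.shape[1]}, got {k}")
    centred = raw - raw.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(raw.shape) * np.finfo(float).eps))
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the centred input")
    return u[:, :k]


def _assemble_design(
    n_trs: int,
    nuisance: NuisanceSet | np.ndarray | None,
    trend_cols: np.ndarray | None,
) -> DesignMatrix:
    cols = [np.ones((n_trs, 1))]
    labels = ["intercept"]
    if nuisance is not None:
        if isinstance(nuisance, NuisanceSet):
            block, nlabels = nuisance.columns(), nuisance.labels()
        else:
            block = np.asarray(nuisance, dtype=float)
            nlabels = [f"nuisance{i + 1}" for i in range(block.shape[1])]
        # centre and unit-normalize for conditioning (residual span unchanged)
        block = block - block.mean(axis=0)
        norms = np.linalg.norm(block, axis=0)
        if np.any(norms == 0):
            raise ValueError("constant nuisance column collides with the intercept")
        cols.append(block / norms)
        labels += [f"nuisance:{lab}" for lab in nlabels]
    if trend_cols is not None and trend_cols.shape[1] > 0:
        cols.append(trend_cols)
        labels += [f"trend:{i + 1}" for i in range(trend_cols.shape[1])]
    return DesignMatrix(np.hstack(cols), tuple(labels))


def denoise(series, design: DesignMatrix) -> np.ndarray:
    """OLS residuals of a series on a design that includes an intercept."""
    from .filters import _as_values

    y = _as_values(series)
    if not isinstance(design, DesignMatrix):
        arr = np.asarray(design, dtype=float)
        design = DesignMatrix(arr, tuple(f"col{i}" for i in range(arr.shape[1])))
        if not np.any(np.ptp(arr, axis=0) == 0):
            raise ValueError("design must include an intercept column")
    elif not design.has_intercept:
        raise ValueError("design must include an intercept column")
    if design.columns.shape[0] != y.size:
        raise ValueError("design and series disagree on n_trs")
    beta, *_ = np.linalg.lstsq(design.columns, y, rcond=None)
    return y - design.columns @ beta


def denoise_detrend(
    series,
    nuisance: NuisanceSet | np.ndarray | None,
    trend: FilterSpec | BaselineFilterSpec | None,
    tr_seconds: float,
) -> np.ndarray:
    """Denoise and detrend in one GLM.

    An SG ``trend`` contributes a single regressor — the SG smooth of the raw
    series itself; a ``dct_detrend`` trend contributes the cosine basis
    columns.  The design is [intercept | nuisance PCs | trend column(s)].
    """
    from .filters import _as_values

    y = _as_values(series)
    trend_cols = None
    if isinstance(trend, FilterSpec):
        trend_cols = sg_smooth(y, trend)[:, None]
    elif isinstance(trend, BaselineFilterSpec):
        if trend.kind != "dct_detrend":
            raise ValueError("only SG or dct_detrend specs detrend within the GLM")
        trend_cols = dct_detrend_basis(y.size, tr_seconds, trend.cutoff_seconds)
    elif trend is not None:
        raise TypeError(f"unsupported trend spec: {trend!r}")
    design = _assemble_design(y.size, nuisance, trend_cols)
    return denoise(y, design)


def clean_after(series, cleaner: FilterSpec | BaselineFilterSpec, tr_seconds: float) -> np.ndarray:
    """Low-pass filter a denoised/detrended residual series ("cleaning")."""
    return apply_filter(series, cleaner, tr_seconds)


@dataclass(frozen=True)
class Pipeline:
    """A named processing chain: optional denoise, detrend and cleaning steps.

    ``apply_matrix`` runs the chain row-wise on a node x time matrix.
    """

    name: str
    use_nuisance: bool = False
    detrend: FilterSpec | BaselineFilterSpec | None = None
    cleaner: FilterSpec | BaselineFilterSpec | None = None

    def apply_series(
        self,
        series,
        nuisance: NuisanceSet | np.ndarray | None,
        tr_seconds: float,
    ) -> np.ndarray:
        from .filters import _as_values

        y = _as_values(series)
        nuis = nuisance if self.use_nuisance else None
        if nuis is None and self.detrend is None and not self.use_nuisance:
            out = y.copy()
        else:
            out = denoise_detrend(y, nuis, self.detrend, tr_seconds)
        if self.cleaner is not None:
            out = clean_after(out, self.cleaner, tr_seconds)
        return out

    def apply_matrix(
        self,
        matrix: np.ndarray,
        nuisance: NuisanceSet | np.ndarray | None,
        tr_seconds: float,
    ) -> np.ndarray:
        mat = np.asarray(matrix, dtype=float)
        return np.vstack(
            [self.apply_series(row, nuisance, tr_seconds) for row in mat]
        )

    def design_labels(self, series, nuisance, tr_seconds: float) -> tuple[str, ...]:
        """Labels of the GLM design this pipeline assembles (for auditing)."""
        from .filters import _as_values

        y = _as_values(series)
        if not self.use_nuisance and self.detrend is None:
            return ()
        nuis = nuisance if self.use_nuisance else None
        trend_cols = None
        if isinstance(self.detrend, FilterSpec):
            trend_cols = sg_smooth(y, self.detrend)[:, None]
        elif isinstance(self.detrend, BaselineFilterSpec):
            trend_cols = dct_detrend_basis(
                y.size, tr_seconds, self.detrend.cutoff_seconds
            )
        return _assemble_design(y.size, nuis, trend_cols).labels


_DCT128 = BaselineFilterSpec("dct_detrend", cutoff_seconds=128.0)
_GAUSS = BaselineFilterSpec("gaussian_lowpass", width_seconds=2.48)
_HRF = BaselineFilterSpec("hrf_lowpass")

#: The nine processing variants compared by the framework.
PRESETS: dict[str, Pipeline] = {
    "raw": Pipeline("raw"),
    "denoise": Pipeline("denoise", use_nuisance=True),
    "detrend_spm": Pipeline("detrend_spm", use_nuisance=True, detrend=_DCT128),
    "clean_hrf": Pipeline(
        "clean_hrf", use_nuisance=True, detrend=_DCT128, cleaner=_HRF
    ),
    "clean_gauss": Pipeline(
        "clean_gauss", use_nuisance=True, detrend=_DCT128, cleaner=_GAUSS
    ),
    "detrend_sg69_6": Pipeline(
        "detrend_sg69_6", use_nuisance=True, detrend=FilterSpec(69, 6)
    ),
    "detrend_sg311_40": Pipeline(
        "detrend_sg311_40", use_nuisance=True, detrend=FilterSpec(311, 40)
    ),
    "clean_sg15_8": Pipeline(
        "clean_sg15_8",
        use_nuisance=True,
        detrend=FilterSpec(69, 6),
        cleaner=FilterSpec(15, 8),
    ),
    "clean_sg3_1": Pipeline(
        "clean_sg3_1",
        use_nuisance=True,
        detrend=FilterSpec(311, 40),
        cleaner=FilterSpec(3, 1),
    ),
}
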