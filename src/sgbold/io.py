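"""Delimited-text interchange formats and JSON configuration.

Matrices are node x time TSV files (first column ``node`` labels, one column
per TR); nuisance regressors are one column per regressor with role-prefixed
headers (``wm_pc1`` ...); event designs are TSV with ``onset_tr`` and
``event_length_trs`` columns.  A dataset directory is tied together by a
``manifest.json`` that records the TR, the shared baseline and per-subject
file paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Dataset, RunData, SubjectData, RUN_LABELS
from .glm import NuisanceSet
from .predictor import EventDesign
from .synth import SimConfig

__all__ = [
    "RunBundle",
    "AnalysisConfig",
    "Config",
    "read_matrix",
    "write_matrix",
    "read_nuisance",
    "write_nuisance",
    "read_design",
    "write_design",
    "write_dataset",
    "load_dataset",
    "load_config",
    "config_hash",
]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RunBundle:
    """File pointers for one subject run inside a dataset directory."""

    subject_id: str
    run_label: str
    matrix_path: Path
    nuisance_path: Path
    design_path: Path

    def __post_init__(self):
        if self.run_label not in RUN_LABELS:
            raise ValueError(f"run_label must be one of {RUN_LABELS}")
        for p in (self.matrix_path, self.nuisance_path, self.design_path):
            if not Path(p).is_file():
                raise FileNotFoundError(p)


def write_matrix(path, matrix: np.ndarray, node_labels=None) -> None:
    """Write a node x time matrix as TSV (rows = nodes, one column per TR)."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2:
        raise ValueError("matrix must be 2-D (nodes x TRs)")
    labels = node_labels or [f"node{i}" for i in range(mat.shape[0])]
    df = pd.DataFrame(mat, index=pd.Index(labels, name="node"),
                      columns=[f"t{j}" for j in range(mat.shape[1])])
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a node x time TSV matrix; returns (matrix, node labels)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty or unparseable matrix file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"matrix file {path} has no data")
    mat = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        bad = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"non-numeric or non-finite cell at row {bad[0]}, column {bad[1]} in {path}"
        )
    return mat, [str(i) for i in df.index]


def write_nuisance(path, nuisance: NuisanceSet) -> None:
    df = pd.DataFrame(nuisance.columns(), columns=nuisance.labels())
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_nuisance(path) -> NuisanceSet:
    df = pd.read_csv(path, sep="\t")
    blocks = {"wm": [], "csf": [], "motion": []}
    for col in df.columns:
        role = col.split("_")[0]
        if role not in blocks:
            raise ValueError(f"unknown nuisance role in column {col!r} of {path}")
        blocks[role].append(df[col].to_numpy(dtype=float))
    return NuisanceSet(
        wm_pcs=np.column_stack(blocks["wm"]),
        csf_pcs=np.column_stack(blocks["csf"]),
        motion_pcs=np.column_stack(blocks["motion"]),
    )


def write_design(path, design: EventDesign) -> None:
    df = pd.DataFrame(
        {
            "onset_tr": design.onsets_trs,
            "event_length_trs": design.event_length_trs,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_design(path, shared_baseline_trs: int) -> EventDesign:
    df = pd.read_csv(path, sep="\t")
    lengths = set(df["event_length_trs"].astype(int))
    if len(lengths) != 1:
        raise ValueError(f"event lengths differ within {path}")
    return EventDesign(
        onsets_trs=tuple(int(o) for o in df["onset_tr"]),
        event_length_trs=lengths.pop(),
        shared_baseline_trs=int(shared_baseline_trs),
    )


def write_dataset(dataset: Dataset, outdir, with_truth: bool = False) -> Path:
    """Write a dataset directory (TSV matrices + manifest.json).

    ``with_truth`` additionally stores the generative components per subject
    as JSON (synthetic data only; intended for desk-scale runs).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"tr_seconds": dataset.tr_seconds, "subjects": []}
    for subj in dataset.subjects:
        entry = {"id": subj.subject_id, "runs": {}}
        design = subj.test.design
        design_path = out / f"{subj.subject_id}_design.tsv"
        write_design(design_path, design)
        entry["design"] = design_path.name
        entry["shared_baseline_trs"] = design.shared_baseline_trs
        for lab in RUN_LABELS:
            run = subj.runs[lab]
            mpath = out / f"{subj.subject_id}_{lab}_matrix.tsv"
            npath = out / f"{subj.subject_id}_{lab}_nuisance.tsv"
            write_matrix(mpath, run.matrix)
            write_nuisance(npath, run.nuisance)
            entry["runs"][lab] = {"matrix": mpath.name, "nuisance": npath.name}
        if with_truth and subj.truth is not None:
            tpath = out / f"{subj.subject_id}_truth.json"
            tpath.write_text(
                json.dumps(
                    {
                        lab: {k: v.tolist() for k, v in comps.items()}
                        for lab, comps in subj.truth.items()
                    }
                )
            )
            entry["truth"] = tpath.name
        manifest["subjects"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out / "manifest.json"


def load_dataset(directory) -> Dataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    root = Path(directory)
    manifest = json.loads((root / "manifest.json").read_text())
    tr = float(manifest["tr_seconds"])
    subjects = []
    for entry in manifest["subjects"]:
        design = read_design(
            root / entry["design"], entry["shared_baseline_trs"]
        )
        runs = {}
        for lab in RUN_LABELS:
            bundle = RunBundle(
                subject_id=entry["id"],
                run_label=lab,
                matrix_path=root / entry["runs"][lab]["matrix"],
                nuisance_path=root / entry["runs"][lab]["nuisance"],
                design_path=root / entry["design"],
            )
            matrix, _ = read_matrix(bundle.matrix_path)
            nuis = read_nuisance(bundle.nuisance_path)
            runs[lab] = RunData(matrix, nuis, design, tr)
        subjects.append(SubjectData(entry["id"], runs))
    return Dataset(subjects)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-side defaults: mask threshold, cutoffs, Pareto fraction, TR."""

    rmse_threshold: float = 0.1
    reliability_cutoffs: tuple[float, ...] = (0.4, 0.6, 0.75)
    pareto_fraction: float = 0.2
    tr_seconds: float = 1.24
    grid_windows: tuple[int, ...] | None = None
    grid_degrees: tuple[int, ...] | None = None
    max_degree: int | None = None
    fisher_z: bool = False

    def __post_init__(self):
        if self.rmse_threshold < 0:
            raise ValueError("rmse_threshold must be >= 0")
        if not 0 < self.pareto_fraction <= 1:
            raise ValueError("pareto_fraction must lie in (0, 1]")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.grid_windows is not None:
            wins = tuple(int(w) for w in self.grid_windows)
            if any(w < 3 or w % 2 == 0 for w in wins):
                raise ValueError("grid windows must be odd integers >= 3")
            object.__setattr__(self, "grid_windows", wins)
        if self.grid_degrees is not None:
            object.__setattr__(
                self, "grid_degrees", tuple(int(d) for d in self.grid_degrees)
            )


@dataclass(frozen=True)
class Config:
    sim: SimConfig
    analysis: AnalysisConfig


def _build_section(cls, payload: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in {section!r} config: {sorted(unknown)}"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
    }
    return cls(**coerced)


def load_config(path_or_dict) -> Config:
    """Load and validate a JSON configuration; defaults fill missing keys.

    Top-level sections: ``sim`` (generator) and ``analysis``.  Unknown keys
    anywhere are rejected by name.
    """
    if isinstance(path_or_dict, dict):
        payload = path_or_dict
    else:
        payload = json.loads(Path(path_or_dict).read_text())
    if not isinstance(payload, dict):
        raise ValueError("configuration must be a JSON object")
    unknown = set(payload) - {"sim", "analysis"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    sim = _build_section(SimConfig, payload.get("sim", {}), "sim")
    analysis = _build_section(AnalysisConfig, payload.get("analysis", {}), "analysis")
    return Config(sim=sim, analysis=analysis)


def config_hash(config: Config) -> str:
    """Stable short hash of a configuration, for run logging."""
    blob = json.dumps(
        {
            "sim": dataclasses.asdict(config.sim),
            "analysis": dataclasses.asdict(config.analysis),
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
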