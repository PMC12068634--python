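"""In-memory containers for paired test/retest multi-node fMRI data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import NuisanceSet
from .predictor import EventDesign

__all__ = ["RunData", "SubjectData", "Dataset", "RUN_LABELS"]

RUN_LABELS = ("test", "retest")


@dataclass
class RunData:
    """One run of one subject: node x time matrix plus nuisance and design."""

    matrix: np.ndarray
    nuisance: NuisanceSet | None
    design: EventDesign
    tr_seconds: float

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2:
            raise ValueError("run matrix must be 2-D (nodes x TRs)")
        if not np.all(np.isfinite(mat)):
            raise ValueError("run matrix contains non-finite values")
        if self.nuisance is not None and self.nuisance.n_trs != mat.shape[1]:
            raise ValueError("nuisance and matrix disagree on n_trs")
        self.matrix = mat

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_trs(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SubjectData:
    """Paired test/retest runs for one subject, with optional ground truth.

    ``truth`` (synthetic data only) maps run label -> component name ->
    node x time array, where the components sum exactly to the run matrix.
    """

    subject_id: str
    runs: dict[str, RunData]
    truth: dict[str, dict[str, np.ndarray]] | None = None

    def __post_init__(self):
        missing = [lab for lab in RUN_LABELS if lab not in self.runs]
        if missing:
            raise ValueError(f"subject {self.subject_id} lacks runs: {missing}")

    @property
    def test(self) -> RunData:
        return self.runs["test"]

    @property
    def retest(self) -> RunData:
        return self.runs["retest"]


@dataclass
class Dataset:
    """A collection of subjects with homogeneous geometry."""

    subjects: list[SubjectData] = field(default_factory=list)

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("a dataset needs at least one subject")
        shapes = {s.runs[lab].matrix.shape for s in self.subjects for lab in RUN_LABELS}
        if len(shapes) != 1:
            raise ValueError(f"subjects disagree on matrix shape: {shapes}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_nodes(self) -> int:
        return self.subjects[0].test.n_nodes

    @property
    def n_trs(self) -> int:
        return self.subjects[0].test.n_trs

    @property
    def tr_seconds(self) -> float:
        return self.subjects[0].test.tr_seconds
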