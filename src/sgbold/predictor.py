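"""Empirical HRF estimation and predictor time-course construction.

The subject-specific "empirical HRF" is the event-related average: the mean
over all task events of the segment starting at each event onset (the event
window plus the portion of the following baseline shared by every event; with
a jittered inter-trial baseline only the shared portion is used).  The
predictor time course is that average concatenated once per event, and serves
as the ground truth against which filtered observed time courses are
correlated during filter optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import _as_values

__all__ = ["EventDesign", "event_average", "build_predictor", "align_observed"]


@dataclass(frozen=True)
class EventDesign:
    """Task event timing in TR units (0-based onsets).

    ``shared_baseline_trs`` is the number of post-event baseline TRs common to
    all events (the minimum inter-trial gap under jitter); each extracted
    segment spans ``event_length_trs + shared_baseline_trs`` TRs.
    """

    onsets_trs: tuple[int, ...]
    event_length_trs: int
    shared_baseline_trs: int

    def __post_init__(self):
        onsets = tuple(int(o) for o in self.onsets_trs)
        if len(onsets) < 2:
            raise ValueError("an event design needs at least 2 events")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        if onsets[0] < 0:
            raise ValueError("onsets must be non-negative")
        if self.event_length_trs < 1:
            raise ValueError("event_length_trs must be >= 1")
        if self.shared_baseline_trs < 0:
            raise ValueError("shared_baseline_trs must be >= 0")
        object.__setattr__(self, "onsets_trs", onsets)

    @property
    def n_events(self) -> int:
        return len(self.onsets_trs)

    @property
    def segment_length_trs(self) -> int:
        return self.event_length_trs + self.shared_baseline_trs


def _extract_segments(x: np.ndarray, design: EventDesign) -> np.ndarray:
    seg = design.segment_length_trs
    bad = [o for o in design.onsets_trs if o + seg > x.size]
    if bad:
        raise ValueError(
            f"event segments exceed the run (length {x.size}): onsets {bad} "
            f"with segment length {seg}"
        )
    return np.stack([x[o : o + seg] for o in design.onsets_trs])


def event_average(series, design: EventDesign) -> np.ndarray:
    """Element-wise mean across the per-event segments (the empirical HRF)."""
    x = _as_values(series)
    return _extract_segments(x, design).mean(axis=0)


def build_predictor(hrf: np.ndarray, design: EventDesign) -> np.ndarray:
    """Tile the empirical HRF once per event to form the predictor series."""
    hrf = np.asarray(hrf, dtype=float)
    if hrf.ndim != 1 or hrf.size == 0:
        raise ValueError("empirical HRF must be a non-empty 1-D array")
    return np.tile(hrf, design.n_events)


def align_observed(series, design: EventDesign) -> np.ndarray:
    """Concatenate the per-event segments of an observed series in run order.

    The tiny baseline fractions not shared among events are omitted, so the
    result has the same length as the matching predictor and the two can be
    correlated sample by sample.
    """
    x = _as_values(series)
    return _extract_segments(x, design).reshape(-1)
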