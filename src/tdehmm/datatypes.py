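"""Core containers shared across the pipeline stages.

Conventions
-----------
Time-series matrices are stored channels x samples (``N x T``).  Channel
*groups* tag each channel as belonging to a cortical cluster (``"frontal"``,
``"sensorimotor"``, ...) or to an STN contact (any tag starting with
``"STN"``); the STN/cortex split gates leakage correction and the
cross-coherence block used for frequency-mode discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegionTimeSeries", "ConcatenatedDataset", "is_stn_group"]


def is_stn_group(tag: str) -> bool:
    """True if a channel-group tag denotes an STN (intracranial) contact."""
    return tag.upper().startswith("STN")


@dataclass
class RegionTimeSeries:
    """One subject's region-level recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Real-valued region time courses.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        One name per channel.
    groups : list of str
        One cluster tag per channel; tags starting with ``"STN"`` mark
        subthalamic contacts which bypass leakage correction.
    subject_id : str
    condition : str
        Experimental condition tag (e.g. ``"A"``/``"B"`` or ``"OFF"``/``"ON"``).
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)
    subject_id: str = "s0"
    condition: str = "A"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = self.data.shape[0]
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(n)]
        if not self.groups:
            self.groups = ["cortical"] * n
        if len(self.labels) != n or len(self.groups) != n:
            raise ValueError("labels/groups length must match channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def stn_indices(self) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if is_stn_group(g)], dtype=int)

    @property
    def cortical_indices(self) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if not is_stn_group(g)], dtype=int)


@dataclass
class ConcatenatedDataset:
    """Subjects stacked along the time axis, ready for embedding.

    ``boundaries`` holds per-subject ``(start, stop)`` index pairs that
    partition the time axis exactly.
    """

    data: np.ndarray
    fs: float
    boundaries: list[tuple[int, int]]
    labels: list[str]
    groups: list[str]
    subject_ids: list[str]
    condition: str = "A"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        t = 0
        for start, stop in self.boundaries:
            if start != t or stop <= start:
                raise ValueError("subject boundaries must partition the time axis")
            t = stop
        if t != self.data.shape[1]:
            raise ValueError("boundaries do not cover the full time axis")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.boundaries)

    def subject_data(self, s: int) -> np.ndarray:
        start, stop = self.boundaries[s]
        return self.data[:, start:stop]

    @property
    def stn_indices(self) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if is_stn_group(g)], dtype=int)

    @property
    def cortical_indices(self) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if not is_stn_group(g)], dtype=int)
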