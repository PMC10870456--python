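"""The COPTrial container: one uniformly sampled planar COP recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

SAMPLING_HZ = 80.0
MIN_BASELINE_S = 5.0
#: relative tolerance for grid uniformity checks
_GRID_RTOL = 1e-6


@dataclass
class COPTrial:
    """Planar COP displacement (cm) on a strictly uniform time grid.

    ``target_onset`` marks the end of the quiet-stance preparation phase
    (>= 5 s of baseline precede it).  ``metadata`` carries subject/group
    identifiers and, for synthetic trials, the generating ground truth.
    """

    time: np.ndarray  # s
    cop_ap: np.ndarray  # cm, + forward
    cop_ml: np.ndarray  # cm
    target_onset: float  # s
    target_id: int
    sampling_hz: float = SAMPLING_HZ
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.cop_ap = np.asarray(self.cop_ap, dtype=float)
        self.cop_ml = np.asarray(self.cop_ml, dtype=float)
        n = self.time.size
        if n < 2 or self.cop_ap.size != n or self.cop_ml.size != n:
            raise ValidationError("time/cop_ap/cop_ml must be equal-length, n >= 2")
        dt = 1.0 / self.sampling_hz
        steps = np.diff(self.time)
        bad = np.nonzero(np.abs(steps - dt) > _GRID_RTOL * dt + 1e-12)[0]
        if bad.size:
            raise ValidationError(
                f"non-uniform time grid at index {int(bad[0]) + 1} "
                f"(step {steps[bad[0]]:.6g} s, expected {dt:.6g} s)"
            )
        if not np.all(np.isfinite(self.cop_ap)) or not np.all(np.isfinite(self.cop_ml)):
            raise ValidationError("COP samples must be finite (no missing values)")
        if self.target_onset - self.time[0] < MIN_BASELINE_S - _GRID_RTOL:
            raise ValidationError(
                f"target_onset={self.target_onset} s leaves less than "
                f"{MIN_BASELINE_S} s of quiet-stance baseline"
            )
        if not 1 <= int(self.target_id) <= 8:
            raise ValidationError(f"target_id={self.target_id} must be in 1..8")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def onset_index(self) -> int:
        """Index of the first sample at or after target onset."""
        return int(np.searchsorted(self.time, self.target_onset - 1e-9))
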