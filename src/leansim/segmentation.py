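"""Five-phase decomposition of a voluntary-lean COP trial.

Phases: preparation (quiet stance before target onset), planning (target
onset to APA onset), APA (the anticipatory excursion opposite the target),
reaching (APA onset to the COP maximum), returning (maximum back to
baseline).  Extracted features:

* t_r       reaction time: target onset -> APA onset,
* t_APA     APA onset -> first return of the signal to baseline,
* t_f       APA onset -> COP maximum toward the target,
* t_b       COP maximum -> first local extremum after the signal settles
            inside a band around baseline,
* APA size  peak-to-peak COP within the APA phase,
* Lean_max  COP maximum relative to the quiet-stance baseline,

with t_total = t_r + t_f + t_b by construction.

APA onset uses the classic threshold rule: the first excursion beyond
twice the baseline standard deviation, in the direction opposite the
target, sustained for a minimum duration.  An absolute threshold floor
guards the noiseless limit where the baseline SD vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import NoAPADetectedError, SegmentationFailedError, ValidationError
from .planning import TargetLayout
from .trial import COPTrial


@dataclass(frozen=True)
class SegmentationConfig:
    baseline_window_s: float = 5.0  # pre-onset window defining "initial signal"
    min_apa_duration_s: float = 0.05  # sustained-crossing requirement
    threshold_floor_cm: float = 1e-4  # absolute floor under 2*SD rule
    # Optional zero-phase Butterworth low-pass for noisy recordings.  Off by
    # default: filtfilt is non-causal, so a sharp APA leaks backward in time
    # and both advances the detected onset and closes the APA window on
    # filter ripple.
    lowpass_hz: float | None = None
    filter_order: int = 4
    settle_band_frac: float = 0.10  # return-phase settling band, fraction of Lean_max

    def __post_init__(self):
        if self.baseline_window_s <= 0 or self.min_apa_duration_s < 0:
            raise ValidationError("segmentation windows must be positive")
        if not 0 < self.settle_band_frac < 1:
            raise ValidationError("settle_band_frac must lie in (0, 1)")


@dataclass(frozen=True)
class SegmentationResult:
    t_r: float
    t_APA: float
    t_f: float
    t_b: float
    apa_size: float  # cm
    lean_max: float  # cm
    apa_onset_idx: int
    apa_end_idx: int
    peak_idx: int
    return_idx: int
    baseline_mean: float  # cm, along the task direction
    baseline_sd: float  # cm

    @property
    def t_total(self) -> float:
        return self.t_r + self.t_f + self.t_b


def project_onto_direction(trial: COPTrial, layout: TargetLayout) -> np.ndarray:
    """Signed scalar COP along the unit vector toward the trial's target.

    The planar signal is centered on its pre-onset baseline mean before
    projecting, so positive values point toward the target.
    """
    target = layout[trial.target_id]
    u_ap, u_ml = target.unit_vector
    i0, i1 = _baseline_slice(trial.time, trial.target_onset, window_s=None)
    ap = trial.cop_ap - trial.cop_ap[i0:i1].mean()
    ml = trial.cop_ml - trial.cop_ml[i0:i1].mean()
    return ap * u_ap + ml * u_ml


def _baseline_slice(time, target_onset, window_s):
    onset_idx = int(np.searchsorted(time, target_onset - 1e-9))
    if window_s is None:
        i0 = 0
    else:
        i0 = int(np.searchsorted(time, target_onset - window_s - 1e-9))
    if onset_idx - i0 < 2:
        raise ValidationError("baseline window before target onset is too short")
    return i0, onset_idx


def _lowpass(x, fs, cutoff, order):
    if cutoff is None or cutoff <= 0 or cutoff >= fs / 2:
        return x
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_apa_onset(
    signal: np.ndarray,
    time: np.ndarray,
    target_onset: float,
    baseline_window_s: float | None = None,
    min_duration_s: float = 0.05,
    threshold_floor: float = 1e-4,
) -> tuple[float, int]:
    """First sustained excursion opposite the target after target onset.

    ``signal`` is the task-direction projection (positive toward the
    target); the APA is therefore a *negative* excursion.  The threshold is
    max(2*SD_baseline, floor) below the baseline mean; the crossing must
    persist for ``min_duration_s``.  Returns (onset time, onset index);
    raises :class:`NoAPADetectedError` when no such crossing exists.
    """
    signal = np.asarray(signal, float)
    time = np.asarray(time, float)
    i0, onset_idx = _baseline_slice(time, target_onset, baseline_window_s)
    mean = signal[i0:onset_idx].mean()
    sd = signal[i0:onset_idx].std(ddof=0)
    thr = max(2.0 * sd, threshold_floor)
    fs = 1.0 / np.median(np.diff(time))
    run_needed = max(int(round(min_duration_s * fs)), 1)

    below = signal[onset_idx:] < mean - thr
    run = 0
    start = -1
    for k, b in enumerate(below):
        if b:
            if run == 0:
                start = k
            run += 1
            if run >= run_needed:
                idx = onset_idx + start
                return float(time[idx]), idx
        else:
            run = 0
    raise NoAPADetectedError(
        f"no excursion beyond {thr:.4g} cm opposite the target sustained for "
        f"{min_duration_s} s after onset"
    )


def segment_signal(
    x: np.ndarray,
    time: np.ndarray,
    target_onset: float,
    config: SegmentationConfig = SegmentationConfig(),
) -> SegmentationResult:
    """Segment a task-direction COP projection (positive toward target)."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    fs = 1.0 / np.median(np.diff(time))
    i0, onset_idx = _baseline_slice(time, target_onset, config.baseline_window_s)
    mean = x[i0:onset_idx].mean()
    xc = _lowpass(x - mean, fs, config.lowpass_hz, config.filter_order)
    sd = xc[i0:onset_idx].std(ddof=0)

    _, apa_onset = detect_apa_onset(
        xc,
        time,
        target_onset,
        baseline_window_s=config.baseline_window_s,
        min_duration_s=config.min_apa_duration_s,
        threshold_floor=config.threshold_floor_cm,
    )

    # APA extremum, then first return to the baseline level (zero-up-cross
    # of the centered signal).
    after = xc[apa_onset:]
    up = np.nonzero(after >= 0.0)[0]
    up = up[up > 0]
    if up.size == 0:
        raise SegmentationFailedError("COP never returns to baseline after the APA")
    apa_end = apa_onset + int(up[0])
    # The phase ends where the signal crosses baseline, between samples
    # apa_end-1 and apa_end; clamp the peak-to-peak to that boundary (value
    # 0 by definition) so the feature does not depend on how far past the
    # crossing the next sample lands.
    apa_win = xc[apa_onset:apa_end]
    apa_size = float(max(apa_win.max(), 0.0) - apa_win.min())
    y0, y1 = xc[apa_end - 1], xc[apa_end]
    frac = 0.0 if y1 == y0 else np.clip(-y0 / (y1 - y0), 0.0, 1.0)
    t_cross = time[apa_end - 1] + frac * (time[apa_end] - time[apa_end - 1])

    # Global toward-target maximum after the APA.
    peak_idx = apa_end + int(np.argmax(xc[apa_end:]))
    lean_max = float(xc[peak_idx])
    if lean_max <= 0:
        raise SegmentationFailedError("no toward-target peak after the APA")
    if peak_idx >= x.size - 1:
        raise SegmentationFailedError("COP maximum at trial end (monotone drift?)")

    # Return phase: first entry into the settling band, then the first
    # local extremum at or after it; the band entry itself is the fallback
    # when the tail is monotone.
    band = config.settle_band_frac * lean_max
    tail = xc[peak_idx:]
    inside = np.nonzero(np.abs(tail) <= band)[0]
    if inside.size == 0:
        raise SegmentationFailedError("COP never settles near baseline after the peak")
    k = peak_idx + int(inside[0])
    ret_idx = k
    d = np.diff(xc[k - 1 :]) if k >= 1 else np.diff(xc[k:])
    for j in range(1, d.size):
        if d[j - 1] * d[j] <= 0:
            ret_idx = k - 1 + j if k >= 1 else k + j
            break
    if ret_idx <= peak_idx:
        ret_idx = k

    t = time
    res = SegmentationResult(
        t_r=float(t[apa_onset] - target_onset),
        t_APA=float(t_cross - t[apa_onset]),
        t_f=float(t[peak_idx] - t[apa_onset]),
        t_b=float(t[ret_idx] - t[peak_idx]),
        apa_size=apa_size,
        lean_max=lean_max,
        apa_onset_idx=apa_onset,
        apa_end_idx=apa_end,
        peak_idx=peak_idx,
        return_idx=ret_idx,
        baseline_mean=float(mean),
        baseline_sd=float(sd),
    )
    if not (res.apa_onset_idx < res.apa_end_idx <= res.peak_idx):
        raise SegmentationFailedError("phase indices out of order")
    return res


def segment_trial(
    trial: COPTrial,
    layout: TargetLayout,
    config: SegmentationConfig = SegmentationConfig(),
) -> SegmentationResult:
    """Project a planar trial onto its task direction and segment it."""
    x = project_onto_direction(trial, layout)
    return segment_signal(x, trial.time, trial.target_onset, config)


FEATURE_COLUMNS = ["t_r", "t_APA", "t_f", "t_b", "t_total", "apa_size", "lean_max"]


def aggregate_subject(
    results_by_direction: dict[int, list[SegmentationResult | None]],
) -> pd.DataFrame:
    """Per-direction means of the features over trial repetitions.

    ``None`` entries mark flagged trials (e.g. no APA detected); they are
    excluded and the surviving count is reported.  A direction with zero
    valid trials yields a row of NaNs with ``missing=True``.
    """
    rows = []
    for direction in sorted(results_by_direction):
        valid = [r for r in results_by_direction[direction] if r is not None]
        row = {"target_id": direction, "n_trials": len(valid), "missing": not valid}
        for col in FEATURE_COLUMNS:
            row[col] = (
                float(np.mean([getattr(r, col) for r in valid])) if valid else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
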