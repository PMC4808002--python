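"""Precursor, onset and recovery detection on measure trajectories.

The precursor sign is a sudden, persistent deflection of a sliding-window
measure away from its baseline level: downward for the Hurst exponent
(memory collapses), upward for the fractal dimension (the signal becomes
more complex).  The detector formalises the visual read-out as a robust
threshold crossing:

* baseline level = median of the trajectory over the first ``baseline_s``;
* noise scale = 1.4826 * MAD(lagged trajectory differences) / sqrt(2),
  with the lag set to one full window so the differenced pairs share no
  samples — consecutive points of a 90 %-overlapping sliding window are so
  strongly correlated that their raw dispersion badly understates the
  estimator's sampling noise.  The scale is evaluated causally (only
  differences observed up to the candidate point), so the large ictal and
  recovery level changes later in a record cannot inflate it;
* the sign is the first time the trajectory stays beyond
  ``baseline -/+ k * scale`` for ``m`` consecutive points, with ``m``
  defaulting to one window of points plus two — any single-window artifact
  persists for window/step points, so shorter runs carry no evidence.

Seizure onset, when not annotated, is located from raw amplitude: the
first time the sliding 1 s peak-to-peak exceeds ``k`` times the baseline
peak-to-peak and holds for 2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EEGRecord, select_dominant_channel
from .hurst import Trajectory, sliding_hurst
from .fractal import sliding_fd
from .synthetic import EventAnnotation

__all__ = [
    "DetectionConfig",
    "DetectionResult",
    "detect_deflection",
    "detect_onset",
    "analyze_record",
    "lead_time",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the record-level analysis."""

    window_s: float = 10.0
    step_s: float = 1.0
    baseline_s: float = 20.0
    k_hurst: float = 4.0
    k_fd: float = 3.0          # FD saturates near 1 during the precursor,
                               # leaving less up-side headroom than H has down-side
    k_onset: float = 5.0
    persistence: int | None = None   # None -> window/step + 2
    transform_hurst: str = "none"
    transform_fd: str = "logit"      # FD saturates against its D=1 ceiling
    fd_q: float = 1.0
    hurst_method: str = "rs"
    concordance_tol_factor: float = 2.0  # x window_s


@dataclass
class DetectionResult:
    """Timestamps (s) of the precursor sign, onset and recovery, plus the
    lead time and the H/FD concordance verdict.  Absent events are None;
    a negative lead is reported but flagged as a detection failure."""

    t_sign: float | None
    t_sign_fd: float | None
    t_onset_detected: float | None
    t_recovery: float | None
    lead_time: float | None
    lead_flagged: bool
    concordant: bool
    diagnostics: dict = field(default_factory=dict)


def _robust_scale(values: np.ndarray, lag: int) -> float:
    d = values[lag:] - values[:-lag]
    d = d[np.isfinite(d)]
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_deflection(traj: Trajectory, direction: str,
                      baseline_s: float = 20.0, k: float = 4.0,
                      m: int | None = None, transform: str = "none") -> float | None:
    """First time the trajectory deflects persistently from its baseline.

    ``transform="logit"`` maps values through log(v/(1-v)) before
    thresholding — appropriate for measures bounded in (0, 1) such as H or
    the dimension of a 1-D value distribution, whose fluctuations are
    compressed against the boundaries exactly where the deflections land.

    Returns the time of the first point of the qualifying run, or None if
    the threshold is never held for ``m`` consecutive points.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    t, v = traj.times, traj.values
    if transform == "logit":
        vv = np.clip(v, 1e-4, 1 - 1e-4)
        v = np.log(vv / (1 - vv))
    elif transform != "none":
        raise ValueError("transform must be 'none' or 'logit'")
    lag = max(1, int(round(traj.window_s / traj.step_s)))
    if m is None:
        m = lag + 2
    base = v[(t < t[0] + baseline_s) & np.isfinite(v)]
    if base.size < 3 or t[-1] - t[0] < baseline_s:
        raise ValueError("trajectory too short for the requested baseline")
    level = float(np.median(base))
    diffs = v[lag:] - v[:-lag]
    start = int(np.searchsorted(t, t[0] + baseline_s))
    run = 0
    for i in range(start, t.size):
        # causal scale: only differences strictly before the candidate
        # window, so neither later regime changes nor the deflection being
        # tested can inflate the noise estimate
        d = diffs[:max(i - 2 * lag + 1, lag)]
        d = d[np.isfinite(d)]
        if d.size < 5 or not np.isfinite(v[i]):
            run = 0
            continue
        mad = np.median(np.abs(d - np.median(d)))
        scale = max(1.4826 * mad / np.sqrt(2.0), 1e-6)
        hit = (v[i] < level - k * scale) if direction == "down" \
            else (v[i] > level + k * scale)
        run = run + 1 if hit else 0
        if run >= m:
            return float(t[i - m + 1])
    return None


def detect_onset(record: EEGRecord, channel: int, baseline_s: float = 20.0,
                 k: float = 5.0, hold_s: float = 2.0) -> float | None:
    """Amplitude-based seizure onset: sliding 1 s peak-to-peak exceeding
    ``k`` times the baseline peak-to-peak for at least ``hold_s``."""
    if record.duration <= baseline_s:
        raise ValueError("record no longer than the baseline period")
    x = record.data[channel]
    w = max(2, int(round(record.fs)))
    base_ptp = np.ptp(x[:int(round(baseline_s * record.fs))])
    if base_ptp == 0:
        base_ptp = np.finfo(float).tiny
    n = x.size - w
    # running min/max via stride tricks would be overkill at 35 Hz
    ptp = np.array([np.ptp(x[i:i + w]) for i in range(n)])
    t = (np.arange(n) + w / 2) / record.fs
    hit = ptp > k * base_ptp
    need = max(1, int(round(hold_s * record.fs)))
    run = 0
    for i, h in enumerate(hit):
        run = run + 1 if h else 0
        if run >= need:
            return float(t[i - need + 1])
    return None


def lead_time(t_sign: float, t_onset: float) -> tuple[float, bool]:
    """Seconds from precursor sign to onset; negative values are flagged
    (sign after onset means the detection failed, not that time ran
    backwards)."""
    lead = t_onset - t_sign
    return float(lead), lead < 0


def analyze_record(record: EEGRecord,
                   annotation: EventAnnotation | None = None,
                   config: DetectionConfig = DetectionConfig()) -> DetectionResult:
    """Full single-record analysis.

    Selects the dominant channel, computes the Hurst and FD trajectories,
    detects the downward H deflection (authoritative for the precursor
    sign) and the upward FD deflection (confirmation), locates onset
    (annotated onset takes precedence, isolating precursor error from
    onset error) and the post-onset recovery, and derives the lead time.
    """
    channel = select_dominant_channel(record)
    traj_h = sliding_hurst(record, channel, config.window_s, config.step_s,
                           method=config.hurst_method)
    traj_fd = sliding_fd(record, channel, config.window_s, config.step_s,
                         q=config.fd_q)
    t_sign = detect_deflection(traj_h, "down", config.baseline_s,
                               config.k_hurst, config.persistence,
                               transform=config.transform_hurst)
    t_sign_fd = detect_deflection(traj_fd, "up", config.baseline_s,
                                  config.k_fd, config.persistence,
                                  transform=config.transform_fd)

    if annotation is not None:
        t_onset = float(annotation.t_onset)
    else:
        t_onset = detect_onset(record, channel, config.baseline_s,
                               config.k_onset)

    concordant = (t_sign is not None and t_sign_fd is not None and
                  abs(t_sign - t_sign_fd)
                  <= config.concordance_tol_factor * config.window_s)

    lead = None
    flagged = False
    if t_sign is not None and t_onset is not None:
        lead, flagged = lead_time(t_sign, t_onset)

    t_recovery = None
    if t_onset is not None:
        after = traj_h.times >= t_onset
        if after.sum() >= 5:
            sub = Trajectory(times=traj_h.times[after],
                             values=traj_h.values[after],
                             window_s=traj_h.window_s, step_s=traj_h.step_s,
                             measure_name=traj_h.measure_name,
                             flags=traj_h.flags[after])
            try:
                t_recovery = detect_deflection(sub, "up", config.baseline_s,
                                               config.k_hurst,
                                               config.persistence,
                                               transform=config.transform_hurst)
            except ValueError:
                t_recovery = None

    base_h = traj_h.values[traj_h.times < traj_h.times[0] + config.baseline_s]
    return DetectionResult(
        t_sign=t_sign, t_sign_fd=t_sign_fd, t_onset_detected=t_onset,
        t_recovery=t_recovery, lead_time=lead, lead_flagged=flagged,
        concordant=concordant,
        diagnostics={
            "channel": channel,
            "baseline_hurst": float(np.nanmedian(base_h)),
            "hurst_scale": _robust_scale(traj_h.values,
                                         max(1, int(round(config.window_s / config.step_s)))),
        })
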