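"""Synthetic EEG-like seizure records with full ground truth.

No public recordings accompany the clinical analysis this package
implements, so every downstream stage is exercised on simulated records
with known event times.  A record is built from three regimes:

* **baseline** — persistent fractional Gaussian noise (fGn), Hurst
  ``h_baseline`` (default 0.9, matching pre-stimulus estimates in the
  0.90-0.94 band);
* **precursor → seizure end** — anti-persistent fGn (``h_precursor``,
  default 0.3) plus a rhythmic triangular discharge emulating preictal
  epileptiform activity.  The discharge both flattens the R/S scaling
  (driving the measured Hurst exponent down) and flattens the window
  amplitude distribution toward uniform (driving the binned fractal
  dimension up) — the two signatures the detection stage looks for;
* **ictal window** — the same process amplitude-scaled on the dominant
  channel (attenuated 0.3x elsewhere) with a positive offset so the
  voltage range is asymmetric, roughly -769 to +1230 uV after the
  35 Hz preprocessing.

fGn is synthesised exactly by circulant embedding (Davies-Harte), with a
sequential-conditional (Hosking) fallback should the embedding ever fail
to be nonnegative-definite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .io import EEGRecord

__all__ = [
    "SyntheticSpec",
    "EventAnnotation",
    "gen_fgn",
    "gen_seizure_record",
    "gen_cohort",
    "DEFAULT_SPEC",
]


@dataclass(frozen=True)
class EventAnnotation:
    """Ground-truth precursor, onset and seizure-end times in seconds."""

    t_precursor: float
    t_onset: float
    t_end: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_precursor < self.t_onset < self.t_end):
            raise ValueError("require 0 <= t_precursor < t_onset < t_end")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic seizure record.

    Amplitudes are RMS values in microvolts; times in seconds.
    ``discharge_amp`` sets the rhythmic preictal discharge (0 disables it,
    yielding the pure segment-wise fGn signal).
    """

    duration_s: float = 180.0
    fs: float = 256.0
    n_channels: int = 24
    h_baseline: float = 0.9
    h_precursor: float = 0.3
    t_precursor: float = 50.0
    t_onset: float = 80.0
    t_end: float = 160.0
    baseline_amp: float = 20.0
    ictal_amp: float = 708.0
    ictal_offset: float = 245.0
    discharge_amp: float = 100.0
    discharge_freq_hz: float = 3.0
    dominant_channel: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.t_precursor < self.t_onset < self.t_end <= self.duration_s):
            raise ValueError("require 0 < t_precursor < t_onset < t_end <= duration_s")
        for h in (self.h_baseline, self.h_precursor):
            if not 0 < h < 1:
                raise ValueError("Hurst targets must lie in (0, 1)")
        if not self.ictal_amp > self.baseline_amp > 0:
            raise ValueError("require ictal_amp > baseline_amp > 0")
        if not 0 <= self.dominant_channel < self.n_channels:
            raise ValueError("dominant_channel out of range")

    def annotation(self) -> EventAnnotation:
        return EventAnnotation(self.t_precursor, self.t_onset, self.t_end)


DEFAULT_SPEC = SyntheticSpec()


@lru_cache(maxsize=64)
def _circulant_eigenvalues(n: int, h: float) -> np.ndarray:
    k = np.arange(n, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * h) - 2 * k ** (2 * h) + np.abs(k - 1) ** (2 * h))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    return np.fft.fft(row).real


def _fgn_hosking(n: int, h: float, rng: np.random.Generator) -> np.ndarray:
    # O(n^2) exact conditional simulation; only reached if the circulant
    # embedding has a negative eigenvalue (not observed for fGn).
    k = np.arange(n, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * h) - 2 * k ** (2 * h) + np.abs(k - 1) ** (2 * h))
    x = np.empty(n)
    phi = np.zeros(n)
    x[0] = rng.standard_normal()
    v = 1.0
    for t in range(1, n):
        phi_t = (gamma[t] - phi[:t - 1] @ gamma[t - 1:0:-1]) / v
        phi[:t - 1] -= phi_t * phi[t - 2::-1]
        phi[t - 1] = phi_t
        v *= 1 - phi_t * phi_t
        x[t] = phi[:t] @ x[t - 1::-1] + np.sqrt(max(v, 0.0)) * rng.standard_normal()
    return x


def gen_fgn(n: int, h: float, seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Exact zero-mean, unit-variance fractional Gaussian noise.

    Parameters
    ----------
    n:
        Series length (>= 2).
    h:
        Hurst parameter in (0, 1); ``h=0.5`` gives white noise.
    seed, rng:
        Either an integer seed or an existing generator (for streaming
        several segments from one source of randomness).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < h < 1:
        raise ValueError("h must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    lam = _circulant_eigenvalues(n, h)
    if lam.min() < -1e-8 * lam.max():
        return _fgn_hosking(n, h, rng)
    lam = np.clip(lam, 0.0, None)
    m = lam.size  # 2n - 2
    V = np.empty(m, dtype=complex)
    V[0] = rng.standard_normal()
    V[m // 2] = rng.standard_normal()
    a = rng.standard_normal(m // 2 - 1)
    b = rng.standard_normal(m // 2 - 1)
    V[1:m // 2] = (a + 1j * b) / np.sqrt(2)
    V[m // 2 + 1:] = np.conj(V[1:m // 2][::-1])
    x = np.fft.ifft(np.sqrt(lam) * V) * np.sqrt(m)
    return np.ascontiguousarray(x.real[:n])


def _triangle(t: np.ndarray, freq: float, phase: float) -> np.ndarray:
    # unit triangle wave; its amplitude distribution is uniform on [-1, 1]
    return 2.0 * np.abs(2.0 * ((t * freq + phase) % 1.0) - 1.0) - 1.0


def gen_seizure_record(spec: SyntheticSpec = DEFAULT_SPEC) -> tuple[EEGRecord, EventAnnotation]:
    """Generate one multichannel record plus its ground-truth annotation.

    Per channel the background is fGn at ``h_baseline`` outside
    [t_precursor, t_end) and ``h_precursor`` inside, mean-matched at the
    joints so no artificial DC step is introduced.  The rhythmic discharge
    (ramped in over 1 s) spans precursor through seizure end; the ictal
    amplitude scaling and positive offset apply on [t_onset, t_end), full
    strength on the dominant channel and 0.3x elsewhere.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    i_pre = int(round(spec.t_precursor * spec.fs))
    i_on = int(round(spec.t_onset * spec.fs))
    i_end = int(round(spec.t_end * spec.fs))
    t = np.arange(n) / spec.fs

    ramp_n = max(1, int(round(spec.fs)))
    gate = np.zeros(n)
    gate[i_pre:i_end] = 1.0
    kernel = np.ones(ramp_n) / ramp_n
    gate = np.convolve(gate, kernel, mode="same")

    data = np.empty((spec.n_channels, n))
    for c in range(spec.n_channels):
        segs = [gen_fgn(i_pre, spec.h_baseline, rng=rng),
                gen_fgn(i_end - i_pre, spec.h_precursor, rng=rng)]
        if n - i_end >= 2:
            segs.append(gen_fgn(n - i_end, spec.h_baseline, rng=rng))
        elif n - i_end == 1:
            segs.append(rng.standard_normal(1))
        for k in range(1, len(segs)):  # continuity at the joints
            segs[k] += segs[k - 1][-1] - segs[k][0]
        bg = np.concatenate(segs) * spec.baseline_amp

        dominant = c == spec.dominant_channel
        atten = 1.0 if dominant else 0.3
        # ictal burst amplifies background fluctuations around their local
        # level (not absolute zero, which would also amplify the continuity
        # shift); the rhythmic discharge keeps its own amplitude throughout
        seg = bg[i_on:i_end]
        mu = seg.mean()
        bg[i_on:i_end] = mu + (seg - mu) * (atten * spec.ictal_amp / spec.baseline_amp)
        phase = rng.uniform(0.0, 1.0)
        x = bg + atten * spec.discharge_amp \
            * _triangle(t, spec.discharge_freq_hz, phase) * gate
        x[i_on:i_end] += atten * spec.ictal_offset
        data[c] = x

    rec = EEGRecord(data=data, fs=spec.fs)
    return rec, spec.annotation()


def gen_cohort(n_subjects: int, trials_per_subject: int, lead_values,
               seed: int = 0, base_spec: SyntheticSpec = DEFAULT_SPEC,
               jitter_s: float = 1.0) -> list[list[tuple[EEGRecord, EventAnnotation]]]:
    """Generate ``n_subjects`` groups of seizure records with known lead times.

    Subject ``i`` receives ``trials_per_subject`` records whose precursor
    precedes onset by ``lead_values[i]`` seconds plus a per-trial uniform
    jitter of +/- ``jitter_s`` (trial-to-trial variability around the
    subject-level lead).  Returns records grouped by subject.
    """
    lead_values = list(lead_values)
    if not lead_values:
        raise ValueError("lead_values may not be empty")
    if len(lead_values) != n_subjects:
        raise ValueError("n_subjects must equal len(lead_values)")
    for lv in lead_values:
        if not 0 < lv < base_spec.t_onset:
            raise ValueError("lead values must lie in (0, t_onset)")
    master = np.random.default_rng(seed)
    cohort = []
    for s in range(n_subjects):
        trials = []
        for tr in range(trials_per_subject):
            jit = master.uniform(-jitter_s, jitter_s)
            t_pre = float(np.clip(base_spec.t_onset - (lead_values[s] + jit),
                                  1.0, base_spec.t_onset - 1.0))
            spec = replace(base_spec, t_precursor=t_pre,
                           seed=int(master.integers(0, 2**31 - 1)))
            rec, ann = gen_seizure_record(spec)
            rec.subject_id = f"S{s + 1:03d}"
            rec.trial_id = f"T{tr + 1}"
            trials.append((rec, ann))
        cohort.append(trials)
    return cohort


def stationary_spec(base: SyntheticSpec = DEFAULT_SPEC, seed: int = 0) -> SyntheticSpec:
    """A precursor-free variant: baseline statistics throughout.

    Used for false-alarm calibration; the annotation times are retained but
    mark no actual change in the generated signal.
    """
    return replace(base, h_precursor=base.h_baseline, discharge_amp=0.0,
                   ictal_amp=base.baseline_amp * 1.0001, ictal_offset=0.0,
                   seed=seed)
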