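"""Cohort-level aggregation of precursor lead times.

Trial-level leads are averaged to one value per subject (failed trials —
flagged or absent leads — are excluded and counted), and subject-level
leads are summarised as mean, sample SD, normal-approximation confidence
interval and extremes.  The packaged reference table carries the printed
per-subject lead times (seconds between the precursor sign and seizure
onset, each the average of eight trials) of the 120-subject clinical
cohort this analysis mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = ["CohortSummary", "subject_leads", "summarize_leads", "load_table1"]


@dataclass(frozen=True)
class CohortSummary:
    """Summary statistics of subject-level lead times (seconds)."""

    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    minimum: float
    maximum: float
    confidence: float = 0.95


def subject_leads(trial_leads, flags=None) -> tuple[float | None, int]:
    """Average the valid trial leads of one subject.

    ``trial_leads`` may contain None for absent detections; ``flags``
    optionally marks failures (e.g. negative leads).  Returns
    ``(mean_or_None, n_excluded)``.
    """
    trial_leads = list(trial_leads)
    if flags is None:
        flags = [False] * len(trial_leads)
    valid = [l for l, f in zip(trial_leads, flags)
             if l is not None and not f and l >= 0]
    excluded = len(trial_leads) - len(valid)
    if not valid:
        return None, excluded
    return float(np.mean(valid)), excluded


def summarize_leads(leads, confidence: float = 0.95,
                    interval: str = "normal") -> CohortSummary:
    """Mean, sample SD (divisor n-1), CI and extremes of a set of leads.

    ``interval`` selects the normal approximation (mean +/- z*sd/sqrt(n),
    the default) or the Student-t interval.
    """
    leads = np.asarray(list(leads), dtype=float)
    if leads.size < 2:
        raise ValueError("need at least two leads to summarise")
    mean = float(leads.mean())
    sd = float(leads.std(ddof=1))
    sem = sd / np.sqrt(leads.size)
    if interval == "normal":
        crit = _stats.norm.ppf(0.5 + confidence / 2)
    elif interval == "t":
        crit = _stats.t.ppf(0.5 + confidence / 2, df=leads.size - 1)
    else:
        raise ValueError("interval must be 'normal' or 't'")
    return CohortSummary(n=int(leads.size), mean=mean, sd=sd,
                         ci_low=mean - crit * sem, ci_high=mean + crit * sem,
                         minimum=float(leads.min()), maximum=float(leads.max()),
                         confidence=confidence)


def load_table1() -> pd.Series:
    """Per-subject lead times (s) of the reference 120-subject cohort.

    Returns a Series indexed by subject number 1..120.
    """
    ref = resources.files("preictal.data").joinpath("table1_leads.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if len(df) != 120 or not {"subject", "lead_s"} <= set(df.columns):
        raise RuntimeError("packaged lead table is corrupt")
    s = df.set_index("subject")["lead_s"]
    if not ((s >= 19) & (s <= 35)).all():
        raise RuntimeError("packaged lead table out of range")
    return s
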