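# preictal

Seizure-precursor analysis of EEG records via sliding-window Hurst
exponents and Rényi generalized fractal dimensions.

## The problem

Epileptic seizures often announce themselves in the EEG tens of seconds
before clinical onset: an internal stimulus perturbs the brain's dynamics,
and the statistical character of the signal changes before its amplitude
does.  This package implements a complete, tested pipeline for that
analysis:

1. **Preprocessing** — multichannel plain-text EEG is low-pass filtered at
   35 Hz (zero-phase) and resampled to 35 values per second, so a 3-minute
   record holds 6300 samples per channel; analysis runs on the channel
   with the biggest fluctuations.
2. **Hurst trajectory** — the Hurst exponent *H* ∈ (0, 1) is estimated by
   rescaled-range (R/S) analysis on a 10 s sliding window (step 1 s):
   *H* = slope of log₂⟨R/S⟩ versus log₂(scale), where R/S is the range of
   cumulative mean-adjusted sums over the segment standard deviation.
   Detrended fluctuation analysis (DFA) is provided as an independent
   cross-check.  *H* ≈ 0.9 marks the persistent, long-memory baseline;
   a collapse toward and below 0.5 marks loss of memory.
3. **Fractal-dimension trajectory** — the voltage range is split into bins
   of width δV; the occupancy weights wᵢ give Rényi entropies
   E_q = log₂(Σ wᵢ^q)/(1−q) and generalized dimensions
   ℵ_q = slope of −E_q against log₂ δV over a geometric grid of bin
   sizes (Shannon form at q = 1).  Rising ℵ_q means a more complex,
   less predictable signal.
4. **Detection** — the precursor sign is the first persistent deflection of
   a trajectory beyond baseline ∓ k·(robust noise scale): *downward* in H
   and *upward* in FD, the two deflections confirming each other.  Onset is
   located from the ictal amplitude burst (or taken from annotations), and
   the **lead time** = onset − sign is aggregated per subject and cohort.

No public recordings accompany the original clinical study, so the package
ships a first-class synthetic-data module: segment-wise fractional
Gaussian noise (exact circulant-embedding synthesis) with a rhythmic
preictal discharge and an ictal amplitude burst, generating records and
whole cohorts with known ground truth.  The printed per-subject lead
times of the 120-patient reference cohort are packaged as a CSV fixture.

## Worked example

```python
import preictal as p

rec, ann = p.gen_seizure_record(p.SyntheticSpec(seed=1))  # 24 ch @ 256 Hz
dec = p.lowpass_decimate(rec)                             # 6300 samples @ 35 Hz
res = p.analyze_record(dec, ann)
print(res.t_sign, res.t_sign_fd, res.lead_time, res.concordant)
```

prints

```
51.0 51.0 29.0 True
```

the Hurst trajectory deflects downward at 51 s (baseline H ≈ 0.83
collapsing to ≈ 0.11), the fractal dimension deflects upward at the same
time, and with onset annotated at 80 s the precursor gives a 29-second
warning.  The same walk-through, with the trajectory table written to
`results/`, is `analysis/03_single_record_analysis.py`; the other numbered
scripts under `analysis/` simulate records and cohorts, validate the
estimators against exact fGn, and summarise the reference lead table
(mean 25.77 s, SD 4.32 s, 95 % CI [24.99, 26.54] s, minimum 19 s).

## Layout

```
src/preictal/    library: synthetic, io, hurst, fractal, detection, cohort
analysis/        numbered narrative drivers writing tables to results/
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  models, estimators, parameter choices, limitations
```
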