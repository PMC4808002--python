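# Methods

## Signal model

The package analyses multichannel voltage records (channels × samples,
microvolts) with a sampling-rate header.  The study design it mirrors is a
3-minute record at 256 Hz from a 24-electrode montage, with a pre-seizure
segment, a seizure whose voltage swings roughly −769…+1230 μV on the most
active electrode, and post-seizure recovery.  Preprocessing low-passes at
35 Hz and resamples to 35 values/s (180 s → 6300 samples), the convention
under which every downstream default is stated.

### Synthetic records

Real recordings from the clinical study were never deposited, so the
generator produces records with the statistical structure the analysis
assumes, plus full ground truth:

* **Background**: exact fractional Gaussian noise (fGn), synthesised by
  circulant embedding (Davies–Harte).  The embedding eigenvalues were
  nonnegative for every (n, H) used; a sequential-conditional (Hosking)
  fallback exists for the degenerate case.  Baseline Hurst target 0.9
  (pre-stimulus estimates in the literature sit at 0.90–0.94); precursor
  target 0.3 (post-stimulus values below 0.5).  Baseline amplitude is
  20 μV RMS (≈ ±60 μV peaks, the conventional "50 μV" scalp-EEG scale);
  no value is reported for it in the source cohort, so this is a
  convention, fixed once.
* **Precursor regime** (t_precursor → t_end): fGn switches to the
  precursor Hurst target, and a rhythmic triangular discharge
  (100 μV, 3 Hz, 1 s onset ramp) is superimposed — the synthetic
  counterpart of rhythmic preictal epileptiform activity.  The discharge
  matters for both measures: a strong oscillation flattens the R/S
  scaling (driving estimated H down) and its triangular sweeps have a
  uniform amplitude distribution (flattening the window histogram and
  driving the binned dimension up).  A pure change of H alone provably
  does *not* move the value-distribution dimension: the histogram of a
  window is a marginal quantity, and measured contrast between H = 0.9
  and H = 0.3 Gaussian windows was below one standard deviation for every
  estimator variant tried (orders −5…2, occupation-time weights,
  fixed-scale entropies).  The two deflections the detection stage relies
  on therefore require a precursor that changes the signal's composition,
  not only its memory — which is also the physiological picture.
* **Ictal window** (t_onset → t_end): background fluctuations amplified
  about their local level to 708 μV RMS on the dominant channel (0.3×
  elsewhere) plus a +245 μV offset, calibrated once so the decimated
  dominant-channel range ≈ −769…+1230 μV (asymmetric, as reported).
* **Joints** are continuity-matched (no artificial DC step); segments are
  otherwise independent.  Cohorts draw per-trial precursor jitter of ±1 s
  around each subject's lead value.

What the generator does **not** emulate: physiological rhythms
(alpha/beta), artifacts, electrode geometry, inter-channel correlation,
non-stationary baselines.  Passing tests therefore demonstrate that the
pipeline recovers the statistical signatures it targets under controlled
long-range-dependence changes — not clinical performance on real EEG.

## Hurst estimation

`rs_hurst` fits log₂⟨R/S⟩ against log₂(scale) over ≤12 geometric scales
from 16 to n/2 samples; segment R/S uses the divisor-n standard
deviation.  The minimum scale of 16 (rather than 8) is bias control: the
R/S statistic of very short segments is biased upward, which drags low-H
estimates toward 0.5 — with scales from 16, 50-seed means at n = 8192 are
0.363/0.532/0.712/0.850 for true 0.3/0.5/0.7/0.9.  The classical
small-sample (Anis–Lloyd-type) correction was evaluated and rejected: it
over-corrects at high H.  Estimates outside (0, 1) — possible on trended
windows — are clamped and flagged rather than raised, so trajectories
stay usable.

`dfa_hurst` is standard DFA (order-1 detrend by default) over scales 8 to
n/4; its recovery errors at n = 8192 are ≤ 0.01.  R/S is the default
trajectory method; DFA serves as the cross-check (|R/S − DFA| ≤ 0.15 on
the same series in tests).

Sliding trajectories use a 10 s window and 1 s step (350 samples per
window at 35 Hz — enough scales for a stable fit while resolving the
20–35 s lead times of interest).  Window centres are the reported times;
degenerate (constant) windows yield flagged gaps.  An expanding-window
variant was considered and dropped: time-localised deflections are the
object of interest.

## Fractal dimensions

`bin_probabilities` histograms a series into left-closed bins of width δV
(final bin closed, ties at the maximum land in the last bin); for a
uniformly sampled series the count-based weights equal the time-in-bin
weights, which is the implemented identity.  `renyi_entropy` skips
zero-weight bins at every order, making E_q continuous through q = 1
(Shannon form) and q = 0 (log₂ of occupied bins).  `generalized_dimension`
regresses −E_q on log₂ δV over a geometric grid, by default from
span/2 down to span/256 but never finer than two samples per bin; at
negative q, bins holding fewer than 2 samples are excluded (they dominate
Σw^q and only carry sampling noise).  Verified against a deterministic
binomial-measure series (closed-form spectrum; max |error| ≈ 2·10⁻⁴ for
q ∈ [−5, 5]) and an iid-uniform series (dimension 1).

`sliding_fd` (default order q = 1, the information dimension) uses a
deliberately coarse per-window grid, span/2…span/16: a 350-sample window
cannot populate fine bins, and their occupancy noise was measured to
halve the deflection signal-to-noise ratio relative to the coarse grid.
Window values are floored at 0.

## Detection

`detect_deflection` formalises the visual read-out of a trajectory:

* baseline level = median over the first 20 s of the trajectory;
* noise scale = 1.4826·MAD(lag-ℓ differences)/√2 with ℓ = window/step,
  so differenced pairs share no samples.  The *baseline* MAD of raw
  points, the obvious choice, under-estimates the sampling scale badly
  (90 %-overlapping windows are heavily correlated; measured false-alarm
  rate 37 % instead of ≤5 %).  The scale is evaluated causally — only
  differences whose points lie a full window before the candidate — so
  neither the deflection being tested nor later ictal/recovery level
  changes inflate it;
* a sign requires the trajectory to stay beyond level ∓ k·scale for
  m = window/step + 2 consecutive points (any single-window excursion
  persists for window/step points, so shorter runs are not evidence), and
  is only sought after the baseline period.

k = 4 for the authoritative H (down) channel, calibrated against the
≤5 % false-alarm contract (measured 0/40 stationary records).  The FD
(up) confirmation channel uses k = 3 on logit-transformed values: the
dimension of a one-dimensional value distribution saturates against its
ceiling of 1 exactly where the precursor lands (baseline ≈ 0.87–0.92,
precursor ≈ 0.99), and the logit stretch plus the smaller multiplier
restore the compressed up-side headroom.  H keeps the raw scale — its
deflection lands mid-range, and the logit would instead magnify ordinary
down-side baseline wander.  Concordance means the two signs agree within
2 windows (20 s).

`detect_onset` needs no trajectory: the first time the sliding 1 s
peak-to-peak exceeds 5× the baseline peak-to-peak for 2 s.  Annotated
onsets take precedence so lead-time error isolates precursor detection.
Negative leads are flagged, not raised; cohort summaries count them as
failures.

## Cohort statistics

Subject lead = mean of valid trial leads (flagged/absent trials excluded
and counted).  Cohort summary = mean, sample SD (n−1), normal
95 % CI mean ± z·sd/√n (z from the exact normal quantile; a Student-t
interval is available), minimum and maximum.  The packaged reference
table holds the 120 printed subject leads; because the printed values are
integers while the underlying per-subject averages were not, its mean
matches the printed 25.76 s to ±0.05, not exactly.

## Problem sizes and numerical choices

Estimator validation uses 50 seeds at n = 8192 per H value.  Cohort
evaluations use 30 subjects × 2 trials (true leads uniform on 19…35 s),
40 stationary records for false alarms, and an end-to-end run of 120
subjects × 1 trial driven by the reference lead values; cohort records
carry 4 channels, since channel count only exercises dominant-channel
selection, which is tested separately.  Measured at these sizes: subject
lead MAE ≈ 1.9 s, H/FD concordance ≈ 95–98 %, false alarms 0/40,
end-to-end cohort mean within ≈ 1.3 s of the reference mean.  All
simulations are seeded; identical seeds give bitwise-identical records.

## Known limitations

* The detected sign lags the true changepoint by 1–3 s on average
  (a window must substantially cover the new regime before the threshold
  holds), so recovered leads are biased slightly short; no correction is
  applied.
* Recovery (post-seizure upward H deflection) is detected only sporadically
  at the default 180 s duration — just 20 s of trajectory remain after the
  seizure ends, barely longer than the persistence requirement.
* The value-binning dimension is blind to purely temporal restructuring of
  a Gaussian signal (see above); on real EEG the FD channel carries
  information exactly insofar as preictal activity changes the amplitude
  distribution.
* Hurst estimates on 350-sample windows carry sampling noise of
  σ ≈ 0.07–0.10 and their trajectories wander accordingly; deflections
  smaller than ~0.3 in H are not reliably detectable at these window
  sizes.
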