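#!/usr/bin/env python
"""Simulate example records: one seizure record with the canonical event
times (precursor 50 s, onset 80 s, end 160 s) and one precursor-free
control, written as plain-text EEG plus annotation CSVs."""

import argparse
from pathlib import Path

import numpy as np

import preictal as p


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    # raw records are tens of MB of text; keep them out of the results tables
    ap.add_argument("--out", type=Path, default=Path("scratch/records"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = p.SyntheticSpec(seed=args.seed)
    rec, ann = p.gen_seizure_record(spec)
    p.write_eeg_text(rec, args.out / "seizure_record.txt")
    p.write_annotation_csv(ann, args.out / "seizure_record_events.csv")

    ctrl, _ = p.gen_seizure_record(p.stationary_spec(seed=args.seed + 1))
    p.write_eeg_text(ctrl, args.out / "control_record.txt")

    dom = spec.dominant_channel
    dec = p.lowpass_decimate(rec)
    x = dec.data[dom]
    fs = dec.fs
    ictal = x[int(ann.t_onset * fs):int(ann.t_end * fs)]
    pre = x[:int(ann.t_onset * fs)]
    print(f"seizure record: {rec.n_channels} channels x {rec.n_samples} samples "
          f"@ {rec.fs:g} Hz -> {dec.n_samples} samples @ 35 Hz")
    print(f"dominant channel {dom}: pre-ictal voltage in "
          f"[{pre.min():.0f}, {pre.max():.0f}] uV, "
          f"ictal in [{ictal.min():.0f}, {ictal.max():.0f}] uV "
          f"({np.ptp(ictal) / np.ptp(pre):.1f}x peak-to-peak)")
    print(f"ground truth: precursor {ann.t_precursor:g} s, onset {ann.t_onset:g} s, "
          f"end {ann.t_end:g} s -> files in {args.out}/")


if __name__ == "__main__":
    main()
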