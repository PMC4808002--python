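#!/usr/bin/env python
"""Full single-record walk-through: preprocess the canonical synthetic
seizure record, track sliding-window H and FD, and detect the precursor
sign, onset and lead time."""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import preictal as p


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rec, ann = p.gen_seizure_record(p.SyntheticSpec(seed=args.seed))
    dec = p.lowpass_decimate(rec)
    ch = p.select_dominant_channel(dec)
    traj_h = p.sliding_hurst(dec, ch)
    traj_fd = p.sliding_fd(dec, ch)

    pd.DataFrame({"time_s": traj_h.times, "hurst": traj_h.values,
                  "fd": traj_fd.values}).to_csv(
        args.out / "single_record_trajectories.csv", index=False,
        float_format="%.4f")

    res = p.analyze_record(dec, ann)
    payload = {k: getattr(res, k) for k in
               ("t_sign", "t_sign_fd", "t_onset_detected", "t_recovery",
                "lead_time", "lead_flagged", "concordant")}
    payload["diagnostics"] = res.diagnostics
    (args.out / "single_record_detection.json").write_text(
        json.dumps(payload, indent=2, default=float) + "\n")

    t, vh = traj_h.times, traj_h.values
    base = np.nanmean(vh[t < ann.t_precursor - 5])
    pre = np.nanmean(vh[(t > ann.t_precursor + 5) & (t < ann.t_onset)])
    print(f"dominant channel: {ch}")
    print(f"baseline H ~ {base:.2f}; after the precursor it falls to ~ {pre:.2f}")
    print(f"H sign at {res.t_sign} s, FD sign at {res.t_sign_fd} s "
          f"(concordant: {res.concordant})")
    print(f"onset (annotated) {ann.t_onset:g} s -> lead time {res.lead_time} s; "
          f"recovery deflection at {res.t_recovery} s")
    print(f"outputs -> {args.out}/single_record_trajectories.csv, "
          f"single_record_detection.json")


if __name__ == "__main__":
    main()
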