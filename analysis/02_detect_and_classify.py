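"""Detect respiratory transitions and R waves, then classify every trial.

Runs the full detection-based pipeline on a freshly simulated default cohort
(no intermediate files needed) and reports detection fidelity against the
generator's ground truth before writing the classified trial table to
results/trials.tsv.

Run:  python analysis/02_detect_and_classify.py [--seed 7] [--subjects 36]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cardioresp import synthetic
from cardioresp.classify import build_trial_table
from cardioresp.pipeline import detect_subject

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--subjects", type=int, default=36)
    ap.add_argument("--out", default=str(ROOT / "results"))
    args = ap.parse_args()

    cfg = synthetic.GeneratorConfig(seed=args.seed, n_subjects=args.subjects)
    parts, sens_t, sens_r, prec_r = [], [], [], []
    for data in synthetic.simulate_cohort(cfg, render_signals=True):
        phases, rri = detect_subject(data.flow, data.ecg)
        true_t = np.sort(np.concatenate([data.phases.ei_times, data.phases.ie_times]))
        det_t = np.sort(np.concatenate([phases.ei_times, phases.ie_times]))
        d = np.abs(true_t[:, None] - det_t[None, :])
        sens_t.append((d.min(axis=1) <= 0.03).mean())
        dr = np.abs(data.r_times[:, None] - rri.r_times[None, :])
        sens_r.append((dr.min(axis=1) <= 0.005).mean())
        prec_r.append((dr.min(axis=0) <= 0.005).mean())
        tdf, _ = build_trial_table(data.subject, data.events, phases, rri)
        parts.append(tdf)
        print(f"subject {data.subject:2d}: transition sens {sens_t[-1]:.4f}, "
              f"R sens {sens_r[-1]:.4f}, R prec {prec_r[-1]:.4f}")

    trials = pd.concat(parts, ignore_index=True)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    trials.to_csv(out / "trials.tsv", sep="\t", index=False, float_format="%.6f")
    print(f"\ncohort: transition sensitivity {np.mean(sens_t):.4f} (±30 ms), "
          f"R-wave sensitivity {np.mean(sens_r):.4f} / precision {np.mean(prec_r):.4f} (±5 ms)")
    print(f"wrote {len(trials)} classified trials -> {out/'trials.tsv'}")
    print(trials["condition"].value_counts().to_string())


if __name__ == "__main__":
    main()
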