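"""Simulate the default synthetic cohort and write its raw data layout.

Generates 36 subjects of flow/ECG traces and DMTS event streams with the
default study conditions and writes them under results/data/ (per-subject
flow.tsv, ecg.tsv, events.tsv, truth.json).  With --light only the first two
subjects' signals are written (the full cohort is ~0.5 GB of TSV) while all
event tables are kept.

Run:  python analysis/01_simulate.py [--seed 7] [--light]
"""

import argparse
from pathlib import Path

from cardioresp import synthetic

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default=str(ROOT / "results" / "data"))
    ap.add_argument("--subjects", type=int, default=36)
    ap.add_argument("--blocks", type=int, default=30)
    ap.add_argument("--light", action="store_true",
                    help="write signals for the first 2 subjects only")
    args = ap.parse_args()

    cfg = synthetic.GeneratorConfig(seed=args.seed, n_subjects=args.subjects,
                                    n_blocks=args.blocks)
    out = Path(args.out)
    synthetic.write_config(out, cfg)
    n_written = 0
    for data in synthetic.simulate_cohort(cfg, render_signals=True):
        if args.light and data.subject > 2:
            data.flow = None
            data.ecg = None
        d = synthetic.write_subject(out, data)
        n_written += 1
        print(f"subject {data.subject:2d}: {len(data.events)} test trials -> {d}")
    print(f"\nwrote {n_written} subjects under {out}")
    print("signal sign convention:", synthetic.FLOW_SIGN_CONVENTION)


if __name__ == "__main__":
    main()
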