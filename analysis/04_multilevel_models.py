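"""Windowed random-intercept models of mean reaction time.

Aggregates the classified trials into 15 windows of 2 blocks per subject,
grand-normalises and within-subject centres the variables, and fits the two
random-intercept models (Model 1: EIt-2nd rate; Model 2: IEt-2nd rate; both
with RRI velocity and accuracy).  Writes results/model{1,2}.json and
results/tables.md.

Run:  python analysis/04_multilevel_models.py [--seed 7]
"""

import argparse
import importlib.util
import json
from pathlib import Path

from cardioresp import mlm

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location("group_stats", ROOT / "analysis" / "03_group_stats.py")
_gs = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_gs)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    trials = _gs.load_or_simulate(args.seed)
    agg = mlm.aggregate_windows(trials)
    prepared = mlm.normalize_and_center(agg)
    fits = mlm.fit_models(prepared)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    for mid, f in fits.items():
        with open(out / f"model{mid}.json", "w") as fh:
            json.dump(f.to_dict(), fh, indent=1)
    md = mlm.tables_markdown(fits)
    (out / "tables.md").write_text(md)
    print(md)


if __name__ == "__main__":
    main()
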