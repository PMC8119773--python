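"""Regenerate the bundled dip null-distribution table.

Simulates the dip statistic of uniform samples over a grid of sample sizes
and stores empirical quantiles on the ``dip * sqrt(n)`` scale (the scale on
which the null distribution is closest to size-invariant, which makes the
log-n interpolation between grid rows accurate).  Run from the repository
root:

    python scripts/make_dip_table.py [--reps 5000] [--seed 20240901]
"""

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cytosweep.dip import _dip_sorted  # noqa: E402

N_GRID = [8, 10, 15, 20, 30, 50, 75, 100, 150, 200, 300, 500, 750,
          1000, 1500, 2000, 3000, 5000, 8000, 12000, 20000, 50000]
PROBS = np.concatenate([np.arange(0.01, 1.00, 0.01),
                        [0.995, 0.998, 0.999, 0.9995]])


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=5000)
    ap.add_argument("--seed", type=int, default=20240901)
    ap.add_argument("--out", default="src/cytosweep/_dip_table.csv")
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    rows = []
    for n in N_GRID:
        dips = np.empty(args.reps)
        chunk = max(1, int(2e7) // n)
        done = 0
        while done < args.reps:
            k = min(chunk, args.reps - done)
            u = np.sort(rng.random((k, n)), axis=1)
            for i in range(k):
                dips[done + i] = _dip_sorted(u[i])
            done += k
        q = np.quantile(dips * np.sqrt(n), PROBS)
        rows.append([n] + list(q))
        print(f"n={n:6d}  median sqrt(n)*dip = {np.median(dips)*np.sqrt(n):.4f}",
              flush=True)

    header = "n," + ",".join(f"{p:g}" for p in PROBS)
    np.savetxt(args.out, np.array(rows), delimiter=",", header=header,
               comments="", fmt="%.6g")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
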