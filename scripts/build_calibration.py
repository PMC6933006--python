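"""Rebuild the corruption <-> smoothness calibration fixture.

Simulates strokes of the standard scale task on a corruption grid for
both motion-capture dialects and stores the mean stroke smoothness per
level as a versioned JSON resource inside the package.  Run from the
repository root:

    python scripts/build_calibration.py [--n-traj 25] [--seed 20260101]
"""

import argparse
from pathlib import Path

from moveson.simulate.calibration import (build_calibration,
                                          CALIBRATION_RESOURCE,
                                          write_calibration)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-traj", type=int, default=25,
                    help="trajectories per corruption level and dialect")
    ap.add_argument("--seed", type=int, default=20260101)
    args = ap.parse_args()
    cal = build_calibration(n_traj_per_level=args.n_traj, seed=args.seed)
    out = (Path(__file__).resolve().parents[1]
           / "src" / "moveson" / "data" / CALIBRATION_RESOURCE)
    write_calibration(out, cal)
    for dialect, d in cal["dialects"].items():
        pairs = ", ".join(f"{c:g}:{s:.2f}"
                          for c, s in zip(d["corruption"], d["smoothness"]))
        print(f"{dialect} ({d['n_strokes']} strokes): {pairs}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
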