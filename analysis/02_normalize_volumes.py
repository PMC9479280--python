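#!/usr/bin/env python
"""Normalize ROI volumes for analysis.

Reads the synthetic cohort back through the validating IO layer, converts
each ROI volume to a proportion of the participant's total brain volume,
T-scores each column (mean 50, SD 10) across participants, and writes one
standardized matrix per network under results/normalized/.
"""

from pathlib import Path

import netmdmr as nm

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "normalized"
    out.mkdir(parents=True, exist_ok=True)
    cohort = nm.read_cohort(ROOT / "synthetic" / "cohort.csv")
    for net in ("FPN", "DMN"):
        spec = nm.load_network_spec(net)
        volumes = nm.read_volumes(ROOT / "synthetic" / "volumes.csv", spec)
        coh, vols = nm.align(cohort, volumes)
        tscores = nm.to_tscores(nm.to_proportions(vols, coh))
        tscores.to_csv(out / f"tscores_{net}.csv")
        print(f"{net}: {tscores.shape[0]} participants x {tscores.shape[1]} columns; "
              f"column means 50 +/- {abs(tscores.mean() - 50).max():.2e}, "
              f"SDs 10 +/- {abs(tscores.std(ddof=1) - 10).max():.2e}")
    print(f"wrote standardized matrices to {out}")


if __name__ == "__main__":
    main()
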