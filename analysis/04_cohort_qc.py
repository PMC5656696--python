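#!/usr/bin/env python
"""Young-normal cohort QC: CL statistics, variance ratio, thresholds.

Converts the young controls' observed SUVRs to CL — PiB via the standard
map, FBB via the direct map fitted in 03_calibrate_fbb.py — and reports
per-tracer mean/SD, their SD ratio (relative measurement noise of FBB vs
PiB), and the upper limits of the amyloid-negative range (2*SD and
mean+2*SD variants, rounded to integer CL).
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from centiloid.calibration import (
    STANDARD_PIB_MAP,
    LinearMap,
    apply_map,
    cohort_stats,
    upper_normal_limit,
    variance_ratio,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = pd.read_csv(OUT / "cohort.csv")
    calib = json.loads((OUT / "fbb_calibration.json").read_text())
    direct = LinearMap(
        calib["direct_cl"]["slope"], calib["direct_cl"]["intercept"], "SUVR_FBB", "CL"
    )
    young = df[df.group == "young_control"]
    pib_cl = apply_map(STANDARD_PIB_MAP, young.suvr_pib.to_numpy())
    fbb_cl = apply_map(direct, young.suvr_tracer.to_numpy())
    pib = cohort_stats(pib_cl, "young_control", "PiB")
    fbb = cohort_stats(fbb_cl, "young_control", "FBB")
    ratio = variance_ratio(fbb, pib)
    payload = {
        "n": pib.n,
        "pib": dataclasses.asdict(pib),
        "fbb": dataclasses.asdict(fbb),
        "variance_ratio": ratio,
        "upper_normal_limit_cl": {
            "pib_2sd": upper_normal_limit(pib, include_mean=False),
            "pib_mean_plus_2sd": upper_normal_limit(pib, include_mean=True),
            "fbb_2sd": upper_normal_limit(fbb, include_mean=False),
            "fbb_mean_plus_2sd": upper_normal_limit(fbb, include_mean=True),
        },
    }
    (OUT / "cohort_qc.json").write_text(json.dumps(payload, indent=2) + "\n")

    print(f"young controls (n={pib.n}):")
    print(f"  PiB CL: {pib.mean_cl:+.2f} +/- {pib.sd_cl:.2f}")
    print(f"  FBB CL: {fbb.mean_cl:+.2f} +/- {fbb.sd_cl:.2f}")
    print(f"  SD ratio (FBB/PiB): {ratio:.2f}")
    print(f"  upper normal limit: PiB {payload['upper_normal_limit_cl']['pib_2sd']:.0f} CL, "
          f"FBB {payload['upper_normal_limit_cl']['fbb_2sd']:.0f} CL (2*SD)")


if __name__ == "__main__":
    main()
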