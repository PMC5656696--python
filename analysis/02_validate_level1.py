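#!/usr/bin/env python
"""Level-1 validation of the image-space pipeline.

Builds a bank of small phantom volumes spanning the amyloid range, computes
each one's SUVR with the package's region statistics, converts to CL with
the standard PiB map, and checks the computed CL values against the
generating (reference) CL values with the published gates: R^2 > 0.98,
slope in [0.98, 1.02], intercept in [-2, +2] CL.
"""

import json
from pathlib import Path

import numpy as np

from centiloid.calibration import STANDARD_PIB_MAP, invert_map, validate_level1
from centiloid.suvr import compute_suvr
from centiloid.synthetic import PhantomSpec, generate_phantom

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260102


def main() -> None:
    OUT.mkdir(exist_ok=True)
    to_suvr = invert_map(STANDARD_PIB_MAP)
    reference_cl = np.linspace(-5.0, 120.0, 15)
    computed_cl = []
    for i, cl in enumerate(reference_cl):
        suvr = to_suvr(cl)
        vol, cortex, cereb = generate_phantom(
            PhantomSpec(cortex_uptake=suvr * 1.25, cerebellum_uptake=1.25,
                        noise_sd=0.002, seed=SEED + i)
        )
        rec = compute_suvr(vol, cortex, cereb, f"P{i:02d}", "PiB")
        computed_cl.append(STANDARD_PIB_MAP(rec.suvr))
    report = validate_level1(computed_cl, reference_cl)
    payload = report.as_dict()
    (OUT / "level1_report.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"slope {payload['slope']:.4f}, intercept {payload['intercept']:.3f} CL, "
          f"R^2 {payload['r_squared']:.5f}")
    print(f"pass_overall: {payload['pass_overall']}")
    if not payload["pass_overall"]:
        raise SystemExit("level-1 validation failed")


if __name__ == "__main__":
    main()
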