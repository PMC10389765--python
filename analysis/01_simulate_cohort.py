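"""Simulate the two study cohorts and summarise what was generated.

Generates the default synthetic collection (29 healthy controls, 9
early-stage Parkinson's subjects; seed 42) and tabulates per-subject
quiet-standing sway dispersion and heart-rate baselines for the PRE and
POST phases, confirming the programmed cohort differences before any
feature extraction runs.

Writes results/cohort_summary.csv.
"""

import numpy as np
import pandas as pd

from swaymetrics.session import PhaseLabel
from swaymetrics.synthetic import SynthParams, generate_phase_segments, iter_subjects

SEED = 42
OUT = "results/cohort_summary.csv"


def main() -> None:
    params = SynthParams(seed=SEED)
    rows = []
    for group, idx, subject_id in iter_subjects(params):
        segs = generate_phase_segments(
            params, group, idx, [PhaseLabel.PRE, PhaseLabel.POST],
            modalities=("cop", "hr"))
        for phase in (PhaseLabel.PRE, PhaseLabel.POST):
            cop = segs["cop"][phase].values
            hr = segs["hr"][phase].values
            rows.append({
                "subject": subject_id, "group": group, "phase": str(phase),
                "sway_sd_ml_mm": float(np.std(cop[:, 0])),
                "sway_sd_ap_mm": float(np.std(cop[:, 1])),
                "hr_mean_bpm": float(np.mean(hr)),
            })
    df = pd.DataFrame(rows)
    df.to_csv(OUT, index=False, float_format="%.4f")

    post = df[df["phase"] == "POST"]
    by_group = post.groupby("group")[["sway_sd_ml_mm", "hr_mean_bpm"]].mean()
    print(f"wrote {OUT} ({len(df)} rows, "
          f"{post['subject'].nunique()} subjects)")
    print("\nPOST-phase group means:")
    print(by_group.round(2).to_string())
    print("\nProgrammed directions visible before analysis: healthy sway "
          "dispersion exceeds PD; PD heart rate sits higher and rises "
          "further in POST.")


if __name__ == "__main__":
    import pathlib

    pathlib.Path("results").mkdir(exist_ok=True)
    main()
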