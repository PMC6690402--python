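#!/usr/bin/env python
"""Generate the working synthetic threshold datasets for all four subjects.

The raw study data are not distributed, so every downstream analysis
runs on synthetic thresholds drawn from the published ground-truth
observer presets, with the published per-subject condition counts,
lognormal measurement noise (sigma = 0.10 log10 units) and display-gamut
censoring.  Writes one CSV per subject under results/.
"""

from pathlib import Path

import tcsfield as t

OUT = Path(__file__).resolve().parents[1] / "results"
SEEDS = {"M1": 101, "M2": 102, "H1": 103, "H2": 104}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for subject in t.SUBJECTS:
        obs = t.table2_preset(subject)
        df = t.generate_thresholds(
            obs,
            t.default_design(subject),
            t.NoiseModel(0.10),
            seed=SEEDS[subject],
            subject=subject,
        )
        path = OUT / f"thresholds_{subject}.csv"
        t.thresholds_to_csv(df, path)
        n_cen = int(df.censored.sum())
        print(
            f"{subject}: {len(df)} thresholds at "
            f"{df.groupby(['r_deg', 'phi_rad']).ngroups} locations, "
            f"{n_cen} censored at the gamut edge -> {path.name}"
        )
    print(
        "\nCensoring is concentrated in opponent (red-green) conditions, "
        "where the display gamut is narrowest."
    )


if __name__ == "__main__":
    main()
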