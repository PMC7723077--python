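"""Whole-root Pi uptake from medium depletion.

Groups of 12 Pi-starved seedlings are transferred to 0.5-mL wells of
Pi-replete (0.25 mM) medium; medium Pi is sampled over time, read out as
emission ratios of a low-affinity in vitro converter sensor, inverted to
concentrations, and converted to cumulative nmol Pi per seedling.  Two
genotypes (wild type and the vacuolar sequestration-null mutant) deplete
the medium at the same true rate: vacuolar import does not limit uptake at
the whole-root level.

Writes results/depletion_uptake.csv.
"""
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from rootpi.flux import medium_depletion_uptake
from rootpi.synth.datasets import make_calibration_dataset, make_depletion_series
from rootpi.synth.sensor import IN_VITRO_SENSOR
from rootpi.calibration import fit_isotherm

OUT = Path(__file__).resolve().parents[1] / "results"

RATE_NMOL_PER_SEEDLING_H = 1.5


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    cal, _ = make_calibration_dataset(
        IN_VITRO_SENSOR, [0.0, 0.02, 0.05, 0.08, 0.15, 0.3], 8, 0.01, seed=seed
    )
    fit = fit_isotherm(cal)
    print(f"in vitro converter fit: Kd = {1000 * fit.kd:.0f} µM")

    frames = []
    finals = {}
    for i, genotype in enumerate(("WT", "sequestration-null")):
        table, _ = make_depletion_series(
            uptake_rate_nmol_per_seedling_h=RATE_NMOL_PER_SEEDLING_H,
            n_wells=4, noise_sd_ratio=0.01, seed=seed + 100 + i,
        )
        series = medium_depletion_uptake(
            table.drop(columns="concentration_mM"), fit, 0.5, 12
        )
        finals[genotype] = series.cumulative_uptake.iloc[-1].to_numpy()
        frames.append(pd.DataFrame({
            "genotype": genotype,
            "time_h": series.time,
            "uptake_nmol_per_seedling": series.mean_uptake,
            "sd": series.sd_uptake,
        }))
        print(f"  {genotype}: {series.mean_uptake[-1]:.1f} ± "
              f"{series.sd_uptake[-1]:.1f} nmol/seedling after "
              f"{series.time[-1]:.0f} h "
              f"(true rate {RATE_NMOL_PER_SEEDLING_H} nmol/seedling/h)")
    pd.concat(frames).to_csv(OUT / "depletion_uptake.csv", index=False)

    stat, p = ttest_ind(finals["WT"], finals["sequestration-null"])
    print(f"genotype difference in final uptake: t = {stat:.2f}, p = {p:.2f} "
          f"({'not ' if p > 0.05 else ''}significant)")


if __name__ == "__main__":
    main()
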