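#!/usr/bin/env python
"""Safety margins and the worst-case lossless heating budget.

Compares the exposure fluxes of the calibration ladder against the
general-public RF reference levels at 1800 MHz, checks the far-field
distance bound of the patch antenna, and evaluates the lossless thermal
budget for a water-filled and a kidney-tissue-filled dish.  Writes
``results/safety_margins.csv``.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rfdosim import dosimetry as dm
from rfdosim import thermal as th
from rfdosim.datasets import published_calibration, published_ladder

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = dm.build_exposure_table(published_ladder(), published_calibration())
    lim = dm.icnirp_limits(1800.0)
    print(f"reference levels @ 1800 MHz: E_max={lim.e_max_v_per_m:.3f} V/m, "
          f"H_max={lim.h_max_a_per_m:.5f} A/m, P_max={lim.p_emg_max_w_per_m2:.1f} W/m^2")

    table = table.dropna().copy()
    table["margin"] = [dm.exposure_margin(p, lim) for p in table["p_emg_w_per_m2"]]
    table.to_csv(OUT / "safety_margins.csv", index=False)
    print(f"largest exposure uses {table['margin'].max():.2e} of the power-flux "
          "reference level — orders of magnitude below the limit")

    d = dm.min_farfield_distance(dm.AntennaGeometry(0.055, wavelength_m=0.165))
    print(f"far-field bound for the 5.5 cm patch at lambda=16.5 cm: "
          f"{d * 100:.2f} cm (sample sits at 16.8 cm: far-field holds)")

    budgets = {}
    for label, cap in (("water", th.WATER_HEAT_CAPACITY_WH_M3K),
                       ("kidney_tissue", th.KIDNEY_HEAT_CAPACITY_WH_M3K)):
        dt = th.delta_t_budget(th.ThermalBudget(
            dish_diameter_m=0.053, incident_power_w_per_m2=1.1e-2,
            duration_h=0.25, heat_capacity_wh_per_m3k=cap, volume_m3=4.5e-6))
        budgets[label] = dt
        print(f"lossless 15-min budget at the peak flux, {label}: {dt:.3e} K")
    (OUT / "thermal_budget.json").write_text(json.dumps(budgets, indent=2))
    print("even the lossless worst case is a millikelvin-scale rise: RF "
          "heating cannot explain any observed response")


if __name__ == "__main__":
    main()
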