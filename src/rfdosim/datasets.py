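"""Published calibration ladder of the exposure system.

The bench characterization swept the generator output from +20 dBm down
to −40 dBm and recorded the spectrum-analyzer reading at each rung (the
−40 dBm rung fell below the −75 dBm sensitivity floor).  The published
E-field and power-flux values are retained alongside, at their printed
precision (2 significant figures; the +20 dBm E cell at 3), so the
chain can be checked against them.
"""

from __future__ import annotations

from typing import List

import numpy as np
import pandas as pd

from .dosimetry import CalibrationConstants, ProbeMeasurement

_P_GENE_DBM = [20, 10, 5, 0, -5, -10, -15, -20, -30, -40]
_P_MES_DBM = [-29.8, -35.5, -40.0, -45.5, -50.0, -55.5, -60.3, -65.5, -72.0, None]
_E_PRINTED = [2.05, 1.06, 6.3e-1, 3.3e-1, 2e-1, 1.1e-1, 6.1e-2, 3.3e-2, 1.6e-2, None]
_PEMG_PRINTED = [1.1e-2, 2.9e-3, 1.1e-3, 2.9e-4, 1.1e-4, 2.9e-5, 9.8e-6, 2.9e-6,
                 6.6e-7, None]


def published_calibration() -> CalibrationConstants:
    """Calibration constants of the physical chain at 1.77 GHz."""
    return CalibrationConstants()


def published_ladder() -> List[ProbeMeasurement]:
    """The x-axis calibration ladder as probe measurements."""
    return [ProbeMeasurement(generator_power_dbm=float(pg), axis="x",
                             measured_power_dbm=pm, frequency_hz=1.77e9)
            for pg, pm in zip(_P_GENE_DBM, _P_MES_DBM)]


def published_ladder_table() -> pd.DataFrame:
    """The ladder with its published E and P_EMG cells (printed precision)."""
    return pd.DataFrame({
        "p_gene_dbm": _P_GENE_DBM,
        "p_mes_dbm": [np.nan if v is None else v for v in _P_MES_DBM],
        "e_printed_v_per_m": [np.nan if v is None else v for v in _E_PRINTED],
        "p_emg_printed_w_per_m2": [np.nan if v is None else v for v in _PEMG_PRINTED],
    })
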