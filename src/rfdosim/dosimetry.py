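"""Probe-to-power dosimetry chain and field-validity statistics.

A dipole electric-field probe inside the exposure box feeds a spectrum
analyzer through an SMA cable.  The analyzer reads an electrical power
``P_MES`` in dBm; converting that reading into the incident plane-wave
power flux at the sample position is a four-step chain:

    P_ELEC = P_MES / A_CABLE          (undo the cable attenuation)
    U_ELEC = sqrt(P_ELEC * Z0)        (RMS voltage at the probe port)
    E      = AF * U_ELEC              (antenna factor -> field amplitude)
    P_EMG  = E**2 / eta0              (plane-wave power flux, W/m^2)

The last step is only valid for a locally plane wave, which is why the
module also provides the field-map statistics used to check that
assumption: power inhomogeneity over the Petri-dish footprint, the
polarization ratios of the mean field components, and the ratio of the
plane-wave flux estimate to the full Poynting-vector flux.

Unit discipline: absolute powers are dBm (or watts), gains/attenuations
are dB (relative).  Readings below the analyzer's sensitivity floor are
carried as a typed below-floor flag, never as fabricated numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Propagation speed used for wavelength from frequency, m/s.
AIR_PROPAGATION_SPEED = 2.998e8


# ---------------------------------------------------------------------------
# scalar power conversions
# ---------------------------------------------------------------------------

def dbm_to_watt(p_dbm: float) -> float:
    """Convert an absolute power in dBm to watts: 10**(p/10)/1000."""
    if not math.isfinite(p_dbm):
        raise ValueError(f"power in dBm must be finite, got {p_dbm!r}")
    return 10.0 ** (p_dbm / 10.0) / 1000.0


def watt_to_dbm(p_w: float) -> float:
    """Convert an absolute power in watts to dBm.  Requires p_w > 0."""
    if not (p_w > 0):
        raise ValueError(f"power must be strictly positive, got {p_w!r}")
    return 10.0 * math.log10(p_w * 1000.0)


def attenuation_db_to_coeff(att_db: float) -> float:
    """Linear power coefficient of a relative gain/attenuation in dB."""
    return 10.0 ** (att_db / 10.0)


# ---------------------------------------------------------------------------
# calibration and measurement records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationConstants:
    """Constants of the probe/analyzer measurement chain.

    Defaults are the calibrated values of the physical chain at 1.77 GHz:
    cable S12 attenuation -3.896 dB (linear coefficient 0.40776), probe
    antenna factor 179.89 1/m, 50 ohm SMA port, ~377 ohm air wave
    impedance, -75 dBm analyzer sensitivity floor.
    """

    cable_attenuation_db: float = -3.896
    antenna_factor_per_m: float = 179.89
    port_impedance_ohm: float = 50.0
    wave_impedance_ohm: float = 377.0
    sensitivity_floor_dbm: float = -75.0

    def __post_init__(self) -> None:
        if self.cable_attenuation_db > 0:
            raise ValueError("a passive cable attenuates: attenuation_db must be <= 0")
        if self.antenna_factor_per_m <= 0:
            raise ValueError("antenna factor must be positive")
        if self.port_impedance_ohm <= 0 or self.wave_impedance_ohm <= 0:
            raise ValueError("impedances must be positive")

    @property
    def a_cable(self) -> float:
        """Linear cable power coefficient, 10**(attenuation_db/10), in (0, 1]."""
        return attenuation_db_to_coeff(self.cable_attenuation_db)

    @classmethod
    def from_linear_attenuation(cls, a_cable: float, **kwargs) -> "CalibrationConstants":
        """Build from a linear cable coefficient instead of dB."""
        if not (0 < a_cable <= 1):
            raise ValueError("linear cable coefficient must be in (0, 1]")
        return cls(cable_attenuation_db=10.0 * math.log10(a_cable), **kwargs)


class BelowFloor:
    """Marker for a reading at/below the analyzer's sensitivity floor."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "BelowFloor()"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BelowFloor)

    def __hash__(self) -> int:
        return hash(BelowFloor)


#: Shared below-floor sentinel.
BELOW_FLOOR = BelowFloor()

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class ProbeMeasurement:
    """One rung of a probe ladder.

    ``measured_power_dbm`` is ``None`` when the analyzer showed nothing
    above its sensitivity floor.
    """

    generator_power_dbm: float
    axis: str = "x"
    measured_power_dbm: Optional[float] = None
    frequency_hz: float = 1.77e9

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}, got {self.axis!r}")
        if self.measured_power_dbm is not None and not math.isfinite(self.measured_power_dbm):
            raise ValueError("measured power must be finite or None (below floor)")


@dataclass(frozen=True)
class FieldEstimate:
    """Chain outputs for one measurement: P_ELEC, U_ELEC, E, P_EMG."""

    p_elec_w: float
    u_elec_v: float
    e_field_v_per_m: float
    p_emg_w_per_m2: float


def probe_chain(measurement: ProbeMeasurement, cal: CalibrationConstants):
    """Run the dosimetry chain on one measurement.

    Returns a :class:`FieldEstimate`, or :data:`BELOW_FLOOR` when the
    reading is absent or below the sensitivity floor.
    """
    p_mes_dbm = measurement.measured_power_dbm
    if p_mes_dbm is None or p_mes_dbm < cal.sensitivity_floor_dbm:
        return BELOW_FLOOR
    p_mes_w = dbm_to_watt(p_mes_dbm)
    p_elec = p_mes_w / cal.a_cable
    u_elec = math.sqrt(p_elec * cal.port_impedance_ohm)
    e_field = cal.antenna_factor_per_m * u_elec
    p_emg = e_field ** 2 / cal.wave_impedance_ohm
    return FieldEstimate(p_elec_w=p_elec, u_elec_v=u_elec,
                         e_field_v_per_m=e_field, p_emg_w_per_m2=p_emg)


def build_exposure_table(ladder: Sequence[ProbeMeasurement],
                         cal: CalibrationConstants) -> pd.DataFrame:
    """Tabulate a ladder of generator/probe readings through the chain.

    Returns one row per rung, sorted by descending generator power, with
    columns ``p_gene_dbm, axis, p_mes_dbm, e_v_per_m, p_emg_w_per_m2``.
    Below-floor rungs carry NaN in the derived columns (rendered as
    ``---`` by the CSV writer).
    """
    if len(ladder) == 0:
        raise ValueError("ladder must be non-empty")
    keys = [(m.generator_power_dbm, m.axis) for m in ladder]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (generator power, axis) rungs: {dupes}")
    rows = []
    for m in sorted(ladder, key=lambda m: -m.generator_power_dbm):
        est = probe_chain(m, cal)
        if isinstance(est, BelowFloor):
            rows.append((m.generator_power_dbm, m.axis, np.nan, np.nan, np.nan))
        else:
            rows.append((m.generator_power_dbm, m.axis, m.measured_power_dbm,
                         est.e_field_v_per_m, est.p_emg_w_per_m2))
    return pd.DataFrame(rows, columns=["p_gene_dbm", "axis", "p_mes_dbm",
                                       "e_v_per_m", "p_emg_w_per_m2"])


# ---------------------------------------------------------------------------
# geometry and safety limits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AntennaGeometry:
    """Source size and wavelength for the far-field distance bound."""

    source_diagonal_m: float
    frequency_hz: Optional[float] = None
    wavelength_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source_diagonal_m <= 0:
            raise ValueError("source diagonal must be positive")
        if self.wavelength_m is None:
            if self.frequency_hz is None or self.frequency_hz <= 0:
                raise ValueError("need a positive frequency or an explicit wavelength")
            object.__setattr__(self, "wavelength_m",
                               AIR_PROPAGATION_SPEED / self.frequency_hz)
        elif self.wavelength_m <= 0:
            raise ValueError("wavelength must be positive")


def min_farfield_distance(geom: AntennaGeometry) -> float:
    """Minimum far-field distance 2*D**2/lambda in meters."""
    return 2.0 * geom.source_diagonal_m ** 2 / geom.wavelength_m


@dataclass(frozen=True)
class SafetyLimits:
    """General-public RF reference levels (whole body, 30 min average)."""

    f_mhz: float
    e_max_v_per_m: float
    h_max_a_per_m: float
    p_emg_max_w_per_m2: float


def icnirp_limits(f_mhz: float) -> SafetyLimits:
    """General-public reference levels for 400-2000 MHz.

    E_max = 1.375*sqrt(f_MHz) V/m, H_max = 0.0037*sqrt(f_MHz) A/m,
    P_max = f_MHz/200 W/m^2.  Frequencies outside the 400-2000 MHz
    validity band raise instead of extrapolating silently.
    """
    if not (400.0 <= f_mhz <= 2000.0):
        raise ValueError(
            f"reference-level formulas are valid for 400-2000 MHz only, got {f_mhz} MHz")
    root = math.sqrt(f_mhz)
    return SafetyLimits(f_mhz=f_mhz,
                        e_max_v_per_m=1.375 * root,
                        h_max_a_per_m=0.0037 * root,
                        p_emg_max_w_per_m2=f_mhz / 200.0)


def exposure_margin(p_emg_w_per_m2: float, limits: SafetyLimits) -> float:
    """Fraction of the power-flux reference level used: P_EMG / P_max."""
    if p_emg_w_per_m2 < 0:
        raise ValueError("power flux must be >= 0")
    return p_emg_w_per_m2 / limits.p_emg_max_w_per_m2


# ---------------------------------------------------------------------------
# gridded field maps and validity statistics
# ---------------------------------------------------------------------------

@dataclass
class FieldMap:
    """Gridded field over the sample plane, 1 mm pixels by default.

    ``power_grid`` holds the power flux per pixel (W/m^2).
    ``e_components`` / ``h_components`` hold complex (ny, nx, 3) field
    component arrays.  The Petri mask selects pixel centers strictly
    inside the dish circle (diameter 0.052 m by default) centered on
    ``petri_center`` (grid center if omitted, in pixel coordinates
    (row, col)).
    """

    power_grid: Optional[np.ndarray] = None
    e_components: Optional[np.ndarray] = None
    h_components: Optional[np.ndarray] = None
    pixel_size_m: float = 1e-3
    petri_center: Optional[tuple] = None
    petri_diameter_m: float = 0.052

    def __post_init__(self) -> None:
        if self.power_grid is None and self.e_components is None:
            raise ValueError("a field map needs a power grid or E components")
        if self.power_grid is not None:
            self.power_grid = np.asarray(self.power_grid, dtype=float)
            if np.any(self.power_grid < 0):
                raise ValueError("power grid values must be >= 0")
        if self.e_components is not None:
            self.e_components = np.asarray(self.e_components, dtype=complex)
            if self.e_components.ndim != 3 or self.e_components.shape[2] != 3:
                raise ValueError("E components must have shape (ny, nx, 3)")
        if self.h_components is not None:
            self.h_components = np.asarray(self.h_components, dtype=complex)
            if self.h_components.shape != self.e_components.shape:
                raise ValueError("H components must match the E component grid")

    @property
    def shape(self) -> tuple:
        grid = self.power_grid if self.power_grid is not None else self.e_components[..., 0]
        return grid.shape

    def petri_mask(self) -> np.ndarray:
        """Boolean mask of pixel centers strictly inside the dish circle."""
        ny, nx = self.shape
        cy, cx = self.petri_center if self.petri_center is not None else ((ny - 1) / 2.0,
                                                                          (nx - 1) / 2.0)
        yy, xx = np.mgrid[0:ny, 0:nx]
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * self.pixel_size_m ** 2
        return r2 < (self.petri_diameter_m / 2.0) ** 2


def inhomogeneity_percent(fmap: FieldMap) -> float:
    """Power inhomogeneity 100*sigma/mean over the Petri mask.

    Uses the population standard deviation (the masked pixels are the
    whole population of interest); scale-invariant by construction.
    """
    if fmap.power_grid is None:
        raise ValueError("inhomogeneity needs a power grid")
    mask = fmap.petri_mask()
    vals = fmap.power_grid[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 pixels inside the Petri mask")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("all-zero power inside the mask: inhomogeneity undefined")
    return 100.0 * vals.std(ddof=0) / mean


def polarization_ratios(fmap: FieldMap) -> tuple:
    """(mean|Ez|/mean|Ex|, mean|Ey|/mean|Ex|) over the Petri mask."""
    if fmap.e_components is None:
        raise ValueError("polarization ratios need E components")
    mask = fmap.petri_mask()
    mags = np.abs(fmap.e_components[mask])  # (npix, 3)
    ex_bar, ey_bar, ez_bar = mags.mean(axis=0)
    if ex_bar == 0:
        raise ValueError("mean |Ex| is zero: polarization ratios undefined")
    return (ez_bar / ex_bar, ey_bar / ex_bar)


def plane_wave_ratio(fmap: FieldMap, wave_impedance_ohm: float = 377.0) -> float:
    """Plane-wave flux estimate over the true Poynting flux, mask-averaged.

    Numerator: mean of |E|^2/(2*eta) per pixel.  Denominator: mean of
    |Re(E x H*/2)| per pixel.  Equals 1 exactly for an ideal plane wave
    with H = z x E / eta.  Raises if H is absent rather than silently
    assuming a plane wave.
    """
    if fmap.e_components is None:
        raise ValueError("plane-wave ratio needs E components")
    if fmap.h_components is None:
        raise ValueError("cannot evaluate the Poynting flux: H components are missing")
    mask = fmap.petri_mask()
    e = fmap.e_components[mask]
    h = fmap.h_components[mask]
    p_plane = (np.abs(e) ** 2).sum(axis=1) / (2.0 * wave_impedance_ohm)
    s = 0.5 * np.cross(e, np.conj(h))
    p_poynting = np.linalg.norm(np.real(s), axis=1)
    denom = p_poynting.mean()
    if denom == 0:
        raise ValueError("zero mean Poynting flux over the mask")
    return p_plane.mean() / denom
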