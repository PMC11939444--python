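"""Dosimetry chain, safety limits and field-map statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfdosim import dosimetry as dm
from rfdosim.dosimetry import (BELOW_FLOOR, AntennaGeometry, BelowFloor,
                               CalibrationConstants, FieldMap,
                               ProbeMeasurement)


# ---------------------------------------------------------------- conversions

@pytest.mark.parametrize("dbm, watt", [(0.0, 1e-3), (10.0, 1e-2), (30.0, 1.0),
                                       (-75.0, 3.1623e-11)])
def test_dbm_watt_definitions(dbm, watt):
    assert dm.dbm_to_watt(dbm) == pytest.approx(watt, rel=1e-4)
    assert dm.watt_to_dbm(watt) == pytest.approx(dbm, abs=1e-3)


@settings(max_examples=200, derandomize=True)
@given(st.floats(min_value=-100.0, max_value=40.0))
def test_dbm_watt_round_trip(p_dbm):
    assert dm.watt_to_dbm(dm.dbm_to_watt(p_dbm)) == pytest.approx(p_dbm, rel=1e-12,
                                                                  abs=1e-10)


def test_dbm_rejects_non_finite():
    with pytest.raises(ValueError):
        dm.dbm_to_watt(float("nan"))
    with pytest.raises(ValueError):
        dm.watt_to_dbm(0.0)
    with pytest.raises(ValueError):
        dm.watt_to_dbm(-1.0)


@pytest.mark.parametrize("db, coeff", [(-3.896, 0.40776), (0.0, 1.0), (-10.0, 0.1)])
def test_attenuation_coefficient(db, coeff):
    assert dm.attenuation_db_to_coeff(db) == pytest.approx(coeff, rel=5e-5)


# ---------------------------------------------------------------- probe chain

def test_probe_chain_oracle(cal):
    """Hand-evaluated chain at -35.5 dBm: each intermediate matches."""
    est = dm.probe_chain(ProbeMeasurement(10.0, "x", -35.5), cal)
    p_mes = 10 ** (-35.5 / 10) / 1000
    p_elec = p_mes / cal.a_cable
    u = math.sqrt(p_elec * 50.0)
    e = 179.89 * u
    assert est.p_elec_w == pytest.approx(p_elec, rel=1e-12)
    assert est.u_elec_v == pytest.approx(u, rel=1e-12)
    assert est.e_field_v_per_m == pytest.approx(e, rel=1e-12)
    assert est.p_emg_w_per_m2 == pytest.approx(e ** 2 / 377.0, rel=1e-12)
    # internal consistency invariants
    assert est.p_emg_w_per_m2 * 377.0 == pytest.approx(est.e_field_v_per_m ** 2)
    assert est.u_elec_v ** 2 == pytest.approx(est.p_elec_w * 50.0)


@pytest.mark.parametrize("p_mes, p_emg", [(-35.5, 2.9e-3), (-72.0, 6.6e-7),
                                          (-75.0, 3.3e-7)])
def test_probe_chain_published_fluxes(cal, p_mes, p_emg):
    est = dm.probe_chain(ProbeMeasurement(0.0, "x", p_mes), cal)
    assert est.p_emg_w_per_m2 == pytest.approx(p_emg, rel=0.05)


def test_probe_chain_below_floor(cal):
    assert dm.probe_chain(ProbeMeasurement(-40.0, "x", None), cal) == BELOW_FLOOR
    assert isinstance(dm.probe_chain(ProbeMeasurement(-40.0, "x", -80.0), cal),
                      BelowFloor)


@settings(max_examples=50, derandomize=True)
@given(st.floats(min_value=-70.0, max_value=0.0))
def test_chain_linearity_in_db(p_mes):
    """A +10 dB shift in P_MES multiplies P_EMG by exactly 10."""
    cal = CalibrationConstants()
    lo = dm.probe_chain(ProbeMeasurement(0.0, "x", p_mes), cal)
    hi = dm.probe_chain(ProbeMeasurement(0.0, "x", p_mes + 10.0), cal)
    assert hi.p_emg_w_per_m2 == pytest.approx(10.0 * lo.p_emg_w_per_m2, rel=1e-9)


# ------------------------------------------------------------ exposure tables

def test_exposure_table_structure(cal, ladder):
    tbl = dm.build_exposure_table(ladder, cal)
    assert list(tbl["p_gene_dbm"]) == sorted(tbl["p_gene_dbm"], reverse=True)
    below = tbl[tbl["p_gene_dbm"] == -40]
    assert below["p_emg_w_per_m2"].isna().all()
    assert tbl["p_emg_w_per_m2"].dropna().gt(0).all()


def test_exposure_table_shift_linearity(cal, ladder):
    shifted = [ProbeMeasurement(m.generator_power_dbm, m.axis,
                                None if m.measured_power_dbm is None
                                else m.measured_power_dbm + 10.0)
               for m in ladder]
    base = dm.build_exposure_table(ladder, cal)["p_emg_w_per_m2"]
    up = dm.build_exposure_table(shifted, cal)["p_emg_w_per_m2"]
    np.testing.assert_allclose(up.dropna(), 10.0 * base.dropna(), rtol=1e-9)


def test_exposure_table_rejects_duplicates(cal):
    rungs = [ProbeMeasurement(0.0, "x", -45.5), ProbeMeasurement(0.0, "x", -45.0)]
    with pytest.raises(ValueError, match="duplicate"):
        dm.build_exposure_table(rungs, cal)


def test_single_rung_at_floor(cal):
    tbl = dm.build_exposure_table([ProbeMeasurement(-40.0, "x", None)], cal)
    assert len(tbl) == 1
    assert tbl["p_emg_w_per_m2"].isna().all()


# ------------------------------------------------------- geometry and safety

def test_min_farfield_published_bound():
    geom = AntennaGeometry(source_diagonal_m=0.055, wavelength_m=0.165)
    d = dm.min_farfield_distance(geom)
    assert d == pytest.approx(0.036667, rel=1e-3)
    assert d > 0.036


def test_farfield_quadratic_in_diagonal():
    d1 = dm.min_farfield_distance(AntennaGeometry(0.05, wavelength_m=0.165))
    d2 = dm.min_farfield_distance(AntennaGeometry(0.10, wavelength_m=0.165))
    assert d2 == pytest.approx(4.0 * d1)
    with pytest.raises(ValueError):
        AntennaGeometry(0.0, wavelength_m=0.165)


def test_wavelength_from_frequency():
    geom = AntennaGeometry(0.055, frequency_hz=1.8e9)
    assert geom.wavelength_m == pytest.approx(2.998e8 / 1.8e9)


def test_icnirp_limits_published():
    lim = dm.icnirp_limits(1800.0)
    assert lim.e_max_v_per_m == pytest.approx(58.336, abs=5e-4)
    assert lim.h_max_a_per_m == pytest.approx(0.15698, abs=5e-6)
    assert lim.p_emg_max_w_per_m2 == pytest.approx(9.0)
    assert dm.icnirp_limits(400.0).e_max_v_per_m == pytest.approx(27.5)


@pytest.mark.parametrize("f", [399.9, 2001.0, 0.0])
def test_icnirp_out_of_band_raises(f):
    with pytest.raises(ValueError, match="400-2000"):
        dm.icnirp_limits(f)


def test_exposure_margin():
    lim = dm.icnirp_limits(1800.0)
    assert dm.exposure_margin(9.0, lim) == pytest.approx(1.0)
    assert dm.exposure_margin(0.0, lim) == 0.0
    assert dm.exposure_margin(2.9e-3, lim) == pytest.approx(3.22e-4, rel=1e-2)


# ------------------------------------------------------- field-map statistics

def _tiny_map(power):
    return FieldMap(power_grid=np.asarray(power, dtype=float),
                    petri_diameter_m=1.0)  # mask covers every pixel


def test_inhomogeneity_two_pixel_oracle():
    assert dm.inhomogeneity_percent(_tiny_map([[1.0, 3.0]])) == pytest.approx(50.0)


def test_inhomogeneity_uniform_and_errors():
    assert dm.inhomogeneity_percent(_tiny_map(np.ones((4, 4)))) == 0.0
    with pytest.raises(ValueError):
        dm.inhomogeneity_percent(_tiny_map(np.zeros((4, 4))))


def test_inhomogeneity_16_pixel_oracle():
    vals = np.arange(1.0, 17.0).reshape(4, 4)
    masked = vals.ravel()
    expected = 100.0 * masked.std(ddof=0) / masked.mean()
    assert dm.inhomogeneity_percent(_tiny_map(vals)) == pytest.approx(expected)


@settings(max_examples=50, derandomize=True)
@given(st.floats(min_value=1e-6, max_value=1e6))
def test_inhomogeneity_scale_invariance(k):
    grid = np.array([[1.0, 2.0], [3.0, 5.0]])
    assert dm.inhomogeneity_percent(_tiny_map(grid * k)) == pytest.approx(
        dm.inhomogeneity_percent(_tiny_map(grid)), rel=1e-9)


def _component_map(ex, ratio_z=0.0, ratio_y=0.0, h_scale=None):
    ny, nx = ex.shape
    e = np.zeros((ny, nx, 3), dtype=complex)
    e[..., 0] = ex
    e[..., 1] = ratio_y * ex
    e[..., 2] = ratio_z * ex
    h = None
    if h_scale is not None:
        zhat = np.array([0.0, 0.0, 1.0])
        h = np.cross(np.broadcast_to(zhat, e.shape), e) / (377.0 * h_scale)
    return FieldMap(power_grid=(np.abs(e) ** 2).sum(axis=2) / (2 * 377.0),
                    e_components=e, h_components=h, petri_diameter_m=1.0)


def test_polarization_pure_x_and_constructed():
    ex = np.ones((3, 3))
    assert dm.polarization_ratios(_component_map(ex)) == (0.0, 0.0)
    rz, ry = dm.polarization_ratios(_component_map(ex, 0.053, 0.015))
    assert rz == pytest.approx(0.053)
    assert ry == pytest.approx(0.015)
    iso = dm.polarization_ratios(_component_map(ex, 1.0, 1.0))
    assert iso == (pytest.approx(1.0), pytest.approx(1.0))


def test_polarization_zero_ex_raises():
    e = np.zeros((2, 2, 3), dtype=complex)
    e[..., 1] = 1.0
    fmap = FieldMap(e_components=e, petri_diameter_m=1.0)
    with pytest.raises(ValueError, match="Ex"):
        dm.polarization_ratios(fmap)


def test_plane_wave_ratio_identity_and_scale():
    ex = np.array([[1.0, 2.0], [0.5, 1.5]])
    assert dm.plane_wave_ratio(_component_map(ex, h_scale=1.0)) == pytest.approx(
        1.0, abs=1e-12)
    assert dm.plane_wave_ratio(_component_map(ex, h_scale=1.01)) == pytest.approx(
        1.01, abs=1e-12)


def test_plane_wave_ratio_standing_wave():
    """Counter-propagating waves: E doubles at the antinode while the net
    Poynting flux drops, so the plane-wave estimate over-reads (ratio != 1).
    Both sides computed by brute force on the constructed two-wave field."""
    ny = nx = 2
    e = np.zeros((ny, nx, 3), dtype=complex)
    h = np.zeros((ny, nx, 3), dtype=complex)
    a, b = 1.0, 0.5  # forward / backward amplitudes at this plane
    e[..., 0] = a + b
    h[..., 1] = (a - b) / 377.0
    fmap = FieldMap(power_grid=np.abs(e[..., 0]) ** 2 / (2 * 377.0),
                    e_components=e, h_components=h, petri_diameter_m=1.0)
    expected = (a + b) ** 2 / ((a + b) * (a - b))
    assert dm.plane_wave_ratio(fmap) == pytest.approx(expected)
    assert dm.plane_wave_ratio(fmap) != pytest.approx(1.0, abs=0.1)


def test_plane_wave_ratio_requires_h():
    fmap = _component_map(np.ones((2, 2)))
    with pytest.raises(ValueError, match="[Hh] components"):
        dm.plane_wave_ratio(fmap)


def test_petri_mask_strictly_inside():
    fmap = FieldMap(power_grid=np.ones((60, 60)))
    mask = fmap.petri_mask()
    # pixel centers strictly inside a 52 mm circle on a 1 mm grid
    assert 0 < mask.sum() < 60 * 60
    yy, xx = np.mgrid[0:60, 0:60]
    r = np.hypot(yy - 29.5, xx - 29.5) * 1e-3
    assert (mask == (r < 0.026)).all()
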