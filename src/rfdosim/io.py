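"""File formats, input validation and the end-to-end pipeline run.

All tabular interchange is comma-separated UTF-8 CSV with a mandatory
header and '.' decimals; column names carry their units
(``p_mes_dbm``, ``e_v_per_m``, ...).  Calibration, plant and run
configuration travel as YAML.  Below-floor analyzer readings are empty
cells in ``measurements.csv`` and ``---`` in rendered exposure tables.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import qpcr, synth, thermal
from .dosimetry import (CalibrationConstants, FieldMap, ProbeMeasurement,
                        build_exposure_table, exposure_margin, icnirp_limits)

log = logging.getLogger("rfdosim")

MISSING = "---"


# ---------------------------------------------------------------------------
# calibration YAML
# ---------------------------------------------------------------------------

_CAL_KEYS = {"cable_attenuation_db": "cable_attenuation_db",
             "antenna_factor_per_m": "antenna_factor_per_m",
             "port_impedance_ohm": "port_impedance_ohm",
             "wave_impedance_ohm": "wave_impedance_ohm",
             "sensitivity_floor_dbm": "sensitivity_floor_dbm"}


def read_calibration(path) -> CalibrationConstants:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: calibration file must be a YAML mapping")
    unknown = set(raw) - set(_CAL_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown calibration keys {sorted(unknown)}")
    try:
        return CalibrationConstants(**{_CAL_KEYS[k]: float(v) for k, v in raw.items()})
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid calibration: {exc}") from exc


def write_calibration(cal: CalibrationConstants, path) -> None:
    data = {k: float(getattr(cal, attr)) for k, attr in _CAL_KEYS.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# measurements and exposure tables
# ---------------------------------------------------------------------------

def read_measurements(path) -> List[ProbeMeasurement]:
    """Read a probe ladder CSV; an empty ``p_mes_dbm`` cell is below floor."""
    df = pd.read_csv(path)
    errors = validate_measurements(df, name=str(path))
    if errors:
        raise ValueError("; ".join(errors))
    out = []
    for _, row in df.iterrows():
        p_mes = row["p_mes_dbm"]
        out.append(ProbeMeasurement(
            generator_power_dbm=float(row["p_gene_dbm"]),
            axis=str(row.get("axis", "x")),
            measured_power_dbm=None if pd.isna(p_mes) else float(p_mes),
            frequency_hz=float(row.get("frequency_hz", 1.77e9))))
    return out


def write_measurements(ladder: Sequence[ProbeMeasurement], path) -> None:
    df = pd.DataFrame({
        "p_gene_dbm": [m.generator_power_dbm for m in ladder],
        "axis": [m.axis for m in ladder],
        "p_mes_dbm": [m.measured_power_dbm for m in ladder],
        "frequency_hz": [m.frequency_hz for m in ladder]})
    df.to_csv(path, index=False)


def write_exposure_table(table: pd.DataFrame, path) -> None:
    """Write an exposure table, rendering below-floor cells as ``---``."""
    table.to_csv(path, index=False, na_rep=MISSING)


def read_exposure_table(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[MISSING])


# ---------------------------------------------------------------------------
# field maps
# ---------------------------------------------------------------------------

_EH_COLS = ["re_ex", "im_ex", "re_ey", "im_ey", "re_ez", "im_ez"]
_H_COLS = ["re_hx", "im_hx", "re_hy", "im_hy", "re_hz", "im_hz"]


def write_field_map(fmap: FieldMap, path) -> None:
    """Write a component field map as long-form CSV (x_mm, y_mm, re/im parts)."""
    if fmap.e_components is None:
        raise ValueError("component CSV needs E components")
    ny, nx, _ = fmap.e_components.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    data = {"x_mm": (xx.ravel() * fmap.pixel_size_m * 1e3),
            "y_mm": (yy.ravel() * fmap.pixel_size_m * 1e3)}
    e = fmap.e_components.reshape(-1, 3)
    for i, (rc, ic) in enumerate(zip(_EH_COLS[::2], _EH_COLS[1::2])):
        data[rc] = e[:, i].real
        data[ic] = e[:, i].imag
    if fmap.h_components is not None:
        h = fmap.h_components.reshape(-1, 3)
        for i, (rc, ic) in enumerate(zip(_H_COLS[::2], _H_COLS[1::2])):
            data[rc] = h[:, i].real
            data[ic] = h[:, i].imag
    pd.DataFrame(data).to_csv(path, index=False)


def read_field_map(path, petri_diameter_m: float = 0.052,
                   wave_impedance_ohm: float = 377.0) -> FieldMap:
    """Read a field-map CSV: either a bare power grid or a component table."""
    df = pd.read_csv(path)
    if {"x_mm", "y_mm"}.issubset(df.columns):
        missing = [c for c in _EH_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: component map missing columns {missing}")
        xs = np.sort(df["x_mm"].unique())
        ys = np.sort(df["y_mm"].unique())
        pitch = float(np.diff(xs).mean()) * 1e-3 if len(xs) > 1 else 1e-3
        df = df.sort_values(["y_mm", "x_mm"])
        e = np.empty((len(ys), len(xs), 3), dtype=complex)
        for i in range(3):
            e[..., i] = (df[_EH_COLS[2 * i]].to_numpy()
                         + 1j * df[_EH_COLS[2 * i + 1]].to_numpy()).reshape(len(ys), len(xs))
        h = None
        if set(_H_COLS).issubset(df.columns):
            h = np.empty_like(e)
            for i in range(3):
                h[..., i] = (df[_H_COLS[2 * i]].to_numpy()
                             + 1j * df[_H_COLS[2 * i + 1]].to_numpy()).reshape(len(ys), len(xs))
        power = (np.abs(e) ** 2).sum(axis=2) / (2.0 * wave_impedance_ohm)
        return FieldMap(power_grid=power, e_components=e, h_components=h,
                        pixel_size_m=pitch, petri_diameter_m=petri_diameter_m)
    # bare power grid: one value per pixel, row-major, no coordinates
    grid = df.to_numpy(dtype=float)
    return FieldMap(power_grid=grid, petri_diameter_m=petri_diameter_m)


# ---------------------------------------------------------------------------
# Ct tables and temperature traces
# ---------------------------------------------------------------------------

def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    errors = validate_ct(df, name=str(path))
    if errors:
        raise ValueError("; ".join(errors))
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_trace(trace: thermal.TemperatureTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.time_s, "temp_c": trace.temp_c,
                       "duty": trace.duty})
    events = dict(trace.events) if trace.events else {}
    df["event"] = [events.get(t, "") for t in trace.time_s]
    df.to_csv(path, index=False)


def read_trace(path) -> thermal.TemperatureTrace:
    df = pd.read_csv(path)
    events = [(float(t), str(e)) for t, e in zip(df["time_s"], df.get("event", []))
              if isinstance(e, str) and e]
    return thermal.TemperatureTrace(time_s=df["time_s"].to_numpy(),
                                    temp_c=df["temp_c"].to_numpy(),
                                    duty=df.get("duty", pd.Series(np.zeros(len(df)))).to_numpy(),
                                    events=events)


# ---------------------------------------------------------------------------
# validation reports
# ---------------------------------------------------------------------------

def validate_measurements(df: pd.DataFrame, name: str = "measurements") -> List[str]:
    """Itemized schema errors for a probe-ladder table (empty if valid)."""
    errors = []
    for col in ("p_gene_dbm", "p_mes_dbm"):
        if col not in df.columns:
            errors.append(f"{name}: missing column {col!r}")
    if errors:
        return errors
    if not pd.api.types.is_numeric_dtype(df["p_gene_dbm"]):
        errors.append(f"{name}: p_gene_dbm has non-numeric cells")
    if not pd.api.types.is_numeric_dtype(df["p_mes_dbm"]):
        errors.append(f"{name}: p_mes_dbm has non-numeric cells (empty = below floor)")
    axes = df["axis"] if "axis" in df.columns else pd.Series(["x"] * len(df))
    dup = df.assign(axis=axes).duplicated(subset=["p_gene_dbm", "axis"])
    for idx in df.index[dup]:
        errors.append(f"{name}: row {idx}: duplicate ladder rung "
                      f"(p_gene_dbm={df.at[idx, 'p_gene_dbm']}, axis={axes[idx]})")
    return errors


def validate_ct(df: pd.DataFrame, name: str = "ct",
                ref_gene: Optional[str] = None) -> List[str]:
    """Itemized schema errors for a Ct table (empty if valid)."""
    errors = []
    for col in qpcr.REQUIRED_COLUMNS:
        if col not in df.columns:
            errors.append(f"{name}: missing column {col!r}")
    if errors:
        return errors
    if not pd.api.types.is_numeric_dtype(df["ct"]):
        errors.append(f"{name}: ct column has non-numeric cells")
    elif not np.isfinite(df["ct"].to_numpy(dtype=float)).all():
        for idx in df.index[~np.isfinite(df["ct"].to_numpy(dtype=float))]:
            errors.append(f"{name}: row {idx}: non-finite ct value")
    if ref_gene is not None:
        samples = set(map(tuple, df[["condition", "replicate"]].drop_duplicates()
                          .itertuples(index=False)))
        ref_samples = set(map(tuple, df.loc[df["gene"] == ref_gene,
                                            ["condition", "replicate"]]
                              .itertuples(index=False)))
        for cond, rep in sorted(samples - ref_samples):
            errors.append(f"{name}: reference gene {ref_gene!r} missing for "
                          f"condition={cond!r} replicate={rep}")
    return errors


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One reproducible end-to-end run.

    When ``measurements_path`` / ``ct_path`` are None the corresponding
    inputs are generated synthetically from the seed.
    """

    out_dir: Path
    calibration_path: Optional[Path] = None
    measurements_path: Optional[Path] = None
    ct_path: Optional[Path] = None
    ref_gene: str = synth.REFERENCE_GENE
    control_condition: str = "sham"
    ct_profile: str = "kiaa_biphasic"
    replicates: int = 3
    f_mhz: float = 1800.0
    exposure_hours: float = 0.25
    dish_diameter_m: float = 0.053
    water_volume_m3: float = 4.5e-6
    alpha: float = 0.05
    log2_scale: bool = False
    skip_qpcr: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"{path}: unknown run-config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.out_dir = Path(cfg.out_dir)
        for attr in ("calibration_path", "measurements_path", "ct_path"):
            val = getattr(cfg, attr)
            if val is not None:
                p = Path(val)
                if not p.exists():
                    raise ValueError(f"{path}: {attr} does not exist: {p}")
                setattr(cfg, attr, p)
        return cfg


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Dosimetry table -> safety margins -> thermal budget -> qPCR -> profiles.

    Writes every stage's CSV plus a Markdown report under
    ``cfg.out_dir`` and returns the in-memory artifacts.  Identical
    config and seed give identical outputs.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cal = (read_calibration(cfg.calibration_path) if cfg.calibration_path
           else CalibrationConstants())
    log.info("calibration: A_CABLE=%.5f AF=%.2f 1/m Z0=%.1f ohm eta0=%.1f ohm "
             "floor=%.1f dBm seed=%d", cal.a_cable, cal.antenna_factor_per_m,
             cal.port_impedance_ohm, cal.wave_impedance_ohm,
             cal.sensitivity_floor_dbm, cfg.seed)

    try:
        if cfg.measurements_path:
            ladder = read_measurements(cfg.measurements_path)
        else:
            from .datasets import published_ladder
            ladder = published_ladder()
        table = build_exposure_table(ladder, cal)
        write_exposure_table(table, out_dir / "exposure_table.csv")
    except Exception as exc:
        raise RuntimeError(f"dosimetry stage failed: {exc}") from exc

    try:
        limits = icnirp_limits(cfg.f_mhz)
        peak_pemg = float(np.nanmax(table["p_emg_w_per_m2"]))
        margin = exposure_margin(peak_pemg, limits)
    except Exception as exc:
        raise RuntimeError(f"safety stage failed: {exc}") from exc

    try:
        budget = thermal.ThermalBudget(
            dish_diameter_m=cfg.dish_diameter_m,
            incident_power_w_per_m2=peak_pemg,
            duration_h=cfg.exposure_hours,
            heat_capacity_wh_per_m3k=thermal.WATER_HEAT_CAPACITY_WH_M3K,
            volume_m3=cfg.water_volume_m3)
        delta_t = thermal.delta_t_budget(budget)
    except Exception as exc:
        raise RuntimeError(f"thermal stage failed: {exc}") from exc

    results = profiles = None
    if not cfg.skip_qpcr:
        try:
            if cfg.ct_path:
                ct = read_ct_table(cfg.ct_path)
            else:
                profile = synth.PROFILES[cfg.ct_profile]
                ct = synth.gen_ct_table(profile, synth.GeneratorConfig(
                    seed=cfg.seed, replicates=cfg.replicates))
            write_ct_table(ct, out_dir / "ct.csv")
            results = qpcr.analyze(ct, cfg.ref_gene, cfg.control_condition,
                                   log2_scale=cfg.log2_scale)
            results.to_csv(out_dir / "results.csv", index=False)
            rows = []
            for gene in results["gene"].unique():
                prof = qpcr.profile_from_results(results, gene, cfg.control_condition)
                shape = qpcr.classify_dose_response(prof, alpha=cfg.alpha)
                rows.append({"gene": gene, "shape": shape,
                             **{f"fold_{a:+g}dBm": f
                                for a, f in zip(prof.amplitudes, prof.fold_changes)}})
            profiles = pd.DataFrame(rows)
            profiles.to_csv(out_dir / "profiles.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"qPCR stage failed: {exc}") from exc

    report = _render_report(cfg, cal, table, limits, margin, delta_t,
                            results, profiles)
    (out_dir / "report.md").write_text(report)
    return {"exposure_table": table, "limits": limits, "margin": margin,
            "delta_t_c": delta_t, "results": results, "profiles": profiles,
            "report": report}


def _render_report(cfg, cal, table, limits, margin, delta_t, results, profiles) -> str:
    buf = _io.StringIO()
    w = buf.write
    w("# RF exposure run report\n\n")
    w(f"Seed: {cfg.seed}\n\n")
    w("## Calibration constants\n\n")
    w(f"- cable coefficient A_CABLE = {cal.a_cable:.5f} "
      f"({cal.cable_attenuation_db} dB)\n")
    w(f"- antenna factor AF = {cal.antenna_factor_per_m} 1/m\n")
    w(f"- port impedance Z0 = {cal.port_impedance_ohm} ohm\n")
    w(f"- wave impedance eta0 = {cal.wave_impedance_ohm} ohm\n")
    w(f"- sensitivity floor = {cal.sensitivity_floor_dbm} dBm\n\n")
    w("## Exposure table\n\n")
    w(table.to_csv(index=False, na_rep=MISSING))
    w("\n## Safety reference levels\n\n")
    w(f"- f = {limits.f_mhz} MHz: E_max = {limits.e_max_v_per_m:.3f} V/m, "
      f"H_max = {limits.h_max_a_per_m:.5f} A/m, "
      f"P_max = {limits.p_emg_max_w_per_m2:.3f} W/m^2\n")
    w(f"- peak exposure / P_max = {margin:.3e}\n")
    w(f"\n## Lossless thermal budget\n\n- dT = {delta_t:.3e} K over "
      f"{cfg.exposure_hours} h at the peak flux\n")
    if results is not None:
        w("\n## Relative expression\n\n")
        w(results.to_csv(index=False))
        w("\n## Dose-response profiles\n\n")
        w(profiles.to_csv(index=False))
    return buf.getvalue()
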