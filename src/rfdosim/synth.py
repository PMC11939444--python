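"""Synthetic inputs with the statistical structure each stage assumes.

No raw Ct tables or field maps are deposited with the study this
package models, so every pipeline stage is exercised against generated
inputs whose ground truth is known:

* Ct tables with per-condition true fold changes, a stable reference
  gene, and normal replicate noise on the cycle scale;
* probe ladders built by inverting the dosimetry chain from true power
  fluxes, with optional dB-scale noise and the −75 dBm sensitivity
  floor applied;
* gridded field maps rescaled to an exact target inhomogeneity and
  constructed with specified polarization ratios;
* hood-opening schedules for the regulation simulator.

Every generator is deterministic given its seed and exposes its
embedded truth, so downstream estimates can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dosimetry import (CalibrationConstants, FieldMap, ProbeMeasurement,
                        watt_to_dbm)

#: Default amplitude ladder labels, control first, as used on the bench.
DEFAULT_CONDITIONS = ("sham", "+10dBm", "0dBm", "-10dBm", "-20dBm",
                      "-30dBm", "-40dBm")

#: Reference gene name used by generated tables.
REFERENCE_GENE = "GAPDH"


@dataclass(frozen=True)
class EffectProfile:
    """True per-condition fold changes for one target gene.

    Baseline Cts are plausible bench values; ``noise_sd`` is the
    replicate standard deviation on the cycle scale (0.15 cycles is a
    typical qPCR replicate scatter).
    """

    name: str
    fold_changes: Dict[str, float]
    ref_baseline_ct: float = 17.0
    target_baseline_ct: float = 24.0
    noise_sd: float = 0.15

    def __post_init__(self) -> None:
        for cond, fold in self.fold_changes.items():
            if not (fold > 0):
                raise ValueError(f"fold change for {cond!r} must be positive, got {fold}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


# Shipped profiles encode the study's verbal effect sizes: a 2.5-fold
# stimulation at the highest amplitude and a ~5-fold increase at the two
# lowest for the biphasic gene; an almost 10-fold peak at -10 dBm with a
# >2-fold suppression at 0 dBm for the peaked gene.  These are derived
# parameters, not measured data; unlisted conditions sit at fold 1.
PROFILES: Dict[str, EffectProfile] = {
    "kiaa_biphasic": EffectProfile(
        name="KIAA",
        fold_changes={"sham": 1.0, "+10dBm": 2.5, "0dBm": 1.0, "-10dBm": 1.0,
                      "-20dBm": 1.0, "-30dBm": 5.0, "-40dBm": 5.0}),
    "krt79_peak": EffectProfile(
        name="KRT79",
        fold_changes={"sham": 1.0, "+10dBm": 1.0, "0dBm": 0.5, "-10dBm": 10.0,
                      "-20dBm": 1.0, "-30dBm": 1.0, "-40dBm": 1.0}),
    "null_flat": EffectProfile(
        name="NULL",
        fold_changes={c: 1.0 for c in DEFAULT_CONDITIONS}),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared knobs of the Ct-table generator."""

    seed: int = 0
    replicates: int = 3
    conditions: Tuple[str, ...] = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def gen_ct_table(profile: EffectProfile, cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate a Ct table for one target gene plus the reference gene.

    Per (condition, replicate): Ct_ref ~ N(ref baseline, sd) and
    Ct_target = target baseline - log2(true fold) + N(0, sd), so a
    higher expression shows up as a proportionally earlier threshold
    cycle.  Deterministic per (profile, cfg.seed).
    """
    missing = [c for c in cfg.conditions if c not in profile.fold_changes]
    if missing:
        raise ValueError(f"profile {profile.name!r} lacks fold changes for {missing}")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for cond in cfg.conditions:
        fold = profile.fold_changes[cond]
        for rep in range(1, cfg.replicates + 1):
            ct_ref = profile.ref_baseline_ct + rng.normal(0.0, profile.noise_sd)
            ct_tgt = (profile.target_baseline_ct - math.log2(fold)
                      + rng.normal(0.0, profile.noise_sd))
            rows.append((REFERENCE_GENE, cond, rep, ct_ref))
            rows.append((profile.name, cond, rep, ct_tgt))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


def gen_probe_ladder(true_pemg_w_per_m2: Sequence[float],
                     cal: CalibrationConstants,
                     generator_powers_dbm: Optional[Sequence[float]] = None,
                     noise_db_sd: float = 0.0,
                     seed: Optional[int] = None,
                     axis: str = "x",
                     frequency_hz: float = 1.77e9) -> List[ProbeMeasurement]:
    """Invert the dosimetry chain into analyzer readings.

    For each true power flux: E = sqrt(P_EMG*eta0), U = E/AF,
    P_ELEC = U**2/Z0, P_MES = P_ELEC*a_cable, plus optional N(0, sd)
    noise in dB.  Readings that land below the sensitivity floor come
    back flagged (no numeric P_MES).  With zero noise the forward chain
    recovers the true fluxes exactly.
    """
    rng = np.random.default_rng(seed)
    if generator_powers_dbm is None:
        generator_powers_dbm = list(range(len(true_pemg_w_per_m2), 0, -1))
    if len(generator_powers_dbm) != len(true_pemg_w_per_m2):
        raise ValueError("generator powers and true fluxes must align")
    out = []
    for p_gene, pemg in zip(generator_powers_dbm, true_pemg_w_per_m2):
        if not (pemg > 0):
            raise ValueError("true power flux must be positive")
        e_field = math.sqrt(pemg * cal.wave_impedance_ohm)
        u_elec = e_field / cal.antenna_factor_per_m
        p_elec = u_elec ** 2 / cal.port_impedance_ohm
        p_mes_dbm = watt_to_dbm(p_elec * cal.a_cable)
        if noise_db_sd > 0:
            p_mes_dbm += rng.normal(0.0, noise_db_sd)
        below = p_mes_dbm < cal.sensitivity_floor_dbm
        out.append(ProbeMeasurement(generator_power_dbm=float(p_gene), axis=axis,
                                    measured_power_dbm=None if below else float(p_mes_dbm),
                                    frequency_hz=frequency_hz))
    return out


def gen_field_map(mean_power_w_per_m2: float,
                  target_inhom_percent: float,
                  polarization_ratios: Tuple[float, float] = (0.0, 0.0),
                  grid_size: Tuple[int, int] = (60, 60),
                  pixel_size_m: float = 1e-3,
                  petri_diameter_m: float = 0.052,
                  seed: Optional[int] = None,
                  with_h: bool = True,
                  h_scale: float = 1.0,
                  wave_impedance_ohm: float = 377.0) -> FieldMap:
    """Construct a field map with exact target statistics over the mask.

    A lognormal texture is affinely rescaled so the coefficient of
    variation over the Petri mask equals ``target_inhom_percent``
    exactly.  E components are x-dominant with |Ez| and |Ey| set to the
    requested fractions of |Ex| pixelwise, so the mask-mean magnitude
    ratios are exactly the targets.  With ``with_h``, H = z x E / eta
    (scaled by 1/h_scale), so the plane-wave/Poynting flux ratio is
    ``h_scale`` for a pure x-polarized map.
    """
    if target_inhom_percent < 0:
        raise ValueError("target inhomogeneity must be >= 0")
    if mean_power_w_per_m2 <= 0:
        raise ValueError("mean power must be positive")
    rz, ry = polarization_ratios
    if rz < 0 or ry < 0:
        raise ValueError("polarization ratios must be >= 0")
    rng = np.random.default_rng(seed)
    ny, nx = grid_size
    if target_inhom_percent == 0:
        power = np.full((ny, nx), mean_power_w_per_m2)
    else:
        texture = rng.lognormal(mean=0.0, sigma=0.25, size=(ny, nx))
        probe = FieldMap(power_grid=np.ones((ny, nx)), pixel_size_m=pixel_size_m,
                         petri_diameter_m=petri_diameter_m)
        mask = probe.petri_mask()
        m = texture[mask].mean()
        s = texture[mask].std(ddof=0)
        z = (texture - m) / s
        power = mean_power_w_per_m2 * (1.0 + (target_inhom_percent / 100.0) * z)
        if np.any(power < 0):
            raise ValueError("target inhomogeneity too large for a nonnegative map")

    # x-polarized amplitude carrying the power flux (peak convention):
    # |Ex|^2 + |Ey|^2 + |Ez|^2 = 2*eta*P with fixed pixelwise ratios.
    norm = math.sqrt(1.0 + ry ** 2 + rz ** 2)
    ex = np.sqrt(2.0 * wave_impedance_ohm * power) / norm
    e = np.zeros((ny, nx, 3), dtype=complex)
    e[..., 0] = ex
    e[..., 1] = ry * ex
    e[..., 2] = rz * ex
    h = None
    if with_h:
        zhat = np.array([0.0, 0.0, 1.0])
        h = np.cross(np.broadcast_to(zhat, e.shape), e) / (wave_impedance_ohm * h_scale)
    return FieldMap(power_grid=power, e_components=e, h_components=h,
                    pixel_size_m=pixel_size_m, petri_diameter_m=petri_diameter_m)


def gen_hood_schedule(n_events: int = 2, open_duration_s: float = 30.0,
                      spacing_s: float = 900.0,
                      start_s: float = 1800.0) -> List[Tuple[float, float]]:
    """Deterministic hood-opening schedule: n disjoint open intervals."""
    if n_events < 0:
        raise ValueError("number of events must be >= 0")
    if n_events and open_duration_s <= 0:
        raise ValueError("open duration must be positive")
    if n_events > 1 and spacing_s <= open_duration_s:
        raise ValueError("events overlap: spacing must exceed the open duration")
    return [(start_s + k * spacing_s, start_s + k * spacing_s + open_duration_s)
            for k in range(n_events)]
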