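"""Specimen-level corrosion parameters and rate/mass conversions.

Computes the full geometric parameter record for one specimen — radius loss,
pitting factor, pit-depth/opening/volume statistics, minimum core width,
volume loss — plus the standard immersion-testing conversions: hydrogen gas
volume → corroded mass (1 mol H2 per mol Mg), volume loss → mass, and the
mm/year corrosion rate CR = 8.76e4 · W / (A · t · ρ).

Conventions: the pitting factor is deepest over average metal penetration,
both measured from the original surface r0 (the quantity the unrolled-surface
heatmaps show); a value of 1 corresponds to perfectly uniform corrosion. All
standard deviations use the n−1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InputError

#: g/mol
M_MG = 24.305
M_H2 = 2.016


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis chain.

    Lengths in µm. Defaults reproduce the reference protocol: 1500 µm initial
    gauge radius, 15 µm voxels, 2° angular sampling, 20% material ratio and a
    strict 50 µm pit-depth filter. ``rho_mg`` is the alloy density in g/cm³
    (1.84 for WE43); ``rho_h2_g_per_l`` the hydrogen gas density at the
    measurement conditions (0.0823 g/L at 25 °C, 1 atm). ``exposed_area_cm2``
    and ``immersion_time_h`` are immersion-test measurements, only needed for
    corrosion rates.
    """

    r0_um: float = 1500.0
    voxel_size_um: float = 15.0
    min_pit_depth_um: float = 50.0
    material_ratio: float = 0.20
    on_threshold_um: float = 0.0
    angular_step_deg: float = 2.0
    center_slices: int = 1
    min_overlap: int = 1
    mid_depth_arc: bool = True
    rho_mg: float = 1.84
    rho_h2_g_per_l: float = 0.0823
    exposed_area_cm2: float | None = None
    immersion_time_h: float | None = None

    def __post_init__(self):
        for name in ("r0_um", "voxel_size_um", "material_ratio",
                     "angular_step_deg", "rho_mg", "rho_h2_g_per_l"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.min_pit_depth_um < 0 or self.on_threshold_um < 0:
            raise InputError("depth thresholds must be non-negative")


@dataclass
class SpecimenMetrics:
    """Full geometric parameter record for one specimen.

    Fields mirror the standard pitting-parameter suite: ML/VL are mass and
    volume loss in percent; n_pits and pits_per_cm2 the count and density of
    tracked pits; VL_pits_pct the volume fraction lost to pits deeper than the
    filter; RL_mean/RL_std the per-layer radius loss 1 − r1/r0; PF the pitting
    factor; d/o/v statistics the pit depth (µm), opening area (µm²) and volume
    (µm³) distributions; r_min the minimum fitted radius and d_min the minimum
    metal core width (µm); CR the corrosion rate in mm/year. Unavailable
    quantities are NaN.
    """

    ML_pct: float
    VL_pct: float
    n_pits: int
    pits_per_cm2: float
    VL_pits_pct: float
    RL_mean: float
    RL_std: float
    PF: float
    d_max_um: float
    d10_mean_um: float
    d_mean_um: float
    d_std_um: float
    o_mean_um2: float
    o_std_um2: float
    v_mean_um3: float
    v_std_um3: float
    r_min_um: float
    d_min_um: float
    CR_mm_per_year: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def nominal_area(r_mm: float) -> float:
    """Initial cross-section area πr² of the gauge section, in mm²."""
    if r_mm <= 0:
        raise InputError("radius must be positive")
    return math.pi * r_mm**2


def corrosion_rate(W_g: float, A_cm2: float, t_h: float,
                   rho_g_cm3: float) -> float:
    """Corrosion rate in mm/year: CR = 8.76e4 · W / (A · t · ρ).

    ``W_g`` corroded mass in g, ``A_cm2`` exposed surface in cm², ``t_h``
    immersion time in hours, ``rho_g_cm3`` metal density in g/cm³.
    """
    if min(W_g, A_cm2, t_h, rho_g_cm3) <= 0:
        raise InputError("all corrosion-rate inputs must be positive")
    return 8.76e4 * W_g / (A_cm2 * t_h * rho_g_cm3)


def mass_from_hydrogen(V_H2_mL: float, rho_h2_g_per_l: float = 0.0823) -> float:
    """Corroded Mg mass (g) from evolved hydrogen volume (mL).

    The anodic reaction releases one mole of H2 per mole of dissolved Mg, so
    W = V·ρ_H2·M_Mg/M_H2 with the gas density at measurement conditions.
    """
    if V_H2_mL < 0:
        raise InputError("hydrogen volume must be non-negative")
    mass_h2 = V_H2_mL / 1000.0 * rho_h2_g_per_l
    return mass_h2 * M_MG / M_H2


def hydrogen_density_ideal_gas(temperature_c: float = 25.0,
                               pressure_atm: float = 1.0) -> float:
    """Ideal-gas H2 density in g/L at the given conditions."""
    R = 0.082057  # L·atm/(mol·K)
    return pressure_atm * M_H2 / (R * (temperature_c + 273.15))


def mass_from_volume_loss(delta_V_mm3: float, rho_g_cm3: float) -> float:
    """Corroded mass (g) from µCT volume loss (mm³): W = ΔV·ρ."""
    if delta_V_mm3 < 0:
        raise InputError("volume loss must be non-negative")
    if rho_g_cm3 <= 0:
        raise InputError("density must be positive")
    return delta_V_mm3 / 1000.0 * rho_g_cm3


def rate_ratio(rate_ct: float, rate_h2: float) -> float:
    """Ratio of µCT-derived to hydrogen-derived corrosion rate.

    µCT volume loss systematically exceeds the hydrogen estimate (incomplete
    gas capture, hydrogen bound in the degradation layer); this ratio
    quantifies the discrepancy between the two measurement routes.
    """
    if rate_h2 <= 0 or rate_ct <= 0:
        raise InputError("rates must be positive")
    return rate_ct / rate_h2


def volume_to_surface_sufficiency(vs_ml_per_mm2: float,
                                  minimum_ml_per_mm2: float = 0.20) -> float:
    """Multiple by which the solution volume/surface ratio exceeds the
    immersion-standard minimum (0.20 mL/mm²). Values > 1 are sufficient."""
    if vs_ml_per_mm2 <= 0 or minimum_ml_per_mm2 <= 0:
        raise InputError("ratios must be positive")
    return vs_ml_per_mm2 / minimum_ml_per_mm2


def _std(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0


def compute_metrics(profiles, pits, config: AnalysisConfig,
                    gauge_length_um: float,
                    core_volume_um3: float | None = None,
                    mass_loss_pct: float = float("nan"),
                    hydrogen_volume_ml: float | None = None) -> SpecimenMetrics:
    """Aggregate per-slice profiles and filtered 3D pits into one record.

    ``pits`` must already carry geometry and be severity-filtered. The volume
    loss denominator is the initial gauge cylinder π·r0²·L; ``core_volume_um3``
    is the voxel-counted remaining metal (NaN volume loss when omitted).
    ``mass_loss_pct`` and ``hydrogen_volume_ml`` are optional immersion
    measurements used for ML and the corrosion rate.
    """
    profiles = list(profiles)
    if not profiles:
        raise InputError("need at least one slice profile")
    r0 = config.r0_um
    notes: list[str] = []

    r1 = np.array([p.r1_um for p in profiles])
    rl = 1.0 - r1 / r0
    tp = np.stack([p.total_penetration for p in profiles])

    # pitting factor: deepest vs average penetration from the original surface
    mean_tp = float(tp.mean())
    if mean_tp < 0.5 * config.voxel_size_um:
        pf = float("nan")
        notes.append("average penetration below half a voxel; "
                     "pitting factor undefined (pristine surface)")
    else:
        pf = float(tp.max()) / mean_tp

    n = len(pits)
    if n:
        depths = np.array(sorted((p.d_max for p in pits), reverse=True))
        openings = np.array([p.opening_area for p in pits])
        volumes = np.array([p.volume for p in pits])
        d_max = float(depths[0])
        d10 = float(depths[: min(10, n)].mean())
        d_mean, d_std = float(depths.mean()), _std(depths)
        o_mean, o_std = float(openings.mean()), _std(openings)
        v_mean, v_std = float(volumes.mean()), _std(volumes)
        pit_volume_total = float(volumes.sum())
    else:
        d_max = d10 = d_mean = d_std = 0.0
        o_mean = o_std = v_mean = v_std = 0.0
        pit_volume_total = 0.0

    gauge_volume = math.pi * r0**2 * gauge_length_um
    vl_pits_pct = pit_volume_total / gauge_volume * 100.0
    if core_volume_um3 is not None:
        vl_pct = (1.0 - core_volume_um3 / gauge_volume) * 100.0
    else:
        vl_pct = float("nan")

    # pit density over the lateral surface at the average fitted radius
    lateral_cm2 = 2 * math.pi * float(r1.mean()) * gauge_length_um * 1e-8
    pits_per_cm2 = n / lateral_cm2 if lateral_cm2 > 0 else float("nan")

    # minimum core width: each ray paired with the ray 90 index positions
    # (180°) across, width through the corrected centre
    widths = []
    for p in profiles:
        half = len(p.d) // 2
        w = (p.r1_um - p.d) + np.roll(p.r1_um - p.d, -half)
        widths.append(w.min())
    d_min = float(min(widths))

    cr = float("nan")
    if (config.exposed_area_cm2 and config.immersion_time_h
            and core_volume_um3 is not None):
        delta_v_mm3 = (gauge_volume - core_volume_um3) * 1e-9
        if delta_v_mm3 > 0:
            W = mass_from_volume_loss(delta_v_mm3, config.rho_mg)
            cr = corrosion_rate(W, config.exposed_area_cm2,
                                config.immersion_time_h, config.rho_mg)
    if (hydrogen_volume_ml is not None and math.isnan(mass_loss_pct)):
        W_h2 = mass_from_hydrogen(hydrogen_volume_ml, config.rho_h2_g_per_l)
        initial_mass = gauge_volume * 1e-12 * config.rho_mg  # µm³ -> cm³
        mass_loss_pct = W_h2 / initial_mass * 100.0

    flagged = int(sum(p.flagged.sum() for p in profiles))
    if flagged:
        notes.append(f"{flagged} rays met no material (treated as full penetration)")

    return SpecimenMetrics(
        ML_pct=float(mass_loss_pct), VL_pct=vl_pct, n_pits=n,
        pits_per_cm2=pits_per_cm2, VL_pits_pct=vl_pits_pct,
        RL_mean=float(rl.mean()), RL_std=_std(rl), PF=pf,
        d_max_um=d_max, d10_mean_um=d10, d_mean_um=d_mean, d_std_um=d_std,
        o_mean_um2=o_mean, o_std_um2=o_std, v_mean_um3=v_mean, v_std_um3=v_std,
        r_min_um=float(r1.min()), d_min_um=d_min, CR_mm_per_year=cr,
        warnings=notes)
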