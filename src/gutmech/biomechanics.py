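"""Force, stress, strain, viscosity, growth and calibration arithmetic.

Unit discipline (all conversions live here): masses in mg, forces in uN,
stresses in Pa, lengths in mm, volumes in mm^3, tissue densities in mg/mm^3,
weight/medium densities in g/cm^3, durations in hours unless suffixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import TubeMorphometry

__all__ = [
    "STEEL_DENSITY_G_CM3",
    "MEDIUM_DENSITY_G_CM3",
    "STANDARD_GRAVITY_M_S2",
    "DEFAULT_MODULUS_PA",
    "DEFAULT_ABSORBED_FRACTION",
    "DEFAULT_BRANCH_COUNT",
    "DensityRefs",
    "MechanicalLoad",
    "StressState",
    "GrowthRecord",
    "CantileverCalibration",
    "ViscosityEstimate",
    "REPORTED",
    "buoyant_force",
    "branch_tension",
    "applied_stress",
    "elastic_strain",
    "effective_viscosity",
    "relative_change",
    "dry_mass_change",
    "cell_number_change",
    "dry_mass_fraction",
    "fit_cantilever",
    "deflection_to_dry_mass",
    "proliferation_density",
    "epithelial_fraction",
]

STEEL_DENSITY_G_CM3 = 7.8
MEDIUM_DENSITY_G_CM3 = 1.0
STANDARD_GRAVITY_M_S2 = 9.81
DEFAULT_MODULUS_PA = 1000.0       # consistent with 70-100 Pa <-> 7-10% strain
DEFAULT_ABSORBED_FRACTION = 0.25  # membrane + artery share of the total force
DEFAULT_BRANCH_COUNT = 2

#: Published reference measurements used as numeric inputs by reporting code
#: (cohort means that depend on real specimens and cannot be re-derived).
REPORTED = {
    "total_force_lower_uN": 9.0,
    "total_force_upper_uN": 17.0,
    "physiological_cell_increase_pct": 500.0,
    "tension_cell_increase_pct": 124.0,
    "control_cell_increase_pct": 55.0,
    "tension_dry_mass_increase_pct": 47.0,
    "proliferation_density_control_mm2": 225.0,
}


@dataclass(frozen=True)
class DensityRefs:
    """Reference tissue densities (dry mass and cells per unit volume)."""

    rho_E8_mg_mm3: float = 0.100
    rho_ctl_mg_mm3: float = 0.104
    rho_tension_mg_mm3: float = 0.081
    n_E8_cells_mm3: float = 4.15e5
    n_cultured_cells_mm3: float = 6.60e5

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MechanicalLoad:
    """Hanging-weight load applied to one specimen."""

    mass_mg: float
    object_density_g_cm3: float = STEEL_DENSITY_G_CM3
    medium_density_g_cm3: float = MEDIUM_DENSITY_G_CM3
    g_m_s2: float = STANDARD_GRAVITY_M_S2
    absorbed_fraction: float = DEFAULT_ABSORBED_FRACTION
    branch_count: int = DEFAULT_BRANCH_COUNT

    def __post_init__(self) -> None:
        if not 0.0 <= self.absorbed_fraction < 1.0:
            raise ValueError("absorbed_fraction must lie in [0, 1)")
        if self.branch_count < 1:
            raise ValueError("branch_count must be >= 1")

    @property
    def force_uN(self) -> float:
        return buoyant_force(
            self.mass_mg, self.object_density_g_cm3,
            self.medium_density_g_cm3, self.g_m_s2,
        )

    @property
    def per_branch_uN(self) -> float:
        return branch_tension(self.force_uN, self.absorbed_fraction, self.branch_count)


@dataclass(frozen=True)
class StressState:
    stress_Pa: float
    cross_section_mm2: float
    modulus_Pa: float = DEFAULT_MODULUS_PA

    @property
    def strain(self) -> float:
        return elastic_strain(self.stress_Pa, self.modulus_Pa)


@dataclass(frozen=True)
class ViscosityEstimate:
    eta_Pa_s: float
    stress_Pa: float
    duration_s: float
    strain: float


@dataclass
class GrowthRecord:
    """Before/after morphometry plus load and derived changes for one gut."""

    specimen_id: str
    before: TubeMorphometry
    after: TubeMorphometry | None = None
    load: MechanicalLoad | None = None
    stress: StressState | None = None
    duration_h: float = 48.0
    dry_mass_final_mg: float | None = None
    cell_count_final: float | None = None
    rel_changes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")

    def compute_changes(self, refs: DensityRefs | None = None) -> dict:
        """Fill ``rel_changes`` from the stored before/after quantities."""
        refs = refs or DensityRefs()
        if self.after is not None:
            self.rel_changes["length"] = relative_change(
                self.before.length_mm, self.after.length_mm)
            self.rel_changes["volume"] = relative_change(
                self.before.volume_mm3, self.after.volume_mm3)
            self.rel_changes["diameter"] = relative_change(
                self.before.mean_diameter_mm, self.after.mean_diameter_mm)
        if self.dry_mass_final_mg is not None:
            self.rel_changes["dry_mass"] = dry_mass_change(
                self.dry_mass_final_mg, self.before.volume_mm3, refs.rho_E8_mg_mm3)
        if self.cell_count_final is not None:
            self.rel_changes["cell_number"] = cell_number_change(
                self.cell_count_final, self.before.volume_mm3, refs.n_E8_cells_mm3)
        return dict(self.rel_changes)


# ---------------------------------------------------------------------------
# forces and stresses
# ---------------------------------------------------------------------------

def buoyant_force(
    mass_mg: float,
    object_density_g_cm3: float = STEEL_DENSITY_G_CM3,
    medium_density_g_cm3: float = MEDIUM_DENSITY_G_CM3,
    g_m_s2: float = STANDARD_GRAVITY_M_S2,
) -> float:
    """Weight of a submerged mass corrected for buoyancy, in uN.

    ``F = m g (1 - rho_medium / rho_object)``; a 1-2 mg steel weight in
    aqueous medium gives 8.6-17.1 uN (9-17 after integer rounding).
    """
    if mass_mg < 0:
        raise ValueError("mass must be nonnegative")
    if object_density_g_cm3 <= 0 or medium_density_g_cm3 <= 0:
        raise ValueError("densities must be positive")
    if object_density_g_cm3 <= medium_density_g_cm3:
        raise ValueError("object density must exceed medium density (weight would float)")
    # mg * m/s^2 = 1e-6 kg m/s^2 = uN exactly
    return mass_mg * g_m_s2 * (1.0 - medium_density_g_cm3 / object_density_g_cm3)


def branch_tension(
    force_total_uN: float,
    absorbed_fraction: float = DEFAULT_ABSORBED_FRACTION,
    branch_count: int = DEFAULT_BRANCH_COUNT,
) -> float:
    """Tension borne by each tube branch after the absorbed share is removed."""
    if not 0.0 <= absorbed_fraction < 1.0:
        raise ValueError("absorbed_fraction must lie in [0, 1)")
    if branch_count < 1:
        raise ValueError("branch_count must be >= 1")
    if force_total_uN < 0:
        raise ValueError("force must be nonnegative")
    return force_total_uN * (1.0 - absorbed_fraction) / branch_count


def applied_stress(force_uN: float, diameter_mm: float) -> float:
    """Axial stress ``sigma = F / S`` with ``S = pi d^2 / 4``, in Pa."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    # uN / mm^2 = 1e-6 N / 1e-6 m^2 = Pa exactly
    return 4.0 * force_uN / (np.pi * diameter_mm**2)


def cross_section_mm2(diameter_mm: float) -> float:
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    return np.pi * diameter_mm**2 / 4.0


def elastic_strain(stress_Pa: float, modulus_Pa: float = DEFAULT_MODULUS_PA) -> float:
    """Instantaneous elastic strain ``eps = sigma / E`` (fraction)."""
    if modulus_Pa <= 0:
        raise ValueError("modulus must be positive")
    return stress_Pa / modulus_Pa


def effective_viscosity(
    stress_Pa: float, duration_h: float, strain_irreversible: float
) -> ViscosityEstimate:
    """Effective tissue viscosity ``eta = sigma * dT / (dl/l)`` in Pa s."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if strain_irreversible <= 0:
        raise ValueError("no irreversible elongation: strain must be positive")
    duration_s = duration_h * 3600.0
    eta = stress_Pa * duration_s / strain_irreversible
    return ViscosityEstimate(
        eta_Pa_s=eta, stress_Pa=stress_Pa,
        duration_s=duration_s, strain=strain_irreversible,
    )


# ---------------------------------------------------------------------------
# growth metrics
# ---------------------------------------------------------------------------

def relative_change(before: float, after: float) -> float:
    if before == 0:
        raise ValueError("reference value is zero")
    return (after - before) / before


def dry_mass_change(m_f_mg: float, V_i_mm3: float, rho_ref_mg_mm3: float = 0.100) -> float:
    """Relative dry-mass change ``(m_f - rho * V_i) / (rho * V_i)``."""
    if V_i_mm3 <= 0:
        raise ValueError("initial volume must be positive")
    if rho_ref_mg_mm3 <= 0:
        raise ValueError("reference density must be positive")
    return relative_change(rho_ref_mg_mm3 * V_i_mm3, m_f_mg)


def cell_number_change(N_f: float, V_i_mm3: float, n_ref_cells_mm3: float = 4.15e5) -> float:
    """Relative cell-number change ``(N_f - n * V_i) / (n * V_i)``."""
    if V_i_mm3 <= 0:
        raise ValueError("initial volume must be positive")
    if n_ref_cells_mm3 <= 0:
        raise ValueError("reference cell density must be positive")
    return relative_change(n_ref_cells_mm3 * V_i_mm3, N_f)


def dry_mass_fraction(rho_mg_mm3: float, water_density_mg_mm3: float = 1.0) -> float:
    """Dry-mass percentage of wet tissue with density ``rho`` (mg/mm^3)."""
    if rho_mg_mm3 < 0:
        raise ValueError("density must be nonnegative")
    if rho_mg_mm3 >= water_density_mg_mm3:
        raise ValueError("dry density must be below the wet (water) density")
    return 100.0 * rho_mg_mm3 / water_density_mg_mm3


# ---------------------------------------------------------------------------
# cantilever calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CantileverCalibration:
    """Linear deflection-force characteristic of a weighing fiber."""

    sensitivity_deg_per_N: float
    intercept_deg: float
    r_squared: float
    stderr_deg_per_N: float
    points: tuple = ()  # ((force_N, deflection_deg), ...)

    def __post_init__(self) -> None:
        if self.sensitivity_deg_per_N <= 0:
            raise ValueError("sensitivity must be positive")


def fit_cantilever(
    points: pd.DataFrame | np.ndarray,
    g_m_s2: float = STANDARD_GRAVITY_M_S2,
) -> CantileverCalibration:
    """Least-squares line through (mass, deflection) calibration points.

    ``points`` carries columns/cols (mass_mg, deflection_deg); the fit is
    deflection vs force in N, so the slope is the sensitivity in deg/N.
    """
    if isinstance(points, pd.DataFrame):
        mass = points["mass_mg"].to_numpy(float)
        defl = points["deflection_deg"].to_numpy(float)
    else:
        arr = np.asarray(points, float)
        mass, defl = arr[:, 0], arr[:, 1]
    if len(np.unique(mass)) < 2:
        raise ValueError("need >= 2 distinct masses to calibrate")
    force_N = mass * 1e-6 * g_m_s2
    res = stats.linregress(force_N, defl)
    return CantileverCalibration(
        sensitivity_deg_per_N=float(res.slope),
        intercept_deg=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr_deg_per_N=float(res.stderr),
        points=tuple(zip(force_N.tolist(), defl.tolist())),
    )


def deflection_to_dry_mass(
    deflection_deg: float,
    calib: CantileverCalibration,
    g_m_s2: float = STANDARD_GRAVITY_M_S2,
) -> float:
    """Invert the calibration: deflection angle -> mass in mg."""
    if deflection_deg < calib.intercept_deg:
        raise ValueError("deflection below the calibration intercept")
    force_N = (deflection_deg - calib.intercept_deg) / calib.sensitivity_deg_per_N
    return force_N / g_m_s2 * 1e6


# ---------------------------------------------------------------------------
# proliferation arithmetic
# ---------------------------------------------------------------------------

def proliferation_density(ph3_count, section_area_mm2):
    """Mitotic cells per section area, cells/mm^2.

    Accepts scalars or per-slice arrays; with arrays the per-slice densities
    and their mean are both returned (per-sample mean over slices).
    """
    count = np.asarray(ph3_count, float)
    area = np.asarray(section_area_mm2, float)
    if np.any(area <= 0):
        raise ValueError("section area must be positive")
    if np.any(count < 0):
        raise ValueError("counts must be nonnegative")
    dens = count / area
    if dens.ndim == 0:
        return float(dens)
    return dens, float(dens.mean())


def epithelial_fraction(count_epithelium: float, count_total: float) -> float:
    """Percentage of the counted cells that lie in the epithelium."""
    if count_total <= 0:
        raise ValueError("total count must be positive")
    if not 0 <= count_epithelium <= count_total:
        raise ValueError("epithelial count must lie in [0, total]")
    return 100.0 * count_epithelium / count_total
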