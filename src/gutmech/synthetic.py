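"""Synthetic inputs with known ground truth.

Every generator is deterministic given its spec's single integer seed and
emits both the artifact (image, movie, table) and the analytic truth the
measurement pipeline is benchmarked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline

from . import biomechanics as bm
from .biomechanics import DensityRefs, GrowthRecord, MechanicalLoad, StressState
from .morphometry import Midline, TubeMorphometry
from .motility import WaveStats

__all__ = [
    "TubePhantomSpec",
    "ResponseLaw",
    "GrowthCohortSpec",
    "PeristalsisMovieSpec",
    "TubePhantom",
    "generate_tube_image",
    "generate_growth_cohort",
    "cohort_to_frame",
    "generate_peristalsis_movie",
    "generate_calibration_data",
    "incompressible_rescale",
]

# sub-pixel offset of the phantom origin; keeps silhouette edges away from
# pixel-center ties so rasterized areas are unbiased
_SUBPIXEL_OFFSET = 0.37


# ---------------------------------------------------------------------------
# tube phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubePhantomSpec:
    """Axisymmetric curved-tube silhouette with known geometry."""

    midline_kind: str = "straight"          # straight | sinusoid | spline
    length_mm: float = 10.0                 # midline (cap-center to cap-center)
    base_diameter_mm: float = 0.4
    taper: float = 0.0                      # fractional diameter change tip-to-tip
    bend_amplitude_mm: float = 0.0
    bend_wavelength_mm: float = 5.0
    scale_mm_per_px: float = 0.01
    noise_sd_px: float = 0.0                # boundary jitter
    seed: int = 0
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.midline_kind not in ("straight", "sinusoid", "spline"):
            raise ValueError(f"unknown midline_kind {self.midline_kind!r}")
        if self.length_mm <= 0 or self.base_diameter_mm <= 0:
            raise ValueError("length and diameter must be positive")
        if self.length_mm / self.base_diameter_mm < 3:
            raise ValueError("not tubular: length/diameter must be >= 3")
        if not -0.5 <= self.taper <= 0.5:
            raise ValueError("taper must lie in [-0.5, 0.5]")
        if self.bend_amplitude_mm < 0 or self.bend_wavelength_mm <= 0:
            raise ValueError("invalid bend parameters")
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale must be positive")
        if self.noise_sd_px < 0:
            raise ValueError("noise sd must be nonnegative")


@dataclass(frozen=True)
class TubePhantom:
    """Generator output: image + mask + analytic truth."""

    image: np.ndarray
    mask: np.ndarray
    truth: TubeMorphometry
    midline: Midline
    spec: TubePhantomSpec


def _midline_points(spec: TubePhantomSpec, step_mm: float) -> np.ndarray:
    """Dense (x, y) midline samples at ~uniform arclength ``step_mm``."""
    L = spec.length_mm
    if spec.midline_kind == "straight":
        n = max(int(math.ceil(L / step_mm)) + 1, 2)
        x = np.linspace(0.0, L, n)
        return np.column_stack([x, np.zeros_like(x)])

    if spec.midline_kind == "sinusoid":
        amp, lam = spec.bend_amplitude_mm, spec.bend_wavelength_mm
        def curve(x):
            return amp * np.sin(2 * np.pi * x / lam)
    else:  # spline: smooth random waviness with the spec's amplitude scale
        rng = np.random.default_rng(spec.seed + 1)
        n_ctrl = max(4, int(round(L / spec.bend_wavelength_mm)) + 2)
        cx = np.linspace(0.0, 1.6 * L, n_ctrl)
        cy = rng.normal(0.0, 1.0, n_ctrl)
        cy = ndimage.uniform_filter1d(cy, 2)
        if np.ptp(cy) > 0:
            cy = (cy - cy.mean()) / (np.abs(cy).max() or 1.0) * spec.bend_amplitude_mm
        spl = CubicSpline(cx, cy)
        def curve(x):
            return spl(x)

    # march in x until the arclength reaches L
    dx = step_mm / 4.0
    x_grid = np.arange(0.0, 4.0 * L + dx, dx)
    y_grid = np.asarray(curve(x_grid), float)
    seg = np.hypot(np.diff(x_grid), np.diff(y_grid))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] < L:
        raise ValueError("midline generator could not reach requested arclength")
    target = np.arange(0.0, L + step_mm / 2, step_mm)
    target = np.clip(target, 0.0, L)
    if target[-1] < L:
        target = np.append(target, L)
    x = np.interp(target, cum, x_grid)
    y = np.interp(target, cum, y_grid)
    return np.column_stack([x, y])


def _curvature(xy: np.ndarray, s: np.ndarray) -> np.ndarray:
    dx = np.gradient(xy[:, 0], s)
    dy = np.gradient(xy[:, 1], s)
    ddx = np.gradient(dx, s)
    ddy = np.gradient(dy, s)
    return np.abs(dx * ddy - dy * ddx) / np.maximum((dx * dx + dy * dy) ** 1.5, 1e-12)


def _radius_profile(spec: TubePhantomSpec, s: np.ndarray) -> np.ndarray:
    d0 = spec.base_diameter_mm
    return 0.5 * d0 * (1.0 + spec.taper * s / spec.length_mm)


def generate_tube_image(spec: TubePhantomSpec) -> TubePhantom:
    """Rasterize a disk swept along the spec's midline; return image + truth.

    The silhouette has hemispherical end caps (the sweep rounds the ends by
    one local radius). Truth quantities refer to the midline: length ``L``,
    arclength-weighted mean diameter and ``V = integral pi r(s)^2 ds``.
    """
    scale = spec.scale_mm_per_px
    step = scale / 2.0
    xy = _midline_points(spec, step)
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    r = _radius_profile(spec, s)

    kappa = _curvature(xy, s)
    min_bend_radius = 1.0 / max(kappa.max(), 1e-12)
    if min_bend_radius <= r.max():
        raise ValueError(
            "self-overlapping phantom: bend radius of curvature "
            f"({min_bend_radius:.3g} mm) does not exceed the tube radius "
            f"({r.max():.3g} mm)")
    if min_bend_radius <= spec.base_diameter_mm:
        raise ValueError("bend radius of curvature must exceed the base diameter")

    if spec.rotation_deg:
        a = math.radians(spec.rotation_deg)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        xy = xy @ rot.T

    r_draw = r.copy()
    if spec.noise_sd_px > 0:
        rng = np.random.default_rng(spec.seed)
        jitter = rng.normal(0.0, spec.noise_sd_px * scale, len(r))
        jitter = ndimage.gaussian_filter1d(jitter, 5.0)
        r_draw = np.clip(r + jitter, 0.2 * r, None)

    margin_mm = r_draw.max() + (spec.noise_sd_px + 6.0) * scale
    origin = xy.min(axis=0) - margin_mm
    pos_px = (xy - origin) / scale + _SUBPIXEL_OFFSET
    r_px = r_draw / scale
    shape = tuple(np.ceil((xy.max(axis=0) - origin) / scale + margin_mm / scale).astype(int)[::-1])

    mask = np.zeros(shape, dtype=bool)
    for (px, py), rad in zip(pos_px, r_px):
        r0 = int(math.floor(py - rad)); r1 = int(math.ceil(py + rad)) + 1
        c0 = int(math.floor(px - rad)); c1 = int(math.ceil(px + rad)) + 1
        rr = np.arange(max(r0, 0), min(r1, shape[0]))
        cc = np.arange(max(c0, 0), min(c1, shape[1]))
        if rr.size == 0 or cc.size == 0:
            continue
        dy = rr[:, None] - py
        dx = cc[None, :] - px
        mask[np.ix_(rr, cc)] |= dy * dy + dx * dx <= rad * rad

    labels, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise ValueError("self-overlapping or fragmented phantom mask")

    image = np.where(mask, 200.0, 30.0)
    image = ndimage.gaussian_filter(image, 0.8)
    image = image.astype(np.uint8)

    length = float(s[-1])
    volume = float(np.trapezoid(np.pi * r * r, s))
    mean_d = float(np.trapezoid(2.0 * r, s) / length)
    truth = TubeMorphometry(
        length_mm=length, mean_diameter_mm=mean_d, volume_mm3=volume,
        diameter_profile=tuple((float(si), float(2 * ri)) for si, ri in zip(s, r)),
    )
    mid_xy_mm = (pos_px * scale)
    midline = Midline(s_mm=s, x_mm=mid_xy_mm[:, 0], y_mm=mid_xy_mm[:, 1], r_mm=r)
    return TubePhantom(image=image, mask=mask, truth=truth, midline=midline, spec=spec)


# ---------------------------------------------------------------------------
# growth cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseLaw:
    """Linear %-change-vs-stress law for length and volume.

    Defaults anchor the zero-stress control means (-18% length, +2% volume)
    and the +200% length / +180% volume upper anchors at 150 Pa. The diameter
    response follows from the axisymmetric identity
    ``(1 + dV/V) = (1 + dl/l)(1 + dd/d)^2``.
    """

    length_intercept_pct: float = -18.0
    length_slope_pct_per_Pa: float = 218.0 / 150.0
    volume_intercept_pct: float = 2.0
    volume_slope_pct_per_Pa: float = 178.0 / 150.0

    def length_pct(self, stress_Pa: float) -> float:
        return self.length_intercept_pct + self.length_slope_pct_per_Pa * stress_Pa

    def volume_pct(self, stress_Pa: float) -> float:
        return self.volume_intercept_pct + self.volume_slope_pct_per_Pa * stress_Pa

    def diameter_pct(self, stress_Pa: float) -> float:
        fl = 1.0 + self.length_pct(stress_Pa) / 100.0
        fv = 1.0 + self.volume_pct(stress_Pa) / 100.0
        if fl <= 0 or fv <= 0:
            raise ValueError("response law produced non-positive scale factor")
        return (math.sqrt(fv / fl) - 1.0) * 100.0


@dataclass(frozen=True)
class GrowthCohortSpec:
    n_specimens: int = 20
    mass_mg_choices: tuple = (0.0, 1.0, 1.5)
    diameter_mm_mean: float = 0.35
    diameter_mm_sd: float = 0.05
    length_mm_mean: float = 10.0
    length_mm_sd: float = 1.0
    response_law: ResponseLaw = field(default_factory=ResponseLaw)
    noise_sd_pct: tuple = (6.0, 7.0, 7.0)   # length, volume, diameter
    refs: DensityRefs = field(default_factory=DensityRefs)
    duration_h: float = 48.0
    seed: int = 0
    max_redraws: int = 50

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("need at least one specimen")
        if any(m < 0 for m in self.mass_mg_choices):
            raise ValueError("masses must be nonnegative")
        if self.diameter_mm_mean <= 0 or self.length_mm_mean <= 0:
            raise ValueError("size distributions must have positive means")


def generate_growth_cohort(spec: GrowthCohortSpec) -> list[GrowthRecord]:
    """Cohort of before/after records following the configured response law."""
    rng = np.random.default_rng(spec.seed)
    law = spec.response_law
    sd_l, sd_v, sd_d = spec.noise_sd_pct
    records: list[GrowthRecord] = []
    masses = [spec.mass_mg_choices[i % len(spec.mass_mg_choices)]
              for i in range(spec.n_specimens)]
    for i, mass in enumerate(masses):
        for attempt in range(spec.max_redraws + 1):
            d0 = rng.normal(spec.diameter_mm_mean, spec.diameter_mm_sd)
            L0 = rng.normal(spec.length_mm_mean, spec.length_mm_sd)
            if d0 > 0.05 and L0 > 3 * d0:
                break
        else:
            raise RuntimeError("could not draw a valid specimen geometry")
        load = MechanicalLoad(mass_mg=mass)
        stress = bm.applied_stress(load.force_uN, d0)
        dl = law.length_pct(stress) + rng.normal(0.0, sd_l)
        dv = law.volume_pct(stress) + rng.normal(0.0, sd_v)
        dd = law.diameter_pct(stress) + rng.normal(0.0, sd_d)
        V0 = math.pi * d0 * d0 / 4.0 * L0
        for attempt in range(spec.max_redraws + 1):
            V1 = V0 * (1.0 + dv / 100.0)
            if V1 > 0:
                break
            dv = law.volume_pct(stress) + rng.normal(0.0, sd_v)
        else:
            raise RuntimeError("volume redraws exhausted")
        L1 = L0 * (1.0 + dl / 100.0)
        d1 = d0 * (1.0 + dd / 100.0)
        if L1 <= 0 or d1 <= 0:
            raise RuntimeError("drawn after-culture geometry is non-physical")
        rho = spec.refs.rho_ctl_mg_mm3 if mass == 0 else spec.refs.rho_tension_mg_mm3
        m_f = rho * V1
        N_f = spec.refs.n_cultured_cells_mm3 * V1
        before = TubeMorphometry(length_mm=L0, mean_diameter_mm=d0, volume_mm3=V0)
        after = TubeMorphometry(length_mm=L1, mean_diameter_mm=d1, volume_mm3=V1)
        rec = GrowthRecord(
            specimen_id=f"s{i:03d}",
            before=before, after=after, load=load,
            stress=StressState(stress_Pa=stress, cross_section_mm2=bm.cross_section_mm2(d0)),
            duration_h=spec.duration_h,
            dry_mass_final_mg=m_f, cell_count_final=N_f,
        )
        rec.compute_changes(spec.refs)
        records.append(rec)
    return records


_COHORT_COLUMNS = ["specimen_id", "mass_mg", "stress_Pa", "d0_mm", "L0_mm",
                   "V0_mm3", "L1_mm", "V1_mm3", "d1_mm", "m_f_mg", "N_f"]


def cohort_to_frame(records: list[GrowthRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "specimen_id": r.specimen_id,
            "mass_mg": r.load.mass_mg if r.load else 0.0,
            "stress_Pa": r.stress.stress_Pa if r.stress else 0.0,
            "d0_mm": r.before.mean_diameter_mm,
            "L0_mm": r.before.length_mm,
            "V0_mm3": r.before.volume_mm3,
            "L1_mm": r.after.length_mm,
            "V1_mm3": r.after.volume_mm3,
            "d1_mm": r.after.mean_diameter_mm,
            "m_f_mg": r.dry_mass_final_mg,
            "N_f": r.cell_count_final,
        })
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def incompressible_rescale(morph: TubeMorphometry, eps: float) -> TubeMorphometry:
    """Volume-preserving stretch: length x(1+eps), diameter x(1+eps)^(-1/2)."""
    if eps <= -1:
        raise ValueError("eps must exceed -1")
    f = 1.0 + eps
    return TubeMorphometry(
        length_mm=morph.length_mm * f,
        mean_diameter_mm=morph.mean_diameter_mm / math.sqrt(f),
        volume_mm3=morph.volume_mm3,
    )


# ---------------------------------------------------------------------------
# peristalsis movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeristalsisMovieSpec:
    frames: int = 600
    frame_interval_s: float = 2.0
    tube: TubePhantomSpec = field(default_factory=lambda: TubePhantomSpec(
        length_mm=10.0, base_diameter_mm=0.4, scale_mm_per_px=0.02))
    wave_frequency_mHz: float = 15.0
    wave_speed_mm_s: float = 0.1
    constriction_depth: float = 0.4
    constriction_width_mm: float = 0.8   # gaussian sigma of the constriction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames < 2 or self.frame_interval_s <= 0:
            raise ValueError("need >= 2 frames with positive interval")
        if self.wave_frequency_mHz < 0 or self.wave_speed_mm_s < 0:
            raise ValueError("frequency and speed must be nonnegative")
        if not 0.0 <= self.constriction_depth < 1.0:
            raise ValueError("constriction depth must lie in [0, 1)")
        if self.constriction_width_mm <= 0:
            raise ValueError("constriction width must be positive")
        nyquist_mHz = 500.0 / self.frame_interval_s
        if self.wave_frequency_mHz >= nyquist_mHz:
            raise ValueError(
                f"Nyquist limit violated: {self.wave_frequency_mHz} mHz >= "
                f"{nyquist_mHz:.1f} mHz for a {self.frame_interval_s} s frame interval")
        if self.wave_frequency_mHz > 0:
            duration = self.frames * self.frame_interval_s
            if duration * self.wave_frequency_mHz * 1e-3 < 2.0:
                raise ValueError("movie shorter than two wave periods")
        if self.tube.midline_kind != "straight":
            raise ValueError("peristalsis movies support straight tubes only")


def generate_peristalsis_movie(spec: PeristalsisMovieSpec) -> tuple[np.ndarray, WaveStats]:
    """Movie of a straight tube with constrictions translating along it.

    Constrictions nucleate at the left end at the stated frequency and move
    right at the stated speed; each multiplies the local radius by
    ``1 - depth * exp(-(x - x_wave)^2 / (2 w^2))``.
    """
    scale = spec.tube.scale_mm_per_px
    L = spec.tube.length_mm
    f_Hz = spec.wave_frequency_mHz * 1e-3
    v = spec.wave_speed_mm_s
    n_x = int(round(L / scale)) + 1
    x = np.arange(n_x) * scale
    r0 = _radius_profile(spec.tube, x)
    half_h = int(math.ceil(r0.max() / scale * 1.6)) + 4
    yc = half_h + _SUBPIXEL_OFFSET
    rows = np.arange(2 * half_h + 1)

    duration = spec.frames * spec.frame_interval_s
    stack = np.empty((spec.frames, len(rows), n_x), dtype=np.uint8)
    if f_Hz > 0 and v > 0:
        period = 1.0 / f_Hz
        k_min = -int(math.ceil((L / v) / period)) - 1
        k_max = int(math.ceil(duration / period)) + 1
        t_nucleate = np.arange(k_min, k_max + 1) * period
    else:
        t_nucleate = np.array([])

    w = spec.constriction_width_mm
    for i in range(spec.frames):
        t = i * spec.frame_interval_s
        r = r0.copy()
        if t_nucleate.size:
            centers = v * (t - t_nucleate)
            centers = centers[(centers > -4 * w) & (centers < L + 4 * w)]
            if centers.size:
                mod = np.exp(-((x[None, :] - centers[:, None]) ** 2) / (2 * w * w)).sum(axis=0)
                r = r0 * np.clip(1.0 - spec.constriction_depth * mod, 0.05, None)
        inside = np.abs(rows[:, None] - yc) * scale <= r[None, :]
        stack[i] = np.where(inside, 200, 30).astype(np.uint8)

    if f_Hz > 0:
        n_waves = int(math.floor(f_Hz * duration))
        direction = "forward"
    else:
        n_waves, direction = 0, "mixed"
    truth = WaveStats(
        frequency_mHz=spec.wave_frequency_mHz if f_Hz > 0 else 0.0,
        speed_mm_s=v if f_Hz > 0 else 0.0,
        n_waves=n_waves, direction=direction,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cantilever calibration data
# ---------------------------------------------------------------------------

def generate_calibration_data(
    sensitivity_deg_per_N: float,
    masses_mg,
    noise_sd_deg: float = 0.0,
    seed: int = 0,
    g_m_s2: float = bm.STANDARD_GRAVITY_M_S2,
) -> pd.DataFrame:
    """Linear deflection table: ``deflection = sensitivity * m g + noise``."""
    masses = np.asarray(masses_mg, float)
    if np.any(masses < 0):
        raise ValueError("masses must be nonnegative")
    if np.any(np.diff(masses) <= 0):
        raise ValueError("masses must be strictly increasing")
    if sensitivity_deg_per_N <= 0:
        raise ValueError("sensitivity must be positive")
    if noise_sd_deg < 0:
        raise ValueError("noise sd must be nonnegative")
    force_N = masses * 1e-6 * g_m_s2
    defl = sensitivity_deg_per_N * force_N
    if noise_sd_deg > 0:
        rng = np.random.default_rng(seed)
        defl = defl + rng.normal(0.0, noise_sd_deg, len(defl))
    return pd.DataFrame({"mass_mg": masses, "deflection_deg": defl})
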