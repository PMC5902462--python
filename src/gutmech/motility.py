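"""Kymograph (motiligram) construction and contraction-wave statistics.

A kymograph is the intensity of a movie sampled along a fixed line ROI,
stacked over time (rows = positions, columns = frames). Propagating
constrictions appear as sloped stripes: their count per unit time is the
wave frequency and their slope the propagation speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["Kymograph", "WaveStats", "MotilityConfig", "build_kymograph", "wave_stats"]


@dataclass(frozen=True)
class Kymograph:
    """Space-by-time intensity matrix with physical scales."""

    matrix: np.ndarray   # (n_positions, n_frames)
    dx_mm: float
    dt_s: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
            raise ValueError("kymograph needs >= 2 positions and >= 2 frames")
        if self.dx_mm <= 0 or self.dt_s <= 0:
            raise ValueError("steps must be positive")
        object.__setattr__(self, "matrix", m)

    @property
    def duration_s(self) -> float:
        return self.matrix.shape[1] * self.dt_s


@dataclass(frozen=True)
class WaveStats:
    frequency_mHz: float
    speed_mm_s: float
    n_waves: int
    direction: str                      # forward | backward | mixed
    detection_floor_mHz: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_mHz < 0 or self.speed_mm_s < 0 or self.n_waves < 0:
            raise ValueError("wave statistics must be nonnegative")
        if self.direction not in ("forward", "backward", "mixed"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class MotilityConfig:
    mixed_peak_ratio: float = 0.8     # secondary/primary amplitude for "mixed"
    min_amplitude_frac: float = 0.1   # positions used for the phase fit


def build_kymograph(
    stack: np.ndarray,
    roi_line: tuple,
    width_px: int,
    scale_mm_per_px: float,
    dt_s: float,
) -> Kymograph:
    """Sample each frame along a line ROI, averaging across its width.

    ``roi_line`` is ``((x0, y0), (x1, y1))`` in pixel coordinates
    (x = column, y = row). Intensity is bilinearly interpolated at unit steps
    along the line and averaged over ``width_px`` parallel offsets.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be a 3D (time, row, col) array")
    if width_px < 1:
        raise ValueError("width must be >= 1")
    if scale_mm_per_px <= 0 or dt_s <= 0:
        raise ValueError("scale and frame interval must be positive")
    (x0, y0), (x1, y1) = roi_line
    p0 = np.array([x0, y0], float)
    p1 = np.array([x1, y1], float)
    length = np.linalg.norm(p1 - p0)
    if length == 0:
        raise ValueError("ROI line has zero length")
    n_pos = int(np.floor(length)) + 1
    u = (p1 - p0) / length
    nvec = np.array([-u[1], u[0]])
    steps = np.linspace(0.0, length, n_pos)
    base = p0[None, :] + steps[:, None] * u[None, :]
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0)
    sample_xy = base[None, :, :] + offsets[:, None, None] * nvec[None, None, :]

    n_rows, n_cols = stack.shape[1:]
    xs, ys = sample_xy[..., 0], sample_xy[..., 1]
    if xs.min() < -0.5 or ys.min() < -0.5 or xs.max() > n_cols - 0.5 or ys.max() > n_rows - 0.5:
        raise ValueError("ROI line (with width) exits the frame")

    coords = np.stack([ys.ravel(), xs.ravel()])  # (row, col) order
    out = np.empty((n_pos, stack.shape[0]), float)
    for t in range(stack.shape[0]):
        vals = ndimage.map_coordinates(stack[t].astype(float), coords, order=1, mode="nearest")
        out[:, t] = vals.reshape(width_px, n_pos).mean(axis=0)
    return Kymograph(matrix=out, dx_mm=scale_mm_per_px, dt_s=dt_s)


def _refine_peak(power: np.ndarray, k: int) -> float:
    """Sub-bin peak position by parabolic interpolation on log power."""
    if k <= 0 or k >= len(power) - 1:
        return float(k)
    with np.errstate(divide="ignore"):
        y = np.log(np.maximum(power[k - 1:k + 2], 1e-300))
    denom = y[0] - 2 * y[1] + y[2]
    if denom >= 0:
        return float(k)
    return float(k + 0.5 * (y[0] - y[2]) / denom)


def wave_stats(kymo: Kymograph, config: MotilityConfig | None = None) -> WaveStats:
    """Dominant wave frequency and propagation speed of a kymograph.

    Frequency: dominant peak of the position-averaged temporal power spectrum
    of the per-position detrended kymograph (Hann-windowed, parabolic sub-bin
    refinement). Speed: slope of the (amplitude-weighted, unwrapped) spectral
    phase across positions at the dominant frequency; a traveling wave
    ``cos(2 pi f (t - x/v))`` has phase ``-2 pi f x / v`` so the slope gives
    ``v`` including its sign. A secondary non-adjacent spectral peak whose
    amplitude reaches ``mixed_peak_ratio`` of the primary flags direction
    "mixed".
    """
    cfg = config or MotilityConfig()
    m = kymo.matrix
    n_pos, n_t = m.shape
    duration = n_t * kymo.dt_s
    floor_mHz = 2.0 / duration * 1e3
    detrended = m - m.mean(axis=1, keepdims=True)
    if np.ptp(detrended) < 1e-9 * max(np.ptp(m), 1.0) or np.ptp(m) == 0:
        return WaveStats(0.0, 0.0, 0, "mixed", detection_floor_mHz=floor_mHz)

    window = np.hanning(n_t)
    spec = np.fft.rfft(detrended * window[None, :], axis=1)
    power = (np.abs(spec) ** 2).mean(axis=0)
    freqs_mHz = np.fft.rfftfreq(n_t, kymo.dt_s) * 1e3
    valid = freqs_mHz >= floor_mHz
    if not valid.any() or power[valid].max() <= 0:
        return WaveStats(0.0, 0.0, 0, "mixed", detection_floor_mHz=floor_mHz)

    idx = np.where(valid)[0]
    k = idx[np.argmax(power[idx])]
    k_ref = _refine_peak(power, k)
    df_mHz = freqs_mHz[1] - freqs_mHz[0]
    f_mHz = k_ref * df_mHz

    # secondary peak: local maxima away from the primary (> 2 bins)
    amp = np.sqrt(power)
    local_max = np.zeros_like(amp, bool)
    local_max[1:-1] = (amp[1:-1] >= amp[:-2]) & (amp[1:-1] >= amp[2:])
    local_max &= valid
    local_max[max(k - 2, 0):k + 3] = False
    mixed = bool(local_max.any() and amp[local_max].max() >= cfg.mixed_peak_ratio * amp[k])

    # phase-slope propagation speed at the dominant bin
    col = spec[:, k]
    amps = np.abs(col)
    use = amps >= cfg.min_amplitude_frac * amps.max()
    x_mm = np.arange(n_pos) * kymo.dx_mm
    speed = 0.0
    direction = "mixed"
    if use.sum() >= 2:
        phase = np.unwrap(np.angle(col[use]))
        wgt = amps[use]
        slope = np.polyfit(x_mm[use], phase, 1, w=wgt)[0]
        omega = 2 * np.pi * f_mHz * 1e-3
        if abs(slope) > 1e-12:
            v = -omega / slope
            speed = abs(v)
            direction = "forward" if v > 0 else "backward"
    if mixed:
        direction = "mixed"
    n_waves = int(np.floor(f_mHz * 1e-3 * duration))
    return WaveStats(
        frequency_mHz=float(f_mHz), speed_mm_s=float(speed),
        n_waves=n_waves, direction=direction, detection_floor_mHz=floor_mHz,
    )
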