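import numpy as np
import pytest

from gutmech.morphometry import (
    bezier_profile_volume,
    extract_contour,
    medial_axis_voronoi,
    morphometry_from_midline,
    segment_silhouette,
)
from gutmech.synthetic import TubePhantomSpec, generate_tube_image


def make_random_specs(n: int, seed: int) -> list[TubePhantomSpec]:
    """Random curved-tube phantoms: sinusoidal midlines with bend amplitude
    up to 2 diameters, taper up to 30%, rasterized at scale = diameter/20."""
    rng = np.random.default_rng(seed)
    specs = []
    while len(specs) < n:
        d = float(rng.uniform(0.30, 0.45))
        length = float(rng.uniform(9.0, 12.0))
        lam = float(rng.uniform(4.0, 6.5))
        k2 = (2 * np.pi / lam) ** 2
        amp_cap = min(2.0 * d, 0.8 / (k2 * d))  # keep bend radius > tube radius
        amp = float(rng.uniform(0.2, 1.0) * amp_cap)
        taper = float(rng.uniform(-0.3, 0.3))
        specs.append(TubePhantomSpec(
            midline_kind="sinusoid", length_mm=length, base_diameter_mm=d,
            taper=taper, bend_amplitude_mm=amp, bend_wavelength_mm=lam,
            scale_mm_per_px=d / 20.0, seed=int(rng.integers(1_000_000)),
        ))
    return specs


@pytest.fixture(scope="session")
def phantom_suite():
    """20 random phantoms measured once by both morphometry routes."""
    results = []
    for spec in make_random_specs(20, seed=1234):
        phantom = generate_tube_image(spec)
        mask = segment_silhouette(phantom.image, spec.scale_mm_per_px)
        contour = extract_contour(mask, spec.scale_mm_per_px)
        midline = medial_axis_voronoi(contour)
        voronoi = morphometry_from_midline(midline)
        bezier = bezier_profile_volume(contour)
        results.append({
            "spec": spec, "phantom": phantom, "contour": contour,
            "midline": midline, "voronoi": voronoi, "bezier": bezier,
        })
    return results
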