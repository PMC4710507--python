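"""Tumour-treating-fields maps: intensity -> spatial mitotic-rate reduction.

Alternating electric fields reduce glioma proliferation in a dose-dependent
way.  Given per-voxel field-intensity maps (V/cm) for the two transducer
orientations, the effective intensity is the voxelwise maximum, converted
through a cubic dose-response curve into a per-voxel factor in [0, 1] that
multiplies the mitotic rate tau.

The package does not compute head-model electric fields; intensity maps are
consumed as input.  The bundled default response curve is synthetic: a
monotone-decreasing cubic with curve(0) = 1, standing in for a fit to
measured dose-response data, with coefficients exposed as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BrainGeometry

__all__ = [
    "ResponseCurve",
    "default_response_curve",
    "combine_orientations",
    "intensity_to_reduction",
    "synthetic_intensity_field",
    "apply_to_tau",
]


@dataclass
class ResponseCurve:
    """Cubic intensity (V/cm) -> relative proliferation (fraction of untreated).

    ``coeffs`` are (c0, c1, c2, c3) for c0 + c1 x + c2 x^2 + c3 x^3;
    ``valid_range`` clamps input intensities.  The curve must satisfy
    curve(0) = 1 (untreated cells proliferate at the full rate) and its
    output is clamped to [0, 1].
    """

    coeffs: tuple[float, float, float, float]
    valid_range: tuple[float, float] = (0.0, 4.0)

    def __post_init__(self) -> None:
        if abs(self.coeffs[0] - 1.0) > 1e-6:
            raise ValueError("response curve must satisfy curve(0) = 1")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("invalid intensity range")

    def __call__(self, intensity) -> np.ndarray:
        x = np.clip(np.asarray(intensity, dtype=float), *self.valid_range)
        c0, c1, c2, c3 = self.coeffs
        y = c0 + c1 * x + c2 * x**2 + c3 * x**3
        return np.clip(y, 0.0, 1.0)


def default_response_curve() -> ResponseCurve:
    """Synthetic monotone-decreasing dose-response cubic on [0, 4] V/cm.

    Proliferation falls from 1 at zero field to ~0.1 at 4 V/cm, mirroring
    the qualitative shape of published in-vitro dose-response data (the
    quantitative points are not bundled; pass your own coefficients to
    use a fitted curve).
    """
    # fit target: 1.0 at 0, ~0.75 at 1, ~0.45 at 2, ~0.22 at 3, ~0.1 at 4
    coeffs = np.polynomial.polynomial.polyfit(
        [0.0, 1.0, 2.0, 3.0, 4.0], [1.0, 0.75, 0.45, 0.22, 0.10], 3
    )
    coeffs[0] = 1.0
    return ResponseCurve(coeffs=tuple(float(c) for c in coeffs))


def combine_orientations(field_lr: np.ndarray, field_fb: np.ndarray) -> np.ndarray:
    """Effective intensity: voxelwise maximum over the two array orientations."""
    a = np.asarray(field_lr, dtype=float)
    b = np.asarray(field_fb, dtype=float)
    if a.shape != b.shape:
        raise ValueError("orientation maps must share one shape")
    return np.maximum(a, b)


def intensity_to_reduction(intensity: np.ndarray, curve: ResponseCurve) -> np.ndarray:
    """Per-voxel proliferation-reduction factor in [0, 1] (multiplies tau)."""
    return curve(intensity)


def apply_to_tau(tau, reduction: np.ndarray) -> np.ndarray:
    """Local proliferation rate: basic mitotic rate times the reduction factor."""
    return np.asarray(tau, dtype=float) * np.asarray(reduction, dtype=float)


def synthetic_intensity_field(
    geom: BrainGeometry,
    seed: int = 0,
    pattern: str = "gradient",
    peak: float = 3.0,
) -> np.ndarray:
    """Smooth synthetic field-intensity map (V/cm) supported on the brain mask.

    ``gradient`` rises monotonically along the column axis (one array
    dominating); ``bifocal`` has two Gaussian hot spots, emulating the
    two-orientation maximum near the transducers.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rows, cols = geom.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    if pattern == "gradient":
        f = peak * (cc + 1.0) / cols
    elif pattern == "bifocal":
        f = np.zeros((rows, cols))
        idx = np.argwhere(geom.mask)
        for _ in range(2):
            r0, c0 = idx[rng.integers(len(idx))]
            w = 0.18 * min(rows, cols)
            f += peak * np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * w * w)))
        f *= peak / max(f.max(), 1e-12)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    f = f * geom.mask
    return f
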