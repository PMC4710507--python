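"""Brain domains: synthetic mask generation, labeled-grid I/O, tumour seeding.

The solver works on a rectangular grid of square voxels.  Brain tissue is a
connected mask; everything outside (skull, skin, background) is impermeable
to tumour cells.  The default voxel edge is 1.5 mm so each voxel covers
2.25 mm^2, matching clinical-MRI resolution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .model_core import TumorState

DEFAULT_SPACING_MM = 1.5  # voxel edge; area 2.25 mm^2

__all__ = [
    "BrainGeometry",
    "EmptyMaskError",
    "generate_synthetic_brain",
    "load_labeled_grid",
    "seed_tumor",
]


class EmptyMaskError(ValueError):
    """Raised when a labeled grid contains no brain-tissue voxels."""


@dataclass
class BrainGeometry:
    """A 2-D brain domain.

    Attributes
    ----------
    mask : bool ndarray
        True on brain tissue; False voxels are impermeable.
    B0 : ndarray
        Initial brain-cell density (1.0 inside the mask, 0 outside).
    D : ndarray
        Dimensionless diffusion-enhancement field (white-matter tracks,
        vessels); 1.0 inside the mask by default, 0 outside.
    spacing : float
        Voxel edge length in mm.
    """

    mask: np.ndarray
    B0: np.ndarray
    D: np.ndarray
    spacing: float = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.B0 = np.asarray(self.B0, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if not (self.mask.shape == self.B0.shape == self.D.shape):
            raise ValueError("mask, B0 and D must share one shape")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if np.any(self.D < 0):
            raise ValueError("D must be non-negative")
        if not self.mask.any():
            raise EmptyMaskError("geometry has no brain voxels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_brain_voxels(self) -> int:
        return int(self.mask.sum())

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path, brain_label: str = "brain", other_label: str = "bone") -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            for row in self.mask:
                w.writerow([brain_label if v else other_label for v in row])

    def to_pgm(self, path, brain_value: int = 255) -> None:
        rows, cols = self.shape
        with open(path, "w") as fh:
            fh.write(f"P2\n{cols} {rows}\n255\n")
            for row in self.mask:
                fh.write(" ".join(str(brain_value if v else 0) for v in row) + "\n")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def generate_synthetic_brain(
    rows: int,
    cols: int,
    seed: int = 0,
    spacing: float = DEFAULT_SPACING_MM,
    white_matter_ridges: bool = False,
) -> BrainGeometry:
    """Generate a roughly elliptical brain mask with an irregular boundary.

    The boundary radius is an ellipse perturbed by a few random low-order
    Fourier modes, giving an organic-looking, connected mask that keeps a
    one-voxel margin to the grid border.  With ``white_matter_ridges`` the
    diffusion-enhancement field carries smooth elevated bands emulating
    white-matter tracks; otherwise D = 1 on brain tissue.
    """
    if rows < 16 or cols < 16:
        raise ValueError("grid too small: need rows, cols >= 16")
    rng = np.random.default_rng(seed)

    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    ar, ac = 0.44 * rows, 0.42 * cols
    rr, cc = np.mgrid[0:rows, 0:cols]
    theta = np.arctan2((rr - r0) / ar, (cc - c0) / ac)
    rho = np.hypot((rr - r0) / ar, (cc - c0) / ac)

    # low-order angular perturbation of the ellipse radius
    bump = np.zeros_like(theta)
    for k in range(2, 6):
        amp = 0.06 * rng.uniform(0.3, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        bump += amp * np.cos(k * theta + phase)
    mask = rho <= 1.0 + bump

    mask[0, :] = mask[-1, :] = False
    mask[:, 0] = mask[:, -1] = False
    mask = _largest_component(mask)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise ValueError("grid too small to contain a brain mask")

    B0 = mask.astype(float)
    D = mask.astype(float)
    if white_matter_ridges:
        # a couple of smooth elevated bands inside the mask
        field = np.zeros((rows, cols))
        for _ in range(3):
            cr = rng.uniform(0.25, 0.75) * rows
            ccn = rng.uniform(0.25, 0.75) * cols
            ang = rng.uniform(0, np.pi)
            d = np.abs(
                (rr - cr) * np.sin(ang) - (cc - ccn) * np.cos(ang)
            )
            field += np.exp(-((d / (0.05 * min(rows, cols))) ** 2))
        D = D * (1.0 + 1.5 * field)
        D[~mask] = 0.0
    return BrainGeometry(mask=mask, B0=B0, D=D, spacing=spacing)


def _read_pgm(path: Path) -> np.ndarray:
    data = path.read_bytes()
    if data[:2] not in (b"P2", b"P5"):
        raise ValueError(f"{path}: not a PGM (P2/P5) file")
    binary = data[:2] == b"P5"
    # strip comments, collect header tokens
    tokens: list[bytes] = []
    i = 2
    while len(tokens) < 3:
        while i < len(data) and data[i : i + 1].isspace():
            i += 1
        if data[i : i + 1] == b"#":
            while i < len(data) and data[i : i + 1] != b"\n":
                i += 1
            continue
        j = i
        while j < len(data) and not data[j : j + 1].isspace():
            j += 1
        tokens.append(data[i:j])
        i = j
    cols, rows, _maxval = (int(t) for t in tokens)
    if binary:
        raster = np.frombuffer(data[i + 1 : i + 1 + rows * cols], dtype=np.uint8)
    else:
        raster = np.array(data[i:].split(), dtype=int)
    if raster.size != rows * cols:
        raise ValueError(f"{path}: raster size does not match header")
    return raster.reshape(rows, cols)


def load_labeled_grid(
    path,
    brain_labels,
    spacing: float = DEFAULT_SPACING_MM,
) -> BrainGeometry:
    """Read a labeled tissue grid (CSV of labels or PGM) into a geometry.

    Voxels whose label is in ``brain_labels`` become brain tissue
    (mask=True, B0=1, D=1); all others are impermeable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels = {str(l) for l in brain_labels}
    if path.suffix.lower() == ".pgm":
        grid = _read_pgm(path)
        mask = np.isin(grid.astype(str), list(labels))
    else:
        rows = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if row:
                    rows.append([c.strip() for c in row])
        if not rows:
            raise ValueError(f"{path}: empty file")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise ValueError(f"{path}: non-rectangular grid")
        mask = np.array([[c in labels for c in r] for r in rows])
    if not mask.any():
        raise EmptyMaskError(f"{path}: no voxel carries a brain label")
    return BrainGeometry(
        mask=mask, B0=mask.astype(float), D=mask.astype(float), spacing=spacing
    )


def seed_tumor(
    geom: BrainGeometry,
    voxel: tuple[int, int] | None = None,
    p0: float = 0.1,
    i0: float = 0.01,
) -> TumorState:
    """Insert a small tumour seed into a single voxel.

    Defaults follow the convention of starting with proliferative cells on
    the order of 1e-1 and invasive cells on the order of 1e-2.  When
    ``voxel`` is None the seed goes to the voxel nearest the mask centroid.
    """
    if p0 < 0 or i0 < 0:
        raise ValueError("seed concentrations must be non-negative")
    if voxel is None:
        idx = np.argwhere(geom.mask)
        centroid = idx.mean(axis=0)
        voxel = tuple(idx[np.argmin(((idx - centroid) ** 2).sum(axis=1))])
    r, c = voxel
    if not (0 <= r < geom.shape[0] and 0 <= c < geom.shape[1]) or not geom.mask[r, c]:
        raise ValueError(f"seed voxel {voxel} is outside the brain mask")
    P = np.zeros(geom.shape)
    I = np.zeros(geom.shape)
    P[r, c] = p0
    I[r, c] = i0
    return TumorState(P=P, I=I, B=geom.B0.copy(), N=np.zeros(geom.shape), t=0.0)
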