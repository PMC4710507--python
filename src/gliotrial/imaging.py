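"""Virtual-MRI readouts: voxel classification, area summaries, progression patterns.

Simulated states are read the way a neuro-radiologist reads serial MRI:

* **necrosis** — voxels where at least 80% of the brain cells have died
  (a "hole in the brain" on imaging);
* **high-density tumour (HiDen)** — total tumour concentration above 0.7,
  the proxy for gadolinium-enhancing mass on T1;
* **FLAIR** — infiltrative, lower-density tumour with total concentration
  between 0.05 and 0.7, the T2/FLAIR-hyperintense signal.

Areas are reported as percent of brain-mask voxels.  Serial summaries are
mapped to progression-pattern labels (Expanding FLAIR, Expanding FLAIR +
Necrosis, Expanding Necrosis) from the direction of change of each signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .geometry import BrainGeometry
from .model_core import TumorState

NECROSIS_BRAIN_FRACTION = 0.2  # B/B0 below this = >80% brain death
HIDEN_THRESHOLD = 0.7
FLAIR_LOWER = 0.05

__all__ = [
    "VoxelClass",
    "ImagingSummary",
    "classify_voxels",
    "summarize",
    "imaging_summary",
    "progression_pattern",
]


class VoxelClass(IntEnum):
    NORMAL = 0
    FLAIR = 1
    HIDEN = 2
    NECROTIC = 3


@dataclass(frozen=True)
class ImagingSummary:
    """Percent-of-brain areas of the three imaging classes at one time."""

    t: float
    pct_necrosis: float
    pct_hiden: float
    pct_flair: float


def classify_voxels(state: TumorState, geom: BrainGeometry) -> np.ndarray:
    """Label every brain voxel as necrotic, high-density, FLAIR or normal.

    Precedence is necrotic > high-density > FLAIR: a voxel whose brain
    tissue is dead reads as necrosis regardless of residual tumour cells.
    Non-mask voxels stay NORMAL.
    """
    mask = geom.mask
    if np.any(geom.B0[mask] <= 0):
        raise ValueError("B0 must be positive inside the brain mask")
    tumor = state.P + state.I
    frac = np.ones_like(geom.B0)
    frac[mask] = state.B[mask] / geom.B0[mask]

    labels = np.zeros(geom.shape, dtype=np.uint8)
    flair = (tumor >= FLAIR_LOWER) & (tumor <= HIDEN_THRESHOLD)
    labels[mask & flair] = VoxelClass.FLAIR
    labels[mask & (tumor > HIDEN_THRESHOLD)] = VoxelClass.HIDEN
    labels[mask & (frac < NECROSIS_BRAIN_FRACTION)] = VoxelClass.NECROTIC
    return labels


def summarize(labels: np.ndarray, geom: BrainGeometry, t: float = 0.0) -> ImagingSummary:
    """Percent of brain voxels in each imaging class."""
    n = geom.n_brain_voxels
    return ImagingSummary(
        t=t,
        pct_necrosis=100.0 * int((labels == VoxelClass.NECROTIC).sum()) / n,
        pct_hiden=100.0 * int((labels == VoxelClass.HIDEN).sum()) / n,
        pct_flair=100.0 * int((labels == VoxelClass.FLAIR).sum()) / n,
    )


def imaging_summary(state: TumorState, geom: BrainGeometry) -> ImagingSummary:
    """Classify and summarise in one call."""
    return summarize(classify_voxels(state, geom), geom, t=state.t)


def _direction(before: float, after: float, threshold: float) -> int:
    """+1 increase, -1 decrease, 0 stable, judged by relative change.

    For a near-zero baseline any appreciable absolute change (the same
    fraction of one percent of brain) counts as a change.
    """
    ref = max(before, threshold * 4)  # floor so 0 -> 0.01% is not an "increase"
    change = (after - before) / ref if ref > 0 else 0.0
    if change > threshold:
        return 1
    if change < -threshold:
        return -1
    return 0


def progression_pattern(
    at_treatment: ImagingSummary,
    first_fu: ImagingSummary,
    at_progression: ImagingSummary,
    rel_change_threshold: float = 0.25,
) -> str:
    """Map serial imaging to a progression-pattern label.

    Change from first follow-up to progression is scored as up / stable /
    down per signal using a relative-change band (default 25%, the same
    fraction used to call an initial response in gadolinium enhancement):

    * FLAIR up, necrosis stable       -> ``ExpandingFLAIR``
    * FLAIR up, necrosis up           -> ``ExpandingFLAIRplusNecrosis``
    * FLAIR stable, necrosis up       -> ``ExpandingNecrosis``
    * anything else                   -> ``NoProgression``
    """
    if not (at_treatment.t <= first_fu.t <= at_progression.t):
        raise ValueError("summaries must be in chronological order")
    thr = rel_change_threshold
    flair = _direction(first_fu.pct_flair, at_progression.pct_flair, thr)
    necro = _direction(first_fu.pct_necrosis, at_progression.pct_necrosis, thr)
    if flair > 0 and necro == 0:
        return "ExpandingFLAIR"
    if flair > 0 and necro > 0:
        return "ExpandingFLAIRplusNecrosis"
    if flair == 0 and necro > 0:
        return "ExpandingNecrosis"
    return "NoProgression"
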