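"""Quantitative ablation-outcome evaluation.

After the pre-ablation tumor mask has been warped onto the intraprocedural
CBCT grid, the residual tumor (tumor AND NOT ablation zone) is measured in
cm^3 and as a percentage of the initial tumor volume, the minimum
periablational margin is computed from Euclidean distance transforms (the
5-10 mm margin being the clinical adequacy criterion), and the case is
classified complete / partial / missed with an explicit retreatment rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import Mask
from .registration import LandmarkPairSet
from .transforms import TransformChain

__all__ = [
    "AblationAssessment",
    "mask_volume_cm3",
    "residual_assessment",
    "min_margin",
    "classify_retreatment",
    "dice",
    "target_registration_error",
    "tre_to_position_score",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of printed clinical
    percentages), avoiding banker's rounding."""
    q = 10.0**decimals
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


@dataclass
class AblationAssessment:
    """Volumes in cm^3, residual percentage of the initial tumor volume,
    minimum margin in mm (negative when the tumor is not fully covered) and
    the complete/partial/missed classification."""

    tumor_volume: float
    ablation_volume: float
    residual_volume: float
    residual_percentage: float
    min_margin: float
    classification: str

    def to_dict(self):
        return {
            "tumor_volume_cm3": self.tumor_volume,
            "ablation_volume_cm3": self.ablation_volume,
            "residual_volume_cm3": self.residual_volume,
            "residual_percentage": self.residual_percentage,
            "min_margin_mm": self.min_margin,
            "classification": self.classification,
        }


def mask_volume_cm3(m: Mask) -> float:
    """Foreground voxel count times voxel volume, in cm^3."""
    return m.count() * m.grid.voxel_volume_mm3 / 1000.0


def _check_common_grid(a: Mask, b: Mask):
    if not a.grid.same_geometry(b.grid, tol=1e-6):
        raise ValueError("masks are not defined on a common grid")


def residual_assessment(tumor_warped: Mask, ablation: Mask) -> AblationAssessment:
    """Residual = tumor AND NOT ablation, on the common (CBCT) grid.

    The percentage is reported to 1 decimal, ties rounded away from zero.
    Classification: ``missed`` iff no tumor voxel is ablated, ``complete``
    iff every tumor voxel is, else ``partial``.
    """
    _check_common_grid(tumor_warped, ablation)
    t = tumor_warped.labels.astype(bool)
    a = ablation.labels.astype(bool)
    if not t.any():
        raise ValueError("empty tumor mask")
    residual = t & ~a
    vox = tumor_warped.grid.voxel_volume_mm3 / 1000.0
    tumor_volume = float(t.sum()) * vox
    ablation_volume = float(a.sum()) * vox
    residual_volume = float(residual.sum()) * vox
    pct = round_half_away(100.0 * residual.sum() / t.sum(), 1)
    if residual.sum() == t.sum():
        cls = "missed"
    elif residual.sum() == 0:
        cls = "complete"
    else:
        cls = "partial"
    margin = min_margin(tumor_warped, ablation) if a.any() else -float("inf")
    return AblationAssessment(tumor_volume, ablation_volume, residual_volume,
                              pct, margin, cls)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels 6-adjacent to background (or on the array border)."""
    from scipy.ndimage import binary_erosion

    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1, 1, :] = structure[1, :, 1] = structure[:, 1, 1] = True
    eroded = binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def min_margin(tumor_warped: Mask, ablation: Mask) -> float:
    """Minimum periablational margin in world mm.

    If the tumor is fully covered: the minimum, over tumor-surface voxels,
    of the Euclidean distance to the nearest non-ablation voxel.  Otherwise:
    minus the maximum penetration depth of uncovered tumor voxels (their
    distance to the nearest ablation voxel).
    """
    from scipy.ndimage import distance_transform_edt

    _check_common_grid(tumor_warped, ablation)
    t = tumor_warped.labels.astype(bool)
    a = ablation.labels.astype(bool)
    if not t.any() or not a.any():
        raise ValueError("min_margin requires non-empty tumor and ablation masks")
    spacing = tumor_warped.spacing
    outside = t & ~a
    if outside.any():
        dist_to_abl = distance_transform_edt(~a, sampling=spacing)
        return -float(dist_to_abl[outside].max())
    dist_to_bg = distance_transform_edt(a, sampling=spacing)
    surf = _surface(t)
    return float(dist_to_bg[surf].min())


def classify_retreatment(a: AblationAssessment, threshold_pct: float = 20.0) -> str:
    """Operational rule applied intraprocedurally: a missed target or a
    residual fraction at/above ``threshold_pct`` calls for immediate
    retreatment; a smaller nonzero residual is observed; zero residual is
    complete.  The default 20% separates the retreated cases in the clinical
    series; a 15% cutoff is the alternative discussed there."""
    if a.classification == "missed" or a.residual_percentage >= threshold_pct:
        return "retreat"
    if a.residual_percentage > 0:
        return "observe"
    return "complete"


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|); undefined (error) for two empty masks."""
    _check_common_grid(a, b)
    am = a.labels.astype(bool)
    bm = b.labels.astype(bool)
    denom = am.sum() + bm.sum()
    if denom == 0:
        raise ValueError("Dice undefined: both masks empty")
    return float(2.0 * (am & bm).sum() / denom)


def target_registration_error(pairs: LandmarkPairSet, chain: TransformChain) -> dict:
    """Per-pair distance between chain-mapped fixed landmarks and their true
    moving positions; reported as per-pair values plus mean and max (mm)."""
    mapped = chain.apply(pairs.fixed_points)
    d = np.linalg.norm(mapped - pairs.moving_points, axis=1)
    return {"per_pair_mm": d, "mean_mm": float(d.mean()), "max_mm": float(d.max())}


def tre_to_position_score(tre_mm: float) -> int:
    """Five-point spatial-position score (5: < 1 mm ... 1: > 7 mm); interval
    boundaries are assigned to the better score (3 mm -> 4)."""
    if tre_mm < 0:
        raise ValueError("TRE must be non-negative")
    if tre_mm <= 1.0:
        return 5
    if tre_mm <= 3.0:
        return 4
    if tre_mm <= 5.0:
        return 3
    if tre_mm <= 7.0:
        return 2
    return 1
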