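"""ROI geometry in a bregma-centred top-view plane.

Coordinates are in millimetres: x is lateral (right positive), y is
anterior-posterior (anterior positive), origin at bregma.  Inter-ROI
distances are Euclidean in this plane, which is only an approximation of
axonal path length, and are normalised by the bregma-lambda distance so
they are comparable across animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

#: The six dorsal-cortex areas imaged per hemisphere.
AREAS = ("V1", "V2am", "RSC", "M1", "A24b", "M2")

#: Areas posterior to bregma (visual / retrosplenial group).
POSTERIOR_AREAS = frozenset({"V1", "V2am", "RSC"})

#: Areas anterior to bregma (motor / cingulate group).
ANTERIOR_AREAS = frozenset({"M1", "A24b", "M2"})

# Approximate area centres (|x| mm lateral, y mm from bregma).
_AREA_CENTERS = {
    "V1": (2.5, -3.4),
    "V2am": (1.7, -2.8),
    "RSC": (0.6, -2.9),
    "M1": (1.7, 1.0),
    "A24b": (0.4, 1.0),
    "M2": (0.9, 2.3),
}


def area_of(roi_id: str) -> str:
    """Area name of an ROI id such as ``'V1_L'``."""
    return roi_id.rsplit("_", 1)[0]


def is_posterior(roi_id: str) -> bool:
    return area_of(roi_id) in POSTERIOR_AREAS


@dataclass(frozen=True)
class RoiGeometry:
    """Centres of the 12 ROIs and the animal's bregma-lambda distance."""

    coords_mm: dict[str, tuple[float, float]]
    bregma_lambda_mm: float = 4.2

    def __post_init__(self) -> None:
        if self.bregma_lambda_mm <= 0:
            raise ValueError("bregma_lambda_mm must be > 0")
        if len(self.coords_mm) != len(set(self.coords_mm)):
            raise ValueError("duplicate ROI ids")

    @property
    def roi_ids(self) -> list[str]:
        return list(self.coords_mm)

    def distance_mm(self, roi_a: str, roi_b: str) -> float:
        xa, ya = self.coords_mm[roi_a]
        xb, yb = self.coords_mm[roi_b]
        return float(np.hypot(xa - xb, ya - yb))

    def d_norm(self, roi_a: str, roi_b: str) -> float:
        """Pair distance in units of the bregma-lambda distance."""
        return self.distance_mm(roi_a, roi_b) / self.bregma_lambda_mm

    def pair_distances(self) -> dict[tuple[str, str], float]:
        """Normalised distance for every unordered ROI pair (a < b)."""
        out = {}
        for a, b in combinations(sorted(self.roi_ids), 2):
            out[(a, b)] = self.d_norm(a, b)
        return out

    def distance_matrix_mm(self, roi_ids: list[str] | None = None) -> np.ndarray:
        ids = roi_ids if roi_ids is not None else self.roi_ids
        xy = np.array([self.coords_mm[r] for r in ids])
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff**2).sum(-1))


def default_geometry(bregma_lambda_mm: float = 4.2) -> RoiGeometry:
    """Canonical 12-ROI layout (six areas, both hemispheres)."""
    coords = {}
    for area, (x, y) in _AREA_CENTERS.items():
        coords[f"{area}_L"] = (-x, y)
        coords[f"{area}_R"] = (x, y)
    return RoiGeometry(coords_mm=coords, bregma_lambda_mm=bregma_lambda_mm)
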