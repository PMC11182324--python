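"""Cone-mosaic spacing metrics and normative z-scores.

The bound nearest-neighbor distance (NND) summarizes mosaic packing:
each cone's Euclidean distance to its nearest neighbor, averaged over
*bound* cones only — those whose Voronoi cell lies entirely inside the
region of interest, so that edge cones with truncated neighborhoods do
not bias the estimate.  Structural and functional metrics are compared
to normative control data as z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi, cKDTree

__all__ = ["MosaicMetricsResult", "NormativeStats", "bound_nnd", "z_score"]


@dataclass
class MosaicMetricsResult:
    mean_bound_nnd: float  # µm
    n_bound_cones: int
    per_cone_nnd: np.ndarray  # µm, for every cone (bound or not)
    bound_mask: np.ndarray  # bool per cone


@dataclass
class NormativeStats:
    """Control mean and SD for one metric at one eccentricity."""

    eccentricity: float  # deg
    metric: str  # "NND" | "OS_length" | "iORG_amplitude"
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("normative sd must be positive")


def _bound_mask(coords: np.ndarray, roi: tuple[float, float, float, float]) -> np.ndarray:
    xmin, ymin, xmax, ymax = roi
    vor = Voronoi(coords)
    mask = np.zeros(coords.shape[0], dtype=bool)
    for i, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if len(region) == 0 or -1 in region:
            continue
        verts = vor.vertices[region]
        mask[i] = bool(
            np.all(verts[:, 0] >= xmin)
            and np.all(verts[:, 0] <= xmax)
            and np.all(verts[:, 1] >= ymin)
            and np.all(verts[:, 1] <= ymax)
        )
    return mask


def bound_nnd(
    coords: np.ndarray,
    roi: tuple[float, float, float, float] | None = None,
    scale: float = 1.0,
) -> MosaicMetricsResult:
    """Bound nearest-neighbor distance of a cone coordinate set.

    Parameters
    ----------
    coords : (N, 2) array
        Cone centers (x, y) in pixels.
    roi : (xmin, ymin, xmax, ymax), optional
        Rectangle (pixel units) that a cone's Voronoi cell must lie
        inside for the cone to count as bound.  Defaults to the
        coordinate bounding box.
    scale : float
        µm per pixel (isotropic).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("bound NND needs >= 2 cones")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if roi is None:
        roi = (
            coords[:, 0].min(), coords[:, 1].min(),
            coords[:, 0].max(), coords[:, 1].max(),
        )
    d, _ = cKDTree(coords).query(coords, k=2)
    nnd_um = d[:, 1] * scale
    mask = _bound_mask(coords, roi)
    if not mask.any():
        raise ValueError(
            f"no bound cones: 0 of {coords.shape[0]} Voronoi cells inside the ROI"
        )
    return MosaicMetricsResult(
        mean_bound_nnd=float(nnd_um[mask].mean()),
        n_bound_cones=int(mask.sum()),
        per_cone_nnd=nnd_um,
        bound_mask=mask,
    )


def z_score(value: float, ref: NormativeStats, absolute: bool = False) -> float:
    """Standardize a metric value against its normative distribution.

    Returns ``(value - mean) / sd``; with ``absolute=True`` the magnitude
    only (the convention of summary tables where only deviation size
    matters).
    """
    z = (value - ref.mean) / ref.sd
    return float(abs(z)) if absolute else float(z)
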