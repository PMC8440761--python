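"""Percentile segmentations and smooth level-set surfaces.

Thresholding the probability map at a level t keeps every voxel with at
least a 100*t % chance of belonging to the segmented class.  Reading the
per-voxel probability as a cumulative distribution, a chosen percentile P
maps to the threshold

    t = 1 - P/100,

so larger percentiles include more voxels: the P = 84.1 (mu + sigma)
segmentation is a superset of the P = 50 median segmentation, which in turn
contains the P = 15.9 (mu - sigma) one.  The three percentiles 15.9 / 50.0 /
84.1 — the standard normal CDF at -1, 0, +1, rounded to one decimal — are
the "standard segmentations" from which the characteristic distribution of
a downstream physics quantity is specified.

The comparison is inclusive (eps >= t): ties belong to the segmentation.

Surfaces are extracted by running marching cubes directly on the real-valued
probability map at level t, never on a binarized mask, which yields a smooth
rather than stair-stepped mesh; vertices are placed at physical coordinates
(index + 0.5) * spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .probmap import ProbabilityMap

__all__ = [
    "STANDARD_PERCENTILES",
    "PercentileSegmentation",
    "StandardSegmentationSet",
    "percentile_to_threshold",
    "threshold_map",
    "standard_segmentations",
    "extract_surface",
    "save_surface_stl",
    "EmptySurfaceError",
]

#: the mu-sigma / median / mu+sigma percentiles, printed to one decimal
STANDARD_PERCENTILES = (15.9, 50.0, 84.1)


class EmptySurfaceError(ValueError):
    """The requested level set does not intersect the map's value range."""


@dataclass
class PercentileSegmentation:
    """A binary volume: mask_v = 1 iff eps[v, class_i] >= threshold."""

    mask: np.ndarray
    percentile: float
    threshold: float
    class_i: int
    provenance: str = ""
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    def issubset(self, other: "PercentileSegmentation") -> bool:
        return bool(np.all(~self.mask | other.mask))


@dataclass
class StandardSegmentationSet:
    """The nested low (15.9) / mid (50.0) / high (84.1) segmentations."""

    low: PercentileSegmentation
    mid: PercentileSegmentation
    high: PercentileSegmentation

    def __post_init__(self):
        if not (self.low.issubset(self.mid) and self.mid.issubset(self.high)):
            raise RuntimeError(
                "standard segmentations are not nested; probability map "
                "mutated between thresholds?"
            )

    def __iter__(self):
        return iter((self.low, self.mid, self.high))


def percentile_to_threshold(P: float) -> float:
    """Map a percentile in (0, 100) to a probability threshold t = 1 - P/100."""
    P = float(P)
    if not 0.0 < P < 100.0:
        raise ValueError(f"percentile must lie strictly in (0, 100), got {P}")
    return 1.0 - P / 100.0


def threshold_map(pmap: ProbabilityMap, class_i: int, P: float,
                  provenance: str = "") -> PercentileSegmentation:
    """Inclusive thresholding of one class map at the percentile-mapped level."""
    t = percentile_to_threshold(P)
    eps = pmap.class_probability(class_i)
    return PercentileSegmentation(
        mask=eps >= t, percentile=float(P), threshold=t, class_i=int(class_i),
        provenance=provenance, voxel_spacing=pmap.voxel_spacing,
    )


def standard_segmentations(pmap: ProbabilityMap, class_i: int,
                           provenance: str = "") -> StandardSegmentationSet:
    """The three standard segmentations at P = 15.9, 50.0 and 84.1."""
    low, mid, high = (threshold_map(pmap, class_i, P, provenance)
                      for P in STANDARD_PERCENTILES)
    return StandardSegmentationSet(low=low, mid=mid, high=high)


def extract_surface(pmap: ProbabilityMap, class_i: int, P: float,
                    spacing=None):
    """Triangle mesh of the eps = t level set via marching cubes.

    Runs on the real-valued class map (smooth level set).  Vertex
    coordinates are physical: cell centers sit at (index + 0.5) * spacing.
    Returns a ``trimesh.Trimesh``.
    """
    import trimesh
    from skimage import measure

    t = percentile_to_threshold(P)
    eps = np.asarray(pmap.class_probability(class_i), dtype=np.float64)
    lo, hi = float(eps.min()), float(eps.max())
    if not lo < t < hi:
        raise EmptySurfaceError(
            f"level {t:.4g} outside the open data range ({lo:.4g}, {hi:.4g}); "
            "no surface to extract"
        )
    sp = tuple(float(s) for s in (spacing if spacing is not None
                                  else pmap.voxel_spacing))
    verts, faces, _, _ = measure.marching_cubes(eps, level=t, spacing=sp)
    verts = verts + 0.5 * np.asarray(sp)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def save_surface_stl(mesh, path) -> None:
    """Export a surface mesh as binary STL."""
    mesh.export(str(path), file_type="stl")
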