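"""Normalized Shannon-entropy uncertainty maps.

A voxel is most uncertain when its class-probability row is uniform and
fully certain when the row is one-hot.  The Shannon entropy of the row,
normalized by log2(n_c), maps this onto [0, 1]:

    H(eps_v) = -sum_i eps[v, i] * log2(eps[v, i]) / log2(n_c)

with the 0*log(0) = 0 convention handled by explicit masking (never by a
numeric epsilon), so one-hot voxels give exactly 0.  The per-class variant
keeps a single term of the sum, so per-class entropies add up to the total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .probmap import ProbabilityMap, ValidationError, save_volume

__all__ = ["UncertaintyMap", "entropy_map", "per_class_entropy_map",
           "entropy_summary"]

#: allowed deviation of a per-voxel probability row sum from 1
ROW_SUM_TOL = 1e-6


@dataclass
class UncertaintyMap:
    """A voxel-wise entropy volume in [0, 1] on the source map's grid."""

    H: np.ndarray
    kind: str  # "total" or "per_class(<i>)"
    n_classes: int
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def save(self, path, format: str | None = None) -> None:
        save_volume(self.H.astype(np.float32), path, format,
                    spacing=self.voxel_spacing)


def _masked_xlog2x(p: np.ndarray) -> np.ndarray:
    """-p*log2(p) with exact zeros at p == 0 and p == 1."""
    out = np.zeros_like(p)
    interior = (p > 0.0) & (p < 1.0)
    pi = p[interior]
    out[interior] = -pi * np.log2(pi)
    return out


def entropy_map(pmap: ProbabilityMap) -> UncertaintyMap:
    """Total normalized Shannon entropy of every voxel's class-probability row.

    Binary single-map inputs auto-expand to the two-class row (eps, 1 - eps).
    Rows must sum to 1 within ``ROW_SUM_TOL``.
    """
    rows = pmap.full_rows()
    n_c = pmap.n_classes
    if n_c < 2:
        raise ValueError("entropy normalizer log2(n_c) requires n_c >= 2")
    row_sum = rows.sum(axis=0)
    if not np.allclose(row_sum, 1.0, atol=ROW_SUM_TOL, rtol=0.0):
        worst = float(np.abs(row_sum - 1.0).max())
        raise ValidationError(
            f"class probabilities must sum to 1 per voxel (worst deviation "
            f"{worst:.3g} > {ROW_SUM_TOL:g}); incomplete class set?"
        )
    H = _masked_xlog2x(rows).sum(axis=0) / np.log2(n_c)
    np.clip(H, 0.0, 1.0, out=H)
    return UncertaintyMap(H=H, kind="total", n_classes=n_c,
                          voxel_spacing=pmap.voxel_spacing)


def per_class_entropy_map(pmap: ProbabilityMap, class_i: int) -> UncertaintyMap:
    """One class's contribution -eps_i*log2(eps_i)/log2(n_c) to the total."""
    n_c = pmap.n_classes
    if n_c < 2:
        raise ValueError("entropy normalizer log2(n_c) requires n_c >= 2")
    p = pmap.class_probability(class_i)
    H = _masked_xlog2x(p) / np.log2(n_c)
    return UncertaintyMap(H=H, kind=f"per_class({class_i})", n_classes=n_c,
                          voxel_spacing=pmap.voxel_spacing)


def entropy_summary(umap: UncertaintyMap) -> dict:
    """Scalar summary used by the CLI's JSON sidecar."""
    H = umap.H
    return {
        "kind": umap.kind,
        "n_classes": umap.n_classes,
        "mean_entropy": float(H.mean()),
        "max_entropy": float(H.max()),
        "fraction_above_half": float(np.count_nonzero(H > 0.5) / H.size),
    }


def write_entropy_summary(umap: UncertaintyMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(entropy_summary(umap), fh, indent=2, sort_keys=True)
        fh.write("\n")
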