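"""Voxel-wise probability maps from ensembles of segmentation samples.

A stack of N co-registered label volumes is the raw evidence of segmentation
uncertainty: every sample is one plausible segmentation of the same 3D image.
The per-voxel, per-class inclusion frequency over the stack,

    eps[v, i] = (1/N) * sum_k [label_k(v) == i],

is the probability map — the central object of the workflow.  All volumes use
the (z, y, x) axis convention, slowest to fastest, matching slice-stack
acquisition.

Accumulation is performed in 64-bit floating point; maps written to disk are
stored as 32-bit floats (N is at most a few hundred, so single precision is
ample and halves storage).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SegmentationSampleStack",
    "ProbabilityMap",
    "compute_probability_map",
    "load_samples",
    "load_probability_map",
    "save_probability_map",
    "save_volume",
    "load_volume",
    "DimensionError",
    "FormatError",
    "ValidationError",
]

#: tolerance for clamping probability values loaded from lossy float storage
CLAMP_TOL = 1e-6

#: tolerance (scaled by N) for the partition-closure check sum_i eps = 1
PARTITION_TOL = 1e-12


class DimensionError(ValueError):
    """Volumes in a stack do not share a common grid."""


class FormatError(ValueError):
    """A file does not parse as an integer label volume of the declared classes."""


class ValidationError(ValueError):
    """Probability values violate the [0, 1] contract beyond tolerance."""


def _as_spacing(spacing) -> tuple[float, float, float]:
    if spacing is None:
        return (1.0, 1.0, 1.0)
    s = tuple(float(x) for x in spacing)
    if len(s) != 3 or any(x <= 0 for x in s):
        raise ValueError(f"voxel_spacing must be 3 positive floats, got {spacing!r}")
    return s


@dataclass
class SegmentationSampleStack:
    """N co-registered label volumes over a common (z, y, x) grid.

    Parameters
    ----------
    samples : ndarray of int, shape (N, Dz, Dy, Dx)
        One label volume per segmentation sample.
    classes : tuple of int
        The class set C; every voxel label must be a member.
    voxel_spacing : tuple of float, length 3
        Physical voxel size per (z, y, x) axis; defaults to isotropic 1.0.
    """

    samples: np.ndarray
    classes: tuple[int, ...]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 4:
            raise DimensionError(
                f"expected samples of shape (N, Dz, Dy, Dx), got {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("a sample stack requires N >= 1 samples")
        if not np.issubdtype(self.samples.dtype, np.integer):
            raise FormatError(f"labels must be integers, got dtype {self.samples.dtype}")
        self.classes = tuple(int(c) for c in self.classes)
        if len(self.classes) < 1:
            raise ValueError("class set must be non-empty")
        self.voxel_spacing = _as_spacing(self.voxel_spacing)
        present = np.unique(self.samples)
        stray = set(present.tolist()) - set(self.classes)
        if stray:
            raise FormatError(
                f"voxel labels {sorted(stray)} are not in the declared class set "
                f"{self.classes}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.samples.shape[1:])


@dataclass
class ProbabilityMap:
    """Per-voxel, per-class inclusion probabilities eps[v, i].

    ``eps`` has shape (n_maps, Dz, Dy, Dx) with one map per entry of
    ``classes``.  For a binary problem (``n_classes == 2``) a single stored
    map for the foreground class suffices; the complement class probability
    is implied as ``1 - eps``.
    """

    eps: np.ndarray
    classes: tuple[int, ...]
    n_classes: int
    n_samples: int | None = None
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.eps = np.asarray(self.eps, dtype=np.float64)
        if self.eps.ndim == 3:
            self.eps = self.eps[None]
        if self.eps.ndim != 4:
            raise DimensionError(
                f"expected eps of shape (n_maps, Dz, Dy, Dx), got {self.eps.shape}"
            )
        self.classes = tuple(int(c) for c in self.classes)
        if len(self.classes) != self.eps.shape[0]:
            raise ValueError(
                f"{self.eps.shape[0]} stored maps but {len(self.classes)} classes"
            )
        if self.n_classes < len(self.classes):
            raise ValueError("n_classes smaller than the number of stored maps")
        if len(self.classes) == 1 and self.n_classes != 2:
            raise ValueError(
                "a single stored map is only meaningful for a binary problem "
                f"(n_classes == 2), got n_classes == {self.n_classes}"
            )
        self.voxel_spacing = _as_spacing(self.voxel_spacing)
        lo, hi = float(self.eps.min()), float(self.eps.max())
        if lo < -CLAMP_TOL or hi > 1 + CLAMP_TOL:
            n_bad = int(np.count_nonzero((self.eps < 0) | (self.eps > 1)))
            raise ValidationError(
                f"{n_bad} probability values outside [0, 1] beyond tolerance "
                f"{CLAMP_TOL:g} (extrema {lo:.6g}, {hi:.6g})"
            )
        np.clip(self.eps, 0.0, 1.0, out=self.eps)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.eps.shape[1:])

    @property
    def is_binary_single(self) -> bool:
        """True when a single foreground map stands for a two-class problem."""
        return len(self.classes) == 1 and self.n_classes == 2

    def class_probability(self, class_i: int) -> np.ndarray:
        """The probability volume for one class.

        For a binary single-map instance the complement class resolves to
        ``1 - eps`` of the stored foreground map.
        """
        if class_i in self.classes:
            return self.eps[self.classes.index(class_i)]
        if self.is_binary_single:
            # any label other than the stored one is the implied complement
            return 1.0 - self.eps[0]
        raise KeyError(f"class {class_i} not in {self.classes}")

    def full_rows(self) -> np.ndarray:
        """Probability rows over the complete class set, shape (n_c, Dz, Dy, Dx)."""
        if self.is_binary_single:
            return np.stack([self.eps[0], 1.0 - self.eps[0]])
        return self.eps


def compute_probability_map(stack: SegmentationSampleStack) -> ProbabilityMap:
    """Average the per-class indicator over all samples (the sample mean).

    Returns one map per class in ``stack.classes``.  Per voxel the maps form
    a probability row summing to 1 exactly (within accumulation tolerance),
    since each sample assigns the voxel to exactly one class.
    """
    n = stack.n_samples
    eps = np.empty((len(stack.classes),) + stack.grid_shape, dtype=np.float64)
    for j, c in enumerate(stack.classes):
        eps[j] = (stack.samples == c).sum(axis=0, dtype=np.float64) / n
    row_sum = eps.sum(axis=0)
    if not np.allclose(row_sum, 1.0, atol=PARTITION_TOL * n, rtol=0.0):
        raise ValidationError("per-voxel class probabilities do not sum to 1")
    return ProbabilityMap(
        eps=eps,
        classes=stack.classes,
        n_classes=len(stack.classes),
        n_samples=n,
        voxel_spacing=stack.voxel_spacing,
    )


# ---------------------------------------------------------------------------
# Volume I/O: multi-page TIFF (one page per z-slice), NRRD (spacing honored),
# NPY (raw array, spacing supplied by the caller).  Little-endian throughout.
# ---------------------------------------------------------------------------

_FORMATS = ("tiff", "nrrd", "npy")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        return "tiff"
    if ext == ".nrrd":
        return "nrrd"
    if ext == ".npy":
        return "npy"
    raise FormatError(f"cannot infer volume format from extension {ext!r}")


def load_volume(path, format: str | None = None):
    """Read one 3D volume; returns ``(array, spacing_or_None)``.

    NRRD spacing metadata is returned in (z, y, x) order; TIFF and NPY carry
    no spacing and return None.
    """
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        import tifffile

        return np.asarray(tifffile.imread(path)), None
    if fmt == "npy":
        return np.load(path), None
    if fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = tuple(reversed(img.GetSpacing()))  # sitk gives (x, y, z)
        return arr, spacing
    raise FormatError(f"unsupported volume format {fmt!r}; expected one of {_FORMATS}")


def save_volume(array: np.ndarray, path, format: str | None = None,
                spacing=None) -> None:
    """Write one 3D volume in the given (or extension-inferred) format."""
    fmt = format or _infer_format(path)
    array = np.asarray(array)
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, array)
        return
    if fmt == "npy":
        np.save(path, array)
        return
    if fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(array)
        if spacing is not None:
            img.SetSpacing(tuple(reversed(_as_spacing(spacing))))
        sitk.WriteImage(img, str(path))
        return
    raise FormatError(f"unsupported volume format {fmt!r}; expected one of {_FORMATS}")


def load_samples(paths: Sequence, format: str | None = None,
                 classes: Sequence[int] | None = None,
                 voxel_spacing=None) -> SegmentationSampleStack:
    """Assemble a sample stack from per-sample volume files.

    Labels are validated against ``classes`` when supplied, otherwise the
    class set is inferred from the union of labels present.  Spacing is read
    from NRRD headers when present; an explicit ``voxel_spacing`` overrides.
    """
    if len(paths) == 0:
        raise ValueError("no sample files given")
    volumes = []
    spacing = None
    for idx, p in enumerate(paths):
        arr, sp = load_volume(p, format)
        if not np.issubdtype(arr.dtype, np.integer):
            if np.allclose(arr, np.round(arr)):
                arr = np.round(arr).astype(np.int32)
            else:
                raise FormatError(f"sample {idx} ({p}) has non-integer voxel values")
        if arr.ndim != 3:
            raise DimensionError(f"sample {idx} ({p}) is not a 3D volume: {arr.shape}")
        if volumes and arr.shape != volumes[0].shape:
            raise DimensionError(
                f"sample {idx} ({p}) has shape {arr.shape}, expected "
                f"{volumes[0].shape}"
            )
        if sp is not None:
            spacing = sp
        volumes.append(arr)
    if voxel_spacing is not None:
        spacing = voxel_spacing
    stack = np.stack(volumes)
    if classes is None:
        classes = tuple(int(c) for c in np.unique(stack))
    return SegmentationSampleStack(
        samples=stack, classes=tuple(classes),
        voxel_spacing=spacing if spacing is not None else (1.0, 1.0, 1.0),
    )


def save_probability_map(pmap: ProbabilityMap, path, format: str | None = None) -> None:
    """Write a probability map as float32 (NPY or NRRD).

    A single-map binary instance writes a 3D volume; a multi-class map writes
    its full (n_maps, Dz, Dy, Dx) array (NPY only — NRRD stores one 3D
    scalar volume, so select a class first via ``class_probability``).
    """
    fmt = format or _infer_format(path)
    eps32 = pmap.eps.astype(np.float32)
    if eps32.shape[0] == 1:
        eps32 = eps32[0]
    if fmt == "npy":
        np.save(path, eps32)
        return
    if fmt == "nrrd":
        if eps32.ndim != 3:
            raise FormatError(
                "NRRD stores a single 3D volume; save one class map at a time"
            )
        save_volume(eps32, path, "nrrd", spacing=pmap.voxel_spacing)
        return
    raise FormatError(f"probability maps support npy/nrrd, not {fmt!r}")


def load_probability_map(path, format: str | None = None,
                         classes: Sequence[int] | None = None,
                         n_classes: int | None = None,
                         voxel_spacing=None) -> ProbabilityMap:
    """Read a probability map written by :func:`save_probability_map`.

    Values outside [0, 1] by more than ``CLAMP_TOL`` are rejected with a
    validation error listing the count and extrema; smaller excursions (from
    lossy float storage) are clamped.  A 3D array is interpreted as the
    foreground map of a binary problem unless ``classes``/``n_classes`` say
    otherwise.
    """
    fmt = format or _infer_format(path)
    if fmt == "npy":
        arr, sp = np.load(path), None
    elif fmt == "nrrd":
        arr, sp = load_volume(path, "nrrd")
    else:
        raise FormatError(f"probability maps support npy/nrrd, not {fmt!r}")
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
        if classes is None:
            classes = (1,)
        if n_classes is None:
            n_classes = 2
    else:
        if classes is None:
            classes = tuple(range(arr.shape[0]))
        if n_classes is None:
            n_classes = arr.shape[0]
    if voxel_spacing is None:
        voxel_spacing = sp
    return ProbabilityMap(
        eps=arr, classes=tuple(classes), n_classes=int(n_classes),
        voxel_spacing=voxel_spacing if voxel_spacing is not None else (1.0, 1.0, 1.0),
    )
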