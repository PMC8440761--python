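"""Synthetic scenes with analytically known probability maps.

Every stage of the workflow is testable without real CT data because the
generators here produce (a) a two-phase ground-truth microstructure, (b) a
blurred/noisy grayscale rendering of it, and (c) ensembles of plausible
segmentation samples whose per-voxel inclusion frequency has a closed form.

The key construction is the *threshold-jitter* sampler: sample k applies a
single threshold tau_k ~ Uniform(0, 1) to the grayscale g, so a voxel is
included with probability P(tau_k <= g_v) = g_v.  The true probability map
therefore equals the grayscale itself, giving an exact target for the
sample-mean probability map.  The *noise-then-threshold* sampler instead
adds fresh Gaussian noise of amplitude a and thresholds at 0.5, so the
inclusion probability is Phi((g_v - 0.5) / a); the amplitude a is the knob
that emulates image-quality differences — a noisier rendering produces a
wider segmentation-uncertainty band and hence wider physics-quantity
distributions.

All generation is driven by a single seeded pseudo-random stream per scene,
with the full recipe (generator, parameters, seed) recorded so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .distfit import QuantityTable
from .probmap import SegmentationSampleStack

__all__ = [
    "SyntheticScene",
    "make_planar_interface",
    "make_blob_microstructure",
    "sample_segmentations",
    "make_quantity_table",
    "SAMPLERS",
]

SAMPLERS = ("threshold_jitter", "noise_then_threshold")

#: default grayscale-noise amplitude for blob scenes (moderate-quality image)
DEFAULT_NOISE_AMPLITUDE = 0.05
#: default rendering blur applied to the truth indicator, in voxels
DEFAULT_RENDER_BLUR = 1.0


@dataclass
class SyntheticScene:
    """Ground truth + grayscale rendering + analytic probability map.

    ``analytic_probmap`` is the exact per-voxel inclusion probability under
    the scene's nominal sampling model (threshold-jitter unless the recipe
    says otherwise); ``recipe`` fully determines every volume.
    """

    truth: np.ndarray
    grayscale: np.ndarray
    analytic_probmap: np.ndarray | None
    recipe: dict = field(default_factory=dict)

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=bool)
        self.grayscale = np.asarray(self.grayscale, dtype=np.float64)
        if self.grayscale.shape != self.truth.shape:
            raise ValueError("scene volumes must share one grid")
        if self.analytic_probmap is not None:
            self.analytic_probmap = np.asarray(self.analytic_probmap,
                                               dtype=np.float64)
            if self.analytic_probmap.shape != self.truth.shape:
                raise ValueError("scene volumes must share one grid")


def make_planar_interface(shape, x0: float, w: float) -> SyntheticScene:
    """A flat two-phase interface with a normal-CDF blur profile.

    The grayscale along the last (x) axis is g(x) = Phi((x - x0) / w)
    evaluated at voxel centers x = index + 0.5, with x0 and w in voxel
    units.  The ground truth is the sharp step x >= x0.  Under threshold
    jitter the analytic probability map equals g, so the mu+/-sigma
    percentile interfaces sit at x0 -/+ w exactly: g(x0 + w) = Phi(1) ~
    0.841, the standard-percentile constant.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"shape must be 3 positive ints, got {shape}")
    if w <= 0:
        raise ValueError(f"blur width must be positive, got {w}")
    if not 0 < x0 < shape[2]:
        raise ValueError(f"interface position {x0} outside the grid extent "
                         f"(0, {shape[2]})")
    x = np.arange(shape[2], dtype=np.float64) + 0.5
    g_line = stats.norm.cdf((x - x0) / w)
    grayscale = np.broadcast_to(g_line, shape).copy()
    truth = np.broadcast_to(x >= x0, shape).copy()
    return SyntheticScene(
        truth=truth, grayscale=grayscale, analytic_probmap=grayscale.copy(),
        recipe={"generator": "planar_interface", "shape": shape,
                "x0": float(x0), "w": float(w), "sampler": "threshold_jitter"},
    )


def make_blob_microstructure(shape, phi: float, ell: float, seed: int,
                             noise_amplitude: float = DEFAULT_NOISE_AMPLITUDE,
                             render_blur: float = DEFAULT_RENDER_BLUR
                             ) -> SyntheticScene:
    """A random two-phase blob microstructure at a target volume fraction.

    A Gaussian random field (white noise smoothed to correlation length
    ``ell`` voxels) is thresholded at its phi-quantile, so the achieved
    volume fraction matches ``phi`` up to the quantile's voxel-count
    granularity.  The grayscale rendering is the truth indicator blurred by
    ``render_blur`` voxels plus additive Gaussian noise of amplitude
    ``noise_amplitude``, clipped to [0, 1] so it can drive the
    threshold-jitter sampler.  The analytic probability map is the clipped
    rendering (threshold-jitter model).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 2 for s in shape):
        raise ValueError(f"shape must be 3 ints >= 2, got {shape}")
    if not 0.0 < phi < 1.0:
        raise ValueError(f"target volume fraction must be in (0, 1), got {phi}")
    if ell < 1.0:
        raise ValueError(f"correlation length must be >= 1 voxel, got {ell}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    fld = ndimage.gaussian_filter(white, sigma=ell, mode="wrap")
    thresh = np.quantile(fld, 1.0 - phi)
    truth = fld >= thresh
    achieved = truth.mean()
    if abs(achieved - phi) > 0.05:
        import warnings

        warnings.warn(f"achieved volume fraction {achieved:.3f} deviates from "
                      f"target {phi}; grid too small for the quantile")
    smooth = ndimage.gaussian_filter(truth.astype(np.float64),
                                     sigma=render_blur, mode="nearest")
    grayscale = smooth + noise_amplitude * rng.standard_normal(shape)
    np.clip(grayscale, 0.0, 1.0, out=grayscale)
    return SyntheticScene(
        truth=truth, grayscale=grayscale, analytic_probmap=grayscale.copy(),
        recipe={"generator": "blob_microstructure", "shape": shape,
                "phi": float(phi), "ell": float(ell), "seed": int(seed),
                "noise_amplitude": float(noise_amplitude),
                "render_blur": float(render_blur),
                "achieved_phi": float(achieved),
                "sampler": "threshold_jitter"},
    )


def sample_segmentations(scene: SyntheticScene, N: int,
                         sampler: str = "threshold_jitter",
                         seed: int = 0,
                         noise_amplitude: float | None = None
                         ) -> SegmentationSampleStack:
    """Draw N plausible binary segmentations of a scene.

    threshold_jitter
        sample k = (g >= tau_k) with tau_k ~ Uniform(0, 1); the exact
        inclusion probability of every voxel is its grayscale value g_v.
    noise_then_threshold
        sample k = (g + a * fresh Gaussian noise >= 0.5); the exact
        inclusion probability is Phi((g_v - 0.5) / a).

    The amplitude ``a`` defaults to the scene recipe's noise_amplitude (or
    0.05).  Labels are {0, 1} with 1 the segmented class.
    """
    if N < 1:
        raise ValueError(f"need N >= 1 samples, got {N}")
    if sampler not in SAMPLERS:
        raise ValueError(f"unknown sampler {sampler!r}; expected one of {SAMPLERS}")
    rng = np.random.default_rng(seed)
    g = scene.grayscale
    samples = np.empty((N,) + g.shape, dtype=np.uint8)
    if sampler == "threshold_jitter":
        taus = rng.uniform(0.0, 1.0, size=N)
        for k in range(N):
            samples[k] = (g >= taus[k]).astype(np.uint8)
    else:
        a = noise_amplitude
        if a is None:
            a = float(scene.recipe.get("noise_amplitude", DEFAULT_NOISE_AMPLITUDE))
        if a <= 0:
            # zero-noise limit: every sample is the g >= 0.5 binarization
            base = (g >= 0.5).astype(np.uint8)
            samples[:] = base
        else:
            for k in range(N):
                samples[k] = (g + a * rng.standard_normal(g.shape) >= 0.5
                              ).astype(np.uint8)
    return SegmentationSampleStack(samples=samples, classes=(0, 1))


def analytic_inclusion_probability(scene: SyntheticScene, sampler: str,
                                   noise_amplitude: float | None = None
                                   ) -> np.ndarray:
    """Closed-form per-voxel inclusion probability for a sampler on a scene."""
    if sampler == "threshold_jitter":
        return np.clip(scene.grayscale, 0.0, 1.0)
    if sampler == "noise_then_threshold":
        a = noise_amplitude
        if a is None:
            a = float(scene.recipe.get("noise_amplitude", DEFAULT_NOISE_AMPLITUDE))
        if a <= 0:
            return (scene.grayscale >= 0.5).astype(np.float64)
        return stats.norm.cdf((scene.grayscale - 0.5) / a)
    raise ValueError(f"unknown sampler {sampler!r}; expected one of {SAMPLERS}")


def make_quantity_table(family: str, params: dict, percentiles) -> QuantityTable:
    """Exact quantile table Q(P) = quantile_family(P/100) for fitting tests.

    Supported families: normal (mean, sigma), beta (a, b, loc, scale),
    half_cauchy (loc, scale).
    """
    percentiles = np.asarray(list(percentiles), dtype=np.float64)
    p = percentiles / 100.0
    if family == "normal":
        q = stats.norm.ppf(p, loc=params["mean"], scale=params["sigma"])
    elif family == "beta":
        q = stats.beta.ppf(p, params["a"], params["b"],
                           loc=params.get("loc", 0.0),
                           scale=params.get("scale", 1.0))
    elif family == "half_cauchy":
        q = stats.halfcauchy.ppf(p, loc=params.get("loc", 0.0),
                                 scale=params["scale"])
    else:
        raise ValueError(f"unsupported family {family!r}")
    return QuantityTable(percentiles=percentiles, values=q,
                         quantity=f"{family}_quantiles",
                         source={"family": family, "params": dict(params)})
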