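"""Nucleoid counting in 3D confocal stacks.

Endosymbiont nucleoids appear as bright, sub-resolution puncta in DNA-stained
confocal z-stacks; host nuclei appear as large, dimmer blobs.  Two counting
procedures are provided:

* full-volume 3D connected-component counting (the computational analog of a
  human scoring every focal plane without double-counting), and
* the semi-automated stage-10 procedure: per-plane 2D counts from the widest
  focal plane (the Z-center of the football-shaped egg chamber) down to the
  bottom of the sample, doubled to approximate the full Z-depth.

An inter-plane redundancy estimator quantifies how often a single nucleoid is
visible in two adjacent planes (signal overlap of ``overlap_min_px`` pixels or
more), which is the error the 3D procedure avoids and the per-plane procedure
incurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import (
    NoSampleError,
    ShallowStackError,
    UndefinedRedundancyError,
)

_CONNECTIVITY_2D = {4: 1, 8: 2}
_CONNECTIVITY_3D = {6: 1, 26: 3}


@dataclass
class ImageStack:
    """A 3D grayscale intensity stack with acquisition metadata.

    Parameters
    ----------
    voxels : ndarray, shape (Z, Y, X)
        Non-negative, finite intensities.  Plane 0 is the top of the
        acquisition (stacks are acquired top to bottom).
    z_step_um : float
        Spacing between focal planes in micrometres (default 1.5).
    pixel_size_um : float, optional
        In-plane pixel size, if known.
    channel : str
        Label of the imaged channel.
    """

    voxels: np.ndarray
    z_step_um: float = 1.5
    pixel_size_um: float | None = None
    channel: str = "DNA"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a (Z, Y, X) array with Z >= 1")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class RoiMaskSet:
    """Per-plane binary *exclusion* masks (1 = voxel removed from analysis).

    Masks stand in for the manual retouching step that removes follicle
    cells, host nuclei and debris before counting.  The plane count must
    equal the stack's Z or be 1 (broadcast to every plane).
    """

    masks: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim == 2:
            m = m[None]
        if m.ndim != 3:
            raise ValueError("masks must be (Z, Y, X) or (Y, X)")
        uniq = np.unique(m)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be strictly binary")
        self.masks = m.astype(bool)

    def for_stack(self, shape: tuple[int, int, int]) -> np.ndarray:
        z, y, x = shape
        if self.masks.shape[1:] != (y, x):
            raise ValueError("mask Y,X does not match stack")
        if self.masks.shape[0] == z:
            return self.masks
        if self.masks.shape[0] == 1:
            return np.broadcast_to(self.masks, shape)
        raise ValueError("mask plane count must equal Z or 1")


@dataclass
class PunctaResult:
    """Outcome of a counting run: the cytology titer datum.

    ``total_reported`` equals ``total_raw`` for full-volume 3D counting and
    ``2 * total_raw`` for the stage-10 half-depth procedure (doubling rule).
    """

    method: str  # "manual_3d" | "semi_auto_2d"
    total_raw: int
    total_reported: int
    threshold_used: float
    per_plane_counts: list[int] | None = None
    planes_used: tuple[int, int] | None = None
    redundancy_fraction: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_plane_counts is not None:
            if self.total_raw != sum(self.per_plane_counts):
                raise ValueError("total_raw must equal sum(per_plane_counts)")
        if self.total_raw < 0:
            raise ValueError("counts must be non-negative")


def _resolve_threshold(data: np.ndarray, policy) -> float:
    """Resolve a threshold policy to a numeric threshold.

    ``policy`` may be a number (fixed threshold), ``"otsu"``,
    ``"fixed:T"`` or ``"pct:Q"`` (the Q-th intensity percentile).
    """
    if isinstance(policy, (int, float, np.floating, np.integer)):
        policy = f"fixed:{float(policy)}"
    s = str(policy).strip().lower()
    if s == "otsu":
        if data.size == 0 or np.ptp(data) == 0:
            warnings.warn(
                "Otsu threshold on a constant image; returning empty foreground",
                stacklevel=3,
            )
            return float(data.max()) if data.size else 0.0
        return float(threshold_otsu(data))
    if s.startswith("fixed:"):
        t = float(s.split(":", 1)[1])
        if data.size and not (data.min() <= t <= data.max()):
            raise ValueError(
                f"fixed threshold {t} outside intensity range "
                f"[{data.min()}, {data.max()}]"
            )
        return t
    if s.startswith("pct:"):
        q = float(s.split(":", 1)[1])
        if not 0 <= q <= 100:
            raise ValueError("percentile must be in [0, 100]")
        return float(np.percentile(data, q))
    raise ValueError(f"unknown threshold policy: {policy!r}")


def binarize_stack(
    stack: ImageStack,
    masks: RoiMaskSet | None = None,
    policy="otsu",
    smooth_sigma: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Threshold a stack to a boolean foreground, honouring exclusion masks.

    An optional in-plane Gaussian pre-smoothing (``smooth_sigma`` pixels)
    suppresses single-voxel shot noise before thresholding; 0 disables it.
    Masked voxels are excluded both from threshold estimation and from the
    returned foreground.  Returns ``(binary, threshold_used)``.
    """
    vox = stack.voxels.astype(float)
    if smooth_sigma > 0:
        vox = ndimage.gaussian_filter(vox, sigma=(0, smooth_sigma, smooth_sigma))
    include = None
    if masks is not None:
        include = ~masks.for_stack(stack.shape)
        sample = vox[include]
    else:
        sample = vox.ravel()
    threshold = _resolve_threshold(sample, policy)
    binary = vox > threshold
    if include is not None:
        binary &= include
    return binary, threshold


def _count_components(binary: np.ndarray, connectivity: int, min_size: int) -> int:
    if not binary.any():
        return 0
    labels = label(binary, connectivity=connectivity)
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.count_nonzero(sizes >= min_size))


def count_particles_2d(
    binary_plane: np.ndarray, connectivity: int = 8, min_size_px: int = 2
) -> int:
    """Count connected components of area >= ``min_size_px`` in one plane."""
    plane = np.asarray(binary_plane)
    if plane.ndim != 2:
        raise ValueError("expected a single 2D plane")
    if connectivity not in _CONNECTIVITY_2D:
        raise ValueError("2D connectivity must be 4 or 8")
    return _count_components(
        plane.astype(bool), _CONNECTIVITY_2D[connectivity], min_size_px
    )


def count_puncta_3d(
    binary_stack: np.ndarray, connectivity: int = 26, min_size_vox: int = 2
) -> int:
    """Count 3D connected components of volume >= ``min_size_vox``."""
    vol = np.asarray(binary_stack)
    if vol.ndim != 3:
        raise ValueError("expected a (Z, Y, X) stack")
    if connectivity not in _CONNECTIVITY_3D:
        raise ValueError("3D connectivity must be 6 or 26")
    return _count_components(
        vol.astype(bool), _CONNECTIVITY_3D[connectivity], min_size_vox
    )


def find_z_center(binary_stack: np.ndarray) -> int:
    """Index of the plane with the largest foreground area.

    The widest plane of a (roughly ellipsoidal) egg chamber marks its
    Z-center.  Ties break toward the lower (shallower) plane index.
    """
    vol = np.asarray(binary_stack).astype(bool)
    areas = vol.sum(axis=(1, 2))
    if areas.sum() == 0:
        raise NoSampleError("no foreground voxels; cannot locate a Z-center")
    return int(np.argmax(areas))


def quantify_stack_3d(
    stack: ImageStack,
    masks: RoiMaskSet | None = None,
    policy="otsu",
    connectivity: int = 26,
    min_size_vox: int = 2,
    smooth_sigma: float = 0.0,
) -> PunctaResult:
    """Full-volume 3D count of a stack (early-stage / manual-analog mode)."""
    binary, thr = binarize_stack(stack, masks, policy, smooth_sigma)
    n = count_puncta_3d(binary, connectivity, min_size_vox)
    return PunctaResult(
        method="manual_3d",
        total_raw=n,
        total_reported=n,
        threshold_used=thr,
        provenance={
            "policy": str(policy),
            "connectivity": connectivity,
            "min_size_vox": min_size_vox,
            "smooth_sigma": smooth_sigma,
        },
    )


def quantify_stage10_cyst(
    stack: ImageStack,
    masks: RoiMaskSet | None = None,
    policy="otsu",
    connectivity: int = 8,
    min_size_px: int = 2,
    smooth_sigma: float = 0.0,
    redundancy_correct: bool = False,
    estimate_redundancy: bool = False,
    overlap_min_px: int = 2,
) -> PunctaResult:
    """Semi-automated stage-10 count: half-depth per-plane counting, doubled.

    Per-plane 2D counts are taken from the Z-center plane down to the deepest
    plane carrying foreground; their sum is doubled to approximate the full
    Z-depth of the cyst.  When ``redundancy_correct`` is set, the doubled
    total is scaled by ``1 - redundancy_fraction`` (the fraction of
    components duplicated between adjacent planes); by default the fraction
    is reported (when requested) but not subtracted.
    """
    binary, thr = binarize_stack(stack, masks, policy, smooth_sigma)
    areas = binary.sum(axis=(1, 2))
    fg_planes = np.flatnonzero(areas)
    provenance = {
        "policy": str(policy),
        "connectivity": connectivity,
        "min_size_px": min_size_px,
        "smooth_sigma": smooth_sigma,
        "redundancy_correct": redundancy_correct,
    }
    if fg_planes.size == 0:
        return PunctaResult(
            method="semi_auto_2d",
            total_raw=0,
            total_reported=0,
            threshold_used=thr,
            per_plane_counts=[],
            planes_used=None,
            provenance=provenance,
        )
    z0, z1 = int(fg_planes[0]), int(fg_planes[-1])
    if z1 - z0 + 1 < 2:
        raise ShallowStackError(
            "foreground spans a single focal plane; half-depth doubling "
            "requires a stack spanning the Z-center"
        )
    zc = find_z_center(binary)
    counted = list(range(zc, z1 + 1))
    per_plane = [count_particles_2d(binary[z], connectivity, min_size_px) for z in counted]
    total_raw = int(sum(per_plane))
    total_reported = 2 * total_raw

    redundancy = None
    if estimate_redundancy or redundancy_correct:
        pairs = [(z, z + 1) for z in range(z0, z1)]
        try:
            redundancy = estimate_plane_redundancy(
                binary, pairs, overlap_min_px, connectivity, min_size_px
            )
        except UndefinedRedundancyError:
            redundancy = None
    if redundancy_correct and redundancy is not None:
        total_reported = int(round(total_reported * (1.0 - redundancy)))

    return PunctaResult(
        method="semi_auto_2d",
        total_raw=total_raw,
        total_reported=total_reported,
        threshold_used=thr,
        per_plane_counts=per_plane,
        planes_used=(zc, z1),
        redundancy_fraction=redundancy,
        provenance=provenance,
    )


def estimate_plane_redundancy(
    binary_stack: np.ndarray,
    plane_pairs: Sequence[tuple[int, int]] | None = None,
    overlap_min_px: int = 2,
    connectivity: int = 8,
    min_size_px: int = 2,
) -> float:
    """Fraction of components duplicated between adjacent focal planes.

    For each adjacent pair ``(i, i+1)``, every 2D component in the second
    plane overlapping the first plane's foreground by at least
    ``overlap_min_px`` pixels is scored as redundant (the same nucleoid seen
    twice).  Returns redundant / examined over all pairs.  One-pixel grazes
    are deliberately not counted.
    """
    vol = np.asarray(binary_stack).astype(bool)
    if vol.ndim != 3:
        raise ValueError("expected a (Z, Y, X) stack")
    if plane_pairs is None:
        plane_pairs = [(z, z + 1) for z in range(vol.shape[0] - 1)]
    examined = 0
    redundant = 0
    for i, j in plane_pairs:
        if j != i + 1:
            raise ValueError(f"plane pair ({i}, {j}) is not adjacent")
        if not (0 <= i and j < vol.shape[0]):
            raise ValueError(f"plane pair ({i}, {j}) out of range")
        labels = label(vol[j], connectivity=_CONNECTIVITY_2D[connectivity])
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= min_size_px)
        keep = keep[keep > 0]
        if keep.size == 0:
            continue
        overlap = np.bincount(
            labels[vol[i] & (labels > 0)], minlength=sizes.size
        )
        examined += keep.size
        redundant += int(np.count_nonzero(overlap[keep] >= overlap_min_px))
    if examined == 0:
        raise UndefinedRedundancyError(
            "no components examined; redundancy fraction is undefined"
        )
    return redundant / examined


@dataclass
class MethodComparison:
    """Agreement between manual and semi-automated counts on paired regions."""

    slope: float
    intercept: float
    r_squared: float
    test: "object"  # stats.TestResult
    n: int


def compare_counting_methods(manual_counts, auto_counts, diag_alpha: float = 0.05,
                             seed: int | None = None) -> MethodComparison:
    """OLS fit of semi-automated on manual counts plus a two-sample test.

    The regression measures agreement of the paired counts; the two-sample
    test (dispatched through the decision tree) asks whether the two scoring
    methods produce different count distributions.
    """
    from scipy.stats import linregress

    from . import stats as _stats

    manual = np.asarray(manual_counts, dtype=float)
    auto = np.asarray(auto_counts, dtype=float)
    if manual.shape != auto.shape or manual.ndim != 1:
        raise ValueError("manual and auto counts must be equal-length vectors")
    if manual.size < 3:
        raise ValueError("need at least 3 paired counts")
    if np.ptp(manual) == 0:
        raise ValueError("zero variance in manual counts; regression undefined")
    fit = linregress(manual, auto)
    test = _stats.compare_two_groups(manual, auto, diag_alpha=diag_alpha, seed=seed)
    return MethodComparison(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        test=test,
        n=int(manual.size),
    )
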