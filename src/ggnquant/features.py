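"""First-order radiomic features of a masked CT nodule.

Every feature is computed from the multiset of integer HU values of the
masked voxels plus the voxel geometry; traversal order never matters.  The
feature vector covers two size measurements (lung and mediastinal window),
voxel-counting volume, mean-attenuation density and mass, histogram shape
(skewness, non-excess kurtosis), five attenuation percentiles (2.5th, 25th,
50th, 75th, 97.5th) and two first-order texture statistics:

* entropy  = -sum_i p_i log2 p_i   (bits; textural irregularity)
* uniformity = sum_i p_i^2         (energy; concentration of grey levels)

where p_i are histogram frequencies over 1-HU-wide bins spanning the
nodule's own HU range.  Higher entropy / lower uniformity mean a more
heterogeneous lesion.  With integer HU and unit bins these statistics are
exactly invariant under a constant HU shift, while the percentiles and the
mean-derived density shift by the corresponding amount.

The "density" here is the physical-density convention (mean HU + 1000)/1000,
so air maps to 0 g/mL and water to 1 g/mL; mass is density x volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
from scipy import ndimage, stats as sps
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import DegenerateSampleError, EmptyMaskError, ShapeMismatchError
from .imaging_io import CTVolume, NoduleMask

#: HU threshold above which a voxel is dense enough to appear on a
#: mediastinal (soft-tissue) window; conventional bound, configurable.
SOLID_HU_THRESHOLD = -160

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class NoduleFeatures:
    """The full per-nodule feature vector (one observer's measurement)."""

    size_lung_mm: float
    size_mediastinal_mm: float
    volume_cm3: float
    density: float
    mass_g: float
    skewness: float  # NaN when undefined (zero-variance sample)
    kurtosis: float  # non-excess convention (Gaussian -> 3); NaN when undefined
    p2_5_hu: float
    p25_hu: float
    p50_hu: float
    p75_hu: float
    p97_5_hu: float
    uniformity: float
    entropy_bits: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in dataclass_fields(NoduleFeatures))


def collect_voxels(volume: CTVolume, mask: NoduleMask) -> np.ndarray:
    """Return the integer HU values of all masked voxels (order-free multiset)."""
    if mask.data.shape != volume.shape:
        raise ShapeMismatchError(
            f"shape mismatch: mask {mask.data.shape} vs volume {volume.shape}"
        )
    sample = volume.voxels[mask.data]
    if sample.size == 0:
        raise EmptyMaskError("empty mask: no voxels to collect")
    return np.asarray(sample)


def histogram_percentiles(sample: np.ndarray) -> tuple[float, float, float, float, float]:
    """Attenuation at the 2.5/25/50/75/97.5th percentiles of the HU histogram.

    Linear interpolation between order statistics; the output is monotone
    non-decreasing by construction.
    """
    sample = np.asarray(sample)
    if sample.size < 2:
        raise DegenerateSampleError(f"need >= 2 voxels for percentiles, got {sample.size}")
    p = np.percentile(sample, [2.5, 25.0, 50.0, 75.0, 97.5], method="linear")
    return tuple(float(v) for v in p)


def shape_stats(sample: np.ndarray) -> tuple[float, float]:
    """Histogram skewness and kurtosis (standardised 3rd/4th central moments).

    Kurtosis uses the non-excess convention so a Gaussian sample gives ~3.
    Raises on samples with fewer than 3 voxels or zero variance, where the
    standardised moments are undefined.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 3:
        raise DegenerateSampleError(f"need >= 3 voxels for shape stats, got {sample.size}")
    if np.var(sample) == 0:
        raise DegenerateSampleError("zero-variance sample: skewness/kurtosis undefined")
    skew = float(sps.skew(sample, bias=True))
    kurt = float(sps.kurtosis(sample, fisher=False, bias=True))
    return skew, kurt


def texture_stats(sample: np.ndarray, bin_width_hu: float = 1.0) -> tuple[float, float]:
    """First-order uniformity and entropy of the HU histogram.

    Bins are ``bin_width_hu`` wide (default 1 HU, exact for integer HU) and
    span the sample's own range, so the statistics are shift-invariant.
    Returns ``(uniformity, entropy_bits)`` with
    uniformity in (0, 1], entropy >= 0, and entropy == 0 iff uniformity == 1.
    """
    sample = np.asarray(sample)
    if sample.size == 0:
        raise DegenerateSampleError("empty sample")
    if bin_width_hu <= 0:
        raise ValueError("bin width must be positive")
    idx = np.floor((sample - sample.min()) / bin_width_hu).astype(np.int64)
    counts = np.bincount(idx)
    p = counts[counts > 0] / sample.size
    uniformity = float(np.sum(p * p))
    entropy = float(-np.sum(p * np.log2(p)))
    # clean up -0.0 from the single-bin case
    return uniformity, abs(entropy)


def volume_density_mass(
    sample: np.ndarray, spacing_mm: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Voxel-counting volume (cm^3), mean-HU density (g/mL) and mass (g).

    density = (mean HU + 1000)/1000, clamped at 0; mass = density x volume.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise DegenerateSampleError("empty sample")
    dx, dy, dz = spacing_mm
    volume_cm3 = sample.size * dx * dy * dz / 1000.0
    density = max(0.0, (float(sample.mean()) + 1000.0) / 1000.0)
    mass_g = density * volume_cm3
    return volume_cm3, density, mass_g


def _inplane_feret_mm(mask_data: np.ndarray, spacing_mm: tuple[float, float, float]) -> float:
    """Largest per-axial-slice Feret (caliper) diameter over the mask, in mm.

    For each slice the maximum pairwise distance between voxel centres is
    taken (via the convex hull for large slices), plus one in-plane voxel
    extent so that a single voxel measures one pixel, not zero.
    """
    dx, dy, _ = spacing_mm
    best = 0.0
    for z in range(mask_data.shape[2]):
        xs, ys = np.nonzero(mask_data[:, :, z])
        if xs.size == 0:
            continue
        pts = np.column_stack([xs * dx, ys * dy])
        if pts.shape[0] == 1:
            d = 0.0
        else:
            if pts.shape[0] > 64:
                try:
                    pts = pts[ConvexHull(pts).vertices]
                except Exception:  # collinear/degenerate slice: brute force
                    pass
            d = float(pdist(pts).max())
        best = max(best, d)
    return best + max(dx, dy)


def size_lung(mask: NoduleMask, spacing_mm: tuple[float, float, float]) -> float:
    """Nodule size on the lung window: in-plane Feret diameter (mm)."""
    return _inplane_feret_mm(mask.data, spacing_mm)


def size_mediastinal(
    volume: CTVolume,
    mask: NoduleMask,
    solid_threshold_hu: float = SOLID_HU_THRESHOLD,
) -> float:
    """Solid-component size on the mediastinal window (mm).

    The solid component is the largest 26-connected cluster of masked voxels
    with HU >= ``solid_threshold_hu``; its in-plane Feret diameter is
    returned, or 0 when no masked voxel reaches the threshold (pure
    ground-glass nodule).
    """
    solid = mask.data & (volume.voxels >= solid_threshold_hu)
    if not solid.any():
        return 0.0
    labels, n = ndimage.label(solid, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(solid, labels, index=np.arange(1, n + 1))
        solid = labels == (int(np.argmax(sizes)) + 1)
    return _inplane_feret_mm(solid, volume.spacing_mm)


def extract_features(
    volume: CTVolume,
    mask: NoduleMask,
    bin_width_hu: float = 1.0,
    solid_threshold_hu: float = SOLID_HU_THRESHOLD,
) -> NoduleFeatures:
    """Compute the full feature vector for one (volume, mask) pair.

    Deterministic composition of the individual operations.  Skewness and
    kurtosis are recorded as NaN (missing) when the sample has zero variance
    rather than aborting the extraction.
    """
    sample = collect_voxels(volume, mask)
    p2_5, p25, p50, p75, p97_5 = histogram_percentiles(sample)
    try:
        skew, kurt = shape_stats(sample)
    except DegenerateSampleError:
        skew, kurt = math.nan, math.nan
    uniformity, entropy = texture_stats(sample, bin_width_hu=bin_width_hu)
    vol, dens, mass = volume_density_mass(sample, volume.spacing_mm)
    return NoduleFeatures(
        size_lung_mm=size_lung(mask, volume.spacing_mm),
        size_mediastinal_mm=size_mediastinal(volume, mask, solid_threshold_hu),
        volume_cm3=vol,
        density=dens,
        mass_g=mass,
        skewness=skew,
        kurtosis=kurt,
        p2_5_hu=p2_5,
        p25_hu=p25,
        p50_hu=p50,
        p75_hu=p75,
        p97_5_hu=p97_5,
        uniformity=uniformity,
        entropy_bits=entropy,
    )


def average_observers(obs1: NoduleFeatures, obs2: NoduleFeatures) -> NoduleFeatures:
    """Per-feature arithmetic mean of two observers' measurements."""
    merged = {
        name: (getattr(obs1, name) + getattr(obs2, name)) / 2.0 for name in FEATURE_NAMES
    }
    return NoduleFeatures(**merged)
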