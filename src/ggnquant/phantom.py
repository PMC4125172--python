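"""Synthetic ground-glass nodule (GGN) phantoms with class structure.

No CT cohort is deposited with this project, so analyses run on phantoms: 3D
HU volumes with ground-truth masks, emulating a surgical cohort of
ground-glass adenocarcinomas in three pathologic classes,

* AIS  — adenocarcinoma in situ: pure lepidic growth, no invasion; the
  lesion is a nearly homogeneous haze of ground-glass attenuation,
* MIA  — minimally invasive adenocarcinoma: invasive component <= 5 mm;
  slightly larger, denser, with a small right tail of denser voxels and
  occasionally a tiny solid focus,
* INV  — invasive adenocarcinoma: invasive component > 5 mm; larger still,
  with a heavier dense-voxel tail and more frequent sub-5-mm solid foci.

The class presets are chosen so that the expected ordering of first-order
features emerges on generated cohorts — increasing size, density,
high-percentile attenuation and entropy, decreasing uniformity from AIS to
MIA to INV — without attempting to match any particular clinical cohort's
means.  Nodules are smooth star-shaped blobs (a sphere with low-amplitude
radial perturbation) embedded in uniform aerated-lung background near
-880 HU; every generated nodule keeps its solid focus under 5 mm so the
whole cohort passes the solid-component inclusion filter.

Generation is a pure function of the spec: identical spec + seed give
bit-identical volumes.  Per-nodule seeds are derived deterministically from
the cohort master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMaskError, SpecificationError
from .imaging_io import CTVolume, NoduleMask

CLASS_LABELS = ("AIS", "MIA", "INV")

#: ground-truth cohort composition: 38 AIS / 61 MIA / 92 invasive.
DEFAULT_CLASS_COUNTS = {"AIS": 38, "MIA": 61, "INV": 92}

#: typical chest-CT geometry: 0.7 mm in-plane pixels, 1.25 mm slices.
DEFAULT_SPACING_MM = (0.7, 0.7, 1.25)

_BACKGROUND_MEAN_HU = -880
_BACKGROUND_SD_HU = 25
#: densest HU allowed for ground-glass matrix voxels; strictly below the
#: -160 HU solid threshold so pure-GGN phantoms have no solid component.
_GGO_HU_CAP = -161
_TAIL_SHIFT_HU = 280.0
_TAIL_SD_HU = 90.0
_SPIKE_SD_HU = 0.5
_LEFT_TAIL_SHIFT_HU = -250.0
_LEFT_TAIL_SD_HU = 80.0
_HAZE_HALF_WIDTH_HU = 300.0
_SHAPE_AMPLITUDE = 0.12


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for a single nodule phantom.

    ``right_tail_weight`` is the fraction of nodule voxels drawn from a
    denser mixture component; it drives the separation of the high
    percentiles and the entropy between classes.  ``solid_focus_mm`` is the
    diameter of an embedded solid core (HU >= -160); 0 means pure GGN.
    ``invasion_extent_mm`` is the pathologic ground truth, consistent with
    the class label (AIS: 0; MIA: (0, 5]; INV: > 5).
    """

    class_label: str
    diameter_mm: float
    ggo_mean_hu: float
    ggo_sd_hu: float
    right_tail_weight: float
    solid_focus_mm: float
    invasion_extent_mm: float
    seed: int
    #: fraction of matrix voxels concentrated in a 1-2 HU-wide mode at a
    #: random offset — the spiky histogram peaks that collapsed alveoli or
    #: central scar produce on real GGN histograms, independent of class.
    #: concentrates mass in one bin, so it moves uniformity far more than
    #: entropy.
    spike_weight: float = 0.0
    #: fraction of voxels in a diffuse wide layer (uniform over ~±300 HU
    #: around the matrix mean): partial-volume haze at the lesion rim.
    #: occupies many sparsely-filled bins, so it moves entropy but leaves
    #: uniformity essentially unchanged.
    haze_weight: float = 0.0
    #: tail morphology varies nodule to nodule: centre offset and width of
    #: the dense component, so third/fourth moments are individual traits
    #: rather than clean class markers.
    tail_shift_hu: float = 280.0
    tail_sd_hu: float = 90.0
    #: fraction of voxels in an air-side component (~-250 HU below the
    #: matrix): air bronchograms and bullae inside the lesion, independent
    #: of class; adds idiosyncratic left-tail mass to the histogram.
    left_tail_weight: float = 0.0
    #: fraction of voxels quantised to a 2-HU grid (reconstruction
    #: granularity differs between nodules; affects the occupied-bin
    #: structure, hence entropy/uniformity, but no percentile).
    quantized_fraction: float = 0.0

    def validate(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise SpecificationError(f"unknown class label {self.class_label!r}")
        if self.diameter_mm <= 0:
            raise SpecificationError("diameter must be positive")
        if not (-900.0 <= self.ggo_mean_hu <= -300.0):
            raise SpecificationError(
                f"ggo_mean_hu {self.ggo_mean_hu} outside [-900, -300]"
            )
        if self.ggo_sd_hu <= 0:
            raise SpecificationError("ggo_sd_hu must be positive")
        if not (0.0 <= self.right_tail_weight <= 1.0):
            raise SpecificationError("right_tail_weight must be in [0, 1]")
        if not (0.0 <= self.spike_weight <= 0.6):
            raise SpecificationError("spike_weight must be in [0, 0.6]")
        if not (0.0 <= self.haze_weight <= 0.5):
            raise SpecificationError("haze_weight must be in [0, 0.5]")
        if not (0.0 <= self.left_tail_weight <= 0.3):
            raise SpecificationError("left_tail_weight must be in [0, 0.3]")
        if not (50.0 <= self.tail_shift_hu <= 500.0):
            raise SpecificationError("tail_shift_hu must be in [50, 500]")
        if not (20.0 <= self.tail_sd_hu <= 300.0):
            raise SpecificationError("tail_sd_hu must be in [20, 300]")
        if not (0.0 <= self.quantized_fraction <= 1.0):
            raise SpecificationError("quantized_fraction must be in [0, 1]")
        if self.solid_focus_mm < 0 or self.solid_focus_mm >= 5.0:
            raise SpecificationError(
                "solid_focus_mm must be in [0, 5) so the nodule passes the "
                "solid-component inclusion filter"
            )
        ext = self.invasion_extent_mm
        if self.class_label == "AIS" and ext != 0:
            raise SpecificationError("AIS requires invasion_extent_mm == 0")
        if self.class_label == "MIA" and not (0 < ext <= 5):
            raise SpecificationError("MIA requires 0 < invasion_extent_mm <= 5")
        if self.class_label == "INV" and not (ext > 5):
            raise SpecificationError("INV requires invasion_extent_mm > 5")


@dataclass(frozen=True)
class ClassPreset:
    """Sampling distributions for PhantomSpec parameters of one class.

    Diameters and HU parameters are drawn from clipped normals; a solid
    focus of size uniform in ``solid_focus_range_mm`` is present with
    probability ``solid_focus_prob``.
    """

    diameter_mean_mm: float
    diameter_sd_mm: float
    diameter_range_mm: tuple[float, float]
    ggo_mean_hu: float
    ggo_mean_sd_hu: float
    #: voxel-level spread of the ground-glass matrix is log-normal across
    #: nodules: heterogeneity is the biology that separates the classes, and
    #: a log-normal spread makes its entropy readout (~log sigma) normally
    #: distributed with equal variance in every class
    ggo_sd_median_hu: float
    ggo_sd_log_sd: float
    tail_weight_mean: float
    tail_weight_sd: float
    tail_weight_range: tuple[float, float]
    solid_focus_prob: float
    solid_focus_range_mm: tuple[float, float]


#: defaults chosen so the class-monotone feature ordering emerges: sizes and
#: densities increase and the dense-voxel tail thickens from AIS to INV;
#: solid-focus frequencies mirror the ~8%/13%/26% part-solid fractions of a
#: GGN surgical cohort.  All are configuration, not hard-coded truth.
DEFAULT_PRESETS: dict[str, ClassPreset] = {
    "AIS": ClassPreset(
        diameter_mean_mm=13.2, diameter_sd_mm=5.0, diameter_range_mm=(6.0, 24.0),
        ggo_mean_hu=-670.0, ggo_mean_sd_hu=75.0,
        ggo_sd_median_hu=46.0, ggo_sd_log_sd=0.22,
        tail_weight_mean=0.06, tail_weight_sd=0.05, tail_weight_range=(0.0, 0.25),
        solid_focus_prob=0.08, solid_focus_range_mm=(1.0, 2.5),
    ),
    "MIA": ClassPreset(
        diameter_mean_mm=15.2, diameter_sd_mm=5.0, diameter_range_mm=(6.0, 26.0),
        ggo_mean_hu=-670.0, ggo_mean_sd_hu=75.0,
        ggo_sd_median_hu=66.0, ggo_sd_log_sd=0.22,
        tail_weight_mean=0.115, tail_weight_sd=0.06, tail_weight_range=(0.0, 0.35),
        solid_focus_prob=0.13, solid_focus_range_mm=(1.0, 3.0),
    ),
    "INV": ClassPreset(
        diameter_mean_mm=18.3, diameter_sd_mm=5.0, diameter_range_mm=(8.0, 30.0),
        ggo_mean_hu=-670.0, ggo_mean_sd_hu=75.0,
        ggo_sd_median_hu=90.0, ggo_sd_log_sd=0.22,
        tail_weight_mean=0.19, tail_weight_sd=0.08, tail_weight_range=(0.02, 0.45),
        solid_focus_prob=0.26, solid_focus_range_mm=(1.5, 4.0),
    ),
}

#: invasion extents of invasive adenocarcinomas default to the 5.1-19.7 mm
#: range (median ~9.8 mm) of resected pure-GGN invasive tumours.
DEFAULT_INV_EXTENT_RANGE_MM = (5.1, 19.7)
_INV_EXTENT_LOG_MEDIAN = np.log(9.8)
_INV_EXTENT_LOG_SD = 0.30


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a whole synthetic cohort."""

    n_ais: int = DEFAULT_CLASS_COUNTS["AIS"]
    n_mia: int = DEFAULT_CLASS_COUNTS["MIA"]
    n_inv: int = DEFAULT_CLASS_COUNTS["INV"]
    voxel_spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    class_presets: dict[str, ClassPreset] = field(default_factory=lambda: dict(DEFAULT_PRESETS))
    observer_noise: float = 1.0  # boundary perturbation magnitude, voxels
    master_seed: int = 0
    inv_extent_range_mm: tuple[float, float] = DEFAULT_INV_EXTENT_RANGE_MM

    def validate(self) -> None:
        if min(self.n_ais, self.n_mia, self.n_inv) < 0:
            raise SpecificationError("class counts must be non-negative")
        if self.n_ais + self.n_mia + self.n_inv == 0:
            raise SpecificationError("cohort must contain at least one nodule")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise SpecificationError("voxel spacing must be positive")
        if self.observer_noise < 0:
            raise SpecificationError("observer noise must be non-negative")


def _nodule_seed(master_seed: int, index: int) -> int:
    """Deterministic per-nodule seed derived from (master_seed, index)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _smooth_radial_field(rng: np.random.Generator, unit_dirs: np.ndarray) -> np.ndarray:
    """Low-order smooth perturbation on the unit sphere, |field| <= 1.

    Sum of linear and quadratic lobes along random directions: the simplest
    smooth, star-shape-preserving boundary irregularity.
    """
    n_lobes = 4
    axes = rng.normal(size=(n_lobes, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    w1 = rng.normal(size=n_lobes)
    w2 = rng.normal(size=n_lobes)
    proj = unit_dirs @ axes.T  # (n_vox, n_lobes), in [-1, 1]
    f = proj @ w1 + (proj**2 - 1.0 / 3.0) @ w2
    norm = np.abs(w1).sum() + np.abs(w2).sum() * (2.0 / 3.0)
    return f / max(norm, 1e-12)


def generate_nodule(
    spec: PhantomSpec,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
) -> tuple[CTVolume, NoduleMask, dict]:
    """Generate one phantom: HU volume, ground-truth mask and a record.

    The mask is a single 26-connected smooth blob of roughly
    ``spec.diameter_mm`` extent.  Ground-glass voxels are drawn from a
    two-component Gaussian mixture (matrix + denser right tail) and capped
    just below the -160 HU solid threshold, so a nodule with
    ``solid_focus_mm == 0`` has no solid voxel by construction; a positive
    ``solid_focus_mm`` embeds a contiguous core with HU >= -160.
    """
    spec.validate()
    dx, dy, dz = spacing_mm
    if any(s <= 0 for s in spacing_mm):
        raise SpecificationError("voxel spacing must be positive")
    if spec.diameter_mm < 2 * max(spacing_mm):
        raise SpecificationError(
            f"degenerate nodule: diameter {spec.diameter_mm} mm spans fewer "
            f"than 2 voxels at spacing {spacing_mm}"
        )
    rng = np.random.default_rng(spec.seed)
    radius = spec.diameter_mm / 2.0
    margin = 3.0  # mm of lung background around the nodule
    half = radius * (1 + _SHAPE_AMPLITUDE) + margin
    nx = max(3, int(np.ceil(2 * half / dx)) | 1)
    ny = max(3, int(np.ceil(2 * half / dy)) | 1)
    nz = max(3, int(np.ceil(2 * half / dz)) | 1)

    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    gx = (np.arange(nx) - cx) * dx
    gy = (np.arange(ny) - cy) * dy
    gz = (np.arange(nz) - cz) * dz
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    pos = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(pos, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(dist[:, None] > 0, pos / np.maximum(dist, 1e-12)[:, None], 0.0)
    perturb = _smooth_radial_field(rng, dirs)
    local_radius = radius * (1.0 + _SHAPE_AMPLITUDE * perturb)
    mask_flat = dist <= local_radius
    mask = mask_flat.reshape(nx, ny, nz)
    if not mask.any():
        raise SpecificationError("degenerate nodule: mask came out empty")

    hu = rng.normal(_BACKGROUND_MEAN_HU, _BACKGROUND_SD_HU, size=(nx, ny, nz))
    n_in = int(mask.sum())
    u = rng.random(n_in)
    rest = 1.0 - spec.right_tail_weight
    tail = u < spec.right_tail_weight
    spike = ~tail & (u < spec.right_tail_weight + rest * spec.spike_weight)
    haze = ~tail & ~spike & (
        u < spec.right_tail_weight + rest * (spec.spike_weight + spec.haze_weight)
    )
    left = ~tail & ~spike & ~haze & (
        u < spec.right_tail_weight
        + rest * (spec.spike_weight + spec.haze_weight + spec.left_tail_weight)
    )
    vals = rng.normal(spec.ggo_mean_hu, spec.ggo_sd_hu, size=n_in)
    vals[tail] = rng.normal(
        spec.ggo_mean_hu + spec.tail_shift_hu, spec.tail_sd_hu, size=int(tail.sum())
    )
    if spike.any():  # one narrow mode per nodule, at a nodule-specific offset
        offset = rng.uniform(-100.0, 100.0)
        vals[spike] = rng.normal(spec.ggo_mean_hu + offset, _SPIKE_SD_HU, size=int(spike.sum()))
    if haze.any():
        vals[haze] = rng.uniform(
            spec.ggo_mean_hu - _HAZE_HALF_WIDTH_HU, spec.ggo_mean_hu + _HAZE_HALF_WIDTH_HU,
            size=int(haze.sum()),
        )
    if left.any():
        vals[left] = rng.normal(
            spec.ggo_mean_hu + _LEFT_TAIL_SHIFT_HU, _LEFT_TAIL_SD_HU, size=int(left.sum())
        )
    if spec.quantized_fraction > 0:
        quant = rng.random(n_in) < spec.quantized_fraction
        vals[quant] = 2.0 * np.round(vals[quant] / 2.0)
    hu[mask] = np.clip(vals, -1000.0, _GGO_HU_CAP)

    if spec.solid_focus_mm > 0:
        focus_r = spec.solid_focus_mm / 2.0
        solid = (dist.reshape(nx, ny, nz) <= focus_r) & mask
        if not solid.any():  # sub-voxel focus: at least the centre voxel
            solid = np.zeros_like(mask)
            solid[int(round(cx)), int(round(cy)), int(round(cz))] = True
            solid &= mask
        n_solid = int(solid.sum())
        hu[solid] = np.clip(rng.normal(-60.0, 35.0, size=n_solid), -159.0, 120.0)

    hu = np.clip(np.rint(hu), -1024, 200).astype(np.int16)
    volume = CTVolume(voxels=hu, spacing_mm=(dx, dy, dz))
    record = {
        "class_label": spec.class_label,
        "invasion_extent_mm": spec.invasion_extent_mm,
        "diameter_mm": spec.diameter_mm,
        "solid_focus_mm": spec.solid_focus_mm,
        "seed": spec.seed,
    }
    return volume, NoduleMask(data=mask), record


def sample_spec(
    class_label: str,
    rng: np.random.Generator,
    seed: int,
    preset: ClassPreset | None = None,
    inv_extent_range_mm: tuple[float, float] = DEFAULT_INV_EXTENT_RANGE_MM,
) -> PhantomSpec:
    """Draw one PhantomSpec from a class preset's parameter distributions."""
    if preset is None:
        preset = DEFAULT_PRESETS[class_label]
    d = float(np.clip(
        rng.normal(preset.diameter_mean_mm, preset.diameter_sd_mm), *preset.diameter_range_mm
    ))
    ggo_mean = float(np.clip(rng.normal(preset.ggo_mean_hu, preset.ggo_mean_sd_hu), -890.0, -320.0))
    ggo_sd = float(max(
        15.0, np.exp(rng.normal(np.log(preset.ggo_sd_median_hu), preset.ggo_sd_log_sd))
    ))
    tail = float(np.clip(
        rng.normal(preset.tail_weight_mean, preset.tail_weight_sd), *preset.tail_weight_range
    ))
    solid = 0.0
    if rng.random() < preset.solid_focus_prob:
        solid = float(rng.uniform(*preset.solid_focus_range_mm))
    if class_label == "AIS":
        extent = 0.0
    elif class_label == "MIA":
        extent = float(rng.uniform(0.5, 5.0))
    else:
        lo, hi = inv_extent_range_mm
        extent = float(np.clip(
            np.exp(rng.normal(_INV_EXTENT_LOG_MEDIAN, _INV_EXTENT_LOG_SD)), lo, hi
        ))
    return PhantomSpec(
        class_label=class_label,
        diameter_mm=d,
        ggo_mean_hu=ggo_mean,
        ggo_sd_hu=ggo_sd,
        right_tail_weight=tail,
        solid_focus_mm=solid,
        invasion_extent_mm=extent,
        seed=seed,
        spike_weight=float(rng.uniform(0.0, 0.15)),
        haze_weight=float(rng.uniform(0.0, 0.12)),
        left_tail_weight=float(rng.uniform(0.0, 0.10)),
        tail_shift_hu=float(rng.uniform(140.0, 400.0)),
        tail_sd_hu=float(rng.uniform(50.0, 160.0)),
        quantized_fraction=float(rng.uniform(0.0, 0.8)),
    )


def generate_cohort(
    cohort: CohortSpec,
) -> list[tuple[CTVolume, NoduleMask, dict]]:
    """Generate the full synthetic cohort, deterministically from the spec.

    Returns one (volume, mask, record) triple per nodule; records carry
    ``nodule_id`` (``ais_000`` ...), class label, invasion extent and the
    per-nodule seed.  Class parameter draws and the phantom itself both
    derive from seeds spawned from ``master_seed``, so the whole cohort is a
    pure function of the CohortSpec.
    """
    cohort.validate()
    out: list[tuple[CTVolume, NoduleMask, dict]] = []
    index = 0
    for label, count in (("AIS", cohort.n_ais), ("MIA", cohort.n_mia), ("INV", cohort.n_inv)):
        for j in range(count):
            seed = _nodule_seed(cohort.master_seed, index)
            param_rng = np.random.default_rng(
                np.random.SeedSequence([int(cohort.master_seed), int(index), 1])
            )
            spec = sample_spec(
                label, param_rng, seed,
                preset=cohort.class_presets.get(label),
                inv_extent_range_mm=cohort.inv_extent_range_mm,
            )
            vol, mask, record = generate_nodule(spec, cohort.voxel_spacing_mm)
            record["nodule_id"] = f"{label.lower()}_{j:03d}"
            out.append((vol, mask, record))
            index += 1
    return out


def cohort_metadata(nodules: list[tuple[CTVolume, NoduleMask, dict]]) -> pd.DataFrame:
    """Cohort metadata table (nodule_id, class_label, invasion_extent_mm, seed)."""
    rows = [
        {
            "nodule_id": rec["nodule_id"],
            "class_label": rec["class_label"],
            "invasion_extent_mm": rec["invasion_extent_mm"],
            "seed": rec["seed"],
        }
        for _, _, rec in nodules
    ]
    return pd.DataFrame(rows)


def simulate_observers(
    mask: NoduleMask, noise: float, seed: int
) -> tuple[NoduleMask, NoduleMask]:
    """Two independent observer segmentations of the same nodule.

    Each observer's mask is a boundary perturbation of the input: the signed
    Euclidean distance to the boundary (in voxels, positive inside) is
    compared against ``noise`` times a smoothed unit-variance Gaussian
    random field, locally eroding or dilating the contour by about ``noise``
    voxels.  ``noise == 0`` returns the input mask twice.  Same seed, same
    pair.
    """
    if noise < 0:
        raise SpecificationError("observer noise must be non-negative")
    if noise == 0:
        return mask, NoduleMask(data=mask.data.copy())
    rng = np.random.default_rng(seed)
    out = []
    inside = ndimage.distance_transform_edt(mask.data)
    outside = ndimage.distance_transform_edt(~mask.data)
    sdf = inside - outside  # voxels, positive inside
    for _ in range(2):
        field = rng.normal(size=mask.data.shape)
        field = ndimage.gaussian_filter(field, sigma=2.0)
        sd = field.std()
        if sd > 0:
            field /= sd
        perturbed = sdf > noise * field
        labels, n = ndimage.label(perturbed, structure=np.ones((3, 3, 3), dtype=bool))
        if n == 0:
            raise EmptyMaskError("observer perturbation emptied the mask")
        if n > 1:  # keep the component overlapping the true nodule
            sizes = ndimage.sum_labels(perturbed, labels, index=np.arange(1, n + 1))
            perturbed = labels == (int(np.argmax(sizes)) + 1)
        out.append(NoduleMask(data=perturbed))
    return out[0], out[1]
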