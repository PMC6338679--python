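"""Contrast-ratio quantification from an aligned volume and LC mask.

Implements the full per-subject procedure: automatic placement of a pontine
reference region relative to the LC mask, signal summaries, the contrast
ratio CR = (S_LC - S_ref) / S_ref, rostral/caudal and left/right
decompositions, mask agreement and overlap metrics, and the negative-CR QC
flag. Regional CRs are always normalized by the one subject-level reference
summary, never by per-region references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import ScalarVolume, VoxelMask

__all__ = [
    "ReferenceSpec",
    "RegionSignalSummary",
    "SubjectCRRecord",
    "InterRaterResult",
    "place_reference_region",
    "summarize_region",
    "compute_cr",
    "split_rostral_caudal",
    "split_left_right",
    "mask_overlap_pct",
    "interrater_conjunction",
    "extract_subject",
]

REGIONS = ("whole", "rostral", "caudal", "left", "right")


@dataclass(frozen=True)
class ReferenceSpec:
    """How to place the pontine reference region.

    ``patch`` mode (default) is a single-slice square, ``patch_width_voxels``
    on a side (10 voxels = 8 mm at 0.8 mm), centered between the two LC
    centroids in x, on the middle mask slice in z, displaced
    ``offset_voxels_anterior`` voxels beyond the mask's anterior (max-y) face.
    ``bilateral3d`` mode places two mirrored cuboids totalling
    ``bilateral3d_total_voxels`` anterior to each LC.
    """

    mode: str = "patch"
    patch_width_voxels: int = 10
    offset_voxels_anterior: int = 5
    bilateral3d_total_voxels: int = 144

    def __post_init__(self) -> None:
        if self.mode not in ("patch", "bilateral3d"):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        if self.patch_width_voxels < 1 or self.offset_voxels_anterior < 0:
            raise ValueError("need patch_width >= 1 and offset >= 0")

    @property
    def patch_width_mm(self) -> float | None:
        return None  # width in mm depends on the grid; see placement result


@dataclass(frozen=True)
class RegionSignalSummary:
    """Raw-intensity summary of one region: mean, median, max, count."""

    s_mean: float
    s_median: float
    s_max: float
    voxel_count: int


@dataclass
class SubjectCRRecord:
    """Per-subject extracted CRs plus covariates and QC flags.

    ``cr[region][stat]`` holds the CR built from the region's mean, median
    or max raw intensity, all normalized by the whole-subject reference
    mean. ``voxel_counts`` partitions exactly: rostral + caudal = whole and
    left + right = whole.
    """

    subject_id: str
    age_years: float
    sex: str
    tr_ms: int
    cr: dict                      # {region: {"mean"|"median"|"max": float}}
    voxel_counts: dict            # {region: int}
    ref_s_mean: float
    lc_s_mean: float
    qc_flags: set = field(default_factory=set)

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "age_years": self.age_years,
            "sex": self.sex,
            "tr_ms": self.tr_ms,
            "ref_s_mean": self.ref_s_mean,
            "lc_s_mean": self.lc_s_mean,
        }
        for region in REGIONS:
            for stat in ("mean", "median", "max"):
                row[f"cr_{stat}_{region}"] = self.cr[region][stat]
            row[f"voxels_{region}"] = self.voxel_counts[region]
        row["qc_negative_cr"] = "negative_cr" in self.qc_flags
        row["qc_motion_suspect"] = "motion_suspect" in self.qc_flags
        return row


@dataclass
class InterRaterResult:
    """Conjunction mask with per-rater agreement and Dice."""

    conjunction: VoxelMask
    agreement_rater1_pct: float
    agreement_rater2_pct: float
    dice: float
    valid_consensus: bool


def _split_sides_by_midplane(mask: VoxelMask) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices on either side of the grid's mid-x plane."""
    idx = mask.indices
    mid = (mask.grid.shape[0] - 1) / 2
    return idx[idx[:, 0] > mid], idx[idx[:, 0] <= mid]


def place_reference_region(lc_mask: VoxelMask, spec: ReferenceSpec = ReferenceSpec()) -> VoxelMask:
    """Automatically place the pontine reference region relative to the LC.

    The patch is centered at the x midpoint between the per-side LC
    centroids (rounded to the nearest voxel), on the middle slice of the
    mask's z-range (floor of the midpoint for even spans), starting
    ``offset_voxels_anterior`` voxels beyond the mask's anterior face along
    +y. The result never intersects the LC mask; running out of grid raises
    with advice to pad the volume.
    """
    if lc_mask.voxel_count == 0:
        raise ValueError("cannot place a reference region for an empty LC mask")
    hi_side, lo_side = _split_sides_by_midplane(lc_mask)
    if len(hi_side) == 0 or len(lo_side) == 0:
        raise ValueError("LC mask must have voxels on both sides of the mid-x plane")
    nx, ny, nz = lc_mask.grid.shape
    idx = lc_mask.indices
    cx = int(np.round((hi_side[:, 0].mean() + lo_side[:, 0].mean()) / 2))
    z_mid = int((idx[:, 2].min() + idx[:, 2].max()) // 2)
    y_start = int(idx[:, 1].max()) + spec.offset_voxels_anterior

    data = np.zeros(lc_mask.grid.shape, dtype=bool)
    if spec.mode == "patch":
        w = spec.patch_width_voxels
        x0, x1 = cx - w // 2, cx - w // 2 + w
        y0, y1 = y_start, y_start + w
        if x0 < 0 or x1 > nx or y0 < 0 or y1 > ny or not (0 <= z_mid < nz):
            raise ValueError(
                "reference patch exceeds grid bounds; pad the volume with more "
                "anterior/lateral background"
            )
        data[x0:x1, y0:y1, z_mid] = True
        label = "reference_patch"
    else:
        # two mirrored cuboids totalling bilateral3d_total_voxels, centered
        # in x under each LC, spanning 3 slices around the middle slice
        per_side = spec.bilateral3d_total_voxels // 2
        dz = 3
        dy = 6
        dx = max(1, int(round(per_side / (dy * dz))))
        z0, z1 = z_mid - dz // 2, z_mid - dz // 2 + dz
        y0, y1 = y_start, y_start + dy
        for side_idx in (hi_side, lo_side):
            sx = int(np.round(side_idx[:, 0].mean()))
            x0, x1 = sx - dx // 2, sx - dx // 2 + dx
            if x0 < 0 or x1 > nx or y0 < 0 or y1 > ny or z0 < 0 or z1 > nz:
                raise ValueError(
                    "bilateral reference cuboids exceed grid bounds; pad the volume"
                )
            data[x0:x1, y0:y1, z0:z1] = True
        label = "reference_bilateral3d"

    if (data & lc_mask.data).any():
        raise ValueError("reference region overlaps the LC mask")
    return VoxelMask(grid=lc_mask.grid, data=data, label=label)


def summarize_region(volume: ScalarVolume, mask: VoxelMask) -> RegionSignalSummary:
    """Mean/median/max raw intensity over the mask's member voxels."""
    if mask.voxel_count == 0:
        raise ValueError("cannot summarize an empty region")
    if volume.grid.shape != mask.grid.shape:
        raise ValueError("volume and mask live on different grids")
    values = volume.intensities[mask.data]
    return RegionSignalSummary(
        s_mean=float(values.mean()),
        s_median=float(np.median(values)),
        s_max=float(values.max()),
        voxel_count=int(values.size),
    )


def compute_cr(s_lc: float, s_ref: float) -> float:
    """Contrast ratio (S_LC - S_ref) / S_ref; requires a positive reference."""
    if s_ref <= 0:
        raise ValueError(f"degenerate reference signal {s_ref}; CR undefined")
    return (s_lc - s_ref) / s_ref


def split_rostral_caudal(mask: VoxelMask) -> tuple[VoxelMask, VoxelMask]:
    """Split at the median voxel z-coordinate: z > median is rostral.

    The median is taken over the z-coordinates of all member voxels, ties
    (z == median) go caudal, so the partition is exhaustive and disjoint.
    """
    idx = mask.indices
    if idx.size == 0 or len(np.unique(idx[:, 2])) < 2:
        raise ValueError("rostral/caudal split needs a mask spanning >= 2 z-slices")
    z_med = float(np.median(idx[:, 2]))
    zz = np.arange(mask.grid.shape[2])[None, None, :]
    rostral = mask.data & (zz > z_med)
    caudal = mask.data & ~(zz > z_med)
    return (
        VoxelMask(mask.grid, rostral, label=f"{mask.label}_rostral"),
        VoxelMask(mask.grid, caudal, label=f"{mask.label}_caudal"),
    )


def split_left_right(mask: VoxelMask, convention: str = "neurological") -> tuple[VoxelMask, VoxelMask]:
    """Split into (left, right) by 26-connected components.

    With exactly two components, sides are assigned by centroid x. Under the
    default neurological convention x increases toward the subject's right,
    so the larger-x component is labeled right; ``convention='radiological'``
    flips the labels. Any other component count falls back to a mid-x plane
    split, which always yields a complete partition.
    """
    if convention not in ("neurological", "radiological"):
        raise ValueError(f"unknown convention {convention!r}")
    if mask.voxel_count == 0:
        raise ValueError("cannot split an empty mask")
    labels, n_comp = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    if n_comp == 2:
        cent = ndimage.center_of_mass(mask.data, labels, [1, 2])
        hi_label = 1 if cent[0][0] > cent[1][0] else 2
        hi = VoxelMask(mask.grid, labels == hi_label)
        lo = VoxelMask(mask.grid, (labels > 0) & (labels != hi_label))
    else:
        xx = np.arange(mask.grid.shape[0])[:, None, None]
        mid = (mask.grid.shape[0] - 1) / 2
        hi = VoxelMask(mask.grid, mask.data & (xx > mid))
        lo = VoxelMask(mask.grid, mask.data & ~(xx > mid))
    if convention == "neurological":
        right, left = hi, lo
    else:
        right, left = lo, hi
    left.label = f"{mask.label}_left"
    right.label = f"{mask.label}_right"
    return left, right


def mask_overlap_pct(a: VoxelMask, b: VoxelMask) -> float:
    """Percent spatial overlap of ``a`` relative to ``b``: 100*|a & b|/|b|."""
    a._check_same_grid(b)
    nb = b.voxel_count
    if nb == 0:
        raise ValueError("overlap relative to an empty mask is undefined")
    return 100.0 * int((a.data & b.data).sum()) / nb


def interrater_conjunction(rater1: VoxelMask, rater2: VoxelMask) -> InterRaterResult:
    """Consensus mask (intersection) with per-rater agreement and Dice.

    Agreement for rater i is the percentage of their voxels kept in the
    conjunction; Dice is the symmetric 2|∩|/(|r1|+|r2|). An empty
    conjunction is returned flagged as an invalid consensus.
    """
    rater1._check_same_grid(rater2)
    n1, n2 = rater1.voxel_count, rater2.voxel_count
    if n1 == 0 or n2 == 0:
        raise ValueError("both rater masks must be non-empty")
    inter = rater1.intersection(rater2, label="lc_consensus")
    ni = inter.voxel_count
    return InterRaterResult(
        conjunction=inter,
        agreement_rater1_pct=100.0 * ni / n1,
        agreement_rater2_pct=100.0 * ni / n2,
        dice=2.0 * ni / (n1 + n2),
        valid_consensus=ni > 0,
    )


def extract_subject(
    volume: ScalarVolume,
    lc_mask: VoxelMask,
    ref_spec: ReferenceSpec = ReferenceSpec(),
    *,
    subject_id: str = "",
    age_years: float = float("nan"),
    sex: str = "",
    tr_ms: int = 0,
    motion_suspect: bool = False,
) -> SubjectCRRecord:
    """Run the whole per-subject quantification.

    Places the reference, summarizes every region (whole, rostral, caudal,
    left, right), computes mean/median/max CRs — all against the single
    whole-subject reference mean — and sets QC flags. Deterministic.
    """
    reference = place_reference_region(lc_mask, ref_spec)
    ref_summary = summarize_region(volume, reference)
    rostral, caudal = split_rostral_caudal(lc_mask)
    left, right = split_left_right(lc_mask)
    regions = {
        "whole": lc_mask, "rostral": rostral, "caudal": caudal,
        "left": left, "right": right,
    }
    cr: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    lc_s_mean = float("nan")
    for name, region_mask in regions.items():
        summary = summarize_region(volume, region_mask)
        cr[name] = {
            "mean": compute_cr(summary.s_mean, ref_summary.s_mean),
            "median": compute_cr(summary.s_median, ref_summary.s_mean),
            "max": compute_cr(summary.s_max, ref_summary.s_mean),
        }
        counts[name] = summary.voxel_count
        if name == "whole":
            lc_s_mean = summary.s_mean
    flags = set()
    if cr["whole"]["mean"] < 0:
        flags.add("negative_cr")
    if motion_suspect:
        flags.add("motion_suspect")
    return SubjectCRRecord(
        subject_id=subject_id, age_years=age_years, sex=sex, tr_ms=tr_ms,
        cr=cr, voxel_counts=counts, ref_s_mean=ref_summary.s_mean,
        lc_s_mean=lc_s_mean, qc_flags=flags,
    )
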