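"""Synthetic brainstem phantom: cohorts of MT-like volumes with known truth.

The generator emulates the features of a neuromelanin-sensitive MRI cohort
that the downstream pipeline must handle, without any real data:

* two bilateral hyperintense tubes (the locus coeruleus) on a flat pontine
  background,
* a contrast-ratio (CR) lifespan trajectory that rises quadratically to a
  peak near 60 years, then declines linearly in the rostral half while the
  caudal half plateaus,
* a weak negative drift of raw pontine signal with age and an additive
  repetition-time (TR) group offset on raw intensities,
* between-subject CR noise whose spread grows with age, and
* a configurable fraction of motion-corrupted subjects whose extracted mean
  CR turns negative.

Every random draw flows from a single integer seed, so cohorts, tables and
volumes are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ScalarVolume, VolumeGrid, VoxelMask

__all__ = [
    "CohortSpec",
    "TrajectoryParams",
    "TubeGeometry",
    "PhantomSubject",
    "true_cr",
    "build_truth_mask",
    "jitter_truth_mask",
    "render_subject_volume",
    "inject_motion",
    "generate_cohort",
    "DEFAULT_GRID",
]

#: Default phantom grid: ample padding around the tubes at 0.8 mm isotropic.
DEFAULT_GRID = VolumeGrid(shape=(48, 48, 32), voxel_size_mm=0.8)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition: size, age range, sex ratio, TR groups, seed.

    Defaults mirror a population-based adult lifespan cohort: ages 18-88,
    roughly balanced sexes, and two repetition-time groups (30 and 50 ms) in
    about a 369:230 ratio.
    """

    n_subjects: int = 605
    age_range_years: tuple[float, float] = (18.0, 88.0)
    sex_ratio_male: float = 0.49
    tr_groups_ms: tuple[int, int] = (30, 50)
    tr_proportions: tuple[float, float] = (369 / 599, 230 / 599)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        lo, hi = self.age_range_years
        if not lo < hi:
            raise ValueError("age_range_years must be increasing")
        if abs(sum(self.tr_proportions) - 1.0) > 1e-9:
            raise ValueError("tr_proportions must sum to 1")
        if not 0.0 <= self.sex_ratio_male <= 1.0:
            raise ValueError("sex_ratio_male must be a fraction")


@dataclass(frozen=True)
class TrajectoryParams:
    """Ground-truth CR trajectory and raw-signal parameters.

    The trajectory is quadratic up to ``peak_age_years`` and piecewise linear
    after it: the rostral region declines at ``rostral_decline_slope`` per
    year while the caudal region follows ``caudal_post_peak_slope`` (flat by
    default), both continuous at the peak. Raw background signal is
    ``background_level`` plus a small negative per-year drift and an additive
    offset for the 50 ms TR group. Between-subject CR noise interpolates
    linearly in age between the young and old standard deviations.
    """

    peak_age_years: float = 60.0
    cr_at_peak: float = 0.094
    quadratic_curvature: float = -2e-5     # CR per year^2, negative (concave)
    rostral_decline_slope: float = -8e-4   # CR per year past the peak
    caudal_post_peak_slope: float = 0.0
    background_level: float = 1000.0       # raw a.u.
    pons_age_slope: float = -0.5           # raw a.u. per year
    tr_effect: float = 80.0                # raw offset for the 50 ms group
    noise_sd_young: float = 0.018
    noise_sd_old: float = 0.026
    voxel_noise_sd: float = 5.0            # raw a.u., additive Gaussian
    background_subject_sd: float = 30.0    # raw a.u., between-subject pons level
    mask_jitter_prob: float = 0.1          # per-voxel drop prob on tube fringes
    motion_fraction: float = 18 / 623
    motion_severity: float = 1.0

    def __post_init__(self) -> None:
        if not (self.noise_sd_old >= self.noise_sd_young >= 0):
            raise ValueError("need noise_sd_old >= noise_sd_young >= 0")
        if not 0.0 <= self.motion_fraction < 1.0:
            raise ValueError("motion_fraction must be in [0, 1)")
        if self.quadratic_curvature >= 0:
            raise ValueError("quadratic_curvature must be negative")

    def noiseless(self) -> "TrajectoryParams":
        """Copy with all noise and motion switched off (identity checks)."""
        return replace(self, noise_sd_young=0.0, noise_sd_old=0.0,
                       voxel_noise_sd=0.0, background_subject_sd=0.0,
                       mask_jitter_prob=0.0, motion_fraction=0.0)


@dataclass(frozen=True)
class TubeGeometry:
    """Placement of the two LC tubes inside the grid.

    In-plane cross-sections are symmetric about each tube's x center; the
    left tube carries one extra voxel per slice so left > right counts hold
    after extraction. Defaults give 16 z-slices and 11 + 10 voxels per slice
    (336 voxels total, a 12.8 mm rostrocaudal slab at 0.8 mm).
    """

    z_start: int = 8
    n_slices: int = 16
    y_center: int = 18
    left_x_center: int = 17    # x increases left -> right, so subject-left
    right_x_center: int = 30   # sits at small x; see extraction.split_left_right
    left_offsets: tuple[tuple[int, int], ...] = (
        (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 0), (0, 1),
        (1, -1), (1, 0), (1, 1), (0, -2), (0, 2),
    )
    right_offsets: tuple[tuple[int, int], ...] = (
        (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 0), (0, 1),
        (1, -1), (1, 0), (1, 1), (0, -2),
    )

    @property
    def z_slices(self) -> range:
        return range(self.z_start, self.z_start + self.n_slices)

    @property
    def fringe_offsets(self) -> tuple[tuple[int, int], ...]:
        """Outer cross-section voxels eligible for per-subject jitter."""
        return tuple(o for o in set(self.left_offsets) | set(self.right_offsets)
                     if max(abs(o[0]), abs(o[1])) >= 2)

    @property
    def z_median(self) -> float:
        # equal per-slice counts -> the voxel-median z is the slab midpoint
        return self.z_start + (self.n_slices - 1) / 2


@dataclass
class PhantomSubject:
    """One simulated participant with ground truth attached."""

    subject_id: str
    age_years: float
    sex: str                       # 'M' or 'F'
    tr_ms: int
    true_cr_rostral: float         # noiseless trajectory value
    true_cr_caudal: float
    cr_rostral_target: float       # trajectory value + subject-level noise,
    cr_caudal_target: float        # i.e. what the volume actually encodes
    motion_flag: bool
    volume: ScalarVolume | None = None
    lc_mask_truth: VoxelMask | None = None


def true_cr(age: float, region: str, params: TrajectoryParams) -> float:
    """Ground-truth CR at ``age`` for ``region`` ('rostral' or 'caudal').

    Quadratic rise ``cr_at_peak + curvature * (age - peak)^2`` up to the
    peak; linear continuation beyond it with a region-specific slope. The
    two pieces meet at the peak, so the curve is continuous.
    """
    if not 0.0 <= age <= 120.0:
        raise ValueError(f"age {age} outside the supported range [0, 120]")
    if region not in ("rostral", "caudal"):
        raise ValueError(f"unknown region {region!r}")
    p = params
    if age <= p.peak_age_years:
        return p.cr_at_peak + p.quadratic_curvature * (age - p.peak_age_years) ** 2
    slope = p.rostral_decline_slope if region == "rostral" else p.caudal_post_peak_slope
    return p.cr_at_peak + slope * (age - p.peak_age_years)


def _background_level(age: float, tr_ms: int, params: TrajectoryParams,
                      offset: float = 0.0) -> float:
    b = params.background_level + params.pons_age_slope * age + offset
    if tr_ms == 50:
        b += params.tr_effect
    return b


def jitter_truth_mask(mask: VoxelMask, geometry: TubeGeometry,
                      params: TrajectoryParams,
                      rng: np.random.Generator) -> VoxelMask:
    """Per-subject mask variability: drop fringe tube voxels at random.

    Only the outer cross-section voxels are eligible, so the tube cores (and
    hence the slab extent and bilaterality) are always preserved. This gives
    realistic between-subject voxel-count spread with no age dependence.
    """
    if params.mask_jitter_prob <= 0:
        return mask
    data = mask.data.copy()
    for z in geometry.z_slices:
        for x_c, offsets in ((geometry.left_x_center, geometry.left_offsets),
                             (geometry.right_x_center, geometry.right_offsets)):
            for dx, dy in offsets:
                if max(abs(dx), abs(dy)) >= 2 and rng.random() < params.mask_jitter_prob:
                    data[x_c + dx, geometry.y_center + dy, z] = False
    return VoxelMask(grid=mask.grid, data=data, label=mask.label)


def build_truth_mask(grid: VolumeGrid, geometry: TubeGeometry = TubeGeometry()) -> VoxelMask:
    """Ground-truth LC mask for the tube geometry on ``grid``."""
    data = np.zeros(grid.shape, dtype=bool)
    for z in geometry.z_slices:
        for x_c, offsets in ((geometry.left_x_center, geometry.left_offsets),
                             (geometry.right_x_center, geometry.right_offsets)):
            for dx, dy in offsets:
                data[x_c + dx, geometry.y_center + dy, z] = True
    nx, ny, nz = grid.shape
    idx = np.argwhere(data)
    if idx.size and (idx.max(axis=0) >= (nx, ny, nz)).any():
        raise ValueError("tube geometry exceeds grid bounds")
    return VoxelMask(grid=grid, data=data, label="lc_truth")


def render_subject_volume(
    age: float,
    tr_ms: int,
    cr_rostral: float,
    cr_caudal: float,
    grid: VolumeGrid = DEFAULT_GRID,
    *,
    params: TrajectoryParams = TrajectoryParams(),
    geometry: TubeGeometry = TubeGeometry(),
    rng: np.random.Generator | None = None,
    background_offset: float = 0.0,
    mask: VoxelMask | None = None,
) -> tuple[ScalarVolume, VoxelMask]:
    """Render one subject: pontine plateau, two LC tubes, voxel noise.

    LC voxels sit at ``background * (1 + CR)`` with the rostral CR in the
    upper half of the slab and the caudal CR in the lower half.
    ``background_offset`` shifts the subject's pontine level (between-subject
    variability); a pre-jittered truth ``mask`` may be supplied. Returns the
    volume together with the ground-truth LC mask.
    """
    g = geometry
    if (g.z_start < 0 or g.z_start + g.n_slices > grid.shape[2]):
        raise ValueError("tube z-extent exceeds grid bounds")
    background = _background_level(age, tr_ms, params, background_offset)
    data = np.full(grid.shape, background, dtype=float)
    if mask is None:
        mask = build_truth_mask(grid, g)
    zz = np.arange(grid.shape[2])[None, None, :]
    rostral = mask.data & (zz > g.z_median)
    caudal = mask.data & ~rostral
    data[rostral] = background * (1.0 + cr_rostral)
    data[caudal] = background * (1.0 + cr_caudal)
    if params.voxel_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        data = data + rng.normal(0.0, params.voxel_noise_sd, size=grid.shape)
    np.clip(data, 0.0, None, out=data)
    return ScalarVolume(grid=grid, intensities=data), mask


def inject_motion(volume: ScalarVolume, severity: float = 1.0,
                  lc_mask: VoxelMask | None = None) -> ScalarVolume:
    """Corrupt the LC neighborhood as brainstem motion would.

    In-plane smearing along y on every slice that contains LC signal, plus
    attenuation of the LC voxels to below the slice background. At the
    default severity the extracted mean CR becomes clearly negative, which
    is exactly what the negative-CR QC rule screens for. ``severity`` scales
    both effects; 0 returns the volume unchanged.
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    data = volume.intensities.copy()
    if severity == 0:
        return ScalarVolume(grid=volume.grid, intensities=data)
    if lc_mask is not None:
        target = lc_mask.data
    else:
        # no mask: treat clearly hyperintense voxels as the target
        target = data > 1.02 * np.median(data)
    z_hit = np.unique(np.argwhere(target)[:, 2]) if target.any() else []
    smear = max(1, int(round(3 * severity)))
    for z in z_hit:
        sl = data[:, :, z]
        smeared = ndimage.uniform_filter1d(sl, size=2 * smear + 1, axis=1, mode="nearest")
        w = min(1.0, 0.7 * severity)
        sl = (1 - w) * sl + w * smeared
        tz = target[:, :, z]
        background = np.median(sl[~tz]) if (~tz).any() else np.median(sl)
        sl[tz] = background * (1.0 - 0.15 * severity)
        data[:, :, z] = sl
    np.clip(data, 0.0, None, out=data)
    return ScalarVolume(grid=volume.grid, intensities=data)


def _noise_sd_at_age(age: float, spec: CohortSpec, params: TrajectoryParams) -> float:
    lo, hi = spec.age_range_years
    frac = np.clip((age - lo) / (hi - lo), 0.0, 1.0)
    return params.noise_sd_young + frac * (params.noise_sd_old - params.noise_sd_young)


def generate_cohort(
    spec: CohortSpec,
    params: TrajectoryParams = TrajectoryParams(),
    *,
    grid: VolumeGrid = DEFAULT_GRID,
    geometry: TubeGeometry = TubeGeometry(),
    render: bool = True,
) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Simulate a cohort; returns the subjects and a tidy cohort table.

    Ages are uniform over the age range. Each subject receives one shared
    CR deviation (SD interpolated between the young and old noise levels by
    age) applied to both regional trajectory values, so regional CRs are
    correlated within subject as they are in vivo. A ``motion_fraction`` of
    subjects is flagged and their volumes corrupted via
    :func:`inject_motion`. With ``render=False`` only the table and truth
    values are produced (no volumes), which is cheap for statistics-only
    simulations.
    """
    root = np.random.SeedSequence(spec.seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    render_seeds = root.spawn(spec.n_subjects)

    n = spec.n_subjects
    ages = cohort_rng.uniform(*spec.age_range_years, size=n)
    sexes = np.where(cohort_rng.random(n) < spec.sex_ratio_male, "M", "F")
    trs = cohort_rng.choice(spec.tr_groups_ms, size=n, p=spec.tr_proportions)
    # exact corrupted count so the retained fraction is stable across seeds
    n_motion = int(round(params.motion_fraction * n))
    motion = np.zeros(n, dtype=bool)
    if n_motion:
        motion[cohort_rng.choice(n, size=n_motion, replace=False)] = True
    base_mask = build_truth_mask(grid, geometry)

    subjects: list[PhantomSubject] = []
    rows = []
    for i in range(n):
        age = float(ages[i])
        cr_r = true_cr(age, "rostral", params)
        cr_c = true_cr(age, "caudal", params)
        delta = cohort_rng.normal(0.0, _noise_sd_at_age(age, spec, params))
        subj = PhantomSubject(
            subject_id=f"sub-{i:04d}",
            age_years=age,
            sex=str(sexes[i]),
            tr_ms=int(trs[i]),
            true_cr_rostral=cr_r,
            true_cr_caudal=cr_c,
            cr_rostral_target=cr_r + delta,
            cr_caudal_target=cr_c + delta,
            motion_flag=bool(motion[i]),
        )
        if render:
            rng = np.random.default_rng(render_seeds[i])
            offset = (rng.normal(0.0, params.background_subject_sd)
                      if params.background_subject_sd > 0 else 0.0)
            subj_mask = jitter_truth_mask(base_mask, geometry, params, rng)
            vol, mask = render_subject_volume(
                age, subj.tr_ms, subj.cr_rostral_target, subj.cr_caudal_target,
                grid, params=params, geometry=geometry, rng=rng,
                background_offset=offset, mask=subj_mask,
            )
            if subj.motion_flag:
                vol = inject_motion(vol, params.motion_severity, lc_mask=mask)
            subj.volume = vol
            subj.lc_mask_truth = mask
        subjects.append(subj)
        rows.append({
            "subject_id": subj.subject_id,
            "age_years": age,
            "sex": subj.sex,
            "tr_ms": subj.tr_ms,
            "motion_flag": subj.motion_flag,
            "true_cr_rostral": cr_r,
            "true_cr_caudal": cr_c,
        })
    return subjects, pd.DataFrame(rows)
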