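"""Seeded synthetic cohort generator.

The animal study behind this pipeline deposited no raw data, so every
stage is exercised on synthetic inputs that reproduce the *statistical
structure* the analysis assumes:

* three rehabilitation profiles — low activity; frequent activity with
  little rest; moderate activity paired with longer daily rest — realised
  as two-state (run/rest) renewal processes on a 1-s cumulative-distance
  grid, flat outside the nightly wheel-access window (20:00-22:00) for
  access-restricted profiles;
* a nonmonotone ("goldilocks") bone-volume response to mean daily running
  distance, saturating in daily rest;
* voxel defect volumes in Hounsfield units with a controllable mineralized
  bridging column and ectopic bone clusters;
* a 13-subject reference cohort with 6 designed unions, whose
  week-2 → week-4 bridging fraction increases for unions and stagnates for
  nonunions, and whose fixation-plate strain targets follow two reference
  curves (union-like decreasing, nonunion-like increasing).

All generators take an explicit integer seed and are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import (
    SECONDS_PER_DAY,
    ActivityFeatures,
    TelemetrySeries,
    daily_metrics,
    weekly_features,
)

__all__ = [
    "RehabProfile",
    "GoldilocksParams",
    "DefectVolumeSpec",
    "VoxelVolume",
    "CohortConfig",
    "SubjectData",
    "CohortBundle",
    "DEFAULT_PROFILES",
    "simulate_telemetry",
    "simulate_outcome",
    "goldilocks_mean",
    "simulate_defect_volume",
    "simulate_cohort",
    "simulate_feature_cohort",
    "default_cohort_config",
]

# Nightly wheel access for access-restricted groups: 20:00-22:00.
ACCESS_WINDOW_START_S = 20 * 3600


@dataclass(frozen=True)
class RehabProfile:
    """Generative parameters of one rehabilitation regimen.

    ``bout_rate`` is the expected number of running bouts per accessible
    hour; together with ``bout_duration_mean`` it sets the mean idle time
    of the run/rest renewal process.
    """

    name: str
    daily_access_hours: float
    bout_rate: float  # bouts per accessible hour
    bout_duration_mean: float  # s
    bout_speed_mean: float  # m/s
    bout_speed_sd: float  # m/s

    def __post_init__(self) -> None:
        if not 0 < self.daily_access_hours <= 24:
            raise ValueError("daily_access_hours must be in (0, 24]")
        for name in ("bout_rate", "bout_duration_mean", "bout_speed_mean",
                     "bout_speed_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def access_window(self) -> tuple[int, int]:
        """(start, end) seconds of the daily wheel-access window."""
        if self.daily_access_hours >= 24:
            return 0, SECONDS_PER_DAY
        start = ACCESS_WINDOW_START_S
        return start, start + int(self.daily_access_hours * 3600)

    @property
    def expected_daily_distance(self) -> float:
        """Renewal-theory expectation of daily distance (m/day)."""
        return (
            self.bout_rate
            * self.daily_access_hours
            * self.bout_duration_mean
            * self.bout_speed_mean
        )


#: The three observed rehabilitation profiles.  Parameter values are chosen
#: so that (i) the low-distance group runs far less than the other two,
#: (ii) restricted and unrestricted groups run roughly the same daily
#: distance despite 2 vs 24 h of access, and (iii) the unrestricted group
#: has by far the shortest daily rest.
DEFAULT_PROFILES: dict[str, RehabProfile] = {
    "low_distance": RehabProfile(
        name="low_distance",
        daily_access_hours=2.0,
        bout_rate=4.0,
        bout_duration_mean=60.0,
        bout_speed_mean=0.20,
        bout_speed_sd=0.05,
    ),
    "restricted": RehabProfile(
        name="restricted",
        daily_access_hours=2.0,
        bout_rate=12.0,
        bout_duration_mean=100.0,
        bout_speed_mean=0.35,
        bout_speed_sd=0.08,
    ),
    "unrestricted": RehabProfile(
        name="unrestricted",
        daily_access_hours=24.0,
        bout_rate=1.2,
        bout_duration_mean=90.0,
        bout_speed_mean=0.35,
        bout_speed_sd=0.08,
    ),
}

_T_GRID = np.arange(SECONDS_PER_DAY)


def simulate_telemetry(
    profile: RehabProfile, n_days: int, seed: int, subject_id: str = "S"
) -> list[TelemetrySeries]:
    """Simulate per-second cumulative-distance telemetry.

    Within the access window, bouts alternate with idle periods in a
    two-state renewal process: idle times are exponential with mean
    ``3600 / bout_rate - bout_duration_mean`` seconds, bout durations are
    exponential with mean ``bout_duration_mean``, and each bout runs at a
    constant speed drawn from a truncated normal.  The cumulative distance
    is nondecreasing and flat outside the window.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    w0, w1 = profile.access_window
    rate = profile.bout_rate
    mean_run = profile.bout_duration_mean
    mean_idle = None
    if rate > 0:
        mean_idle = 3600.0 / rate - mean_run
        if mean_idle <= 0:
            raise ValueError(
                "bout_rate too high for bout_duration_mean: idle time "
                "would be nonpositive"
            )
    days: list[TelemetrySeries] = []
    for day in range(n_days):
        inc = np.zeros(SECONDS_PER_DAY)
        if rate > 0 and mean_run > 0:
            cur = w0 + rng.exponential(mean_idle)
            while cur < w1:
                dur = rng.exponential(mean_run)
                speed = max(
                    rng.normal(profile.bout_speed_mean, profile.bout_speed_sd),
                    0.01,
                )
                end = min(cur + dur, w1)
                s0, s1 = int(cur), int(np.ceil(end))
                secs = np.arange(s0, min(s1, SECONDS_PER_DAY))
                overlap = np.minimum(secs + 1.0, end) - np.maximum(secs, cur)
                inc[secs] += speed * np.clip(overlap, 0.0, 1.0)
                cur = end + rng.exponential(mean_idle)
        days.append(
            TelemetrySeries(
                subject_id=subject_id,
                day_index=day,
                t=_T_GRID,
                cum_distance=np.cumsum(inc),
            )
        )
    return days


@dataclass(frozen=True)
class GoldilocksParams:
    """Parameters of the synthetic bone-volume response.

    Mean response: ``bv_max * exp(-(d - d_opt)^2 / (2 d_width^2))
    * rest / (rest + rest_half_sat)`` — Gaussian in mean daily distance
    ``d`` (m/day), saturating in daily rest (h).  Values are generator
    plumbing chosen at rat-femoral-defect scale, not measured quantities.
    """

    bv_max: float = 30.0  # mm^3
    d_opt: float = 600.0  # m/day
    d_width: float = 300.0  # m/day
    rest_half_sat: float = 4.0  # h
    noise_sd: float = 1.5  # mm^3
    bridge_bv_threshold: float = 15.0  # mm^3

    def __post_init__(self) -> None:
        if self.bv_max <= 0 or self.d_width <= 0:
            raise ValueError("bv_max and d_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def goldilocks_mean(
    distance: float | np.ndarray,
    rest: float | np.ndarray,
    params: GoldilocksParams,
) -> float | np.ndarray:
    """Noise-free bone-volume response component (mm^3)."""
    d = np.asarray(distance, dtype=float)
    r = np.asarray(rest, dtype=float)
    out = (
        params.bv_max
        * np.exp(-((d - params.d_opt) ** 2) / (2.0 * params.d_width**2))
        * (r / (r + params.rest_half_sat))
    )
    return out if out.ndim else float(out)


def simulate_outcome(
    features: ActivityFeatures,
    params: GoldilocksParams,
    seed: int,
) -> tuple[float, bool]:
    """Draw an end-point (bone volume mm^3, bridged) outcome for a subject.

    Bridging is determined by the noise-free response component exceeding
    ``bridge_bv_threshold``; the reported bone volume adds Gaussian noise
    and is truncated at zero.
    """
    if not features.is_complete():
        raise ValueError("features contain missing (non-finite) values")
    rng = np.random.default_rng(seed)
    mean = goldilocks_mean(features.distance, features.rest, params)
    bv = max(0.0, float(mean + rng.normal(0.0, params.noise_sd)))
    return bv, bool(mean > params.bridge_bv_threshold)


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D intensity grid (HU) with isotropic voxel size (mm) and a
    defect (healing-region) mask."""

    intensities: np.ndarray
    voxel_size: float
    defect_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.intensities.shape != self.defect_mask.shape:
            raise ValueError("intensities and defect_mask shapes differ")


@dataclass(frozen=True)
class DefectVolumeSpec:
    """Recipe for a synthetic defect intensity volume.

    The grid is oriented with the bone axis along ``z``: a few slices of
    cortical bone at each end, the defect gap in the middle.  A mineralized
    column filling ``bridging_fraction`` of the defect cross-section spans
    the gap; ectopic clusters confined to the outer thirds of the gap add
    non-bridging mineral scaled by ``ectopic_fraction``.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 20)
    voxel_size: float = 0.3  # mm
    defect_length: float = 3.0  # mm (2 or 3)
    bridging_fraction: float = 0.0
    ectopic_fraction: float = 0.0
    intensity_mineralized_mean: float = 3000.0  # HU
    intensity_soft_mean: float = 30.0  # HU
    intensity_noise_sd: float = 0.0  # HU
    outer_radius: float | None = None  # mm; default 90% of grid half-extent
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bridging_fraction <= 1.0):
            raise ValueError("bridging_fraction must be in [0, 1]")
        if not (0.0 <= self.ectopic_fraction <= 1.0):
            raise ValueError("ectopic_fraction must be in [0, 1]")
        if self.intensity_mineralized_mean <= self.intensity_soft_mean:
            raise ValueError(
                "intensity_mineralized_mean must exceed intensity_soft_mean"
            )
        nz_gap = int(round(self.defect_length / self.voxel_size))
        if nz_gap + 2 > self.grid_shape[2]:
            raise ValueError(
                "grid too small to contain defect_length plus end slices"
            )

    @property
    def gap_slices(self) -> tuple[int, int]:
        """(z0, z1) voxel-slice bounds of the defect gap."""
        nz_gap = int(round(self.defect_length / self.voxel_size))
        z0 = (self.grid_shape[2] - nz_gap) // 2
        return z0, z0 + nz_gap

    @property
    def radius(self) -> float:
        if self.outer_radius is not None:
            return self.outer_radius
        nx, ny, _ = self.grid_shape
        return 0.45 * min(nx, ny) * self.voxel_size


def simulate_defect_volume(spec: DefectVolumeSpec) -> VoxelVolume:
    """Generate a defect intensity volume in HU from a spec.

    Deterministic per ``spec.seed``.  Mineralized structures (cortical end
    rings, bridging column, ectopic clusters) take
    ``intensity_mineralized_mean``; everything else inside the region takes
    ``intensity_soft_mean``; Gaussian noise is added on top.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    h = spec.voxel_size
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    cx, cy = nx * h / 2.0, ny * h / 2.0
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2  # (nx, ny)
    r_out = spec.radius
    in_disc = r2 <= r_out**2

    z0, z1 = spec.gap_slices
    intens = np.full(spec.grid_shape, spec.intensity_soft_mean)

    # Cortical rings at both ends (annulus, inner radius 60% of outer).
    ring = in_disc & (r2 > (0.6 * r_out) ** 2)
    intens[:, :, :z0][ring] = spec.intensity_mineralized_mean
    intens[:, :, z1:][ring] = spec.intensity_mineralized_mean

    # Bridging column: cross-sectional fill equals bridging_fraction of the
    # full defect disc.
    if spec.bridging_fraction > 0:
        rb2 = spec.bridging_fraction * r_out**2
        col = r2 <= rb2
        intens[:, :, z0:z1][col] = spec.intensity_mineralized_mean

    # Ectopic clusters: ellipsoids confined to the outer thirds of the gap
    # so they can never form an end-to-end path on their own.
    if spec.ectopic_fraction > 0:
        gap_len = (z1 - z0) * h
        n_clusters = max(1, int(round(spec.ectopic_fraction * 8)))
        zc_grid = (np.arange(nz) + 0.5) * h
        gap_z0 = z0 * h
        for _ in range(n_clusters):
            side = rng.integers(0, 2)
            zc = gap_z0 + (
                rng.uniform(0.0, 0.28) if side == 0 else rng.uniform(0.72, 1.0)
            ) * gap_len
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.3, 0.8) * r_out
            ccx, ccy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            a_xy = rng.uniform(0.2, 0.45) * r_out
            a_z = min(rng.uniform(0.5, 1.5) * a_xy, 0.15 * gap_len)
            d2 = (
                ((x[:, None, None] - ccx) / a_xy) ** 2
                + ((y[None, :, None] - ccy) / a_xy) ** 2
                + ((zc_grid[None, None, :] - zc) / a_z) ** 2
            )
            blob = (d2 <= 1.0) & in_disc[:, :, None]
            blob[:, :, :z0] = False
            blob[:, :, z1:] = False
            intens[blob] = spec.intensity_mineralized_mean

    if spec.intensity_noise_sd > 0:
        intens = intens + rng.normal(
            0.0, spec.intensity_noise_sd, size=intens.shape
        )

    defect_mask = np.zeros(spec.grid_shape, dtype=bool)
    defect_mask[:, :, z0:z1] = in_disc[:, :, None]
    return VoxelVolume(
        intensities=intens, voxel_size=h, defect_mask=defect_mask
    )


# ---------------------------------------------------------------------------
# Cohort bundle


@dataclass
class SubjectData:
    """All synthetic inputs for one subject (one instrumented 3 mm defect)."""

    subject_id: str
    group: str
    defect_size: float
    telemetry: list[TelemetrySeries]
    daily_features: list[ActivityFeatures]
    weekly: ActivityFeatures
    designed_union: bool
    defect_specs: dict[int, DefectVolumeSpec]  # keyed by week (2, 4, 8)
    plate_strain_targets: dict[int, float]  # microstrain, weeks 2 and 4


@dataclass
class CohortBundle:
    subjects: list[SubjectData]
    config: "CohortConfig"

    def outcome_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "defect_size": s.defect_size,
                "union": int(s.designed_union),
            }
            for name in (
                "distance",
                "duration",
                "bouts_per_day",
                "bout_duration",
                "velocity",
                "rest",
            ):
                row[name] = getattr(s.weekly, name)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the reference cohort.

    Defaults mirror the instrumented arm of the study design: thirteen
    3 mm defects drawn from the low-distance (n=6) and restricted (n=7)
    groups, six of which achieve union; plate-strain targets follow a
    decreasing union-like curve and an increasing nonunion-like curve.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"low_distance": 6, "restricted": 7}
    )
    union_counts: dict[str, int] = field(
        default_factory=lambda: {"low_distance": 2, "restricted": 4}
    )
    n_days: int = 21
    defect_size: float = 3.0
    grid_shape: tuple[int, int, int] = (10, 10, 10)
    voxel_size: float = 0.5
    intensity_noise_sd: float = 40.0
    # Reference plate-strain curves (microstrain) at weeks 2 and 4.
    union_targets: tuple[float, float] = (500.0, 350.0)
    nonunion_targets: tuple[float, float] = (350.0, 450.0)
    target_jitter: float = 0.08  # relative SD applied per subject
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group {g!r} has nonpositive size")
            if self.union_counts.get(g, 0) > n:
                raise ValueError(f"union count exceeds group size for {g!r}")


def default_cohort_config(seed: int = 0) -> CohortConfig:
    return CohortConfig(seed=seed)


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full cohort bundle: telemetry, activity features,
    week-2/4/8 defect volume specs, and plate-strain targets.

    Designed unions get a bridging column that appears between weeks 2 and
    4 and consolidates by week 8; nonunions never bridge but accrue ectopic
    bone, so their bone volume still grows.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    profiles = DEFAULT_PROFILES
    subjects: list[SubjectData] = []
    sid = 0
    for group, n in config.group_sizes.items():
        if group not in profiles:
            raise ValueError(f"unknown rehabilitation profile {group!r}")
        n_union = config.union_counts.get(group, 0)
        union_idx = set(
            rng.choice(n, size=n_union, replace=False).tolist()
        )
        for i in range(n):
            sid += 1
            subject_id = f"{group[:3]}{sid:02d}"
            tele_seed = int(ss.entropy % (2**31)) ^ (7919 * sid)
            telemetry = simulate_telemetry(
                profiles[group],
                n_days=config.n_days,
                seed=tele_seed,
                subject_id=subject_id,
            )
            daily = [daily_metrics(day) for day in telemetry]
            weekly = weekly_features(daily, weeks=(1, 3))
            union = i in union_idx

            if union:
                bf = {2: 0.0, 4: float(rng.uniform(0.5, 0.8)), 8: 0.9}
                ec = {2: 0.3, 4: 0.5, 8: 0.5}
                t2, t4 = config.union_targets
            else:
                bf = {2: 0.0, 4: 0.0, 8: 0.0}
                ec = {2: 0.2, 4: 0.35, 8: 0.45}
                t2, t4 = config.nonunion_targets
            specs = {
                wk: DefectVolumeSpec(
                    grid_shape=config.grid_shape,
                    voxel_size=config.voxel_size,
                    defect_length=config.defect_size,
                    bridging_fraction=bf[wk],
                    ectopic_fraction=ec[wk],
                    intensity_noise_sd=config.intensity_noise_sd,
                    seed=(sid * 101 + wk) % (2**31),
                )
                for wk in (2, 4, 8)
            }
            jit = config.target_jitter
            targets = {
                2: float(t2 * rng.normal(1.0, jit)),
                4: float(t4 * rng.normal(1.0, jit)),
            }
            subjects.append(
                SubjectData(
                    subject_id=subject_id,
                    group=group,
                    defect_size=config.defect_size,
                    telemetry=telemetry,
                    daily_features=daily,
                    weekly=weekly,
                    designed_union=union,
                    defect_specs=specs,
                    plate_strain_targets=targets,
                )
            )
    return CohortBundle(subjects=subjects, config=config)


def simulate_feature_cohort(
    n_subjects: int = 60,
    params: GoldilocksParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted goldilocks feature table for the multivariate models.

    Distance and rest carry the bone-volume signal through
    :func:`goldilocks_mean`; the other four activity parameters are drawn
    independently (decoys).  Returns a DataFrame with the six feature
    columns plus ``bone_volume`` and ``union``.
    """
    if n_subjects < 5:
        raise ValueError("need at least 5 subjects")
    p = params or GoldilocksParams()
    rng = np.random.default_rng(seed)
    distance = rng.uniform(50.0, 1500.0, n_subjects)
    rest = rng.uniform(1.0, 23.0, n_subjects)
    duration = rng.uniform(10.0, 240.0, n_subjects)
    bouts = rng.uniform(5.0, 60.0, n_subjects)
    bout_duration = rng.uniform(30.0, 300.0, n_subjects)
    velocity = rng.uniform(0.1, 0.6, n_subjects)
    mean = goldilocks_mean(distance, rest, p)
    bv = np.maximum(0.0, mean + rng.normal(0.0, p.noise_sd, n_subjects))
    return pd.DataFrame(
        {
            "subject_id": [f"G{i:03d}" for i in range(n_subjects)],
            "distance": distance,
            "duration": duration,
            "bouts_per_day": bouts,
            "bout_duration": bout_duration,
            "velocity": velocity,
            "rest": rest,
            "bone_volume": bv,
            "union": (mean > p.bridge_bv_threshold).astype(int),
        }
    )
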