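"""Synthetic tumor-bearing CT-like phantom cohorts.

Each phantom subject is a tumor-centered crop containing one lesion: an
ellipsoid whose surface is perturbed by smooth angular spikes (emulating
spiculation), with an internal texture whose contrast varies across
subjects. The perturbation magnitude and texture contrast jointly define a
per-subject *morphology score* (z-scored across the cohort), which drives
an exponential survival hazard — so the cohort carries a planted,
recoverable morphology→outcome signal with known strength.

Serial follow-up scans rescale the lesion along one of three trajectory
classes (responder / stable / progressor), producing measurement series
that exercise the RECIST engines; progression times derived from the
trajectory feed the local progression-free survival endpoint.

Appearance is deliberately schematic (lesion/background contrast plus
Gaussian noise, no Hounsfield calibration): the cohorts test mechanism,
not clinical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .recist_engine import (MeasurementSeries, RecistParams, ResponseCategory,
                            categorize_unidimensional, longest_axial_diameter)

TRAJECTORY_CLASSES = ("responder", "stable", "progressor")

# a lesion axis below this (in voxel units) renders no voxels: resolved
_RESOLVE_VOXELS = 0.75


@dataclass
class PhantomConfig:
    n_patients: int = 120
    grid_shape: tuple[int, int, int] = (96, 96, 48)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radius_range: tuple[float, float] = (5.0, 10.0)   # mm semi-axes
    spiculation_strength: float = 0.3                  # fractional radius
    texture_noise_sd: float = 0.15                     # intensity units
    background_noise_sd: float = 0.05
    baseline_hazard: float = 0.35                      # events / year
    log_hr_morphology: float = 1.5                     # beta on z
    censoring_rate: float = 0.15                       # / year
    cancer_death_fraction: float = 0.75
    followup_first_months: float = 2.0
    followup_interval_months: float = 3.0
    n_followups: int = 4
    trajectory_mix: tuple[float, float, float] = (0.35, 0.30, 0.35)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not abs(sum(self.trajectory_mix) - 1.0) < 1e-9:
            raise ValueError("trajectory_mix must sum to 1")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValueError("rates must be > 0")
        if not 0 <= self.spiculation_strength <= 1:
            raise ValueError("spiculation_strength must be in [0, 1]")
        lo, hi = self.radius_range
        if not 0 < lo <= hi:
            raise ValueError("radius_range must satisfy 0 < min <= max")
        half = min(s * sp / 2 for s, sp in zip(self.grid_shape,
                                               self.voxel_spacing))
        if hi * (1 + self.spiculation_strength) + 2 * max(self.voxel_spacing) > half:
            raise ValueError("lesion out of bounds: radius_range does not "
                             "fit the grid with a 2-voxel margin")

    @classmethod
    def desk(cls, **kw) -> "PhantomConfig":
        """Small-grid preset matched to the desk U-Net (32x32x16)."""
        kw.setdefault("grid_shape", (32, 32, 16))
        kw.setdefault("radius_range", (2.5, 4.5))
        return cls(**kw)

    @property
    def followup_times_months(self) -> list[float]:
        return [self.followup_first_months + k * self.followup_interval_months
                for k in range(self.n_followups)]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_spacing))


@dataclass
class _LesionGeometry:
    """Analytic description of one lesion, re-renderable at any scale.

    A single latent ``severity`` in [0, 1] drives the three correlated
    image expressions of aggressive morphology: boundary spiculation,
    lesion density (mean contrast), and internal texture heterogeneity —
    so the planted score remains visible after voxelization and pooling.
    """

    semi_axes: np.ndarray            # mm, (3,)
    spike_dirs: np.ndarray           # (n_spikes, 3) unit vectors
    spike_amps: np.ndarray           # (n_spikes,)
    spike_scale: float               # severity * spiculation_strength
    spike_width: float               # angular sd, radians
    texture_sd: float                # intensity sd inside the lesion
    texture_rel: float               # the severity draw, in [0, 1]
    density: float = 1.0             # mean lesion contrast

    def bump(self, unit_dirs: np.ndarray) -> np.ndarray:
        """Fractional radial perturbation at the given unit directions."""
        if self.spike_scale == 0 or len(self.spike_dirs) == 0:
            return np.zeros(unit_dirs.shape[:-1])
        cosang = np.clip(unit_dirs @ self.spike_dirs.T, -1.0, 1.0)
        ang = np.arccos(cosang)
        return self.spike_scale * (
            self.spike_amps * np.exp(-ang ** 2 / (2 * self.spike_width ** 2))
        ).sum(axis=-1)


@dataclass
class PhantomPatient:
    patient_id: str
    baseline_volume: np.ndarray
    baseline_mask: np.ndarray
    morphology_score: float          # z across the cohort
    morphology_raw: float
    trajectory_class: str = "stable"
    followup_volumes: list = field(default_factory=list)
    followup_masks: list = field(default_factory=list)
    scan_times_months: list = field(default_factory=list)   # incl. baseline 0
    true_diameters: list = field(default_factory=list)
    true_volumes: list = field(default_factory=list)
    progression_time_yr: float | None = None
    os_time: float = np.nan
    os_event: int = 0
    dss_time: float = np.nan
    dss_event: int = 0
    lpfs_time: float = np.nan
    lpfs_event: int = 0
    two_year_os: int | None = None
    two_year_dss: int | None = None
    two_year_lpfs: int | None = None
    geometry: _LesionGeometry | None = None

    def measurement_series(self) -> MeasurementSeries:
        return MeasurementSeries(
            patient_id=self.patient_id,
            scan_times_months=list(self.scan_times_months),
            diameters_mm=list(self.true_diameters),
            volumes_mm3=list(self.true_volumes),
            source="manual",
        )


def _fibonacci_sphere(n: int = 256) -> np.ndarray:
    """Near-uniform unit directions for perturbation-magnitude quadrature."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)

_QUAD_DIRS = _fibonacci_sphere(256)


def _render(geom: _LesionGeometry, config: PhantomConfig,
            scale: np.ndarray) -> np.ndarray:
    """Voxelize the lesion at per-axis scale factors; returns binary mask."""
    semi = geom.semi_axes * scale
    if np.min(semi) / np.max(config.voxel_spacing) < _RESOLVE_VOXELS:
        return np.zeros(config.grid_shape, dtype=np.uint8)
    shape = config.grid_shape
    sp = np.asarray(config.voxel_spacing)
    center = (np.asarray(shape) - 1) / 2.0
    axes = [(np.arange(s) - c) * p for s, c, p in zip(shape, center, sp)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([gx, gy, gz], axis=-1)
    r = np.linalg.norm(coords, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[..., None] > 0, coords / np.maximum(r, 1e-12)[..., None], 0.0)
    rho = 1.0 + geom.bump(unit)
    rnorm = np.linalg.norm(coords / semi, axis=-1)
    mask = (rnorm <= rho).astype(np.uint8)
    # bounds check: lesion must not touch the 2-voxel margin
    margin = 2
    if (mask[:margin].any() or mask[-margin:].any()
            or mask[:, :margin].any() or mask[:, -margin:].any()
            or mask[:, :, :margin].any() or mask[:, :, -margin:].any()):
        raise ValueError("lesion out of bounds")
    return mask


def _paint(mask: np.ndarray, geom: _LesionGeometry, config: PhantomConfig,
           rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    vol = rng.normal(0.0, config.background_noise_sd,
                     size=config.grid_shape).astype(np.float32)
    inside = mask.astype(bool)
    n_in = int(inside.sum())
    if n_in:
        # heterogeneity is half smooth lumpiness (survives downsampling),
        # half voxel-wise grain
        smooth = gaussian_filter(
            rng.standard_normal(config.grid_shape), sigma=1.5)[inside]
        sd = smooth.std()
        smooth = smooth / sd if sd > 0 else smooth
        grain = rng.standard_normal(n_in)
        vol[inside] = (geom.density
                       + 0.5 * geom.texture_sd * (smooth + grain)
                       ).astype(np.float32)
    return vol


def generate_lesion(config: PhantomConfig, rng: np.random.Generator,
                    semi_axes=None,
                    ) -> tuple[np.ndarray, np.ndarray, float, _LesionGeometry]:
    """One baseline lesion: (intensity volume, mask, raw morphology, geometry).

    The raw morphology score is the RMS fractional radial perturbation
    (quadrature over fixed sphere directions) modulated by the relative
    texture contrast; it is z-scored across the cohort by
    :func:`generate_cohort`. With ``spiculation_strength == 0`` the mask is
    an exact discrete ellipsoid and the raw score is 0.
    """
    lo, hi = config.radius_range
    if semi_axes is None:
        semi_axes = rng.uniform(lo, hi, size=3)
    semi_axes = np.asarray(semi_axes, dtype=float)
    severity = float(rng.uniform(0.0, 1.0))
    n_spikes = 8
    dirs = rng.standard_normal((n_spikes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.uniform(0.5, 1.0, size=n_spikes)
    # normalize so the peak radial perturbation equals the drawn scale
    # (overlapping spikes would otherwise sum past the grid margin)
    peak = float((amps * np.exp(
        -np.arccos(np.clip(_QUAD_DIRS @ dirs.T, -1, 1)) ** 2
        / (2 * 0.3 ** 2))).sum(axis=-1).max())
    amps = amps / max(peak, 1e-9)
    geom = _LesionGeometry(
        semi_axes=semi_axes, spike_dirs=dirs, spike_amps=amps,
        spike_scale=severity * config.spiculation_strength, spike_width=0.3,
        texture_sd=config.texture_noise_sd * (0.5 + severity),
        texture_rel=severity,
        # density spans the subsolid-to-solid contrast spectrum (0.6x-1.4x
        # the nominal lesion contrast), tied to the same severity axis
        density=1.0 + 0.8 * (severity - 0.5))
    mask = _render(geom, config, scale=np.ones(3))
    vol = _paint(mask, geom, config, rng)
    rms = float(np.sqrt(np.mean(geom.bump(_QUAD_DIRS) ** 2)))
    raw_score = rms * (1.0 + 0.5 * geom.texture_rel)
    return vol, mask, raw_score, geom


def _trajectory_factors(traj_class: str, baseline_diameter_mm: float,
                        n_scans: int, rng: np.random.Generator) -> np.ndarray:
    """Per-scan diameter scale factors relative to baseline.

    Schedules keep every scan deep inside one category zone of the response
    rules, with a ~2 mm margin for voxelization jitter, so categorizations
    from mask-measured diameters agree with the recorded true diameters:

    * responder — a slow-shrink phase clearly above the -30% line, then a
      drop clearly below it (possibly to full resolution);
    * stable — every factor in (0.95, 1.05); with the 5 mm absolute floor
      this cannot reach the progression rule at the lesion sizes generated;
    * progressor — a ramp whose absolute growth stays under 3 mm (safe from
      the 5 mm floor), then a final jump past both +20% and +6.5 mm.
    """
    d0 = baseline_diameter_mm
    if traj_class == "responder":
        final = float(rng.uniform(0.15, 0.55))
        lo = 0.7 - 2.0 / d0              # deep-PR boundary with jitter margin
        hi = min(0.95, 0.7 + 2.0 / d0)   # still clearly SD
        if lo <= 0.05:
            return np.full(n_scans, final)
        final = min(final, 0.95 * lo)
        n_hi = n_scans // 2
        his = np.linspace(0.96, hi, n_hi + 1)[1:]
        los = np.linspace(0.95 * lo, final, n_scans - n_hi)
        return np.concatenate([his, los])
    if traj_class == "stable":
        return rng.uniform(0.95, 1.05, size=n_scans)
    if traj_class == "progressor":
        # final growth guarantees the PD rule (+20% relative to nadir and
        # >= 5 mm absolute) with margin for voxelization jitter
        final = max(1.35, 1.0 + 6.5 / d0)
        if n_scans == 1:
            return np.asarray([final])
        low = 1.0 + 3.0 / d0             # < 5 mm absolute: cannot be PD yet
        ramp = 1.0 + (low - 1.0) * np.arange(1, n_scans) / (n_scans - 1)
        return np.concatenate([ramp, [final]])
    raise ValueError(f"unknown trajectory class {traj_class!r}")


def simulate_trajectory(patient: PhantomPatient, config: PhantomConfig,
                        rng: np.random.Generator,
                        traj_class: str | None = None) -> PhantomPatient:
    """Render follow-up scans and record the true measurement series.

    True diameters scale the baseline mask's longest axial diameter by the
    trajectory factor; true volumes are voxel count x voxel volume of each
    rendered mask. Progressor growth is applied in-plane only (the crop is
    thin along z), which leaves the axial diameter rule unaffected.
    """
    if patient.geometry is None:
        raise ValueError("patient has no baseline lesion")
    if traj_class is None:
        traj_class = TRAJECTORY_CLASSES[
            rng.choice(len(TRAJECTORY_CLASSES), p=config.trajectory_mix)]
    d0 = longest_axial_diameter(patient.baseline_mask, config.voxel_spacing)
    v0 = float(patient.baseline_mask.sum()) * config.voxel_volume
    factors = _trajectory_factors(traj_class, d0, config.n_followups, rng)
    patient.trajectory_class = traj_class
    patient.scan_times_months = [0.0] + config.followup_times_months
    patient.true_diameters = [d0]
    patient.true_volumes = [v0]
    patient.followup_volumes, patient.followup_masks = [], []
    for f in factors:
        if traj_class == "progressor":
            scale = np.array([f, f, 1.0])
        else:
            scale = np.full(3, f)
        mask = _render(patient.geometry, config, scale)
        vol = _paint(mask, patient.geometry, config, rng)
        patient.followup_masks.append(mask)
        patient.followup_volumes.append(vol)
        resolved = mask.sum() == 0
        patient.true_diameters.append(0.0 if resolved else d0 * float(f))
        patient.true_volumes.append(float(mask.sum()) * config.voxel_volume)
    # progression time: first follow-up scan categorized PD on true diameters
    cats = categorize_unidimensional(patient.measurement_series())
    patient.progression_time_yr = None
    for t, c in zip(patient.scan_times_months[1:], cats):
        if c == ResponseCategory.PD:
            patient.progression_time_yr = t / 12.0
            break
    return patient


def simulate_survival(morphology_z: np.ndarray, config: PhantomConfig,
                      rng: np.random.Generator,
                      progression_times_yr=None) -> list[dict]:
    """Censored OS/DSS/LPFS outcomes from the planted morphology signal.

    Death times are exponential with hazard
    ``baseline_hazard * exp(log_hr_morphology * z)``; censoring is an
    independent exponential at ``censoring_rate``. A fraction of deaths is
    flagged cancer-related (DSS events are a subset of OS events; DSS
    censors non-cancer deaths at the death date). LPFS takes the earlier of
    the trajectory-derived progression time and death.
    """
    z = np.asarray(morphology_z, dtype=float)
    n = len(z)
    if progression_times_yr is None:
        progression_times_yr = [None] * n
    out = []
    for i in range(n):
        h = config.baseline_hazard * np.exp(config.log_hr_morphology * z[i])
        t_death = rng.exponential(1.0 / h)
        t_cens = rng.exponential(1.0 / config.censoring_rate)
        cancer = rng.uniform() < config.cancer_death_fraction
        os_time = min(t_death, t_cens)
        os_event = int(t_death <= t_cens)
        dss_event = int(os_event and cancer)
        p = progression_times_yr[i]
        p = np.inf if p is None else p
        lpfs_time = min(p, t_death, t_cens)
        lpfs_event = int(min(p, t_death) <= t_cens)
        rec = dict(os_time=os_time, os_event=os_event,
                   dss_time=os_time, dss_event=dss_event,
                   lpfs_time=lpfs_time, lpfs_event=lpfs_event)
        for ep in ("os", "dss", "lpfs"):
            t, e = rec[f"{ep}_time"], rec[f"{ep}_event"]
            if e and t <= 2.0:
                rec[f"two_year_{ep}"] = 1
            elif t >= 2.0:
                rec[f"two_year_{ep}"] = 0
            else:
                rec[f"two_year_{ep}"] = None    # insufficient follow-up
        out.append(rec)
    return out


def generate_cohort(config: PhantomConfig,
                    with_followups: bool = True) -> list[PhantomPatient]:
    """Fully seeded synthetic cohort.

    Per-patient RNG streams are derived from ``(seed, patient index)``, so
    patient ``i`` is identical regardless of cohort size; morphology scores
    are z-scored across the cohort after all lesions are drawn.
    """
    patients: list[PhantomPatient] = []
    raws = []
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i, 0])
        vol, mask, raw, geom = generate_lesion(config, rng)
        p = PhantomPatient(
            patient_id=f"P{i:04d}", baseline_volume=vol, baseline_mask=mask,
            morphology_score=0.0, morphology_raw=raw, geometry=geom)
        patients.append(p)
        raws.append(raw)
    raws = np.asarray(raws)
    sd = raws.std()
    z = (raws - raws.mean()) / sd if sd > 0 else np.zeros_like(raws)
    prog_times = []
    for i, p in enumerate(patients):
        p.morphology_score = float(z[i])
        if with_followups:
            rng = np.random.default_rng([config.seed, i, 1])
            simulate_trajectory(p, config, rng)
        prog_times.append(p.progression_time_yr)
    for i, p in enumerate(patients):
        rng = np.random.default_rng([config.seed, i, 2])
        rec = simulate_survival(np.asarray([p.morphology_score]), config, rng,
                                [prog_times[i]])[0]
        p.os_time, p.os_event = rec["os_time"], rec["os_event"]
        p.dss_time, p.dss_event = rec["dss_time"], rec["dss_event"]
        p.lpfs_time, p.lpfs_event = rec["lpfs_time"], rec["lpfs_event"]
        p.two_year_os = rec["two_year_os"]
        p.two_year_dss = rec["two_year_dss"]
        p.two_year_lpfs = rec["two_year_lpfs"]
    return patients


# ---------------------------------------------------------------------------
# on-disk representation: NIfTI volumes + clinical CSV


def _affine(config: PhantomConfig) -> np.ndarray:
    """LPS-consistent affine carrying the voxel spacing."""
    sx, sy, sz = config.voxel_spacing
    return np.diag([-sx, -sy, sz, 1.0])


def write_cohort(patients: list[PhantomPatient], config: PhantomConfig,
                 out_dir) -> "Path":
    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    aff = _affine(config)
    rows = []
    for p in patients:
        scans = [(0.0, p.baseline_volume, p.baseline_mask)]
        scans += list(zip(p.scan_times_months[1:], p.followup_volumes,
                          p.followup_masks))
        for j, (t, vol, mask) in enumerate(scans):
            stem = f"{p.patient_id}_scan{j:02d}"
            nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), aff),
                     out / "images" / f"{stem}_ct.nii.gz")
            nib.save(nib.Nifti1Image(np.asarray(mask, np.uint8), aff),
                     out / "images" / f"{stem}_mask.nii.gz")
            rows.append(dict(
                patient_id=p.patient_id, scan_time_months=t,
                diameter_mm=p.true_diameters[j] if p.true_diameters else np.nan,
                volume_mm3=p.true_volumes[j] if p.true_volumes else np.nan,
                os_time_yr=p.os_time, os_event=p.os_event,
                dss_time_yr=p.dss_time, dss_event=p.dss_event,
                lpfs_time_yr=p.lpfs_time, lpfs_event=p.lpfs_event,
                two_year_os=p.two_year_os, two_year_dss=p.two_year_dss,
                two_year_lpfs=p.two_year_lpfs,
                trajectory_class=p.trajectory_class,
                morphology_score=p.morphology_score,
            ))
    pd.DataFrame(rows).to_csv(out / "clinical.csv", index=False)
    return out


def load_cohort(cohort_dir) -> tuple[list[PhantomPatient], "object"]:
    """Read a written cohort back; returns (patients, clinical DataFrame)."""
    import nibabel as nib
    import pandas as pd

    out = Path(cohort_dir)
    df = pd.read_csv(out / "clinical.csv")
    patients = []
    for pid, g in df.groupby("patient_id", sort=True):
        g = g.sort_values("scan_time_months")
        vols, masks = [], []
        for j in range(len(g)):
            stem = f"{pid}_scan{j:02d}"
            vols.append(np.asarray(
                nib.load(out / "images" / f"{stem}_ct.nii.gz").dataobj,
                dtype=np.float32))
            masks.append(np.asarray(
                nib.load(out / "images" / f"{stem}_mask.nii.gz").dataobj,
                dtype=np.uint8))
        r0 = g.iloc[0]

        def _label(v):
            return None if pd.isna(v) else int(v)

        p = PhantomPatient(
            patient_id=str(pid), baseline_volume=vols[0],
            baseline_mask=masks[0],
            morphology_score=float(r0["morphology_score"]),
            morphology_raw=np.nan,
            trajectory_class=str(r0["trajectory_class"]),
            followup_volumes=vols[1:], followup_masks=masks[1:],
            scan_times_months=list(g["scan_time_months"]),
            true_diameters=list(g["diameter_mm"]),
            true_volumes=list(g["volume_mm3"]),
            os_time=float(r0["os_time_yr"]), os_event=int(r0["os_event"]),
            dss_time=float(r0["dss_time_yr"]), dss_event=int(r0["dss_event"]),
            lpfs_time=float(r0["lpfs_time_yr"]),
            lpfs_event=int(r0["lpfs_event"]),
            two_year_os=_label(r0["two_year_os"]),
            two_year_dss=_label(r0["two_year_dss"]),
            two_year_lpfs=_label(r0["two_year_lpfs"]),
        )
        patients.append(p)
    return patients, df
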