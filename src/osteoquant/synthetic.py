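"""Synthetic micro-CT, torsion-trace, and two-arm study generation.

Emulates the data of a sheep tibial-osteotomy healing study: a hollow
diaphysis interrupted by a transverse gap (3 mm non-critical or 17 mm
critical size), a mineralizing callus rendered as a fusiform periosteal
sleeve plus an endosteal plug, a density phantom for HU calibration, and
torque-rotation loading ramps from a torsion rig (5 deg/min, 20 Hz, stop
at 10 Nm or 12 deg). Every generator is a pure function of its parameters
and seed and returns analytic ground truth (masks, calibration line, true
stiffness), so each downstream stage can be validated against truth.

Group set-points default to the published two-arm summaries of the study
design being emulated (control vs. combined electric and magnetic field
stimulation, n = 6 per arm); the treatment enters only as a shift in the
sampled group distributions, never as a mechanistic model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .biomech import TorqueRotationTrace

logger = logging.getLogger(__name__)

__all__ = [
    "ScanGeometry",
    "CallusSpec",
    "SyntheticScan",
    "PhantomScan",
    "ArmSpec",
    "StudyDesign",
    "SubjectDraw",
    "CapacityError",
    "make_phantom_scan",
    "make_tibia_scan",
    "make_torsion_trace",
    "sample_study",
    "make_label_section",
    "SETPOINTS_3MM",
    "SETPOINTS_17MM",
]


class CapacityError(ValueError):
    """Requested callus volume cannot fit in the field of view."""


@dataclass(frozen=True)
class ScanGeometry:
    """Idealized operated-tibia geometry (all lengths in mm)."""

    outer_radius: float = 10.0
    cortical_thickness: float = 3.0
    bone_length: float = 60.0
    gap_width: float = 17.0
    voxel_spacing: float = 0.2
    fov_margin: float = 8.0  # transverse margin around the cortex for callus
    callus_extent: float = 20.0  # axial half-extent of the sleeve beyond the gap

    def __post_init__(self) -> None:
        if not self.outer_radius > self.cortical_thickness > 0:
            raise ValueError("need outer_radius > cortical_thickness > 0")
        if not 0 <= self.gap_width < self.bone_length:
            raise ValueError("gap must be shorter than the bone")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel spacing must be positive")

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.cortical_thickness


@dataclass(frozen=True)
class CallusSpec:
    """Target morphometry of the rendered callus."""

    target_volume: float  # cm^3
    target_mean_density: float  # mg HA/cm^3
    periosteal_fraction: float = 0.7  # share of callus outside the cortex envelope
    density_noise_sd: float = 50.0  # mg HA/cm^3, voxel-to-voxel heterogeneity

    def __post_init__(self) -> None:
        if self.target_volume < 0:
            raise ValueError("target volume must be non-negative")
        if self.target_volume > 0 and not 0 < self.target_mean_density < 1500:
            raise ValueError("target mean density must lie in (0, 1500) mg HA/cm^3")
        if not 0 <= self.periosteal_fraction <= 1:
            raise ValueError("periosteal fraction must lie in [0, 1]")


@dataclass
class SyntheticScan:
    """HU volume plus the analytic ground truth used to validate pipelines."""

    hu: np.ndarray
    spacing: float  # mm
    truth_old_bone_mask: np.ndarray
    truth_callus_mask: np.ndarray
    truth_calibration: tuple[float, float]  # (slope HU per mg HA/cm^3, intercept HU)
    truth_density: np.ndarray | None = None  # noiseless density field
    meta: dict = field(default_factory=dict)

    def truth_callus_volume_cm3(self) -> float:
        return float(self.truth_callus_mask.sum()) * self.spacing**3 / 1000.0


@dataclass
class PhantomScan:
    """Density-phantom scan: one homogeneous rod per known density."""

    hu: np.ndarray
    spacing: float
    rod_masks: list[np.ndarray]
    rod_densities: np.ndarray
    truth_calibration: tuple[float, float]


def make_phantom_scan(
    rod_densities,
    calibration: tuple[float, float] = (1.0, 0.0),
    noise_sd: float = 0.0,
    spacing: float = 0.2,
    rod_radius: float = 2.0,
    rod_length: float = 6.0,
    seed: int = 0,
) -> PhantomScan:
    """Generate a calibration-phantom scan with cylindrical rods.

    Rods of the given densities (mg HA/cm^3) are laid side by side along x;
    HU = slope * density + intercept + N(0, noise_sd).
    """
    densities = np.asarray(rod_densities, dtype=float)
    if densities.size < 2:
        raise ValueError("calibration is underdetermined with fewer than 2 rods")
    slope, intercept = calibration
    rng = np.random.default_rng(seed)
    pitch = 2.0 * rod_radius + 2.0  # mm between rod centres
    nx = int(np.ceil((pitch * densities.size + 2.0) / spacing))
    ny = int(np.ceil((2 * rod_radius + 4.0) / spacing))
    nz = int(np.ceil(rod_length / spacing))
    x = (np.arange(nx) + 0.5) * spacing
    y = (np.arange(ny) + 0.5) * spacing
    yc = ny * spacing / 2.0
    hu = np.full((nx, ny, nz), intercept, dtype=float)
    masks = []
    for i, rho in enumerate(densities):
        xc = (i + 0.5) * pitch + 1.0
        in_rod = (x[:, None] - xc) ** 2 + (y[None, :] - yc) ** 2 <= rod_radius**2
        mask = np.repeat(in_rod[:, :, None], nz, axis=2)
        hu[mask] = slope * rho + intercept
        masks.append(mask)
    if noise_sd > 0:
        hu += rng.normal(0.0, noise_sd, size=hu.shape)
    return PhantomScan(hu, spacing, masks, densities, (slope, intercept))


def _match_volume(count_fn, target_voxels: float, hi: float) -> float:
    """Bisect a monotone voxel-count function to hit a target count."""
    lo = 0.0
    if count_fn(hi) < target_voxels:
        return hi  # caller checks achieved volume
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if count_fn(mid) < target_voxels:
            lo = mid
        else:
            hi = mid
    return hi


def make_tibia_scan(
    geometry: ScanGeometry,
    callus: CallusSpec,
    cortical_density: float = 1200.0,
    calibration: tuple[float, float] = (1.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    volume_tolerance: float = 0.02,
) -> SyntheticScan:
    """Render an operated tibia: interrupted cortex + mineralizing callus.

    The cortex is a hollow cylinder (density ``cortical_density``) with a
    transverse gap of ``geometry.gap_width`` at mid-shaft. The callus is an
    endosteal plug (a cylinder filling the medullary canal around the gap)
    plus a fusiform periosteal sleeve; plug length and sleeve thickness are
    bisected on the actual voxel grid until the rendered volume matches
    ``callus.target_volume`` within ``volume_tolerance``. Callus voxel
    densities are ``target_mean_density`` plus recentred Gaussian
    heterogeneity, so the true mask mean equals the set-point exactly.
    """
    g, c = geometry, callus
    h = g.voxel_spacing
    rng = np.random.default_rng(seed)
    half_fov = g.outer_radius + g.fov_margin
    n_xy = int(np.ceil(2 * half_fov / h))
    n_z = int(round(g.bone_length / h))
    xy = (np.arange(n_xy) + 0.5) * h - n_xy * h / 2.0
    z = (np.arange(n_z) + 0.5) * h
    zc = g.bone_length / 2.0
    r2 = xy[:, None] ** 2 + xy[None, :] ** 2  # (nx, ny)
    in_gap = np.abs(z - zc) < g.gap_width / 2.0  # (nz,)

    annulus = (r2 >= g.inner_radius**2) & (r2 <= g.outer_radius**2)
    old_bone = annulus[:, :, None] & ~in_gap[None, None, :]

    callus_mask = np.zeros_like(old_bone)
    if c.target_volume > 0:
        target_vox = c.target_volume * 1000.0 / h**3
        reach = min(g.gap_width / 2.0 + 10.0, zc - h)  # axial extent of the plug
        # interior family: radius fraction t of the local cap (full gap
        # cylinder inside the gap, medullary canal outside), empty at t=0
        r_cap = np.where(
            np.abs(z - zc) < g.gap_width / 2.0,
            g.outer_radius,
            np.where(np.abs(z - zc) <= reach, g.inner_radius, 0.0),
        )

        def interior(t: float) -> np.ndarray:
            return (r2[:, :, None] <= (t * r_cap) ** 2) & ~old_bone

        target_endo = (1.0 - c.periosteal_fraction) * target_vox
        plug = np.zeros_like(old_bone)
        if target_endo > 0:
            t = _match_volume(lambda v: int(interior(v).sum()), target_endo, 1.0)
            plug = interior(t)

        remaining = target_vox - plug.sum()
        sleeve = np.zeros_like(plug)
        if remaining > 0:
            sleeve_half = min(g.gap_width / 2.0 + g.callus_extent, zc - h)
            profile = np.where(
                np.abs(z - zc) <= sleeve_half,
                0.5 + 0.5 * np.cos(np.pi * (z - zc) / sleeve_half),
                0.0,
            )  # 1 at the gap centre, 0 at the sleeve ends
            h_cap = half_fov - g.outer_radius - h

            def sleeve_mask(h_max: float) -> np.ndarray:
                r_out = g.outer_radius + h_max * profile
                return (
                    (r2[:, :, None] > g.outer_radius**2)
                    & (r2[:, :, None] <= (r_out**2)[None, None, :])
                )

            h_max = _match_volume(lambda v: int(sleeve_mask(v).sum()), remaining, h_cap)
            sleeve = sleeve_mask(h_max)
        callus_mask = plug | sleeve
        achieved = callus_mask.sum()
        if abs(achieved - target_vox) / target_vox > volume_tolerance:
            raise CapacityError(
                f"requested callus volume {c.target_volume} cm^3 not renderable "
                f"within the field of view (achieved "
                f"{achieved * h**3 / 1000.0:.2f} cm^3); enlarge fov_margin or "
                "bone_length"
            )

    density = np.zeros((n_xy, n_xy, n_z))
    density[old_bone] = cortical_density
    n_cal = int(callus_mask.sum())
    if n_cal:
        jitter = rng.normal(0.0, c.density_noise_sd, size=n_cal)
        jitter -= jitter.mean()  # truth mask mean hits the set-point exactly
        density[callus_mask] = np.clip(c.target_mean_density + jitter, 0.0, None)

    slope, intercept = calibration
    hu = slope * density + intercept
    if noise_sd > 0:
        hu = hu + rng.normal(0.0, noise_sd, size=hu.shape)
    return SyntheticScan(
        hu=hu,
        spacing=h,
        truth_old_bone_mask=old_bone,
        truth_callus_mask=callus_mask,
        truth_calibration=(slope, intercept),
        truth_density=density,
        meta={"geometry": g.__dict__ | {}, "callus": c.__dict__ | {}, "seed": seed},
    )


def make_torsion_trace(
    true_stiffness: float,
    rate: float = 5.0,  # deg/min
    sampling: float = 20.0,  # Hz
    torque_cap: float = 10.0,  # Nm
    angle_cap: float = 12.0,  # deg
    noise_sd: float = 0.0,  # Nm
    toe_region: float = 0.5,  # deg of settling before linear response
    seed: int = 0,
) -> TorqueRotationTrace:
    """Simulate the rig's loading ramp for a limb of known stiffness.

    Rotation advances ``rate / (60 * sampling)`` deg per sample; torque is
    ``max(0, k * (theta - toe))`` plus measurement noise; the ramp stops at
    the first sample whose recorded torque reaches ``torque_cap`` or whose
    rotation reaches ``angle_cap``.
    """
    if true_stiffness <= 0:
        raise ValueError("true stiffness must be positive")
    rng = np.random.default_rng(seed)
    d_theta = rate / (60.0 * sampling)
    max_samples = 1_000_000
    rotations, torques = [], []
    for n in range(max_samples):
        theta = n * d_theta
        tq = max(0.0, true_stiffness * (theta - toe_region))
        if noise_sd > 0:
            tq += rng.normal(0.0, noise_sd)
        rotations.append(theta)
        torques.append(tq)
        if tq >= torque_cap or theta >= angle_cap:
            return TorqueRotationTrace(
                np.array(rotations),
                np.array(torques),
                sampling,
                {"true_stiffness": true_stiffness, "toe_region": toe_region},
            )
    raise RuntimeError("neither cap reached within 1e6 samples")


# ---------------------------------------------------------------------------
# Two-arm study sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmSpec:
    """Per-arm (mean, SD) set-points for the sampled subject quantities.

    Volumes in cm^3, densities in mg HA/cm^3, rigidities and VTR in
    Nm^2/deg.
    """

    callus_volume: tuple[float, float]
    callus_density: tuple[float, float]
    rigidity_op: tuple[float, float]
    rigidity_nonop: tuple[float, float]
    vtr_op: tuple[float, float] | None = None
    vtr_nonop: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("callus_volume", "callus_density", "rigidity_op", "rigidity_nonop"):
            m, s = getattr(self, name)
            if s < 0:
                raise ValueError(f"{name} SD must be non-negative")


# published group summaries of the emulated study, used as generator set-points
SETPOINTS_3MM: dict[str, ArmSpec] = {
    "Control": ArmSpec((11.0, 8.0), (659.0, 54.0), (0.47, 0.39), (0.88, 0.23),
                       (0.60, 0.42), (1.01, 0.09)),
    "CEMF": ArmSpec((10.9, 4.1), (750.0, 87.0), (0.95, 0.41), (1.14, 0.29),
                    (1.00, 0.45), (1.16, 0.19)),
}
SETPOINTS_17MM: dict[str, ArmSpec] = {
    "Control": ArmSpec((7.3, 1.3), (674.0, 82.0), (0.32, 0.31), (1.10, 0.20),
                       (0.32, 0.27), (1.10, 0.17)),
    "CEMF": ArmSpec((12.0, 2.3), (762.0, 56.0), (0.85, 0.37), (1.25, 0.21),
                    (0.90, 0.33), (1.29, 0.21)),
}


@dataclass(frozen=True)
class StudyDesign:
    """Two-arm study layout: arm set-points, group size, seed."""

    n_per_arm: int = 6
    arm_specs: dict = field(default_factory=lambda: dict(SETPOINTS_17MM))
    seed: int = 0
    model: str = "17mm"

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("need at least 2 subjects per arm")
        if len(self.arm_specs) != 2:
            raise ValueError("a two-arm design needs exactly 2 arm specs")


@dataclass(frozen=True)
class SubjectDraw:
    """One sampled animal: inputs for the image/biomech stages plus truth."""

    subject_id: str
    arm: str
    model: str
    callus_volume: float  # cm^3
    callus_density: float  # mg HA/cm^3
    rigidity_op: float  # Nm^2/deg (true operated-limb rigidity)
    rigidity_nonop: float  # Nm^2/deg
    vtr_op: float | None
    vtr_nonop: float | None
    seed: int  # per-subject stream for image/trace noise

    def callus_spec(self, **kwargs) -> CallusSpec:
        return CallusSpec(self.callus_volume, self.callus_density, **kwargs)


def _draw_positive(rng: np.random.Generator, mean: float, sd: float) -> tuple[float, int]:
    """Normal draw, redrawn until strictly positive (truncation counted)."""
    if sd == 0:
        return mean, 0
    redraws = 0
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v), redraws
        redraws += 1
    raise RuntimeError(f"could not draw a positive value from N({mean}, {sd})")


def sample_study(design: StudyDesign) -> list[SubjectDraw]:
    """Sample per-subject quantities for a two-arm study.

    Strictly positive quantities use truncated-normal redraws (count
    logged). Per-subject seeds are spawned from the design seed, so the
    subject list is reproducible and each subject's downstream image/trace
    noise stream is independent.
    """
    rng = np.random.default_rng(design.seed)
    child_seeds = np.random.SeedSequence(design.seed).generate_state(
        2 * design.n_per_arm
    ) % (2**31)
    subjects: list[SubjectDraw] = []
    total_redraws = 0
    idx = 0
    for arm, spec in design.arm_specs.items():
        for i in range(design.n_per_arm):
            vol, r1 = _draw_positive(rng, *spec.callus_volume)
            den, r2 = _draw_positive(rng, *spec.callus_density)
            rig_op, r3 = _draw_positive(rng, *spec.rigidity_op)
            rig_non, r4 = _draw_positive(rng, *spec.rigidity_nonop)
            total_redraws += r1 + r2 + r3 + r4
            vtr_op = vtr_non = None
            if spec.vtr_op is not None:
                vtr_op, r5 = _draw_positive(rng, *spec.vtr_op)
                total_redraws += r5
            if spec.vtr_nonop is not None:
                vtr_non, r6 = _draw_positive(rng, *spec.vtr_nonop)
                total_redraws += r6
            subjects.append(
                SubjectDraw(
                    subject_id=f"{arm.lower()}_{i + 1:02d}",
                    arm=arm,
                    model=design.model,
                    callus_volume=vol,
                    callus_density=den,
                    rigidity_op=rig_op,
                    rigidity_nonop=rig_non,
                    vtr_op=vtr_op,
                    vtr_nonop=vtr_non,
                    seed=int(child_seeds[idx]),
                )
            )
            idx += 1
    if total_redraws:
        logger.info("sample_study: %d truncated-normal redraws", total_redraws)
    return subjects


# ---------------------------------------------------------------------------
# Synthetic histology sections
# ---------------------------------------------------------------------------


def make_label_section(
    class_percentages: dict[str, float],
    shape: tuple[int, int] = (200, 200),
    background_fraction: float = 0.3,
    sector_split: tuple[float, float, float] | None = None,
    seed: int = 0,
):
    """Render a labeled histology section with exact tissue percentages.

    Non-background pixels are allocated to classes by largest-remainder
    rounding of ``class_percentages`` (which must sum to 100), then placed
    at shuffled positions. If ``sector_split`` is given, callus pixels
    (class name containing ``"new_bone"`` or ``"callus"``) are split into
    cis/endosteal/trans sector masks in those exact proportions.

    Returns ``(LabelSection, sector_masks | None)``.
    """
    from .histomorphometry import LabelSection

    if abs(sum(class_percentages.values()) - 100.0) > 1e-9:
        raise ValueError("class percentages must sum to 100")
    rng = np.random.default_rng(seed)
    n_total = shape[0] * shape[1]
    n_bg = int(round(background_fraction * n_total))
    n_fg = n_total - n_bg
    names = list(class_percentages)
    quotas = np.array([class_percentages[k] * n_fg / 100.0 for k in names])
    counts = np.floor(quotas).astype(int)
    rem = n_fg - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:rem]] += 1

    labels = np.zeros(n_total, dtype=np.int32)  # 0 = background
    pos = rng.permutation(n_total)[n_fg:]  # background positions
    fg_pos = np.setdiff1d(np.arange(n_total), pos, assume_unique=False)
    rng.shuffle(fg_pos)
    legend = {0: "background"}
    start = 0
    class_positions = {}
    for code, (name, cnt) in enumerate(zip(names, counts), start=1):
        sel = fg_pos[start : start + cnt]
        labels[sel] = code
        legend[code] = name
        class_positions[name] = sel
        start += cnt
    section = LabelSection(labels.reshape(shape), legend, background_label=0)

    sectors = None
    if sector_split is not None:
        callus_names = [n for n in names if "new_bone" in n or "callus" in n]
        if not callus_names:
            raise ValueError("sector split requested but no callus class present")
        cal_pos = np.concatenate([class_positions[n] for n in callus_names])
        frac = np.asarray(sector_split, dtype=float)
        frac = frac / frac.sum()
        n_cal = cal_pos.size
        cuts = np.floor(np.cumsum(frac) * n_cal + 0.5).astype(int)
        sectors = {}
        prev = 0
        for name, cut in zip(("cis", "endosteal", "trans"), cuts):
            m = np.zeros(n_total, dtype=bool)
            m[cal_pos[prev:cut]] = True
            sectors[name] = m.reshape(shape)
            prev = cut
        # sectors must partition the analysis region: spread non-callus
        # foreground pixels across the sectors too (they carry 0 callus)
        non_cal = np.setdiff1d(fg_pos, cal_pos)
        thirds = np.array_split(non_cal, 3)
        for m, extra in zip(sectors.values(), thirds):
            m.reshape(-1)[extra] = True
    return section, sectors


def save_scan_nifti(scan: SyntheticScan, path, masks_path=None) -> None:
    """Write the HU volume (and optionally truth masks) as NIfTI."""
    import nibabel as nib

    aff = np.diag([scan.spacing, scan.spacing, scan.spacing, 1.0])
    nib.save(nib.Nifti1Image(scan.hu.astype(np.float32), aff), str(path))
    if masks_path is not None:
        lab = np.zeros(scan.hu.shape, dtype=np.uint8)
        lab[scan.truth_old_bone_mask] = 1
        lab[scan.truth_callus_mask] = 2
        nib.save(nib.Nifti1Image(lab, aff), str(masks_path))


def save_study_manifest(design: StudyDesign, subjects: list[SubjectDraw], path) -> None:
    payload = {
        "design": {
            "n_per_arm": design.n_per_arm,
            "seed": design.seed,
            "model": design.model,
            "arm_specs": {
                arm: {k: list(v) for k, v in spec.__dict__.items() if v is not None}
                for arm, spec in design.arm_specs.items()
            },
        },
        "subjects": [s.__dict__ | {} for s in subjects],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
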