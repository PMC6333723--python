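"""Digital two-phase brain phantom.

Generates paired early-phase (perfusion-weighted) and late-phase
(amyloid-weighted) volumes on a labelled schematic anatomy: a cerebral
ellipsoid with a cortical grey-matter shell carved by sinusoidal sulci,
a white-matter core, ventricular and sulcal CSF, and cerebellum plus
pons/peduncle structures inferiorly. The cortical shell is partitioned
into the eight regions a visual amyloid read inspects (frontal, lateral
temporal, anterior/posterior cingulate, precuneus, striatum,
temporoparietal, insula) by angular sector.

Intensity calibration (all arbitrary units, ratios are what matter):

* early phase — GM 1.0, WM 0.35, pons 0.8, CSF 0.05: grey matter
  dominates because the early signal tracks perfusion;
* late phase — WM carries the nonspecific uptake (``late_wm_level``),
  and each cortical region r sits at ``(0.40 + 0.70 * burden[r]) * WM``.
  A burden of 0 gives a clearly negative GM/WM ratio of 0.40 and the
  ratio crosses 1.0 (cortex as hot as white matter, the visual
  positivity boundary) at burden 6/7 ~= 0.857, so burden sweeps cross
  the decision boundary inside [0, 1].

Everything is deterministic given the spec, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import Volume

# Label integers. 0 is background.
BACKGROUND = 0
CSF = 1
WM = 2
FRONTAL = 3
LATERAL_TEMPORAL = 4
ANTERIOR_CINGULATE = 5
POSTERIOR_CINGULATE = 6
PRECUNEUS = 7
STRIATUM = 8
TEMPOROPARIETAL = 9
INSULA = 10
CEREBELLAR_GM = 11
PONS = 12

LEGEND: dict[int, str] = {
    BACKGROUND: "background",
    CSF: "CSF",
    WM: "WM",
    FRONTAL: "frontal GM",
    LATERAL_TEMPORAL: "lateral temporal GM",
    ANTERIOR_CINGULATE: "anterior cingulate GM",
    POSTERIOR_CINGULATE: "posterior cingulate GM",
    PRECUNEUS: "precuneus GM",
    STRIATUM: "striatum",
    TEMPOROPARIETAL: "temporoparietal GM",
    INSULA: "insula GM",
    CEREBELLAR_GM: "cerebellar GM",
    PONS: "pons+peduncles",
}

#: Cortical labels that receive an amyloid burden, in fixed sector order.
CORTICAL_REGIONS: tuple[int, ...] = (
    FRONTAL,
    LATERAL_TEMPORAL,
    ANTERIOR_CINGULATE,
    POSTERIOR_CINGULATE,
    PRECUNEUS,
    STRIATUM,
    TEMPOROPARIETAL,
    INSULA,
)

# Noiseless early-phase intensity per tissue class.
EARLY_LEVELS = {"gm": 1.0, "wm": 0.35, "pons": 0.8, "csf": 0.05, "bg": 0.0}


class DegenerateAnatomyError(ValueError):
    """The requested spec collapses a structure below the voxel grid."""


@dataclass
class PhantomSpec:
    """Parameters of one simulated patient.

    ``amyloid_burden`` maps cortical label -> fraction in [0, 1]; missing
    regions default to 0 (no amyloid). ``atrophy`` thins the cortical
    ribbon and dilates the ventricles. ``noise_scale`` is the expected
    Poisson count per unit intensity (0 = noiseless); ``motion_sigma`` is
    the width in mm of the intra-frame motion blur.
    """

    shape: tuple[int, int, int] = (96, 96, 80)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    atrophy: float = 0.0
    gm_thickness: float = 4.0
    amyloid_burden: dict[int, float] = field(default_factory=dict)
    early_wm_level: float = 0.35
    late_wm_level: float = 1.0
    noise_scale: float = 200.0
    motion_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.atrophy <= 1:
            raise ValueError("atrophy must be in [0, 1]")
        for region, b in self.amyloid_burden.items():
            if not 0 <= b <= 1:
                raise ValueError(f"amyloid burden for region {region} not in [0, 1]: {b}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.motion_sigma < 0:
            raise ValueError("motion_sigma must be >= 0")

    def affine(self) -> np.ndarray:
        """RAS+ affine placing the grid centre at the world origin."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)
        return A


@dataclass
class RegionLabelMap:
    """Integer-labelled phantom anatomy aligned with its volumes."""

    labels: np.ndarray
    affine: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(LEGEND))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def region_counts(self) -> dict[int, int]:
        return {lab: int((self.labels == lab).sum()) for lab in self.legend}


def _world_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World (mm) coordinates of every voxel centre, origin at grid centre."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.shape, spec.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def angular_sector(x: np.ndarray, y: np.ndarray, n_sectors: int = 8) -> np.ndarray:
    """Azimuthal sector index in [0, n_sectors) about the +z axis.

    Shared between the phantom region partition and the label-free
    regional split of the auto-rater, so the two paths agree by
    construction.
    """
    az = np.mod(np.arctan2(y, x), 2 * np.pi)
    sector = np.floor(az / (2 * np.pi / n_sectors)).astype(int)
    return np.clip(sector, 0, n_sectors - 1)


# Geometry constants (mm, world coordinates with origin at grid centre).
_CEREBRUM_CENTER = np.array([0.0, 5.0, 12.0])
_CEREBRUM_AXES = np.array([60.0, 75.0, 50.0])
_VENTRICLE_AXES = np.array([10.0, 22.0, 9.0])
_CEREBELLUM_CENTER = np.array([0.0, -42.0, -52.0])
_CEREBELLUM_AXES = np.array([38.0, 28.0, 22.0])
_PONS_CENTER = np.array([0.0, 4.0, -52.0])
_PONS_AXES = np.array([11.0, 11.0, 16.0])
_SULCAL_AMPLITUDE = 0.035  # fractional radial perturbation
_SULCAL_FREQ_AZ = 7
_SULCAL_FREQ_EL = 4


def build_label_map(spec: PhantomSpec) -> RegionLabelMap:
    """Construct the schematic anatomy for one phantom.

    Raises
    ------
    DegenerateAnatomyError
        If atrophy thins the cortical ribbon below one voxel.
    """
    thickness = spec.gm_thickness * (1.0 - spec.atrophy)
    if thickness < min(spec.spacing):
        raise DegenerateAnatomyError(
            f"cortical ribbon {thickness:.2f} mm is thinner than a voxel "
            f"({min(spec.spacing):.2f} mm); reduce atrophy or refine the grid"
        )

    X, Y, Z = _world_grid(spec)
    labels = np.zeros(spec.shape, dtype=np.int16)

    # --- cerebrum ---------------------------------------------------------
    dx = X - _CEREBRUM_CENTER[0]
    dy = Y - _CEREBRUM_CENTER[1]
    dz = Z - _CEREBRUM_CENTER[2]
    rho = np.sqrt(
        (dx / _CEREBRUM_AXES[0]) ** 2
        + (dy / _CEREBRUM_AXES[1]) ** 2
        + (dz / _CEREBRUM_AXES[2]) ** 2
    )
    # Sinusoidal sulcal indentation of the outer surface: the effective
    # radius dips periodically, carving CSF-filled sulci into the shell.
    az = np.arctan2(dy, dx)
    el = np.arctan2(dz, np.hypot(dx, dy))
    rho_eff = rho * (
        1.0
        + _SULCAL_AMPLITUDE * np.sin(_SULCAL_FREQ_AZ * az) * np.cos(_SULCAL_FREQ_EL * el)
    )
    # Radial distance (mm) from voxel to the perturbed outer surface.
    with np.errstate(divide="ignore", invalid="ignore"):
        r_dir = np.where(rho_eff > 1e-9, np.sqrt(dx**2 + dy**2 + dz**2) / np.maximum(rho_eff, 1e-9), np.inf)
    depth = (1.0 - rho_eff) * r_dir  # >0 inside, mm below the cortical surface

    inside = rho_eff <= 1.0
    gm_shell = inside & (depth <= thickness)
    wm_core = inside & (depth > thickness)
    labels[wm_core] = WM
    # Sulcal CSF: inside the unperturbed ellipsoid but outside the wavy surface.
    sulcal = (rho <= 1.0) & ~inside
    labels[sulcal] = CSF

    sectors = angular_sector(dx, dy)
    for idx, region in enumerate(CORTICAL_REGIONS):
        labels[gm_shell & (sectors == idx)] = region

    # --- ventricles (dilate with atrophy) ---------------------------------
    vent_axes = _VENTRICLE_AXES * (1.0 + 1.5 * spec.atrophy)
    rho_v = np.sqrt(
        (dx / vent_axes[0]) ** 2
        + (dy / vent_axes[1]) ** 2
        + (dz / vent_axes[2]) ** 2
    )
    labels[(rho_v <= 1.0) & inside] = CSF

    # --- posterior fossa --------------------------------------------------
    rho_c = np.sqrt(
        ((X - _CEREBELLUM_CENTER[0]) / _CEREBELLUM_AXES[0]) ** 2
        + ((Y - _CEREBELLUM_CENTER[1]) / _CEREBELLUM_AXES[1]) ** 2
        + ((Z - _CEREBELLUM_CENTER[2]) / _CEREBELLUM_AXES[2]) ** 2
    )
    labels[rho_c <= 1.0] = CEREBELLAR_GM
    rho_p = np.sqrt(
        ((X - _PONS_CENTER[0]) / _PONS_AXES[0]) ** 2
        + ((Y - _PONS_CENTER[1]) / _PONS_AXES[1]) ** 2
        + ((Z - _PONS_CENTER[2]) / _PONS_AXES[2]) ** 2
    )
    labels[rho_p <= 1.0] = PONS

    lmap = RegionLabelMap(labels, spec.affine())
    empty = [name for lab, name in LEGEND.items() if not np.any(labels == lab) and lab != BACKGROUND]
    if empty:
        raise DegenerateAnatomyError(f"empty anatomy regions for this spec: {empty}")
    return lmap


def render_early(labels: RegionLabelMap, spec: PhantomSpec) -> Volume:
    """Noiseless early-phase (perfusion) volume: GM-dominant signal."""
    lab = labels.labels
    data = np.zeros(lab.shape, dtype=float)
    data[lab == CSF] = EARLY_LEVELS["csf"]
    data[lab == WM] = spec.early_wm_level
    for region in CORTICAL_REGIONS:
        data[lab == region] = EARLY_LEVELS["gm"]
    data[lab == CEREBELLAR_GM] = EARLY_LEVELS["gm"]
    data[lab == PONS] = EARLY_LEVELS["pons"]
    return Volume(data, labels.affine, phase="early")


def render_late(labels: RegionLabelMap, spec: PhantomSpec) -> Volume:
    """Noiseless late-phase (amyloid) volume.

    White matter carries the nonspecific uptake; cortical region r sits at
    ``(0.40 + 0.70 * burden[r]) * late_wm_level``. Cerebellar cortex stays
    amyloid-spared at 0.40, the pons (display reference) at 0.55.
    """
    lab = labels.labels
    wm = spec.late_wm_level
    data = np.zeros(lab.shape, dtype=float)
    data[lab == CSF] = 0.05
    data[lab == WM] = wm
    for region in CORTICAL_REGIONS:
        burden = spec.amyloid_burden.get(region, 0.0)
        data[lab == region] = (0.40 + 0.70 * burden) * wm
    data[lab == CEREBELLAR_GM] = 0.40 * wm
    data[lab == PONS] = 0.55 * wm
    return Volume(data, labels.affine, phase="late")


def apply_noise(volume: Volume, noise_scale: float, seed: int) -> Volume:
    """Poisson count noise: voxel -> Poisson(scale * v) / scale.

    Emulates count-limited PET speckle; larger ``noise_scale`` means more
    counts and less relative noise. Zero-intensity voxels stay zero.
    """
    if noise_scale <= 0:
        raise ValueError(f"noise_scale must be > 0, got {noise_scale}")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(noise_scale * volume.data).astype(float) / noise_scale
    return volume.with_data(noisy)


def apply_motion(volume: Volume, sigma_mm: float, seed: int = 0) -> Volume:
    """Intra-frame motion blur: isotropic Gaussian of width sigma in mm.

    Head movement during a frame smears activity across tissue borders;
    on the late phase this pushes white-matter signal into the cortical
    ribbon and inflates GM/WM ratios (the false-positive mechanism).
    sigma 0 is the identity. The seed is accepted for interface symmetry
    with the stochastic operators; the blur itself is deterministic.
    """
    if sigma_mm < 0:
        raise ValueError(f"motion sigma must be >= 0, got {sigma_mm}")
    if sigma_mm == 0:
        return volume.copy()
    sigma_vox = sigma_mm / volume.spacing
    blurred = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode="constant")
    return volume.with_data(blurred)


def apply_rigid_misalignment(
    volume: Volume,
    rotation_deg: tuple[float, float, float],
    translation_mm: tuple[float, float, float],
) -> Volume:
    """Resample the volume under a rigid transform about the grid centre.

    Produces deliberately misaligned test inputs for the registration
    module. The transform convention matches
    :class:`gmedge.registration.RigidTransform`.
    """
    from .registration import RigidTransform, apply_transform

    return apply_transform(volume, RigidTransform(rotation_deg, translation_mm))


def generate_pair(spec: PhantomSpec) -> tuple[Volume, Volume, RegionLabelMap]:
    """Full generator: labelled anatomy plus noisy early/late volumes.

    Noise (if ``noise_scale`` > 0) and motion blur (if ``motion_sigma`` > 0,
    applied to the late phase only, mimicking late-frame head movement)
    are derived deterministically from ``spec.seed``.
    """
    labels = build_label_map(spec)
    early = render_early(labels, spec)
    late = render_late(labels, spec)
    if spec.motion_sigma > 0:
        late = apply_motion(late, spec.motion_sigma)
    if spec.noise_scale > 0:
        early = apply_noise(early, spec.noise_scale, seed=spec.seed * 2 + 1)
        late = apply_noise(late, spec.noise_scale, seed=spec.seed * 2 + 2)
    return early, late, labels
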