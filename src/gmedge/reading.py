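"""The GM-EDGE reading method and an automated regional rater.

The visual problem in amyloid PET is that the tracer is retained
nonspecifically in white matter, so a positive scan (cortical uptake) and
a negative one differ mainly in *where* the signal sits relative to the
grey/white boundary — hard to judge when atrophy thins the cortical
ribbon. The method here exploits the early perfusion frame, whose signal
is grey-matter dominant: thresholding it yields the grey-matter
compartment, whose one-voxel boundary shell ("edges" isocontour) is
alpha-blended onto the late amyloid frame, display-windowed so that the
pons/cerebellar-peduncle reference mean sits at 90% of the range.

The automated rater mirrors the product-label visual rule: a cortical
region is clearly abnormal when its late-phase level reaches the adjacent
white-matter level (GM/WM ratio >= 1, inclusive), and one clearly
abnormal region makes the scan positive. Medians summarize regional
levels for robustness to spillover voxels. The five-point score and
confidence mappings are explicit operational conventions of this
package, not human-reader scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import phantom as ph
from .volumes import DegenerateInputError, Mask, Volume, robust_max

#: Default edge threshold as a fraction of the robust maximum: lands
#: between white-matter (~0.35 of GM) and grey-matter perfusion levels.
EDGE_THRESHOLD_FRACTION = 0.45

#: Regional grade cutpoints on the GM/WM ratio.
CUT_CLEAR = 1.00
CUT_BORDER = 0.90


class AlignmentError(ValueError):
    pass


@dataclass
class DisplayWindow:
    """Linear display window [lower, upper] in activity units."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower < 0 or self.upper <= self.lower:
            raise ValueError(f"invalid window [{self.lower}, {self.upper}]")


@dataclass
class ColourTable:
    """Piecewise-linear colour lookup table.

    Stops map normalized position in [0, 1] to an RGB triple; positions
    are strictly increasing from 0 to 1. The shipped tables are open
    approximations of common PET display scales.
    """

    name: str
    stops: list[tuple[float, tuple[float, float, float]]]

    def __post_init__(self) -> None:
        pos = [p for p, _ in self.stops]
        if len(pos) < 2 or pos[0] != 0.0 or pos[-1] != 1.0 or any(
            b <= a for a, b in zip(pos, pos[1:])
        ):
            raise ValueError("colour stops must strictly increase from 0 to 1")


COLOUR_TABLES: dict[str, ColourTable] = {
    "spectrum": ColourTable(
        "spectrum",
        [
            (0.0, (0.0, 0.0, 0.0)),
            (1 / 6, (0.0, 0.0, 1.0)),
            (2 / 6, (0.0, 1.0, 1.0)),
            (3 / 6, (0.0, 1.0, 0.0)),
            (4 / 6, (1.0, 1.0, 0.0)),
            (5 / 6, (1.0, 0.0, 0.0)),
            (1.0, (1.0, 1.0, 1.0)),
        ],
    ),
    "edges": ColourTable(
        "edges",
        [(0.0, (0.0, 0.0, 0.0)), (1.0, (0.1, 1.0, 0.1))],
    ),
    "warm_metal": ColourTable(
        "warm_metal",
        [
            (0.0, (0.0, 0.0, 0.0)),
            (0.35, (0.8, 0.0, 0.0)),
            (0.6, (1.0, 0.5, 0.0)),
            (0.85, (1.0, 1.0, 0.0)),
            (1.0, (1.0, 1.0, 1.0)),
        ],
    ),
}


@dataclass
class EdgeMap:
    """One-voxel boundary shell of the thresholded grey-matter region."""

    data: np.ndarray
    threshold_used: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def empty(self) -> bool:
        return not bool(self.data.any())


@dataclass
class RegionAssessment:
    region: int
    region_name: str
    gm_level: float
    wm_level: float
    ratio: float
    grade: str  # normal | borderline | clearly_abnormal


@dataclass
class ScanReport:
    method: str  # std | gmedge
    score5: int
    binary: str  # negative | positive
    confidence5: int
    assessments: list[RegionAssessment]


def window_from_reference(late: Volume, reference: Mask, fraction: float = 0.90) -> DisplayWindow:
    """Display window with the reference-region mean at ``fraction`` of range.

    The pons and cerebellar peduncles are amyloid-spared, so anchoring the
    window upper bound at mean(reference)/fraction standardizes the
    late-phase display across patients: lower = 0, upper = mean/0.9 puts
    the reference mean at 90% of the range.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if reference.count() == 0:
        raise DegenerateInputError("reference mask is empty")
    mean_ref = float(late.data[reference.data].mean())
    if mean_ref <= 0:
        raise DegenerateInputError("reference region has nonpositive mean intensity")
    return DisplayWindow(lower=0.0, upper=mean_ref / fraction)


def auto_edge_threshold(early: Volume, fraction: float = EDGE_THRESHOLD_FRACTION) -> float:
    """Automatic isocontour threshold for the grey-matter ribbon.

    ``fraction`` of the robust maximum (99th percentile of positive
    voxels): scales with the image (homogeneous of degree 1) and sits
    between white-matter and grey-matter perfusion levels, so the
    supra-threshold region is the grey-matter compartment. The manual
    step of a human read becomes an explicit, overridable parameter.
    """
    if float(early.data.max()) == float(early.data.min()):
        raise DegenerateInputError("early volume is constant; no threshold exists")
    return fraction * robust_max(early, 0.99)


def extract_edges(early: Volume, threshold: float, min_component_fraction: float = 0.01) -> EdgeMap:
    """Binary boundary ribbon of the supra-threshold early-phase region.

    Binarizes at ``>= threshold``, drops speckle components smaller than
    ``min_component_fraction`` of the largest (26-connectivity), and keeps
    the retained mask minus its 6-neighbour erosion: a one-voxel shell
    marking both the outer cortical surface and the inner GM/WM
    interface. An empty result is legal (e.g. threshold above the
    maximum) and returned as an empty EdgeMap.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    mask = early.data >= threshold
    if not mask.any():
        return EdgeMap(mask, threshold, early.affine.copy())
    labelled, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labelled, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component_fraction * sizes.max()) + 1
        mask = np.isin(labelled, keep)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return EdgeMap(mask & ~eroded, threshold, early.affine.copy())


def apply_colour(volume: Volume, window: DisplayWindow, table: ColourTable) -> np.ndarray:
    """Map intensities through a window and colour table to an RGB grid.

    Returns an array of shape ``volume.shape + (3,)`` with channels in
    [0, 1]; values outside the window clamp to the end-stop colours.
    """
    norm = (volume.data - window.lower) / (window.upper - window.lower)
    norm = np.clip(norm, 0.0, 1.0)
    positions = np.array([p for p, _ in table.stops])
    colours = np.array([c for _, c in table.stops])
    rgb = np.empty(volume.shape + (3,))
    for ch in range(3):
        rgb[..., ch] = np.interp(norm, positions, colours[:, ch])
    return rgb


def blend_overlay(
    late_rgb: np.ndarray,
    edges: EdgeMap,
    edge_colour: tuple[float, float, float] = (0.1, 1.0, 0.1),
    alpha: float = 0.5,
) -> np.ndarray:
    """Alpha-blend the edge ribbon onto a rendered late-phase image.

    On edge voxels: ``(1 - alpha) * late + alpha * edge_colour``;
    elsewhere the late image passes through unchanged.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if late_rgb.shape[:3] != edges.data.shape:
        raise AlignmentError(
            f"late image shape {late_rgb.shape[:3]} != edge map shape {edges.data.shape}"
        )
    out = late_rgb.copy()
    out[edges.data] = (1 - alpha) * late_rgb[edges.data] + alpha * np.asarray(edge_colour)
    return out


def assess_region(
    late: Volume,
    region_gm: Mask,
    adjacent_wm: Mask,
    region: int = 0,
    region_name: str = "",
    cut_clear: float = CUT_CLEAR,
    cut_border: float = CUT_BORDER,
) -> RegionAssessment:
    """Grade one cortical region by its GM/WM late-phase median ratio.

    ``clearly_abnormal`` at ratio >= cut_clear (inclusive: cortical signal
    "the same or higher" than white matter counts as abnormal),
    ``borderline`` in [cut_border, cut_clear), ``normal`` below.
    """
    if region_gm.count() == 0 or adjacent_wm.count() == 0:
        raise DegenerateInputError("empty region or white-matter mask")
    gm_level = float(np.median(late.data[region_gm.data]))
    wm_level = float(np.median(late.data[adjacent_wm.data]))
    if wm_level <= 0:
        raise DegenerateInputError("white-matter reference median is nonpositive")
    ratio = gm_level / wm_level
    if ratio >= cut_clear:
        grade = "clearly_abnormal"
    elif ratio >= cut_border:
        grade = "borderline"
    else:
        grade = "normal"
    return RegionAssessment(region, region_name, gm_level, wm_level, ratio, grade)


def rate_scan(
    assessments: list[RegionAssessment],
    method: str = "gmedge",
    cut_clear: float = CUT_CLEAR,
    cut_border: float = CUT_BORDER,
) -> ScanReport:
    """Scan-level call from regional assessments.

    Positive iff at least one region is clearly abnormal (an ambiguous
    best grade resolves negative: positivity requires a *clearly*
    abnormal region). The five-point score follows the maximal ratio:
    5 at >= 1.10, 4 for clearly abnormal below that, 3 for borderline,
    2 for a best ratio in [0.70, cut_border), 1 below. Confidence grows
    with distance from the decision boundary:
    ``1 + min(4, floor(|max_ratio - cut_clear| / 0.05))``.
    """
    if not assessments:
        raise ValueError("at least one regional assessment is required")
    max_ratio = max(a.ratio for a in assessments)
    any_clear = any(a.grade == "clearly_abnormal" for a in assessments)
    any_border = any(a.grade == "borderline" for a in assessments)
    if any_clear:
        score5 = 5 if max_ratio >= 1.10 else 4
        binary = "positive"
    elif any_border:
        score5 = 3
        binary = "negative"
    else:
        score5 = 2 if max_ratio >= 0.70 else 1
        binary = "negative"
    confidence5 = 1 + min(4, int(abs(max_ratio - cut_clear) / 0.05))
    return ScanReport(method, score5, binary, confidence5, list(assessments))


def derive_masks_from_edges(
    early: Volume,
    threshold: float,
    labels: ph.RegionLabelMap | None = None,
) -> tuple[dict[int, Mask], Mask]:
    """Regional grey-matter masks and an adjacent white-matter mask.

    A human reads the overlay visually; the automated rater needs voxel
    masks. With an anatomy label map, each cortical region is intersected
    with the supra-threshold early mask and white matter is the WM label
    eroded once. Without labels, the supra-threshold region itself serves
    as grey matter, white matter is the head interior minus the dilated
    grey-matter mask (eroded once), and the regional split reuses the
    same angular sectors as the phantom anatomy, taken about the
    grey-matter centroid.
    """
    gm_all = early.data >= threshold
    if not gm_all.any():
        raise DegenerateInputError("no voxels above the edge threshold")
    struct = ndimage.generate_binary_structure(3, 1)

    if labels is not None:
        region_masks = {}
        for region in ph.CORTICAL_REGIONS:
            m = labels.mask(region) & gm_all
            if m.any():
                region_masks[region] = Mask(m, early.affine.copy())
        wm = ndimage.binary_erosion(labels.mask(ph.WM), structure=struct, border_value=0)
        if not wm.any():
            raise DegenerateInputError("white-matter mask empty after erosion")
        return region_masks, Mask(wm, early.affine.copy())

    head = early.data > 0.05 * robust_max(early, 0.99)
    wm = head & ~ndimage.binary_dilation(gm_all, structure=struct)
    wm = ndimage.binary_erosion(wm, structure=struct, border_value=0)
    if not wm.any():
        raise DegenerateInputError("derived white-matter mask is empty")
    centroid = np.array(ndimage.center_of_mass(gm_all))
    idx = np.indices(early.shape, dtype=float)
    dx = (idx[0] - centroid[0]) * early.spacing[0]
    dy = (idx[1] - centroid[1]) * early.spacing[1]
    sectors = ph.angular_sector(dx, dy)
    region_masks = {}
    for i, region in enumerate(ph.CORTICAL_REGIONS):
        m = gm_all & (sectors == i)
        if m.any():
            region_masks[region] = Mask(m, early.affine.copy())
    return region_masks, Mask(wm, early.affine.copy())


def rate_volume(
    late: Volume,
    early: Volume,
    labels: ph.RegionLabelMap | None = None,
    method: str = "gmedge",
    threshold: float | None = None,
    cut_clear: float = CUT_CLEAR,
    cut_border: float = CUT_BORDER,
) -> ScanReport:
    """End-to-end automated read of one early/late pair."""
    thr = auto_edge_threshold(early) if threshold is None else threshold
    region_masks, wm = derive_masks_from_edges(early, thr, labels)
    assessments = [
        assess_region(
            late, m, wm, region=r, region_name=ph.LEGEND.get(r, str(r)),
            cut_clear=cut_clear, cut_border=cut_border,
        )
        for r, m in region_masks.items()
    ]
    return rate_scan(assessments, method=method, cut_clear=cut_clear, cut_border=cut_border)
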