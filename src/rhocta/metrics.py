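"""Per-image vessel metrics and the relative capillary capacity (RCC).

The metric quadruple per en-face image is: vessel density VD (segmented
vessel area as a percent of the image), length of the vascular network
LVN (skeleton centerline length per mm^2), number of branch points NBP
(skeleton junctions, a raw count per analyzed field), and the mean
vessel diameter VD/LVN in micrometers. A baseline/peak image pair
condenses into the RCC statistic

    RCC = (VD_peak/VD_base) * (LVN_peak/LVN_base) * (NBP_peak/NBP_base) - 1,

a percent-change summary of the perfusion reserve recruited by reactive
hyperemia.
"""

from __future__ import annotations

from dataclasses import dataclass

from .segmentation import SkeletonMap, VesselMask, skeleton_length_px


@dataclass(frozen=True)
class VesselMetrics:
    """The per-image metric quadruple plus the analyzed field area."""

    vd: float  # percent of image area
    lvn: float  # mm of centerline per mm^2
    nbp: int  # junction count per analyzed field
    diameter_um: float  # mean vessel diameter, VD/LVN in um
    field_area_mm2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vd <= 100.0:
            raise ValueError("vd must be a percentage in [0, 100]")
        if self.lvn < 0 or self.nbp < 0:
            raise ValueError("lvn and nbp must be non-negative")


@dataclass(frozen=True)
class RCCResult:
    """Paired baseline/peak metrics and their RCC."""

    baseline: VesselMetrics
    peak: VesselMetrics
    rcc: float  # dimensionless fraction; x100 for percent


def vessel_density(mask: VesselMask) -> float:
    """Vessel area as a percentage of the entire image."""
    if mask.mask.size == 0:
        raise ValueError("empty mask grid")
    return 100.0 * float(mask.mask.mean())


def vascular_network_length(
    skel: SkeletonMap,
    pixel_pitch_um: float | None = None,
    field_area_mm2: float | None = None,
    estimator: str = "calibrated",
) -> float:
    """Skeleton centerline length per image area, in mm per mm^2.

    ``estimator`` selects the digital length measure (see
    :func:`rhocta.segmentation.skeleton_length_px`): "pixel" is a plain
    pixel count x pitch; the default "calibrated" weights orthogonal and
    diagonal steps to be orientation-unbiased against Euclidean length.
    """
    pitch = skel.pixel_pitch_um if pixel_pitch_um is None else pixel_pitch_um
    if pitch <= 0:
        raise ValueError("pixel pitch must be positive")
    if field_area_mm2 is None:
        h, w = skel.skeleton.shape
        field_area_mm2 = h * w * (pitch / 1000.0) ** 2
    if field_area_mm2 <= 0:
        raise ValueError("field area must be positive")
    length_mm = skeleton_length_px(skel.skeleton, estimator=estimator) * pitch / 1000.0
    return length_mm / field_area_mm2


def mean_vessel_diameter(vd_percent: float, lvn_mm_per_mm2: float) -> float:
    """Mean vessel diameter VD/LVN in micrometers.

    Vessel area per unit image area (the VD fraction) divided by
    centerline length per unit area has units of length: 1000 x
    (vd/100) / lvn with lvn in mm/mm^2 yields micrometers.
    """
    if lvn_mm_per_mm2 <= 0:
        raise ValueError("mean vessel diameter is undefined for lvn <= 0")
    return 1000.0 * (vd_percent / 100.0) / lvn_mm_per_mm2


def image_metrics(
    mask: VesselMask, skel: SkeletonMap, estimator: str = "calibrated"
) -> VesselMetrics:
    """Assemble the full metric quadruple for one segmented image."""
    vd = vessel_density(mask)
    lvn = vascular_network_length(skel, estimator=estimator)
    nbp = len(skel.branch_points)
    diameter = mean_vessel_diameter(vd, lvn) if lvn > 0 else float("nan")
    return VesselMetrics(
        vd=vd,
        lvn=lvn,
        nbp=nbp,
        diameter_um=diameter,
        field_area_mm2=mask.field_area_mm2,
    )


def compute_rcc(baseline: VesselMetrics, peak: VesselMetrics) -> RCCResult:
    """RCC = product of the three peak/baseline metric ratios, minus 1.

    Every baseline component must be positive; a zero component is
    reported by name so a failed segmentation is diagnosable.
    """
    for name, value in (("vd", baseline.vd), ("lvn", baseline.lvn), ("nbp", baseline.nbp)):
        if value <= 0:
            raise ValueError(f"baseline {name} must be > 0 to form the RCC ratio")
    rcc = (
        (peak.vd / baseline.vd)
        * (peak.lvn / baseline.lvn)
        * (peak.nbp / baseline.nbp)
        - 1.0
    )
    return RCCResult(baseline=baseline, peak=peak, rcc=rcc)
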