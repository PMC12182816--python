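"""Flow quantification: net flow, regurgitation grading, accuracy criteria.

Through-plane flow through a vessel cross-section is the velocity integral
over the lumen contour.  With pixel area ``a`` (cm^2) and velocity in cm/s
the instantaneous flow rate is already in ml/s; integrating over the cycle
with the uniform retrospective-gating phase duration dt = RR / N gives
volumes in ml per beat.

Forward and backward volumes are split per pixel and per phase (a pixel
moving retrograde during systole counts as backward even if the bulk flow is
antegrade), matching the behaviour of common clinical analysis packages.
Positive velocity is antegrade by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import AlgoParams, PCSeries, PlaneGeometry, StructuralError

__all__ = [
    "Vessel",
    "RegurgGrade",
    "VesselContour",
    "FlowResult",
    "compute_flow",
    "grade_regurgitation",
    "accuracy_flag",
    "phantom_qc",
    "judge_classification",
]


class Vessel(str, Enum):
    AAO = "AAo"  # ascending aorta / aortic valve plane
    PA = "PA"    # pulmonary artery


class RegurgGrade(str, Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


# Severity boundaries (% regurgitation fraction).  Shared edges belong to the
# interval they open: 5 -> mild, 20 -> moderate; the severe cut is strict
# (">33%" AAo, ">40%" PA), so the boundary value itself grades moderate.
_SEVERE_CUT = {Vessel.AAO: 33.0, Vessel.PA: 40.0}


@dataclass
class VesselContour:
    """Lumen mask, shared across phases and across correction variants."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise StructuralError("vessel contour is empty")

    @classmethod
    def from_circle(cls, geometry: PlaneGeometry, center_px: tuple[float, float],
                    radius_mm: float) -> "VesselContour":
        sr, sc = geometry.pixel_spacing
        ii, jj = np.meshgrid(np.arange(geometry.rows), np.arange(geometry.cols),
                             indexing="ij")
        d = np.hypot((ii - center_px[0]) * sr, (jj - center_px[1]) * sc)
        return cls(mask=d <= radius_mm)


@dataclass
class FlowResult:
    per_phase_rate: np.ndarray       # ml/s
    forward_volume: float            # ml/beat
    backward_volume: float           # ml/beat
    net_volume: float                # ml/beat
    regurg_fraction: float           # %, NaN when undefined
    grade: RegurgGrade | None
    vessel: Vessel
    diagnostics: dict = field(default_factory=dict)


def compute_flow(series: PCSeries, contour: VesselContour,
                 vessel: Vessel = Vessel.AAO,
                 per_pixel_split: bool = True) -> FlowResult:
    """Per-phase flow curve and beat volumes through the contour.

    ``per_pixel_split=False`` switches the forward/backward decomposition to
    the per-phase aggregate rate (a phase is wholly forward or backward).
    """
    if contour.mask.shape != series.geometry.shape:
        raise StructuralError("contour shape does not match series")
    area = series.geometry.pixel_area_cm2
    dt = series.rr_duration / 1000.0 / series.n_phases  # s
    v = series.velocity[:, contour.mask]  # (phases, pixels) cm/s
    rate = v.sum(axis=1) * area  # ml/s per phase

    if per_pixel_split:
        forward = float(np.clip(v, 0.0, None).sum() * area * dt)
        backward = float((-np.clip(v, None, 0.0)).sum() * area * dt)
    else:
        vol = rate * dt
        forward = float(np.clip(vol, 0.0, None).sum())
        backward = float((-np.clip(vol, None, 0.0)).sum())
    net = forward - backward

    diagnostics: dict = {}
    if forward > 0:
        fraction = backward / forward * 100.0
        grade = grade_regurgitation(fraction, vessel)
    elif backward == 0:
        fraction, grade = 0.0, RegurgGrade.NONE
    else:
        fraction, grade = float("nan"), None
        diagnostics["regurg_undefined"] = "backward flow with zero forward flow"

    return FlowResult(
        per_phase_rate=rate,
        forward_volume=forward,
        backward_volume=backward,
        net_volume=net,
        regurg_fraction=fraction,
        grade=grade,
        vessel=vessel,
        diagnostics=diagnostics,
    )


def grade_regurgitation(fraction: float, vessel: Vessel) -> RegurgGrade:
    """Severity grade of a regurgitation fraction (%).

    none < 5, mild 5-20, moderate 20-33 (AAo) / 20-40 (PA), severe beyond.
    """
    if fraction < 0:
        raise ValueError("regurgitation fraction cannot be negative")
    vessel = Vessel(vessel)
    if fraction < 5.0:
        return RegurgGrade.NONE
    if fraction < 20.0:
        return RegurgGrade.MILD
    if fraction <= _SEVERE_CUT[vessel]:
        return RegurgGrade.MODERATE
    return RegurgGrade.SEVERE


def accuracy_flag(net: float, net_reference: float,
                  params: AlgoParams | None = None) -> bool:
    """Clinical-accuracy criterion: |relative net-flow error| <= threshold."""
    params = params or AlgoParams()
    if net_reference == 0:
        raise ValueError("accuracy undefined for zero reference net flow")
    return abs(net - net_reference) / abs(net_reference) <= params.accuracy_threshold


def phantom_qc(series: PCSeries, phantom: PCSeries, roi: np.ndarray,
               params: AlgoParams | None = None) -> bool:
    """Static-phantom usability check (Hofman criterion).

    The phantom offset can drift from the in-vivo offset (coil load,
    temperature, scanner drift); the phantom is usable only when the static-
    tissue ROI temporal-mean velocities of the two acquisitions agree within
    the configured tolerance.
    """
    params = params or AlgoParams()
    if phantom.geometry.shape != series.geometry.shape:
        raise StructuralError("phantom geometry mismatch")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise StructuralError("empty QC ROI")
    m_vivo = float(series.velocity.mean(axis=0)[roi].mean())
    m_phantom = float(phantom.velocity.mean(axis=0)[roi].mean())
    return abs(m_vivo - m_phantom) <= params.phantom_qc_threshold


def judge_classification(label, net_npccor: float, net_uncorrected: float,
                         net_phantom: float,
                         params: AlgoParams | None = None,
                         literal_use_uncorrected: bool = False) -> bool:
    """Was the automatic triage decision successful?

    * use-npccor: success when the corrected net flow is accurate against the
      phantom reference.
    * use-uncorrected: success when the *selected* (uncorrected) net flow is
      accurate (``literal_use_uncorrected=True`` instead judges the corrected
      series for this class as well).
    * perform-rescan: success when *neither* corrected nor uncorrected net
      flow is accurate -- i.e. a rescan really was warranted.
    """
    from .failure import TriageLabel

    params = params or AlgoParams()
    label = TriageLabel(label)
    acc_n = accuracy_flag(net_npccor, net_phantom, params)
    acc_u = accuracy_flag(net_uncorrected, net_phantom, params)
    if label is TriageLabel.USE_NPCCOR:
        return acc_n
    if label is TriageLabel.USE_UNCORRECTED:
        return acc_n if literal_use_uncorrected else acc_u
    return (not acc_n) and (not acc_u)
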