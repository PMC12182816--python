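"""End-to-end correction pipeline: masks -> fit -> guard -> failure modes.

``run_npccor`` wires the stages together in acquisition order and returns
everything downstream consumers need: the masks, the fit, the (possibly
unchanged) corrected series and the triage decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .background import (
    ConcomitantModel,
    FitResult,
    apply_correction,
    fit_surface,
    overfit_guard,
)
from .core import AlgoParams, PCSeries, plane_coordinates
from .failure import (
    ClassificationResult,
    FailureDecisionTree,
    TriageLabel,
    classify,
    failure_mode_1,
    failure_mode_2,
    failure_mode_3,
    fm2_features,
    fm3_centered_static_roi,
)
from .static_tissue import StaticMasks, build_static_masks

__all__ = ["PipelineResult", "run_npccor"]


@dataclass
class PipelineResult:
    series: PCSeries
    corrected: PCSeries
    masks: StaticMasks
    fit: FitResult | None
    applied: bool
    classification: ClassificationResult

    @property
    def label(self) -> TriageLabel:
        return self.classification.label

    def selected_series(self) -> PCSeries:
        """The series the triage decision designates for analysis.

        perform-rescan has no usable series; the uncorrected one is returned
        as the conservative fallback (callers should normally rescan).
        """
        if self.label is TriageLabel.USE_NPCCOR:
            return self.corrected
        return self.series


def run_npccor(series: PCSeries, params: AlgoParams | None = None,
               model: ConcomitantModel | None = None,
               tree: FailureDecisionTree | None = None) -> PipelineResult:
    """Run the full non-linear correction and triage pipeline on one series."""
    params = params or AlgoParams()
    model = model or ConcomitantModel()
    coords = plane_coordinates(series.geometry)

    masks = build_static_masks(series, params, model)

    fit: FitResult | None = None
    applied = False
    corrected = series
    fit_failed = False
    if masks.n_static >= 6:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_surface(masks, coords, model)
        applied = overfit_guard(fit, series.geometry, params)
        corrected = apply_correction(series, fit, apply=applied)
    else:
        fit_failed = True

    fm1 = failure_mode_1(masks, series.geometry, params)
    if masks.n_static > 0:
        features = fm2_features(series.velocity.mean(axis=0), masks.union_mask)
        fm2 = failure_mode_2(features, tree, params)
        roi_radius, roi = fm3_centered_static_roi(masks.union_mask,
                                                  series.geometry, params)
        fm3 = failure_mode_3(series, corrected, masks, roi, params)
    else:
        features = None
        fm2 = True
        roi_radius = None
        fm3 = True

    label = classify(fm1, fm2, fm3)
    classification = ClassificationResult(
        fm1=fm1, fm2=fm2, fm3=fm3, label=label, features=features,
        fm3_roi_radius=roi_radius,
        diagnostics={
            "n_static": masks.n_static,
            "guard_applied_correction": applied,
            "fit_skipped": fit_failed,
        },
    )
    return PipelineResult(series=series, corrected=corrected, masks=masks,
                          fit=fit, applied=applied,
                          classification=classification)
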