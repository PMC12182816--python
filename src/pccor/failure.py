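"""Failure-mode evaluation and three-class triage of corrected PC datasets.

Image-based background correction fails in recognisable ways; three checks
run automatically after fitting:

* **Failure mode 1 -- insufficient static tissue.**  The union of the global
  and quiescent masks covers less than 5% of the FoV: the fit has too little
  support to be trusted and too little to be *evaluated*, so a rescan is
  advised.
* **Failure mode 2 -- insufficient velocity-to-noise ratio.**  Noisy or
  structured static-tissue velocity (high VNR statistic, or band means that
  cannot be computed) makes the fitted surface unreliable.  The feature set
  is the static-tissue VNR plus slope/curvature summaries of the temporal-
  mean velocity image over three horizontal and three vertical sections.
* **Failure mode 3 -- uncorrected better than corrected.**  Near the vessel
  (a central ROI grown just large enough to contain a minimum fraction of
  static pixels), the mean static-tissue velocity did not decrease after
  correction; the uncorrected images should be used.

Triage: no failure -> use the corrected series; only FM3 -> use the
uncorrected series; FM1 and/or FM2 -> perform a rescan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .core import (
    AlgoParams,
    PCSeries,
    PlaneGeometry,
    StructuralError,
    _center_distance_cm,
)
from .static_tissue import StaticMasks

__all__ = [
    "TriageLabel",
    "FM2Features",
    "FailureDecisionTree",
    "ClassificationResult",
    "failure_mode_1",
    "fm2_features",
    "failure_mode_2",
    "train_failure_tree",
    "fm3_centered_static_roi",
    "failure_mode_3",
    "classify",
]


class TriageLabel(str, Enum):
    USE_NPCCOR = "use_npccor"
    USE_UNCORRECTED = "use_uncorrected"
    PERFORM_RESCAN = "perform_rescan"


FEATURE_NAMES = ("vnr", "dx1", "dx2", "dx", "ddx", "dy1", "dy2", "dy", "ddy")


@dataclass
class FM2Features:
    """VNR and slope/curvature features of the static-tissue mean velocity.

    ``mean_x`` holds the static-pixel means of the three vertical strips
    (left / middle / right, variation along the column axis), ``mean_y``
    those of the three horizontal bands.  First differences are slopes,
    second differences curvatures, all in cm/s.  ``complete`` is False when
    some band contains no static pixels.
    """

    vnr: float
    mean_x: tuple[float, float, float]
    mean_y: tuple[float, float, float]
    complete: bool = True

    @property
    def dx1(self) -> float: return self.mean_x[1] - self.mean_x[0]

    @property
    def dx2(self) -> float: return self.mean_x[2] - self.mean_x[1]

    @property
    def dx(self) -> float: return self.mean_x[2] - self.mean_x[0]

    @property
    def ddx(self) -> float: return self.dx2 - self.dx1

    @property
    def dy1(self) -> float: return self.mean_y[1] - self.mean_y[0]

    @property
    def dy2(self) -> float: return self.mean_y[2] - self.mean_y[1]

    @property
    def dy(self) -> float: return self.mean_y[2] - self.mean_y[0]

    @property
    def ddy(self) -> float: return self.dy2 - self.dy1

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass
class ClassificationResult:
    """Outcome of the three failure-mode checks and the derived triage label."""

    fm1: bool
    fm2: bool
    fm3: bool
    label: TriageLabel
    features: FM2Features | None = None
    fm3_roi_radius: float | None = None
    diagnostics: dict = field(default_factory=dict)


def failure_mode_1(masks: StaticMasks, geometry: PlaneGeometry,
                   params: AlgoParams) -> bool:
    """Too little static tissue: union mask below the FoV fraction floor."""
    total = geometry.rows * geometry.cols
    return masks.n_static / total < params.fm1_min_static_fraction


def _band_slices(n: int) -> list[slice]:
    # three equal bands; remainder pixels go to the last band
    third = n // 3
    return [slice(0, third), slice(third, 2 * third), slice(2 * third, n)]


def fm2_features(mean_velocity: np.ndarray,
                 static_union: np.ndarray) -> FM2Features:
    """Compute the FM2 feature set from the temporal-mean velocity image.

    VNR is the SD of the static-pixel values of the mean-velocity image.
    Band statistics are computed over static pixels only; a band without
    static pixels yields NaN and marks the feature set incomplete.
    """
    if not static_union.any():
        raise StructuralError("no static pixels for FM2 features")
    vals = mean_velocity[static_union]
    vnr = float(np.std(vals))

    rows, cols = mean_velocity.shape
    mean_x = []
    for sl in _band_slices(cols):  # vertical strips: variation along columns
        m = static_union[:, sl]
        mean_x.append(float(mean_velocity[:, sl][m].mean()) if m.any()
                      else float("nan"))
    mean_y = []
    for sl in _band_slices(rows):  # horizontal bands: variation along rows
        m = static_union[sl, :]
        mean_y.append(float(mean_velocity[sl, :][m].mean()) if m.any()
                      else float("nan"))
    complete = not any(np.isnan(mean_x + mean_y))
    return FM2Features(vnr=vnr, mean_x=tuple(mean_x), mean_y=tuple(mean_y),
                       complete=complete)


# ---------------------------------------------------------------------------
# decision tree (trainable FM2 predictor)


@dataclass
class FailureDecisionTree:
    """Binary decision tree over FM2 features, serialisable to JSON.

    Nodes are nested dicts: internal nodes hold ``feature`` (index into
    ``FEATURE_NAMES``), ``threshold``, ``left``/``right`` children (left =
    feature <= threshold); leaves hold ``leaf`` (bool, True = predict
    failure).
    """

    root: dict
    training_meta: dict = field(default_factory=dict)

    def predict(self, features: FM2Features) -> bool:
        vec = features.as_vector()
        node = self.root
        while "leaf" not in node:
            node = node["left"] if vec[node["feature"]] <= node["threshold"] \
                else node["right"]
        return bool(node["leaf"])

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"feature_names": list(FEATURE_NAMES),
                           "root": self.root,
                           "training_meta": self.training_meta}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FailureDecisionTree":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        obj = json.loads(text)
        return cls(root=obj["root"], training_meta=obj.get("training_meta", {}))


def train_failure_tree(labeled_features: list[tuple[FM2Features, bool]],
                       depth_limit: int = 3,
                       seed: int = 0) -> FailureDecisionTree:
    """Fit a small decision tree predicting correction failure.

    A convenience harness for regenerating an FM2 predictor from labelled
    (synthetic or clinical) feature sets; the shipped default FM2 rule does
    not depend on it.  Deterministic for a given seed.
    """
    if len(labeled_features) < 20:
        raise ValueError("need at least 20 labelled samples")
    X = np.stack([f.as_vector() for f, _ in labeled_features])
    y = np.array([bool(lab) for _, lab in labeled_features])
    if y.all() or not y.any():
        raise ValueError("both failure labels must be present")

    from sklearn.tree import DecisionTreeClassifier

    clf = DecisionTreeClassifier(max_depth=depth_limit, random_state=seed)
    clf.fit(X, y)

    tree = clf.tree_

    def _convert(node: int) -> dict:
        if tree.children_left[node] == -1:
            counts = tree.value[node][0]
            return {"leaf": bool(counts[1] >= counts[0])}
        return {
            "feature": int(tree.feature[node]),
            "threshold": float(tree.threshold[node]),
            "left": _convert(tree.children_left[node]),
            "right": _convert(tree.children_right[node]),
        }

    return FailureDecisionTree(
        root=_convert(0),
        training_meta={"n_samples": len(y), "depth_limit": depth_limit,
                       "seed": seed},
    )


def failure_mode_2(features: FM2Features,
                   tree: FailureDecisionTree | None = None,
                   params: AlgoParams | None = None) -> bool:
    """Insufficient VNR / unreliable static-tissue statistics.

    With a trained tree the flag is its prediction.  Without one, a
    transparent default rule applies: flag when VNR exceeds the configured
    threshold or when any band mean is undefined.  Incomplete features flag
    regardless (a predictor cannot be evaluated on NaNs).
    """
    if not features.complete:
        return True
    if tree is not None:
        return tree.predict(features)
    params = params or AlgoParams()
    return features.vnr > params.fm2_vnr_threshold


# ---------------------------------------------------------------------------
# failure mode 3


def fm3_centered_static_roi(static_union: np.ndarray,
                            geometry: PlaneGeometry,
                            params: AlgoParams
                            ) -> tuple[float, np.ndarray]:
    """Smallest FoV-centred disc whose static-pixel fraction meets the floor.

    Candidate radii are the sorted pixel-centre distances from the FoV
    centre; the first radius at which static pixels make up at least
    ``fm3_roi_static_fraction`` of the disc is returned with its mask.  When
    no radius qualifies the full FoV is returned with a diagnostic attached
    to the mask via the returned radius = max distance.
    """
    if not static_union.any():
        raise StructuralError("no static pixels; FM3 ROI undefined")
    dist = _center_distance_cm(geometry)
    order = np.argsort(dist.ravel(), kind="stable")
    d_sorted = dist.ravel()[order]
    s_sorted = static_union.ravel()[order].astype(int)
    cum_static = np.cumsum(s_sorted)
    cum_total = np.arange(1, d_sorted.size + 1)
    # a radius is only valid at the end of a tie-group of equal distances
    is_group_end = np.ones(d_sorted.size, dtype=bool)
    is_group_end[:-1] = d_sorted[1:] > d_sorted[:-1]
    ok = is_group_end & (cum_static >= params.fm3_roi_static_fraction * cum_total) \
        & (cum_static > 0)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        radius = float(d_sorted[-1])
    else:
        radius = float(d_sorted[idx[0]])
    return radius, dist <= radius


def _static_roi_mean(series: PCSeries, masks: StaticMasks,
                     roi: np.ndarray, params: AlgoParams) -> float:
    """Static-tissue mean velocity inside the ROI, per the sampling split:

    global pixels contribute their all-phase mean, quiescent pixels their
    quiescent-phase mean.  Returns the absolute value of the signed mean by
    default (``fm3_mean_of_abs`` switches to the mean of |v|).
    """
    mean_all = series.velocity.mean(axis=0)
    mean_q = series.velocity[masks.quiescent_phase_indices].mean(axis=0)
    sel_g = masks.global_mask & roi
    sel_q = masks.quiescent_mask & roi
    vals = np.concatenate([mean_all[sel_g], mean_q[sel_q]])
    if vals.size == 0:
        return float("nan")
    if params.fm3_mean_of_abs:
        return float(np.mean(np.abs(vals)))
    return abs(float(np.mean(vals)))


def failure_mode_3(uncorrected: PCSeries, corrected: PCSeries,
                   masks: StaticMasks, roi: np.ndarray,
                   params: AlgoParams | None = None) -> bool:
    """Uncorrected-better-than-corrected check near the vessel.

    Flagged when the absolute mean static-tissue velocity inside the central
    ROI is equal or smaller before correction than after it (including the
    degenerate case corrected == uncorrected).  No static pixels in the ROI
    flags as well: the correction cannot be evaluated locally.
    """
    params = params or AlgoParams()
    if uncorrected.geometry.shape != corrected.geometry.shape:
        raise StructuralError("series geometry mismatch in FM3")
    m_before = _static_roi_mean(uncorrected, masks, roi, params)
    m_after = _static_roi_mean(corrected, masks, roi, params)
    if np.isnan(m_before) or np.isnan(m_after):
        return True
    return m_before <= m_after


def classify(fm1: bool, fm2: bool, fm3: bool) -> TriageLabel:
    """Map failure-mode flags to the triage label.

    FM1 and/or FM2 always advise a rescan (the data cannot support or
    evaluate a correction); FM3 alone means the uncorrected series is the
    better choice; no flags means the corrected series should be used.
    """
    if fm1 or fm2:
        return TriageLabel.PERFORM_RESCAN
    if fm3:
        return TriageLabel.USE_UNCORRECTED
    return TriageLabel.USE_NPCCOR
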