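"""Automatic static-tissue identification for PC CINE series.

Static tissue (chest wall, liver, muscle) has negligible true velocity across
the cardiac cycle and therefore samples the background phase offset directly.
Two masks are built:

* a *global* mask -- pixels whose mean magnitude is well above the noise
  floor and whose velocity is temporally stable over the whole cycle;
* a *quiescent* mask -- pixels that satisfy the same criteria only during the
  quiescent (diastasis) part of the cycle.  These are typically peri-vessel
  pixels contaminated by systolic flow ghosting; excluded from the global
  mask, they still carry clean background samples during diastole and sit
  closest to the vessel of interest, which is where the fitted surface
  matters most.

An optional linear pre-fit removes a gross planar offset before the masks are
re-derived (large offsets inflate the temporal SD criterion), and iterative
robust pruning strips boundary pixels whose residuals against the background
model are outlying.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .background import ConcomitantModel, design_matrix, solve_least_squares
from .core import (
    AlgoParams,
    PCSeries,
    fov_center_coordinates,
    plane_coordinates,
)

__all__ = [
    "StaticMasks",
    "raw_global_mask",
    "initial_linear_prefit",
    "iterative_prune",
    "quiescent_phases",
    "build_static_masks",
]


@dataclass
class StaticMasks:
    """Static-tissue masks and the per-pixel velocity samples used in fitting.

    ``sample_velocity`` is NaN outside the union; global pixels hold their
    all-phase mean velocity, quiescent pixels their quiescent-phase mean.
    The two masks are disjoint by construction.
    """

    global_mask: np.ndarray
    quiescent_mask: np.ndarray
    quiescent_phase_indices: np.ndarray
    sample_velocity: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.global_mask & self.quiescent_mask):
            raise ValueError("global and quiescent masks must be disjoint")

    @property
    def union_mask(self) -> np.ndarray:
        return self.global_mask | self.quiescent_mask

    @property
    def n_static(self) -> int:
        return int(self.union_mask.sum())


def raw_global_mask(series: PCSeries, params: AlgoParams,
                    velocity: np.ndarray | None = None,
                    phases: np.ndarray | None = None) -> np.ndarray:
    """Threshold-based static-tissue candidate mask.

    A pixel qualifies when its mean magnitude exceeds ``mag_frac_threshold``
    of the image maximum of the mean-magnitude map and its velocity SD stays
    below ``vel_sd_threshold`` (cm/s), both over the selected phases (all
    phases by default).  ``velocity`` may substitute a pre-corrected stack
    for the identification step.
    """
    vel = series.velocity if velocity is None else velocity
    mag = series.magnitude
    if phases is not None:
        vel = vel[phases]
        mag = mag[phases]
    mean_mag = mag.mean(axis=0)
    peak = float(mean_mag.max())
    if peak <= 0:
        warnings.warn("all-zero magnitude; empty static mask", stacklevel=2)
        return np.zeros(mean_mag.shape, dtype=bool)
    vel_sd = vel.std(axis=0)
    return (mean_mag > params.mag_frac_threshold * peak) & \
           (vel_sd < params.vel_sd_threshold)


def initial_linear_prefit(series: PCSeries, mask: np.ndarray,
                          params: AlgoParams
                          ) -> tuple[np.ndarray, bool]:
    """Optionally remove a gross planar offset before re-identification.

    A first-order plane (1, x, y, z) is fitted to the masked all-phase mean
    velocity.  If the plane's through-plane offset magnitude at the FoV
    centre exceeds ``perp_offset_threshold`` the plane is subtracted from
    every phase and ``applied=True`` is returned.  The returned stack is used
    ONLY to re-run static-tissue identification -- it never feeds the final
    correction.
    """
    n = int(mask.sum())
    if n < 5:
        warnings.warn("mask too small for the linear pre-fit; skipped",
                      stacklevel=2)
        return series.velocity, False
    coords = plane_coordinates(series.geometry)
    design_img = design_matrix(coords, None)
    beta, dropped = solve_least_squares(design_img[mask],
                                          series.velocity.mean(axis=0)[mask],
                                          expected_deficiency=1)
    if len(dropped) >= 3:
        warnings.warn("degenerate pre-fit design; pre-fit skipped", stacklevel=2)
        return series.velocity, False
    cx, cy, cz = fov_center_coordinates(series.geometry)
    center_value = beta[0] + beta[1] * cx + beta[2] * cy + beta[3] * cz
    if abs(center_value) <= params.perp_offset_threshold:
        return series.velocity, False
    plane = design_img @ beta
    return series.velocity - plane[None], True


def iterative_prune(mask: np.ndarray, sample_velocity: np.ndarray,
                    design_img: np.ndarray, params: AlgoParams,
                    floor: int = 6) -> np.ndarray:
    """Robust iterative outlier rejection against the background model.

    Each iteration fits the surface to the currently masked samples, then
    removes pixels whose |residual| exceeds ``prune_k`` times the robust SD
    (1.4826 * MAD) of the residuals.  Tissue-boundary pixels with ghosting
    artefacts fail this test.  The mask never shrinks below ``floor`` pixels:
    an iteration that would cross the floor is skipped, leaving downstream
    failure-mode logic to flag the dataset instead.
    """
    current = mask.copy()
    n0 = int(current.sum())
    if n0 < 6:
        warnings.warn("mask below minimum fit size; pruning skipped",
                      stacklevel=2)
        return current
    # a mask already below the floor is pruned normally down to the fit
    # minimum; the failure-mode check flags it regardless
    floor = floor if n0 >= floor else 6
    for _ in range(params.prune_iterations):
        idx = np.flatnonzero(current.ravel())
        A = design_img.reshape(-1, design_img.shape[-1])[idx]
        y = sample_velocity.ravel()[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, _ = solve_least_squares(A, y)
        resid = y - A @ beta
        mad = float(np.median(np.abs(resid - np.median(resid))))
        robust_sd = 1.4826 * mad
        # absolute floor on the cut: residuals far below any clinically
        # relevant offset are never outliers.  Without it, near-noise-free
        # data lets the outliers' own leverage footprint (smooth residual
        # structure ~ the collapsed MAD) trigger cascading removal.
        cut = max(params.prune_k * robust_sd, params.prune_min_cut)
        keep = np.abs(resid) <= cut
        n_next = int(keep.sum())
        if n_next == idx.size:
            break
        if n_next < max(floor, 6):
            break  # would empty/undersize the mask; stop early
        removed = idx[~keep]
        current.ravel()[removed] = False
    return current


def quiescent_phases(series: PCSeries,
                     window_fraction: float = 0.2) -> np.ndarray:
    """Indices of the quiescent (diastasis) cardiac phases.

    A contiguous cyclic window of length ceil(window_fraction * N) minimising
    the summed spatial-mean |frame-to-frame velocity change| is selected;
    ties break to the smallest starting index, so the result is
    deterministic.  The spatial mean is taken over pixels with tissue-level
    magnitude (one tenth of the mean-magnitude maximum): air pixels carry
    uniform phase noise that would otherwise swamp the motion signal.
    """
    n = series.n_phases
    if n < 4:
        raise ValueError("quiescent-phase detection needs at least 4 phases")
    length = int(np.ceil(window_fraction * n))
    mean_mag = series.magnitude.mean(axis=0)
    tissue = mean_mag > 0.10 * float(mean_mag.max())
    if not tissue.any():
        tissue = np.ones(mean_mag.shape, dtype=bool)
    diff = np.abs(np.diff(series.velocity, axis=0, prepend=series.velocity[-1:]))
    activity = diff[:, tissue].mean(axis=1)  # mean |v_t - v_{t-1}| in tissue
    costs = np.array([
        activity[(np.arange(start, start + length)) % n].sum()
        for start in range(n)
    ])
    start = int(np.argmin(costs))
    return (np.arange(start, start + length)) % n


def build_static_masks(series: PCSeries, params: AlgoParams | None = None,
                       model: ConcomitantModel | None = None) -> StaticMasks:
    """Full static-tissue identification pipeline.

    Orchestrates: raw global mask -> linear pre-fit (with re-identification
    when triggered) -> iterative pruning -> quiescent-phase mask (same
    criteria restricted to the quiescent window, minus the global mask,
    pruned) -> per-pixel sample velocities.
    """
    params = params or AlgoParams()
    model = model or ConcomitantModel()
    coords = plane_coordinates(series.geometry)
    design_img = design_matrix(coords, model)
    total_px = series.geometry.rows * series.geometry.cols
    fm1_floor = max(6, int(np.ceil(params.fm1_min_static_fraction * total_px)))

    candidate = raw_global_mask(series, params)
    ident_velocity, prefit_applied = initial_linear_prefit(
        series, candidate, params)
    if prefit_applied:
        candidate = raw_global_mask(series, params, velocity=ident_velocity)

    mean_all = series.velocity.mean(axis=0)
    global_mask = iterative_prune(candidate, mean_all, design_img, params,
                                  floor=fm1_floor)

    qp = quiescent_phases(series, params.quiescent_window_fraction)
    quiescent_candidate = raw_global_mask(
        series, params,
        velocity=ident_velocity if prefit_applied else None,
        phases=qp,
    ) & ~global_mask
    mean_quiescent = series.velocity[qp].mean(axis=0)
    if quiescent_candidate.sum() >= 6:
        quiescent_mask = iterative_prune(quiescent_candidate, mean_quiescent,
                                         design_img, params, floor=6)
    else:
        quiescent_mask = quiescent_candidate

    sample = np.full(series.geometry.shape, np.nan)
    sample[global_mask] = mean_all[global_mask]
    sample[quiescent_mask] = mean_quiescent[quiescent_mask]

    return StaticMasks(
        global_mask=global_mask,
        quiescent_mask=quiescent_mask,
        quiescent_phase_indices=qp,
        sample_velocity=sample,
        provenance={
            "prefit_applied": prefit_applied,
            "prune_iterations": params.prune_iterations,
            "n_candidate": int(candidate.sum()),
            "n_global": int(global_mask.sum()),
            "n_quiescent": int(quiescent_mask.sum()),
        },
    )
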