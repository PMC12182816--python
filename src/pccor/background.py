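"""Background-phase surface model: 5-term basis, fitting and corrections.

Residual background velocity offsets in phase-contrast imaging are spatially
smooth.  They are modelled here as

    v_bg(x, y, z) = c0 + c1*x + c2*y + c3*z + c4 * S(x, y, z)

where (x, y, z) are magnet-frame positions (cm) of the pixel centres and S is
the spatial shape of the Maxwell concomitant field

    S0(x, y, z) = A*(x^2 + y^2)/4 + B*z^2 - C*x*z - D*y*z

with (A, B, C, D) the time integrals of (Gz^2, Gx^2+Gy^2, Gx*Gz, Gy*Gz) over
the gradient waveform.  Only the *shape* matters: the physical prefactor
gamma/(2*B0) and the overall amplitude are absorbed into the fitted c4, so S
is normalised to unit RMS over the image before entering the design matrix.

The coefficients are estimated by ordinary least squares on static-tissue
samples.  A deliberately restricted 5-term model (rather than the full
10-term quadratic) keeps the fit robust when static tissue is scarce; an
over-fitting guard refuses to apply corrections whose amplitude near the FoV
centre is below the clinical significance floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core import (
    AlgoParams,
    ConfigurationError,
    PCSeries,
    PlaneGeometry,
    StructuralError,
    fov_center_roi,
    plane_coordinates,
)

__all__ = [
    "ConcomitantModel",
    "FitResult",
    "concomitant_shape",
    "design_matrix",
    "solve_least_squares",
    "fit_surface",
    "overfit_guard",
    "apply_correction",
    "linear_correction",
    "phantom_correction",
]

GAMMA_PROTON = 2.675e8  # rad/s/T


@dataclass(frozen=True)
class ConcomitantModel:
    """Concomitant-field configuration.

    ``moments`` holds (A, B, C, D), the squared-gradient time integrals.  The
    default symmetric bipolar flow-encoding model (1, 1, 0, 0) gives the
    canonical bowl shape A*(x^2+y^2)/4 + B*z^2; only the relative weights of
    the quadratic terms influence the fit because the amplitude is estimated.
    """

    b0: float = 1.5
    gamma: float = GAMMA_PROTON
    moments: tuple[float, float, float, float] = (1.0, 1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ConfigurationError("main field strength must be positive")
        a, b, _, _ = self.moments
        if a < 0 or b < 0:
            raise ConfigurationError("A and B moments must be non-negative")


@dataclass
class FitResult:
    """Fitted surface coefficients and the evaluated correction image.

    ``coefficients`` are (c0..c4) for the basis (1, x, y, z, S); ``surface``
    is the basis expansion evaluated at every pixel (cm/s) and satisfies
    ``surface == design @ coefficients`` exactly.
    """

    coefficients: np.ndarray
    surface: np.ndarray
    n_samples: int
    residual_rms: float
    dropped_columns: tuple[int, ...] = ()
    guard_triggered: bool | None = None
    diagnostics: dict = field(default_factory=dict)


def concomitant_shape(coords: tuple[np.ndarray, np.ndarray, np.ndarray],
                      model: ConcomitantModel) -> np.ndarray:
    """Unit-RMS concomitant-field shape evaluated on the plane.

    Raises if all moments vanish (the shape is then undefined).  The raw
    (un-normalised) shape is zero at the magnet isocenter.
    """
    x, y, z = coords
    a, b, c, d = model.moments
    raw = a * (x * x + y * y) / 4.0 + b * z * z - c * x * z - d * y * z
    rms = float(np.sqrt(np.mean(raw * raw)))
    if rms == 0.0:
        raise ConfigurationError(
            "concomitant shape is identically zero (all moments zero?)"
        )
    return raw / rms


def design_matrix(coords: tuple[np.ndarray, np.ndarray, np.ndarray],
                  model: ConcomitantModel | None) -> np.ndarray:
    """Per-pixel design tensor, shape (rows, cols, K).

    K = 5 with the concomitant column, K = 4 (1, x, y, z) when ``model`` is
    None -- the latter is the linear baseline correction model.
    """
    x, y, z = coords
    cols = [np.ones_like(x), x, y, z]
    if model is not None:
        cols.append(concomitant_shape(coords, model))
    return np.stack(cols, axis=-1)


def solve_least_squares(design: np.ndarray, y: np.ndarray,
                        rcond: float = 1e-10,
                        expected_deficiency: int = 0
                        ) -> tuple[np.ndarray, tuple[int, ...]]:
    """OLS with column standardisation and pivoted rank handling.

    Columns (except the intercept) are centred and scaled to unit RMS before
    solving, which keeps the normal equations well conditioned for planes far
    off isocenter.  Collinear or constant columns are detected by pivoted QR
    on the standardised design; their coefficients are returned as exactly
    zero with a warning.

    Returns (coefficients in the original basis, indices of dropped columns).
    """
    A = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = A.shape
    means = A.mean(axis=0)
    means[0] = 0.0  # keep the intercept column as-is
    centered = A - means
    scales = np.sqrt(np.mean(centered * centered, axis=0))
    scales[0] = 1.0
    centered[:, 0] = 1.0

    degenerate = [j for j in range(1, k) if scales[j] < rcond * max(scales.max(), 1.0)]
    usable = [j for j in range(k) if j not in degenerate]
    Z = centered[:, usable] / scales[usable]

    q, r, piv = scipy.linalg.qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > rcond * (diag[0] if diag[0] > 0 else 1.0)))
    keep_local = sorted(piv[:rank])
    dropped = tuple(sorted(degenerate + [usable[j] for j in piv[rank:]]))
    if len(dropped) > expected_deficiency:
        warnings.warn(
            f"rank-deficient design: dropping columns {dropped}", stacklevel=2
        )

    kept_cols = [usable[j] for j in keep_local]
    Zk = Z[:, keep_local]
    beta_std, *_ = np.linalg.lstsq(Zk, y, rcond=None)

    beta = np.zeros(k)
    for b, j in zip(beta_std, kept_cols):
        beta[j] = b / scales[j]
    # fold the centring shifts back into the intercept
    if 0 in kept_cols:
        beta[0] -= float(np.dot(beta[1:], means[1:]))
    return beta, dropped


def canonical_coefficients(design_img: np.ndarray, surface: np.ndarray,
                           rcond: float = 1e-8) -> np.ndarray:
    """Canonical (minimum-norm) coefficient representative of a surface.

    On a single slice the plane equation makes z an exact affine function of
    x and y, so the (1, x, y, z) columns are rank deficient *for every
    plane*: a surface determines its coefficients only up to the plane's
    null vector.  All reported coefficients (fits and simulator ground
    truth alike) are therefore the minimum-norm solution of
    ``design @ c = surface`` over the full pixel grid, which is a fixed,
    sample-independent representative -- two equal surfaces always map to
    identical coefficient vectors.
    """
    D = design_img.reshape(-1, design_img.shape[-1])
    c, *_ = np.linalg.lstsq(D, np.asarray(surface, dtype=float).ravel(),
                            rcond=rcond)
    return c


def fit_surface(masks, coords: tuple[np.ndarray, np.ndarray, np.ndarray],
                model: ConcomitantModel) -> FitResult:
    """Fit the 5-term background model to static-tissue samples.

    Every pixel of the global and quiescent masks contributes one equally
    weighted sample: global pixels their all-phase mean velocity, quiescent
    pixels their quiescent-phase mean.  Feeding quiescent pixels (which sit
    closest to the vessel) their quiet-interval mean is what up-weights the
    quiescent measurements without explicit weights.
    """
    union = masks.union_mask
    n = int(union.sum())
    if n < 6:
        raise StructuralError(
            f"need at least 6 static samples to fit 5 coefficients, got {n}"
        )
    design_img = design_matrix(coords, model)
    A = design_img[union]
    y = masks.sample_velocity[union]
    # on a single plane z is affine in (x, y): one dropped column is expected
    beta, dropped = solve_least_squares(A, y, expected_deficiency=1)
    resid = y - A @ beta
    beta = canonical_coefficients(design_img, design_img @ beta)
    surface = design_img @ beta
    return FitResult(
        coefficients=beta,
        surface=surface,
        n_samples=n,
        residual_rms=float(np.sqrt(np.mean(resid * resid))),
        dropped_columns=dropped,
    )


def overfit_guard(fit: FitResult, geometry: PlaneGeometry,
                  params: AlgoParams) -> bool:
    """Decide whether the fitted surface should be applied.

    The surface is evaluated over a disc at the FoV centre (where the vessel
    of interest is assumed to sit).  If its mean amplitude there is below the
    clinical-significance floor the correction is withheld: a surface that
    barely moves velocities near the vessel has nothing to correct and any
    apparent structure is more likely fit noise.

    Returns True when the correction should be applied.  Also records the
    decision on ``fit.guard_triggered`` (True = correction withheld).
    """
    roi = fov_center_roi(geometry, params.guard_roi_radius)
    vals = fit.surface[roi]
    mean_amp = float(np.mean(np.abs(vals)) if params.guard_use_abs
                     else abs(np.mean(vals)))
    apply = mean_amp >= params.guard_velocity_threshold
    fit.guard_triggered = not apply
    fit.diagnostics["guard_roi_mean_cm_s"] = mean_amp
    return apply


def apply_correction(series: PCSeries, fit: FitResult, *,
                     apply: bool = True) -> PCSeries:
    """Subtract the fitted surface from every phase of the velocity stack.

    With ``apply=False`` (the guard said no) the input series is returned
    unchanged and the reason recorded in the fit diagnostics.
    """
    if not apply:
        fit.diagnostics["skipped"] = "guard withheld correction"
        return series
    if fit.surface.shape != series.geometry.shape:
        raise StructuralError("surface shape does not match series geometry")
    return series.with_velocity(series.velocity - fit.surface[None, :, :])


def linear_correction(series: PCSeries, masks,
                      coords: tuple[np.ndarray, np.ndarray, np.ndarray]
                      ) -> tuple[PCSeries, FitResult]:
    """First-order (1, x, y, z) baseline correction, no guard.

    This is the plain linear static-tissue correction used as comparator;
    it is always applied.
    """
    union = masks.union_mask
    n = int(union.sum())
    if n < 5:
        raise StructuralError("too few static samples for the linear fit")
    design_img = design_matrix(coords, None)
    A = design_img[union]
    y = masks.sample_velocity[union]
    beta, dropped = solve_least_squares(A, y, expected_deficiency=1)
    resid = y - A @ beta
    beta = canonical_coefficients(design_img, design_img @ beta)
    surface = design_img @ beta
    fit = FitResult(
        coefficients=beta,
        surface=surface,
        n_samples=n,
        residual_rms=float(np.sqrt(np.mean(resid * resid))),
        dropped_columns=dropped,
    )
    return series.with_velocity(series.velocity - surface[None]), fit


def phantom_correction(series: PCSeries, phantom: PCSeries, *,
                       per_phase: bool = False) -> PCSeries:
    """Reference-standard correction by static-phantom subtraction.

    The phantom offset defaults to the phantom's per-pixel temporal mean
    (the phantom is static, so averaging over phases maximises SNR); set
    ``per_phase=True`` to subtract phase by phase instead.
    """
    if phantom.geometry.shape != series.geometry.shape:
        raise StructuralError("phantom geometry does not match series")
    if per_phase:
        if phantom.n_phases != series.n_phases:
            raise StructuralError("per-phase subtraction needs equal phase counts")
        offset = phantom.velocity
    else:
        offset = phantom.velocity.mean(axis=0)[None, :, :]
    return series.with_velocity(series.velocity - offset)
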