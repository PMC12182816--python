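"""Synthetic PC CINE scenes with known ground truth.

The generator emulates the statistical structure the correction algorithm
relies on, at the image level (no k-space physics):

* an elliptical "torso" of static tissue at constant magnitude,
* a circular vessel at the FoV centre carrying pulsatile through-plane flow
  (plug or Poiseuille profile, half-sine systolic ejection plus an optional
  regurgitant lobe),
* an injected smooth background-phase surface that lies exactly in the
  5-term fitting basis (offset, three linear terms, concomitant shape), so
  exact-recovery tests are well posed,
* a peri-vessel ghosting annulus whose velocity is disturbed during systole
  only -- these pixels fail the whole-cycle temporal-SD criterion but are
  clean during diastasis, exercising the quiescent-mask logic,
* VENC-scaled noise: Gaussian velocity noise inside tissue, uniform phase
  noise in the air background,
* a matched static-phantom series holding the same background surface (plus
  a configurable drift) and no flow.

Every scene is deterministic given its seed, and the ground truth (surface,
coefficients, masks, analytic beat volumes) is returned alongside, rich
enough to score every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .background import ConcomitantModel, canonical_coefficients, design_matrix
from .core import (
    ConfigurationError,
    PCSeries,
    PlaneGeometry,
    SeriesRole,
    fov_center_point,
    plane_coordinates,
    save_pc_series,
)

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "oblique_geometry",
    "generate",
    "OffsetSampler",
    "SCANNER_OFFSET_PROFILES",
    "scanner_offset_profile",
    "generate_cohort",
    "CohortDataset",
]


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def oblique_geometry(rows: int, cols: int, pixel_spacing: tuple[float, float],
                     tilt_deg: float = 0.0, roll_deg: float = 0.0,
                     offset_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)
                     ) -> PlaneGeometry:
    """Plane geometry tilted/rolled from axial and centred at ``offset_cm``.

    The FoV centre lands exactly at ``offset_cm`` (magnet frame).  A nonzero
    tilt makes z vary across the plane, which keeps the z and concomitant
    basis columns non-degenerate -- as they are for clinically prescribed
    double-oblique planes.
    """
    rot = _rot_z(roll_deg) @ _rot_x(tilt_deg)
    row_dir = rot @ np.array([1.0, 0.0, 0.0])
    col_dir = rot @ np.array([0.0, 1.0, 0.0])
    sr, sc = pixel_spacing
    ci, cj = (rows - 1) / 2.0, (cols - 1) / 2.0
    origin = (np.asarray(offset_cm, dtype=float) * 10.0
              - ci * sr * row_dir - cj * sc * col_dir)
    return PlaneGeometry(rows=rows, cols=cols, pixel_spacing=pixel_spacing,
                         origin=origin, row_dir=row_dir, col_dir=col_dir)


@dataclass
class PhantomConfig:
    """Scene description for the synthetic generator.

    Defaults describe a nominal adult through-plane acquisition: ~29 cm FoV
    on a 96x96 grid, 30 reconstructed phases over a 1000 ms cycle, a 12 mm
    radius central vessel peaking at 100 cm/s over a 10-phase systole,
    VENC 180 cm/s, 0.6 cm/s velocity noise in tissue.
    """

    rows: int = 96
    cols: int = 96
    n_phases: int = 30
    pixel_spacing: tuple[float, float] = (3.0, 3.0)  # mm
    plane_tilt_deg: float = 12.0
    plane_roll_deg: float = 8.0
    plane_offset_cm: tuple[float, float, float] = (1.0, -2.0, 5.0)

    torso_semiaxes_cm: tuple[float, float] = (10.5, 8.5)
    torso_magnitude: float = 100.0
    vessel_magnitude: float = 140.0
    air_magnitude: float = 3.0
    magnitude_noise_sd: float = 2.0

    vessel_radius_mm: float = 12.0
    peak_velocity: float = 100.0       # cm/s, systolic spatial peak
    systolic_phases: tuple[int, int] = (2, 12)   # [start, stop)
    flow_profile: str = "plug"         # "plug" | "poiseuille"
    regurg_peak_velocity: float = 0.0  # cm/s, diastolic retrograde lobe
    regurg_phases: tuple[int, int] = (14, 20)

    background_coeffs: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    moments: tuple[float, float, float, float] = (1.0, 1.0, 0.0, 0.0)
    b0: float = 1.5

    noise_sd: float = 0.6              # cm/s, tissue velocity noise
    air_noise_fraction: float = 1.0    # air phase noise, fraction of VENC
    contamination: float = 25.0        # cm/s peri-vessel systolic ghosting
    contamination_annulus: tuple[float, float] = (1.0, 1.6)  # x vessel radius
    static_roughness_sd: float = 0.0   # cm/s frozen spatial noise in tissue
    static_fraction_target: float | None = None
    phantom_drift: float = 0.0         # cm/s offset between series

    venc: float = 180.0
    rr_duration: float = 1000.0        # ms
    seed: int = 0

    def concomitant_model(self) -> ConcomitantModel:
        return ConcomitantModel(b0=self.b0, moments=self.moments)


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline on a generated scene."""

    background_surface: np.ndarray
    background_coeffs: np.ndarray
    static_mask: np.ndarray
    vessel_mask: np.ndarray            # pixels with any lumen coverage
    contaminated_mask: np.ndarray      # static pixels with systolic ghosting
    waveform: np.ndarray               # spatial-peak velocity per phase, cm/s
    vessel_area_cm2: float
    net_volume: float                  # ml/beat, analytic
    forward_volume: float
    backward_volume: float
    regurg_fraction: float             # %
    phantom_offset: np.ndarray

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {
            "background_surface": self.background_surface,
            "background_coeffs": self.background_coeffs,
            "static_mask": self.static_mask,
            "vessel_mask": self.vessel_mask,
            "contaminated_mask": self.contaminated_mask,
            "waveform": self.waveform,
            "scalars": np.array([self.vessel_area_cm2, self.net_volume,
                                 self.forward_volume, self.backward_volume,
                                 self.regurg_fraction]),
            "phantom_offset": self.phantom_offset,
        }


def _disc_coverage(geometry: PlaneGeometry, center_px: tuple[float, float],
                   radius_mm: float, supersample: int = 4) -> np.ndarray:
    """Sub-pixel area fraction of each pixel covered by the disc."""
    sr, sc = geometry.pixel_spacing
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    cover = np.zeros(geometry.shape)
    ii, jj = np.meshgrid(np.arange(geometry.rows), np.arange(geometry.cols),
                         indexing="ij")
    for oi in offs:
        for oj in offs:
            d = np.hypot((ii + oi - center_px[0]) * sr,
                         (jj + oj - center_px[1]) * sc)
            cover += d <= radius_mm
    return cover / supersample**2


def _waveform(config: PhantomConfig) -> np.ndarray:
    w = np.zeros(config.n_phases)
    s0, s1 = config.systolic_phases
    ns = s1 - s0
    if ns > 0 and config.peak_velocity != 0.0:
        k = np.arange(ns)
        w[np.arange(s0, s1) % config.n_phases] = \
            config.peak_velocity * np.sin(np.pi * (k + 0.5) / ns)
    r0, r1 = config.regurg_phases
    nr = r1 - r0
    if nr > 0 and config.regurg_peak_velocity != 0.0:
        k = np.arange(nr)
        w[np.arange(r0, r1) % config.n_phases] -= \
            config.regurg_peak_velocity * np.sin(np.pi * (k + 0.5) / nr)
    return w


def generate(config: PhantomConfig) -> tuple[PCSeries, PCSeries, GroundTruth]:
    """Generate an in-vivo-like scene, its matched static phantom and truth."""
    rng = np.random.default_rng(config.seed)
    geometry = oblique_geometry(
        config.rows, config.cols, config.pixel_spacing,
        config.plane_tilt_deg, config.plane_roll_deg, config.plane_offset_cm)
    coords = plane_coordinates(geometry)
    sr, sc = geometry.pixel_spacing

    # injected background surface, exactly in the fitting basis span
    coeffs = np.asarray(config.background_coeffs, dtype=float)
    if coeffs.shape != (5,):
        raise ConfigurationError("background_coeffs must have 5 entries")
    design_img = design_matrix(coords, config.concomitant_model())
    surface = design_img @ coeffs
    # ground-truth coefficients are stored in the same canonical
    # (minimum-norm) representative the fitter reports
    coeffs_canonical = canonical_coefficients(design_img, surface)

    # torso ellipse in in-plane physical coordinates
    ci, cj = fov_center_point(geometry)
    ii, jj = np.meshgrid(np.arange(config.rows), np.arange(config.cols),
                         indexing="ij")
    u = (ii - ci) * sr / 10.0  # cm
    w_ = (jj - cj) * sc / 10.0
    a, b = config.torso_semiaxes_cm
    if config.static_fraction_target is not None:
        fov_area = (config.rows * sr / 10.0) * (config.cols * sc / 10.0)
        scale = np.sqrt(config.static_fraction_target * fov_area / (np.pi * a * b))
        a, b = a * scale, b * scale
    torso = (u / a) ** 2 + (w_ / b) ** 2 <= 1.0

    vessel_cover = _disc_coverage(geometry, (ci, cj), config.vessel_radius_mm)
    vessel_support = vessel_cover > 0
    if np.any(vessel_support & ~torso):
        raise ConfigurationError("vessel extends outside the torso")

    # flow velocity field
    waveform = _waveform(config)
    rho = np.hypot((ii - ci) * sr, (jj - cj) * sc)  # mm from vessel axis
    if config.flow_profile == "plug":
        profile = vessel_cover
        area_eff = np.pi * (config.vessel_radius_mm / 10.0) ** 2
    elif config.flow_profile == "poiseuille":
        par = np.clip(1.0 - (rho / config.vessel_radius_mm) ** 2, 0.0, None)
        profile = vessel_cover * par
        area_eff = np.pi * (config.vessel_radius_mm / 10.0) ** 2 / 2.0
    else:
        raise ConfigurationError(f"unknown flow profile {config.flow_profile!r}")

    velocity = surface[None] + waveform[:, None, None] * profile[None]

    # peri-vessel systolic ghosting (static tissue, contaminated in systole)
    annulus = np.zeros(geometry.shape, dtype=bool)
    if config.contamination > 0:
        lo, hi = config.contamination_annulus
        annulus = (rho > lo * config.vessel_radius_mm) \
            & (rho <= hi * config.vessel_radius_mm) & torso & ~vessel_support
        amp = np.zeros(geometry.shape)
        n_ann = int(annulus.sum())
        amp[annulus] = (config.contamination
                        * rng.uniform(0.9, 1.1, size=n_ann)
                        * rng.choice([-1.0, 1.0], size=n_ann))
        s0, s1 = config.systolic_phases
        ns = max(s1 - s0, 1)
        shape_t = np.zeros(config.n_phases)
        shape_t[np.arange(s0, s1) % config.n_phases] = \
            np.sin(np.pi * (np.arange(s1 - s0) + 0.5) / ns)
        velocity = velocity + shape_t[:, None, None] * amp[None]

    if config.static_roughness_sd > 0:
        rough = np.zeros(geometry.shape)
        rough[torso] = rng.normal(0.0, config.static_roughness_sd,
                                  size=int(torso.sum()))
        velocity = velocity + rough[None]

    air = ~torso
    if config.noise_sd > 0:
        velocity = velocity + rng.normal(0.0, config.noise_sd, velocity.shape)
    if config.air_noise_fraction > 0:
        velocity[:, air] = rng.uniform(
            -config.air_noise_fraction * config.venc,
            config.air_noise_fraction * config.venc,
            size=(config.n_phases, int(air.sum())))
    velocity = np.clip(velocity, -config.venc, config.venc)

    magnitude = np.full(geometry.shape, config.air_magnitude)
    magnitude[torso] = config.torso_magnitude
    magnitude = magnitude + (config.vessel_magnitude
                             - config.torso_magnitude) * vessel_cover
    magnitude = np.broadcast_to(magnitude,
                                (config.n_phases, *geometry.shape)).copy()
    if config.magnitude_noise_sd > 0:
        magnitude += rng.normal(0.0, config.magnitude_noise_sd,
                                magnitude.shape)
    magnitude = np.clip(magnitude, 0.0, None)

    in_vivo = PCSeries(magnitude=magnitude, velocity=velocity,
                       venc=config.venc, rr_duration=config.rr_duration,
                       geometry=geometry, series_role=SeriesRole.IN_VIVO)

    # matched static phantom: same background (+drift), no flow
    phantom_offset = surface + config.phantom_drift
    ph_velocity = np.broadcast_to(phantom_offset, velocity.shape).copy()
    if config.noise_sd > 0:
        ph_velocity = ph_velocity + rng.normal(0.0, config.noise_sd,
                                               ph_velocity.shape)
    ph_velocity = np.clip(ph_velocity, -config.venc, config.venc)
    ph_magnitude = np.full((config.n_phases, *geometry.shape),
                           config.torso_magnitude)
    if config.magnitude_noise_sd > 0:
        ph_magnitude += rng.normal(0.0, config.magnitude_noise_sd,
                                   ph_magnitude.shape)
    phantom = PCSeries(magnitude=np.clip(ph_magnitude, 0.0, None),
                       velocity=ph_velocity, venc=config.venc,
                       rr_duration=config.rr_duration, geometry=geometry,
                       series_role=SeriesRole.STATIC_PHANTOM)

    # analytic beat volumes from the waveform
    dt = config.rr_duration / 1000.0 / config.n_phases
    rate = waveform * area_eff  # ml/s per phase (spatial integral is exact)
    forward = float(np.clip(rate, 0.0, None).sum() * dt)
    backward = float((-np.clip(rate, None, 0.0)).sum() * dt)
    regurg = backward / forward * 100.0 if forward > 0 else float("nan")

    truth = GroundTruth(
        background_surface=surface,
        background_coeffs=coeffs_canonical,
        static_mask=torso & ~vessel_support,
        vessel_mask=vessel_support,
        contaminated_mask=annulus,
        waveform=waveform,
        vessel_area_cm2=area_eff,
        net_volume=forward - backward,
        forward_volume=forward,
        backward_volume=backward,
        regurg_fraction=regurg,
        phantom_offset=phantom_offset,
    )
    return in_vivo, phantom, truth


def save_scene(out_dir: str | Path, in_vivo: PCSeries, phantom: PCSeries,
               truth: GroundTruth) -> tuple[Path, Path]:
    """Write a generated scene as two archives (truth rides with in-vivo)."""
    out_dir = Path(out_dir)
    p1 = save_pc_series(out_dir / "in_vivo.npz", in_vivo,
                        ground_truth=truth.to_arrays())
    p2 = save_pc_series(out_dir / "phantom.npz", phantom)
    return p1, p2


# ---------------------------------------------------------------------------
# per-scanner background-offset profiles

# median and IQR of the uncorrected mean absolute velocity offset (cm/s)
SCANNER_OFFSET_PROFILES = {
    "scanner1": (0.7, 0.1, 1.0),
    "scanner2": (1.4, 0.6, 2.9),
    "scanner3": (0.2, 0.1, 0.4),
}

# relative scale of the random coefficient direction: constant, three linear
# terms (per cm), concomitant amplitude (unit-RMS shape)
_COEFF_DIRECTION_SCALES = np.array([1.0, 0.07, 0.07, 0.07, 0.7])


class OffsetSampler:
    """Draws background coefficient sets matching a scanner's offset scale.

    The master amplitude (mean |offset| over static tissue) follows a
    log-normal whose median equals the scanner's reported median and whose
    quartile ratio matches the reported IQR; the spatial direction is an
    isotropic random mix of the five basis terms, rescaled so the realised
    static-tissue mean |offset| equals the drawn amplitude exactly.
    """

    def __init__(self, scanner: str, seed: int = 0,
                 config: PhantomConfig | None = None):
        if scanner not in SCANNER_OFFSET_PROFILES:
            raise ConfigurationError(f"unknown scanner profile {scanner!r}")
        median, q1, q3 = SCANNER_OFFSET_PROFILES[scanner]
        self.scanner = scanner
        self._mu = np.log(median)
        self._sigma = np.log(q3 / q1) / (2.0 * 0.6744897501960817)
        self._rng = np.random.default_rng(seed)
        cfg = config or PhantomConfig()
        geometry = oblique_geometry(
            cfg.rows, cfg.cols, cfg.pixel_spacing, cfg.plane_tilt_deg,
            cfg.plane_roll_deg, cfg.plane_offset_cm)
        coords = plane_coordinates(geometry)
        self._design = design_matrix(coords, cfg.concomitant_model())
        ci, cj = fov_center_point(geometry)
        ii, jj = np.meshgrid(np.arange(cfg.rows), np.arange(cfg.cols),
                             indexing="ij")
        sr, sc = cfg.pixel_spacing
        u = (ii - ci) * sr / 10.0
        w_ = (jj - cj) * sc / 10.0
        aa, bb = cfg.torso_semiaxes_cm
        self._static = (u / aa) ** 2 + (w_ / bb) ** 2 <= 1.0

    def draw(self) -> np.ndarray:
        """One coefficient set (c0..c4)."""
        amp = float(self._rng.lognormal(self._mu, self._sigma))
        while True:
            direction = self._rng.standard_normal(5) * _COEFF_DIRECTION_SCALES
            realised = float(np.mean(np.abs(
                (self._design @ direction)[self._static])))
            if realised > 0:
                break
        return direction * (amp / realised)


def scanner_offset_profile(scanner: str, seed: int = 0,
                           config: PhantomConfig | None = None) -> OffsetSampler:
    """Sampler of background coefficient sets for one scanner profile."""
    return OffsetSampler(scanner, seed, config)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortDataset:
    in_vivo: PCSeries
    phantom: PCSeries
    truth: GroundTruth
    scenario: str   # nominal | fm1 | fm2 | fm3
    scanner: str
    seed: int


_SCENARIOS = ("nominal", "fm1", "fm2", "fm3")


def generate_cohort(n: int,
                    scanner_mix: dict[str, float] | None = None,
                    failure_scenario_rates: dict[str, float] | None = None,
                    seed: int = 0,
                    base_config: PhantomConfig | None = None
                    ) -> list[CohortDataset]:
    """A reproducible cohort of scenes with controlled failure scenarios.

    ``failure_scenario_rates`` gives the probability of FM1-inducing
    (low-static-tissue), FM2-inducing (rough static velocity) and
    FM3-inducing (near-zero offset, over-fit bait) scenes; the remainder are
    nominal.  Scanner membership controls the background-offset scale.
    """
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    scanner_mix = scanner_mix or {"scanner1": 1 / 3, "scanner2": 1 / 3,
                                  "scanner3": 1 / 3}
    rates = failure_scenario_rates or {}
    p_fail = [rates.get("fm1", 0.0), rates.get("fm2", 0.0),
              rates.get("fm3", 0.0)]
    if sum(p_fail) > 1.0 + 1e-12:
        raise ConfigurationError("failure scenario rates exceed 1")
    probs = np.array([1.0 - sum(p_fail)] + p_fail)
    scanners = list(scanner_mix)
    s_probs = np.array([scanner_mix[s] for s in scanners], dtype=float)
    s_probs = s_probs / s_probs.sum()

    base = base_config or PhantomConfig()
    rng = np.random.default_rng(seed)
    scenario_idx = rng.choice(len(_SCENARIOS), size=n, p=probs)
    scanner_idx = rng.choice(len(scanners), size=n, p=s_probs)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    samplers = {s: OffsetSampler(s, seed=int(rng.integers(0, 2**31 - 1)),
                                 config=base)
                for s in scanners}

    cohort: list[CohortDataset] = []
    for i in range(n):
        scenario = _SCENARIOS[scenario_idx[i]]
        scanner = scanners[scanner_idx[i]]
        coeffs = samplers[scanner].draw()
        cfg = replace(base, seed=int(child_seeds[i]),
                      background_coeffs=tuple(coeffs))
        if scenario == "fm1":
            cfg = replace(cfg, static_fraction_target=0.03)
        elif scenario == "fm2":
            cfg = replace(cfg, static_roughness_sd=6.0)
        elif scenario == "fm3":
            # over-fit bait: offset-free data -- any applied surface can
            # only inject error near the vessel
            cfg = replace(cfg, background_coeffs=(0.0,) * 5)
        in_vivo, phantom, truth = generate(cfg)
        cohort.append(CohortDataset(in_vivo=in_vivo, phantom=phantom,
                                    truth=truth, scenario=scenario,
                                    scanner=scanner, seed=int(child_seeds[i])))
    return cohort
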