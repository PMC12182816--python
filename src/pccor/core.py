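"""Core data model for 2D through-plane phase-contrast (PC) CINE series.

A PC CINE acquisition produces, for one imaging plane, a stack of magnitude
images and a stack of velocity images over the cardiac cycle.  The through-
plane velocity component is encoded in the image phase: a phase of +/-pi maps
to +/-VENC (the velocity-encoding limit, cm/s).  The plane itself sits
arbitrarily in the magnet frame, described by its pixel spacing, the position
of the first pixel and the direction cosines of the image rows and columns --
exactly the DICOM plane-geometry convention.

All physical positions handed to fitting code are in centimetres so velocity
gradients carry units of cm/s per cm; DICOM-facing attributes stay in
millimetres as stored in the header.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "StructuralError",
    "ConfigurationError",
    "SeriesRole",
    "PlaneGeometry",
    "PCSeries",
    "AlgoParams",
    "decode_velocity",
    "encode_velocity",
    "plane_coordinates",
    "fov_center_point",
    "fov_center_roi",
    "save_pc_series",
    "load_pc_series",
    "load_ground_truth_arrays",
]


class StructuralError(ValueError):
    """Inconsistent input structure (shape/geometry mismatch, bad stacks)."""


class ConfigurationError(ValueError):
    """Missing or invalid configuration (e.g. no VENC available)."""


class SeriesRole(str, Enum):
    IN_VIVO = "in_vivo"
    STATIC_PHANTOM = "static_phantom"


_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class PlaneGeometry:
    """Plane position and orientation of a PC slice in the magnet frame.

    Attributes
    ----------
    rows, cols : int
        Pixel grid size.
    pixel_spacing : (float, float)
        Row and column pixel spacing in mm (DICOM PixelSpacing order).
    origin : ndarray, shape (3,)
        Magnet-frame position of the centre of pixel (0, 0), in mm.
    row_dir, col_dir : ndarray, shape (3,)
        Unit direction cosines of increasing row index and column index.
    """

    rows: int
    cols: int
    pixel_spacing: tuple[float, float]
    origin: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "row_dir", np.asarray(self.row_dir, dtype=float))
        object.__setattr__(self, "col_dir", np.asarray(self.col_dir, dtype=float))
        if self.rows < 1 or self.cols < 1:
            raise StructuralError("grid must have at least one pixel per axis")
        for name in ("origin", "row_dir", "col_dir"):
            if getattr(self, name).shape != (3,):
                raise StructuralError(f"{name} must be a 3-vector")
        for name in ("row_dir", "col_dir"):
            n = np.linalg.norm(getattr(self, name))
            if abs(n - 1.0) > _ORTHO_TOL:
                raise StructuralError(f"{name} is not unit norm (|v|={n:.8f})")
        if abs(float(np.dot(self.row_dir, self.col_dir))) > _ORTHO_TOL:
            raise StructuralError("row_dir and col_dir are not orthogonal")
        if min(self.pixel_spacing) <= 0:
            raise StructuralError("pixel spacing must be positive")

    @property
    def normal(self) -> np.ndarray:
        """Slice normal (row_dir x col_dir), the through-plane direction."""
        return np.cross(self.row_dir, self.col_dir)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def pixel_area_cm2(self) -> float:
        sr, sc = self.pixel_spacing
        return sr * sc / 100.0


@dataclass
class PCSeries:
    """Paired magnitude/velocity CINE stacks with geometry and timing.

    ``magnitude`` and ``velocity`` are ``(n_phases, rows, cols)`` arrays;
    velocity is in cm/s (signed through-plane component, already decoded
    from phase), magnitude in arbitrary units >= 0.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    venc: float
    rr_duration: float  # ms
    geometry: PlaneGeometry
    series_role: SeriesRole = SeriesRole.IN_VIVO

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if isinstance(self.series_role, str):
            self.series_role = SeriesRole(self.series_role)
        if self.magnitude.ndim != 3:
            raise StructuralError("stacks must be (n_phases, rows, cols)")
        if self.magnitude.shape != self.velocity.shape:
            raise StructuralError(
                "magnitude and velocity stacks differ in shape: "
                f"{self.magnitude.shape} vs {self.velocity.shape}"
            )
        if self.magnitude.shape[0] < 2:
            raise StructuralError("a CINE series needs at least 2 phases")
        if self.magnitude.shape[1:] != self.geometry.shape:
            raise StructuralError("stack shape does not match geometry")
        if self.venc <= 0:
            raise ConfigurationError("VENC must be positive")
        if self.rr_duration <= 0:
            raise ConfigurationError("RR duration must be positive")

    def check_encoding_range(self) -> None:
        """Assert |velocity| <= VENC, as holds for freshly decoded data.

        Called by the loaders; corrected series may legitimately exceed the
        encoding range after surface subtraction.
        """
        if np.nanmax(np.abs(self.velocity)) > self.venc * (1 + 1e-9):
            raise StructuralError("decoded |velocity| exceeds VENC")

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[0]

    def with_velocity(self, velocity: np.ndarray) -> "PCSeries":
        """A copy of the series with a replaced velocity stack."""
        return replace(self, velocity=np.asarray(velocity, dtype=float))


@dataclass
class AlgoParams:
    """Tunable thresholds of the correction and triage pipeline.

    Velocity thresholds are cm/s, radii cm, fractions dimensionless.
    Defaults follow the published operating point of the algorithm.
    """

    mag_frac_threshold: float = 0.10      # static-tissue mean-magnitude floor
    vel_sd_threshold: float = 7.5         # static-tissue temporal-SD ceiling
    perp_offset_threshold: float = 0.6    # pre-fit plane offset trigger
    prune_iterations: int = 4             # outlier-rejection passes
    prune_k: float = 3.0                  # residual cut, multiples of robust SD
    prune_min_cut: float = 0.05           # absolute residual-cut floor, cm/s
    guard_roi_radius: float = 4.0         # over-fit guard ROI radius
    guard_velocity_threshold: float = 0.6  # guard mean-|surface| floor
    fm1_min_static_fraction: float = 0.05  # failure mode 1 static floor
    fm3_roi_static_fraction: float = 0.15  # FM3 ROI static-pixel fraction
    fm2_vnr_threshold: float = 3.0        # default FM2 rule VNR cut
    accuracy_threshold: float = 0.10      # net-flow accuracy criterion
    phantom_qc_threshold: float = 0.6     # phantom/in-vivo agreement limit
    quiescent_window_fraction: float = 0.2
    guard_use_abs: bool = True            # guard on mean |surface| vs |mean|
    fm3_mean_of_abs: bool = False         # FM3 on |mean v| (default) vs mean |v|

    def __post_init__(self) -> None:
        for name in ("mag_frac_threshold", "fm1_min_static_fraction",
                     "fm3_roi_static_fraction", "accuracy_threshold",
                     "quiescent_window_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        for name in ("vel_sd_threshold", "perp_offset_threshold", "prune_k",
                     "guard_roi_radius", "guard_velocity_threshold",
                     "fm2_vnr_threshold", "phantom_qc_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.prune_iterations < 0:
            raise ConfigurationError("prune_iterations must be >= 0")


# ---------------------------------------------------------------------------
# velocity encoding


def decode_velocity(phase: np.ndarray, venc: float) -> np.ndarray:
    """Map phase (radians) to velocity (cm/s): v = VENC * phi / pi."""
    return np.asarray(phase, dtype=float) * (venc / np.pi)


def encode_velocity(velocity: np.ndarray, venc: float) -> np.ndarray:
    """Inverse of :func:`decode_velocity` for in-range velocities."""
    return np.asarray(velocity, dtype=float) * (np.pi / venc)


# ---------------------------------------------------------------------------
# plane geometry


def plane_coordinates(geometry: PlaneGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnet-frame coordinates (cm) of every pixel centre.

    position(i, j) = origin + i * dr * row_dir + j * dc * col_dir, with the
    header geometry in mm converted to cm on output.  Returns the three
    coordinate images ``(x, y, z)`` each of shape (rows, cols).
    """
    sr, sc = geometry.pixel_spacing
    i = np.arange(geometry.rows, dtype=float)[:, None, None]
    j = np.arange(geometry.cols, dtype=float)[None, :, None]
    pos = (geometry.origin[None, None, :]
           + i * sr * geometry.row_dir[None, None, :]
           + j * sc * geometry.col_dir[None, None, :]) / 10.0
    return pos[..., 0], pos[..., 1], pos[..., 2]


def fov_center_point(geometry: PlaneGeometry) -> tuple[float, float]:
    """Continuous (row, col) pixel index of the FoV centre.

    For even grids this lies between pixels; distances are measured to the
    continuous point rather than snapping to a pixel.
    """
    return (geometry.rows - 1) / 2.0, (geometry.cols - 1) / 2.0


def fov_center_coordinates(geometry: PlaneGeometry) -> np.ndarray:
    """Magnet-frame position (cm) of the continuous FoV centre."""
    ci, cj = fov_center_point(geometry)
    sr, sc = geometry.pixel_spacing
    pos = (geometry.origin + ci * sr * geometry.row_dir
           + cj * sc * geometry.col_dir) / 10.0
    return pos


def _center_distance_cm(geometry: PlaneGeometry) -> np.ndarray:
    ci, cj = fov_center_point(geometry)
    sr, sc = geometry.pixel_spacing
    ii, jj = np.meshgrid(np.arange(geometry.rows), np.arange(geometry.cols),
                         indexing="ij")
    return np.hypot((ii - ci) * sr, (jj - cj) * sc) / 10.0


def fov_center_roi(geometry: PlaneGeometry, radius_cm: float) -> np.ndarray:
    """Boolean disc of the given physical radius centred at the FoV centre."""
    if radius_cm <= 0:
        raise ConfigurationError("ROI radius must be positive")
    sr, sc = geometry.pixel_spacing
    half_diag = 0.5 * np.hypot(geometry.rows * sr, geometry.cols * sc) / 10.0
    if radius_cm > half_diag:
        warnings.warn(
            f"ROI radius {radius_cm:.1f} cm exceeds half the FoV diagonal "
            f"({half_diag:.1f} cm); mask clipped to the image",
            stacklevel=2,
        )
    return _center_distance_cm(geometry) <= radius_cm


# ---------------------------------------------------------------------------
# archive IO (single-file .npz container)


def _geometry_meta(g: PlaneGeometry) -> dict:
    return {
        "rows": g.rows,
        "cols": g.cols,
        "pixel_spacing": list(g.pixel_spacing),
        "origin": g.origin.tolist(),
        "row_dir": g.row_dir.tolist(),
        "col_dir": g.col_dir.tolist(),
    }


def _geometry_from_meta(m: dict) -> PlaneGeometry:
    return PlaneGeometry(
        rows=int(m["rows"]),
        cols=int(m["cols"]),
        pixel_spacing=tuple(m["pixel_spacing"]),
        origin=np.array(m["origin"]),
        row_dir=np.array(m["row_dir"]),
        col_dir=np.array(m["col_dir"]),
    )


def save_pc_series(path: str | Path, series: PCSeries,
                   ground_truth: dict[str, np.ndarray] | None = None) -> Path:
    """Write a series (and optional ground-truth block) to one .npz archive.

    The round trip through :func:`load_pc_series` is bit exact: arrays are
    stored as float64 without rescaling, metadata as a JSON sidecar entry.
    """
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = {
        "venc": series.venc,
        "rr_duration": series.rr_duration,
        "series_role": series.series_role.value,
        "geometry": _geometry_meta(series.geometry),
    }
    payload = {
        "magnitude": series.magnitude,
        "velocity": series.velocity,
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if ground_truth:
        for key, arr in ground_truth.items():
            payload[f"truth__{key}"] = np.asarray(arr)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **payload)
    return path


def _load_archive(path: Path) -> PCSeries:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        series = PCSeries(
            magnitude=data["magnitude"],
            velocity=data["velocity"],
            venc=float(meta["venc"]),
            rr_duration=float(meta["rr_duration"]),
            geometry=_geometry_from_meta(meta["geometry"]),
            series_role=SeriesRole(meta["series_role"]),
        )
    return series


def load_ground_truth_arrays(path: str | Path) -> dict[str, np.ndarray]:
    """Ground-truth block stored alongside a simulated series, if any."""
    out: dict[str, np.ndarray] = {}
    with np.load(Path(path)) as data:
        for key in data.files:
            if key.startswith("truth__"):
                out[key[len("truth__"):]] = data[key]
    return out


# ---------------------------------------------------------------------------
# DICOM IO

_PHASE_IMAGE_TYPES = {"P", "PHASE", "VELOCITY", "PHASE MAP"}
_GE_VENC_TAG = (0x0019, 0x10CC)  # GE private VENC, mm/s


def _is_phase_dataset(ds) -> bool:
    image_type = [str(t).upper() for t in getattr(ds, "ImageType", [])]
    return any(t in _PHASE_IMAGE_TYPES for t in image_type)


def _frame_geometry(ds) -> PlaneGeometry:
    iop = np.array([float(v) for v in ds.ImageOrientationPatient])
    return PlaneGeometry(
        rows=int(ds.Rows),
        cols=int(ds.Columns),
        # DICOM PixelSpacing is (row spacing, column spacing)
        pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
        origin=np.array([float(v) for v in ds.ImagePositionPatient]),
        # IOP stores the direction of increasing column first, then row
        row_dir=iop[3:6],
        col_dir=iop[0:3],
    )


def _rescaled_pixels(ds) -> np.ndarray:
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def _load_dicom(path: Path, venc: float | None,
                phase_scale: float) -> PCSeries:
    import pydicom

    files = sorted(p for p in path.rglob("*") if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:
            continue
    if not datasets:
        raise StructuralError(f"no readable DICOM files under {path}")

    by_series: dict[str, list] = {}
    for ds in datasets:
        by_series.setdefault(str(ds.SeriesInstanceUID), []).append(ds)
    if len(by_series) != 2:
        raise StructuralError(
            f"expected one magnitude and one phase series, found "
            f"{len(by_series)} series"
        )
    groups = list(by_series.values())
    phase_group = next((g for g in groups if _is_phase_dataset(g[0])), None)
    if phase_group is None:
        raise StructuralError("no phase/velocity series identified by ImageType")
    mag_group = groups[0] if groups[1] is phase_group else groups[1]
    if len(mag_group) != len(phase_group):
        raise StructuralError("magnitude and phase series frame counts differ")

    for g in (mag_group, phase_group):
        g.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))

    geom = _frame_geometry(mag_group[0])
    geom_phase = _frame_geometry(phase_group[0])
    for a, b in (
        (geom.pixel_spacing, geom_phase.pixel_spacing),
        (geom.origin, geom_phase.origin),
        (geom.row_dir, geom_phase.row_dir),
        (geom.col_dir, geom_phase.col_dir),
    ):
        if not np.allclose(np.asarray(a), np.asarray(b), atol=1e-6):
            raise StructuralError("magnitude/phase plane geometry mismatch")

    if venc is None:
        tag = phase_group[0].get(_GE_VENC_TAG)
        if tag is not None:
            venc = float(tag.value) / 10.0  # mm/s -> cm/s
        else:
            raise ConfigurationError(
                "VENC not present in the DICOM header; pass venc= explicitly"
            )

    magnitude = np.stack([_rescaled_pixels(ds) for ds in mag_group])
    phase = np.stack([_rescaled_pixels(ds) for ds in phase_group]) * phase_scale
    velocity = decode_velocity(phase, venc)

    rr = getattr(phase_group[0], "NominalInterval", None)
    if rr in (None, "", 0):
        hr = getattr(phase_group[0], "HeartRate", None)
        if hr:
            rr = 60000.0 / float(hr)
        else:
            warnings.warn("no cardiac timing in header; assuming RR = 1000 ms",
                          stacklevel=2)
            rr = 1000.0
    series = PCSeries(magnitude=magnitude, velocity=velocity, venc=float(venc),
                      rr_duration=float(rr), geometry=geom)
    series.check_encoding_range()
    return series


def load_pc_series(path: str | Path, format: str = "archive", *,
                   venc: float | None = None,
                   phase_scale: float = 1.0) -> PCSeries:
    """Load a PC series from a simulator archive or a DICOM directory.

    Parameters
    ----------
    path:
        Archive file (.npz) or a directory containing exactly one magnitude
        and one phase DICOM series (classic, one file per frame).
    format:
        ``"archive"`` or ``"dicom"``.
    venc:
        Velocity-encoding limit in cm/s.  For DICOM it overrides (or supplies,
        when the private tag is absent) the header value.
    phase_scale:
        Linear factor mapping rescaled phase pixel values to radians; the
        default assumes RescaleSlope/Intercept already yield radians.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "archive":
        return _load_archive(path)
    if format == "dicom":
        return _load_dicom(path, venc, phase_scale)
    raise ConfigurationError(f"unknown format {format!r}")
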