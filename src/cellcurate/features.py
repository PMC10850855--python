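"""The 26 morphological and phase-contrast intensity features.

Phase-contrast images of bacteria show a dark cell body surrounded by a
bright halo. Before any intensity feature is measured the frame is inverted
(cells become bright) and background-subtracted, so that a perfectly empty
region averages to zero and "more cell" means "more signal".

Geometry features are computed from the mesh (lengths, widths, volume,
surface area) and from the derived contour (area, perimeter, shape indices,
curvature). Intensity features sample the preprocessed image along the
contour, an expanded/eroded copy of it, the midline, and over the interior.

All lengths are multiplied by ``pixel_size`` (µm per pixel, default 1.0 so
uncalibrated features come out in pixel units), areas by its square, volumes
by its cube.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew
from shapely.geometry import Polygon as _ShapelyPolygon

from .exceptions import BoundaryError, ValidationError
from .mesh import (
    CellMesh,
    CellRecord,
    Contour,
    Midline,
    _dedup_consecutive,
    contour_from_mesh,
    midline_from_mesh,
)

logger = logging.getLogger(__name__)

#: Canonical feature manifest: name -> (unit, one-line description).
FEATURE_INFO: dict[str, tuple[str, str]] = {
    "cell_length": ("um", "sum of midpoint-to-midpoint step lengths along the mesh"),
    "cell_width": ("um", "mean of the top one-third of mesh segment widths"),
    "cell_area": ("um^2", "polygon (shoelace) area of the cell contour"),
    "cell_volume": ("um^3", "trapezoidal sum of per-segment cylinder volumes"),
    "cell_surface_area": ("um^2", "trapezoidal sum of per-segment cylinder lateral areas"),
    "max_contour_curvature": ("1/um", "maximum signed curvature along the contour"),
    "min_contour_curvature": ("1/um", "minimum signed curvature along the contour"),
    "mean_contour_curvature": ("1/um", "mean signed curvature along the contour"),
    "cell_perimeter": ("um", "closed-loop sum of consecutive contour vertex distances"),
    "circularity": ("dimensionless", "4*pi*area / perimeter^2"),
    "compactness": ("dimensionless", "perimeter^2 / area"),
    "sphericity": ("dimensionless", "2*sqrt(pi*area) / perimeter"),
    "total_phaco_intensity": ("A.U.", "sum of preprocessed intensities inside the contour"),
    "max_phaco_intensity": ("A.U.", "maximum preprocessed intensity inside the contour"),
    "mean_phaco_intensity": ("A.U.", "mean preprocessed intensity inside the contour"),
    "phaco_contour_intensity_peaks": ("count", "local maxima of the contour intensity profile"),
    "max_contour_intensity": ("A.U.", "maximum intensity along the contour"),
    "min_contour_intensity": ("A.U.", "minimum intensity along the contour"),
    "mean_contour_intensity": ("A.U.", "mean intensity along the contour"),
    "max_contour_intensity_variability": ("A.U.", "max rolling std (window 10) of contour intensity"),
    "mean_contour_intensity_variability": ("A.U.", "mean rolling std (window 10) of contour intensity"),
    "midline_intensity_skewness": ("dimensionless", "skewness of intensities along the midline"),
    "midline_intensity_kurtosis": ("dimensionless", "excess kurtosis of intensities along the midline"),
    "max_expanded_contour_intensity": ("A.U.", "maximum intensity along the contour expanded by 2 px"),
    "mean_expanded_contour_intensity": ("A.U.", "mean intensity along the contour expanded by 2 px"),
    "mean_cell_edge_gradient": ("A.U.", "mean (eroded - expanded) contour intensity difference"),
}

FEATURE_NAMES: list[str] = list(FEATURE_INFO)
assert len(FEATURE_NAMES) == 26

META_COLUMNS = ["frame", "cell_id", "contour"]


def describe_features() -> list[dict[str, str]]:
    """Manifest of the 26 features with units and descriptions."""
    return [
        {"name": name, "unit": unit, "description": desc}
        for name, (unit, desc) in FEATURE_INFO.items()
    ]


# ---------------------------------------------------------------------------
# Frame preprocessing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PreprocessedImage:
    """Inverted, background-subtracted intensity grid for one frame."""

    data: np.ndarray
    background_value: float

    @property
    def shape(self):
        return self.data.shape


def _interior_pixel_centers(polygon, shape) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) integer pixel centres inside or on the polygon, clipped to image."""
    minx, miny, maxx, maxy = polygon.bounds
    h, w = shape
    x0 = max(0, math.ceil(minx - 1e-9))
    x1 = min(w - 1, math.floor(maxx + 1e-9))
    y0 = max(0, math.ceil(miny - 1e-9))
    y1 = min(h - 1, math.floor(maxy + 1e-9))
    if x1 < x0 or y1 < y0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    xs, ys = xs.ravel(), ys.ravel()
    shapely.prepare(polygon)
    inside = shapely.intersects_xy(polygon, xs, ys)
    return xs[inside], ys[inside]


def _filled_polygon(vertices: np.ndarray):
    poly = _ShapelyPolygon(vertices)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def preprocess_frame(image: np.ndarray, meshes=()) -> PreprocessedImage:
    """Invert a phase-contrast frame and subtract its background.

    The output is ``(max(image) - image) - background`` where the background
    is the mean inverted intensity outside the union of all filled cell
    contours of the frame (or over the whole frame when no meshes are given).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValidationError("frame image must be a non-empty 2-D array")
    inverted = image.max() - image
    cell_mask = np.zeros(image.shape, dtype=bool)
    for mesh in meshes:
        verts = np.vstack([mesh.left, mesh.right[::-1]])
        verts = _dedup_consecutive(verts)
        if len(verts) < 3:
            continue
        poly = _filled_polygon(verts)
        if poly.is_empty:
            continue
        xs, ys = _interior_pixel_centers(poly, image.shape)
        cell_mask[ys, xs] = True
    outside = ~cell_mask
    if not outside.any():
        raise ValidationError("cell masks cover the entire frame; background undefined")
    background = float(inverted[outside].mean())
    return PreprocessedImage(inverted - background, background)


def sample_image(pimage: PreprocessedImage, points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the preprocessed frame at (x, y) points."""
    pts = np.asarray(points, dtype=float)
    h, w = pimage.shape
    eps = 1e-9
    if (
        pts[:, 0].min() < -eps
        or pts[:, 0].max() > w - 1 + eps
        or pts[:, 1].min() < -eps
        or pts[:, 1].max() > h - 1 + eps
    ):
        raise BoundaryError("sampling points fall outside the image")
    coords = np.vstack([pts[:, 1], pts[:, 0]])  # map_coordinates wants (row, col)
    return ndimage.map_coordinates(pimage.data, coords, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryProfile:
    """Step lengths, segment widths and the midline of one mesh, in µm."""

    step_lengths: np.ndarray
    widths: np.ndarray
    midline: Midline


def geometry_profile(mesh: CellMesh, pixel_size: float = 1.0) -> GeometryProfile:
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be positive")
    midline = midline_from_mesh(mesh)
    steps = np.linalg.norm(np.diff(midline.points, axis=0), axis=1) * pixel_size
    widths = mesh.widths * pixel_size
    return GeometryProfile(steps, widths, midline)


def cell_length(profile: GeometryProfile) -> float:
    """Total midline length: the sum of the per-segment step lengths."""
    return float(profile.step_lengths.sum())


def cell_width(profile: GeometryProfile) -> float:
    """Mean of the top one-third of segment widths (at least one width)."""
    widths = np.sort(profile.widths)[::-1]
    n = len(widths)
    k = max(1, int(math.floor(n / 3 + 0.5)))  # round half away from zero
    return float(widths[:k].mean())


def cell_area(contour: Contour, pixel_size: float = 1.0) -> float:
    area = abs(contour.signed_area) * pixel_size**2
    if area <= 0:
        raise ValidationError("degenerate contour has zero area")
    return float(area)


def cell_perimeter(contour: Contour, pixel_size: float = 1.0) -> float:
    verts = contour.vertices
    closed = np.vstack([verts, verts[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum() * pixel_size)


def shape_indices(area: float, perimeter: float, *, sphericity_formula: str = "sqrt_circularity"):
    """(circularity, compactness, sphericity) from area and perimeter.

    circularity = 4*pi*A/P^2 (1 for a circle), compactness = P^2/A, and
    sphericity = 2*sqrt(pi*A)/P = sqrt(circularity). ``sphericity_formula``
    is a hook for alternative conventions ("sqrt_circularity" only, for now).
    """
    if area <= 0 or perimeter <= 0:
        raise ValidationError("area and perimeter must be positive")
    if sphericity_formula != "sqrt_circularity":
        raise ValidationError(f"unknown sphericity formula: {sphericity_formula}")
    circularity = 4.0 * math.pi * area / perimeter**2
    compactness = perimeter**2 / area
    sphericity = 2.0 * math.sqrt(math.pi * area) / perimeter
    return circularity, compactness, sphericity


def cell_volume(profile: GeometryProfile) -> float:
    """Per-segment cylinder volume by the trapezoidal rule, summed."""
    r = profile.widths / 2.0
    r2 = (r[:-1] ** 2 + r[1:] ** 2) / 2.0
    return float(np.sum(math.pi * r2 * profile.step_lengths))


def cell_surface_area(profile: GeometryProfile) -> float:
    """Per-segment cylinder lateral surface, trapezoidal in the radius."""
    r = profile.widths / 2.0
    rm = (r[:-1] + r[1:]) / 2.0
    return float(np.sum(2.0 * math.pi * rm * profile.step_lengths))


def curvature_stats(contour, pixel_size: float = 1.0) -> tuple[float, float, float]:
    """(max, min, mean) signed curvature along a closed contour.

    Per-vertex plane-curve curvature k = (x'y'' - y'x'') / (x'^2 + y'^2)^1.5
    with wrap-around central differences. Counter-clockwise traversal (in the
    shoelace sense) gives positive curvature on convex arcs; reversing the
    traversal negates every value.
    """
    verts = contour.vertices if isinstance(contour, Contour) else np.asarray(contour, float)
    verts = _dedup_consecutive(verts)
    if len(verts) < 5:
        raise ValidationError("curvature needs a contour with >= 5 distinct vertices")
    nxt = np.roll(verts, -1, axis=0)
    prv = np.roll(verts, 1, axis=0)
    d1 = (nxt - prv) / 2.0
    d2 = nxt - 2.0 * verts + prv
    speed2 = np.sum(d1**2, axis=1)
    if np.any(speed2 < 1e-24):
        raise ValidationError("zero tangent vector on contour (repeated vertices)")
    kappa = (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]) / speed2**1.5
    kappa = kappa / pixel_size
    return float(kappa.max()), float(kappa.min()), float(kappa.mean())


def offset_contour(contour: Contour, offset_px: float) -> Contour:
    """Displace every vertex along its outward normal by ``offset_px``.

    Positive offsets expand, negative erode. Vertex count and ordering are
    preserved so offset contours stay in one-to-one correspondence with the
    original — required for paired edge-gradient sampling.
    """
    verts = contour.vertices
    if len(_dedup_consecutive(verts)) != len(verts):
        raise ValidationError("contour has repeated consecutive vertices")
    d1 = (np.roll(verts, -1, axis=0) - np.roll(verts, 1, axis=0)) / 2.0
    norms = np.linalg.norm(d1, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValidationError("zero tangent vector on contour")
    tangent = d1 / norms
    orient = 1.0 if contour.signed_area >= 0 else -1.0
    outward = orient * np.column_stack([tangent[:, 1], -tangent[:, 0]])
    moved = verts + offset_px * outward
    result = Contour(moved, normalize=False)
    if offset_px < 0:
        flipped = np.sign(result.signed_area) != np.sign(contour.signed_area)
        if flipped or not result.is_simple:
            raise ValidationError(
                "erosion collapsed the contour into self-intersection"
            )
    return result


# ---------------------------------------------------------------------------
# Intensity features
# ---------------------------------------------------------------------------


def contour_profile(pimage: PreprocessedImage, contour: Contour) -> np.ndarray:
    """Preprocessed intensity at each contour vertex, in traversal order."""
    return sample_image(pimage, contour.vertices)


def contour_stats(intensities) -> tuple[float, float, float]:
    vals = np.asarray(intensities, dtype=float)
    if vals.size == 0:
        raise ValidationError("empty intensity sequence")
    return float(vals.max()), float(vals.min()), float(vals.mean())


def contour_peak_count(intensities) -> int:
    """Strict local maxima (plateaus once, at their midpoint), linear traversal."""
    vals = np.asarray(intensities, dtype=float)
    if vals.size == 0:
        raise ValidationError("empty intensity sequence")
    peaks, _ = find_peaks(vals)
    return int(len(peaks))


def contour_variability(intensities, window: int = 10) -> tuple[float, float]:
    """(max, mean) rolling sample standard deviation over full windows."""
    vals = np.asarray(intensities, dtype=float)
    if vals.size < window:
        raise ValidationError(f"need >= {window} samples for rolling std")
    stds = pd.Series(vals).rolling(window).std(ddof=1).to_numpy()[window - 1 :]
    return float(np.nanmax(stds)), float(np.nanmean(stds))


def midline_moments(pimage: PreprocessedImage, midline: Midline) -> tuple[float, float]:
    """Fisher skewness and excess kurtosis of midline intensities.

    Bias-uncorrected moment estimators; a (near-)constant profile returns
    (0, 0) instead of dividing by a vanishing variance.
    """
    if midline.points.shape[0] < 4:
        raise ValidationError("midline needs >= 4 points")
    vals = sample_image(pimage, midline.points)
    if np.var(vals) < 1e-12:
        return 0.0, 0.0
    return (
        float(_skew(vals, bias=True)),
        float(_kurtosis(vals, fisher=True, bias=True)),
    )


def expanded_contour_stats(
    pimage: PreprocessedImage, contour: Contour, offset_px: float = 2.0
) -> tuple[float, float]:
    """(max, mean) intensity along the contour expanded outward."""
    profile = contour_profile(pimage, offset_contour(contour, offset_px))
    mx, _, mean = contour_stats(profile)
    return mx, mean


def edge_gradient(
    pimage: PreprocessedImage, contour: Contour, offset_px: float = 2.0
) -> float:
    """Mean paired difference (eroded - expanded) of contour intensities.

    Bright (inverted) cells on a dark background give a positive gradient;
    the sharper the edge, the larger the value.
    """
    inner = contour_profile(pimage, offset_contour(contour, -offset_px))
    outer = contour_profile(pimage, offset_contour(contour, +offset_px))
    return float(np.mean(inner - outer))


def interior_intensity_stats(
    pimage: PreprocessedImage, contour: Contour
) -> tuple[float, float, float]:
    """(total, max, mean) intensity over pixel centres inside/on the contour."""
    poly = _ShapelyPolygon(contour.vertices)
    xs, ys = _interior_pixel_centers(poly, pimage.shape)
    if xs.size == 0:
        raise ValidationError("contour contains no pixel centres")
    vals = pimage.data[ys, xs]
    return float(vals.sum()), float(vals.max()), float(vals.mean())


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def extract_features(
    record: CellRecord,
    pimage: PreprocessedImage,
    pixel_size: float = 1.0,
    *,
    expand_px: float = 2.0,
    variability_window: int = 10,
    sphericity_formula: str = "sqrt_circularity",
) -> tuple[dict, np.ndarray | None, str | None]:
    """Compute all 26 features for one record.

    Returns ``(features, contour_vertices, failure_reason)``. A record that
    fails any sub-step (off-image mesh, degenerate geometry, ...) yields an
    all-NaN feature dict and the reason; it never raises.
    """
    try:
        contour = contour_from_mesh(record.mesh, record=(record.frame, record.cell_id))
        profile = geometry_profile(record.mesh, pixel_size)
        length = cell_length(profile)
        width = cell_width(profile)
        area = cell_area(contour, pixel_size)
        perimeter = cell_perimeter(contour, pixel_size)
        circ, comp, spher = shape_indices(
            area, perimeter, sphericity_formula=sphericity_formula
        )
        volume = cell_volume(profile)
        surface = cell_surface_area(profile)
        kmax, kmin, kmean = curvature_stats(contour, pixel_size)

        prof = contour_profile(pimage, contour)
        imax, imin, imean = contour_stats(prof)
        peaks = contour_peak_count(prof)
        vmax, vmean = contour_variability(prof, variability_window)
        skewness, kurt = midline_moments(pimage, profile.midline)
        emax, emean = expanded_contour_stats(pimage, contour, expand_px)
        gradient = edge_gradient(pimage, contour, expand_px)
        total, pmax, pmean = interior_intensity_stats(pimage, contour)
    except ValidationError as exc:
        nan_features = dict.fromkeys(FEATURE_NAMES, float("nan"))
        return nan_features, None, str(exc)

    features = {
        "cell_length": length,
        "cell_width": width,
        "cell_area": area,
        "cell_volume": volume,
        "cell_surface_area": surface,
        "max_contour_curvature": kmax,
        "min_contour_curvature": kmin,
        "mean_contour_curvature": kmean,
        "cell_perimeter": perimeter,
        "circularity": circ,
        "compactness": comp,
        "sphericity": spher,
        "total_phaco_intensity": total,
        "max_phaco_intensity": pmax,
        "mean_phaco_intensity": pmean,
        "phaco_contour_intensity_peaks": peaks,
        "max_contour_intensity": imax,
        "min_contour_intensity": imin,
        "mean_contour_intensity": imean,
        "max_contour_intensity_variability": vmax,
        "mean_contour_intensity_variability": vmean,
        "midline_intensity_skewness": skewness,
        "midline_intensity_kurtosis": kurt,
        "max_expanded_contour_intensity": emax,
        "mean_expanded_contour_intensity": emean,
        "mean_cell_edge_gradient": gradient,
    }
    return features, contour.vertices, None


class CellFeatureExtractor:
    """Transformer-style feature extractor over (records, frame images).

    Follows the scikit-learn estimator protocol (``get_params`` /
    ``set_params``; ``fit`` validates and returns self) but ``transform``
    takes cell records plus frame images rather than a 2-D array, so it sits
    upstream of, not inside, an sklearn Pipeline.

    Parameters
    ----------
    pixel_size : float
        Microns per pixel; 1.0 leaves features in pixel units.
    expand_px : float
        Outward/inward offset in pixels for the expanded-contour and
        edge-gradient features.
    variability_window : int
        Rolling-std window along the contour intensity profile.
    """

    def __init__(
        self,
        pixel_size: float = 1.0,
        expand_px: float = 2.0,
        variability_window: int = 10,
        sphericity_formula: str = "sqrt_circularity",
    ):
        self.pixel_size = pixel_size
        self.expand_px = expand_px
        self.variability_window = variability_window
        self.sphericity_formula = sphericity_formula

    # -- sklearn protocol ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "expand_px": self.expand_px,
            "variability_window": self.variability_window,
            "sphericity_formula": self.sphericity_formula,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, records=None, images=None):
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        return self

    def transform(self, records, images) -> pd.DataFrame:
        """Feature table for a batch of records.

        ``images`` maps frame index -> raw frame; each frame is preprocessed
        once with all of its meshes. Failed records are retained as all-NaN
        rows; the failure count is stored on ``failure_count_``.
        """
        self.fit()
        records = list(records)
        by_frame: dict[int, list[CellRecord]] = {}
        for rec in records:
            by_frame.setdefault(rec.frame, []).append(rec)
        missing = sorted(f for f in by_frame if f not in images)
        if missing:
            raise ValidationError(f"no image for frames {missing}")
        pimages = {
            f: preprocess_frame(images[f], [r.mesh for r in recs])
            for f, recs in by_frame.items()
        }
        rows, failures = [], 0
        for rec in records:
            feats, contour, reason = extract_features(
                rec,
                pimages[rec.frame],
                self.pixel_size,
                expand_px=self.expand_px,
                variability_window=self.variability_window,
                sphericity_formula=self.sphericity_formula,
            )
            if reason is not None:
                failures += 1
                logger.warning(
                    "features failed for (frame=%d, cell_id=%d): %s",
                    rec.frame,
                    rec.cell_id,
                    reason,
                )
            rows.append(
                {"frame": rec.frame, "cell_id": rec.cell_id, "contour": contour, **feats}
            )
        self.failure_count_ = failures
        return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_NAMES)

    def fit_transform(self, records, images) -> pd.DataFrame:
        return self.fit(records, images).transform(records, images)
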