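"""Seeded synthetic phase-contrast scenes with ground-truth meshes.

Rod-shaped bacteria are modelled as 2-D capsules (a rectangle capped by two
half-discs). Rendering is a stylized phase-contrast model — dark cell lumen,
bright Gaussian halo ring just outside the edge, additive Gaussian noise on a
flat background — not an optics simulation; it exists to give every geometry
and intensity feature a controlled, reproducible signal.

Bad detections reproduce the classic segmentation failure modes:

* ``truncated``  — only a contiguous 40-70% run of mesh rows is kept;
* ``shifted``    — the whole mesh is translated 2-5 px off the cell;
* ``merged``     — the mesh splices into the mesh of an end-to-end neighbor
                   (a missed division);
* ``adjacent``   — the mesh is correct but a second cell is rendered within
                   ~1 px, corrupting width and edge-intensity measurements.

A record's truth class is *bad* iff its defect type is not ``none``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString

from .exceptions import ValidationError
from .mesh import CellMesh, CellRecord, contour_from_mesh

DEFECT_TYPES = ("truncated", "shifted", "merged", "adjacent")


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for synthetic scene generation (units: px, A.U.)."""

    image_size: tuple[int, int] = (512, 512)
    cells_per_frame: int = 20
    length_range: tuple[float, float] = (25.0, 55.0)
    width_range: tuple[float, float] = (9.0, 13.0)
    background_level: float = 10000.0
    depression_depth: float = 3000.0
    halo_amplitude: float = 1500.0
    halo_offset: float = 2.0
    halo_width: float = 1.5
    edge_softness: float = 0.8
    noise_sd: float = 150.0
    #: fractions of truncated / shifted / merged / adjacent defects
    defect_fractions: tuple[float, float, float, float] = (0.1, 0.1, 0.1, 0.1)
    min_gap: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if min(self.length_range) <= 0 or min(self.width_range) <= 0:
            raise ValidationError("length and width ranges must be positive")
        if any(f < 0 for f in self.defect_fractions) or sum(self.defect_fractions) > 1:
            raise ValidationError("defect fractions must be in [0, 1] and sum <= 1")
        if self.width_range[1] >= self.length_range[0]:
            raise ValidationError("cells must be longer than they are wide")


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one record."""

    frame: int
    cell_id: int
    is_good: bool
    defect_type: str  # none | truncated | shifted | merged | adjacent


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray
    records: list[CellRecord]
    truth: list[CellTruth]

    def __post_init__(self):
        if len(self.records) != len(self.truth):
            raise ValidationError("one truth entry per record required")
        for t in self.truth:
            if t.is_good != (t.defect_type == "none"):
                raise ValidationError("truth class must be bad iff defect_type != none")


@dataclass(frozen=True)
class _Capsule:
    """Axis-aligned description of one rendered cell."""

    center: np.ndarray  # (x, y)
    axis: np.ndarray  # unit vector
    length: float  # tip-to-tip
    width: float

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def half_core(self) -> float:
        """Half-length of the straight (cylindrical) part."""
        return self.length / 2.0 - self.radius

    @property
    def segment(self) -> np.ndarray:
        """(2, 2) endpoints of the core axis segment (cap centres)."""
        return np.array(
            [
                self.center - self.half_core * self.axis,
                self.center + self.half_core * self.axis,
            ]
        )


def capsule_mesh(
    center, theta: float, length: float, width: float, n_rows: int | None = None
) -> CellMesh:
    """Analytic capsule mesh: rows sampled uniformly along the axis.

    Pole rows coincide (zero width) at the capsule tips.
    """
    center = np.asarray(center, dtype=float)
    u = np.array([math.cos(theta), math.sin(theta)])
    nrm = np.array([-u[1], u[0]])
    r = width / 2.0
    a = length / 2.0 - r
    if a < 0:
        raise ValidationError("capsule length must exceed its width")
    if n_rows is None:
        n_rows = max(11, int(round(length)) + 1)
    s = np.linspace(-length / 2.0, length / 2.0, n_rows)
    h = np.where(
        np.abs(s) <= a, r, np.sqrt(np.maximum(r**2 - (np.abs(s) - a) ** 2, 0.0))
    )
    mid = center[None, :] + s[:, None] * u[None, :]
    left = mid + h[:, None] * nrm[None, :]
    right = mid - h[:, None] * nrm[None, :]
    return CellMesh(np.hstack([left, right]))


def _render_stamp(capsule: _Capsule, config: SceneConfig):
    """Additive intensity stamp of one cell on its bounding box.

    Returns ``(x0, y0, stamp)`` where ``stamp[y, x]`` is the raw-intensity
    contribution at pixel (x0 + x, y0 + y).
    """
    pad = capsule.radius + config.halo_offset + 4 * config.halo_width
    p0, p1 = capsule.segment
    x0 = int(math.floor(min(p0[0], p1[0]) - pad))
    x1 = int(math.ceil(max(p0[0], p1[0]) + pad))
    y0 = int(math.floor(min(p0[1], p1[1]) - pad))
    y1 = int(math.ceil(max(p0[1], p1[1]) + pad))
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = np.stack([xs, ys], axis=-1).astype(float)

    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    rel = pts - p0
    t = np.clip((rel @ seg) / max(seg_len2, 1e-12), 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    dist = np.linalg.norm(pts - closest, axis=-1) - capsule.radius

    interior = 1.0 / (1.0 + np.exp(np.clip(dist / config.edge_softness, -50, 50)))
    halo = np.exp(-((dist - config.halo_offset) ** 2) / (2.0 * config.halo_width**2))
    stamp = -config.depression_depth * interior + config.halo_amplitude * halo
    return x0, y0, stamp


def _add_stamp(image: np.ndarray, x0: int, y0: int, stamp: np.ndarray) -> None:
    h, w = image.shape
    sy = slice(max(0, y0), min(h, y0 + stamp.shape[0]))
    sx = slice(max(0, x0), min(w, x0 + stamp.shape[1]))
    image[sy, sx] += stamp[sy.start - y0 : sy.stop - y0, sx.start - x0 : sx.stop - x0]


def generate_cell(config: SceneConfig, rng: np.random.Generator):
    """Draw one random capsule cell; returns (truth mesh, rendered stamp).

    The stamp is ``(x0, y0, array)`` — the additive raw-intensity
    contribution of the cell on its bounding box.
    """
    capsule = _random_capsule(config, rng)
    mesh = capsule_mesh(capsule.center, math.atan2(capsule.axis[1], capsule.axis[0]),
                        capsule.length, capsule.width)
    return mesh, _render_stamp(capsule, config)


def _random_capsule(
    config: SceneConfig,
    rng: np.random.Generator,
    existing: list[_Capsule] | None = None,
    max_tries: int = 200,
) -> _Capsule:
    h, w = config.image_size
    for _ in range(max_tries):
        length = rng.uniform(*config.length_range)
        width = rng.uniform(*config.width_range)
        theta = rng.uniform(0, math.pi)
        margin = length / 2.0 + width / 2.0 + config.halo_offset + 4 * config.halo_width + 3
        if 2 * margin >= min(h, w):
            raise ValidationError("cells do not fit the configured image size")
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        cap = _Capsule(
            np.array([cx, cy]), np.array([math.cos(theta), math.sin(theta)]), length, width
        )
        if existing is None or _clearance_ok(cap, existing, config.min_gap):
            return cap
    raise ValidationError("could not place a cell without overlap")


def _clearance_ok(cap: _Capsule, existing: list[_Capsule], gap: float) -> bool:
    line = LineString(cap.segment)
    for other in existing:
        d = line.distance(LineString(other.segment))
        if d < cap.radius + other.radius + gap:
            return False
    return True


def _neighbor_capsule(
    cap: _Capsule, mode: str, config: SceneConfig, rng: np.random.Generator
) -> _Capsule:
    """A second cell placed deliberately close to ``cap``.

    ``side``: parallel, within ~1 px of the first cell's flank (adjacent
    defect). ``end``: end-to-end beyond a pole with a small gap (merged
    defect / missed division).
    """
    length = rng.uniform(*config.length_range)
    width = rng.uniform(*config.width_range)
    nrm = np.array([-cap.axis[1], cap.axis[0]])
    if mode == "side":
        side = rng.choice([-1.0, 1.0])
        offset = cap.radius + width / 2.0 + rng.uniform(0.5, 1.0)
        center = cap.center + side * offset * nrm + rng.uniform(-3, 3) * cap.axis
        axis = cap.axis if rng.random() < 0.8 else -cap.axis
        return _Capsule(center, axis, length, width)
    # end-to-end, slightly tilted
    tilt = rng.uniform(-0.25, 0.25)
    c, s = math.cos(tilt), math.sin(tilt)
    axis = np.array([cap.axis[0] * c - cap.axis[1] * s, cap.axis[0] * s + cap.axis[1] * c])
    gap = rng.uniform(0.5, 2.0)
    center = cap.center + (cap.length / 2.0 + gap + length / 2.0) * axis
    return _Capsule(center, axis, length, width)


def perturb_detection(
    mesh: CellMesh,
    defect_type: str,
    rng: np.random.Generator,
    neighbor_mesh: CellMesh | None = None,
    max_tries: int = 10,
) -> CellMesh:
    """Corrupt a correct mesh into a defective detection.

    ``truncated`` keeps a random contiguous 40-70% run of rows, ``shifted``
    translates the mesh 2-5 px in a random direction, ``merged`` splices the
    first part of the mesh onto the tail of a neighboring cell's mesh (a
    translated copy of the input when no neighbor is supplied). Resamples up
    to ``max_tries`` if the perturbed contour self-intersects.
    """
    if defect_type not in ("truncated", "shifted", "merged"):
        raise ValidationError(
            f"defect_type must be truncated/shifted/merged, got {defect_type!r}"
        )
    last_error = None
    for _ in range(max_tries):
        if defect_type == "truncated":
            n = mesh.n_rows
            keep = max(4, int(round(rng.uniform(0.4, 0.7) * n)))
            start = int(rng.integers(0, n - keep + 1))
            candidate = CellMesh(mesh.coords[start : start + keep])
        elif defect_type == "shifted":
            dist = rng.uniform(2.0, 5.0)
            angle = rng.uniform(0, 2 * math.pi)
            candidate = mesh.translated(dist * math.cos(angle), dist * math.sin(angle))
        else:  # merged
            other = neighbor_mesh
            if other is None:
                poles = mesh.coords[-1, :2] - mesh.coords[0, :2]
                step = poles / max(np.linalg.norm(poles), 1e-9)
                shift = (np.linalg.norm(poles) + rng.uniform(2, 4)) * step
                other = mesh.translated(shift[0], shift[1])
            m = max(4, int(round(rng.uniform(0.5, 0.8) * mesh.n_rows)))
            m2 = max(4, int(round(rng.uniform(0.2, 0.5) * other.n_rows)))
            candidate = CellMesh(
                np.vstack([mesh.coords[:m], other.coords[other.n_rows - m2 :]])
            )
        try:
            contour_from_mesh(candidate)
            return candidate
        except ValidationError as exc:
            last_error = exc
    raise ValidationError(f"could not perturb mesh ({defect_type}): {last_error}")


def generate_scene(config: SceneConfig, frame: int, rng: np.random.Generator) -> SyntheticScene:
    """One rendered frame with its records and per-record ground truth."""
    h, w = config.image_size
    image = np.full((h, w), config.background_level, dtype=float)
    capsules: list[_Capsule] = []
    records: list[CellRecord] = []
    truth: list[CellTruth] = []

    probs = list(config.defect_fractions) + [1.0 - sum(config.defect_fractions)]
    kinds = list(DEFECT_TYPES) + ["none"]

    for cell_id in range(config.cells_per_frame):
        defect = kinds[int(rng.choice(len(kinds), p=probs))]
        try:
            cap = _random_capsule(config, rng, existing=capsules)
        except ValidationError:
            break  # frame is full; keep what fits
        capsules.append(cap)
        theta = math.atan2(cap.axis[1], cap.axis[0])
        mesh = capsule_mesh(cap.center, theta, cap.length, cap.width)
        x0, y0, stamp = _render_stamp(cap, config)
        _add_stamp(image, x0, y0, stamp)

        neighbor_mesh = None
        if defect in ("merged", "adjacent"):
            mode = "side" if defect == "adjacent" else "end"
            neighbor = _neighbor_capsule(cap, mode, config, rng)
            capsules.append(neighbor)
            nx0, ny0, nstamp = _render_stamp(neighbor, config)
            _add_stamp(image, nx0, ny0, nstamp)
            ntheta = math.atan2(neighbor.axis[1], neighbor.axis[0])
            neighbor_mesh = capsule_mesh(
                neighbor.center, ntheta, neighbor.length, neighbor.width
            )

        if defect in ("truncated", "shifted", "merged"):
            try:
                mesh = perturb_detection(mesh, defect, rng, neighbor_mesh=neighbor_mesh)
            except ValidationError:
                defect = "none"  # unperturbable: keep the correct mesh, label good
        records.append(CellRecord(frame, cell_id, mesh))
        truth.append(CellTruth(frame, cell_id, defect == "none", defect))

    image += rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    return SyntheticScene(image, records, truth)


def generate_dataset(config: SceneConfig, n_frames: int) -> list[SyntheticScene]:
    """``n_frames`` scenes from one generator seeded by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    return [generate_scene(config, frame, rng) for frame in range(n_frames)]


def dataset_tables(scenes: list[SyntheticScene]):
    """Flatten scenes into (images dict, records list, truth list)."""
    images = {s.records[0].frame if s.records else i: s.image for i, s in enumerate(scenes)}
    records = [r for s in scenes for r in s.records]
    truth = [t for s in scenes for t in s.truth]
    return images, records, truth


def truth_labels(truth: list[CellTruth]) -> np.ndarray:
    """Ground-truth labels, 1 = good detection, 0 = bad."""
    return np.array([1 if t.is_good else 0 for t in truth], dtype=int)
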