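"""Synthetic AFM scenes with known ground truth.

The generator emulates the statistical structure of tapping-mode AFM
topographs of amyloid aggregates on mica:

* fibrils are discrete worm-like chains (fixed arc-length step, Gaussian
  turning angles set by a persistence length) painted as flat-topped ridges
  of nm-scale height and tip-broadened apparent width;
* oligomers are round parabolic-cap bumps;
* the instrument background is a tilted plane plus a per-scan-line quadratic
  bow and per-line offsets, with additive Gaussian pixel noise;
* finite tip size is emulated as a Gaussian blur of the ideal topography.

Objects are placed with a small guaranteed separation so that each painted
object maps to exactly one connected component — the regime in which
pipeline measurements can be compared object-by-object against truth.
Ground truth (centerlines, arc lengths, peak heights, painted coverage) is
recorded before blur and noise are applied.

A 3 x 3 condition grid (DHA concentration x incubation time) mirrors the
study design: per-condition fibril length medians rise with incubation time,
with the 30 uM < 0 uM < 100 uM ordering at every time point and the 24 h
medians set to ~126 / 250 / 421 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import ConditionLabel, HeightMap, write_height_map


class SceneError(RuntimeError):
    """Raised when a scene specification cannot be realised (e.g. too many
    objects for the image area)."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic AFM image.

    Lengths and heights are in nm; the image is ``image_px`` square pixels
    covering ``scan_size`` nm (default 10 x 10 um at 1024 px, i.e.
    ~9.77 nm/px).  Fibril lengths are log-normal (median, geometric sd),
    truncated below at ``min_fibril_length`` so every object labelled
    "fibril" in truth satisfies the operational fibril definition
    (length >= 2 x width), and above at 35% of the scan size so each fibril
    fits in the image.
    """

    image_px: int = 1024
    scan_size: float = 10000.0  # nm
    n_fibrils: int = 60
    n_oligomers: int = 40
    length_median: float = 250.0  # nm
    length_gsd: float = 1.4  # geometric standard deviation
    min_fibril_length: float = 50.0  # nm
    fibril_height: tuple[float, float] = (2.0, 0.25)  # mean, sd nm
    apparent_width: float = 20.0  # nm, tip-broadened
    persistence_length: float = 1500.0  # nm
    oligomer_radius: tuple[float, float] = (15.0, 3.0)  # mean, sd nm
    oligomer_height: tuple[float, float] = (1.8, 0.3)  # mean, sd nm
    plane_tilt: tuple[float, float] = (3.0, 4.0)  # nm rise across image (x, y)
    bow_amplitude: float = 1.5  # nm, per-row quadratic bow
    line_offset_sigma: float = 0.15  # nm, per-row random offset
    noise_sigma: float = 0.1  # nm
    tip_blur_px: float = 0.5  # Gaussian sigma, px
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "image_px",
            "scan_size",
            "length_median",
            "apparent_width",
            "persistence_length",
            "min_fibril_length",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.length_gsd <= 1.0:
            raise ValueError("length_gsd must be > 1")

    @property
    def pixel_size(self) -> float:
        return self.scan_size / self.image_px


@dataclass(frozen=True)
class TruthObject:
    """Ground truth for one painted object."""

    kind: str  # fibril | oligomer
    centerline: np.ndarray  # (N, 2) nm, (x, y); a single point for oligomers
    true_length: float  # nm: centerline arc length / oligomer diameter
    true_peak_height: float  # nm, before blur and noise
    true_width: float  # nm


@dataclass(frozen=True)
class GroundTruth:
    """Per-image ground truth: objects plus painted coverage fraction."""

    objects: tuple[TruthObject, ...]
    coverage_fraction: float  # painted-pixel fraction before blur/noise

    @property
    def fibril_lengths(self) -> np.ndarray:
        return np.array(
            [o.true_length for o in self.objects if o.kind == "fibril"]
        )

    @property
    def fibril_heights(self) -> np.ndarray:
        return np.array(
            [o.true_peak_height for o in self.objects if o.kind == "fibril"]
        )


def sample_fibril_path(
    length: float,
    persistence_length: float,
    rng: np.random.Generator,
    step: float = 5.0,
) -> np.ndarray:
    """Discrete worm-like chain centerline of the requested arc length.

    The chain takes fixed steps of ``step`` nm; the turning angle between
    consecutive steps is N(0, sqrt(2 * step / persistence_length)), which
    makes the tangent autocorrelation decay as exp(-s / persistence_length)
    and reproduces the Kratky-Porod mean-squared end-to-end distance
    <R^2> = 2 P L - 2 P^2 (1 - exp(-L / P)).  The realised arc length is
    within one step of the request; self-intersection is allowed.

    Returns an (n_steps + 1, 2) array of (x, y) positions in nm starting at
    the origin heading along +x.
    """
    if length <= 0 or persistence_length <= 0:
        raise ValueError("length and persistence_length must be positive")
    n_steps = max(int(round(length / step)), 1)
    sigma = np.sqrt(2.0 * step / persistence_length)
    turns = rng.normal(0.0, sigma, size=n_steps)
    turns[0] = 0.0  # initial heading is the caller's to set
    theta = np.cumsum(turns)
    dx = step * np.cos(theta)
    dy = step * np.sin(theta)
    pts = np.zeros((n_steps + 1, 2))
    pts[1:, 0] = np.cumsum(dx)
    pts[1:, 1] = np.cumsum(dy)
    return pts


def _arc_length(polyline: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(polyline, axis=0), axis=1)))


def _densify(polyline: np.ndarray, ds: float) -> np.ndarray:
    """Resample a polyline at ~ds spacing (keeping the original vertices)."""
    out = [polyline[:1]]
    for a, b in zip(polyline[:-1], polyline[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / ds)), 1)
        t = np.linspace(0, 1, n + 1)[1:, None]
        out.append(a + t * (b - a))
    return np.vstack(out)


def _paint_fibril(
    canvas: np.ndarray,
    occupancy: np.ndarray,
    polyline_px: np.ndarray,
    half_width_px: float,
    height: float,
    separation_px: int,
) -> bool:
    """Paint a flat-topped, butt-capped tube along a centerline (pixel
    coordinates).  Returns False without painting if it would come within
    ``separation_px`` of an existing object."""
    dense = _densify(polyline_px, ds=0.35)
    pad = int(np.ceil(half_width_px)) + separation_px + 1
    c0 = int(np.floor(dense[:, 0].min())) - pad
    c1 = int(np.ceil(dense[:, 0].max())) + pad
    r0 = int(np.floor(dense[:, 1].min())) - pad
    r1 = int(np.ceil(dense[:, 1].max())) + pad
    ny, nx = canvas.shape
    if c0 < 0 or r0 < 0 or c1 >= nx or r1 >= ny:
        return False
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pix = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    tree = cKDTree(dense)
    dist, idx = tree.query(pix, k=1)
    tube = dist <= half_width_px
    # butt caps: drop pixels projecting beyond the terminal tangent planes
    for end_i, prev_i in ((0, min(3, len(dense) - 1)), (-1, max(-4, -len(dense)))):
        u = dense[end_i] - dense[prev_i]
        norm = np.linalg.norm(u)
        if norm == 0:
            continue
        u = u / norm
        at_end = idx == (end_i % len(dense))
        beyond = (pix - dense[end_i]) @ u > 0
        tube &= ~(at_end & beyond)
    tube2d = tube.reshape(rows.shape)
    if not tube2d.any():
        return False
    grown = ndimage.binary_dilation(tube2d, iterations=separation_px)
    window = (slice(r0, r1 + 1), slice(c0, c1 + 1))
    if (grown & occupancy[window]).any():
        return False
    canvas[window] = np.where(tube2d, np.maximum(canvas[window], height), canvas[window])
    occupancy[window] |= grown
    return True


def _paint_oligomer(
    canvas: np.ndarray,
    occupancy: np.ndarray,
    center_px: np.ndarray,
    radius_px: float,
    height: float,
    separation_px: int,
) -> bool:
    """Paint a parabolic-cap bump h(r) = height * (1 - (r/R)^2)."""
    pad = int(np.ceil(radius_px)) + separation_px + 1
    cx, cy = center_px
    c0, c1 = int(np.floor(cx)) - pad, int(np.ceil(cx)) + pad
    r0, r1 = int(np.floor(cy)) - pad, int(np.ceil(cy)) + pad
    ny, nx = canvas.shape
    if c0 < 0 or r0 < 0 or c1 >= nx or r1 >= ny:
        return False
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    r2 = (cols - cx) ** 2 + (rows - cy) ** 2
    bump = height * np.clip(1.0 - r2 / radius_px**2, 0.0, None)
    inside = bump > 0
    if not inside.any():
        return False
    grown = ndimage.binary_dilation(inside, iterations=separation_px)
    window = (slice(r0, r1 + 1), slice(c0, c1 + 1))
    if (grown & occupancy[window]).any():
        return False
    canvas[window] = np.maximum(canvas[window], bump)
    occupancy[window] |= grown
    return True


def _truncated_lognormal(
    rng: np.random.Generator, median: float, gsd: float, lo: float, hi: float
) -> float:
    sigma = np.log(gsd)
    for _ in range(1000):
        v = float(np.exp(rng.normal(np.log(median), sigma)))
        if lo <= v <= hi:
            return v
    raise SceneError(
        f"length distribution (median {median}, gsd {gsd}) incompatible with "
        f"bounds [{lo}, {hi}]"
    )


def render_scene(spec: SceneSpec) -> tuple[HeightMap, GroundTruth]:
    """Render one synthetic AFM image and its ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises :class:`SceneError` when
    the requested object count cannot be placed with the required separation.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_px
    px = spec.pixel_size
    canvas = np.zeros((n, n))
    occupancy = np.zeros((n, n), dtype=bool)
    separation_px = 3
    objects: list[TruthObject] = []

    half_w_px = 0.5 * spec.apparent_width / px
    max_len = 0.35 * spec.scan_size
    for _ in range(spec.n_fibrils):
        length = _truncated_lognormal(
            rng, spec.length_median, spec.length_gsd, spec.min_fibril_length, max_len
        )
        height = max(float(rng.normal(*spec.fibril_height)), 0.3)
        placed = False
        for _attempt in range(200):
            path = sample_fibril_path(length, spec.persistence_length, rng)
            angle = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
            )
            path_rot = path @ rot.T
            span = path_rot.max(axis=0) - path_rot.min(axis=0)
            margin_nm = (half_w_px + separation_px + 2) * px
            free = spec.scan_size - span - 2 * margin_nm
            if (free <= 0).any():
                continue
            origin = margin_nm - path_rot.min(axis=0) + rng.uniform(0, 1, 2) * free
            poly_nm = path_rot + origin
            if _paint_fibril(
                canvas, occupancy, poly_nm / px, half_w_px, height, separation_px
            ):
                objects.append(
                    TruthObject(
                        kind="fibril",
                        centerline=poly_nm,
                        true_length=_arc_length(poly_nm),
                        true_peak_height=height,
                        true_width=spec.apparent_width,
                    )
                )
                placed = True
                break
        if not placed:
            raise SceneError(
                f"could not place fibril #{len(objects) + 1} of "
                f"{spec.n_fibrils}; image too crowded"
            )

    for _ in range(spec.n_oligomers):
        # keep oligomer footprints above the detection limit (~1.5 px)
        radius = max(float(rng.normal(*spec.oligomer_radius)), 1.5 * px)
        height = max(float(rng.normal(*spec.oligomer_height)), 0.3)
        placed = False
        for _attempt in range(200):
            margin_nm = radius + (separation_px + 2) * px
            center = rng.uniform(margin_nm, spec.scan_size - margin_nm, 2)
            if _paint_oligomer(
                canvas, occupancy, center / px, radius / px, height, separation_px
            ):
                objects.append(
                    TruthObject(
                        kind="oligomer",
                        centerline=center[None, :],
                        true_length=2 * radius,
                        true_peak_height=height,
                        true_width=2 * radius,
                    )
                )
                placed = True
                break
        if not placed:
            raise SceneError("could not place oligomer; image too crowded")

    coverage = float((canvas > 0).mean())
    # overlapping paint already takes per-pixel maxima; cap guards the sum rule
    if objects:
        canvas = np.minimum(canvas, 1.5 * max(o.true_peak_height for o in objects))

    topo = canvas
    if spec.tip_blur_px > 0:
        topo = ndimage.gaussian_filter(topo, spec.tip_blur_px)

    xs = np.linspace(0.0, 1.0, n)
    ys = np.linspace(0.0, 1.0, n)
    background = (
        spec.plane_tilt[0] * xs[None, :] + spec.plane_tilt[1] * ys[:, None]
    )
    xnorm = np.linspace(-1.0, 1.0, n)
    background = background + spec.bow_amplitude * xnorm[None, :] ** 2
    if spec.line_offset_sigma > 0:
        background = background + rng.normal(0, spec.line_offset_sigma, (n, 1))
    heights = topo + background
    if spec.noise_sigma > 0:
        heights = heights + rng.normal(0, spec.noise_sigma, (n, n))

    hmap = HeightMap(heights, px, source_id=f"scene-seed{spec.seed}")
    return hmap, GroundTruth(objects=tuple(objects), coverage_fraction=coverage)


# --- condition grid -------------------------------------------------------

#: Study grid: per-condition generator parameters.  Length medians rise with
#: incubation time within each concentration, keep the 30 < 0 < 100 uM
#: ordering at every time point, and hit ~126 / 250 / 421 nm at 24 h.
#: Heights follow the same trend; counts give the 100 uM samples the
#: densest coverage and the 30 uM samples the sparsest.
CONDITION_TABLE: dict[tuple[float, float], dict] = {
    (0.0, 1.0): dict(length_median=120.0, length_gsd=1.40, fibril_height=(1.6, 0.25), n_fibrils=60, n_oligomers=50),
    (0.0, 6.0): dict(length_median=180.0, length_gsd=1.40, fibril_height=(2.0, 0.25), n_fibrils=70, n_oligomers=40),
    (0.0, 24.0): dict(length_median=250.0, length_gsd=1.40, fibril_height=(2.3, 0.25), n_fibrils=80, n_oligomers=30),
    (30.0, 1.0): dict(length_median=64.0, length_gsd=1.35, fibril_height=(1.5, 0.25), n_fibrils=45, n_oligomers=40),
    (30.0, 6.0): dict(length_median=88.0, length_gsd=1.35, fibril_height=(1.7, 0.25), n_fibrils=50, n_oligomers=35),
    (30.0, 24.0): dict(length_median=126.0, length_gsd=1.35, fibril_height=(1.9, 0.25), n_fibrils=55, n_oligomers=30),
    (100.0, 1.0): dict(length_median=180.0, length_gsd=1.50, fibril_height=(1.8, 0.25), n_fibrils=70, n_oligomers=60),
    (100.0, 6.0): dict(length_median=290.0, length_gsd=1.50, fibril_height=(2.4, 0.25), n_fibrils=85, n_oligomers=50),
    (100.0, 24.0): dict(length_median=421.0, length_gsd=1.55, fibril_height=(2.8, 0.25), n_fibrils=100, n_oligomers=40),
}


@dataclass(frozen=True)
class SceneSample:
    """One generated image with its condition label and ground truth."""

    hmap: HeightMap
    condition: ConditionLabel
    truth: GroundTruth


def generate_condition_grid(
    seed: int,
    n_images: int = 8,
    image_px: int = 1024,
    scan_size: float = 10000.0,
    count_scale: float | None = None,
    base_spec: SceneSpec | None = None,
    conditions: dict[tuple[float, float], dict] | None = None,
) -> list[SceneSample]:
    """Generate the full 3 x 3 condition grid with ``n_images`` per condition.

    Object counts in :data:`CONDITION_TABLE` are stated for the default
    10 x 10 um field of view; ``count_scale`` rescales them (default: the
    area ratio ``(scan_size / 10000)^2``, so smaller fields keep the same
    object density).  Per-image seeds are derived deterministically from
    ``seed``; two calls with the same arguments produce identical datasets.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    conditions = conditions or CONDITION_TABLE
    if count_scale is None:
        count_scale = (scan_size / 10000.0) ** 2
    base = base_spec or SceneSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(conditions) * n_images)
    samples: list[SceneSample] = []
    i = 0
    for (conc, time), params in sorted(conditions.items()):
        params = dict(params)
        n_fib = max(int(round(params.pop("n_fibrils") * count_scale)), 1)
        n_oli = max(int(round(params.pop("n_oligomers") * count_scale)), 0)
        for rep in range(1, n_images + 1):
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            spec = replace(
                base,
                image_px=image_px,
                scan_size=scan_size,
                n_fibrils=n_fib,
                n_oligomers=n_oli,
                seed=child_seed,
                **params,
            )
            hmap, truth = render_scene(spec)
            label = ConditionLabel(conc, time, replicate=rep)
            hmap = HeightMap(
                hmap.heights,
                hmap.pixel_size,
                source_id=f"dha{conc:g}uM_t{time:g}h_rep{rep}",
            )
            samples.append(SceneSample(hmap=hmap, condition=label, truth=truth))
    return samples


def write_dataset(
    samples: list[SceneSample], out_dir: str | Path, format: str = "tiff"
) -> pd.DataFrame:
    """Write images, a manifest CSV and a ground-truth CSV to ``out_dir``.

    Returns the manifest (path, condition fields, pixel size, truth
    aggregates per image).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "tif" if format == "tiff" else "txt"
    manifest_rows = []
    truth_rows = []
    for s in samples:
        fname = f"{s.hmap.source_id}.{ext}"
        write_height_map(s.hmap, out_dir / fname, format=format)
        fl = s.truth.fibril_lengths
        manifest_rows.append(
            {
                "path": fname,
                "dha_concentration": s.condition.dha_concentration,
                "incubation_time": s.condition.incubation_time,
                "replicate": s.condition.replicate,
                "pixel_size_nm": s.hmap.pixel_size,
                "true_n_fibrils": fl.size,
                "true_mean_length_nm": fl.mean() if fl.size else np.nan,
                "true_coverage_percent": 100 * s.truth.coverage_fraction,
            }
        )
        for j, obj in enumerate(s.truth.objects):
            truth_rows.append(
                {
                    "path": fname,
                    "object_id": j + 1,
                    "kind": obj.kind,
                    "true_length_nm": obj.true_length,
                    "true_peak_height_nm": obj.true_peak_height,
                    "true_width_nm": obj.true_width,
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest
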