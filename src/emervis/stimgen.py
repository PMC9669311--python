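"""Synthetic viewpoint-controllable object stimulus renderer.

Parametric 3-D objects built from axis-aligned cuboids are rotated on a
horizontal orbit, orthographically projected with flat per-face shading,
and composited onto phase-randomized 1/f backgrounds.  Every emitted image
is calibrated to a fixed pixel-intensity distribution (mean 127.5, sd 51.0)
so that object class is not decodable from first-order luminance or
contrast statistics.

Three dataset builders mirror the three stimulus protocols used throughout
the analysis pipeline:

* the *object* dataset (many identities per class, small random viewpoint
  jitter, plus a block-scrambled control set) used to find selective units;
* the *viewpoint* dataset (a fixed symmetric azimuth grid, identities split
  into an analysis subset and a held-out classification subset);
* the *svm* dataset (fresh identities rendered within graded viewpoint
  variation ranges) used by the object-detection task.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TARGET_MEAN = 127.5
TARGET_SD = 51.0

# light direction for flat shading; x-component is zero so that rendering
# commutes with left-right mirroring of mirror-symmetric objects
_LIGHT = np.array([0.0, 0.45, 0.893])
_LIGHT = _LIGHT / np.linalg.norm(_LIGHT)
_AMBIENT = 0.35


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cuboid:
    """Axis-aligned cuboid primitive: center, size and a base reflectance."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]
    tone: float = 0.7

    def __post_init__(self):
        if min(self.size) <= 0:
            raise ValueError(f"degenerate primitive (zero volume): size={self.size}")


@dataclass(frozen=True)
class JitterParams:
    """Per-identity multiplicative size noise and additive position noise."""

    size_range: float = 0.12
    pos_range: float = 0.03


@dataclass(frozen=True)
class ObjectSpec:
    class_name: str
    primitives: tuple[Cuboid, ...]
    jitter_params: JitterParams = field(default_factory=JitterParams)
    identity_seed: int = 0

    def materialize(self) -> tuple[Cuboid, ...]:
        """Apply identity jitter; deterministic in (class_name, identity_seed)."""
        key = np.frombuffer(self.class_name.encode(), dtype=np.uint8)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.identity_seed)] + key.tolist())
        )
        out = []
        j = self.jitter_params
        for c in self.primitives:
            smul = rng.uniform(1 - j.size_range, 1 + j.size_range, 3)
            dpos = rng.uniform(-j.pos_range, j.pos_range, 3)
            out.append(
                Cuboid(
                    tuple(np.asarray(c.center) + dpos),
                    tuple(np.asarray(c.size) * smul),
                    c.tone,
                )
            )
        return tuple(out)


@dataclass(frozen=True)
class RenderConfig:
    image_size: int = 227
    azimuth: float = 0.0          # degrees on the horizontal orbit, mod 360
    target_mean: float = TARGET_MEAN
    target_sd: float = TARGET_SD
    background_kind: str = "phase_scrambled"   # or "uniform"
    scramble_grid: int = 8
    background_seed: int = 0
    object_scale: float = 0.55    # fraction of image width spanned by the unit cube

    def __post_init__(self):
        if self.target_mean <= 0 or self.target_sd <= 0:
            raise ValueError("target_mean and target_sd must be positive")


@dataclass
class StimulusImage:
    pixels: np.ndarray            # (H, W) float in [0, 255]
    class_name: str
    identity: int
    viewpoint_deg: float
    dataset_tag: str = "object"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2-D array")
        if not self.class_name or not self.dataset_tag:
            raise ValueError("metadata fields must be non-empty")


@dataclass
class StimulusSet:
    images: list[StimulusImage]
    manifest: pd.DataFrame

    def __post_init__(self):
        if len(self.images) != len(self.manifest):
            raise ValueError("manifest row count must equal image count")

    def pixel_stack(self) -> np.ndarray:
        return np.stack([im.pixels for im in self.images]).astype(np.float32)


# ---------------------------------------------------------------------------
# built-in object classes
# ---------------------------------------------------------------------------

def _C(cx, cy, cz, sx, sy, sz, tone=0.7) -> Cuboid:
    return Cuboid((cx, cy, cz), (sx, sy, sz), tone)


# Nine parametric cuboid compositions evoking the silhouettes of common
# furniture classes.  All primitives fit inside the unit bounding cube.
BUILTIN_CLASSES: Mapping[str, tuple[Cuboid, ...]] = {
    "toilet": (
        _C(0.0, -0.25, 0.1, 0.4, 0.3, 0.45, 0.85),    # bowl
        _C(0.0, 0.1, -0.3, 0.44, 0.5, 0.16, 0.9),     # tank
        _C(0.0, -0.07, 0.1, 0.46, 0.08, 0.5, 0.8),    # seat
    ),
    "sofa": (
        _C(0.0, -0.25, 0.0, 0.9, 0.3, 0.5, 0.55),     # base
        _C(0.0, 0.05, -0.18, 0.9, 0.42, 0.14, 0.5),   # back
        _C(-0.41, -0.05, 0.0, 0.1, 0.34, 0.5, 0.6),   # left arm
        _C(0.41, -0.05, 0.0, 0.1, 0.34, 0.5, 0.6),    # right arm
    ),
    "monitor": (
        _C(0.0, 0.1, 0.0, 0.74, 0.5, 0.07, 0.35),     # screen slab
        _C(0.0, -0.25, 0.0, 0.09, 0.22, 0.09, 0.4),   # post
        _C(0.0, -0.42, 0.0, 0.4, 0.06, 0.26, 0.45),   # base
    ),
    "table": (
        _C(0.0, 0.12, 0.0, 0.9, 0.07, 0.55, 0.65),    # top
        _C(-0.4, -0.2, -0.22, 0.07, 0.58, 0.07, 0.6),
        _C(0.4, -0.2, -0.22, 0.07, 0.58, 0.07, 0.6),
        _C(-0.4, -0.2, 0.22, 0.07, 0.58, 0.07, 0.6),
        _C(0.4, -0.2, 0.22, 0.07, 0.58, 0.07, 0.6),
    ),
    "chair": (
        _C(0.0, -0.1, 0.05, 0.42, 0.07, 0.4, 0.7),    # seat
        _C(0.0, 0.22, -0.13, 0.42, 0.55, 0.07, 0.68),  # back
        _C(-0.17, -0.33, -0.1, 0.06, 0.4, 0.06, 0.62),
        _C(0.17, -0.33, -0.1, 0.06, 0.4, 0.06, 0.62),
        _C(-0.17, -0.33, 0.2, 0.06, 0.4, 0.06, 0.62),
        _C(0.17, -0.33, 0.2, 0.06, 0.4, 0.06, 0.62),
    ),
    "bed": (
        _C(0.0, -0.3, 0.05, 0.85, 0.18, 0.8, 0.75),   # mattress
        _C(0.0, 0.0, -0.4, 0.85, 0.5, 0.1, 0.6),      # headboard
        _C(0.0, -0.42, 0.05, 0.9, 0.1, 0.85, 0.5),    # frame
    ),
    "desk": (
        _C(0.0, 0.1, 0.0, 0.9, 0.08, 0.5, 0.6),       # top
        _C(-0.38, -0.2, 0.0, 0.14, 0.55, 0.46, 0.55),  # left pedestal
        _C(0.38, -0.2, 0.0, 0.14, 0.55, 0.46, 0.55),   # right pedestal
    ),
    "dresser": (
        _C(0.0, 0.0, 0.0, 0.7, 0.85, 0.45, 0.6),      # body
        _C(0.0, 0.26, 0.24, 0.6, 0.2, 0.04, 0.75),    # drawer fronts
        _C(0.0, 0.0, 0.24, 0.6, 0.2, 0.04, 0.75),
        _C(0.0, -0.26, 0.24, 0.6, 0.2, 0.04, 0.75),
    ),
    "nightstand": (
        _C(0.0, 0.1, 0.0, 0.45, 0.45, 0.4, 0.65),     # body
        _C(0.0, 0.14, 0.21, 0.36, 0.16, 0.04, 0.8),   # drawer
        _C(-0.18, -0.3, -0.14, 0.06, 0.35, 0.06, 0.55),
        _C(0.18, -0.3, -0.14, 0.06, 0.35, 0.06, 0.55),
        _C(-0.18, -0.3, 0.14, 0.06, 0.35, 0.06, 0.55),
        _C(0.18, -0.3, 0.14, 0.06, 0.35, 0.06, 0.55),
    ),
}

DEFAULT_CLASSES: tuple[str, ...] = tuple(BUILTIN_CLASSES)


def object_spec(class_name: str, identity_seed: int = 0,
                jitter: JitterParams | None = None) -> ObjectSpec:
    if class_name not in BUILTIN_CLASSES:
        raise ValueError(f"unknown class label: {class_name!r}")
    return ObjectSpec(class_name, BUILTIN_CLASSES[class_name],
                      jitter or JitterParams(), identity_seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

# cuboid faces as (vertex indices, outward normal); vertices are the 8 corners
# in the order produced by _cuboid_vertices
_FACES = (
    ((0, 1, 3, 2), (-1, 0, 0)),
    ((4, 5, 7, 6), (1, 0, 0)),
    ((0, 1, 5, 4), (0, -1, 0)),
    ((2, 3, 7, 6), (0, 1, 0)),
    ((0, 2, 6, 4), (0, 0, -1)),
    ((1, 3, 7, 5), (0, 0, 1)),
)


def _cuboid_vertices(c: Cuboid) -> np.ndarray:
    cx, cy, cz = c.center
    hx, hy, hz = np.asarray(c.size) / 2.0
    corners = np.array(
        [[sx, sy, sz] for sx in (-hx, hx) for sy in (-hy, hy) for sz in (-hz, hz)]
    )
    # index bit order: x (bit2), y (bit1), z (bit0)
    return corners + np.array([cx, cy, cz])


def _fill_convex(img: np.ndarray, poly: np.ndarray, value: float) -> None:
    """Rasterize a convex polygon (screen coords) with an inclusive edge rule."""
    # orient counter-clockwise so the inclusive half-plane test is symmetric
    # under left-right mirroring
    area2 = 0.0
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        area2 += x0 * y1 - x1 * y0
    if area2 < 0:
        poly = poly[::-1]
    elif area2 == 0:
        return
    h, w = img.shape
    xmin = max(int(np.floor(poly[:, 0].min())), 0)
    xmax = min(int(np.ceil(poly[:, 0].max())), w - 1)
    ymin = max(int(np.floor(poly[:, 1].min())), 0)
    ymax = min(int(np.ceil(poly[:, 1].max())), h - 1)
    if xmin > xmax or ymin > ymax:
        return
    xs = np.arange(xmin, xmax + 1, dtype=np.float64)
    ys = np.arange(ymin, ymax + 1, dtype=np.float64)
    gx, gy = np.meshgrid(xs, ys)
    inside = np.ones(gx.shape, dtype=bool)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        inside &= (x1 - x0) * (gy - y0) - (y1 - y0) * (gx - x0) >= -1e-9
    img[ymin:ymax + 1, xmin:xmax + 1][inside] = value


def render_object(spec: ObjectSpec, config: RenderConfig) -> StimulusImage:
    """Render one object at the configured azimuth onto its background.

    Orthographic projection along +z (toward the viewer) after rotating the
    object about the vertical (y) axis; faces are flat-shaded from their
    outward normal and drawn back-to-front (painter's algorithm).  The
    result is deterministic in (spec, config) and is *not* yet intensity
    calibrated.
    """
    size = config.image_size
    # normalize to (-180, 180]: keeps sin/cos exactly odd/even in the angle
    # so mirror-symmetric objects render as exact left-right mirrors
    az = -((-config.azimuth + 180.0) % 360.0 - 180.0)
    theta = np.deg2rad(az)
    ct, st = np.cos(theta), np.sin(theta)
    rot = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])

    if config.background_kind == "phase_scrambled":
        img = make_background(config.background_seed, config).pixels.copy()
    else:
        img = np.full((size, size), config.target_mean, dtype=np.float64)

    scale = config.object_scale * size
    c0 = (size - 1) / 2.0

    faces = []   # (depth, polygon, shade)
    for cub in spec.materialize():
        verts = _cuboid_vertices(cub) @ rot.T
        for idx, normal in _FACES:
            nrm = rot @ np.asarray(normal, dtype=float)
            if nrm[2] <= 1e-12:        # back-face culling
                continue
            quad = verts[list(idx)]
            shade = cub.tone * (_AMBIENT + (1 - _AMBIENT) * max(0.0, nrm @ _LIGHT))
            poly = np.column_stack([c0 + scale * quad[:, 0], c0 - scale * quad[:, 1]])
            faces.append((quad[:, 2].mean(), poly, 255.0 * shade))
    for _, poly, value in sorted(faces, key=lambda f: f[0]):
        _fill_convex(img, poly, value)

    return StimulusImage(img, spec.class_name, spec.identity_seed, config.azimuth)


def make_background(seed: int, config: RenderConfig) -> StimulusImage:
    """Random-phase 1/f texture, intensity-calibrated; reproducible by seed."""
    n = config.image_size
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    f = np.hypot(fx, fy)
    amp = np.zeros_like(f)
    amp[f > 0] = 1.0 / f[f > 0]
    spec = amp * (rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n)))
    tex = np.fft.ifft2(spec).real
    img = calibrate_intensity(tex, config.target_mean, config.target_sd)
    return StimulusImage(img, "background", int(seed), 0.0, dataset_tag="background")


def calibrate_intensity(pixels: np.ndarray, target_mean: float = TARGET_MEAN,
                        target_sd: float = TARGET_SD, max_iter: int = 5) -> np.ndarray:
    """Affine-rescale to the target mean/sd, clipping to [0, 255].

    Clipping perturbs the moments, so the rescale+clip step is iterated (at
    most ``max_iter`` times) until the post-clip mean is within 0.5 and the
    sd within 1.5 of the targets.
    """
    img = np.asarray(pixels, dtype=np.float64)
    if float(img.std()) == 0.0:
        raise ValueError("constant image: sd undefined, cannot calibrate")
    for _ in range(max_iter):
        m, s = img.mean(), img.std()
        if abs(m - target_mean) <= 0.5 and abs(s - target_sd) <= 1.5:
            break
        img = np.clip(target_mean + target_sd * (img - m) / s, 0.0, 255.0)
    return img


def _calibrated(im: StimulusImage, config: RenderConfig) -> StimulusImage:
    return dataclasses.replace(
        im, pixels=calibrate_intensity(im.pixels, config.target_mean, config.target_sd)
    )


def scramble_object(img: StimulusImage, grid: int, seed: int) -> StimulusImage:
    """Block-permutation scramble: grid×grid central blocks uniformly permuted.

    ``grid=1`` is the identity transform (one block, nothing to permute).
    """
    if grid < 1:
        raise ValueError("scramble grid must be at least 1")
    px = img.pixels.copy()
    n = px.shape[0]
    block = n // grid
    span = block * grid
    off = (n - span) // 2
    region = px[off:off + span, off:off + span]
    blocks = region.reshape(grid, block, grid, block).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(grid * grid, block, block)
    perm = np.random.default_rng(seed).permutation(grid * grid)
    shuffled = blocks[perm].reshape(grid, grid, block, block).transpose(0, 2, 1, 3)
    px[off:off + span, off:off + span] = shuffled.reshape(span, span)
    return StimulusImage(px, "scrambled", img.identity, img.viewpoint_deg,
                         img.dataset_tag)


def mean_block_displacement(grid: int, seed: int) -> float:
    """Mean Euclidean displacement (in block units) of one uniform permutation."""
    perm = np.random.default_rng(seed).permutation(grid * grid)
    src = np.column_stack(np.divmod(np.arange(grid * grid), grid))
    dst = np.column_stack(np.divmod(perm, grid))
    return float(np.hypot(*(src - dst).T).mean())


# ---------------------------------------------------------------------------
# dataset builders
# ---------------------------------------------------------------------------

def _manifest_row(im: StimulusImage, seed: int, **extra) -> dict:
    row = dict(path="", **{"class": im.class_name}, identity=im.identity,
               viewpoint_deg=im.viewpoint_deg, dataset_tag=im.dataset_tag, seed=seed)
    row.update(extra)
    return row


def render_dataset_image(class_name: str, identity: int, azimuth: float,
                         seed: int, config: RenderConfig,
                         tag: str) -> StimulusImage:
    """Shared dataset renderer: jittered identity at one azimuth, calibrated.

    All three dataset builders go through this function, so e.g. a 0-degree
    image of the viewpoint dataset is pixel-identical to an object-dataset
    render of the same identity at azimuth 0 under the same builder seed.
    """
    cfg = dataclasses.replace(config, azimuth=azimuth,
                              background_seed=(seed * 100003 + identity) % (2**31))
    im = render_object(object_spec(class_name, identity), cfg)
    im.dataset_tag = tag
    return _calibrated(im, cfg)


def build_object_dataset(n_per_class: int = 200, seed: int = 0,
                         classes: Sequence[str] = DEFAULT_CLASSES,
                         target_class: str = "toilet",
                         config: RenderConfig | None = None) -> StimulusSet:
    """Object dataset: per class, identities at random azimuth in [-30, +30],
    plus one block-scrambled control set derived from the target class."""
    if n_per_class < 2:
        raise ValueError("need at least 2 images per class")
    for cl in list(classes) + [target_class]:
        if cl not in BUILTIN_CLASSES:
            raise ValueError(f"unknown class label: {cl!r}")
    config = config or RenderConfig()
    rng = np.random.default_rng(seed)
    images, rows = [], []
    target_images = []
    for ci, cl in enumerate(classes):
        azimuths = rng.uniform(-30.0, 30.0, n_per_class)
        for ident in range(n_per_class):
            im = render_dataset_image(cl, ident, float(azimuths[ident]), seed, config, "object")
            images.append(im)
            rows.append(_manifest_row(im, seed))
            if cl == target_class:
                target_images.append(im)
    for ident, src in enumerate(target_images):
        scr = scramble_object(src, config.scramble_grid,
                              seed=int(rng.integers(2**31)))
        scr = _calibrated(scr, config)
        scr.dataset_tag = "object"
        images.append(scr)
        rows.append(_manifest_row(scr, seed))
    return StimulusSet(images, pd.DataFrame(rows))


def build_viewpoint_dataset(n_steps: int = 13, span_deg: tuple[float, float] = (-90.0, 90.0),
                            n_identities: int = 250, n_heldout: int = 50,
                            seed: int = 0, classes: Sequence[str] = ("toilet",),
                            config: RenderConfig | None = None) -> StimulusSet:
    """Viewpoint dataset: every identity rendered at each grid azimuth.

    Identities are partitioned into an *analysis* subset (used to quantify
    invariance of already-identified selective units) and a *heldout* subset
    (used only to classify units as viewpoint-specific vs -invariant).
    """
    if n_steps % 2 == 0:
        raise ValueError("n_steps must be odd so that 0 deg is on the grid")
    if abs(span_deg[0] + span_deg[1]) > 1e-12:
        raise ValueError("viewpoint span must be symmetric about 0")
    if not 0 < n_heldout < n_identities:
        raise ValueError("n_heldout must be in (0, n_identities)")
    config = config or RenderConfig()
    grid = np.linspace(span_deg[0], span_deg[1], n_steps)
    images, rows = [], []
    for cl in classes:
        if cl not in BUILTIN_CLASSES:
            raise ValueError(f"unknown class label: {cl!r}")
        for ident in range(n_identities):
            subset = "analysis" if ident < n_identities - n_heldout else "heldout"
            for az in grid:
                im = render_dataset_image(cl, ident, float(az), seed, config, "viewpoint")
                images.append(im)
                rows.append(_manifest_row(im, seed, subset=subset))
    return StimulusSet(images, pd.DataFrame(rows))


SVM_IDENTITY_OFFSET = 100_000


def build_svm_dataset(n_identities: int = 60, n_ranges: int = 18, seed: int = 0,
                      classes: Sequence[str] = DEFAULT_CLASSES,
                      include_zero_range: bool = True,
                      config: RenderConfig | None = None) -> StimulusSet:
    """Detection-task dataset: per viewpoint-variation range V (evenly spaced
    in (0, 180]), each identity is rendered at an azimuth ~ U[-V/2, +V/2].

    Identities are offset by ``SVM_IDENTITY_OFFSET`` so they are disjoint
    from the identities used to find selective units.  A V=0 (front-view
    only) subset is included for the fixed-viewpoint training regime.
    """
    config = config or RenderConfig()
    ranges = list(np.linspace(180.0 / n_ranges, 180.0, n_ranges))
    if include_zero_range:
        ranges = [0.0] + ranges
    rng = np.random.default_rng(seed)
    images, rows = [], []
    for cl in classes:
        if cl not in BUILTIN_CLASSES:
            raise ValueError(f"unknown class label: {cl!r}")
        for V in ranges:
            azimuths = (np.zeros(n_identities) if V == 0
                        else rng.uniform(-V / 2, V / 2, n_identities))
            for k in range(n_identities):
                ident = SVM_IDENTITY_OFFSET + k
                im = render_dataset_image(cl, ident, float(azimuths[k]), seed, config, "svm")
                images.append(im)
                rows.append(_manifest_row(im, seed, variation_range=float(V)))
    return StimulusSet(images, pd.DataFrame(rows))


def save_images(stim_set: StimulusSet, directory) -> pd.DataFrame:
    """Write a stimulus set as 8-bit PNGs plus a manifest CSV.

    Returns the manifest with its ``path`` column filled in.
    """
    from pathlib import Path

    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = stim_set.manifest.copy()
    paths = []
    for i, im in enumerate(stim_set.images):
        name = (f"{im.dataset_tag}_{im.class_name}_{im.identity:05d}"
                f"_{i:06d}.png")
        Image.fromarray(np.clip(np.round(im.pixels), 0, 255).astype(np.uint8)
                        ).save(directory / name)
        paths.append(name)
    manifest["path"] = paths
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# low-level control audit
# ---------------------------------------------------------------------------

def audit_low_level_controls(stim_set: StimulusSet, tol_sd: float = 2.0,
                             max_pairs: int = 20) -> pd.DataFrame:
    """Per-class low-level statistics with outlier flags.

    Reports mean/sd intensity, object bounding-box center and area (object
    pixels taken as those deviating from the image median by more than 1.5
    image-sd), and mean within-class pairwise pixel correlation; a class is
    flagged when a statistic deviates from the grand mean across classes by
    more than ``tol_sd`` across-class standard deviations.
    """
    classes = sorted(set(im.class_name for im in stim_set.images))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to audit")
    recs = []
    for cl in classes:
        imgs = [im.pixels for im in stim_set.images if im.class_name == cl]
        means = [float(p.mean()) for p in imgs]
        sds = [float(p.std()) for p in imgs]
        cx, cy, area = [], [], []
        for p in imgs:
            mask = np.abs(p - np.median(p)) > 1.5 * p.std()
            if mask.any():
                ys, xs = np.nonzero(mask)
                cx.append(float(xs.mean()))
                cy.append(float(ys.mean()))
                area.append(float(mask.sum()))
        sub = imgs[:max_pairs]
        flat = np.array([p.ravel() for p in sub])
        if len(sub) >= 2:
            cc = np.corrcoef(flat)
            corr = float(cc[np.triu_indices(len(sub), 1)].mean())
        else:
            corr = np.nan
        recs.append({
            "class": cl, "n": len(imgs),
            "mean_intensity": float(np.mean(means)),
            "sd_intensity": float(np.mean(sds)),
            "bbox_cx": float(np.mean(cx)) if cx else np.nan,
            "bbox_cy": float(np.mean(cy)) if cy else np.nan,
            "bbox_area": float(np.mean(area)) if area else np.nan,
            "within_class_corr": corr,
        })
    df = pd.DataFrame(recs).set_index("class")
    stats = ["mean_intensity", "sd_intensity", "bbox_cx", "bbox_cy",
             "bbox_area", "within_class_corr"]
    flags = pd.DataFrame(False, index=df.index, columns=stats)
    for st in stats:
        vals = df[st].dropna()
        if len(vals) >= 2 and vals.std() > 0:
            flags.loc[vals.index, st] = (
                np.abs(vals - vals.mean()) > tol_sd * vals.std(ddof=0)
            )
    df["flagged"] = flags.any(axis=1)
    return df.reset_index()
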