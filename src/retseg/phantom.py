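"""Synthetic color fundus phantoms with exact vessel ground truth.

The generator rasterizes a recursive binary-branching vessel tree as dark
tubes with Gaussian cross-section shading on a brighter background, and
reproduces the degradations the segmentation pipeline targets: a narrow
bright central-light-reflex streak along vessels wider than 3 px, a radial
vignette and a linear illumination tilt, channel-dependent vessel contrast
(deepest in green, as in real fundus photographs), additive Gaussian
noise, and a circular field of view outside which the frame is black.

Ground truth is derived from the analytic tube geometry (distance to the
centerline segments), never from thresholding the rendered image, so it is
independent of noise and shading.  The Gaussian cross-section profile is
truncated at the tube half-width, making the rendered vessel support and
the ground-truth support coincide exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import DegenerateSpecError, ParameterError
from .io import ColorFundusImage

__all__ = ["PhantomSpec", "generate_phantom", "default_drive_like_spec",
           "small_phantom_spec", "segment_angle"]


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic description of one synthetic fundus image.

    Widths follow root_width * width_decay**generation clamped at
    min_width; segment lengths follow root_length * length_decay**generation.
    vessel_contrast and base_levels are (red, green, blue) triples of the
    vessel darkening depth and the background level.
    """

    height: int = 584
    width: int = 768
    n_trees: int = 6
    branch_depth: int = 6
    root_width: float = 10.0
    width_decay: float = 0.62
    min_width: float = 1.0
    root_length: float = 60.0
    length_decay: float = 0.85
    vessel_contrast: tuple[float, float, float] = (0.25, 0.45, 0.18)
    base_levels: tuple[float, float, float] = (0.80, 0.52, 0.30)
    reflex_amplitude: float = 0.12
    reflex_width_fraction: float = 0.3
    vignette_strength: float = 0.25
    illumination_tilt: float = 0.08
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.min_width < 1:
            raise ParameterError("min_width must be >= 1 px")
        if not all(0 < c < 1 for c in self.vessel_contrast):
            raise ParameterError("vessel contrasts must lie in (0,1)")
        if self.branch_depth < 1 or self.n_trees < 1:
            raise ParameterError("need at least one tree and one generation")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vessel_contrast"] = list(self.vessel_contrast)
        d["base_levels"] = list(self.base_levels)
        return d


def default_drive_like_spec(seed: int = 0) -> PhantomSpec:
    """768x584 phantom with vessel widths spanning 1-10 px.

    The deepest generation's width, root_width * width_decay**(depth-1),
    falls below 1 px and clamps to min_width, so single-pixel vessels are
    present by construction; green vessel depth exceeds red and blue.
    """
    return PhantomSpec(seed=seed)


def small_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Reduced 384x288 phantom with the same degradations, for fast runs."""
    return PhantomSpec(height=288, width=384, n_trees=4, branch_depth=5,
                       root_width=8.0, root_length=30.0, seed=seed)


def segment_angle(p0: np.ndarray, p1: np.ndarray) -> float:
    """Detector-convention orientation (degrees in [0,180)) of a segment.

    Matches the ridge-kernel rotation u = x cos(theta) - y sin(theta),
    v = x sin(theta) + y cos(theta) with x = column offset, y = row offset:
    a ridge extended along the kernel's v axis, direction (sin(theta),
    cos(theta)) in (col, row), is detected at that theta.
    """
    drow = p1[0] - p0[0]
    dcol = p1[1] - p0[1]
    return float(np.rad2deg(np.arctan2(dcol, drow)) % 180.0)


def _grow_tree(rng: np.random.Generator, spec: PhantomSpec,
               start: np.ndarray, direction: np.ndarray) -> list[tuple]:
    """Depth-first binary branching; returns [(p0, p1, width, generation)]."""
    segments = []
    stack = [(start, direction, 0)]
    while stack:
        p0, d, gen = stack.pop()
        length = spec.root_length * spec.length_decay ** gen * rng.uniform(0.8, 1.2)
        width = max(spec.min_width, spec.root_width * spec.width_decay ** gen)
        p1 = p0 + length * d
        segments.append((p0, p1, width, gen))
        if gen + 1 < spec.branch_depth:
            for sign in (+1.0, -1.0):
                ang = sign * np.deg2rad(rng.uniform(20.0, 50.0))
                rot = np.array([[np.cos(ang), -np.sin(ang)],
                                [np.sin(ang), np.cos(ang)]])
                stack.append((p1, rot @ d, gen + 1))
    return segments


def _render_segment(p0, p1, width, depth_map, reflex_map, truth, spec):
    """Accumulate one tube into the shared maps over its bounding window."""
    h, w = depth_map.shape
    half = width / 2.0
    pad = half + 2.0
    r0 = max(int(np.floor(min(p0[0], p1[0]) - pad)), 0)
    r1 = min(int(np.ceil(max(p0[0], p1[0]) + pad)) + 1, h)
    c0 = max(int(np.floor(min(p0[1], p1[1]) - pad)), 0)
    c1 = min(int(np.ceil(max(p0[1], p1[1]) + pad)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1, dtype=np.float64)
    cols = np.arange(c0, c1, dtype=np.float64)
    pr, pc = np.meshgrid(rows, cols, indexing="ij")

    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0:
        dist = np.hypot(pr - p0[0], pc - p0[1])
    else:
        t = ((pr - p0[0]) * seg[0] + (pc - p0[1]) * seg[1]) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(pr - (p0[0] + t * seg[0]), pc - (p0[1] + t * seg[1]))

    inside = dist <= half
    # FWHM = width: the shading falls to half its peak exactly at the truth
    # boundary d = w/2, so the rendered width equals the nominal width.
    sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    profile = np.where(inside, np.exp(-dist ** 2 / (2.0 * sigma ** 2)), 0.0)
    win = (slice(r0, r1), slice(c0, c1))
    np.maximum(depth_map[win], profile, out=depth_map[win])
    truth[win] |= inside

    if width > 3.0 and spec.reflex_amplitude > 0:
        r_half = spec.reflex_width_fraction * width / 2.0
        r_sigma = spec.reflex_width_fraction * width / 4.0
        streak = np.where(dist <= r_half,
                          np.exp(-dist ** 2 / (2.0 * r_sigma ** 2)), 0.0)
        np.maximum(reflex_map[win], streak, out=reflex_map[win])


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns (ColorFundusImage, truth, fov, centerlines) where truth is the
    boolean vessel map, fov the inscribed circular aperture, and
    centerlines an (N, 2) integer array of (row, col) centerline pixels.
    Fully deterministic given spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    center = np.array([h / 2.0, w / 2.0])
    radius = min(h, w) / 2.0 - 4.0

    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    dist_center = np.hypot(rr - center[0], cc - center[1])
    fov = dist_center <= radius

    depth_map = np.zeros((h, w))
    reflex_map = np.zeros((h, w))
    truth = np.zeros((h, w), dtype=bool)
    centerline_pts: list[np.ndarray] = []

    base_angles = np.linspace(0.0, 2.0 * np.pi, spec.n_trees, endpoint=False)
    for k in range(spec.n_trees):
        ang = base_angles[k] + rng.uniform(-0.3, 0.3)
        start = center + 0.85 * radius * np.array([np.sin(ang), np.cos(ang)])
        inward = (center - start)
        inward /= np.linalg.norm(inward)
        jit = np.deg2rad(rng.uniform(-25.0, 25.0))
        rot = np.array([[np.cos(jit), -np.sin(jit)], [np.sin(jit), np.cos(jit)]])
        segments = _grow_tree(rng, spec, start, rot @ inward)

        in_frame = any((0 <= p[0] < h and 0 <= p[1] < w)
                       for p0, p1, _, _ in segments for p in (p0, p1))
        if not in_frame:
            raise DegenerateSpecError(f"tree {k} lies entirely outside the frame")

        for p0, p1, width, _gen in segments:
            _render_segment(p0, p1, width, depth_map, reflex_map, truth, spec)
            n_samples = max(int(np.ceil(np.linalg.norm(p1 - p0) * 2.0)), 2)
            ts = np.linspace(0.0, 1.0, n_samples)
            pts = np.rint(p0[None, :] + ts[:, None] * (p1 - p0)[None, :]).astype(int)
            ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
            centerline_pts.append(pts[ok])

    centerlines = np.unique(np.concatenate(centerline_pts, axis=0), axis=0)
    cl_mask = np.zeros((h, w), dtype=bool)
    cl_mask[centerlines[:, 0], centerlines[:, 1]] = True
    truth |= cl_mask  # rounded centerline pixels always count as vessel
    truth &= fov
    keep = fov[centerlines[:, 0], centerlines[:, 1]]
    centerlines = centerlines[keep]

    vignette = 1.0 - spec.vignette_strength * (dist_center / radius) ** 2
    tilt = 1.0 + spec.illumination_tilt * (cc / max(w - 1, 1) - 0.5)
    shading = vignette * tilt

    channels = []
    for base, depth in zip(spec.base_levels, spec.vessel_contrast):
        ch = base * shading - depth * depth_map + spec.reflex_amplitude * reflex_map
        if spec.noise_sigma > 0:
            ch = ch + rng.normal(0.0, spec.noise_sigma, size=ch.shape)
        ch[~fov] = 0.0
        channels.append(np.clip(ch, 0.0, 1.0))

    image = ColorFundusImage(red=channels[0], green=channels[1], blue=channels[2])
    return image, truth, fov, centerlines
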