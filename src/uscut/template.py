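"""Seed-centered circular ray template and radial intensity sampling.

The segmentation graph is scaffolded on a circular template placed at a
user-chosen seed point inside the lesion: ``R`` rays leave the seed at
equidistant angles (clockwise in screen coordinates, starting east) and
``L`` nodes are sampled along each ray out to the template radius.  The
seed itself is not a node; it contributes a local average gray value that
anchors the edge costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CircularTemplate",
    "RaySamples",
    "build_template",
    "sample_rays",
    "seed_average",
]


@dataclass(frozen=True)
class CircularTemplate:
    """Ray/node geometry of the circular template.

    Attributes
    ----------
    seed : (float, float)
        Seed point ``(x, y)`` in 0-based pixel coordinates, origin top-left.
    radius : float
        Template radius in pixels; the outermost node sits at this distance.
    R : int
        Number of rays (>= 3).
    L : int
        Nodes per ray (>= 2); node 0 is innermost, at distance ``radius/L``.
    angles : ndarray, shape (R,)
        Ray directions in radians; equidistant, clockwise on screen
        (y grows downward), starting at 0 (east).
    node_positions : ndarray, shape (R, L, 2)
        Continuous ``(x, y)`` position of every node.
    """

    seed: tuple[float, float]
    radius: float
    R: int
    L: int
    angles: np.ndarray = field(repr=False)
    node_positions: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class RaySamples:
    """Intensities sampled under a template plus the seed-region average."""

    template: CircularTemplate
    gray: np.ndarray  # (R, L) float
    seed_avg: float


def build_template(
    seed: tuple[float, float], radius: float, R: int, L: int
) -> CircularTemplate:
    """Construct the seed-centered circular template.

    Node ``i`` of every ray lies at distance ``(i + 1) * radius / L`` from
    the seed, so nodes are equidistant along the ray and the seed is
    excluded.  Pure geometry: positions may fall outside any particular
    image; they are clamped later, at sampling time.

    Raises
    ------
    ValueError
        If ``radius <= 0``, ``R < 3`` or ``L < 2``.
    """
    if not radius > 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if R < 3:
        raise ValueError(f"R (number of rays) must be >= 3, got {R}")
    if L < 2:
        raise ValueError(f"L (nodes per ray) must be >= 2, got {L}")

    sx, sy = float(seed[0]), float(seed[1])
    angles = 2.0 * np.pi * np.arange(R) / R
    # Clockwise on screen: y grows downward, so +sin moves down the image.
    dx = np.cos(angles)
    dy = np.sin(angles)
    dist = radius * (np.arange(L) + 1) / L  # (L,)
    xs = sx + dx[:, None] * dist[None, :]
    ys = sy + dy[:, None] * dist[None, :]
    positions = np.stack([xs, ys], axis=-1)
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite node positions (check seed/radius)")
    return CircularTemplate(
        seed=(sx, sy), radius=float(radius), R=int(R), L=int(L),
        angles=angles, node_positions=positions,
    )


def _as_gray_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 2:
        raise ValueError(f"expected 2D grayscale image, got shape {image.shape}")
    return image.astype(float, copy=False)


def sample_rays(image: np.ndarray, template: CircularTemplate) -> np.ndarray:
    """Sample one intensity per template node by bilinear interpolation.

    Positions outside the image are clamped to the nearest border pixel
    first, so the graph keeps its fixed structure wherever the seed sits.

    Returns
    -------
    ndarray, shape (R, L)
    """
    img = _as_gray_float(image)
    h, w = img.shape
    pos = template.node_positions
    x = np.clip(pos[..., 0], 0.0, w - 1.0)
    y = np.clip(pos[..., 1], 0.0, h - 1.0)

    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = x - x0
    fy = y - y0

    top = img[y0, x0] * (1 - fx) + img[y0, x1] * fx
    bot = img[y1, x0] * (1 - fx) + img[y1, x1] * fx
    return top * (1 - fy) + bot * fy


def seed_average(
    image: np.ndarray, seed: tuple[float, float], avg_radius: float = 3.0
) -> float:
    """Mean gray value of pixels within ``avg_radius`` of the seed.

    A pixel belongs to the disc when its center lies within Euclidean
    distance ``avg_radius`` of the seed; ``avg_radius = 0`` reduces to the
    seed pixel alone.  This local average is the reference echogenicity of
    the lesion interior from which all edge costs are measured.
    """
    img = _as_gray_float(image)
    h, w = img.shape
    sx, sy = float(seed[0]), float(seed[1])
    if not (0 <= sx <= w - 1 and 0 <= sy <= h - 1):
        raise ValueError(f"seed {seed!r} outside image of shape {(h, w)}")
    if avg_radius < 0:
        raise ValueError("avg_radius must be >= 0")
    if avg_radius == 0:
        return float(img[int(round(sy)), int(round(sx))])

    x0 = max(int(np.floor(sx - avg_radius)), 0)
    x1 = min(int(np.ceil(sx + avg_radius)), w - 1)
    y0 = max(int(np.floor(sy - avg_radius)), 0)
    y1 = min(int(np.ceil(sy + avg_radius)), h - 1)
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    inside = (xx - sx) ** 2 + (yy - sy) ** 2 <= avg_radius ** 2
    if not inside.any():  # tiny radius between pixel centers
        return float(img[int(round(sy)), int(round(sx))])
    return float(img[y0:y1 + 1, x0:x1 + 1][inside].mean())


def sample(
    image: np.ndarray,
    template: CircularTemplate,
    avg_radius: float = 3.0,
) -> RaySamples:
    """Bundle :func:`sample_rays` and :func:`seed_average` for one template."""
    gray = sample_rays(image, template)
    avg = seed_average(image, template.seed, avg_radius)
    return RaySamples(template=template, gray=gray, seed_avg=avg)
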