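"""From cut vector to contour polygon, binary mask, and collapse detection.

The per-ray cut levels are turned into ``R`` boundary points (one per
ray, at the radial midpoint between the last lesion-side node and the
first background-side node), closed into a polygon in ray order and
rasterized.  When every ray cuts at level zero the contour has contracted
onto the seed — the interactive feedback that no lesion edge is present
under the cursor — and the result is flagged ``collapsed`` rather than
treated as an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask

from . import graphcut, template as tpl
from .graphcut import CutVector
from .template import CircularTemplate

__all__ = ["SegmentationResult", "cut_to_contour", "contour_to_mask", "segment"]


@dataclass(frozen=True)
class SegmentationResult:
    """Output of one seed placement.

    Attributes
    ----------
    cut_vector : CutVector
        Per-ray lesion-side node counts and the min-cut cost.
    contour : ndarray, shape (R, 2)
        Boundary points ``(x, y)``, one per ray, in ray order.
    mask : ndarray of bool
        Rasterized lesion mask, same shape as the input image.
    collapsed : bool
        True when the contour contracted onto the seed (no lesion found).
    seed : (float, float)
        The generating seed point.
    """

    cut_vector: CutVector
    contour: np.ndarray
    mask: np.ndarray
    collapsed: bool
    seed: tuple[float, float]


def cut_to_contour(cut: CutVector, template: CircularTemplate) -> np.ndarray:
    """Boundary points for a cut vector, one per ray.

    For ``k[r] >= 1`` the point sits on ray ``r`` at the radial midpoint
    between node ``k[r]-1`` and node ``k[r]`` (at the outer template
    radius when ``k[r] = L``); for ``k[r] = 0`` it is the seed itself.
    """
    k = np.asarray(cut.k)
    if k.shape != (template.R,):
        raise ValueError(
            f"cut vector length {k.shape} does not match template R={template.R}"
        )
    step = template.radius / template.L
    # node i sits at (i+1)*step; midpoint of nodes k-1 and k is (2k+1)/2*step
    dist = np.where(k >= 1, np.minimum((2 * k + 1) / 2.0, template.L) * step, 0.0)
    sx, sy = template.seed
    x = sx + np.cos(template.angles) * dist
    y = sy + np.sin(template.angles) * dist
    return np.stack([x, y], axis=-1)


def contour_to_mask(contour: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the closed ray-order polygon into a boolean mask.

    Pixels whose centers fall inside or on the polygon are foreground;
    the polygon is clipped to the image bounds.  Fewer than 3 distinct
    points yield an empty mask.
    """
    pts = np.asarray(contour, dtype=float)
    if len(np.unique(np.round(pts, 9), axis=0)) < 3:
        return np.zeros(image_shape, dtype=bool)
    # polygon2mask expects (row, col) vertex order
    return polygon2mask(image_shape, pts[:, ::-1])


def segment(
    image: np.ndarray,
    seed: tuple[float, float],
    radius: float = 60.0,
    R: int = 60,
    L: int = 40,
    delta_r: int = 2,
    avg_radius: float | None = None,
) -> SegmentationResult:
    """Segment a star-shaped lesion around ``seed``.

    Full pipeline for one seed placement: build the circular template,
    sample intensities along its rays, convert them to costs and terminal
    weights, solve the s-t min-cut, and rasterize the resulting contour.
    Deterministic: identical inputs give identical masks.  Re-invoking
    with a new seed emulates the interactive mouse-move loop.

    Parameters
    ----------
    image : 2D array
        Grayscale image (any intensity scale).
    seed : (x, y)
        Pixel coordinates of a point inside the suspected lesion.
    radius : float
        Template radius in pixels; must exceed the lesion radius.
    R, L : int
        Number of rays and nodes per ray.
    delta_r : int
        Smoothness parameter: maximum cut-level jump between adjacent rays.
    avg_radius : float, optional
        Radius of the disc around the seed over which the reference gray
        value is averaged.  Default ``0.7 * radius``: for a template about
        twice the lesion size the disc then straddles the lesion boundary,
        so the reference level falls between lesion and parenchyma
        echogenicity and the minimum-cost cut locks onto the level
        crossing at the boundary.  Pass a small value (a few pixels) to
        average over the lesion interior only.
    """
    img = np.asarray(image)
    if avg_radius is None:
        avg_radius = 0.7 * radius
    t = tpl.build_template(seed, radius, R, L)
    samples = tpl.sample(img, t, avg_radius)
    profile = graphcut.compute_costs(samples)
    graph = graphcut.build_graph(profile, delta_r)
    cut = graphcut.solve_min_cut(graph)
    contour = cut_to_contour(cut, t)
    mask = contour_to_mask(contour, img.shape)
    collapsed = bool(np.all(cut.k == 0))
    if collapsed:
        mask = np.zeros(img.shape, dtype=bool)
    return SegmentationResult(
        cut_vector=cut, contour=contour, mask=mask, collapsed=collapsed,
        seed=t.seed,
    )
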