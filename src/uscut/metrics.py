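"""Segmentation evaluation: Dice overlap and Hausdorff boundary distance.

Both measures compare an algorithmic binary mask A against a reference
mask Ref of identical shape.  Dice is the relative area overlap
2|A∩Ref| / (|A|+|Ref|); the Hausdorff distance is the larger of the two
directed maximum nearest-neighbour distances between the masks' boundary
pixel centers, reported in pixels.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "dice",
    "boundary_points",
    "directed_hausdorff",
    "hausdorff",
    "evaluate_pairs",
]


def _check_pair(a: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if a.shape != ref.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {ref.shape}")
    return a, ref


def dice(a: np.ndarray, ref: np.ndarray) -> float:
    """Dice similarity coefficient, 2|A∩Ref| / (|A|+|Ref|), in [0, 1].

    Areas are pixel counts.  Raises when both masks are empty (the
    overlap ratio is undefined).
    """
    a, ref = _check_pair(a, ref)
    denom = int(a.sum()) + int(ref.sum())
    if denom == 0:
        raise ValueError("Dice undefined: both masks are empty")
    return 2.0 * np.logical_and(a, ref).sum() / denom


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Centers ``(x, y)`` of the boundary pixels of a binary mask.

    A boundary pixel is a foreground pixel with at least one background
    4-neighbour, or one lying on the image edge.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    border = m & ~interior
    rows, cols = np.nonzero(border)
    return np.stack([cols, rows], axis=-1).astype(float)


def directed_hausdorff(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """h(A, B) = max over a in A of the distance from a to its nearest b."""
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    if pa.size == 0 or pb.size == 0:
        raise ValueError("point sets must be non-empty")
    dists, _ = cKDTree(pb).query(pa)
    return float(np.max(dists))


def hausdorff(a: np.ndarray, ref: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two mask boundaries, in pixels.

    H(A, Ref) = max(h(A, Ref), h(Ref, A)) over the boundary pixel
    centers of the two masks.  Raises if either mask is empty.
    """
    a, ref = _check_pair(a, ref)
    if not a.any() or not ref.any():
        raise ValueError("Hausdorff undefined for an empty mask")
    pa = boundary_points(a)
    pr = boundary_points(ref)
    return max(directed_hausdorff(pa, pr), directed_hausdorff(pr, pa))


def evaluate_pairs(
    pairs: list[tuple[str, np.ndarray, np.ndarray]],
) -> list[dict]:
    """Per-case evaluation rows for paired (case_id, predicted, reference).

    Returns one dict per case with keys ``case_id``, ``dsc``,
    ``hd_pixels``, ``area_A_px``, ``area_Ref_px``.  An empty prediction
    against a non-empty reference records DSC 0 and a missing (NaN)
    Hausdorff distance.
    """
    rows = []
    for case_id, a, ref in pairs:
        a, ref = _check_pair(a, ref)
        area_a, area_ref = int(a.sum()), int(ref.sum())
        if area_a + area_ref == 0:
            d, h = float("nan"), float("nan")
        else:
            d = dice(a, ref)
            h = hausdorff(a, ref) if (area_a and area_ref) else float("nan")
        rows.append(
            {
                "case_id": case_id,
                "dsc": d,
                "hd_pixels": h,
                "area_A_px": area_a,
                "area_Ref_px": area_ref,
            }
        )
    return rows
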