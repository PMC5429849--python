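"""Synthetic B-mode-like speckle phantoms with ground-truth lesion masks.

A phantom is a piecewise-constant echogenicity map — homogeneous liver
background, an elliptical lesion, optionally a dark halo rim around it —
degraded by unit-mean multiplicative speckle (gamma-distributed factors)
and a Gaussian point-spread blur.  Five echo-pattern classes are
supported, matching how liver metastases present relative to the
surrounding parenchyma:

========== ==========================================================
``hyper``       lesion brighter than background
``iso``         lesion indistinguishable by level (no edge to find)
``hypo``        lesion darker than background
``hyper_halo``  brighter lesion with a hypoechoic rim
``iso_halo``    iso-level lesion whose only visible edge is the rim
========== ==========================================================

This is a caricature of B-mode appearance sufficient to exercise the
segmentation and metrics end to end; it does not model attenuation,
shadowing or fan geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "generate_phantom", "phantom_suite", "CLASSES"]

CLASSES = ("hyper", "iso", "hypo", "hyper_halo", "iso_halo")

#: relative level difference below which a lesion counts as isoechoic
ISO_TOL = 0.02


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom; identical spec + seed => identical image.

    Levels are mean echogenicity values (arbitrary gray units, > 0);
    ``speckle_scale`` is the dispersion (std/mean) of the multiplicative
    noise factors; ``blur_sigma`` the point-spread smoothing in pixels.
    """

    image_shape: tuple[int, int]
    background_level: float
    lesion_center: tuple[float, float]  # (x, y)
    lesion_axes: tuple[float, float]  # semi-axes in px
    lesion_rotation: float  # radians
    lesion_level: float
    halo_width: float | None = None  # px; None = no halo
    halo_level: float | None = None
    speckle_scale: float = 0.25
    blur_sigma: float = 1.0
    rng_seed: int = 0

    @property
    def echo_class(self) -> str:
        rel = (self.lesion_level - self.background_level) / self.background_level
        if abs(rel) <= ISO_TOL:
            base = "iso"
        elif rel > 0:
            base = "hyper"
        else:
            base = "hypo"
        return f"{base}_halo" if self.halo_width else base

    def to_dict(self) -> dict:
        d = asdict(self)
        d["echo_class"] = self.echo_class
        return d


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    rotation: float,
) -> np.ndarray:
    h, w = shape
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    cos, sin = np.cos(rotation), np.sin(rotation)
    u = dx * cos + dy * sin
    v = -dx * sin + dy * cos
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def speckle_field(
    shape: tuple[int, int], scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-mean multiplicative speckle factors with dispersion ``scale``.

    Gamma-distributed with shape 1/scale² and mean 1, so the expected
    gray level of each region is preserved; ``scale = 0`` returns ones.
    """
    if scale < 0:
        raise ValueError("speckle_scale must be >= 0")
    if scale == 0:
        return np.ones(shape)
    shape_param = 1.0 / scale**2
    return rng.gamma(shape_param, 1.0 / shape_param, size=shape)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom.

    Returns ``(image, mask)`` where ``mask`` marks the lesion interior
    (the halo rim, being surrounding tissue, is excluded).
    """
    h, w = spec.image_shape
    if spec.background_level <= 0 or spec.lesion_level <= 0:
        raise ValueError("echogenicity levels must be > 0")
    extent = max(spec.lesion_axes) + (spec.halo_width or 0.0)
    cx, cy = spec.lesion_center
    if not (extent <= cx <= w - 1 - extent and extent <= cy <= h - 1 - extent):
        raise ValueError("lesion (incl. halo) does not fit inside the image")
    if spec.halo_width:
        if spec.halo_level is None:
            raise ValueError("halo_width set but halo_level missing")
        if spec.halo_level >= min(spec.lesion_level, spec.background_level):
            raise ValueError("halo must be hypoechoic to lesion and background")

    lesion = _ellipse_mask(
        spec.image_shape, spec.lesion_center, spec.lesion_axes, spec.lesion_rotation
    )
    echo = np.full(spec.image_shape, float(spec.background_level))
    if spec.halo_width:
        a, b = spec.lesion_axes
        outer = _ellipse_mask(
            spec.image_shape,
            spec.lesion_center,
            (a + spec.halo_width, b + spec.halo_width),
            spec.lesion_rotation,
        )
        echo[outer & ~lesion] = float(spec.halo_level)
    echo[lesion] = float(spec.lesion_level)

    rng = np.random.default_rng(spec.rng_seed)
    image = echo * speckle_field(spec.image_shape, spec.speckle_scale, rng)
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.blur_sigma)
    return image, lesion


def _allocate_counts(n: int, class_mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n cases to classes."""
    props = {k: float(v) for k, v in class_mix.items()}
    for k in props:
        if k not in CLASSES:
            raise ValueError(f"unknown echo class {k!r}; choose from {CLASSES}")
    total = sum(props.values())
    if not np.isclose(total, 1.0, atol=1e-9) or any(v < 0 for v in props.values()):
        raise ValueError("class proportions must be non-negative and sum to 1")
    quotas = {k: n * v for k, v in props.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(
        props, key=lambda k: (-(quotas[k] - counts[k]), list(props).index(k))
    )
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def phantom_suite(
    n: int,
    class_mix: dict[str, float],
    rng_seed: int,
    image_shape: tuple[int, int] = (160, 160),
    speckle_scale: float = 0.25,
    blur_sigma: float = 1.0,
) -> list[tuple[np.ndarray, np.ndarray, PhantomSpec]]:
    """Reproducible randomized suite of phantoms with ground truth.

    Class counts follow largest-remainder allocation of ``class_mix``
    (e.g. ``{"hypo": 0.8, "iso_halo": 0.1, "hyper": 0.1}``, echoing the
    echogenicity distribution of hepatic metastases, most of which are
    hypoechoic).  Per-case geometry — center jitter, semi-axes 12–22 px,
    rotation — is drawn from ``rng_seed``; each case also receives its
    own derived speckle seed, so the whole suite is a pure function of
    its arguments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = _allocate_counts(n, class_mix)
    rng = np.random.default_rng(rng_seed)
    h, w = image_shape
    background = 100.0
    out = []
    case = 0
    for cls in CLASSES:
        for _ in range(counts.get(cls, 0)):
            axes = tuple(rng.uniform(12.0, 22.0, size=2))
            center = (
                w / 2 + rng.uniform(-5, 5),
                h / 2 + rng.uniform(-5, 5),
            )
            rotation = rng.uniform(0, np.pi)
            if cls.startswith("hypo"):
                level = rng.uniform(50.0, 70.0)
            elif cls.startswith("hyper"):
                level = rng.uniform(130.0, 150.0)
            else:  # iso
                level = background * (1 + rng.uniform(-ISO_TOL, ISO_TOL) / 2)
            halo = cls.endswith("_halo")
            spec = PhantomSpec(
                image_shape=image_shape,
                background_level=background,
                lesion_center=center,
                lesion_axes=axes,
                lesion_rotation=rotation,
                lesion_level=level,
                halo_width=rng.uniform(4.0, 6.0) if halo else None,
                halo_level=rng.uniform(45.0, 60.0) if halo else None,
                speckle_scale=speckle_scale,
                blur_sigma=blur_sigma,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, mask = generate_phantom(spec)
            out.append((image, mask, spec))
            case += 1
    return out
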