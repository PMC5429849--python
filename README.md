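# uscut

Interactive star-shaped graph-cut segmentation of liver lesions in 2D
B-mode ultrasound.

Liver metastases are routinely measured by hand in ultrasound because the
contrast between a lesion and the surrounding parenchyma is low and the
speckle noise is heavy; fully automatic methods fail too often to be
trusted. `uscut` implements an interactive alternative: the user supplies a
single seed point inside the suspected lesion, and the tool returns a
star-shaped contour around it fast enough to be recomputed on every mouse
move. When no lesion edge is present under the seed, the contour collapses
onto the seed point — immediate visual feedback that there is nothing to
segment there.

The package is aimed at researchers in medical image analysis who want a
reference implementation of the ray-template graph-cut with its matching
evaluation metrics (Dice, Hausdorff), plus a synthetic speckle-phantom
generator so the whole pipeline is testable without clinical data.

## Method

A circular template of radius ρ is centred on the seed: R rays leave the
seed clockwise at equidistant angles, and L nodes are sampled along each
ray by bilinear interpolation (node *i* at distance (*i*+1)ρ/L). An average
gray value ḡ is computed over a disc around the seed, and every node gets a
cost

&nbsp;&nbsp;&nbsp;&nbsp;c<sub>r,i</sub> = |ḡ − g<sub>r,i</sub>|,

the absolute deviation of its sampled intensity from the reference level.
The template becomes an s-t flow network: along each ray, ∞-capacity
intra-edges force the cut to sever exactly one level per ray (a star-shaped
region around the seed); ∞-capacity inter-edges between cyclically adjacent
rays, connecting level *i* to level max(*i*−Δr, 0), bound the cut-level
difference of neighbouring rays by the smoothness parameter Δr. Terminal
capacities come from the costs: the innermost node binds to the source with
c<sub>r,0</sub>, the outermost to the sink with c<sub>r,L−1</sub>, and each
intermediate node carries the difference c<sub>r,i</sub> − c<sub>r,i−1</sub>
(sink edge if ≥ 0, else source edge with the absolute value). A sharp
echogenicity transition therefore produces a high-capacity sink edge just
outside the boundary which the minimum cut avoids severing — the cut falls
before it. The min-cut (Boykov–Kolmogorov max-flow) yields one cut level
per ray; boundary points are placed at the radial midpoint between the last
lesion-side and first background-side node and closed into a polygon.

Evaluation uses the standard segmentation measures between an algorithmic
mask A and a reference mask R:

- DSC = 2|A∩R| / (|A|+|R|)
- H(A,R) = max( h(A,R), h(R,A) ),  h(A,R) = max<sub>a∈A</sub> min<sub>r∈R</sub> ‖a−r‖

on boundary pixel centres, in pixels.

## Worked example

```python
import numpy as np
from uscut import segment, dice, hausdorff
from uscut.phantom import PhantomSpec, generate_phantom

spec = PhantomSpec(
    image_shape=(160, 160), background_level=100.0,
    lesion_center=(80.0, 80.0), lesion_axes=(20.0, 16.0),
    lesion_rotation=0.5, lesion_level=60.0,       # hypoechoic lesion
    speckle_scale=0.25, blur_sigma=1.0, rng_seed=42,
)
image, truth = generate_phantom(spec)

result = segment(image, seed=(80, 80), radius=40, R=60, L=40, delta_r=2)
print(f"collapsed:  {result.collapsed}")
print(f"cut cost:   {result.cut_vector.cut_cost:.2f}")
print(f"area:       {int(result.mask.sum())} px (truth: {int(truth.sum())} px)")
print(f"DSC:        {dice(result.mask, truth):.4f}")
print(f"HD:         {hausdorff(result.mask, truth):.2f} px")
```

prints

```
collapsed:  False
cut cost:   2779.55
area:       1093 px (truth: 999 px)
DSC:        0.9551
HD:         2.83 px
```

The phantom is an elliptical hypoechoic lesion (level 60 on parenchyma
level 100) under 25 % multiplicative speckle; seeding at its centre
recovers the lesion with a Dice overlap of 0.955 and a worst boundary
error below 3 px. Running `segment` again with a seed in a lesion-free
area returns `collapsed: True` and an empty mask.

The same workflow is available from the shell:

```bash
uscut phantom --suite 20 --mix hypo=0.8,iso_halo=0.1,hyper=0.1 --seed 7 --out phantoms/
uscut segment --image phantoms/case000.png --seed 80,80 --radius 40 --out seg/
uscut evaluate --pred seg/ --ref phantoms/ --out report.csv
```

## Limitations

The method is restricted to star-shaped lesions by construction, the
contour is a closed R-gon (no spline smoothing), and the phantom generator
is a deliberate caricature of B-mode appearance (no attenuation, shadowing
or fan geometry). See `docs/methods.md` for the model assumptions, the
parameter defaults and how they were chosen, and known failure modes
(isoechoic lesions without a halo, and rim-delimited lesions under heavy
speckle).
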