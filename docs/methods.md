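# Methods

## Model

`uscut` segments a single, approximately star-shaped lesion in a 2D
grayscale ultrasound image from one interior seed point. The segmentation
is posed as a minimum s-t cut on a graph built over a circular ray
template:

- **Template.** R rays leave the seed at equidistant angles, clockwise in
  screen coordinates (y down), starting east. Each ray carries L nodes at
  radial distances (i+1)·ρ/L, i = 0…L−1, for template radius ρ. The seed
  itself is not a node; node positions are continuous and intensities are
  sampled by bilinear interpolation (positions outside the image are
  clamped to the nearest border pixel so the graph structure never
  changes).
- **Costs.** A reference gray value ḡ is the mean over a disc around the
  seed. Node costs are c[r,i] = |ḡ − g[r,i]|.
- **Terminal capacities.** Per ray: node 0 → source with capacity c[r,0];
  node L−1 → sink with capacity c[r,L−1]; intermediate node i carries
  w = c[r,i] − c[r,i−1], a sink edge when w ≥ 0, else a source edge with
  |w|. The boundary nodes carry only their absolute-cost binding, no
  additional difference edge.
- **Structural edges.** Directed ∞ intra-edges (i → i−1 within a ray)
  make the source side of every ray a prefix — the star-shape guarantee.
  Directed ∞ inter-edges from (r, i) to both cyclic neighbours at level
  max(i−Δr, 0) bound the cut-level difference of adjacent rays by Δr.
  Note the level-0 clamp couples the innermost ring: a fully collapsed ray
  cannot neighbour a non-collapsed one, so collapse is an all-or-nothing
  event — which is exactly the interactive feedback the tool wants.
- **Cut.** The min cut's source side, read per ray as a level count k[r],
  is the lesion. Boundary points sit at the radial midpoint between node
  k[r]−1 and node k[r] (at ρ when k[r] = L, at the seed when k[r] = 0);
  the R points close into a polygon in ray order and are rasterized with
  an inclusive (centre inside-or-on) convention.

## Why the reference window matters

For a single ray the cut cost telescopes: cost(k) = const − 2c[r,0] +
c[r,k−1]. The optimal cut therefore sits just outside the node whose
intensity is **closest to the reference level** (or collapses when even
the best match is poor). This has a direct design consequence: if the
reference equals the lesion's own mean (a tiny averaging window), every
interior node of a homogeneous lesion matches it equally well and the cut
position inside the lesion is decided by noise. If instead the averaging
disc **straddles the expected lesion boundary**, ḡ falls between the
lesion and parenchyma levels and the best-matching sample is the level
crossing at the true edge — a robust criterion under speckle.

The default is therefore `avg_radius = 0.7 × radius`: with the template
sized to roughly twice the lesion (the natural interactive choice), the
disc covers about half lesion and half surroundings. An explicit
`avg_radius` (e.g. a few pixels, giving a lesion-mean reference) is
accepted everywhere.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `radius` | 60 (API); 2× max lesion semi-axis in the evaluation scripts | px | template radius; must exceed the lesion radius |
| `R` | 60 | rays | angular resolution; 6° spacing ≈ sub-pixel arc length at typical lesion radii |
| `L` | 40 | nodes/ray | radial resolution; ~1 px node spacing at radius 40 |
| `delta_r` | 2 | levels | smoothness: max cut-level jump between adjacent rays (0 forces a concyclic contour) |
| `avg_radius` | 0.7·radius | px | seed-averaging disc for the reference level ḡ |

R, L and the `avg_radius` rule were frozen after a calibration grid on
phantoms (a dedicated calibration seed, disjoint from the test suites)
covering all five echo-pattern classes — mirroring the intended clinical
workflow, where the algorithm is adjusted once on example lesions of each
echogenicity class and then applied unchanged. Δr = 2 is the standard
operating value for this family of methods.

## Numerical choices

- **∞ representation:** structural edges carry 1 + Σ(terminal capacities),
  provably never severed by a minimum cut; every solve asserts the cut
  cost stays below it.
- **Solver:** Boykov–Kolmogorov max-flow (networkx) on float capacities;
  no intensity quantization.
- **Tie-break:** among multiple minimum cuts the canonical *minimal*
  source set (nodes reachable from s in the residual network) is returned.
  This makes output deterministic, makes an exactly uniform image collapse
  (all capacities zero ⇒ empty source set), and prefers the inner edge of
  a hypoechoic halo when both edges tie.
- **Oracle:** `brute_force_min_cut` enumerates all cut vectors that sever
  no ∞ edge (guarded to (L+1)^R ≤ 10⁷) and returns the lexicographically
  first minimum, which coincides with the minimal source set by the
  lattice structure of minimum cuts; the solver is tested against it on
  hundreds of random instances.
- **Degenerate inputs:** empty images, seeds outside the image, radii ≤ 0,
  R < 3, L < 2 and negative Δr raise parameter errors naming the offending
  field. Collapse (all k = 0) is a reported flag, never an error.

## The phantom generator

`uscut.phantom` renders a piecewise-constant echogenicity map — uniform
parenchyma (level 100), one elliptical lesion, optionally a darker halo
ring — multiplied by unit-mean gamma-distributed speckle factors
(dispersion `speckle_scale`) and smoothed with a Gaussian point spread
(`blur_sigma`, default 1 px). Ellipses are used because hepatic metastases
grow roughly spherically. The five supported classes mirror how liver
masses present in B-mode: hyper-, iso- and hypoechoic, and iso/hyper with
a hypoechoic rim. Suite generation draws lesion geometry (semi-axes
12–22 px, centre jitter, rotation) and per-case speckle seeds from a
single RNG seed, so a suite is a pure function of its arguments;
hypoechoic levels are 50–70, hyperechoic 130–150, halo 45–60 with width
4–6 px, echoing that most hepatic metastases of pancreatic origin are
hypoechoic.

What the phantoms do *not* emulate: depth-dependent attenuation and focus,
acoustic shadowing and enhancement, fan (curvilinear) geometry, spatially
correlated speckle, heterogeneous lesion interiors. Passing the phantom
suite therefore shows that the graph construction, solver and metrics are
correct and that the method tolerates multiplicative noise at realistic
contrast — not that clinical-grade accuracy is reached on real scans.

## Known limitations and failure modes

- **Isoechoic lesions without a halo** offer no intensity evidence at all;
  they are generated (class `iso`) but are expected to collapse or produce
  arbitrary contours, and are excluded from recovery checks.
- **Rim-delimited lesions under heavy speckle:** a hypoechoic halo
  separating two regions of equal level is symmetric for the level-based
  cost — nothing prefers its inner over its outer edge once speckle breaks
  the exact tie. Under 25 % speckle such cases land on either edge
  (Dice ≈ 0.95 vs ≈ 0.66 against a rim-excluded reference); on noise-free
  images the exact tie resolves to the inner edge.
- **Bright lesions with a dark rim** can defeat the straddling reference:
  when the window's lesion/halo mixture averages to ≈ the parenchyma
  level, the background matches the reference better than the rim crossing
  and the contour overshoots. A narrower window fixes this class but
  degrades plain hypoechoic lesions under speckle; the unified default
  favours the (far more frequent) plain classes.
- The contour is an R-gon with vertices mid-way between nodes: boundary
  localization is limited to half the node spacing, and no sub-pixel
  refinement or smoothing is applied.

## Problem sizes

Default solves use R = 60, L = 40 (2400 nodes, ≈ 12k edges) and complete
in well under a second per seed on one CPU — fast enough for the
interactive loop the tool emulates (a list of seeds produces one result
per seed). Oracle-equivalence tests run at R ≤ 6, L ≤ 5 where exhaustive
enumeration is feasible; recovery tests use a 20-phantom suite at
160×160 px.
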