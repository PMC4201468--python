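# Methods

## The model

`directorfield` simulates a coarse-grained model of primary visual cortex
(V1) built to do one thing well: detect long, partially occluded contours in
cluttered scenes. The neural state of a cortical patch is reduced to a single
complex number per lattice site,

```
psi(z, t) = rho * exp(2i * theta),
```

with magnitude `rho` the mean firing rate and phase twice the dominant edge
orientation `theta`. Doubling the angle makes the encoding a *director*
(theta and theta + pi are the same state) and makes two equal orthogonal
edges cancel rather than average — cross-orientation suppression falls out of
the algebra. The price is that a site cannot represent two orientations at
once; the simulations test whether contour detection survives this loss.

One Euler iteration on the L x L periodic lattice does three things:

1. **Co-circular excitation.** Every active site broadcasts through an
   interaction kernel aligned with its own orientation:

   ```
   E(z) = sum_{z'} |psi(z')| * exp(2i*theta') * K((z - z') * exp(-i*theta'))
   K(z) = exp(4i * arg z) * exp(-|z|^2 / sigma^2) * exp(-(R_min / R_c(z))^2)
   R_c(z) = |z|^2 / (2 |Im z|),   K(0) = 0.
   ```

   The phase factor points each target toward the orientation tangent, at
   that displacement, to the circle through the source tangent to the
   source's own orientation (co-circularity); `sigma` sets the spatial range;
   the curvature gate suppresses links requiring circles tighter than
   `R_min`, giving the kernel its bow-tie shape. Contributions from
   co-circularly consistent neighbours add in phase; clutter and isotropic
   blobs largely cancel — the phase integral of `exp(4i * arg z)` over a full
   ring is zero, which is the model's main defence against diffuse spurious
   activity.

2. **Complex step nonlinearity.** Where `|E| > E_th` the field gains a fixed
   increment `dt * zeta * E/|E|` (coincidence detection); elsewhere nothing.

3. **Inhibition in exponential form.** The whole field is multiplied by
   `exp(-dt * (g1 + g2 * A))`, `A` the summed magnitude over the lattice
   (optionally a disc). To first order in `dt` this is linear local + global
   inhibition, but the multiplicative form cannot overshoot.

The stimulus enters as the initial condition only; a persistent-stimulus
mode exists behind a flag. Hard threshold plus linear decay makes asymptotic
magnitudes bimodal: sites either sit near the steady level
`m* : m = (m + dt*zeta) * exp(-dt*(g1 + g2*n*m))` or decay to zero, so
"active" is well defined.

The rotated kernel is precomputed for 64 source-orientation bins by analytic
re-evaluation at exact rotated coordinates, not by nearest-lattice-point
lookup; resampling a square lattice would re-introduce the angular
anisotropy that the discretization otherwise causes. A nearest-neighbour
compatibility mode and a per-pair exact mode (the oracle used in tests) are
both available.

## Synthetic scenes

Targets are "amoebas": closed contours whose radius is a random
low-frequency Fourier series in polar angle (`k <= 5`, amplitudes falling as
1/k, uniform phases), rejection-sampled so all radii lie in
`[0.10 L, 0.25 L]` with min/max ratio >= 0.5. The stimulus paints every
lattice site within one lattice spacing of the curve (a band about two sites
thick) with unit magnitude and the local tangent direction.

Occlusions hide 2–4 random arcs totalling 25% of the contour length; hidden
points keep their ground-truth tangents but drive nothing. Segment lengths
are a uniform random partition (symmetric Dirichlet) of the total, so single
segments range from a few sites up to ~25.

Clutter is made *from* targets: an extra amoeba is rasterized, the lattice is
tiled into 16 x 16 regions, regions are randomly permuted, and each region is
rigidly rotated about the centre of mass of its sites until its dominant
orientation (principal axis of the second moments) differs from every
already-placed 8-connected neighbour by more than 20 degrees. Rigid motions
preserve curvature, brightness and local statistics exactly; only long-range
continuity is destroyed. An exclusion zone then deletes clutter within 8
sites of a target whose orientation is within 15 degrees of the nearest
tangent, so clutter can never accidentally help detection.

What the generator does **not** emulate: natural-image statistics (texture,
contrast variation, junctions), multiple orientations per location, and
luminance noise. Passing tests therefore show that co-circular lateral
dynamics can separate closed contours from locally identical open fragments —
not that the model is a practical natural-image edge detector.

## Scoring

Precision is activity-weighted: the fraction of supra-cutoff `|psi|` lying
within one site (Chebyshev) of the full ground-truth contour, occluded parts
included. Recall is the fraction of ground-truth contour points with an
active site within the same tolerance. Orientation agreement is not
required. Precision is undefined (and excluded from curves) when nothing is
active. Sweeping cutoffs (absolute 0.05–0.95 in 0.05 steps, or the same grid
as fractions of the field maximum) at each recorded time yields PR curves;
the trapezoid area over the recall-sorted defined points — anchored at
recall 0 with the highest-cutoff precision, so a perfect curve scores
exactly 1 — is the optimizer's fitness, and the recorded time with the
largest mean area is the *optimal time* — performance genuinely peaks at intermediate times, because early
fields still carry clutter and late fields grow spurious widening around the
surviving contour.

## Parameter initialization and refinement

`init_params` converts scene statistics into starting parameters:

- `sigma = 1.2 x` mean occluded-segment arc length (just above the gaps the
  excitation must bridge; pushing `sigma` much past ~0.6 of the typical
  curvature radius destabilizes the band itself, so the factor is kept
  modest);
- `R_min = 0.22 x` typical curvature radius (median over the contour). The
  gate must sit well *below* the curvatures the targets exhibit: gating at
  the target's own curvature scale blocks the curved continuations needed to
  fill occlusions while leaving straighter spurious offsets favoured. At
  0.22 the target's own curvature passes almost ungated while the tight
  "side-by-side parallel row" channel that drives line widening stays
  suppressed;
- `E_th = 0.48 x` the median band support of an ideal circle of the typical
  amoeba radius at unit magnitude, computed deterministically from the
  kernel itself (`circle_band_support`). This places the threshold below
  nearly the whole closed-contour band but above the one-sided support of a
  clutter fragment endpoint, so fragments erode from their ends while closed
  contours are self-sustaining;
- `zeta = 0.05` and `g1, g2` solved from the steady-state fixed point so a
  contour of the expected size sustains magnitude 1 per site, split 30%
  local / 70% global. The slow increment matters: clutter decay, gap filling
  and spurious widening are all paced by `ln(1 + zeta)` per iteration, and
  the slower pace widens the usable window of intermediate times.

The constants 1.2 / 0.22 / 0.48 / 0.05 / 0.3 were calibrated once on a small
development batch (4 scenes) and checked on a held-out batch (12 scenes);
they are the package defaults and all remain keyword-configurable.

Refinement is a single-chain fixed-temperature Metropolis search: each free
parameter (`zeta, E_th, g1, g2, sigma, R_min`) is multiplied by `(1 + u)`,
`u ~ U(-1%, 1%)`; a candidate is accepted when `exp(df/T) > U(0,1)` with
`T = 0.005`; fitness is the mean best-time PR area over a fixed
common-random-number scene batch, so fitness comparisons are noise-free. A
deterministic coarse grid pre-scan (`grid_prescan`) replaces interactive
manual tuning where a larger jump is wanted.

## Numerical choices

- Euler step `dt = 1`; all times are reported in iteration counts.
- Source orientations are quantized to 64 kernel bins in the fast path; the
  simulation loop additionally skips sources below `1e-3` magnitude and
  kernel entries below `1e-3` of the peak weight (each changes `|E|` by well
  under 1%; both knobs default to exact in `excitatory_input` itself, and
  the brute-force equivalence tests run with them off).
- Orientations are canonicalized modulo pi before encoding; exact bit
  identity under `theta -> theta + pi` is impossible for arbitrary floats
  (the addition itself rounds), so parity is guaranteed to ~1 ulp and tested
  at 1e-9.
- Kernel half-extent is `ceil(3 sigma)`; rotations by multiples of pi/2 are
  snapped so parity and quarter-turn identities hold exactly.
- Degenerate inputs: zero fields are exact fixed points; zero-magnitude
  sites carry NaN orientation rather than an implicit horizontal; undefined
  precision (no active sites) is excluded from curve areas rather than
  imputed; steady-state parameters with no positive fixed point raise.
- Argmax ties in the Gabor front-end go to the lowest angle index; filters
  are DC-free and image borders are reflected, so a uniform image maps to a
  zero field.

## Problem sizes

The shipped experiment protocols use a 50-scene batch at L = 128 with 100
iterations recorded every 10, a 30-iteration annealing refinement scored on
2 scenes of 60 iterations, 20-scene batches for the clutter-suppression and
occlusion-filling experiments, and 10-scene batches per condition for the
robustness trends. These sizes give stable means (scene-to-scene standard
error of the headline means is about 0.02) at minutes of runtime on one CPU.

## Known limitations

- With this kernel, occlusion segments much longer than ~1.3 sigma cannot
  always be bridged before spurious widening erodes precision: the mean
  precision/recall frontier on held-out batches peaks around 0.86–0.91
  depending on the batch, with long-gap scenes the binding constraint.
  Raising `sigma` to reach across such gaps destabilizes the contour band
  once `sigma` approaches the typical curvature radius.
- Clutter regions are rotated rigidly and re-rasterized, losing a few
  percent of sites to collisions (audited in tests).
- The model has no stochastic neural noise, no synaptic plasticity, and no
  feedback from higher areas; the late-time "hallucinated" widening is
  therefore never corrected, which is exactly why evaluation happens at the
  intermediate optimal time.
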