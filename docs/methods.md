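# Methods

## Scope and model

The package models a badge-type passive aerosol sampler: a 12 mm SEM
stub carrying a sticky collection surface (polycarbonate filter segment,
PC, or adhesive carbon tab, CT) under a perforated mesh cap.  In still
air, particles reach the surface with an effective deposition velocity
V_dep(d_ae); the mesh cap passes a size-dependent fraction η(d_ae).  The
deposited mass per area and time is therefore C·η·V_dep for airborne mass
concentration C, and the analysis chain inverts this relation particle by
particle from microscope images.

The chain assumes:

- deposition in still air (no wind-driven or turbulent enhancement);
- spherical-equivalent sizing of irregular particles through fixed shape
  factors, uniform across the aerosol;
- particles are fully retained where they land (no bounce, washing or
  re-entrainment);
- segmentation resolves individual particles — touching particles count
  as one (no watershed splitting), and nothing below the minimum area is
  measurable.

## Image segmentation

Per tile, the grey-level histogram is thresholded by maximising the sum
of background and foreground Rényi entropies for orders α = ½, 1 and 2;
the three per-order optima are combined with the standard β-weight rule
(concordant estimates within 5 grey levels share weight, discordant ones
are dominated by the middle estimate).  The scan starts at the first
populated level with best-so-far initialised to −∞ and requires strict
improvement, so ties resolve to the lowest grey level and a histogram
where every split has zero entropy (two delta classes) returns the first
valid separator.  Thresholds are computed per tile, not per stub, because
tiles are acquired independently and drift in brightness; this is a
config switchable choice.

The bright class is foreground (backscatter imaging of mineral dust on a
carbon substrate; invertible by config).  Components are labelled with
8-connectivity and converted to physical area by the pixel pitch
(0.64 µm default); components outside 0.41–10000 µm² are dropped.

Two guards handle blank-like tiles.  A histogram with fewer than two
populated levels is degenerate and yields an empty detection list with a
warning.  Beyond that, an automatic entropy threshold *always* splits the
histogram somewhere, so a tile containing no real bright class gets cut
inside its background noise; such a split leaves the two class means
nearly equal, and a minimum class contrast (default 25 grey levels,
configurable) rejects it as blank-like.  Without this guard a noise-only
tile yields thousands of spurious speckle components.

## Sizing and physics

- d_pa = √(4A/π); d_ve = (6·f_V/π)^{1/3}·d_pa with f_V = 1.6 under the
  convention V = f_V·d_pa³ (a sphere has f_V = π/6 ≈ 0.524 — the value
  1.6 is only meaningful with the convention stated).
- d_ae solves d_ae²·C_c(d_ae)·ρ₀ = d_ve²·C_c(d_ve)·ρ_p/χ with χ = 1.4,
  ρ_p = 2.0 g cm⁻³, by a half-step-damped fixed point from the no-slip
  solution; the iteration tolerance (1e-9 on the step) is well inside the
  1e-6 contract and is cross-checked against a bisection oracle in tests.
- C_c = 1 + Kn(1.142 + 0.558·e^{−0.999/Kn}), Kn = 2λ/d, with λ = 0.0665 µm
  at 293 K and 101.3 kPa (Allen–Raabe solid-particle constants); air
  state fully overridable.
- Mass m = ρ_p·f_V·d_pa³ with unit handling such that a 1 µm d_pa
  particle at the defaults weighs 3.2×10⁻³ ng.
- V_dep: default `settling_plus_diffusion` — Stokes settling of the
  unit-density d_ae sphere plus Stokes–Einstein diffusion across a
  boundary layer δ = 1 mm; `settling_only` selectable.  δ is the one free
  deposition parameter; 1 mm is a typical indoor still-air value and only
  matters below ~0.5 µm.
- η: monotone piecewise-linear interpolation of a knot table, clamped at
  the ends.  The published curves for this cap geometry are not openly
  tabulated, so the shipped default used in analysis is the unit curve,
  and a clearly-labelled placeholder (declining from 1.0 below 1 µm to
  0.2 at 15 µm) is provided for sensitivity studies; users with the real
  curves load them from CSV.  Efficiency is applied per particle by
  default; a per-fraction scalar mode exists because the original
  workflow is ambiguous on this point.

## Quantification

C_f = Σ m_i·w_f(d_ae,i)/(η_i·V_dep,i)/(A·T) in mg m⁻³.  PM weights are
sharp-cut and boundary-inclusive (d_ae ≤ 2.5 counts toward PM₂.₅); a
smooth lognormal-ogive convention is selectable.  The normalising area A
defaults to the analyzed (summed tile) area capped at the stub disc;
this choice rescales C multiplicatively and is exposed in config.
Particle counts per fraction below 55 (PM₂.₅) / 71 (PM₁₀) raise
counting-statistics warnings without blocking results.

Field-blank means are pooled per collection surface across locations and
subtracted from every result of that surface; transport blanks are
summarised but never subtracted; negative corrected concentrations are
retained, since truncating them would bias campaign means and blank
variance estimates.  Time averages weight each occasion by its duration.
Every result row carries a `config_id` hash of the full physics
configuration so results from different physics cannot be pooled
silently.

## References

Impactor: C = (mean(post) − mean(pre) − blank)/Q̄t with duplicate
weighings and the mean of start/end flow readings; flows outside
10 ± 0.5 L min⁻¹ flag a warning but still compute.  Optical counter:
per-bin mass = n·(π/6)·d_rep³·ρ with d_rep the geometric mean of the bin
edges (arithmetic mode available; the instrument's internal algorithm is
proprietary, so the choice is logged with every output), cumulated over
bins with upper edge ≤ the PM level; PM₀.₇₅ = (PM₀.₅ + PM₁.₀)/2 exactly.

## Synthetic deposition generator

The generator is the exact inverse of the chain.  A count-lognormal
aerodynamic-diameter distribution (median `cmad_um`, GSD; GSD = 1 is an
exact monodisperse population) is discretized into log-spaced bins;
expected deposited counts follow λ(d) = C·f(d)/E[m]·η(d)·V_dep(d)·A·T and
realized counts are Poisson.  Placement is complete spatial randomness
over a rectangular tile grid (still air); border particles belong to the
tile containing their centre and are clipped there.

Particles are rendered as ellipses with aspect ratio U(1, 3): pixels are
ranked by subpixel coverage (4×4 sampling) and exactly round(area/px²)
pixels are filled, so the rendered pixel count equals the target
projected area up to rounding — the projected area, not the shape, is
the controlled quantity, and thin sub-pixel ellipses cannot collapse
between pixel centres.  Overlapping footprints are flagged `merged` in
the truth table; the segmenter will count them as one particle.  Grey
levels are Gaussian (background mean 60, sd 8; particles 200, sd 8 on
the 8-bit scale) with the tails truncated at 2 sd toward each other,
emulating the bounded brightness ranges of a uniform substrate versus
dense mineral particles under backscatter imaging; consequently the two
classes never bleed and the entropy threshold lands between them whenever
particles are present.  All randomness flows from one integer scenario
seed through named, stable sub-streams (population, placement, shape,
render, contamination, gravimetry).

Fabricated references share the same binned distribution: filter gains
are C_fraction·Q·t (optional Gaussian weighing noise, default 0 — the
real weighing precision is unknown), and OPC bin counts are the number
concentrations integrated over the counter's 0.3–10 µm channels.

What the generator does *not* emulate: real substrate texture and
focus/charging gradients, aggregated or non-convex particle shapes,
electrostatic or humidity effects, and any mesh-cap physics beyond the
supplied η curve.  Passing recovery tests therefore demonstrate the
correctness of the inversion chain, not field accuracy of the sampler.

## Validation sizes and numerical choices

The recovery campaign deposits ≈6300 particles (2.0 mg m⁻³ × 24 h over
3.0 mm²; CMAD 2.5 µm, GSD 1.6, sizes 1.5–12 µm) on a 6×5 tile grid and
recovers PM₂.₅ and PM₁₀ within ±10% (typically within 5%).  Imaging for
this check is synthesized at 0.25 µm/px: fine enough that the
pixel-quantized measured-size grid resolves the 2.5 µm cut.

At the historical 0.64 µm pixel the quantization is qualitatively
different: measured areas of 3 and 4 pixels map to 2.18 and 2.52 µm
aerodynamic diameter, so no measurable size exists in (2.18, 2.5], and
every particle whose true size falls in that band is mis-sized out of
PM₂.₅ — one-sidedly, because the next grid point lies just above the
cut.  Together with the 0.41 µm² minimum area (one pixel is 0.4096 µm²),
this caps coarse-pixel PM₂.₅ recovery near ~78% for this size
distribution while PM₁₀ stays near 98%.  The package treats this as a
feature to demonstrate, not a defect to hide: a dedicated test and an
acceptance-script quantity report the coarse-pixel deficit, which is a
concrete mechanism for passive-sampler PM₂.₅ readings falling well below
impactor values at low magnification.

Other numerical choices: thresholding tie-breaks to the lowest grey
level; the fixed-point iterations are damped and run to 1e-9 step
tolerance (≤200 iterations, error raised on non-convergence); efficiency
and PM-weight evaluations are clamped interpolations; blank statistics
use the sample standard deviation (ddof = 1).

## Known limitations

- Touching particles are measured as one (no de-clumping); at the
  recovery conditions merging affects ~2–3% of particles and is part of
  the quoted tolerance.
- The blank-like contrast guard trades a small false-negative risk on
  sparse genuine deposits for robustness against noise splits; its
  threshold is configurable.
- The shipped efficiency placeholder is synthetic; quantitative fidelity
  to a specific mesh cap requires the measured curves.
- No uncertainty propagation beyond blank standard deviations.
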