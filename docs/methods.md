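# Methods

## Model

The simulation represents the contact interface between a T-cell plasma
membrane and an opposing surface (a functionalized coverslip or an APC
membrane) as a periodic square lattice with lattice constant a = 10 nm.
State per pixel i:

* the inter-surface separation z_i > 0 (nm), initialized at 70 nm;
* at most one molecule per surface (single occupancy) — the 10 nm pixel is
  the molecular footprint, so a 1×1 µm² patch holds at most 10,000
  molecules per surface.

Molecules are agents with a species identity; species are described by a
small physical parameter set (lengths in nm, energies in kT):

| parameter | meaning |
|---|---|
| l_mol, k_mol | uncompressed length and compressional stiffness: the molecule pays k(z − l)² when the gap closes below its length |
| ligand, U_bind, l_complex, w_bind | square binding well: U when \|z − l_complex\| < w (strict inequality), centred on the engaged complex length |
| D | diffusion coefficient (nm²/s) |
| J_self | nearest-neighbour same-species pair energy (negative = self-clustering) |
| pinned_height | if set, occupied pixels hold z exactly at this value |

All energies are in units of kT, so Metropolis acceptance is exp(−ΔE) with
no explicit temperature.  The Hamiltonian is H = H_int + H_el: H_int sums
the wells and springs over occupied pixels plus the J pair terms; H_el =
Σ_i κ/(2a²)(Δ_d z_i)² with the 5-point periodic Laplacian Δ_d z_i =
z_i1 + z_i2 + z_i3 + z_i4 − 4 z_i and the effective rigidity of two
stacked membranes κ = κ1·κ2/(κ1 + κ2) (a rigid coverslip has κ2 = ∞, so
κ = κ1).

### Dynamics

One iteration represents dt = 0.01 s:

1. Every mobile molecule independently attempts a hop to one of its 4
   nearest neighbours with probability p = 4·D·dt/a².  This p makes the
   accepted free walk reproduce the 2D law MSD = 4Dt exactly; it requires
   p ≤ 1, i.e. D ≤ a²/(4dt) = 2,500 nm²/s at the defaults (a
   configuration error otherwise).
2. Attempts onto occupied pixels (same surface) are rejected outright.
   Surviving attempts are accepted with the two-stage product
   P(old→free)·P(free→new), each factor the Metropolis probability of the
   corresponding energy difference.  ΔE(leave) contains the molecule's own
   well/spring terms and J bonds at the old pixel (the vacated pixel keeps
   its height); ΔE(enter) contains the same terms at the target plus, for
   pinned species, the elastic cost of snapping the target pixel to the
   pinned height.
3. Accepted attempts colliding on one target pixel are resolved in favour
   of the largest total energy decrease; exact ties are broken by the
   seeded RNG.  Moves are applied synchronously (proposal energies are
   evaluated against the pre-move state), then the field is re-pinned at
   the new pixels of pinned species.
4. Every unpinned pixel receives one height proposal Δz ~ N(0, σ_z²) with
   σ_z = 1 nm, evaluated sequentially in a fresh random pixel order
   against the current field (simultaneous Laplacian updates would be
   inconsistent), accepted by the Metropolis criterion on the local ΔE;
   proposals that would make z non-positive are rejected.

Hops run before height moves within an iteration.  All randomness flows
from one `numpy.random.Generator` seeded by the run seed, so trajectories
are bit-reproducible and a run is reconstructible from its manifest.

An optional translocation mode adds a centripetal bias to the neighbour
choice of selected species: weights 1/4 + b/2·(e_k·u) with u the unit
vector toward the target and b = v·dt/(p·a), giving a mean drift of
exactly v·dt per iteration (0.19 nm at the default v = 19 nm/s) on top of
unbiased diffusion.  b ≤ 1/2 is required for non-negative weights.  In
translocation scenarios the self-clustering of the translocated species is
switched off so the imposed drift is not hindered.

### Pinning

Pixels occupied by TCR or CD11 hold the separation at the engaged heights
13 nm and 35 nm respectively for the whole run (`pin_mode="always"`,
the default), whether or not a ligand is currently engaged; a
`pin_mode="when_bound"` switch disables the static pins.  When a pinned
molecule vacates a pixel, the pixel retains its last height and resumes
fluctuating — this avoids discontinuous energy injection.  Pinned pixels
are skipped by the height sweep (not counted as attempts).

## Parameter defaults and rationale

The engaged complex lengths (13 nm, 35 nm), lattice constant, initial
separation, σ_z, dt and iteration count are fixed by the model.  The
remaining numeric values are implementation-chosen defaults, overridable
from configuration:

| species | l_mol | k_mol | ligand | U_bind | w_bind | D | J_self | pin |
|---|---|---|---|---|---|---|---|---|
| TCR | 10 | 2 | αCD3 / pMHC | −8 | 2 | 1250 | −2 | 13 |
| CD45 | 40 | 0.5 | — | — | — | 1250 | 0 | — |
| CD11 | 20 | 2 | ICAM (APC) | −6 | 2 | 1250 | −2 | 35 |
| pMHC | 7 | 2 | — | — | — | 1250 | 0 | — |
| ICAM | 19 | 2 | — | — | — | 1250 | 0 | — |

* D = 1,250 nm²/s (p = 0.5): membrane-protein diffusion on the
  10⁻² µm²/s scale; the hop rule caps admissible D at 2,500 nm²/s for
  dt = 0.01 s, so faster diffusion requires a smaller dt.
* Binding wells of several kT depth and 2 nm half-width: strong specific
  engagement without irreversibility at the 100 s timescale.
* CD45: a 40 nm, relatively soft spring — compression to the 13 nm
  TCR-contact height would cost ≈ 360 kT, so CD45 is effectively excluded
  from tight-contact zones (the kinetic-segregation mechanism).
* κ1 = 30 kT, a standard plasma-membrane bending rigidity; with σ_z fixed
  at 1 nm this value was calibrated once so the post-burn-in membrane-move
  acceptance on the default coverslip scenario falls inside the 40–50%
  tuning window (measured ≈ 44%), then frozen.  The APC scenario gives the
  second membrane the same rigidity (κ_eff = κ1/2).
* PLL coverslips: a species-independent well of depth pll_U (default
  −2 kT) centred on each molecule's own length with a 5 nm half-width —
  wide enough to overlap the pinned TCR height.  The αCD3 scenario models
  only the specific coat (an immobile ligand at every substrate pixel).
* APC scenarios add mobile pMHC and ICAM on a second occupancy layer; a
  configurable cognate fraction (1% in the low-antigen variant) splits the
  pMHC population into a TCR-binding and a physically identical
  non-binding species.

## Synthetic initial conditions

The generator emulates the placements seen in early-synapse imaging:

* `gaussian_clusters` — microvilli-like tight TCR clusters (default 2
  clusters/µm², 60 molecules/cluster, 50 nm SD);
* `halo` — annular placement around the TCR cluster centres: interstitial
  CD11 at 120 ± 40 nm (just outside the ~100 nm cluster edge) and
  ring-like CD45 at 350 ± 100 nm (defaults 150 and 400 molecules/µm²);
* `uniform` — CSR placement (the APC ligands; also available for the
  robustness-style "diffuse" variants of CD45/CD11);
* `ring` — a single annulus around a fixed centre;
* `localizations` — ThunderSTORM-style CSV import (x/y in nm, optional
  crop window and blink-merge radius; each record is one molecule by
  default).

Points are rasterized to pixels by floor division; colliding records are
displaced to the nearest free pixel (breadth-first Chebyshev rings,
nearest-Euclidean within a ring, seeded tie-break), so counts are
preserved up to the capacity limit.  Pixel indexing is 0-based, row-major,
origin at the lower-left; x maps to columns.

What the generator does *not* emulate: localization uncertainty and
multiple blinking of one fluorophore (unless a merge radius is used),
drift/registration artefacts, cell-scale footprint geometry (the periodic
window has no cell boundary), and molecular crowding beyond single
occupancy.  Passing tests therefore demonstrate the mechanism — kinetic
segregation by size plus membrane-height coupling — under idealized
point-pattern inputs, not a quantitative fit of any experimental image.

## Topology analysis and PCFs

The topology analysis grows disks of radius r around every reference
point; the band between consecutive dilations of the union (the Minkowski
perimeter region) defines the conditional density of each other species:
its point count in the band divided by the band area (nm⁻²).  A
per-perimeter-length normalization (band area / band width) is exposed as
an option.  Distances are exact Euclidean distances between pixel centres,
computed by a distance transform on a 3×3-tiled raster for periodic
windows; imported crops use plain (clipped) bands whose densities are
normalized by the clipped band area.  Band 0 covers distance 0 (on a
reference pixel) up to the first radius.  The reference species itself is
summarized by its univariate pair-correlation function g(r) (ring binning,
window-area normalization; g → 1 for CSR).  `peak_shift` reports the
radius of each species' density maximum; ties report the smaller radius
and flat curves report "no peak" with the plateau value.

In the default analyses the dilation radii run from 20 to 400 nm in 20 nm
bands: beyond ~400 nm (at 2 clusters/µm²) the bands shrink to a few void
pixels and their densities are shot-noise dominated.

## Numerical choices

* Binding wells use strict inequality at the boundary; the spring is
  continuous (0) at z = l_mol.
* Localized ΔE evaluations (hop and height moves) touch only the affected
  pixels and their Laplacian stencils and agree with full-grid
  recomputation to 1e−9 kT (property-tested against an independent
  loop-based Hamiltonian).  The five-pixel stencil requires grids of at
  least 3×3; the lattice type itself accepts any size ≥ 1 pixel for
  capacity accounting.
* Metropolis exponents are clipped at 700 kT to avoid floating-point
  underflow warnings; the acceptance there is 0 to double precision.
* Cross-gap binding in APC scenarios requires the T-cell molecule and its
  ligand to occupy the same (row, col) pixel on opposite surfaces; the
  pair energy is stored on the T-cell species so it is counted once.
* Trajectory reports carry per-iteration hop/height acceptance counts;
  full energy breakdowns are computed at snapshot iterations (an
  every-iteration full-grid energy would dominate runtime at 256²+).

## Default problem sizes

The shipped end-to-end checks run the default coverslip scenario at
256×256 pixels (2.56 × 2.56 µm², ≈ 4,400 molecules) for 10,000 iterations
(100 s), and the acceptance-rate measurement at 128×128 for 1,000
iterations; both are the package's default verification scales.  Larger
grids (the 400×400, 4×4 µm² scale with wider margins) are configured the
same way and scale linearly in pixels × iterations.

## Known limitations

* No endocytosis/recycling, no cytosolic proteins, no signaling state
  machines: binding is purely energetic (no explicit on/off rate
  constants), and the only molecular state is bound/unbound.
* No membrane tension or continuum curvature elasticity beyond the
  discrete Laplacian-squared term; a single separation field carries both
  membranes' fluctuations through the effective rigidity (the APC-side
  ligands diffuse on their own occupancy layer but do not carry an
  independent height field).
* Synchronous hop application with contention resolution is one reading of
  "all molecules attempt to hop each iteration"; sequential per-molecule
  updates would slightly change collision statistics at high density.
* PCFs for bounded (non-periodic) windows apply no edge correction;
  prefer generous crops or the periodic window.
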