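# Models and methods

This note documents the models implemented in `t6phase`, the defaults and
units of every parameter that matters, the numerical choices made where
the design was genuinely open, and what the synthetic inputs do and do not
capture about real colony images.

## Individual-based model (`t6phase.ibm`)

State: a W×H lattice (default 500×500) whose sites hold strain A (+1),
strain B (−1) or an empty patch (0), seeded fully occupied with
`round(W·H·init_freq_A)` A-cells at uniformly random positions.

Per time step, each occupied cell is independently marked a *killer* with
probability `kill_fraction` (default 0.05/step) and a *reproducer* with
probability `repro_fraction` (default 0.05/step). The update is then
applied sequentially in row-major order from the upper-left corner:

* a visited killer empties all Moore (8-)neighbours of the opposite
  genotype — kin and empty patches are untouched;
* a visited reproducer copies itself into one uniformly chosen adjacent
  empty patch, or aborts if all eight neighbours are occupied;
* a cell killed earlier in the sweep loses its marks (the state at visit
  time governs), and newborns never act within the sweep in which they
  were placed.

Design choices where the update rule is under-determined, all exposed as
configuration rather than hard-wired:

* *Bernoulli marks, not exact 5% quotas.* Independent per-cell draws give
  the stated rate in expectation, avoid a global shuffle, and differ from
  a quota only at O(1/√N) for N lattice sites.
* *A cell may be both killer and reproducer in one step*; killing is
  applied before reproduction at the visited cell.
* *Boundary*: `closed` (no wrap) by default, mirroring a finite colony;
  `periodic` is available and is used for all structure-factor work in
  this package, since the discrete Fourier transform assumes a periodic
  image and a closed boundary would contribute edge leakage to S(q).

Invariants maintained (and tested): labels stay in {+1, −1, 0}; an absent
strain never reappears; with `kill_fraction = 0` a fully occupied lattice
is frozen; killing transiently creates empties but reproduction refills
them (long-run empty fraction ≈ 2% at defaults).

## Ising model (`t6phase.ising`)

The statistical-mechanics reference point for the same universality class.
The local Hamiltonian of a site is the sum of its eight nearest neighbours
(periodic lookup) multiplied by the centre spin — +8 when fully aligned,
−8 when fully anti-aligned; energy decreases with alignment, and since a
single flip only negates the local Hamiltonian, the energy difference of a
flip is ΔE = 2·H_old in units of k_B·T. A flip is accepted iff
`exp(−β·ΔE) > u` with `u ~ Uniform[0,1)`. Because `u < 1`, every
energetically non-increasing move is accepted, and capping the weight at 1
(the Metropolis form) would not change any outcome. A sweep is W·H flip
attempts at uniformly random sites (with replacement); one sweep is one
time unit. Default β = 1 (the ratio of coupling to k_B·T used throughout),
no external field, spins initialised 50:50 at random ("infinite
temperature"). Magnetization is *not* conserved — the hallmark of Model A
dynamics — and its sample variance over a coarsening run is positive.

## Reaction–diffusion model (`t6phase.pde`)

Two strains with identical basal growth rate `r` (1/time) and
density-dependent mortality `s` (1/(density·time)) kill each other on
contact, B killing A at rate `alpha_ab` and A killing B at `alpha_ba`
(1/(density·time)); cells disperse with coefficient `d` (length²/time):

    dA/dt = A (r − s(A+B) − alpha_ab·B) + d ∇²A
    dB/dt = B (r − s(A+B) − alpha_ba·A) + d ∇²B

These right-hand sides are validated against every closed-form result of
the well-mixed analysis (see below): all four equilibria are fixed points
to machine precision, and the linearised growth rate of a compositional
mode `a·sin(βx)` measured from short integrations matches
`alpha·A₀ − d·β²` (symmetric killing) to better than 1%.

The public-goods extension makes strain A a cooperator secreting a
diffusible good S at rate `rho`, decaying at `lam` (1/time), diffusing
with `D` (length²/time), raising both strains' growth rate by `b` per unit
concentration, and costing the producer `c` (1/time):

    dA/dt = A (r − c + b·S − s(A+B) − alpha·B) + d ∇²A
    dB/dt = B (r     + b·S − s(A+B) − alpha·A) + d ∇²B
    dS/dt = rho·A − lam·S + D ∇²S

`s > rho·b/lam` is enforced so a pure cooperator population has a finite
equilibrium. Defaults throughout: r = 2, s = 2, alpha = 0.5, d = 0.01 and
b = 1.9, c = 0.1, rho = lam = 100, D = 0.1 — at which a pure cooperator
population equilibrates at density 19 versus 1 for pure cheats.

### Numerics

* **Time stepping**: explicit forward Euler on a periodic grid, with the
  diffusive stability bound `dt < dx²/(4·max(d, D))` checked up front
  (violations raise with the bound printed). First-order convergence in
  `dt` is verified by Richardson comparison in the tests.
* **Stiff good dynamics**: with `lam = 100` the decay term would dictate
  `dt`. The production/decay part of the S equation is therefore
  integrated exactly over each step (`S ← S·e^{−λΔt} + (F/λ)(1−e^{−λΔt})`
  with the slowly varying source F frozen), so `dt` is limited only by
  the ecological rates and the diffusive bound.
* **Grid spacing**: `dx = 0.1` by default. With `d = 0.01` the interface
  width `√(d/(αA₀))` is about 0.2 length units; at `dx = 1` that is far
  below the grid scale, interfaces pin to the lattice and coarsening
  artificially freezes, while `dx = 0.1` resolves them with ≈2 cells.
* **Negative-density guard**: Euler undershoot near extinction fronts is
  clipped at 0; clip events are counted, reported in snapshot metadata
  and warned about, and vanish as `dt → 0`.
* **Initial conditions for spatial runs**: the default is a random
  per-cell genotype assignment at density r/s — the continuum analogue of
  the randomly seeded lattice used by the discrete models. Smooth
  mean-zero noise around coexistence (amplitude configurable, 1% of the
  mean density in the CLI two-strain preset) is also available, but it
  biases the early pattern towards the longest wavelengths (all modes
  with `d·β² < α·A₀` grow, the widest fastest), which shortens the
  observable scaling window; and for invasion-from-rarity experiments it
  cannot work at all, since a uniform 5% cooperator composition plus
  small noise never locally crosses the basin boundary, so cooperators
  would die everywhere at once. Per-cell seeding instead nucleates locally
  pure patches, as a plated colony does.

### Perturbation growth and the uphill-diffusion check

`perturbation_growth` initialises `A = A₀ + a·sin(βx)`,
`B = B₀ − a·sin(βx)` on a 1-D periodic domain commensurate with the
wavelength (incommensurate domains are rejected to avoid mode leakage),
integrates briefly, and fits the exponential rate of the sin(βx) mode of
the composition φ_A = A/(A+B). Amplitudes above 1% of the base density
trigger a nonlinearity warning. Without killing the mode decays at exactly
`−d·β²`; with killing the rate is positive for sufficiently small β and d
and decreases monotonically in both — in the growing regime the
composition change opposes the sign of ∇²φ_A at the mode extrema,
i.e. effective diffusion runs uphill.

### Cooperation scenarios

`run_cooperation_scenarios` contrasts cooperator fate across the four
combinations of {non-spatial, spatial} × {no killing, killing}:
non-spatial runs integrate the three-variable ODE (LSODA) from a mixed
state at total density r/s; spatial runs use a 1-D periodic domain of
1,024 cells (dx = 0.1) with per-cell genotype seeding. Horizons default
to 200 (non-spatial) and 600 (spatial) time units, by which the outcomes
are resolved: cheats fix whenever killing is absent; with killing but no
space the system is bistable with the smaller basin belonging to the
cooperator (the interior saddle satisfies A − B = c/alpha > 0); with both
killing and space, phase separation assorts producers with producers and
cooperators sweep to fixation even from a 5% start.

## Well-mixed analysis (`t6phase.wellmixed`)

Closed forms are hard-coded from the model and verified numerically (each
equilibrium's residual must be < 1e−12; classifications are cross-checked
against numerically differentiated Jacobians in the tests):

* two-strain equilibria: (0,0) unstable (tr J = 2r, |J| = r²);
  (r/s, 0) and (0, r/s) stable for positive killing
  (tr J = −r(s+α)/s, |J| = α·r²/s); coexistence
  `A* = α_AB·r/(s(α_AB+α_BA)+α_AB·α_BA)` (and symmetrically B*) a saddle,
  with `A*/B* = α_AB/α_BA` — which is also the separatrix ratio used by
  `domination_outcome`;
* cooperator/cheat equilibria under the quasi-steady good `S = ρA/λ`
  (valid because the good relaxes at rate λ ≫ the ecological rates; the
  full three-variable integration agrees with the reduced equilibria to
  1e−6 at λ = 100): pure cooperator `A* = λ(r−c)/(λs−ρb)`, stable iff
  `α > c(λs−ρb)/(λ(r−c))`; pure cheat `B* = r/s`, always stable; interior
  saddle at `A = (r + sc/α)/(2s + α − bρ/λ)`, `B = A − c/α`, which exists
  above the same threshold and always has A > B when c > 0.

Stability is classified from eigenvalue real parts with tolerance 1e−9
(trace and determinant are reported alongside); the general condition for
cooperator increase is exposed numerically as
`fitness_difference(A, B) = −c + α(A−B)`, whose sign flips with A−B —
the positive frequency dependence induced by killing.

## Spatial statistics (`t6phase.spatial_stats`)

**Structure factor.** `S(q_x,q_y) = |FFT(I − mean)|²/(W·H)` of the ±1
label image (empties mapped to 0), radially averaged over annuli of one
fundamental frequency 2π/max(W,H) with the DC bin dropped. The
normalisation makes the sum of S over all non-DC bins equal the image's
total centred squared magnitude (Parseval), so curves from equal-sized
images are directly comparable. No window is applied by default
(simulation output is periodic); a Hann taper is available for
closed-boundary or experimental images.

**Peak.** The characteristic wavenumber is the first moment
`q_m = Σ q·S(q)/Σ S(q)` over the full retained band — the standard choice
in coarsening studies, scaling exactly as the inverse domain size under
dynamic scaling and robust to the sampling noise of the lowest annuli
(which hold only a few Fourier modes each). A binned-argmax alternative is
provided; it is bin-exact for sharply peaked spectra (stripes) but
degenerates on broad late-coarsening spectra, where the maximum wanders
among the noisy lowest bins, so scaling fits with it are only meaningful
on strongly peaked inputs. Curves whose 95th-percentile/median ratio is
below 2 are flagged as lacking a characteristic scale.

**Scaling and collapse.** `coarsening_fit` least-squares fits
log S(q_m) against log q_m (Model A: slope −2) and log q_m against log t
(slope −1/2), discarding the earliest 10% of snapshots as transient.
`collapse_curves` rescales curves onto (q/q_m, S·q_m²·L²) and scores
overlap as the median pairwise RMS distance on a shared abscissa grid;
rescaling curves from one coarsening process drives the score down, and
IBM and Ising curves collapse onto a common master curve.

**Assortment.** For focal strain g at interaction radius h, every
trimmed-interior g-pixel's (2h+1)² window (centre excluded) contributes
the local frequency of g among *occupied* neighbours; with p the mean
local frequency and f_g the global frequency of g among occupied sites,

    r_g = (p − f_g) / (1 − f_g),

computed via FFT convolution with the all-ones window kernel and verified
exactly (to 1e−12) against a brute-force sliding window. The
normalisation is a reconstruction constrained by the statistic's stated
properties: range [−1, 1], 0 under random mixing, 1 under complete
segregation at scales ≫ h, and "mean frequency of g within radius h
relative to its global frequency". Empty sites are excluded from the
neighbour count — a choice that matters only for lattice snapshots, since
experimental-style binarised images are fully occupied. Radii run 1…36 by
default; a border of width h is trimmed before averaging.

## Synthetic fixtures and what passing tests show

`t6phase.fixtures` generates label images with known ground truth: i.i.d.
random (r = 0, flat S), stripes (peak at 2π/period), checkerboard
(non-positive r), half-plane splits (r high and decreasing in h, with
brute-force-enumerated values), and a self-similar labyrinth series built
by block-rescaling one pattern (peak scaling exponent −2 by construction,
validating the fitting machinery independently of any simulator).

These fixtures, and the simulator outputs, emulate *segmented, binarised*
colony images on a regular grid. They do not model optical blur,
segmentation error, irregular cell sizes and shapes, partial occupancy at
colony edges, or three-dimensional structure projected into the imaging
plane. Passing tests therefore demonstrate correctness of the statistics
and the model dynamics, not robustness of the pipeline to microscopy
artefacts; experimental images should be binarised and quality-checked
before being fed to `read_label_image`.

## Problem sizes

The bundled analyses use 256×256 lattices over ≤3,200 update steps
(IBM), ≤320 sweeps (Ising) and ≤400 time units (PDE), with three seeds
pooled for scaling fits, and 1-D domains of 1,024 cells for the
cooperation scenarios; these sizes resolve a decade of coarsening and
fully resolved invasion outcomes. The package runs the original 500×500
scale unchanged when asked.

## Known limitations

* The IBM supports exactly two strains and symmetric killing rates;
  asymmetric killing is studied in the PDE (alpha_ab ≠ alpha_ba).
* No demographic noise in the PDE (deterministic fields); stochastic
  effects enter only through initial conditions.
* Forward Euler is first-order; halve `dt` to check any quantitative
  conclusion that depends on trajectory details.
* The assortment normalisation and the q_m estimator are reconstructions
  constrained by their stated properties (see above), not transcriptions
  of a reference implementation.
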