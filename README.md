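# t6phase

Simulation and analysis toolkit for **contact-killing-driven phase
separation** in dense bacterial populations, and its consequences for the
evolution of public-goods cooperation.

Many bacteria carry a Type VI secretion system (T6SS), a molecular
speargun that kills adjacent cells lacking the matching immunity proteins.
When two mutually antagonistic strains grow in a densely packed layer, this
purely local killing is enough to demix an initially well-mixed population
into growing clonal domains — an order–disorder transition in the
non-conserved ("Model A") universality class, whose coarsening obeys
`S(q_m) ∝ q_m⁻²`. The resulting genetic assortment can in turn protect
secreted public goods from exploitation by non-producing cheats.

The package is aimed at researchers in microbial ecology and evolution who
want to reproduce, probe or extend these dynamics. It provides:

* **Simulators**
  * `t6phase.ibm` — individual-based lattice model: each step 5% of cells
    fire their T6SS (killing opposite-genotype Moore neighbours) and 5%
    reproduce into an adjacent empty patch, updated sequentially in
    row-major order;
  * `t6phase.ising` — Ising spin model with the eight-neighbour local
    Hamiltonian `H = (Σ neighbours) × centre`, flip rule
    `exp(−β·2H_old) > u`, and sweeps of `W·H` random flip attempts;
  * `t6phase.pde` — two-strain reaction–diffusion model
    `∂A/∂t = A(r − s(A+B) − α_AB B) + d∇²A` (and symmetrically for `B`),
    with an optional diffusible public good
    `∂S/∂t = ρA − λS + D∇²S` produced by a cooperator strain at growth
    cost `c` and benefiting both strains at rate `b` per unit
    concentration.
* **Analytics** (`t6phase.wellmixed`) — the four equilibria of the
  well-mixed two-strain system, their Jacobian trace/determinant
  classification (coexistence is a saddle: one strain always wins, `A`
  dominates iff `A/B > α_AB/α_BA`), and the cooperator/cheat equilibria
  under the quasi-steady good `S = ρA/λ`, including the stability
  threshold `α > c(λs − ρb)/(λ(r − c))`.
* **Spatial statistics** (`t6phase.spatial_stats`) — radially averaged
  structure factor `S(q)` with peak extraction and scaling/collapse fits,
  and the assortment statistic `r(h)` (kin enrichment within interaction
  radius `h`, normalised to `[−1, 1]`, 0 under random mixing).
* A **CLI** (`t6phase simulate|analyze|fixtures …`) writing CSV/PNG/text
  outputs plus a checksummed run manifest.

## Worked example

```python
import numpy as np
from t6phase import IBMParams, run_ibm
from t6phase.spatial_stats import assortment_profile, coarsening_fit

steps = [50, 100, 200, 400, 800, 1600, 3200]
params = IBMParams(width=256, height=256, seed=1, boundary="periodic")
snaps, summary = run_ibm(params, n_steps=3200, record_steps=steps)

fit = coarsening_fit([snaps[s].grid for s in steps], [float(s) for s in steps])
print(f"S(q_m) vs q_m exponent: {fit.slope_S_vs_qm:.2f} +- {fit.stderr_S_vs_qm:.2f}")
prof = assortment_profile(snaps[3200].grid, h_max=10)
print(f"assortment r(h=1) = {prof.r_g[0]:.3f}, r(h=10) = {prof.r_g[9]:.3f}")
```

prints

```
S(q_m) vs q_m exponent: -2.14 +- 0.12
assortment r(h=1) = 0.979, r(h=10) = 0.747
```

The exponent is the Model-A coarsening signature (−2 within fit error): as
clonal domains grow, the characteristic wavenumber `q_m` falls and the peak
height rises as `q_m⁻²`. The assortment values show strong kin enrichment
around each cell (r ≈ 0.98 among immediate neighbours after 3,200 update
steps, still ≈ 0.75 at distance 10), compared with r ≈ 0 for the random
initial condition — the spatial structure that shields public-good
producers from cheats.

The same analyses are available from the shell:

```bash
t6phase simulate ibm --width 256 --height 256 --boundary periodic \
    --steps 3200 --record-steps 50,100,200,400,800,1600,3200 --seed 1 --out run/
t6phase analyze scaling --in run/ --out scaling.csv
t6phase analyze assortment --in run/snap_003200.txt --h-max 36 --out assortment.csv
```

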