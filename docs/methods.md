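# Model and methods

`parabd` simulates depolymerization-driven chromosome translocation by the
bacterial ParABS system: a coarse-grained ParB-decorated polymer (the
ParB-parS-ori complex, "ParB polymer") bound to a cross-linked bundle of ParA
filaments that it disassembles. Destroying ParA ahead of itself, the polymer
maintains a co-moving ParA concentration gradient and rides it across the
cell — a self-diffusiophoretic mechanism that needs no processive coupler.

## Coarse-grained representation

All species are spheres of diameter `a` (the length unit). Energies are in
`kT`, drags in units of the reference subunit friction `gamma0 = kT / D0`,
and times in `tau0 = a^2 / D0`. A documentation-level conversion
(`parabd.units`) maps to physical units with `a ~ 5 nm` and a cytoplasmic
subunit diffusivity of order `1 um^2/s`; no computation depends on it.

* **ParA bundle** — `n_filaments` straight chains of `filament_length`
  subunits on a triangular lattice (or a ring, the "tube" variant) at
  spacing `d0`, axis along +x. The +x terminal subunit of each filament is
  anchored (the swarmer pole); the -x ends are the free, disassembling tips.
  A configurable fraction (default 40%) of subunits carries a harmonic
  crosslink to the same-index subunit of the nearest neighbouring filament.
* **ParB polymer** — a flexible self-avoiding chain of `parb_total_length`
  subunits (default 100); the central `parb_binding_length` subunits
  (default 50) bind ParA, the flanking segments are inert and carry a larger
  drag factor (default `alpha = 5`) representing the bulk of the chromosome.
* Every subunit carries a unit polarization vector marking its binding-site
  direction; sites are arranged helically along each chain.

## Interactions

Functional forms are the simplest smooth potentials satisfying the model's
qualitative requirements; every constant is a config field.

| term | form | default |
|---|---|---|
| excluded volume | `(k_ev/2)(r-a)^2` for `r < a`, else 0 | `k_ev = 100 kT/a^2` |
| chain bond | harmonic, rest length `a` | `k_bond = 100 kT/a^2` |
| crosslink | harmonic, rest length `d0` | `k_x = 50 kT/a^2`, `d0 = 2a` |
| bending | `k_bend (1 - cos theta)` | ParA `50 kT`, ParB `0` |
| alignment | `(k/2)(p.b_hat - cos theta0)^2` per adjacent bond | `10 kT`, `theta0 = 90 deg` |
| helix (nn, nnn) | `(k/2)(p_i.p_j - cos psi)^2` | `10 kT`; ParA 60/120 deg, ParB 30/60 deg |
| binding | `-eps_b f(r) h1(c1) h2(c2) h3(c3)` | `eps_b = 10 kT` |

The binding radial factor is a quartic bump `f = (1 - s^2)^2`,
`s = (r - r_b)/(range_b - r_b)` (`r_b = a`, `range_b = 1.5a`), so the well
depth is exactly `eps_b` at contact and the potential is C1 at its edges.
The angular factors `h(c) = exp(-(1-c)^2 / 2 kappa^2)` select configurations
in which the two polarization vectors point at each other along the
connecting line (`c1 = p_A.u`, `c2 = -p_B.u`, `c3 = -p_A.p_B`; widths 0.6 in
cosine). Variant forms for tip-binding and side-binding without ParB
polarization drop the `h2 h3` factors; the tip variant additionally points
the ParA sites out of the filament tip (`theta0 = 180 deg` relative to the
tip->anchor bond) and uses a narrower axial width (0.3), since a tip
presents a single axial interface.

Design notes:

* Excluded volume is a **soft harmonic sphere** rather than a truncated
  Lennard-Jones core. All qualitative contracts are identical (purely
  repulsive iff `r < a`, continuous at contact) and the bounded force keeps
  the Euler-Maruyama integrator stable at the practical time step; overlaps
  deeper than ~0.15 a still cost several kT.
* Angular potentials are harmonic in the **cosine** of the angle, not the
  angle itself: same minima and symmetry, but smooth at parallel and
  antiparallel configurations, so forces and torques are exact gradients
  everywhere (verified by randomized finite differences at 1e-5 relative).

## Equations of motion

First-order (Euler-Maruyama) overdamped Langevin dynamics:

    dr_i = F_i dt / (alpha_i gamma0) + xi_i,   <xi^2> = 2 kT dt / (alpha_i gamma0)

per component. Polarizations rotate by `w x p` with
`w = T_i dt_rot / gamma_rot + eta`, `<eta^2> = 2 kT dt_rot / gamma_rot` per
axis, followed by renormalization (torque `T = -p x dU/dp`). Rotational
updates are applied every 4th step with `dt_rot = 4 dt`; orientational
relaxation times (`gamma_rot / 2kT ~ 0.17 tau0` and slower) are two orders
of magnitude longer than `dt`, and the rotational diffusion coefficient is
preserved exactly (verified to 10%). `gamma_rot` defaults to `gamma0 a^2/3`
(a rigid sphere of diameter `a`). Anchored subunits never move.

The default time step is `1e-4 tau0`; the scenario presets use `1e-3 tau0`,
which resolves the stiffest default interaction (`k dt / gamma = 0.1`) and
is monitored at run time — any deterministic per-step displacement above
`0.1 a` is counted and reported. Translational noise is pre-generated in
chunks with numpy's PCG64 generator; the integrator seed fully determines
the trajectory.

## Biochemistry

Binding licenses hydrolysis; hydrolysis licenses disassembly:

1. a polymerized ParA-ATP subunit whose strongest instantaneous binding
   energy satisfies `|U| >= eps_threshold` (default `0.5 eps_b`) converts to
   ADP with per-step probability `1 - exp(-k_h dt)`; ADP is permanent;
2. an ADP subunit at a free filament tip detaches with probability
   `1 - exp(-k_d dt)` (standard model); in the severing variant any interior
   ADP subunit may instead cut its filament;
3. a detached monomer keeps only excluded volume: it cannot re-bind ParB and
   never repolymerizes (monomers rapidly diffuse away; nucleotide exchange
   and repolymerization are out of scope).

Severing convention: the severed subunit becomes a free monomer; the
anchor-side run keeps its chain identity, the tip-side run becomes a
separate unanchored *fragment* that keeps its bonds and its ability to bind
ParB but loses its crosslinks to the bundle (a cut protofilament is no
longer held in the lattice — without this release, 40% crosslinking would
pin every fragment and the severing failure mode could not occur).

"Bundle" observables (attachment, penetration, detachment) refer to the
original, non-fragment filaments: ParB bound only to severed fragments has
detached from the pulling structure even though it is still bound to ParA.
Both counts (`n_bound`, `n_bound_bundle`) are recorded.

## Companion theory

* Peripheral-segment relaxation time `tau = n_seg gamma_sub Rg_x^2 / kT`
  (internal drag over the entropic spring constant; prefactor configurable,
  default 1).
* Maximum per-filament disassembly rate: serial-rate form
  `k_max = [1/k_d + lam/(k_h delta_max)]^{-1}` with `lam` a fit length
  (default `a`) — linear in `k_h` at small `k_h`, saturating at `k_d`.
* Regimes by `k_max tau`: I below 0.1 (`v = a k_max`), III above 10
  (detachment), II between (stretched; `a k_max` is an upper bound). The
  0.1/10 thresholds are artifact choices for "<<" and ">>" and are fields of
  `TheoryInputs`.
* Detachment under load: the polymer COM in
  `U_eff(x) = -eps_b N_B Phi(-x/Rg_x) - F x` (bundle on the half-line
  x <= 0, `Phi` the normal CDF — the error-function overlap follows from the
  Gaussian-cloud description of the bound strip). Escape time from the
  standard two-curvature overdamped Kramers formula; the well is the
  leftmost local minimum (under strong force the tilted potential dips below
  the well far downhill, so the global minimum is not usable). With the
  barrier erased the code falls back to a flagged drift-time estimate.
  The detachment force solves `t_esc(F) = t_trans` by bracketed root
  finding.

## What the generator emulates, and what it does not

The builder is the package's synthetic-data generator: every initial
condition is constructed programmatically (bundle lattice, seeded crosslink
sampling, self-avoiding ParB walk briefly equilibrated with chemistry off,
placement of the ParB COM one measured `Rg_x` from the free tips, and a
short chemistry-off pre-binding relaxation). It emulates the geometry and
stochasticity of the modelled system, not real data: there is no
hydrodynamic coupling, no explicit cytoplasm or nucleoid, no ParA
repolymerization or cytosolic pool, and no replication machinery. Passing
tests therefore validate the model's internal physics (thermostat,
mechanics, chemistry statistics, scaling laws), not agreement with any
in-vivo measurement.

## Desk-scale study conditions

Simulations in the test suite and acceptance script are scaled down so the
full battery runs on one CPU:

* regime-I workhorse: 7 filaments x 30 subunits, 60-subunit ParB polymer
  with a 50-subunit strip, `k_h = 30`, `k_d = 0.006` (`k_max tau ~ 0.05`),
  3.2e6 steps at `dt = 1e-3`;
* replicate-heavy comparisons (failure modes, thresholds, arrangement
  sweeps): 4 filaments x 12 subunits, 40-subunit polymer with a 30-subunit
  strip; the failure-mode contrast uses a matched weaker binding
  (`eps_b = 5 kT`, angular widths 0.45) where the standard model still
  crosses robustly but the tip-binding and severing variants detach within
  a few hundred `tau0`;
* stretching sweep: the same weak-binding system with 8-subunit inert tails
  (46-subunit polymer, `tau ~ 28 tau0`), so the regime boundary is crossed
  within the reachable `k_max` (at the strong default binding the
  adsorption elongation described under "Known limitations" masks the
  stretching trend entirely, and with 5-subunit tails `k_max tau` saturates
  below the boundary because `k_max <= k_d` is hydrolysis-limited);
* the unanchored force balance varies `gamma_A/gamma_B` through the
  filament length (15/30/60) and tests the per-increment momentum residual
  `gamma_A dx_A + gamma_B dx_B`, which removes the erosion bias of a
  shrinking bundle's COM.

## Estimator conventions

* velocity: least-squares slope of the ParB COM x(t) with block-bootstrap
  standard error;
* penetration depth: 90th percentile of bundle-bound ParB x minus the mean
  free-tip x (percentile rather than maximum for noise robustness);
* detachment: bundle binding count zero *and* COM farther than
  `range_b + a` from every bundle subunit, sustained for a configurable
  dwell (default a few tau0), scanned from the first attached sample;
  replicates that never detach are right-censored at the run length;
* crossing: ParB COM advance by the initial bundle length;
* anisotropy `<Rg_x^2>/<Rg_y^2>`: time-averaged; for cross-speed
  comparisons the average is taken over a *displacement-matched* window
  (COM advance between fixed bounds), so every pulling speed is compared at
  the same translocation phase rather than the same elapsed time.

## Known limitations

* Bound ParB adsorbs along the permeable bundle surface, so even
  slow-disassembly (regime I) configurations show axial elongation of order
  the penetration depth; the regime-I/II stretching trend is monotone on
  top of this offset, but the attached-polymer anisotropy does not approach
  1 at small `k_max tau` the way a free coil does.
* Pairwise-additive binding lets several ParB subunits engage one ParA
  subunit (and vice versa); binding-strip thresholds therefore sit at very
  small strip sizes unless the binding energy is reduced.
* The Bernoulli per-step chemistry requires `k dt << 1` (enforced); exact
  event-time sampling is not implemented.
* Observables assume a single ParB polymer.
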