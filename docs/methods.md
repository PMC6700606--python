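# Methods

## The models

`lassofold` simulates the folding of complex-lasso proteins — structures in
which a covalent loop, sealed by a disulfide bridge between two cysteines,
is pierced by another stretch of the backbone — at one bead per residue,
placed at the Calpha position. Reduced units are used throughout: length
sigma = 3.8 Å (the consecutive-Calpha spacing), energy E, bead mass m, and
time tau_MD = sigma sqrt(m/E); temperature is in E/k_B.

### Elastic folder model (EFM)

The total potential is

    U = U_steric + U_bonds + U_angular + U_bridges

- **Sterics.** Weeks–Chandler–Andersen repulsion of diameter sigma between
  all bead pairs, bonded pairs included. Together with the FENE bonds
  (k_FENE = 30, R0 = 1.5 sigma) this gives the classic bead-spring bond with
  an equilibrium length of ~0.96 sigma. Including bonded pairs in the WCA
  sum is essential: FENE alone has its minimum at zero extension, so a chain
  without bonded sterics would collapse its bonds. An `exclude_bonded_wca`
  flag exists for experimentation.
- **Angular terms.** Bending U = k (theta − theta0)² (no ½ factor) and
  torsion U = k1 [1 − cos(phi − phi0)] + (k1/3) [1 − cos 3(phi − phi0)],
  parameterized so the reference (native) internal angles are the global
  minimum with zero energy. The third-harmonic amplitude is locked to k1/3.
  The per-angle stiffnesses form the force-field vector
  K = (k_bend_1..k_bend_{N−2}, k_tor_1..k_tor_{N−3}); neighbouring
  coefficients are constrained pairwise, halving the search dimensionality
  for the optimizer. The homogeneous model ("HM") uses k_bend = 36.5 and
  k_tor = 38.5 everywhere.
- **Cysteine bridges.** In oxidizing conditions each natively bridged pair
  interacts through a truncated, force-shifted Lennard-Jones well whose
  minimum sits exactly at the native pair distance
  (sigma_b = d_native / 2^(1/6)). Well depth defaults to 10 k_B T, deep
  enough that a formed bridge rarely reopens thermally; the cutoff defaults
  to 2.5 sigma_b — force-shifting makes results insensitive to this choice.
  Reducing conditions simply omit the term.

Because the native bond lengths (~1.0 sigma) differ slightly from the
FENE+WCA equilibrium (~0.96 sigma), the reference structure is close to,
but not exactly at, the model's mechanical minimum; quenching the reference
(L-BFGS on the total energy) moves it by ~0.1 sigma RMSD. Stationarity
holds at the quenched minimum, and the folded basin (RMSD < 0.9 sigma) is
insensitive to this offset.

### Gō model

A Clementi-style native-contact model: contacts (|i−j| ≥ 3, from a contact
file or a 7.5 Å Calpha cutoff) interact via
U = E_ij [5 (r0/r)¹² − 6 (r0/r)¹⁰], minimal at the native distance, with
E_ij = 1 E by default; non-contact pairs get a 12-power excluded volume of
diameter 4 Å; local pairs (|i−j| ≤ 2) keep the WCA chain diameter; bonds
are FENE as in the EFM. Angular terms use the same functional forms with
homogeneous k_bend = 40, k1 = 1, k3 = 0.5. Oxidizing conditions rescale the
contact amplitude of natively bridged cysteine pairs to 10 k_B T (the
contact is added if the map lacks it).

## Langevin dynamics

BAOAB splitting (half-kick, half-drift, Ornstein–Uhlenbeck, half-drift,
half-kick) with friction gamma = m/tau_frict = 1, time step dt = 5e-4 and
Maxwell–Boltzmann initial velocities. BAOAB was chosen for its accurate
configurational averages at finite step size; the suite verifies
equipartition per bending degree of freedom at T = 0.1 and energy
conservation (< 1e-4 relative drift over 1e5 steps) with the thermostat
disabled.

Two numerical regularizations deal with the collinear singularity of
internal-angle forces (the 1/sin(theta) geometry factors diverge when three
beads align, which happens transiently in stretched starting states):

- the 1/sin factors of the bending gradient and the torsion normals are
  floored at sin = 0.05 (active only within ~3° of collinearity);
- the first tau_MD of every trajectory is integrated at dt/5 (a "soft
  launch" absorbing the stretched-start transient), and a per-bead cap of
  1e4 E/sigma on the *angular* force (never the bonded/steric walls) bounds
  any residual spike.

These leave forces exact (finite-difference consistency to ~1e-9) away
from collinearity and do not measurably perturb equilibrium statistics. At
extreme stiffness (homogeneous k = 80) roughly 1 trajectory in 10 still
blows up; such runs are truncated, flagged, and score as failed folds —
which also penalizes numerically unstable force fields during optimization.

Initial states are stretched chains: beads along a random direction at
1 sigma spacing with transverse Gaussian noise (sd 0.05 sigma), then 100
steepest-descent steps on the bonded terms; end-to-end distance stays above
0.85 (N−1) sigma.

## Topology descriptors

The structure is reduced to a few representative residues: M_l loop
residues (ends = the bridge cysteines), fan-triangulated into M_l − 2
triangles, and M_t tail residues, split at the hairpin turn for an L2
lasso.

- **Lasso variable L ∈ [0, 1].** Each required native piercing event (tail
  part, crossing direction) is scored by smooth Fermi switches (width
  w = 0.2 sigma) on the in-plane edge margins and the along-segment margins
  of the segment/triangle intersection. Because the fan triangles tile one
  surface, a segment's score sums over the fan (clipped at 1) — a piercing
  near an interior diagonal then scores ~0.5 + 0.5 instead of being
  spuriously halved — and the best segment realizes the event. L is the
  product over required events; surplus non-native crossings do not lower
  it. In the sharp-switch limit L reproduces the binary piercing test.
- **Gauss linking number G.** The double line integral over the reduced
  loop polyline (integrated between the two cysteines, so G responds to
  loop opening) and the tail, evaluated exactly per straight-segment pair
  by the solid-angle formula; the test suite checks it against adaptive
  quadrature (1e-6) and the Hopf link. For L2 lassos the second tail part
  integrates with reversed orientation so the two opposite piercings add
  (G ≳ 1 in the native state) instead of cancelling.

## Trajectory analysis

MSD from the native structure F = (1/N sigma²) Σ |r_i − r_i⁰|² is computed
after optimal rigid-body superposition (Kabsch); sqrt(F) is the RMSD in
sigma units. Superposition is the right choice here because trajectories
start in random orientations; it is toggleable. A configuration is *folded*
when sqrt(F) < 0.9 and L > 0.9; the lasso condition removes RMSD false
positives with non-native topology.

Transition times are first sample times from which a condition persists for
10 tau_MD: bridge closure t_b (d_b1 < 1.5 sigma_b1), topology formation t_k
(L > 0.9) and folding t_f (the folded test). Successful trajectories are
classified by comparing t_k with t_b only (t_f may precede t_b inside the
native basin): *open-loop* if the topology forms before the bridge closes;
otherwise *threading* if d_b1 stays below the reopening threshold
(2.0 sigma_b1, chosen above the closure threshold for hysteresis) until
t_k, else *bridge reopening*. Folding landscapes are F = −log f with f the
probability-normalized 2-D histogram over chosen reaction variables; empty
bins are masked, no pseudo-counts.

## Force-field optimization

SFFO: mutate one paired coefficient group by delta_k ~ N(0, 2.5²) (floored
at k = 1), score the mutant by the average of F(tau_min) — the minimum of
the sampled MSD trace — over n test trajectories from fresh stretched
states, and accept with probability min{1, exp(<F>_old − <F>_new)}. The
incumbent's stored <F> is reused rather than re-measured (halves the cost;
the stochastic acceptance already absorbs evaluation noise). The folding
proxy pi_f = (1/n) Σ theta[(F0 − F_i)/w] (Fermi switch, F0 = 0.9, w = 0.2)
of every tested mutant — accepted or not — feeds an exponential moving
average Π_f (alpha = 0.03, decay 33 steps), since a single local mutation
perturbs folding propensity only slightly.

MFFO: N_K = 16 force fields run m = 50 SFFO steps per cycle, are ranked by
Π_f (ties by index), the best N_win = 6 survive, and the rest are rebuilt
by uniform crossover per constrained group from the winners plus N_low = 4
freshly randomized parents (coefficients uniform in [30, 60]); hybrids
start with no Π_f history (their first measured pi_f initializes it). The
initial population is homogeneous with (k_bend, k_tor) on the
{20, 40, 60, 80}² grid.

## Synthetic test systems and desk-scale study conditions

The mini-lasso generator builds a native complex lasso from scratch: an
almost-closed planar loop (n_loop beads, 1.2 sigma "cysteine" gap) threaded
by a hairpin (L2; both strands pierce in opposite directions) or a single
strand (L1), with a connector routed outside the loop rim, deterministic
zigzag offsets that keep every dihedral well-defined, and seeded jitter.
All non-bonded separations exceed 0.9 sigma; the returned topology spec's
native signature is computed from the generated geometry itself. The
default L2 (n_loop = 12, n_tail = 10, N = 26) has native L ≈ 0.996 and
G ≈ 1.43. What the fixture does *not* emulate: real secondary structure,
sequence heterogeneity, and the ~120-residue scale of real lasso proteins —
passing tests demonstrate correctness of the machinery and qualitative
folding behaviour, not quantitative agreement with any specific protein.

Desk-scale conditions used by the test suite and `scripts/acceptance.py`,
chosen once as the smallest systems where each effect is resolvable:

- folding ensembles: 24 trajectories × tau_run = 200 per redox condition on
  the default N = 26 mini-lasso at T = 0.1 (typical folding times are
  15–100 tau_MD there);
- optimizer comparison: the N = 21 mini-lasso (n_loop = 10, n_tail = 8) in
  oxidizing conditions with tau_run = 10 — short enough that only fast
  routes fold, giving the optimizer headroom — and a scaled configuration
  (n_test = 3, m = 3 steps/cycle, N_K = 4, N_win = 2, N_low = 2, 10
  cycles). The EMA smoothing is scaled to alpha = 0.25 so that its decay
  time (~3.5 steps) keeps the same proportion to the steps per cycle as the
  full-size setting (33 vs 50); with alpha = 0.03 a 30-step run would
  barely move the average.

Full-size experiment configurations (121-residue protein, 2048 × 1.5e4
trajectories, 30 MFFO cycles at the defaults above) ship under `configs/`;
they need a user-supplied PDB file and hours-to-days of CPU.

## Known limitations

- The reduced-structure descriptors are specific to a known native
  topology; they do not classify arbitrary entanglements.
- L depends mildly on the chosen reduction; the defaults for a real protein
  (five loop residues, three tail residues) must be sanity-checked on the
  native structure (L > 0.9) before production use.
- The collinearity regularizations above make the integrator's effective
  force field differ from the analytic gradient within ~3° of collinear
  triples.
- Very stiff force fields (k ≳ 80) occasionally destabilize the dt = 5e-4
  integration; such trajectories count as failed folds rather than being
  re-run.
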