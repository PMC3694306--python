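# Methods

## Scope and model

`peldock` reconstructs the architecture of a C2-symmetric protein dimer
from pulsed EPR (PELDOR/DEER) distance measurements. Three models are
composed:

1. a signal model for four-pulse dipolar evolution data,
2. a geometric model for the nitroxide spin label attached at an
   engineered cysteine, and
3. a rigid-body model of the dimer as one protomer plus its image under a
   two-fold rotation.

All distances are in ångströms at the API surface and times in
microseconds; the `r³` dipolar law is evaluated in nanometers internally.

## Dipolar signal model

The echo intensity is `V(t) = B(t)·[1-λ+λF(t)]` with a homogeneous-3D
background `B(t)=exp(-kt)` (a uniform spatial distribution of remote spins
gives a pure exponential), modulation depth `λ`, and form factor
`F(t)=∫K(t,r)P(r)dr`. The kernel is the powder average
`K(t,r)=∫₀¹cos[(1-3z²)·2πD t/r³]dz`, evaluated by 512-node Gauss–Legendre
quadrature (absolute error far below 1e-6 over the working grids). The
point-dipole constant `D = μ₀ g²μ_B²/(4πh) ≈ 52.041 MHz·nm³` is computed
from physical constants at import time, never hard-coded. Excitation
bandwidth, orientation selection and multi-spin effects are outside the
model (the isotropic point-dipole treatment standard for nitroxide pairs).

Defaults: distance grid 15–80 Å at 0.5 Å; time grid 0–8 µs at 16 ns. The
8 µs window resolves oscillation periods for the 38–66 Å range where the
method is quantitative; above ~70 Å less than one period fits the window
and widths become unreliable.

## Inversion

Recovering `P(r)` from `F(t)` is a first-kind Fredholm problem. We solve
`min_{P≥0} ‖KP-F‖² + α²‖LP‖²` with `L` the second-difference operator,
using active-set non-negative least squares on the α-augmented system. The
regularization factor is chosen at the maximum-curvature corner of the
log–log L-curve (residual norm vs roughness norm) over a 16-rung ladder
spanning 1e-2–1e3; curvature is computed by smoothed finite differences
with the ladder ends excluded (one-sided estimates there are unreliable),
and ties break toward larger α (the smoother distribution).

Background handling is two-stage. A tail fit of `a·exp(-kt)` (default
window: the last half of the trace) provides starting values; because the
oscillation of long distances has not decayed within the acquisition
window, tail fitting alone is biased there. A separable re-fit then
optimizes `(k, λ)` over the full trace with the distribution as the inner
regularized non-negative solution (Nelder–Mead outer loop). This removed
the dominant error for 60–66 Å test cases while leaving short-distance
cases unchanged. Zero time is located by maximizing the evenness of the
trace around its origin (equivalently, minimizing the imaginary Fourier
component): grid search over samples, then parabolic refinement.

A trace whose fitted modulation depth is ~0, or an identically zero form
factor, raises a no-dipolar-signal error rather than returning a guessed
distribution — mirroring how oscillation-free measurements must be treated
as "no reliable distance", not as data.

## Spin-label model

The label is modeled by accessible-volume sampling, not a rotamer library:
a pseudo-atom chain (CB–SG–SD–CE–ring attachment–N-O midpoint, bond
lengths 1.81/2.03/1.81/1.50/2.90 Å with tetrahedral-to-planar angles) is
grown from the residue's backbone by natural-extension placement with
uniformly random dihedrals. Internally infeasible conformers (atom pairs
three or more bonds apart closer than 2.8 Å; the bulky ring closer than
4.0 Å to the backbone) are re-sampled during generation — they are not
rotamers at all, so they do not count against a site's accessibility. A
generated conformer is *accepted* when no pseudo-atom lies within
`3.4 Å − clash_tolerance` of any protein heavy atom outside the labeled
residue (uniform 1.7 Å radii; tolerance 0 reproduces the loose screening
mode of accessible-volume labeling tools; larger tolerance is more
permissive, so the accepted count is monotone in it). In free space the
N–O midpoint lies 4–12 Å from the CA, matching the label's reach. Sites
with zero accepted conformers are flagged inaccessible, not raised.
Hydrogens and label energetics are not modeled. Sampling is seeded and the
construction is frame-local, so labeling commutes with rigid transforms to
float64 precision — the property that lets docking cache ensembles in the
monomer frame and transform them per pose.

Distance distributions between two ensembles are weighted pairwise
histograms (0.5 Å bins from 10–100 Å by default, grid points are bin
centers, trapezoid-normalized). The summaries are the modal distance
(global maximum, ties toward smaller r) and the width at half height
(outermost half-maximum crossings, linearly interpolated). An optional
Gaussian smoothing of the histogram (σ = 1.5 bins) is off by default and
used where a stable mode of a finite sample matters (docking, the
synthetic benchmark).

## Docking

A candidate dimer is protomer A (fixed in its own frame) plus its image
under a C2 transform. The set of C2 transforms — rotation by π about any
line — is a 4-parameter family (axis direction, 2; in-plane offset, 2),
and we parametrize it directly, so symmetry is exact by construction
rather than enforced by penalty. With a fixed, already-dimeric component
supplied, its two-fold is inherited and the mobile pair's 6-DoF placement
is optimized instead.

The energy is a flat-bottom harmonic on each site's inter-label modal
distance — zero within `half-width` of the target, quadratic outside —
plus a soft-sphere clash penalty on inter-protomer CA pairs (onset 4 Å,
weight 0.2). The default half-width is `width/4` capped at 0.5 Å: the
modal distance of a DEER distribution is far better determined than its
width, and looser bottoms leave the pose underdetermined (we measured
zero-violation pose families extending beyond 2 Å RMSD with 1.5 Å
bottoms). The per-pose modal statistic smooths the pairwise histogram
(σ = 1.5 bins) and refines the peak parabolically; without smoothing the
raw argmax of a finite sample jumps between competing peaks and is not a
usable objective.

Optimization is Metropolis simulated annealing over the C2 parameters
(geometric cooling over 500 steps from T=20 to 0.02 in energy units, step
sizes shrinking with temperature, plus a quarter-temperature reheat
cycle), with two structural moves beyond plain Gaussian perturbations:
occasional global axis jumps, and "offset snapping" — for a trial axis,
the in-plane offset is solved directly by Gauss–Newton multilateration of
the label-cloud centroids (for a C2 about direction n, the site-to-image
distance is `|2p_⊥ - t|` in the plane, a 2-D trilateration problem). This
reduces the effective search to axis orientation and made 20-start
recovery reliable. Each start ends with a deterministic shrinking pattern
search (Hooke–Jeeves), which walks the piecewise-constant fine structure
of the binned objective where gradient-style steps stall. Rigid-body
molecular dynamics is deliberately not re-implemented: only the restrained
minimum matters for model selection, and annealed minimization of the same
restraint energy reaches it; the annealing temperature is a plain schedule
parameter in energy units, not a physical temperature. Starts place the
protomer pair at ~50 Å centroid separation with random orientation;
results are returned sorted by violation (ties: lower clash, then start
index) and are deterministic for a fixed seed, with per-start independent
substreams so that the best violation is monotone in the number of starts.

## Synthetic data

The generator emulates the study conditions end to end. A protomer is two
antiparallel ideal α-helices (rise 1.5 Å/residue, 100° twist, CA radius
2.3 Å; backbone N, CA, C, O plus ideal CB — side chains beyond CB are not
generated). The planted two-fold is perpendicular to the helix axes so the
protomers stack across a packed (~7 Å closest-approach) interface; this
geometry puts labeled sites on both sides of the axis, which is what makes
the five-distance docking problem well conditioned. The five default label
sites were chosen by an explicit design computation: among accessible
surface sites with inter-label distances in the quantitative PELDOR window
(~39–55 Å), the subset minimizing the worst-case pose error of the
distance→pose Jacobian (≈1 Å at the restraint resolution). Simulated
traces use modulation depth 0.3, background 0.05 /µs and additive white
Gaussian noise of sd 0.005 — a well-oscillating, realistically noisy
regime; all randomness derives from a single seed and outputs are
byte-reproducible.

What the fixtures do not emulate: real side-chain packing (our label
clouds at fully exposed ideal-helix sites are broader, width ~8–13 Å, than
the 4–8 Å typical of partially sheltered sites on real proteins), membrane
or detergent environment, orientation selection, and incomplete labeling.
Consequently a passing benchmark shows the pipeline's internal
consistency under honest noise, not instrument-level fidelity. One
measured consequence: for those broad distributions the mode location
itself is soft, and the trace round trip reproduces it to ~4%, whereas in
the narrow-peak regime (widths 4–8 Å) modal recovery is exact to the grid
and widths are recovered within 25% at the L-curve corner.

## Numerical choices and edge cases

- Kernel quadrature: 512 Gauss–Legendre nodes, chunked to bound memory.
- NNLS on the augmented system is exact (active set); the independent
  check is scipy's bounded-variable least squares on the same system.
- Modal ties break toward smaller r; L-curve corner ties toward larger α.
- Alternate locations: highest occupancy kept; hydrogens dropped on read;
  author residue numbering preserved (sites are `(chain, author number)`).
- Degenerate inputs raise: empty coordinate sets, non-orthonormal or
  improper rotations, collinear superposition selections, distance grids
  that do not cover the data, α ladders narrower than 3 decades.
- Float64 coordinates are carried alongside the float32 AtomArray storage;
  all geometry invariants (involution, equivariance, distance
  preservation) hold at 1e-6 Å or better.

## Known limitations

- No orientation-selective DEER, pulse-shape effects, or multi-spin
  corrections.
- Width estimates from Tikhonov inversion are biased upward for narrow
  peaks at long distance (≲8 µs traces); modal distances are robust.
- The docking energy restrains modal distances only, with width-derived
  flat bottoms; full-distribution restraining is not implemented.
- The fixed-component mode assumes the supplied component is itself
  C2-symmetric (checked at 1e-3).
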