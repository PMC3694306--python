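# peldock

Integrative modeling of C2-symmetric protein dimers from pulsed EPR
distance data.

PELDOR (pulsed electron–electron double resonance, also called DEER)
measures the dipolar coupling between pairs of nitroxide spin labels
attached to engineered cysteines, yielding nanometer-range distance
distributions. For a homodimer labeled at one site per protomer, each
labeled position reports one inter-protomer distance; a handful of such
distances, combined with monomer crystal structures, suffices to determine
the dimer architecture. `peldock` implements that whole loop:

- **`peldock.deer`** — four-pulse dipolar evolution traces. The echo signal
  is modeled as `V(t) = exp(-k t) · [1 - λ + λ F(t)]`, with `λ` the
  modulation depth, `exp(-k t)` the homogeneous-3D intermolecular
  background, and the form factor `F(t) = ∫ K(t,r) P(r) dr` built from the
  powder-averaged dipolar kernel
  `K(t,r) = ∫₀¹ cos[(1 - 3z²) ω(r) t] dz`, `ω(r) = 2π D / r³`
  (`D ≈ 52.04 MHz·nm³`, computed from physical constants). Recovery of
  `P(r)` from a measured trace is done by background fitting, zero-time
  optimization, and non-negative Tikhonov regularization
  `min_{P≥0} ‖KP - F‖² + α²‖LP‖²` with the regularization factor α chosen
  at the corner of the L-curve.
- **`peldock.labeling`** — accessible-volume MTSSL modeling: a
  coarse-grained nitroxide side chain is grown from the labeled residue's
  backbone with random dihedrals, sterically filtered against the protein,
  and summarized as a cloud of N–O midpoints. Distance distributions
  between two site ensembles carry the standard summaries (modal distance,
  width at half height).
- **`peldock.docking`** — rigid-body docking of a monomer into a C2 dimer.
  The two-fold is parametrized directly (axis direction + in-plane offset),
  so every candidate is exactly symmetric; poses are scored by flat-bottom
  harmonic restraints on per-site inter-label modal distances plus a
  soft-sphere clash term and optimized by simulated annealing from many
  random starts. Models are ranked by total restraint violation.
- **`peldock.structures`** — PDB I/O, rigid transforms, least-squares
  superposition.
- **`peldock.synthetic`** — fully ground-truthed fixtures: ideal-helix C2
  dimers with a planted two-fold, analytic distance distributions, and
  noisy simulated traces, so the entire pipeline is testable with no
  external data.

## Worked example

Generate a synthetic benchmark (a planted C2 helical dimer with five
labeled sites and noisy PELDOR traces), invert one trace, and dock the
monomer back into a dimer from the restraint table:

```sh
peldock synth --out-dir bench --seed 1
peldock invert --trace bench/trace_site28.dat --out-dir inv
peldock dock --monomer bench/monomer.pdb --restraints bench/restraints.tsv \
             --out-dir dock --starts 20 --seed 7
```

The `invert` step prints

```
modal distance 44.0 A, width 13.2 A, lambda 0.300, k 0.0501 /us
```

meaning the dipolar trace at site 28 was background-corrected (recovering
the simulated modulation depth 0.3 and background rate 0.05 /µs to three
decimals) and inverted to a distance distribution peaking at 44.0 Å —
within 1.5 Å (3.3%) of the ground-truth inter-label modal distance
recorded in `bench/ground_truth.json` (45.5 Å; the label-pair distribution
at this fully exposed site is ~12 Å wide, so its mode is a soft summary —
see `docs/methods.md`). The `dock` step prints the best model's
start index and total restraint violation (0 when every site distance sits
inside its flat bottom) and writes ranked dimer PDBs plus per-restraint
violation tables (site, model distance, target, deviation).

To score an existing dimer model against a restraint table (one row per
site, the model-vs-experiment comparison):

```sh
peldock score --dimer bench/dimer.pdb --restraints bench/restraints.tsv --out-dir sc
```

With your own coordinates the same commands apply: supply a monomer (and
optionally a fixed, already-dimeric component whose two-fold the mobile
pair inherits) plus a TSV of per-site modal distances and widths from your
PELDOR analysis. `peldock distances --structure dimer.pdb --site-a A:273
--site-b B:273` predicts the inter-label distribution for a labeled site
on a crystal structure — the computation used to discriminate a
physiological dimer from a crystal-packing pairing.

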