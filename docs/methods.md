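# Methods

## Reaction encoding

Input reactions must be balanced, atom-mapped and carry explicit
hydrogens; the atom-map bijection and per-map element identity are
verified at parse time, and hydrogens not written as mapped atoms must
agree per atom across the two sides.  Atoms are ordered by ascending
atom-map index everywhere downstream.

The condensed reaction graph concatenates reactant-side and product-side
feature vectors per atom and per bond (reactant half first); the edge set
is the union of both sides' bond sets, and an absent bond is encoded as
the all-zero half-vector with no separate presence bit — the all-zero
one-hot order block is already unambiguous.  One-hot blocks: atomic
number over a configurable element list (default H, C, N, O, F, S, Cl,
Br, I; out-of-list elements raise rather than bucket), degree and
hydrogen count 0–4 with an overflow slot, formal charge −2…+2 with
overflow slots on both sides, hybridization over {S, SP, SP2, SP3, SP3D,
SP3D2, other}, bond order {single, double, triple, aromatic}, conjugation
flag, in-ring flag and ring size 3–8 one-hot (larger rings set only the
flag).  Atomic mass is divided by 100.  Pure two-sided concatenation was
chosen over a concatenation-plus-difference variant: a difference block
is a fixed linear map of the concatenation, so it adds no information to
the first linear layer.  Stereochemistry in the SMILES is ignored.

## Network

Directed-edge message passing with the reverse-edge-excluded update

    h⁰_vw = W_i e_vw                (linear, no activation at init)
    h^{t+1}_vw = ReLU(h⁰_vw + W_h Σ_{k∈N(v)\{w}} h^t_kv)

followed by atom embeddings ReLU(W_0 cat(x_v, Σ incoming h^T)), mean
pooling (sum configurable) and a feed-forward head.  ReLU is used
throughout; biases are included in every linear map; weights are
initialised from a seeded uniform fan-in scheme so runs are exactly
reproducible.  Dropout (off by default) is applied after each
message-passing step and between head layers.

Auxiliary per-atom blocks (ml-QM columns, positional descriptors) join
the model by one of three routes: raw concatenation; a linear layer with
ReLU; or linear + ReLU followed by one single-head scaled-dot-product
self-attention pass over the atoms of the reaction with a residual
connection — the minimal reading of "an additional attention layer", as
no further architectural detail is fixed by the design.  Placement is
either before message passing (the block joins `x_v`, so it propagates
through the graph) or after (it joins `h_v` just ahead of pooling).
Molecule-level extras are appended to the pooled vector before the head.
Bond-level extras concatenate onto the per-side bond features directly.

The network, its gradients and the optimizer are implemented in NumPy on
a small reverse-mode tape (`rxnbarrier.autodiff`); a deliberately naive
per-edge-loop evaluation (`rxnbarrier._reference`) serves as an
independent oracle in the tests and the acceptance script, and the two
agree to ~1e-16 on fixture graphs.

## Positional descriptors

AEV: element-resolved radial symmetry functions
`Σ_j exp(−η(r_ij−R_s)²) f_C(r_ij)` on 16 shifts inside a 5.2 Å cutoff
(η = 16), and angular terms
`2^{1−ζ}(1+cos(θ−θ_s))^ζ exp(−η_a(r̄−R_s)²) f_C f_C` over element pairs
(ζ = 32, η_a = 8, 4 radial × 8 angle shifts inside 3.5 Å), with the smooth
cosine cutoff `f_C`.  The inter-neighbour angle is computed as
`atan2(‖u×v‖, u·v)`: the arccos form loses ~8 digits at collinear
geometries and breaks rigid-motion invariance at the 1e-8 level.

SOAP: the neighbour density (central atom excluded, neighbours weighted
by the same cosine cutoff, 5.0 Å default) is expanded in Gaussian radial
primitives (n = 6, σ = 0.5 Å) and spherical harmonics up to l = 4, and
contracted to the invariant power spectrum p_{nn'l} per element pair.
The spherical-harmonic sum over m is eliminated with the Legendre
addition theorem, so only pairwise distances and angles enter; the
displaced-Gaussian radial integrals use exponentially scaled modified
spherical Bessel functions on a 64-point Gauss–Legendre grid for
stability at large arguments.  Both descriptor families are exactly
E(3)-invariant by construction and local: atoms at or beyond the cutoff
contribute nothing.

Defaults follow the reference descriptor implementations, since published
runs name only the descriptor families; every parameter is configurable.
Per reaction, descriptors are computed per role on the full recorded
complex (so inter-fragment terms inside the cutoff are included), rows
are re-ordered to graph atom order through the conformer's atom-map
alignment, and role blocks concatenate in fixed r, ts, p order.  A
missing conformer is a hard error; a zero-filled block is available
behind an explicit flag for ablations.  Learned descriptors (MACE,
Equiformer hidden states) are supported only as precomputed per-atom
provider tables keyed like conformers; running foundation models is out
of scope.

## ml-QM schema and feature bookkeeping

The ml-QM registry is fixed at 13 atom-level, 4 bond-level and 20
molecular-level descriptors (37 total).  Entries named in the published
description (NPA charge, Parr function, NMR shielding, valence orbital
occupancies; bond order, bond length, bonding electrons, natural
ionicity; energy gap, ionization potential, electron affinity, dipole and
quadrupole moments) carry those names; the remaining slots carry stable
placeholder ids (`mlqm_atom_06` …) so column selection and importance
reports stay well defined without the full supplementary name table.
Values are supplied per reactant/product side by table; they may be
z-scored per column with training-set statistics before attachment
(recommended — QM descriptor magnitudes span orders of magnitude — but
configurable off).  Reactant- and product-side vectors are concatenated,
not differenced, mirroring the graph convention; molecule-level extras
from both sides concatenate into the pooled vector.

## Training protocol

AdamW (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, decoupled weight decay off by
default), MSE loss on z-scored targets, batch 50, 100 epochs by default.
The scheduler ramps linearly over the first 10 invocations and then
follows cosine decay to a 1% floor; invocations are per epoch, the more
conservative reading of "10 warmup steps".  The checkpoint with the
lowest validation MAE is returned.  Gradient clipping is available but
off.  All randomness (init, batch order, dropout) derives from the
config seed, so identical configs reproduce bit-identical histories.

## Splits

Random: seeded shuffle, floor-sized validation/test (5% each by default),
remainder to train.  Reaction core: the core is the set of bonds formed,
broken or order-changed plus their endpoint atoms (environment radius 0,
the strictest reading of a "common core"); the key is the canonical
SMILES of the two core subgraphs joined by `>>`, hence stable under atom
relabeling; identity reactions are a degenerate-core error.  Whole
clusters are assigned largest-first (a seeded shuffle breaks size ties)
to the partition minimising the squared deviation from target sizes —
the usual scaffold-split heuristic; realised fractions are recorded in
the split provenance since lopsided clusters can push them off target.
Barrier height: records sorted by (value, id) — the id tie-break makes
the split deterministic — lowest 5% to validation and highest 5% to test
by default; which extreme goes where is a convention the data do not fix,
so it is configurable and recorded in the provenance.

## Permutation importance

Each auxiliary column is shuffled across the dataset at prediction time
(atom-level columns across the pooled atom axis, molecule-level across
reactions), 5 repeats by default with derived seeds, and the mean change
in MAE against the unpermuted baseline is reported.  Negative values are
legitimate (a column whose scrambling helps).  A column with zero
downstream weights yields a ΔMAE of exactly 0.

## Synthetic fixtures

The generator emits hydrogen-transfer reactions R1–H + R2 → R1 + H–R2
over methyl, ethyl, amino, hydroxyl and thiyl fragments, with barrier

    β·(bond-change counts) + γ·d_TS + ε,   ε ~ N(0, σ²)

where d_TS, the forming-bond distance in the collinear X–H···Y transition
state, is drawn uniformly from 1.1–2.1 Å independently of the fragment
choice.  Defaults: β on a 15–30 kcal/mol hydrogen-transfer scale,
γ = 7 kcal/mol/Å (geometry-term standard deviation ≈ 2 kcal/mol),
σ = 0.5 kcal/mol, 2000 reactions.  Because d_TS is independent of
everything the 2D graph shows, a graph-only model's test MAE is floored
at the geometry term's mean absolute deviation (γ·width/4 =
1.75 kcal/mol at defaults), while a TS-coordinate model can remove it —
the same separation that makes transition-state geometry valuable on
real barrier data, reproduced at desk scale.  Conformer file order is
shuffled per record so the map alignment path is always exercised, and
each conformer is randomly rotated and translated.

What the fixtures do not emulate: real TS geometries and energetics
(fragment placements are idealised and collinear), conformer ensembles,
charged or radical-specific electronic effects, and dataset-scale class
imbalance.  Passing tests therefore demonstrate the correctness of the
pipeline and the geometry/graph signal separation, not chemical accuracy
on real datasets.

## Problem sizes and numerical choices

The test suite and acceptance script run at n = 2000 reactions, hidden
size 64, depth 3, 30 epochs — sizes chosen so the whole pipeline
(featurization, two trainings, invariance sweeps) completes in a few
minutes on one CPU while keeping the coordinate-gap effect an order of
magnitude above its estimation noise.  Tolerances: oracle equivalence
1e-6, prediction invariance under relabeling 1e-5, descriptor rigid-
motion invariance 1e-8, coordinate round-trips 1e-12.  Degenerate inputs
are errors, not silent defaults: empty graphs cannot be pooled, identity
reactions have no core, missing conformers and uncovered extra-feature
rows raise, and non-finite training loss aborts with the epoch index.

## Known limitations

No stereochemistry or charge/radical feature extensions beyond formal
charge; no multi-task heads or uncertainty estimates; the config-grid
hook replaces Bayesian hyperparameter search; checkpoints store plain
arrays with no versioned migration; the NumPy implementation targets
desk-scale datasets — at the scale of the large public barrier sets a
GPU implementation of the same architecture would be required.
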