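# Methods

## The problem

Multi-state NMR structure determination fits N coexisting conformational
states per conformer to ensemble-averaged data, most prominently exact
NOE (eNOE) distances.  The conventional quality measures — the distance
target function and the bundle RMSD — lose discriminating power in the
multi-state setting because a wrong restraint's violation can dissolve
into the extra degrees of freedom.  The structural correlation parameter
mu quantifies instead how *separable* the modelled states are, and turns
out to be the more sensitive dial for validating state counts,
populations, calculation effort and individual restraints.

## The correlation engine

Every state of every conformer is one **entity**; an M-conformer,
N-state bundle has M x N entities.  For each residue r of the L-residue
chain:

1. Each entity is described by the vector of distances from r's reference
   atom (Calpha by default; Cbeta or the heavy-atom centroid are
   configurable) to every other residue.
2. Feature columns whose standard deviation across entities falls below a
   **significance threshold** (default 0.5 Å) are discarded.  The
   threshold's job is to absorb random thermal motion: with per-atom
   thermal noise sigma the distance features carry noise ~ sigma * sqrt(2),
   so the default absorbs thermal motion up to sigma ~ 0.35 Å while
   state-driven displacements of 1 Å and more pass.
3. The entities are clustered into K components with a Gaussian mixture
   model (diagonal covariances, because the features routinely outnumber
   the entities; 10 seeded restarts, best likelihood kept).

Residue-specific clusterings X, Y are compared by mutual information in
bits,

    I(X, Y) = sum_{x,y} p(x,y) log2[ p(x,y) / (p(x) p(y)) ],

adjusted for chance with the fixed-marginals permutation model (adjusted
mutual information, arithmetic-mean normalization): identical non-trivial
clusterings score 1, random clusterings score ~0.  A clustering with a
single effective label (e.g. from a fully filtered feature matrix)
carries no state information and scores 0 by convention.  The L x L AMI
matrix A is averaged to the scalar

    mu = mean of A_ij ,

by default over off-diagonal entries only, so that mu = 0 corresponds to
the absence of correlated motion; a flag restores the literal double sum
including the self-agreement diagonal (which floors mu at 1/L for any
informative clustering).  Chance-level negative means are clamped to 0
for reporting; the raw value is retained.  The residue with the highest
mean correlation to all others is the **key residue** and its clustering
vector is the global state assignment of the bundle.  Degenerate residues
contribute zero rows/columns and are *included* in the mu average — the
conservative choice; a flag excludes them.

## Restraints and the target function

CYANA-style `.upl`/`.lol` files are parsed into typed restraints (upper,
lower, steric).  The distance target function is the weighted sum of
squared violations over currently violated restraints, with the model
distance of an N-state conformer given by r^-6 ensemble averaging

    d* = ( (1/N) sum_i d_i^-6 )^(-1/6) ,

which always lies between min(d_i) and min(d_i) * N^(1/6) — the average
is dominated by the shortest state distance.  V_d is evaluated per
conformer and averaged over the bundle.  Restraint-class weights default
to 1 and are configurable.  Restraints naming unresolvable protons can
optionally match equivalent protons by r^-6 summation (the NOE
pseudo-atom convention); this is off by default since eNOE restraints are
mostly stereospecific.

## The toy structure-calculation backend

A licensed torsion-angle-dynamics engine is out of scope; the built-in
backend is a coarse-grained Cartesian stand-in sufficient for the assays:
Calpha bead chains (bond length 3.8 Å, harmonic weight 10), per-state
steric repulsion below 4.0 Å, the distance-restraint term on r^-6
averaged distances, and flat-bottom **bundling** between corresponding
beads of different states (bottom width 1.2 Å).  Side-chain restraints
are mapped to their residue's bead with a 1.5 Å bound relaxation.

Design choices that emerged as essential during development:

* **Distance-geometry initialization with uncertainty-scaled diversity.**
  Distance bounds are assembled from the bonds, the restraints and the
  steric floor, upper bounds are triangle-smoothed (shortest paths over
  the bound graph), and the resulting matrix (restrained pairs at bound
  midpoints) is embedded by classical MDS.  Every conformer starts from
  this embedding plus a per-bead random displacement whose amplitude is
  that bead's positional uncertainty — a quarter of its mean bound width
  (floored at `init_jitter`).  A tightly determined network therefore
  yields a tight starting pool, while a sparse network yields genuinely
  diverse random folds, so the bundle spread honestly reflects how well
  the data determine the structure.  A smaller per-state jitter breaks
  the symmetry between states.  Alternatives were evaluated and rejected:
  pure random-chain starts never reach the convergence regime on dense
  networks; fixed-amplitude jitter makes sparse-data bundles artificially
  tight and correlated; EMBED-style randomized metrization (full or
  partial) injects too much noise through the loose bounds of
  unrestrained pairs even when the network is dense.
* **Per-partner bundling normalization.**  Pairwise bundling weights are
  divided by N-1 so the aggregate pull on a state is independent of the
  state count; without this, ten-state calculations are an order of
  magnitude more tightly bundled than two-state ones.
* **Huber-shaped bundling well.**  Quadratic up to 0.5 Å beyond the
  bottom, linear outside.  The quadratic region damps the anti-correlated
  inter-state drift that r^-6 averaged restraints leave unconstrained,
  while genuine multi-Ångström state separations demanded by the data are
  not quadratically taxed.  The default weight 0.02 ("weak" relative to
  restraint weight 1) balances the two roles.
* **Monotone batched descent.**  All conformers are minimized in parallel
  by gradient descent with per-conformer adaptive step sizes (a step that
  would raise the objective is rejected and the step size halved) and a
  three-stage step-size annealing schedule (0.5 / 0.15 / 0.05 Å caps).
  The objective trace is therefore non-increasing by construction, and
  runs are bit-reproducible for a fixed seed.

With a grouping scheme (population scans) intra-group bundling is strong
(weight 5) and inter-group bundling weak, so a group of k states behaves
as one state of population k/N.

## The synthetic testbed

The generator produces the situation the method is designed for, with
known ground truth:

* A compact self-avoiding Calpha chain (bond 3.8 Å, non-neighbour floor
  4.0 Å, confined to a sphere of radius 3.3 * L^(1/3)) — the protein fold.
* A two-state hinge: a contiguous central segment (default half the
  chain) displaced along a random direction with a smooth sine envelope
  peaking at 4.5 Å, redrawn until clash-free.  The amplitude is chosen so
  the states genuinely exchange contact partners; motions much smaller
  than the contact range leave the averaged distance network embeddable
  as a single structure, i.e. a truth that no method could recover from
  distance data.
* Populations (default 50/50) enter the ground-truth averaging as weights
  p_i replacing 1/N; at equal populations this reduces exactly to the
  equal-weight average.
* Bundles are sampled with i.i.d. isotropic Gaussian noise (default
  0.3 Å) on every bead — random thermal motion, sized to sit below what
  the 0.5 Å significance threshold absorbs.
* Restraints: every residue pair whose population-weighted r^-6 averaged
  distance is within the contact cutoff becomes an *exact* eNOE — an
  upper and a lower limit at that distance ±0.02 Å.  The cutoff default
  is 9 Å: the restraints connect Calpha beads, and a 5 Å proton-proton
  NOE reaches Calpha pairs up to ~9 Å apart once side-chain extent is
  accounted for; this choice also reproduces realistic restraint
  densities (~10 per residue).  A 5 Å cutoff on Calpha distances yields
  ~3 restraints per residue — a network too sparse to encode state
  separation at all.  Upper-only generation is available behind a flag
  but leaves the network trivially satisfiable by a collapsed single
  structure.
* Corruption: entry (i, s) rescales the i-th contact's distance by s,
  moving both of its limits — a misassigned or misfitted eNOE.

What the generator does **not** emulate: side chains and proton
positions, spin diffusion, angular restraints, non-discrete (continuous)
dynamics, and state exchange kinetics.  Passing tests therefore
demonstrate that the correlation machinery extracts what the synthetic
data encode, not that every real dataset behaves this way.

## The assays

All assays are bit-reproducible given (restraints, seed, config); every
random choice derives from the assay seed through spawned generators.

* **State-number scan**: recalculate with N = 1..S states; report the
  normalized target function (V_d per restraint — the normalization is a
  package choice, reported alongside raw V_d) for every N and mu (K = N)
  for N >= 2.  The correct state count shows as a mu maximum, while the
  target function only flattens.
* **Population scan**: ten-state calculations with controlled groups of
  size k and 10-k; one representative per group (the member state closest
  to the group mean) feeds a two-state correlation analysis.  mu peaks
  near the true population split; the signal is noisy — as population
  estimation is in practice.
* **Titration**: random restraint subsets (fresh per replicate, seeded
  per (fraction, replicate)) map the fold-acquisition (RMSD drop) and
  state-separation (mu rise) transitions.
* **Leave-one-out ranking**: each long-range distance (the atom pair —
  an exact eNOE's upper and lower limit leave together; sequence
  separation >= 5 counts as long-range, configurable) is removed in
  turn.  Sorted ascending by the resulting mu: the bottom set are key
  state-defining restraints, the top set (mu rises on removal) are
  suspects.  A common backend seed across runs isolates the restraint
  effect from the random start.
* **Distance profile**: residue pairs sorted by ensemble-mean
  Calpha-Calpha distance, split into equal-count bins (remainder to the
  last bins); per-bin mean distance and mean correlation show the
  spatial reach of correlated motion.
* **Convergence scan**: mu over a (steps x conformers) effort grid;
  flags the cheapest cell within 5% of the maximal-effort mu.
  Under-sampled calculations visibly depress mu.

## Numerical choices and degenerate inputs

* Superposition is Kabsch (SVD with determinant correction); collinear
  point sets are rejected.  Ensemble RMSD iterates the mean structure to
  convergence (tolerance 1e-10, cap 50 iterations) rather than a fixed
  iteration count, which makes the estimator well defined and invariant
  under entity reordering; a pairwise-mean variant is available.
* GMM clustering seeds are spawned per residue from the analysis seed;
  duplicate-row feature matrices are handled by covariance regularization
  (1e-6 floor).
* Distances of exactly 0 between restrained atoms raise an error rather
  than silently producing infinite r^-6 terms.
* Model sizes in the test-suite and reproduction script are chosen as the
  smallest systems in which the studied effects are distinguishable from
  sampling noise: length-30 chains throughout; 12 calculated / 6 kept
  conformers for the state scan (800 descent steps) and titration
  (16/8, 800 steps); 8 calculated / 4 kept at 300 steps for the
  leave-one-out ranking; 4 calculated / 3 kept at 300 steps
  for the ten-state population scan; 20-conformer sampled bundles for the
  direct correlation analyses.  Full-scale protocols (hundreds of
  conformers, the best 20 kept) run through the same code paths via
  ``BackendConfig``.

## Known limitations

* The backend is a bead-chain caricature: no torsion-angle dynamics, no
  chirality (the distance-geometry embedding is mirror-blind), no
  all-atom packing.  Its purpose is to respond to restraints and to be
  able to express state splitting, not to produce protein structures.
* mu from bundles of few conformers (< ~8) is noisy; the assays
  therefore report means and standard deviations over replicates or
  seeds where they matter.
* Under-restrained bundles can show spurious correlations (conformers
  cluster by fold rather than by state); the titration assay shows this
  as a non-monotonic low-density shoulder before the genuine rise.
* Population estimation via mu is the weakest of the assays here as in
  practice: on the bead-chain testbed the mu-vs-group-size curve is
  nearly flat, because weighted r^-6 bounds from a 50/50 truth can be
  satisfied at any group split by smoothly repositioning the hinge.
  Expect ±1 group around the truth at best, and treat the scan as
  exploratory.
* Leave-one-out corruption detection is strong per contact when bundles
  are well converged (the corrupted distance ranks at the very top of
  the removal ranking), but at small bundle sizes the mu-ranking noise
  across ~70 candidate contacts leaves per-run detection at roughly a
  coin-flip-to-two-thirds rate; reliable flagging needs bundles of ~16
  kept conformers or repeated calculations.
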