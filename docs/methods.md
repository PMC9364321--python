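# Methods

This note documents the models, procedures and numerical choices behind
`dockbench`: a deterministic docking pipeline with a pluggable scoring
backend, chemical-space tooling, and three docking-based benchmark suites
with classical optimization baselines.

## Ligand preparation

A SMILES string becomes a docking-ready ligand in five deterministic steps.

1. **Validation.** Multi-fragment inputs (salts, mixtures) and open-shell
   species are rejected with a structured reason; rejection is a value, not
   an exception, so library-scale preparation can account for failures
   exactly.
2. **Protonation at pH 7.4.** Ionizable groups are switched to their
   majority microstate by a fixed SMARTS transform table (carboxylic,
   sulfonic and phosphonic acids, tetrazoles, aryl thiols, aliphatic
   amines, amidines/guanidines), each with a literature-typical pKa. A rule
   fires when its pKa lies on the far side of the pH. The table is
   deliberately transparent and swappable behind a `ProtonationEngine`
   interface: automated protonation is never perfect, and a rule table can
   be inspected, tested (idempotence is asserted) and replaced. Tautomer
   enumeration and microstate ensembles are out of scope.
3. **Embedding.** One conformer from ETKDG (v3) distance geometry with a
   caller-supplied seed (default 0). Defined stereocenters are preserved by
   the embedding; undefined stereocenters are fixed *before* embedding by
   an RNG seeded from a SHA-256 content hash of the canonical SMILES, so
   the assignment is identical across runs, processes, library orderings
   and conformer seeds.
4. **Refinement.** MMFF94 minimization, at most 1000 iterations, gradient
   tolerance 1e-4. Non-convergence alone is tolerated when the energy
   decreased by more than 1e-6; otherwise the molecule is rejected as
   REFINE_FAILED. These tolerances are conventional choices; nothing
   downstream is sensitive to them.
5. **Charges and serialization.** Gasteiger partial charges (their sum is
   asserted to match the net formal charge within 0.01 e) and an AutoDock
   PDBQT writer with a native torsion tree: rotatable bonds are acyclic
   single bonds between non-terminal heavy atoms not involved in triple
   bonds (the *non-strict* rotatable-bond convention; the druglikeness
   profile reports the same convention so the two counts agree by
   construction). The rigid root is the largest rigid fragment; TORSDOF is
   the number of active torsions. Nonpolar hydrogens are kept and typed
   `H`; hydrogens on N/O/S are typed `HD`.

## Search boxes and receptors

The docking search box derives from a bound reference ligand: per axis,
`size = max(span + 2 * padding, min_side)` with `padding = 12.5` Å per side
and `min_side = 30` Å, centered at the span midpoint. The rule is exactly
translation-equivariant and monotone in the coordinate cloud; both are
property-tested. All atoms present in the reference file are used (the
choice between all atoms and heavy atoms only moves the box by fractions
of an ångström against a 25 Å padding). Boxes can also be set manually for
pockets chosen by visual inspection.

Receptor standardization (hydrogen addition, PDBQT conversion) chains
external tools in practice, so it is an adapter contract invoked via
subprocess. The built-in `NullAdapter` performs a minimal native
conversion — element normalization (e.g. `ZN` → `Zn`), zero charges,
coarse AutoDock types, heavy-atom conservation asserted — which is enough
for fixtures and tests; real receptors should go through an external tool
(`CommandAdapter` wraps any stdin/stdout converter such as Open Babel).

## Docking backends

`VinaBackend` shells out to an AutoDock Vina executable with defaults
exhaustiveness 8, up to 9 binding modes, energy range 3, and an explicit
`--seed`; scores are parsed from the output pose file, which keeps the
adapter independent of the binary version (recorded in result metadata).
The benchmark score of a molecule is always the lowest (best) pose score.
Positive best scores are flagged as "constrained" in logs, since they
indicate a pose squeezed by the search box.

`MockBackend` makes every suite runnable with no binary and no downloads.
It scores a molecule as a smooth deterministic function of a 16-dimensional
descriptor vector (MW/100, cLogP, ring count, HBD, HBA, rotatable bonds,
and ten hashed Morgan bits): `score = -8.5 - 4.5 * tanh(z / 2.5)` where `z`
is a weighted sum of standardized descriptors. The tanh bounds scores to
the realistic docking range (-13, -4); the weight on size and lipophilicity
reproduces the classic bias of docking scores toward large hydrophobic
molecules, which is what makes the QED-penalized objectives meaningful on
the mock backend. Because the map is monotone in `z`, the correlation
between two targets over a library is controlled by the angle between
their weight vectors: the fixtures module draws weights in the whitened
principal-component space of the library's standardized descriptors, where
the pre-squash correlation of two targets equals the inner product of
their unit direction vectors exactly, and the squash attenuates it by only
a few percent (a requested 0.8 realizes within ±0.1 at n = 2000). Poses
are synthesized deterministically around the box center.

Mock objective evaluations use a descriptor-level fast path without 3D
embedding, so an optimization run with a 1000-evaluation budget takes
seconds; full 3D preparation is exercised whenever poses are requested.

## Chemical space

* **Fingerprints**: RDKit path fingerprints of maximum path length 6
  (2048 bits) for clustering and similarity search; 1024-bit radius-2
  Morgan fingerprints as the alternative kind. Canonicalization makes them
  invariant to input atom ordering. A bondless molecule (single heavy
  atom) would have an empty path fingerprint, making all such molecules
  mutually indistinguishable with Jaccard distance 0; one element-derived
  bit is set instead.
* **Clustering**: DBSCAN (scikit-learn, precomputed Jaccard distances)
  with neighborhood cutoff eps = 0.25. `min_core_neighbors` defaults to 5
  and follows the usual `min_samples` convention (the count includes the
  molecule itself). Correctness is pinned against a brute-force
  density-reachability oracle on instances with n ≤ 50; border-point
  assignment is order-dependent in DBSCAN, so the comparison requires
  identical partitions on core points and a legitimately reachable cluster
  for every border point.
* **Generic scaffolds**: Bemis–Murcko decomposition (ring systems plus
  linkers) followed by carbonization of heteroatoms *and* reduction of all
  bonds to single order. The bond reduction is a deliberate design choice:
  without it, "same scaffold" would distinguish aromatic from saturated
  analogues of the same ring skeleton, which defeats the purpose of the
  generic key. Acyclic molecules map to the empty scaffold.
* **Cluster splits**: cluster ids (noise points count as singletons) are
  shuffled by seed and assigned whole to the test side until the requested
  fraction is reached. No cluster ever straddles the split, which is the
  point: chemical datasets are full of near-duplicates, and random splits
  leak them across sides and inflate test performance. A single-cluster
  labelling is reported as degenerate rather than silently split.
* **Profiles**: cLogP, MW, HBD, HBA, rotatable bonds (non-strict, see
  above), QED, and the Lipinski rule-of-five verdict
  (MW ≤ 500 ∧ logP ≤ 5 ∧ HBD ≤ 5 ∧ HBA ≤ 10).

## Benchmarks

* **Regression**: R² = 1 − SSres/SStot, MSE, MAE. Zero-variance truth
  makes R² undefined; it is reported as missing, never as an arbitrary
  number. The shipped benchmark target list is {PARP1, F2, KIT, ESR2,
  PGR}.
* **Virtual screening**: rank the library, dock the top-k (default 5000),
  label a molecule active when its actual best score is below the
  threshold, and report EF = (active rate in selection) / (active rate in
  library). The activity threshold is the lowest 0.1-percentile order
  statistic (rank ⌈p/100 · n⌉ of the ascending scores); the published
  per-target constants (KIT −10.7, PARP1 −12.1, PGR −10.1) are served from
  config because they derive from a billion-molecule commercial library
  that is not recomputable at desk scale. Ties at the top-k boundary break
  on canonical SMILES for determinism; preparation-rejected molecules are
  excluded from the selection, other backend failures count as inactive.
* **De novo objectives** (all minimized, all with the druglikeness penalty
  `10 · (1 − QED)` — 0 for a perfectly druglike molecule, 10 for a
  hopeless one):
  * *F2*: `s(F2) + penalty` — single-target binding.
  * *Promiscuous PPAR*: `max(s(PPARA), s(PPARD), s(PPARG)) + penalty` —
    the worst of the three, so all three nuclear receptors must bind.
  * *Selective JAK2*: `s(JAK2) − min(s(LCK), −8.1) + penalty` — bind the
    kinase JAK2 while avoiding the off-target kinase LCK, whose score is
    anchored at its dataset median (−8.1). The anchor creates a flat
    region: scoring *worse* than median on LCK earns nothing extra, so the
    optimizer cannot farm reward by trashing the off-target.
* **Budget**: 5000 objective evaluations, counted over *unique* molecules
  by an append-only ledger. Cache hits are free; failed preparations
  consume budget with value +∞, so an optimizer cannot probe for free or
  exploit failures. The 5001st unique evaluation raises. Trajectories
  report the k-th best value after each call (k = 1 and 25), missing while
  fewer than k calls exist.

## Optimizers

* **Tanimoto GP**: exact Gaussian process with kernel
  `k(a, b) = amplitude · T(a, b) + noise · 1[a ≡ b]` and a constant mean.
  Since `T(a, a) = 1`, the prior variance is the amplitude and a query
  dissimilar to all training points reverts to the mean. Hyperparameters
  maximize the log-marginal likelihood via L-BFGS on log scales with
  analytic gradients and a variance-heuristic restart; the returned
  parameters never score below the initialization. Posterior algebra is
  dense Cholesky with 1e-8 jitter; a block-bordering update appends
  observations in O(n²b) for the BO loop. Correctness is pinned to 1e-8
  against a textbook explicit-inverse oracle. A caveat for users: with
  druglike path fingerprints, pairwise similarities are small (median
  ≈ 0.08), so amplitude and noise are only weakly separable when the noise
  is a small fraction of the amplitude; the parameter-recovery test runs
  at signal-to-noise 2 where the MLE is informative.
* **Graph GA**: population 250, offspring 25, mutation rate 0.01.
  Offspring come from fragment recombination (each parent cut at a random
  acyclic single bond, complementary fragments joined) plus an optional
  point mutation (element swap, atom insertion/deletion, bond-order
  change); failed recombinations fall back to cloning after bounded
  retries. Parent selection is fitness-proportional on rank-transformed
  scores; survival is elitist, so the best value never worsens. Children
  are capped at 60 heavy atoms.
* **Token GA**: mutation-only GA on a compact robust string representation
  built in the spirit of SELFIES: atoms carry the bond order to their
  predecessor, branches are explicit push/pop markers, ring closures
  reference an atom k steps back, and the decoder caps every requested
  bond by the free valence of both endpoints and skips inapplicable
  tokens. Every single-token edit (insert/delete/replace) of any sequence
  therefore decodes to a valid molecule — the property this GA relies on.
  The grammar covers neutral molecules over C/N/O/S/F/Cl/Br (round-trip
  verified on the synthetic library); charged or exotic inputs are
  rejected at encoding time and skipped as parents. Stereochemistry is not
  represented.
* **GP-BO**: the GP trains once on the 2000 lowest-objective points plus
  3000 random points from the dataset; hyperparameters stay fixed
  afterwards. Each iteration proposes a batch of 5 by maximizing UCB
  (μ + 10σ) or expected improvement over the incumbent, exploring with the
  graph GA's variation operators (offspring 1000, 25 generations by
  default). Objectives are minimized, so the GP models the *negated*
  objective and "maximize μ + βσ" applies literally. Acquisition values
  are not re-fantasized within a batch — the simplest batched reading.
  If the search surfaces too few novel molecules the batch is filled with
  the best unevaluated candidates seen, and the shortfall is logged.
* **Fingerprint similarity search**: each library molecule inherits the
  active/inactive flag of its Tanimoto-nearest reference,
  predicted-inactives are discarded, survivors are ranked by similarity,
  top-k returned.
* **Random baseline**: uniform sampling without replacement from the
  library — the no-information control every other optimizer must beat.

GA populations initialize from the dataset's best `population_size`
molecules by default (a `random` mode is provided); with free access to
the dataset, starting from its best members is the natural reading and the
stronger baseline.

## What the synthetic data does and does not show

The generator decorates a pool of 20 common druglike ring scaffolds with
typical substituents (occasionally joining two scaffolds through a short
linker), yielding libraries where ≥ 70% (in practice ≈ 95%) of molecules
pass Lipinski's rules — emulating the druglike profile of curated
bioactivity datasets. Defects (radicals, salts) can be planted for exact
rejection accounting. Mock targets emulate the observed score range and
inter-target correlation structure of real docking matrices.

What passing tests on this data shows: the pipeline's determinism and
accounting, the correctness of the box rule, clustering, GP algebra,
objective forms and budget mechanics, and the *qualitative* ordering of
optimizers (model-based and evolutionary search beat random sampling on a
smooth descriptor-level objective). What it does not show: performance on
real docking scores (rugged, 3D-dependent, slow), real dataset-scale
cluster/scaffold counts, or published benchmark numbers — those require
the full dataset, a commercial screening library, and real Vina runs, none
of which are desk-reproducible. The seed-stability claim for Vina
(best-score spread ≤ 0.1 kcal/mol) is an integration test that runs only
where a Vina executable is installed.

## Problem sizes used by the test suite

Tests run the study's mechanisms at reduced scale as the package's own
choice of fixture sizes: libraries of 300–2000 molecules, screens of
1000 molecules with top-k 100–200 at a 10th-percentile threshold (base
rate 0.1), a 1000-evaluation optimizer-ordering study over 10 seeds, and
a scaled BO inner loop (batch 25, offspring 40, 4 generations, 100 best +
150 random training points). Library defaults everywhere remain the
full-scale values (budget 5000, top-k 5000, batch 5, offspring 1000,
25 generations, 2000 + 3000 training points).
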