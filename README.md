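# dockbench

A deterministic molecular-docking pipeline with pluggable scoring
backends, chemical-space tooling, and docking-based benchmark suites for
machine learning in drug discovery.

Docking scores are a cheap, physically grounded stand-in for binding
affinity, which makes them attractive ground truth for benchmarking
molecular ML — but only if the pipeline producing them is reproducible
end to end. `dockbench` provides that pipeline and the evaluation
machinery around it, for three audiences: practitioners who want docking
scores from SMILES in a few lines, dataset builders who need
cluster-respecting splits and scaffold analysis, and ML researchers who
want standardized regression, virtual-screening and de novo design
benchmarks with classical baselines to beat.

## What's inside

* **Ligand preparation** — validation (single fragment, no radicals),
  rule-based (de)protonation at pH 7.4, one ETKDG conformer refined with
  MMFF94, Gasteiger charges, PDBQT output with a torsion tree. Identical
  `(SMILES, seed)` gives bitwise-identical output.
* **Target preparation** — docking search boxes from a bound reference
  ligand: per axis `size = max(span + 2·12.5 Å, 30 Å)`, centered on the
  ligand; receptor conversion behind an external-tool adapter.
* **Docking** — an AutoDock Vina subprocess adapter (explicit seed,
  version-independent parsing) and a deterministic mock backend with
  realistic score ranges and controllable inter-target correlation, so
  every benchmark runs with no binary and no downloads. The score of a
  molecule is the best (lowest) of up to nine poses.
* **Chemical space** — path/Morgan fingerprints, Jaccard-distance DBSCAN
  (eps 0.25), generic Bemis–Murcko scaffolds, leak-free cluster splits,
  druglikeness profiles (QED, Lipinski).
* **Benchmarks** — regression metrics (R², MSE, MAE); enrichment-factor
  virtual screening (rank, dock top-k, EF against a 0.1-percentile
  activity threshold); three QED-penalized de novo objectives under a
  5000-evaluation budget ledger:

  * F2: `s(ℓ, F2) + 10·(1 − QED(ℓ))`
  * Promiscuous PPAR: `max{s(ℓ,t) : t ∈ {PPARA, PPARD, PPARG}} + 10·(1 − QED(ℓ))`
  * Selective JAK2: `s(ℓ, JAK2) − min(s(ℓ, LCK), −8.1) + 10·(1 − QED(ℓ))`

  all minimized; lower is better.
* **Optimizers** — exact Tanimoto-kernel Gaussian process (analytic-gradient
  marginal-likelihood fit, incremental posterior updates), GP Bayesian
  optimization with UCB (β = 10) or expected improvement in batches of 5,
  a graph GA (population 250, offspring 25, mutation 0.01), a
  mutation-only GA on a robust token representation, fingerprint
  similarity search, and a seeded random baseline.
* **Fixtures** — deterministic synthetic druglike libraries, mock score
  matrices with requested correlations (e.g. ρ = 0.8 between two kinase
  stand-ins), and a miniature synthetic receptor.

See `docs/methods.md` for models, conventions and numerical choices.

## Worked example

Generate fixtures, dock a molecule against the miniature receptor with
the mock backend, and run a short de novo design loop:

```console
$ dockbench fixtures make --n-molecules 50 --seed 0 --out-dir fx
fixtures -> fx

$ dockbench dock --target MINI --smiles "CC(=O)Nc1ccc(O)cc1"
CC(=O)Nc1ccc(O)cc1,MINI,-11.054

$ dockbench denovo --objective f2 --optimizer graph_ga --budget 200 \
      --library-size 500 --seed 0 --out-dir run
{"optimizer": "graph_ga", "objective": "f2", "best": -10.384188474442169, "evaluations": 200}
```

The dock line is `smiles,target,score`: −11.054 is the best mock docking
score (kcal/mol scale, lower = stronger predicted binding). The denovo
summary says the graph GA spent its full budget of 200 unique objective
evaluations and its best molecule reached an F2 objective of −10.38
(docking score plus druglikeness penalty). `run/` holds the evaluation
ledger, the best / 25th-best trajectories, and a config snapshot with all
seeds for an exact re-run:

```console
$ head -3 run/trajectory.csv
call,best,best25
1,-2.79928249004983,
2,-4.995176696170346,
```

The same loop with `--optimizer gp_bo_ei` or `--optimizer random` (and the
same seed) gives the comparison the de novo benchmark is about; the random
baseline is the floor every model must beat.

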