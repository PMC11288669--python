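# eigenchoice

A reproducible pipeline linking brain gene co-expression to population,
social treatment and display-trait variation:

1. **simulate** — negative-binomial bulk RNA-seq counts with planted
   co-expression modules, constitutive population shifts, treatment
   effects, and module–trait covariation whose slope can differ in sign
   between populations (ground truth for every downstream stage).
2. **preprocess** — median-of-ratios size factors, a
   `log2(count/sf + pseudocount)` variance-stabilizing transform,
   top-variance gene filtering, sample PCA, and QC flags for suspected
   sample swaps (Mahalanobis rule in PC space) and low read-mapping
   samples.
3. **network** — signed weighted co-expression network: biweight
   midcorrelation (with side-wise outlier capping), soft-threshold signed
   adjacency `((1 + cor)/2)^power`, topological overlap, average-linkage
   clustering with a dynamic-hybrid-style branch cut, module eigengenes
   (first PC per module) and eigengene-based module merging.
4. **models** — trait principal components (two per block of female
   behaviour, male behaviour, male morphology), Welch t-test contrast
   batteries, OLS models `eigengene ~ population * trait` with type-II
   sums-of-squares ANOVA, candidate-gene models, and a simplified
   negative-binomial differential-expression emulator.
5. **efdr** — permutation empirical FDR: response rows are shuffled
   (10 000 permutations by default, same plan for every response), models
   refit, and each term's parametric p-value converted to the proportion
   of shuffles at least as extreme.

## Command line

Each stage is a subcommand; `run` drives the whole pipeline from one YAML
file:

```sh
eigenchoice simulate   --config sim.yaml --out sim/
eigenchoice preprocess --counts sim/counts.tsv --meta sim/samples.csv --fraction 0.9 --out pre/
eigenchoice network    --expr pre/vst_filtered.tsv --out net/
eigenchoice efdr       --responses net/eigengenes.tsv --meta sim/samples.csv \
                       --traits sim/traits.csv --n-perm 10000 --seed 17 --out ef/
eigenchoice run        --config run.yaml [--resume]
```

A minimal `run.yaml`:

```yaml
seed: 1
out_dir: runs/demo
simulate:            # or: inputs: {counts: ..., samples: ..., traits: ...}
  n_genes: 2000
  module_sizes: [100, 100, 100]
  n_per_cell: 6
  within_module_cor: 0.7
  pop_effect_sd: 0.5
network:
  power: 9
  min_module_size: 30
efdr:
  n_perm: 1000
```

Re-running with the same configuration reproduces byte-identical outputs;
the manifest (`manifest.json`) records the effective configuration,
checksums of every artifact, sample exclusions and per-stage wall-clock.

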