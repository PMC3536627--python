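# cisevo

Sequence-explicit simulation of gene-regulatory-network evolution.

Each of the `n` genes in a genotype carries an explicit promoter (upstream
regulatory region, URR) of `L` base pairs. Per-TF binding landscapes score
every possible 8-mer; thresholding the normalized score at `0.209` defines
each TF's binder set, and the specificity gap `gamma` sets how sharply
binding strength falls off across it. Scanning all overlapping URR windows
against the landscapes yields an interaction matrix, whose sigmoid
expression dynamics are iterated to a steady state (the phenotype).
Populations then evolve under per-URR sexual reproduction, per-base point
mutation, viability selection (must reach a steady state) and stabilizing
selection toward the founder phenotype. The analysis suite quantifies how
robustness to point mutations evolves: mutation-event classification
(silent / preserved / deleted / created, unique vs redundant / combined),
the constant-frequency decomposition of the robustness change, TFBS
conservation and avoidance, de-novo binding-site propensity, redundancy with
a random-network correction, and network rewiring with a
connectivity-matched baseline.

## Layout

| module | contents |
| --- | --- |
| `cisevo.landscape` | synthetic binding landscapes over all 65,536 8-mers: generation, normalization, specificity tables, TSV I/O |
| `cisevo.genome` | genotypes (URR strings + fixed signs/initial state), window scanning, interaction-matrix construction, mutation and recombination |
| `cisevo.dynamics` | discrete-time sigmoid expression dynamics, stability test, phenotype distance |
| `cisevo.evolution` | founder search, generational population cycles, trajectory records |
| `cisevo.analysis` | robustness probing, event classification, decomposition, conservation/avoidance, rewiring, redundancy |
| `cisevo.cli` | `cisevo` command-line interface |

## CLI

```sh
# write one 65,536-row landscape TSV per TF
cisevo generate-landscapes --n-tfs 10 --gamma 0.05 --seed 1 --out landscapes/

# run replicate simulations (JSONL trajectory per replicate + manifest)
cisevo run --length 50 --gamma 0.05 --pop-size 500 --generations 2000 \
    --eval-interval 10 --replicates 4 --seed 1 --out runs/demo

# tidy TSV reports (per generation x replicate x statistic)
cisevo analyze --run-dir runs/demo --out runs/demo/report
cisevo report --run-dir runs/demo
```

All flags can also be given via `--config config.yaml`; flags win on
conflict. Every run directory contains a `manifest.json` (full
configuration, per-replicate seeds, landscape digests, package version)
sufficient to reproduce it.

## Python API sketch

```python
import numpy as np
from cisevo import landscape as ls, evolution, analysis

panel = ls.generate_panel(n_tfs=10, gamma=0.05, seed=1)
tables = ls.tables_of(panel)
config = evolution.SimulationConfig(L=50, gamma=0.05, M=500,
                                    generations=2000, seed=1)
records = evolution.run_simulation(config, tables)
```
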