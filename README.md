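# activepath

Active-subnetwork pathway analysis for differential proteomics studies.

Starting from a protein-intensity table (proteins × samples) with a
sample→group mapping, the pipeline:

1. **differential** — per-group fold changes and Welch t-tests against a
   (possibly pooled) control group, an inclusive two-fold + significance
   selection filter, CV quality control, and one-way ANOVA with
   Bonferroni-corrected pairwise comparisons;
2. **subnetwork** — converts gene p-values to z-scores
   (z = Φ⁻¹(1 − p)), aggregates candidate modules as z_A = Σz/√k,
   standardizes against a Monte-Carlo background of random connected
   size-k sets, and searches for high-scoring connected modules by
   simulated annealing, reporting several modules with pairwise overlap
   ≤ 50 %;
3. **enrichment** — two-sided (enrichment/depletion) hypergeometric tests
   of each module against a GMT gene-set collection, Bonferroni-corrected
   per module, aggregated per pathway (best corrected p, "times found",
   genes found / not found);
4. **randomization** — re-runs the whole pipeline on label-shuffled group
   assignments to show that reported pathways are specific to the true
   grouping;
5. **synthetic** — a ground-truth generator (scale-free network, gene-set
   collection with a designated pathway, log-normal intensities with a
   planted connected module of ≥ 2-fold effects) used throughout the tests.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with one test per acceptance criterion
(brute-force oracles for the hypergeometric test and the module search,
null calibration, planted-module and end-to-end recovery, randomization
specificity, type-I control, CV emulation).

## CLI

```sh
# generate a synthetic study with planted ground truth
activepath simulate --outdir sim/ --seed 7

# stage by stage
activepath diff --study sim/study.tsv --groups sim/groups.tsv --map sim/map.tsv \
    --group CIS --control CONTROL --out genes.tsv
activepath subnet --scores genes.tsv --network sim/edges.tsv \
    --modules 5 --seed 17 --out modules.tsv
activepath enrich --modules modules.tsv --gmt sim/pathways.gmt \
    --network sim/edges.tsv --out report.tsv
activepath randomize --study sim/study.tsv --groups sim/groups.tsv \
    --map sim/map.tsv --network sim/edges.tsv --gmt sim/pathways.gmt \
    --group CIS --control CONTROL --runs 10 --seed 42 --out counts.tsv

# or everything from a YAML config
activepath run-all --config config.yaml
```

A minimal `config.yaml`:

```yaml
study: sim/study.tsv
groups: sim/groups.tsv
map: sim/map.tsv
network: sim/edges.tsv
gmt: sim/pathways.gmt
case_groups: [CIS, RRMS, PMS]
control_groups: [CONTROL]
search: {n_modules: 5, sa_iterations: 2000, restarts: 3}
randomization: {runs: 10, scope: all}
threshold: 0.05
seed: 7
outdir: out/
```

Outputs are deterministic given the seed (byte-identical reruns); the run
manifest records versions, seeds, and the enrichment-universe definition.

## File formats

Intensity TSV (header row = sample IDs, first column = protein IDs, empty
cells = missing), two-column sample→group TSV, two-column protein→gene TSV,
Broad-dialect GMT, and two-column edge-list TSV or three-column SIF for
networks. All writers emit UTF-8, Unix line endings, sorted records.
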