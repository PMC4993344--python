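# comethage

Analysis toolkit for multi-region brain DNA methylation cohorts: epigenetic-clock
age estimation with acceleration measures, per-lobe case/control EWAS with signed
Stouffer meta-analysis, consensus weighted co-methylation networks with
module–trait association, and CpG→gene representative collapsing with
hypergeometric gene-set enrichment. A fully ground-truthed synthetic cohort
generator makes every stage testable offline.

## Package layout

| Module | Purpose |
| --- | --- |
| `comethage.core_io` | Beta matrices, sample sheets, CpG annotation; TSV readers/writers; intensity→beta conversion; region→lobe grouping |
| `comethage.synthetic` | Latent-factor cohort simulation with planted clock CpGs, consensus co-methylation modules, HD effects, age/sex/neuron covariate effects |
| `comethage.clock` | Linear clock with log/linear age calibration, DNAm age, within-individual winsorization, 2-df spline control trend, acceleration and intrinsic (neuron-adjusted) acceleration |
| `comethage.association` | Kruskal–Wallis with ties, biweight midcorrelation (capped outlier down-weighting), correlation tests, PCs, OLS coefficient tables, coefficient→years conversion |
| `comethage.ewas` | Variance filter, age/sex residualization, per-lobe rank tests with median-based direction, p→signed-z, Stouffer meta, genomic-control lambda, Bonferroni thresholds, Manhattan export |
| `comethage.network` | Signed-hybrid adjacency (soft power 6), TOM, quantile calibration across lobes, quantile consensus dissimilarity, average-linkage module cut, module eigenvectors, fuzzy membership, module–trait meta-analysis |
| `comethage.enrichment` | Gene→CpG grouping, consensus kIM / consensus-sd representative selection (1 / 2 / ≥3 CpG rules), gene→module assignment, hypergeometric enrichment, GMT I/O |
| `comethage.pipeline` / `comethage.cli` | Stage orchestration, run manifest with checksums, `comethage` command line |

## Command line

```bash
# generate a synthetic fixture set (beta matrices, sample sheet, clock,
# annotation, gene sets, ground truth)
comethage simulate --seed 7 --out fixtures/

# run the full pipeline from a YAML config
comethage run --config run.yaml --out results/run1

# summarize a completed run as markdown
comethage report results/run1
```

A minimal `run.yaml`:

```yaml
beta_paths:
  frontal: fixtures/beta_frontal.tsv
  parietal: fixtures/beta_parietal.tsv
  occipital: fixtures/beta_occipital.tsv
sheet_path: fixtures/samples.tsv
clock_path: fixtures/clock.tsv
annotation_path: fixtures/annotation.tsv
gene_sets_path: fixtures/gene_sets.gmt
out_dir: results/run1
network:
  min_module_size: 20
```

Stages run in order `clock → association → ewas → network → enrichment`; each
writes TSV outputs and the run ends with `run_manifest.json` (per-stage
summaries, timings, warnings, output checksums).

## Tests

```bash
python -m pytest -q tests/
```

The suite includes per-module unit tests, property tests (hypothesis), and
`tests/test_acceptance.py` which checks worked-example reproduction and
multi-seed recovery of planted simulation parameters (clock accuracy,
acceleration bias, EWAS calibration, module recovery).

## Notes

- Meta-analysis p-values are labelled descriptive, not inferential: tests
  ignore the dependence from multiple samples per individual.
- Inputs are plain delimited text; array-level preprocessing (idat scanning,
  normalization, detection filtering) is out of scope — beta matrices are the
  interface.
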