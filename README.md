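# rankbank

Community-ecology analysis of amplicon OTU count tables, built around a
dominance statistic for highly uneven communities — the **interpolated
median rank**, the (possibly fractional) rank at which the cumulative
descending-abundance curve reaches one half — plus the surrounding
pipeline: rank-abundance model fits, alpha/beta diversity, cluster
stability, permutational MANOVA, composition summaries, and a
bank-model / kill-the-winner community simulator for generating
realistic synthetic datasets.

## Modules

| module | contents |
| --- | --- |
| `rankbank.otu_io` | `OtuTable` (samples × OTUs, non-negative integer counts), mothur `.shared` and plain-matrix TSV readers/writers, sample metadata CSV (with `BDL` / `n.d.` missing codes), relative abundance, subsetting |
| `rankbank.median_rank` | interpolated median rank, dominance classification (stable 1–4 band vs outliers), dwell-fraction estimate with Clopper–Pearson interval |
| `rankbank.alpha_diversity` | analytic (hypergeometric) rarefaction, Chao1 (classic / bias-corrected), inverse Simpson (plugin / unbiased) |
| `rankbank.rad_fits` | least-squares rank-abundance fits (power law, exponential, lognormal), SSE model selection, b–k parameter correlation |
| `rankbank.beta_structure` | Bray-Curtis / Euclidean / Manhattan / Canberra distances, UPGMA with newick export, bootstrap Jaccard node stability (0–100 scale), PERMANOVA (global + pairwise) |
| `rankbank.composition` | top-OTU dominance summaries, masked sample-contribution matrices, occupancy (persistent/sporadic), OTU-group composition |
| `rankbank.synthetic_communities` | bank-model communities (geometric abundant ladder + lognormal rare bank), kill-the-winner cycle snapshots, month × depth dataset generator (85-sample layout), block datasets for clustering checks |
| `rankbank.cli` | `rankbank` command-line interface and the orchestrated pipeline runner |

## CLI

```bash
# generate a synthetic 85-sample month x depth dataset
rankbank simulate --out-table table.tsv --out-meta meta.csv --seed 1

# per-stage analyses
rankbank alpha      --table table.tsv --out alpha.csv
rankbank medianrank --table table.tsv --out medianrank.csv
rankbank radfit     --table table.tsv --out fits.csv
rankbank beta       --table table.tsv --meta meta.csv --metric bray_curtis \
                    --factor month --permutations 9999 --seed 1 --out-dir beta/
rankbank composition --table table.tsv --groups groups.csv --out-dir comp/

# or one reproducible run from a YAML config
rankbank run --config run.yaml
```

A minimal `run.yaml`:

```yaml
seed: 1
output_dir: runs/demo
simulate:
  bank: {n_abundant: 3, abundant_mass: 0.6, s_bank: 500}
  design: {layout: bats}
alpha: {}
beta: {metric: bray_curtis, factor: month, permutations: 999}
composition: {}
```

Each run directory contains per-stage CSV/newick outputs plus
`manifest.json` (package version, config hash, seed, per-stage row
counts); identical config and seed reproduce byte-identical numeric
outputs.

## Conventions

* Samples are rows and OTUs are columns everywhere.
* The cumulative abundance curve is anchored at (0, 0), which is what
  permits median ranks below 1 when a single OTU holds more than half a
  sample.
* RAD fits minimise SSE on untransformed fractions; log-space
  regressions are used only as starting points.
* Distances default to relative abundances; raw-count mode is retained
  for sensitivity analysis.
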