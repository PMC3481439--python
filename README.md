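# netdms

Network-assisted gene-set analysis of GWAS summary statistics.

`netdms` combines SNP-level association P-values into gene-wise P-values
(three strategies, with LD-aware multivariate-normal simulation), overlays
the resulting z-weights onto a protein–protein interaction network, greedily
grows dense modules with a restricted disjoint-module search, standardises
module scores against an empirically fitted null, evaluates the pooled
module genes with a SNP-resampling gene-set test (Benjamini–Hochberg
corrected), and runs hypergeometric pathway enrichment. A synthetic-data
module generates LD-block genotypes, null/planted association statistics,
scale-free networks with planted dense modules, and pathway sets, so the
whole stack is exercisable offline.

## Layout

| module | purpose |
| --- | --- |
| `netdms.formats_io` | readers/writers: PLINK-like `.assoc`, gene locus TSV, edge-list TSV, GMT, genotype TSV, module TSV |
| `netdms.gene_score` | SNP→gene mapping (50 kb flank), LD estimation with PSD repair, gene-wise P (`all` / `top` / `minp`), z-transform, length-bias/Q-Q diagnostics |
| `netdms.network_build` | weighted simple background network (dedup, self-loop removal, unscored-node drop) |
| `netdms.module_search` | Stouffer module score Σz/√k, greedy growth (d=2, r=0.1, proportional-increment rule), restricted disjoint search (min size 5) |
| `netdms.significance` | median-centering, censored-normal central fit of (δ, σ), ZS and module P = 1 − Φ(ZS) |
| `netdms.gene_set_eval` | SNP-resampling significance test for gene sets (1/B floor, B=10,000 default), step-up BH |
| `netdms.enrichment` | upper-tail hypergeometric over-representation, Bonferroni |
| `netdms.synthetic_data` | synthetic genotypes/associations/networks/pathways with planted structure |
| `netdms.pipeline`, `netdms.cli` | six-stage orchestration with a reproducibility manifest; `netdms` CLI |

## CLI

Generate a synthetic study and run the full pipeline:

```sh
netdms simulate --seed 1 --out-dir sim/
cat > run.yaml <<'YAML'
inputs:
  assoc: sim/assoc.tsv
  loci: sim/loci.tsv
  geno: sim/genotypes.tsv
  edges: sim/edges.tsv
  sets: sim/pathways.gmt
method: all          # all | top | minp
seed: 1
YAML
netdms run --config run.yaml --out-dir out/
```

`out/` receives one file per stage (`gene_scores.tsv`, `network_edges.tsv`,
`modules_raw.tsv`, `modules.tsv`, `module_genes.gmt`, `gene_set_eval.tsv`,
`enrichment.tsv`) plus `manifest.json` with the config snapshot, seeds,
output digests and timings; re-running with the same config is
byte-identical. Stage-level subcommands (`gene-score`, `build-net`,
`search`, `significance`, `evaluate`, `enrich`) expose the same steps
individually; see `netdms <cmd> --help`. Exit codes: 0 ok, 2 config error,
3 data error, 4 numerical failure.

Defaults follow the published configuration: 50 kb gene flank, autosomes
only, top-fraction 0.10, d=2, r=0.1, minimum module size 5, module
selection at P<0.05, B=10,000 resamples, pathway size bounds 5–300.

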