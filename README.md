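# foldnet

Differential-function analysis for gene-knockdown expression experiments:

- **degs** — fold-change filtering (inclusive ≥2-fold by default), many-to-one
  probe→gene collapsing with discordance handling, and the unique/common
  partition between two knockdown conditions.
- **enrichment** — category over-representation (one-sided Fisher's exact /
  upper hypergeometric tail) with a randomization FDR for GO-like catalogs
  and Bonferroni correction over fixed pathway collections (38 by default).
- **ppinet** — "depth of 1 plus" interactome expansion (seeds, their immediate
  interactors, and all interactions among them), and network-level pathway
  enrichment tested against an empirical null of random size-matched seed
  networks (one-sample Student t with prediction-interval variance inflation,
  empirical percentile reported alongside).
- **qpcr** — comparative-CT relative quantification (fold change = 2^−ΔΔCT)
  with geometric-mean normalization over multiple reference genes.
- **synthetic** — generators for expression tables, probe maps, scale-free
  interactomes with a planted dense module, GMT annotation catalogs, and CT
  plates, all with known ground truth and per-artifact deterministic RNG
  streams.
- **pipeline / cli** — file-based orchestration of the full analysis with a
  manifest (checksums, seeds, counts) for reproducibility.

## Test

```sh
python -m pytest -q tests/
```

The suite includes oracle tests (exhaustive hypergeometric enumeration,
brute-force induced-subgraph expansion), calibration tests for both
randomization procedures, planted-signal recovery tests, and
`tests/test_acceptance.py` with one test per acceptance property.

## CLI

```sh
foldnet simulate --seed 1 --out-dir data/            # synthetic dataset
foldnet degs --expression data/expression.tsv \
    --probe-map data/probe_map.tsv --out partition.tsv
foldnet enrich --genes genes.txt --catalog data/kegg.gmt \
    --universe data/universe.txt --collection kegg_like --out enrich.tsv
foldnet ppinet --graph data/ppi.tsv --seeds genes.txt \
    --catalog data/kegg.gmt --pool data/pool.txt \
    --universe data/universe.txt --out-prefix net
foldnet qpcr --ct-table plate.tsv --reference ACTB --reference B2M \
    --control-sample control --out qpcr.tsv
foldnet compare --array-fc array.tsv --qpcr-fc qpcr.tsv --out compare.tsv
foldnet all --config run.yaml                        # full pipeline
```

Exit codes: 0 success, 1 user error, 2 internal error. All file formats are
plain text: TSV tables, GMT gene sets, TSV/SIF edge lists, YAML configs.

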