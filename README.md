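# efdb

Platform-independent databases of **effective-fold (EF) transcriptional
profiles**: build them from raw multi-sample expression series, search them
with thresholded fold signatures, and score the results.

Instead of requiring a control/treatment assignment, every measurement is
expressed relative to its experimental series average through the bounded
fold measure `f = 2(s − s̄)/(s + s̄)` (computed per probe over the samples
surviving a low-expression cutoff). Profiles from unrelated experiments and
platforms thereby share a common scale and can be compared directly by
Pearson correlation over shared genes, ranked by the Fisher-z score
`s = √(N−3) · atanh(r)`.

## What is included

| module | purpose |
| --- | --- |
| `efdb.ef` | delog / rescale / cutoff preprocessing, per-sample EF profiles, pooled treatment-vs-control fold profiles with t-test p-values |
| `efdb.collapse` | probe → gene collapse: annotation parsing, corpus-wide RMS probe statistics, one representative probe per gene |
| `efdb.store` | line-oriented flat database format (`#EFDB`), streaming record reader, append |
| `efdb.query` | query construction from replicates, shared-gene Pearson correlation, Fisher-z ranking, two-tailed database search |
| `efdb.cmap` | ranked-list → pseudo-fold conversion, replicate pooling per compound, binary-signature scoring against instance sets |
| `efdb.enrichment` | enrichment curves, exact hypergeometric (Fisher exact) tail tests, permutation K-S significance |
| `efdb.signatures` | unanimous sense-conserved ±1 signatures across studies |
| `efdb.simulate` | seeded synthetic series / databases / ranked instances with known ground truth |
| `efdb.cli` | `efdb` command with `simulate`, `build`, `search`, `cmap-pool`, `signature`, `signature-score`, `enrich` subcommands |

## CLI walkthrough

```sh
# synthetic fixture with a planted 4-fold effect on 12 genes
efdb simulate --seed 7 --out-dir sim --n-genes 60 --effect-genes 12 --effect-size 4

# EF -> collapse -> flat database
efdb build --expression sim/expression.tsv --annotation sim/annotation.tsv \
    --gene-universe sim/gene_universe.txt --platform SIMPL1 --out sim/db.efdb

# search with a gene/fold/p query signature (both tails are written)
efdb search --db sim/db.efdb --query query.tsv --top 100 --min-genes 5 \
    --alpha 0.05 --out hits.tsv

# enrichment statistics over a correlation-ranked labelled sample list
efdb enrich --labels labels.tsv --k 25 --n-perm 10000 --seed 1 --out enrich.json

# pool ranked perturbagen instances and score a binary signature
efdb cmap-pool --manifest manifest.tsv --alpha 0.05 --min-replicates 3 --out pooled/
efdb signature --profile study1.tsv --profile study2.tsv --out sig.tsv
efdb signature-score --signature sig.tsv --manifest manifest.tsv --out scores.tsv
```

Every subcommand writes a `*.runlog.json` with its resolved configuration so
a run can be repeated from the log alone.

## Flat database format

```
#EFDB	1	platform=GPL96	species=human	genes=M	samples=S
GENES	g1	…	gM
<sample_id>	<series_id>	v1	…	vM
```

One file per platform; folds are 4-decimal fixed-point, `NA` marks genes
removed by the cutoff. The format streams record by record, so search
memory is bounded by one record plus the gene list.
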