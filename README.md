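# amygdex

Candidate-gene analysis for developmental amygdala expression:

1. **genesets** — load scored gene lists (SFARI-style categories S, 1–6),
   filter by evidence category, form unions/intersections, and test
   overlap significance with a log-space hypergeometric tail.
2. **human_expression** — aggregate a developmental expression matrix
   (log2 intensities, region/period/hemisphere/donor metadata): average
   hemispheres, take per-period medians, and keep genes whose amygdala
   expression rises strictly above a log2 threshold (default 6.0) in a
   developmental window (default periods 2–8); summarize per-gene
   expression variance.
3. **mouse_atlas** — apply structure/level/age criteria (default
   RSP/Tel/PedHy, level ≥ 2.0 on the [−1.5, 3.5] scale, stages
   E11.5–P4) to a long-form atlas table, partitioning query genes into
   pass / fail / no-data.
4. **sc_de** — single-nucleus differential expression between ASD and
   control: depth normalization (`log2(1 + count·10⁴/total)`), a
   re-implemented two-part hurdle model (logistic detection + Gaussian
   level, each with diagnosis/age/sex/RIN/PMI fixed effects and a donor
   random intercept), likelihood-ratio tests of the diagnosis term,
   fold-change gating under both the full and a diagnosis-only model,
   BH FDR within cluster, one-vs-rest marker identification, and
   cell-type-resolved gene-set overlap. The mixed models are fitted by
   maximum likelihood: adaptive Gauss–Hermite quadrature for the
   logistic part, profiled closed-form GLS for the linear part
   (`amygdex.mixed`).
5. **simulate** — deterministic synthetic fixtures for all of the above,
   including a hurdle-process single-nucleus generator with donor random
   intercepts and planted effects.
6. **pipeline** — end-to-end orchestration from a YAML config with a
   JSON/TSV report.

## CLI

```bash
amygdex --help
amygdex simulate --what snuc --out fixtures/snuc          # synthetic MTX bundle
amygdex integrate --list-a a.tsv --list-b b.tsv --keep S,1,2,3 --out out/
amygdex filter-human --expr expr.tsv --meta meta.tsv --genes genes.txt \
    --region AMY --periods 2:8 --threshold 6.0 --out out/
amygdex filter-mouse --atlas atlas.tsv --genes genes.txt --out out/
amygdex de --mtx fixtures/snuc --fdr 0.05 --fc 0.10 --out de_table.tsv
amygdex markers --mtx fixtures/snuc --cluster all --out markers.tsv
amygdex overlap --de-table de_table.tsv --sets set80.txt,set271.txt --out overlap.tsv
amygdex run --config pipeline.yaml                        # full pipeline
```

A pipeline YAML names the inputs and thresholds:

```yaml
list_a: fixtures/list_a.tsv
list_b: fixtures/list_b.tsv
expression: fixtures/expression.tsv
sample_meta: fixtures/sample_meta.tsv
atlas: fixtures/atlas.tsv
snuc_dir: fixtures/snuc
out_dir: results/run1
seed: 1
human: {threshold: 6.0, period_lo: 2, period_hi: 8}
mouse: {min_level: 2.0}
```

## File formats

All plain text: gene lists as 2-column TSV (symbol, category); gene sets
as 1-column text; expression as genes × samples TSV plus a sample
metadata TSV (region, period, hemisphere, donor); atlas as long-form TSV
(gene, structure, age, level); single-nucleus data as a MatrixMarket
triplet (`matrix.mtx`, `genes.tsv`, `cell_meta.tsv`).

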