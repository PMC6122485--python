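# spongescout

Discovery of lncRNA-mediated miRNA sponge (ceRNA) triplets from matched
lncRNA / miRNA / mRNA expression profiles, with downstream survival,
clustering and genomic-proximity analyses.

For a candidate triplet (lncRNA X, miRNA Z, mRNA G) the pipeline:

1. **preprocess** — flags RPKM values below 0.05 as missing, drops rows
   missing in more than 20% of samples, imputes remaining missing values at
   the floor, log2-transforms, and removes rows with median absolute
   deviation below 0.5.
2. **screen** — keeps lncRNA:mRNA pairs with Spearman ρ > 0.5 (p < 0.05) and
   scores every miRNA by the sensitivity S = ρ − ρ_partial (partial Spearman
   correlation controlling for the miRNA); triplets with S ≥ t (default
   t = 0.2, a stricter t = 0.3 supported) survive.
3. **kci** — kernel independence tests with Gaussian kernels and simulated
   weighted-chi-squared nulls: the pair must be *dependent* unconditionally
   (p < 0.01) and *not demonstrably dependent* conditional on the miRNA
   (conditional-independence test not rejected at 0.01).
4. **filter-targets** — the miRNA must have target-database support against
   both the lncRNA and the mRNA (provenance and per-side source counts kept).
5. **prognostic** — patients are split by the up-down-up / down-up-down
   expression pattern at per-RNA cutoffs chosen by minimal single-RNA
   log-rank p (candidates: P10, P90, mean, median, Q1, Q3; both split sides
   must exceed 10 patients). A triplet is prognostic when the pattern split
   separates survival (p < 0.05) while no single RNA does; triplets are
   ranked by f = −log10(p_triplet / min single p).
6. **downstream** — Ward clustering (Mojena stopping rule, Milligan–Cooper
   c = 1.25) of mRNAs sharing a lncRNA:miRNA pair; proximity flags for
   member pairs within 100 kb on one chromosome (inclusive interval gap);
   node/edge network tables (SIF, GraphML, TSV).

A `synthetic_data` module generates expression matrices with planted sponge
triplets (conditionally independent given their miRNA), confounded and
independent null triplets, pattern-linked survival, target databases with
decoys, and GTF annotations with a controlled proximal fraction — so the
entire pipeline is exercisable offline with known ground truth.

## CLI

```sh
spongescout simulate --seed 1 --out data/            # synthetic dataset
spongescout preprocess --expression data/expression.tsv --out pre.tsv
spongescout screen --expression pre.tsv --t 0.2 --out cand.tsv
spongescout kci --expression pre.tsv --candidates cand.tsv \
    --alpha 0.01 --null-draws 1000 --seed 1 --out confirmed.tsv
spongescout filter-targets --triplets confirmed.tsv --db data/targets.tsv \
    --out filtered.tsv
spongescout prognostic --expression pre.tsv --triplets filtered.tsv \
    --survival data/survival.tsv --out prognostic.tsv
spongescout cluster   --expression pre.tsv --triplets filtered.tsv --out cl.tsv
spongescout proximity --triplets filtered.tsv --gtf data/annotation.gtf \
    --out prox.tsv
spongescout network   --triplets filtered.tsv --out-prefix net
spongescout run --config run.yaml                    # full multi-cohort run
```

`run.yaml` holds the fields of `spongescout.pipeline.RunConfig`
(per-cohort expression TSVs, survival/target/annotation paths, thresholds,
seed). Every stochastic stage consumes a seed derived from the run seed, so
repeated runs are bit-identical.

## File formats

- expression TSV: rows = RNA ids with a `class` column
  (`lncRNA`/`miRNA`/`mRNA`), columns = sample ids; RPKM before
  preprocessing, log2(RPKM) after.
- survival TSV: `patient`, `time`, `event` (1 = death observed).
- target TSV: `mirna`, `target`, `target_class`, `source`, `evidence`
  (`P` predicted / `E` experimental).
- annotation: 9-column GTF, feature `gene`, 1-based inclusive coordinates,
  `gene_id` attribute.
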