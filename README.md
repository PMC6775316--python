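# lncnet

Co-expression network analysis of lncRNA–mRNA interactions across
multiple treatment groups, as a tested, reusable pipeline:

- **catalog** — stepwise transcript classification (known lncRNA / known
  mRNA / novel lncRNA / discards) from FASTA + GTF + optional
  coding-evidence flags, with an ATG-initiated ORF scanner.
- **expression** — median-of-ratios size factors, shifted-log
  normalization, negative-binomial Wald differential expression
  (treated vs control), Benjamini–Hochberg adjustment.
- **network** — unsigned weighted co-expression networks: soft-threshold
  selection by scale-free fit, topological overlap (TOM), module
  detection by average-linkage clustering of 1 − TOM, module eigengenes,
  module–trait correlation, outlier-sample detection.
- **enrich** — gene-set over-representation with the EASE-modified
  one-tailed Fisher statistic against user GMT files; extraction of
  terms (and their common genes) enriched in every group.
- **conserved** — the cross-group funnel: all within-module TOM pairs →
  intersection across groups → mRNA–mRNA / lncRNA–mRNA pairs touching
  the common genes → simultaneous top-quantile filter → conserved edge
  list and node table.
- **syndata** — a synthetic-data generator (negative-binomial counts
  with planted latent-factor modules, a treated/control trait effect,
  planted conserved hub pairs, transcript sequences with controllable
  ORF content, planted enriched gene sets) plus a ground-truth channel
  used by the recovery tests.

## CLI

One entry point with one subcommand per stage:

```sh
# generate a synthetic dataset (counts, samples, FASTA, GTF, GMT, truth)
lncnet syndata --outdir data/ --seed 7            # optional --config cfg.yaml

# classify transcripts
lncnet catalog --fasta data/transcripts.fasta --gtf data/annotation.gtf \
    --evidence data/evidence.tsv --out catalog.tsv

# differential expression for one group (trait 1 vs 0)
lncnet de --counts data/counts_grp1.tsv --samples data/samples_grp1.tsv \
    --p 0.05 --fc 2 --out de_grp1.tsv

# per-group network / module / module-trait analysis
lncnet network --counts data/counts_grp1.tsv --samples data/samples_grp1.tsv \
    --powers 1:15 --r2 0.8 --out-prefix results/grp1

# enrichment of a gene list against GMT sets
lncnet enrich --genes module_genes.txt --gmt data/genesets.gmt \
    --background data/background_genes.txt --out enrich.tsv

# conserved interactions from per-group module TOMs
lncnet conserved --tom-dir results/ --groups grp1,grp2,grp3 \
    --catalog catalog.tsv --common-genes common_genes.txt --q 0.20 \
    --mode any --out-prefix results/conserved

# or run every stage on a syndata-style directory
lncnet pipeline --data-dir data/ --outdir results/
```

All inputs and outputs are plain text (TSV / FASTA / GTF / GMT / JSON).

## Acceptance

The acceptance suite (`tests/test_acceptance.py`) checks oracle
equivalence (TOM vs a triple-loop reference, EASE vs exact hypergeometric
tails on every table with N ≤ 60, BH vs brute-force step-up, ORF scan vs
exhaustive enumeration), statistical calibration (type-I error, power),
and recovery of planted structure (catalog classes, modules, the
trait-associated module, conserved pairs).  The report script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

writes the acceptance-target report (empty for this property-based
suite).
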