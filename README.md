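# sdikit

Per-gene scoring of subcellular localization diversity from Gene Ontology
cellular-component (GO-CC) annotations, plus an offline evaluation harness.

Each gene's deduplicated CC term set is scored with the **Subcellular
Diversity Index (SDI)**: every term *i* receives a penalty *p_i* — the root
mean square (by default) of its pairwise Wang semantic similarities to the
gene's other *n−1* terms, or exactly 1 when *n* = 1 — and

```
SDI = (1 − p_1) + (1 − p_2) + … + (1 − p_n)
```

Wang's similarity is computed over the is_a / part_of ancestor DAG with
contribution factors 0.8 / 0.6 (configurable). Higher SDI means a gene's
products occupy a more diverse set of cellular components.

## Layout

| module | purpose |
|---|---|
| `sdikit.ontology_io` | OBO parsing into a typed-edge DAG; ancestor subgraphs |
| `sdikit.annotation_io` | NCBI gene2go parsing with taxon/evidence filters; label & feature tables |
| `sdikit.wang_similarity` | Wang S-value profiles and pairwise term similarity |
| `sdikit.sdi_core` | penalties, per-gene SDI, genome scoring + summary, TSV I/O |
| `sdikit.evaluation` | ROC/AUC, decile enrichment + chi-square, Spearman, CV logistic regression, annotation-perturbation sensitivity |
| `sdikit.synthetic_fixtures` | deterministic toy ontologies / annotations / labels / features |
| `sdikit.cli` | `sdikit` command-line entry point |

## CLI

```sh
# generate a synthetic fixture set (OBO + gene2go + labels)
sdikit fixtures --n-terms 40 --n-genes 200 --seed 1 --out-dir fx/

# score a genome: ontology + annotations -> scores.tsv + summary.tsv
sdikit compute --obo fx/ontology.obo --gene2go fx/annotations.gene2go.tsv \
    --taxon 9606 --out-dir scores/
# flags: --exclude-iea --include-not --aggregator {rms|mean|gmean}
#        --w-is-a 0.8 --w-part-of 0.6 --full-precision

# evaluate against a label list or feature table
sdikit evaluate --scores scores/scores.tsv --mode roc     --labels fx/labels.txt --out-dir eval/
sdikit evaluate --scores scores/scores.tsv --mode deciles --labels fx/labels.txt --out-dir eval/
sdikit evaluate --scores scores/scores.tsv --mode spearman --features feats.tsv \
    --feature-column degree --out-dir eval/
sdikit evaluate --scores scores/scores.tsv --mode cv-logit --labels fx/labels.txt \
    --features feats.tsv --folds 10 --seed 0 --out-dir eval/

# robustness grid: perturb a fraction of genes, rescore, AUC per replicate
sdikit sensitivity --obo fx/ontology.obo --gene2go fx/annotations.gene2go.tsv \
    --taxon 9606 --labels fx/labels.txt --fractions 0.05,0.10,0.20 \
    --replicates 3 --seed 0 --out-dir sens/
```

Every subcommand writes a provenance JSON beside its outputs and is
byte-stable for a fixed seed.

Real inputs are the standard public formats: a go-basic OBO file and an
NCBI gene2go table (gzip accepted); species aliases (human, mouse, rat,
fly, worm, zebrafish, arabidopsis, yeast) map to their tax_ids. Label
lists are one gene id per line; feature tables are TSV with a header row
and gene ids in the first column.

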