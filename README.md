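# ptmx

Toolkit for analysing and predicting *in situ* cross-talk between
O-GlcNAcylation and phosphorylation — Ser/Thr positions carrying both
modification types. It covers:

- **io_data** — FASTA / site-table / GO-annotation parsing, site
  classification into crosstalk / phospho-only / O-GlcNAc-only, greedy
  identity-based redundancy reduction, and ratio-controlled training-set
  sampling (default negative:positive of 10:1 for the phosphosite-based
  classifier, 2:1 for the O-GlcNAc-based one).
- **conservation** — residue conservation ratio (RCR) on pre-aligned
  ortholog groups, relative RCR (percentile within the ±20-residue flanking
  window), two-sample Kolmogorov–Smirnov comparison, motif conservation.
- **features** — 21-residue windows one-hot encoded at 21 bits per position
  (20 amino acids + `*` terminus padding, 441 bits), concatenated with
  per-protein binary GO indicators.
- **mrmr** — minimal-redundancy–maximal-relevance ranking of GO features by
  incremental mutual information (nats), top-500 preselection.
- **model_eval** — RBF-SVM with class weighting, wrapper forward selection
  over the ranking tracked by pooled 10-fold CV AUC, grid search, and
  stringency-level reports (Sp > 0.95 / 0.90 / 0.85).
- **enrichment_motif** — two-tailed Fisher GO enrichment with Bonferroni
  correction and ratio > 4 filter; motif-x-style overrepresented-motif
  extraction with a 0.4 conservation filter and per-motif enrichment.
- **synthetic** — seeded generator for proteins, site catalogs, GO
  annotations and ortholog MSAs with known ground truth.

## CLI

Everything is reachable through the `ptmx` command. A minimal end-to-end
run on synthetic data:

```bash
ptmx simulate --seed 1 --out bundle/
ptmx build-dataset --fasta bundle/proteins.fasta --sites bundle/sites.tsv \
    --go bundle/go.tsv --basis phos --seed 1 \
    --out dataset.tsv --features-out features.tsv
ptmx rank --features features.tsv --labels dataset.tsv --k 500 --out ranking.tsv
ptmx train --features features.tsv --labels dataset.tsv --ranking ranking.tsv \
    --max-steps 50 --seed 1 --out model/
ptmx evaluate --features features.tsv --labels dataset.tsv --model model/ \
    --seed 1 --out eval.tsv
ptmx predict --model model/ --fasta bundle/proteins.fasta \
    --sites bundle/sites.tsv --go bundle/go.tsv --out predictions.tsv
```

Conservation, enrichment and motif analyses:

```bash
ptmx conserve --msa-dir bundle/msa --manifest bundle/msa_manifest.tsv \
    --sites bundle/sites.tsv --fasta bundle/proteins.fasta --out cons.tsv
ptmx enrich --fg fg.txt --bg bg.txt --go bundle/go.tsv --out enrich.tsv
ptmx motifs --sites bundle/sites.tsv --fasta bundle/proteins.fasta \
    --msa-dir bundle/msa --manifest bundle/msa_manifest.tsv \
    --go bundle/go.tsv --out motifs/
```

Defaults can be overridden with a YAML config (`ptmx --config ptmx.yaml ...`)
whose keys mirror the module defaults, e.g.:

```yaml
mrmr:
  k: 500
svm:
  weight_mode: positive   # or "negative" for the literal ratio-on-negatives
wrapper:
  retune_every: 0
motifx:
  p_threshold: 1.0e-6
  min_count: 20
conservation:
  cutoff: 0.4
```

Each output file is written atomically and accompanied by a
`*.manifest.json` sidecar with the tool version, config hash, seeds, input
digests and the decision flags in effect.

## Notes on numeric behaviour

- Class weighting defaults to weighting the **positive** (minority) class by
  the negative/positive ratio; the literal weight-the-negatives variant is
  available via `svm.weight_mode: negative`.
- Mutual information is reported in nats; any logarithm base yields the same
  ranking (tested).
- The rRCR percentile excludes the site itself from its flanking reference
  distribution and uses mid-rank tie handling.
- Wrapper hyperparameters are grid-searched once on the sequence-only
  baseline and then frozen; `wrapper.retune_every` re-tunes periodically.
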