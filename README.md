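# hvrforest

Random-forest taxonomic classification of 16S rRNA hypervariable regions
(HVRs) from k-mer frequency profiles.

## The problem

Amplicon surveys of microbial communities sequence one short hypervariable
region of the 16S rRNA gene (V2–V8, or a combined span such as V3–V5)
rather than the full gene. Homology search against a reference database is
accurate but slow, and the classic naive-Bayes classifiers lose accuracy on
these short fragments. `hvrforest` takes the prediction route: it excises a
chosen HVR from full-length reference sequences by fuzzy primer matching,
represents each sequence as a normalized 4-mer frequency vector, and trains
one random forest per taxonomic rank (phylum → genus). Query reads are then
assigned a lineage by the per-rank forests and written in the taxonomy
format QIIME consumes.

## The method in brief

* **Features.** For a sequence with `n` valid windows, the frequency of
  k-mer `w` is `count(w) / n`; windows containing non-ACGT symbols are
  skipped. With k = 4 the feature space has 4⁴ = 256 variables.
* **Forests.** Bagged classification trees (scikit-learn); each tree trains
  on a bootstrap sample (≈2/3 of the data) and the held-out third gives the
  out-of-bag (OOB) error used everywhere for model selection.
* **Tuning.** `mtry` (variables tried per split) starts at
  `floor(sqrt(4^k)/2)` — 8 for 4-mers — and is refined by an OOB-driven
  search (step factor 1.5, relative-improvement cutoff 0.02). `ntree`
  defaults to 1000, where the OOB error curve saturates. A pruning
  experiment that drops the 25 least important variables per step
  (256 → 231 → 206 → 181, ranked by OOB permutation importance) shows the
  error rising under pruning, so all 256 variables are kept.
* **Evaluation.** ~10% of each dereplication cluster is held out, test reads
  receive 1% random substitutions to emulate sequencing error, and
  performance is reported as the macro average over one-vs-rest rank groups
  of sensitivity, specificity, precision, accuracy, G-mean, F-measure and
  MCC.

## Worked example

Everything below runs on a synthetic reference generated by the package
itself (planted primer sites, a balanced toy taxonomy), so no downloads are
needed:

```bash
hvrforest simulate --out-dir run --seed 3 --n-phyla 2 --seqs-per-genus 3
hvrforest extract  --input run/reference.fasta --taxonomy run/taxonomy.tsv \
                   --region V3 --out-fasta run/v3.fasta --out-coords run/v3.coords.tsv
hvrforest train    --input run/v3.fasta --taxonomy run/taxonomy.tsv --region V3 \
                   --ntree 200 --mtry default --seed 1 --model-dir run/models
hvrforest classify --region V3 --model-dir run/models \
                   --input run/v3.fasta --output run/assignments.tsv
```

`simulate` reports `wrote 144 sequences to run/reference.fasta` and
`extract` reports `region V3: extracted 144/144 (coverage 1.000)` — every
synthetic sequence carries intact primer sites. `train` prints one line per
rank, ending with `genus: 45 taxa, mtry=8, OOB error 0.0000` (the toy set is
small enough to fit perfectly out-of-bag). The first line of
`assignments.tsv` is

```
fx00000	k__Bacteria;p__P1;c__P1.1;o__P1.1.1;f__P1.1.1.1;g__P1.1.1.1.1	0.8650
```

where the last field, the confidence, is the smallest vote fraction among
the assigned ranks.

The same pipeline driven from Python (see `tests/test_acceptance.py`) trains
on ~90% of the dereplicated fixture and classifies the held-out reads: over
five generator seeds the median genus-level accuracy is 0.95 on clean reads
and does not improve when 1% substitutions are injected.

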