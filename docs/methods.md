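# Methods

## Pipeline and model

`hvrforest` classifies short 16S rRNA amplicons by hypervariable region
(HVR). The training pipeline is: (1) excise the target HVR from full-length
reference sequences by ungapped fuzzy primer matching; (2) group sequences
by taxon at each rank from phylum to genus; (3) dereplicate within each
group; (4) convert each representative to a normalized 4-mer frequency
vector; (5) train one random forest per rank. Classification featurizes each
query read the same way and lets every rank's forest vote independently.

The per-rank forests are flat, not cascaded: the genus forest never sees the
phylum prediction. Predicted lineages can therefore be hierarchically
inconsistent; an optional `--consistent` mode re-scores each rank over only
the children (observed in training) of the taxon chosen one rank above.
The default reports ranks as predicted, since the per-rank training design
defines no repair rule.

## Primer extraction

Primer matching is IUPAC-aware Hamming scoring of every window, leftmost
window with fewest mismatches, no indels. The mismatch budget defaults to 0:
degenerate primer bases already absorb documented site variability, and
exact matching is reproducible. If the forward strand fails, the reverse
complement of the source is searched and coordinates are mapped back, since
reference databases mix orientations. The excised region is the span
*between* the two primer sites; primers are trimmed everywhere (training and
query) so both sides of the classifier see the same sequence. A primer pair
that extracts from ≤50% of the reference collection is flagged rejected —
the rule that excludes V1/V9 from the shipped primer table. The shipped
table (V2–V8 plus combined regions, classic E. coli-numbered primers) is
data, not algorithm, and is overridable via TSV.

## Dereplication

Identity-1 dereplication is exact string grouping (first-seen
representative). Below 1 (0.999 for full-length sequences at genus) a
greedy, longest-first pass assigns each sequence to the first cluster whose
representative it matches at ≥ threshold global identity, where identity is
best ungapped-offset matches divided by the longer length, with a
length-difference short-circuit. This deliberately replaces CD-HIT's word
filters and banded alignment: at thresholds ≥0.999 on ~1.4 kb sequences
almost every merge is a ≤1-mismatch pair, which this definition handles
exactly.

## Forest protocol

The forest algorithm is scikit-learn's `RandomForestClassifier`
(bootstrap=True, oob_score=True); the package owns the protocol around it.

* `default_mtry(k) = floor(sqrt(4^k)/2)` (8 at k = 4, the working size).
* `tune_mtry` walks up (×1.5) then down (÷1.5, round half-up, clipped to
  [1, p]) from the default, continuing while the relative OOB improvement
  over the best error so far exceeds 0.02; all candidate forests share one
  seed, so the trace is deterministic. Tuning is OOB-based throughout; no
  cross-validated variant is provided because OOB is the quantity the rest
  of the protocol (saturation curve, pruning decision) is defined on.
* Permutation importance is the OOB flavour: per tree, the drop in accuracy
  on that tree's out-of-bag examples when one column is shuffled, averaged
  over trees. scikit-learn's holdout-based `permutation_importance` is not
  used because the protocol's importances are defined on OOB data. The
  implementation calls the fitted trees' internal predictor directly, which
  keeps 256 variables × hundreds of trees inside seconds.
* `variable_pruning_experiment` ranks variables by the full-model OOB
  importance and retrains after removing the `block` (default 25) least
  important per step, visiting 256/231/206/181 at k = 4.
* Labels with <2 training sequences are dropped with a warning by default
  (configurable to a hard error): a singleton class cannot receive a
  meaningful OOB vote. Class weights are not rebalanced by default.

Defaults for final models: k = 4, all 256 variables, ntree = 1000. The test
suite and the end-to-end experiment use ntree in the 40–200 range — at the
fixture's problem size (≈300 training vectors) the OOB error is already
stable there and the full protocol is exercised unchanged.

## Evaluation harness

Test sets hold out `round(0.10·size)` (minimum 1, never the whole cluster)
members of each multi-member dereplication cluster; singletons train.
Sequencing error is emulated by substituting each position independently
with probability 0.01, drawing uniformly from the three other bases (never
silent, no indels — the regions are fixed-length spans, and indel-tolerant
matching is out of scope). Metrics are computed one-vs-rest per rank group
from the printed formulas; any zero denominator leaves that metric undefined
for that group, and macro averages are taken over defined groups only, with
exclusion counts reported. Averaging is unweighted (macro) across groups.

## Synthetic reference generator

The generator plants two regions (V3-analog, 150 nt core; V4-analog,
207 nt core — inside the real HVR length range of ~86–542 nt) between fixed
20-nt unambiguous primer sites, separated by conserved 40-nt spacers. A
balanced taxonomy (default 3 phyla × 2 × 2 × 2 × 3 genera × 5 sequences =
360 sequences) is descended from a root sequence, substituting variable-core
positions at per-rank rates (phylum 0.20, class 0.12, order 0.08,
family 0.06, genus 0.05) so sibling genera differ by ≥~5% in their cores;
a within-genus rate of 0.005 leaves some copies identical to the genus core,
which produces the multi-member dereplication clusters the splitter needs.
Conserved blocks are bit-identical across sequences, so primer coverage is
1.0 by construction; a `primer_corrupt_fraction` option scrambles forward
primer sites in an exact fraction of sequences to exercise coverage
accounting. The generator does not emulate secondary structure, PCR bias,
chimeras, indels, or real databases' extreme class imbalance — green tests
demonstrate correct mechanics and planted-signal recovery, not field
accuracy on real communities.

Measured under these conditions (five generator seeds, ntree = 200): median
held-out genus accuracy 0.95 on clean reads, unchanged at 1% substitutions —
1–2 substitutions in a 150-nt read barely perturb a 4-mer profile.

## Numerical and design choices

* Ambiguity codes match by expansion-set intersection; sequence symbols
  outside the IUPAC set match nothing.
* Window ties in primer matching break leftmost; orientation ties in
  `orient_read` break to forward; k-mer columns are fixed lexicographic.
* Reads shorter than k (or all-ambiguous) are Unclassified with reason
  `too_short`, not an error.
* Feature subsetting never renormalizes: a subset row keeps the mass the
  subset carried in the full distribution, modelling importance-pruning on
  the same underlying frequencies.
* Lineages violating the prefix property (a named rank below an unnamed
  one) are truncated at the first gap with a warning; grouping requires
  consistent prefixes.
* Seeds: every stochastic step (generator, splitter, mutation injector,
  forests, tuning) takes an explicit seed; identical seeds reproduce
  outputs byte-for-byte.

## Known limitations

No indel-tolerant primer matching; no species-rank models; no V1/V9 default
primers; single-threshold clustering only; no comparison drivers for
external classifiers. Reported fixture accuracies bound behaviour on the
synthetic conditions above, not on real metagenomes.
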