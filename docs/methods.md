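# Methods

## Problem

Position weight matrices (PWMs) score each base of a candidate
transcription-factor binding site independently, so they systematically miss
binding sites whose information is carried by base *interdependencies* —
non-canonical sites that a factor binds with high affinity but that lack the
canonical consensus. This package implements the alternative: a
convolutional-recurrent neural classifier trained on selection-derived
binding reads against dinucleotide-matched shuffles of those same reads, then
applied with a sliding window to ChIP-Seq peak sequences. Disagreement
between the two scorers — neural score above 0.99 while the best PWM
log-odds hit stays below background — flags candidate non-canonical sites.
The same classifier scores all single-base variants of a site (in-silico
saturation mutagenesis) and its scores are correlated against measured
dissociation constants.

## Negative construction

Non-binding controls are dinucleotide-preserving shuffles of the binding
reads, built with the Altschul–Erickson Eulerian-walk construction: the
sequence is an Eulerian path in the multigraph whose edges are its
overlapping 2-mers; a uniformly sampled in-tree toward the terminal base
fixes each vertex's last exit edge, the remaining edge lists are permuted,
and the walk is read off. The output has exactly the input's dinucleotide
multiset (hence mononucleotide counts and GC content) and the same first and
last base. Sequences shorter than 3 nt are rejected (no nontrivial
rearrangement exists). Per-read random streams are derived by hashing the
read id with the top-level seed, so negatives do not depend on collection
order.

Shuffling a motif-bearing read occasionally *reconstructs* a motif-like
window by chance (about 25% of shuffles of canonical-motif reads contain a
window with positive canonical log-odds at the default conditions). This is
intrinsic to shuffle negatives — the classifier is trained against it — but
it caps the achievable separation: the Bayes-optimal score of a motif window
is the posterior probability that a window with that appearance came from a
binding read, which is strictly below 1.

## Classifier

Architecture (all sizes configurable through `ModelConfig`):

    one-hot (L x 4, N = all-zero row)
      -> 1-D convolution (64 filters, width 8, ReLU)
      -> max pooling (configurable width, default 1) -> dropout 0.10
      -> bidirectional LSTM (48 units per direction, final hidden states)
      -> dense (96 units, ReLU, dropout 0.25, per-unit max-norm 3.0)
      -> single logistic output in [0, 1]; > 0.5 means "binding"

The network is implemented directly in numpy (float64) with hand-written
backpropagation — including backpropagation through time for both LSTM
directions — and verified against central finite differences in the test
suite. Training minimizes binary cross-entropy with Adam (initial learning
rate 1e-3, batch 256), halves the learning rate after a 3-epoch validation
plateau, stops early after 15 non-improving epochs (max 100) and restores
the best-epoch weights. All randomness flows from integer seeds through
`numpy.random.Generator`, so training and prediction are bit-reproducible
on any platform; no GPU or framework nondeterminism exists by construction.

Hyperparameter defaults were chosen by the package's own selection
protocol — validation ROC-AUC on the default synthetic study conditions —
over a grid spanning convolution on/off, kernel width (6/8/12), dense
dropout (0.25/0.5), directionality, and capacity. `grid_search` reruns that
protocol on any dataset; `consistency_check` retrains over repeated
re-splits to probe stability.

Splitting is 70/15/15, stratified, and a read is always co-assigned with
its own shuffle: placing a shuffle in the test set while its source read
was trained on would leak composition information. The label-permutation
control (chance-level AUC after destroying the label association) guards
the whole arrangement.

## PWM comparator

Counts from a JASPAR-format matrix become log2-odds against a background
(uniform by default, pseudocount 0.1):

    w[b, i] = log2( (c[b, i] + pc * bg[b]) / (colsum_i + pc) / bg[b] )

Scores are in bits; the scan takes the maximal window over both strands by
default, and "below 0" means "more background-like than motif-like" — the
non-binding arm of the discovery filter. The neural scanner defaults to the
forward strand (training reads are single-stranded); both policies are
explicit arguments.

## Synthetic data

The generator produces the three data kinds the pipeline consumes, with
ground-truth tables as first-class outputs. Defaults define the package's
study conditions:

* **Reads** — 7,200 reads of 20 nt (so the balanced, 70/15/15-split
  dataset has ~10,000 training and ~2,000 validation records), background
  i.i.d. at GC 0.5, every read planted with a motif instance at a uniform
  offset, per-position mismatch probability 0.05. A fixed 10% of planted
  reads carry a second, non-canonical motif (`TTTTCCACTTTG`, verified free
  of the canonical CNNG core on both strands at construction) instead of
  the canonical consensus `AAACCGGTTT` — emulating a selection library
  containing two binding modes, only one of which the PWM describes.
* **Peaks** — 500 positive 100-nt windows with the site's centre within
  ±10 nt of the summit. Peak rank r carries generative strength
  s = exp(-decay * r / (n-1)) (decay 1.0); the instance's mismatch
  probability is 0.05 + 0.25(1 - s) and the ChIP score is 10 s with
  lognormal noise (sd 0.1). The -log10 q-value is the deterministic
  function 5 + score, so every positive passes a linear q < 1e-5 filter by
  construction. 10% of peaks (exact count) carry the non-canonical motif;
  those peaks are resampled until the whole window scores below 0 under
  the canonical PWM and the instance neighbourhood is CNNG-free on both
  strands — the truth label "carries only a non-canonical site" is then
  true by construction, not by luck. Each positive window has a matched
  decoy: a dinucleotide shuffle of itself, re-shuffled until neither motif
  PWM finds a positive window (a chance reconstruction would falsify the
  decoy's "no motif" label).
* **Affinities** — Kd = kd_min * exp(slope * (1 - strength)) µM
  (kd_min 0.1, slope 6), censored ("no binding detected") above a 9 µM
  detection threshold and imputed at 10 µM in rank analyses. The default
  nine-ligand panel spans strengths 1.0–0.05, giving six measurable and
  three censored constants.

What the generator does *not* emulate: selection-round enrichment dynamics,
sequencing error, read pileup shape, genomic repeat structure, or
co-occurring motifs. Passing tests therefore demonstrate that the pipeline's
machinery recovers planted structure under its stated assumptions, not that
any particular biological dataset would yield the same numbers.

## Evaluation

ROC-AUC is the Mann–Whitney pair statistic computed from midranks (exact
under ties; curve points are for plotting only). PR-AUC integrates the
precision–recall sweep trapezoidally; its random baseline is the class
prevalence. The binned protocol sorts positive peaks by decreasing ChIP
score, cuts consecutive bins of 500 (the last bin may be short), and for
each bin repeatedly draws negatives without replacement, reporting per-bin
mean and sd of the AUC over repeats.

Affinity correlation follows the censoring rule of a calorimetric panel
with a 9 µM detection limit: Pearson on raw (score, Kd) pairs *excluding*
censored records, Spearman on ranks of *all* records with censored Kd
imputed at 10 µM. Signed coefficients are reported; because strong binding
means low Kd at high score, the expected sign is negative, and the absolute
magnitude is exposed alongside. Fewer than three uncensored pairs leaves
Pearson unreported (with a note) while Spearman is still computed;
zero-variance input raises an explicit error.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere internally; variant reports
  are 1-based (position 12 of a 20-mer ligand is the panel's convention).
* Summit windows overrunning a contig are dropped, never clipped: the
  scorers need fixed-length input and clipping would bias scores.
* narrowPeak column 7 (signalValue) is the ChIP score used for sorting and
  binning; column 5 is ignored. Column 9 is -log10(q); thresholds are
  given as linear q and converted (q < t  ⇔  -log10 q > -log10 t).
* Scan ties break toward the smallest offset, then the + strand; variant
  selection ties break by position, then alternate base.
* The discovery filter uses strict inequalities (score > 0.99, log-odds
  < 0).
* Percentiles are midrank-based (100 · rank / N) within each dataset.
* N bases one-hot to all-zero rows; windows containing N are unmatchable
  for the PWM (-inf) and rejected for training.

## Pipeline and reproducibility

The `crnn-tfbs` command exposes one subcommand per stage (simulate,
shuffle, split, train, predict, pwm-scan, scan, discover, mutate,
evaluate, correlate) plus `run` for chains, all driven by one YAML config
validated against a full schema (every error reported at once). Each stage
appends a manifest entry — input content hashes, parameters and their
hash, seed, package version — so any output file is traceable, and
rerunning an identical config reproduces outputs byte for byte.
`scripts/acceptance.py` re-executes the whole study from a single seed:
oracle agreement checks for the shuffle, PWM scan and AUC primitives, then
default-model training (~10,000 training / ~2,000 validation records), the
label-permutation control, the discovery experiment (500 positive peaks,
500 decoys), the saturation-mutagenesis panel and the affinity protocol;
the problem sizes are the package's default study conditions throughout.

## Known limitations

* The score a calibrated classifier assigns to a degraded motif instance
  is bounded by the shuffle-reconstruction posterior (see above), so the
  fraction of weak non-canonical sites passing a fixed 0.99 confidence
  filter depends on the degree of training-loss interpolation; recovery of
  strongly degraded instances is not guaranteed.
* The LSTM is the only recurrent cell offered; scores are not calibrated
  probabilities of binding in any physical sense.
* PWM p-values (dynamic-programming score distributions) are not
  implemented; the discovery filter uses raw log-odds.
* Training at selection-experiment scale (hundreds of thousands of reads)
  works but is slow in pure numpy; the package targets desk-scale studies.
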