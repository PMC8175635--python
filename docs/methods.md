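# Methods

## Model

A k-th order Markov chain over {A,C,G,T} assigns each base a probability
conditional on the k preceding bases. Word counts are strand-symmetric:
every valid (k+1)-window increments both the observed word and its reverse
complement, because sequencing and assembly report an arbitrary strand and
the classifier must be invariant to it. A palindromic word is therefore
incremented twice per occurrence; the convention is constant across training
and scoring, and λ — a ratio of mean log-likelihoods — is insensitive to it.

Transition probabilities are estimated with additive smoothing,
`P(x|u) = (N(ux)+c)/denom`. Two denominators are available:

* **row** (default): the smoothed row sum `Σ_x' N(ux') + 4c`. Every context
  row is a proper conditional distribution, including contexts never seen in
  training — unavoidable at k = 9, where a finite corpus cannot cover all
  4^10 words.
* **prefix**: the smoothed k-mer window count `N(u) + 4c`, the plain
  maximum-likelihood form. It differs from row mode only through windows at
  sequence boundaries, and it satisfies an exact strand identity used as a
  cross-check in the tests: for any clean sequence y,
  `(N−k)·[LL(rc y) − LL(y)] = ln Ñ(first k-mer) − ln Ñ(last k-mer)` with
  `Ñ(u) = N(u)+4c`.

Logs are natural; λ is invariant to the base (asserted in tests).

## GC-quantile ensembles

Each class's training genomes are split into M groups at the j/M empirical
quantiles (linear interpolation) of their per-genome GC fraction, one chain
per group; a class's score for a query is the best mean log-likelihood over
its M chains. Each class is binned by its *own* GC distribution. A genome's
GC is computed over the concatenation of its records; counting never crosses
record boundaries. A genome exactly on an interior edge goes to the lower
bin (deterministic); requesting more bins than distinct GC values is an
error rather than a silently empty bin.

## λ, calibration, and filtering

Mean log-likelihoods are negative, so the score is oriented as
`λ = LL_host / LL_virus`, which makes λ > 1 exactly when the viral
likelihood is larger; a `literal` orientation (viral numerator) is kept as a
configuration option for comparison. The decision rule is λ ≥ cutoff ⇒
viral.

Because λ distributions shift with sequence length, calls are calibrated by
an empirical p-value: the fraction of stored held-out bacterial fragments
with λ strictly greater than the query's. The null is stratified by
floor(log2(length)) with fallback to the nearest populated stratum ("pooled"
is available as an option); strict-greater counting is the default, with
optional add-one smoothing. Benjamini–Hochberg q-values (with an optional
Storey π0 correction) control the FDR over a batch of calls.

Paired-end reads are scored jointly: per chain, the window log-probability
sums of both mates are pooled and divided by the total window count, so no
window spans the mate junction and a missing or all-ambiguous mate reduces
exactly to single-mate scoring. Filtering supports a fixed λ threshold or a
top-fraction rule (keep the floor(f·n) highest-λ pairs; ties broken by pair
id; the realized cutoff is reported). Unscoreable pairs are a separate
stream and are excluded from assembly by default — conservative for viral
assembly — with a `keep` option.

## Synthetic benchmark

The generator emulates the model's own premise — that the two classes
follow different Markov chains — rather than any real taxon. A generating
chain of order 2 has rows centred on a GC-biased base distribution
(GC 0.35 for the viral class, 0.65 for the bacterial class) perturbed
multiplicatively by `exp(0.15·N(0,1))` per (context, base) cell and
renormalized, giving context-specific word usage on top of the GC signal.
The standard corpus is 8 genomes × 125 kb (1 Mb) per class; per-genome GC
varies only by sampling noise, which is enough to exercise quantile
binning. Benchmark scale elsewhere: 2,000 test fragments per class at
lengths 200/500/1,000/3,000 bp, and a 10,000-fragment bacterial null at
500 bp.

Fragmentation is non-overlapping with the trailing remainder discarded;
fragment ids carry 0-based half-open coordinates. Mixtures keep all V viral
fragments and draw `ceil(V·(1−f)/f)` host fragments uniformly without
replacement — 9V at 10% viral, V at 50%, ceil(V/9) at 90% — with an epsilon
guard so binary-float fractions cannot push an exact product (e.g. 9V) over
the next integer. The read simulator draws uniform fragment positions
(coverage proportional to genome length), takes mate 1 as the fragment
prefix and mate 2 as the reverse complement of its suffix, and is error-free
by default (optional uniform substitutions): the claims under test concern
the compositional signal, not sequencing-error robustness. Everything is
seed-deterministic.

What the generator does *not* emulate: repeats and mobile elements, shared
k-mer content between a phage and its host, codon structure, GC overlap
between classes, abundance profiles, or real error models. Passing
benchmarks therefore demonstrate correctness of the machinery and
recoverability of a genuine compositional signal at the stated sizes — not
field performance on real metagenomes, where class separations are far
smaller.

## Evaluation

AUROC is the Mann–Whitney U statistic divided by n_pos·n_neg, ties counted
0.5 (midrank), with the curve from a threshold sweep over distinct scores;
the tests cross-check both against scikit-learn. Bootstrap SEs (default 30
replicates) resample with replacement stratified by class, so every
replicate contains both classes. Precision/recall tables report NA precision
when no call is made, plus the cutoff where |precision − recall| is
minimal. Contaminant FPR is the fraction of contaminant-only fragments with
λ ≥ cutoff.

## Numerical and design choices

* Windows containing any non-ACGT base are skipped in counting and scoring;
  lowercase is accepted and uppercased; a sequence with no scoreable window
  is reported as `unscoreable`, never given a default score.
* `k = 0` is supported (a base-composition model); the empty context has a
  single row.
* Model files are a versioned container (JSON header + raw little-endian
  arrays) written deterministically: identical inputs give byte-identical
  files, and scores round-trip exactly. A version mismatch is a clear error,
  not a crash.
* Scoring is embarrassingly parallel over records; the CLI `--threads`
  option keeps output order identical to input order.
* Multi-line FASTA is accepted; FASTQ must be 4-line records; gzip is
  detected by magic bytes on input and by the `.gz` suffix on output.

## Known limitations

* The empirical p-value is discrete (granularity 1/n_null) and exactly 0 for
  queries above the whole null; add-one smoothing is available when zeros
  are unacceptable downstream.
* Quantile binning assumes enough genomes with distinct GC; tiny corpora
  should use M = 1.
* The length-stratified null needs fragments in (or near) the query's
  stratum; far-off lengths silently fall back to the nearest stratum.
* Chains are fixed-order; no interpolation or variable-order smoothing.
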