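# Methods

This note documents the models, conventions and design choices behind
`genomehub`, what the synthetic data emulates, and what passing the test
suite does and does not demonstrate.

## Coordinate and encoding conventions

All internal intervals are BED-style: 0-based, half-open, with strand
`+`/`-`. VCF positions (1-based) are converted on ingestion
(`pos - 1`), so only one convention exists inside the package.
Intervals may extend past chromosome ends in either direction; the
fetch layer returns `N` for out-of-range positions rather than raising,
because variant-centered windows near chromosome edges are routine.

One-hot encoding uses column order A, C, G, T. `N` encodes to an
all-zero row rather than 0.25s: this keeps the DNASeq schema binary,
makes padding visible to models, and lets decoding recover `N` exactly.
Reverse complementation of a one-hot matrix is a flip of both axes
(position reversal composed with the A↔T, C↔G column swap).

## The descriptor standard and registry

A model directory is described by a single `model.yaml`: name, a
framework kind from the closed set `{pwm, linear, mlp}`, input/output
array schemas (shapes with a leading `"*"` batch wildcard, optional
`DNASeq` tag), a data-loader configuration (FASTA key, interval-source
key, sequence length), artifact file roles, and a test block. The kind
set is closed deliberately — descriptors select one of the built-in
implementations and never trigger code loading, which keeps registry
trees safe to index and test. Artifact matrices are TSV with a header
row; PWM weights use the header `A C G T` with one probability row per
motif position. `mlp` models name their artifacts
`layer<k>.weight` / `layer<k>.bias`; hidden layers are relu, the final
layer sigmoid (binary outputs). Registry `linear` models use the
identity link; sigmoid-linked linear models arise programmatically as
fitted heads and are not round-tripped through descriptors.

The test harness (`registry.test_model`) re-runs the bundled example
inputs through the data-loader and model and compares element-wise
against the stored expected output. The comparison metric is maximum
absolute deviation, not relative error, because fixture outputs are
bounded scores and probabilities; the per-model tolerance defaults to
1e-5. Failures are reported, never raised, so a whole tree can be
tested in one sweep.

## PWM scanning

Log-odds are base-2 (bit scale, the motif-literature convention). The
pseudocount enters as `(p + eps*q) / ((1+eps)*q)` — i.e. the motif
distribution is mixed with the background and renormalised — so every
odds ratio is finite for `eps > 0`; `eps = 0` is honored exactly, with
zero-probability bases scoring −inf. An `N` input row has base
probability 0 and contributes `log2(eps/(1+eps))`, a strong but finite
penalty. The reported score max-pools over all window offsets on the
forward strand and the reverse complement; max is the standard scanning
convention and makes the score strand-symmetric.

## Variant effect prediction

Only SNVs are scored; indels and symbolic alleles are counted and
skipped (no mechanism is defined for them here). Multiallelic VCF
records expand to one variant per ALT. A variant whose stated REF does
not match the genome is flagged, warned about, and reported unscored —
real call sets contain such records and a run abort would be hostile.

`centered` mode places the variant at offset `L//2` of an `L`-window;
`anchored` mode pairs variants with every overlapping region from a
supplied BED (half-open overlap on the 0-based position) and
midpoint-resizes regions that differ from the model's input length. A
variant overlapping several regions yields one record per region; the
VCF annotation layer collapses those to the score of largest magnitude
(sign kept), which is lossless at the record level and conservative at
the annotation level.

Scoring functions: `DIFF = p_alt − p_ref` is the raw in-silico-
mutagenesis contrast and applies to any output; `LOGIT` contrasts on the
log-odds scale and suits probability outputs, with predictions clipped
to `[1e-7, 1 − 1e-7]` so that saturated predictions stay finite. Both
are exactly antisymmetric under ref/alt exchange.

Annotated VCFs are produced by streaming the input text and appending
INFO keys (`KV_<MODEL>_<OUTPUT>_<SCORING>`, sanitized to
`[A-Za-z0-9_]`, declared `Number=A, Type=Float`, values `%.6g`), which
keeps every other byte of the file identical to the input — a property
htslib round-tripping would not guarantee.

Mutation maps reuse the same scoring engine. Reference-base cells are
structural zeros (written, not computed, so they are exact), `N`
columns are zero and flagged, and evaluation is batched with results
independent of batch size (asserted in tests).

## Built-in models and training

The three executable kinds are a PWM scanner, a linear model
(identity/sigmoid link), and a small fully-connected net with
relu/sigmoid/identity layers exposing post-nonlinearity activations for
every layer id (0 = flattened input, D = prediction). Nets are trained
by full-batch gradient descent with a fixed step and epoch count,
seeded from numpy's PCG64 — deliberately plain so fixture pretraining
is deterministic across platforms. Logistic heads
(`fit_head_on_activations`) are L2-penalised maximum-likelihood fits
(objective: sum of log-losses + (l2/2)·‖w‖², intercept unpenalised),
solved by scikit-learn's lbfgs at tolerance 1e-8.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed); randomness comes
from numpy `default_rng` (PCG64) seeded per operation as
`default_rng([seed, stream_id])` with fixed stream ids, so outputs are
byte-identical across runs and platforms and independent across
generators.

* **Genomes** are i.i.d. bases with configurable GC content (default
  0.5, one 100 kb chromosome). They emulate background composition
  only: no repeats, no isochores, no assembly gaps.
* **Bound/unbound windows** (default 200 + 200 windows of 100 bp)
  implant one motif *instance sampled from the PWM* per positive window
  at a uniform-random offset — instances vary, so the classification
  task is non-degenerate. Real ChIP-seq peaks additionally carry
  cooperating motifs, accessibility structure and peak-calling noise;
  the benchmark here shows scanner correctness and ranking behavior,
  not biological performance.
* **Variant sets** (default 50 SNVs) are uniform over the genome with
  REF read from the genome, so REF always matches; an optional fraction
  can be forced outside a region set to exercise anchored-mode
  accounting.
* **Ensemble datasets** (default n = 5000) draw features i.i.d.
  standard normal with labels Bernoulli(sigmoid(X·w + b)),
  w = (1.5, −1.0, 0.5, 0.0) by default, plus a standard-normal
  "conservation" stand-in feature (generative weight 0 by default) and
  per-component missingness masks. Real pathogenicity panels have
  correlated, non-Gaussian features; this design tests the fitting,
  imputation and cross-validation machinery, not clinical accuracy.
* **Toy model trees** contain one model per framework kind with example
  inputs and expected outputs computed at generation time, so the
  harness passes out of the box and any later perturbation is detected.

## The transfer-learning experiment

A dense (non-convolutional) net cannot learn a motif implanted at a
uniformly random offset at this scale — it has no weight sharing across
positions — so the two-task experiment constrains implants to the
window center ± 2 positions. Task A pretrains on 3000 windows (800
full-batch epochs, 200→32→1, lr 1.0); task B uses a related motif (one
position's base preferences rotated) with 500 labeled windows. The
transferred model is a logistic head on the pretrained net's
penultimate activations (a convex, converged fit); the baseline is an
identically shaped net trained from random initialization on the same
500 windows under a small budget of 15 epochs, mirroring the regime in
which transfer helps: limited labels and limited training. Held-out
auROC is averaged over ≥ 5 seeds. The experiment demonstrates the
activation-extraction and head-fitting machinery and the qualitative
advantage of feature reuse; absolute gains are specific to this toy
design.

## Composite models

Missing scores are imputed with per-feature means computed on training
data only — inside cross-validation, on each training fold separately —
so no test information leaks into the fit (asserted by recomputation
under test-label shuffling). No missingness-indicator columns are added
and features are not scaled; regularisation is L2 with strength 1.0.
Folds are stratified and seed-controlled; the same folds are reused
across prefixes in incremental evaluation so prefix curves differ only
by the feature set. auROC uses the Mann–Whitney rank formulation with
average ranks for ties, which makes it invariant under strictly
monotone transforms of the scores.

## Numerical and degenerate-input policy

Matrix TSVs are written with `%.17g` (exact float round trip) for
artifacts and expected outputs, `%.6g` for human-facing annotation
output. Sigmoids are computed in the numerically stable split form.
Empty interval lists yield zero batches; empty VCF bodies yield zero
variants; single-class label vectors are rejected with explicit errors;
an all-masked ensemble feature is an error naming the component.
Midpoint resizing uses `start = (start+end)//2 − target//2`,
deterministic for even lengths.

## Known limitations

No convolutional or recurrent architectures, no external model-format
import, no bigWig/BAM inputs, no indel scoring, no real conservation
tracks, no network layer. Problem sizes throughout (100 kb genomes,
hundreds of windows, n = 5000 ensembles, 5-seed experiment averages)
were chosen so the full suite and the acceptance script each run in
well under a minute on a single CPU while keeping the statistical
assertions comfortably away from their tolerances.
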