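# genomehub

A self-contained, local model zoo for regulatory genomics. `genomehub`
defines a descriptor standard for trained sequence models, a
directory-tree registry with a reproducibility test harness, data-loaders
that turn genome FASTA + BED intervals into one-hot batches, a unified
prediction API, in-silico-mutagenesis variant effect prediction with
annotated-VCF output and mutation maps, activation-based transfer
learning, and logistic composite (ensemble) pathogenicity models. Every
pipeline is exercisable end to end with built-in toy models and
deterministic synthetic data — no downloads, no GPUs.

It is aimed at computational genomicists who want model exchange and
variant interpretation machinery (the registry/VEP/ISM workflow) in a
form that is easy to test, extend and script, and at method developers
who need a faithful desk-scale harness for these workflows.

## What it computes

**PWM scanning.** A motif of length $m$ is a position weight matrix
$P \in [0,1]^{m\times 4}$. A window $w$ at offset $i$ of a one-hot
sequence scores

$$s_i = \sum_{j=1}^{m} \log_2 \frac{P_{j,b_j} + \epsilon\, q_{b_j}}{(1+\epsilon)\, q_{b_j}}$$

with background $q$ (uniform by default) and pseudocount $\epsilon$; the
reported score is the maximum over all offsets on both strands.

**Variant effect prediction (ISM).** For an SNV with reference allele
$r$ and alternative $a$, the model is evaluated on two identical windows
differing only at the variant base:
$\mathrm{DIFF} = p_a - p_r$ and
$\mathrm{LOGIT} = \mathrm{logit}(p_a) - \mathrm{logit}(p_r)$
(predictions clipped to $[10^{-7}, 1-10^{-7}]$). Genome-wide models use
windows centered on the variant; anchored models (valid only on
predefined regions, e.g. exon boundaries) score each variant once per
overlapping region and leave non-overlapping variants explicitly
unscored. A mutation map extends this to all $3L$ substitutions of an
interval.

**Transfer learning.** For layered models the package exposes
intermediate-layer activations; a new binary task is fitted as an
L2-penalised logistic head on the penultimate activations of a
pretrained net.

**Composite models.** Per-variant scores from $K$ components form a
feature matrix; missing cells (unscored variants) are mean-imputed from
training data only; a logistic regression head combines the columns.
Evaluation is stratified 10-fold cross-validated auROC
(Mann–Whitney rank form), with incremental prefix evaluation and
per-component unscored fractions.

## Worked example

```
$ genomehub fixtures make --out demo --seed 42
fixture set written under demo

$ genomehub ls demo/registry
NAME                                     KIND     TAGS
linear/toy_linear                        linear   toy
mlp/toy_mlp                              mlp      toy,activations
pwm/toy_pwm                              pwm      binding,motif

$ genomehub predict --model pwm/toy_pwm --registry demo/registry \
      --fasta demo/genome.fa --bed demo/windows.bed --out demo/preds.tsv
$ head -4 demo/preds.tsv
# genomehub 0.1.0: ...
chrom   start   end     name    strand  score
chr1    0       100     w0286   +       2.51057
chr1    100     200     w0385   +       15.6399
```

The fixture genome carries an implanted 8-mer motif in half the windows;
window `w0385` scores 15.6 bits (a strong match) against 2.5 bits of
background. A mutation map over that window pinpoints the implanted
motif — every substitution inside it destroys the only strong match and
scores −6.56 bits, while positions outside contribute nothing:

```
$ printf 'chr1\t100\t200\n' > demo/iv.bed
$ genomehub mutation-map --model pwm/toy_pwm --registry demo/registry \
      --fasta demo/genome.fa --bed demo/iv.bed --out demo/mm.tsv
$ awk 'NR==1 || $3!=0 || $4!=0 || $5!=0 || $6!=0' demo/mm.tsv | head -5
position        ref     A       C       G       T
115     A       0       -6.56466        -6.56466        -6.56466
116     C       -6.56466        0       -6.56466        -6.56466
117     T       -6.56466        -6.56466        -6.56466        0
118     T       -6.56466        -6.56466        -6.56466        0
```

Variant annotation and the registry self-test use the same registry and
genome:

```
$ genomehub score-variants --model pwm/toy_pwm --registry demo/registry \
      --fasta demo/genome.fa --vcf demo/variants.vcf --out demo/annotated.vcf \
      --scoring DIFF,LOGIT
scored 50/50 SNVs (0 non-SNV alleles skipped) -> demo/annotated.vcf

$ genomehub test demo/registry/pwm/toy_pwm
pwm/toy_pwm: PASS max|dev|=0 (tol 1e-05)
```

The annotated VCF carries one INFO key per (model, output, scoring),
e.g. `KV_pwm_toy_pwm_score_DIFF`, declared in the header; unscored
variants carry `.`.

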