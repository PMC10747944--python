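# Methods

## Attributes and the descriptor

SMILES strings are treated purely as text. An attribute is one lexeme: a
bracket block `[...]` (no nesting), the two-character elements `Cl` and
`Br` outside brackets, a two-digit ring closure `%nn`, or a single
character. Closing parentheses are folded into `(`, since an opening and a
closing branch mark the same structural feature; raw lexemes are kept
available so detokenization reproduces the input exactly. Unicode minus
characters in transcribed tables are normalized to ASCII `-`. No chemical
perception of any kind is performed — validity, aromaticity and
canonicalization are deliberately out of scope, because the method operates
on the string representation itself.

Token frequencies are **molecule-level**: the count of a token in a subset
is the number of molecules containing it at least once, not the number of
occurrences. (The shipped reference tables force this reading: the most
common token's frequency equals roughly the subset size, which is
impossible for occurrence counts.) A token is *active* when its frequency
in the active training set strictly exceeds the threshold T (default 1);
all other tokens are *blocked* and their weight pinned to 0, so rare
features never influence the model.

The descriptor DCW is the sum of weights over the token *list* — every
occurrence contributes. The latent line Y = C0 + C1·DCW is fitted by
ordinary least squares of the 0/1 endpoint on the descriptor over the
active training set; the category rule is Y ≥ 0.5 (boundary inclusive). A
constant descriptor or a zero slope raises a degenerate-fit error rather
than producing a sham classifier.

## Target functions

TF0 = r_AT + r_PT − |r_AT − r_PT|·0.1 balances the correlations on the two
training subsets while penalizing their divergence. TF1 adds 0.5·IIC_C.
Both constants are configuration fields (`TargetFunctionConfig`), not
hard-coded. The source formula for TF0 is typeset ambiguously in the
literature; the balance-of-correlations form used here is the standard one
and reduces to 2r when both subsets agree.

IIC_C = r_C · min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺) is computed on the
calibration set only, from residuals Δ = observed − calculated on the Y
scale. Δ = 0 counts toward the non-negative side. (The published form of
the min/max arguments drops the ± superscripts; they are restored here.)
Degenerate cases return 0: when either residual side is empty or all
residuals vanish, the ratio is undefined and the optimizer is given no
reward it cannot justify. These events are logged at debug level.

Correlations inside the optimizer are computed between the labels and the
raw descriptor rather than Y: Pearson r is invariant under the
positive-slope affine map of the latent line, and this removes any
dependence on refitting order. A constant vector yields a correlation
contribution of 0 instead of an error during optimization.

## Monte Carlo optimization

One run: initialize every active weight uniformly in (−0.5, 0.5); then for
N epochs (default 15) pass over the active tokens in seeded-random order.
For each token, proposals δ are drawn with random sign and magnitude
log-uniform over 2.5 decades below the maximum step (default 1.0); a
proposal is kept only if the target strictly increases (ties reject, which
keeps runs deterministic and drift-free), and proposals on that token
continue until 3 consecutive rejections, at most 12 per epoch. The
latent-line coefficients are refit by OLS at every evaluation because the
IIC residuals live on the Y scale.

The multi-scale proposal ladder is the load-bearing numerical choice. A
single fixed-width proposal per token per epoch was measured to leave the
target far from its attainable value within 15 epochs (the accepted trace
was still climbing steeply at the end, and held-out performance suffered
accordingly): a weight sometimes has to travel by ~1 and at other times
needs refinement by ~0.01, and a fixed step cannot serve both. Drawing the
magnitude log-uniformly lets every epoch mix coarse carries with fine
polish; with the per-token patience rule the optimizer then approaches the
correlation optimum reliably within the 15-epoch budget at roughly 2–3
thousand target evaluations per run (well under a second on a 2000-molecule
corpus).

Determinism: all randomness flows from one `numpy` Generator seeded by the
run seed; identical split + seed gives bit-identical weights. Probe runs
differ only in seed (seed+0 … seed+k−1).

## The four-subset design

A corpus is divided uniformly at random into active training, passive
training, calibration and validation subsets of near-equal size (⌊n/4⌋ or
⌈n/4⌉). No stratification by class is applied by default — the subsets of
the original study visibly vary in class balance — but a `stratify` flag is
available. The validation set is untouched during training; r_AT drives the
fit, r_PT cross-checks it on molecules the optimizer never fits, and the
calibration set alone feeds the IIC overtraining guard.

The self-consistency matrix applies model i to validation set j; its
summary reports mean and sample standard deviation both over all k² cells
and over the diagonal, since the two can differ and the literature does not
pin down which is meant by "average ± dispersion".

## Feature interpretation

Probe runs are repeated optimizations differing only in seed. A token
active in all probes is a class-1 promoter (weight > 0 in every probe), a
class-2 promoter (< 0 in every probe) or unclear otherwise; an exact zero
in any probe means the signs are not uniform, hence unclear. Blocked tokens
are excluded — they were never used in the simulation. The cross-split
presence table marks each promoter with `+` per split. The statistical-
defect applicability-domain measure that sometimes accompanies such tables
is not computed here: no self-contained definition is available, and
guessing one would misrepresent the method.

## Synthetic corpora

The generator emulates the *shape* of the eye-irritation corpus the method
was developed on: 5220 molecules, 74.2% active, SMILES over an alphabet of
about forty attribute tokens with a realistic frequency ordering (common
`C`/`c`/`O` down to rare bracket atoms). Strings come from a small grammar
— atom chains with balanced branches, paired ring-closure digits,
occasional bond symbols and bracket atoms — that guarantees syntactic
plausibility and tokenizer reversibility, **not** chemical validity,
mirroring the method's string-level treatment. Labels derive from a latent
linear score (planted per-token effects × occurrence counts) plus Gaussian
score noise; the activity threshold is auto-tuned to the target positive
fraction (within 2 points; heavy score ties raise an error) or given
explicitly. Noise acts on the score, never by flipping labels, so the
Bayes-optimal classifier stays analytically known.

The planted recovery benchmark (`planted_demo_config`: 2000 molecules,
noise 0, promoter `Br` at +2 per occurrence, suppressor `n` at −2,
threshold 0) uses a *two-family* design: every molecule carries at least
one occurrence of exactly one of the two markers. This makes the planted
rule exactly linearly separable in token counts and balances the classes
(~52% active). Both properties are deliberate. Two weaker designs were
measured and rejected: with independently sampled markers and a
count-threshold rule, even the exactly correlation-optimal linear model
misclassifies adjacent count levels (held-out MCC 0.90–0.97 depending on
the split); and with a strongly imbalanced corpus the IIC term of TF1
trades separation for one-sided-residual balance. A recovery benchmark
should test whether the optimizer finds the solution, not whether the
corpus geometry permits one — so the benchmark is built so the ceiling is
known to be MCC ≈ 1.

What passing the benchmark does **not** show: real corpora are noisy,
imbalanced, and not linearly separable in token counts; on the study-shape
defaults (score noise 1.0, 74% positive) the same pipeline yields validation
MCC around 0.5, which is the realistic operating regime. The benchmark
isolates optimizer correctness, not real-world accuracy.

## Reference fixtures

The package ships transcriptions of the published reference tables: the
worked-example weights, the five per-split trained weight tables with
per-subset frequencies and active flags, the per-split latent-line
coefficients, and the per-split/per-subset confusion counts. The published
count columns are headed "TN TP" but are only arithmetically consistent
with the first column being TP; the shipped CSV carries the corrected
header, and the loader docstring documents the swap. The worked-example
weights differ from the split-1 table (different optimization runs in the
source); both are kept as separate fixtures and neither is treated as
canonical. Printed weights are rounded to 4 decimals, so recomputed sums
match the printed descriptor within ±0.0002 and the printed Y within
±0.001; tests use exactly those tolerances.

## Problem sizes and limitations

Tests and the acceptance script use 2000-molecule corpora with 500-molecule
subsets, 15-epoch runs, 5 probes and up to 20 repetitions — sizes chosen so
a full run completes in about a minute while leaving the recovery margins
wide. Known limitations: the trained weights of the original study are not
reproducible (its corpus is not deposited, and a stochastic optimizer on
different data cannot match printed weights); the optimizer is a local hill
climber with no annealing, relying on the multi-scale proposals and
restarts (probes) for robustness; and the tokenizer's two-character element
list covers only `Cl`/`Br`, the halogens occurring in the reference
vocabulary.
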