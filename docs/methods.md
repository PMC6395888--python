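# Methods

## Coordinates and nomenclature

All analysis happens on the protospacer strand. The Cas9 cut is the boundary
between protospacer positions −4 and −3 (3 nt upstream of the PAM) and is
coordinate 0; bases 5′ of it are −1, −2, … and bases 3′ are +1, +2, … (there
is no base 0). A deletion is addressed by its leftmost deleted base, an
insertion by the boundary at which bases sit, giving names like `-4:2D` and
`0:1I`. Minus-strand sites are projected onto the protospacer strand before
coordinate conversion, with inserted sequences reverse-complemented.

Because aligners place indels arbitrarily inside repeats, every indel is
normalized to its leftmost reference-equivalent placement before windowing.
Left-alignment is idempotent and is verified in tests against an oracle that
enumerates all placements producing the same edited sequence.

## Indel identification

The cascade: (1) drop duplicate-flagged reads and reads with MAPQ < 38;
(2) extract one raw indel per I/D CIGAR element, rejecting records whose
CIGAR does not consume exactly the query sequence (kept in a rejects log);
(3) project to the protospacer strand and left-align; (4) keep indels whose
left-aligned start satisfies |start| ≤ 5 (window membership is start-based
by default; an any-overlap mode exists behind the `membership="overlap"`
switch for sensitivity analysis, since either reading of "within 5
nucleotides of the cleavage site" is defensible); (5) remove events whose
key also appears in the unedited control profile (probable pre-existing
somatic variants); (6) drop sites with fewer than 10 indel reads summed
across samples and replicates. Reads with no windowed indel count toward the
library size but contribute nothing to profiles. Events are keyed by
(kind, start, size, inserted sequence), so two insertions sharing a name but
inserting different bases remain distinct outcomes; names are display-only.

Sequencing-error background is estimated from experiments in which a site's
amplicon was sequenced but not targeted: the mean windowed indel count
across those off-target experiments is reported beside the on-target count.

## Site-level statistics

Precision classes cut the commonest-indel frequency at 0.25 and 0.5 with
closed upper boundaries (0.25 → imprecise, 0.5 → middle). Commonest ties
break insertions-over-deletions, then longest deletion; among tied
insertions — a case the tie rule must cover but that has no stated
convention — the larger, then lexicographically larger insertion wins, so
the choice is deterministic. Frameshift potential is size mod 3 ≠ 0; with
sizes equidistributed across residue classes the expectation is exactly 2/3.
Size spectra use 13 bins (insertions > 1, insertion 1, deletions 1–10
individually, deletions > 10) and are clustered with Ward-D2 linkage on
Euclidean distances (scipy's `ward`, equivalent to R's `hclust ward.D2`),
cutting the tree at k = 4 by default. Editing efficiency is the fraction of
reads spanning the full ±5 window that carry a valid windowed indel;
substitution-only reads stay in the denominator. The "normalized number of
distinct indels" reported per site is n_distinct divided by total indel
reads — no precise definition exists for this quantity, so the choice is
documented here and fixed.

For externally produced (time-course style) profiles, events below 1 % of a
site's indel reads are removed and sites under 10 % efficiency dropped;
frequencies are deliberately not recomputed after removal, so the filter is
single-pass.

## Homology

Deletion MH: for n = 1..min(50, deletion length), compare the 5′ n deleted
bases with the first n bases downstream of the 3′ join, and the 3′ n deleted
bases with the last n bases upstream of the 5′ join; a match on either side
counts, and the largest matching n is the MH length (a stricter
both-sides-required mode exists for sensitivity analysis). Insertion
homology compares the first inserted base with the −4 base; judging
multi-nucleotide insertions by their first base (after left alignment) is
the conservative executable rule for a feature defined on single templated
bases. Commonest insertions are only reported for sites with ≥ 5 insertion
reads to avoid low-count bias. Chance MH expectations are Monte-Carlo
estimates under i.i.d. base draws with a specified deletion-size
distribution; tests pin the k = 1 single-base case to its closed form
1 − (1 − Σp²)².

## Sequence models

Encoding: 21 variable positions (protospacer −20..−1 and the PAM N), 4
binary entries each in A,C,G,T order, plus two constant entries for the
invariant PAM GG — 86 features, invertible on the variable positions.

`PrecisionANN` is a numpy implementation of an 86–512–1 network: ReLU
hidden layer, softplus output (strictly positive; may exceed 1, so
predictions can optionally be clamped into (0, 1] for classification), MSE
loss, mini-batch SGD (batch 100, last partial batch dropped) with Nesterov
momentum 0.9 and learning rate 0.001 for 800 epochs. Weights start uniform
in [−c, c] with c = 2.24/√(0.5(n_in + n_out)) per layer — the printed
constant 2.24 is configurable and the square root resolves the ambiguous
rendering of the initialization formula — and biases start at zero (the
natural reading where bias initialization is unstated). Training is
bit-reproducible given `random_state`.

LASSO is scikit-learn coordinate descent on
(1/2n)‖Xw − y‖² + α‖w‖₁ with α = 0.002592943797404667 by default and
optional 10-fold CV selection.

Fit evaluation reports Pearson R, the R² of the OLS regression of observed
on predicted, RMSE, and a Wald test (squared slope t referred to χ²₁).
Bootstrap validation resamples 80 % of the training items with replacement,
refits, and scores RMSE on items never drawn.

Permutation importance shuffles the raw base column(s) across test sites —
preserving each column's marginal composition — re-encodes, re-predicts,
and reports the mean percent reduction in R² (± SD over 10 shuffles)
relative to the unpermuted test R², plus whether the mean Wald p exceeds
0.05. Position sets (e.g. the precision core {−2, −3, −4, −5}) shuffle each
column independently, not jointly.

## Treatment comparison

Two normalizations: counts divided by the condition's library size (total
filtered reads for the amplicon in that condition/replicate — "library
size" is given this executable definition), with events under 1 % of the
library in every condition filtered; and counts divided by the condition's
total detected indels (size factor), restricted to the 10 most frequent
untreated events. Efficiency changes are log₂ fold-changes versus the
untreated condition, per replicate and averaged. Rank trajectories anchor
rank identity in the untreated condition while the per-condition commonest
is computed separately to flag dominant-indel identity changes.

## Synthetic data: what it emulates, and what it does not

The generator models pooled-library amplicon sequencing: most reads at a
site are unedited (default edited fraction 0.3); edited reads carry one
outcome from a per-site truth distribution. Insertion mass depends on the −4
base (T 0.91, A 0.77, C 0.45, G 0.21 — the T/A/G values follow observed
target-level insertion-vs-deletion proportions, reused as per-read rates
since no per-read model is published; C is unreported and set between A and
G). Within insertions, the −4-copying base takes probability 0.82 (the
observed commonest-insertion homology rate) and the other three bases share
the rest. Deletions are drawn from cut-overlapping spans weighted by
(1 + MH)^k (default k = 2) with geometric size decay 0.75 and maximum size
15; spans whose left-aligned start falls outside the ±5 window are excluded
because the caller could never observe them. Truth outcomes are
canonicalized with the caller's own left-alignment so zero-noise round trips
are exact by construction. Noise: 1-nt spurious indels on unedited reads at
10⁻⁴/read, substitutions at 10⁻³/base. Reads are emitted pre-aligned (MAPQ
60, no duplicates) spanning cut ± 75 with small start jitter; reference
windows default to 200-nt flanks (~420 nt total), a deliberate scale choice
— real capture designs use ~2 kb windows, and `flank_len` accepts any size.

Not emulated: capture efficiency, PCR duplicates, paired-end geometry,
alignment errors, multi-indel reads, and pool infection dynamics. Passing
tests therefore demonstrate correctness of the analysis given aligned
reads, not robustness to alignment artifacts.

The planted model-recovery cohort (600 sites, 80/20 split) sets the target
frequency to four −4-dependent levels (T 0.56, A 0.42, C 0.35, G 0.21 —
the published medians where available) plus a smaller +0.04 bonus for C at
−5 and Gaussian noise (SD 0.05). The secondary −5 effect mirrors the
observed importance hierarchy (−4 dominant, −5 next) and gives joint
precision-core randomization strictly more to destroy than −4 alone; with a
−4-only signal both reductions saturate at ~100 % and become
indistinguishable.

## Problem sizes and numerical choices

Test and acceptance runs use 20–150 sites at 1,500–5,000 reads per site,
600-site model cohorts, 10,000-case MH oracle sweeps, and 200-spectrum
clustering problems — sizes chosen so the full suite completes in well
under a minute per stage while leaving statistical margins of ≥ 5 SDs on
every stochastic assertion. Outcome probabilities must sum to 1 within
1e-9; MH lengths are capped at 50; all RNG flows through
`numpy.random.default_rng` seeded explicitly.

## Known limitations

The caller consumes aligned records and inherits any upstream alignment
bias; two-phase alignment strategies used on real pooled data are out of
scope. Published cohort-level benchmark numbers (e.g. 80.1 % frameshift,
73.3 % MH deletions, test R = 0.49) derive from a specific deposited
dataset and are not desk-scale reproducible; the acceptance script instead
reports the same statistics computed on the synthetic cohort, where ground
truth is known.
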