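# Methods

## Model

`sparsemotif` represents a set of unaligned DNA strings with a two-level
convolutional sparse model. At level one, each one-hot sequence
`s_n ∈ R^{4×L}` is a non-negative combination of placements of M PFM
filters `d_m ∈ P_ℓ` (every column on the probability simplex) on the
forward strand and of their reverse complements on the other strand:

    s_n ≈ Σ_m d_m * x_mn + rc(d_m) * y_mn,   x_mn, y_mn ≥ 0.

The codes index the L−ℓ+1 valid placement offsets; the filter is stamped,
not flipped, so a code entry is an indicator of "this pattern starts
here". With rows ordered (A,C,G,T), the reverse complement of a filter is
a flip of both axes. Concatenating the code columns gives the code image
(P × 2M; forward codes in columns 1..M, reverse codes in M+1..2M).

Level two gives the code image its own sparse representation: K
non-negative image filters `F_k ∈ R^{h×2M}` with unit Frobenius norm,
placed by an α-sparse code `Z_n`, must match the scaled image
β·(X_n, Y_n). The scaling β = 100 keeps the image-level residual on a
numerically comfortable scale, and β multiplies the (X, Y) target
everywhere it appears — the Z-step, both dual updates, the F-step and the
training loss — so the two levels see one consistent constraint.

An image-code component at row p covers nucleotides [p, p+h+ℓ−2]: h code
rows, each indexing an ℓ-wide placement. All coordinates in the package
are 1-based closed intervals on the forward strand.

## Classical solver

With filters fixed, codes are solved per sequence by ADMM:

* ISTA sweeps for (X, Y): a *simultaneous* step for all filters and both
  strands against the shared residual Δ = Σ d*x + rc(d)*y − s, followed by
  the non-negative soft threshold `max(v − λη, 0)`. The image coupling
  enters as the exact gradient of ρ/2‖L_m − βx_m + Γ_m‖².
* a projected gradient step for Z (gradient of the quadratic penalty, then
  hard top-α projection; ties broken at the smallest flat index),
* a scaled dual update.

With codes fixed, the PFM filters take entropic mirror-descent steps —
multiply by `exp(−π·g)` and renormalize each column, which keeps columns
strictly inside the simplex — and the image filters take a non-negative
ISTA step followed by Frobenius normalization (an all-zero filter after
thresholding is redrawn: a zero matrix cannot be normalized).

### Step sizes

Fixed step sizes are only stable below 2/L of the relevant quadratic, and
L grows with the number of filters and their sharpness. All three gradient
steps therefore use *relative* steps: the configured η, γ, ω (defaults
0.9) are fractions of 1/L, with L estimated by a short power iteration on
the corresponding operator (code-phase Gram, image-filter Gram, code-image
Gram) at the current filters. The mirror step π (default 20; the
exact-reconstruction benchmark uses 5) is scale-free by construction. The penalty
ρ (= τ, see below) defaults to 1e−6 so that the image coupling ρβ² stays
two orders below the data-term curvature: with hard α-sparsity the image
constraint is generally infeasible, and a small penalty keeps the
(cycling, not vanishing) scaled dual from squeezing the codes.

### Initialization and restarts

PFM filters are seeded from the data: softened random length-ℓ windows
(0.7 on the observed base), taken at the peak-mass offset of a randomly
chosen sequence — on one-hot data every window has equal mass and this is
a uniform draw; on sparse real-valued data it aligns the seed with the
covered stretch. Data seeding is what lets the sparsity threshold λ
(default 2.0, between the expected background window score ℓ/4 = 2 and a
seeded-site score ≈ 5) separate repeated sites from background; a cold
Dirichlet start collapses every filter onto one blurred average. Image
filters start as |N(0,1)| entries, Frobenius-normalized. Codes and all
scaled duals start at zero, and are re-zeroed at the start of every outer
round — the same contract as the unfolded network's forward pass, and
empirically necessary: warm-started codes pin the alternation.

Every few rounds, filters that carry (almost) no code mass or that
duplicate another filter are re-seeded from the worst-reconstructed
windows of the data (the standard dead-atom treatment in dictionary
learning).

Iteration budgets are fixed counts, not tolerance-based stopping, to
mirror the finite-depth unfolded architecture. Because the hard-sparsity
constraint is infeasible for a random image bank, the ADMM primal residual
settles into a narrow band rather than decreasing monotonically, and the
total objective can rise while the data term falls; the tests assert those
honest properties.

## Unfolded network

The network parameterizes the classical iterates: 2·K1 layers interleaving
the code step and the Z/dual step, then 2·K2 layers of filter iterates.
Trainable parameters are the two filter banks, log-parameterized λ, μ and
a single ADMM penalty shared by both splits (ρ = τ; with the 30,400 filter
weights, 3 scalars and 2K1+2K2 = 18 per-layer step sizes this gives 30,421
parameters at the full-scale configuration M=50, ℓ=8, K=24, h=12, K1=6,
K2=3). Positivity of every scalar is enforced by exp reparameterization.

The forward pass runs the *same* iterate functions as the classical
solver, dispatched onto a small in-package reverse-mode autodiff tape
(numpy arrays, six convolution/correlation kernels whose adjoints are each
other); with shared step sizes the two paths are bitwise identical, which
the tests assert. The hard top-α projection is handled
straight-through-on-support: gradients flow only through kept entries.
Training minimizes the batch mean of the sequence and image reconstruction
residuals with AdaBelief (batch 6; epochs and learning rate default 10–20
and 1e−3 and are configurable); after every step the filter parameters are
projected back to their constraint sets (simplex columns; non-negative
unit-Frobenius). Sequences are batched within equal-length groups since
code-image shapes depend on L. Gradients of the full unrolled loss are
verified against central finite differences in the tests.

## From codes to motifs

For each sequence the non-zeros of Z are enumerated in q-subsets
(q = 3 by default; at α = 32 this is at most C(32,3) = 4,960 subsets per
sequence). A subset's configuration records its filter indices in spatial
order and the nucleotide distances between consecutive coverage intervals;
overlapping components give negative distances and are kept — overlapping
arrangements are exactly how gapped and embedded motifs surface when the
component span h+ℓ−1 exceeds the spacing of the planted blocks.
Configurations whose span overruns the sequence are skipped; covered
substrings containing N are dropped so counts stay integral over
{A,C,G,T}.

Substrings sharing a configuration key form a fixed-width MSA. Keys are
ranked by bucket occupancy, the top J (default 1000) become candidates,
and candidates are merged greedily by ALLR column similarity (threshold 0
bits over at least max(6, ⌈w/2⌉) aligned columns, both strands; merged
counts are summed at the best alignment offset). Only the training
records contribute to the MSAs: the held-out test fraction must stay
untouched by both fitting and motif construction, or the enrichment test
conditions on its own sequences (we observed a systematic hit depletion
when held-out records fed the buckets).

### PWM refinement

A bucket MSA is a biased, diluted sample of a motif's site population
(partially anchored subsets contribute background rows). Each merged
candidate is therefore polished on its own hit windows — scan the training
records, rebuild the count matrix from the windows above threshold
(reverse-strand hits contribute their reverse complement), repeat — with
the first scan at a 10× more permissive p-value so a weak seed can gather
the population before the strict threshold sharpens it. This is the
standard seed-polishing step of enumerative motif finders. Without it the
held-out enrichment of a recovered planted motif varies by three orders of
magnitude across model seeds; with it the recovery is stable, and
pure-background null runs remain clean (the held-out test set never enters
refinement).

## Significance

The hit threshold of each PWM is the smallest achievable discretized score
whose tail probability under the background does not exceed the scanning
p-value (default 1e−3); the tail distribution is computed exactly by
column-wise convolution of the per-column score distributions, discretized
at 1e−3 score units, and "above threshold" means ≥ throughout. Scanning
covers every placement of both strands (reverse strand via the
reverse-complement PWM on the forward text); a placement counts once even
if both strands pass, and windows containing N never hit. τ_h is the
number of hit placements in the held-out records, with N_T = Σ L_t
available positions; the control set is a per-record dinucleotide-
preserving shuffle (Euler-tour construction with fixed terminal
nucleotides, deterministic per seed), and significance is the two-sided
Fisher exact test of unit odds ratio, reported with the sample odds ratio
(τ_h/τ_m)/(c_h/c_m). Motifs are reported most-significant first; the
default significance gate is p < 1e−6. A motif's instance count is its
number of hit placements over the whole dataset.

Background is uniform 0.25 per base by default (configurable); count
matrices carry a background-distributed pseudocount of 1.0 so log-odds
stay finite on small MSAs.

## Synthetic data

The generator emulates what the model assumes: i.i.d. uniform or
first-order-Markov background carrying sparse, localized conserved sites —
one primary site per sequence at a configurable occurrence rate, a pair of
boxes joined by a fixed- or variable-length spacer, or a primary site
embedded in fixed flanks. Plants overwrite the background at a uniform
random valid offset, optionally reverse-complemented, at most one insert
per sequence so truth coordinates are unambiguous; ground truth is a
BED-like 1-based closed table with strand. It does not emulate ChIP-seq
peak shape, positional enrichment toward peak summits, or repeat-family
sequence structure, so passing recovery tests demonstrate correctness of
the machinery under the model's own assumptions, not performance on every
artefact of real peak sets.

## Problem sizes and defaults

The package's test and acceptance runs use the desk-scale profile — M=12,
K=8, h=6, α=32, β=100, q=3, 8 outer rounds of 10 ADMM iterations — on
datasets of 300 sequences × 120 nt, which a laptop CPU completes in under
a minute per run; the full-scale profile (M=50, K=24, h=12) is the same
code on bigger banks. The acceptance script's null control runs 3
background datasets; the test suite's null criterion runs 10.

## Known limitations

* The entropic mirror step tends to sharpen PFM filters toward one-hot
  columns and then freeze (the re-solved codes zero the gradient); with
  diffuse generating PFMs (e.g. Dirichlet(0.2) columns) the classical fit
  plateaus near 8% relative reconstruction error, versus ~2% for
  high-information PFMs. The recovery pipeline is insensitive to this —
  motif PWMs come from MSAs and refinement, not from the filters directly.
* Enrichment power at desk scale is bounded by the held-out set (45
  sequences): a weak or short planted signal can recover cleanly by
  Pearson yet miss a stringent significance gate.
* The threshold DP assumes a mononucleotide background; higher-order
  backgrounds enter only through the shuffled controls.
* Merging compares candidates by column ALLR only; two motifs sharing a
  partial overlap smaller than the minimum-overlap floor stay separate.
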