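# Methods

This note documents the models, parameters and design choices behind
`xerscan`, and what its validation on synthetic data does and does not
establish.

## Coordinates and sequence handling

All coordinates are 0-based half-open internally and in BED output;
human-readable reports print 1-based inclusive. Replicons are circular:
motif scans, k-mer counts and window extraction wrap the origin, and
"centering" a replicon on a site means rotating it so the site lands at
index ⌊L/2⌋ (the parity convention for odd L). N bases are accepted on
input but never match any motif and are excluded from k-mer counting —
a conservative choice for draft sequence.

## KOPS orientation bias

KOPS instances are all circular matches of `GGG[ACGT]AGGG` (forward)
and `CCCT[ACGT]CCC` (reverse), overlaps included, counted per strand
separately. After rotation to the xrs-centered frame, position lᵢ maps
to θᵢ = 2πlᵢ/L; clustering is R² = (Σcosθᵢ/N)² + (Σsinθᵢ/N)² and the
Rayleigh p-value uses the series approximation

p = e^(−Z) · [1 + (2Z−Z²)/(4N) − (24Z−132Z²+76Z³−9Z⁴)/(288N²)],  Z = N·R²,

clipped to (0, 1]. This is the approximation used by the standard
circular-statistics routines; the test suite cross-checks it against an
independently written transcription (1e-12) and against pingouin's
Rayleigh test, which implements Zar's alternative approximation — the
two agree to ~2e-3 at N=5, ~1e-4 at N=20 and ~5e-6 at N=100, and the
cross-check tolerances are set at those analytic gaps.

**Convergence rule.** With the xrs at angle π, the replicon is called
`convergent_at_xrs` when both strands reject uniformity at α (default
0.05, conventional) *and* the forward mean direction lies in (0, π)
while the reverse mean lies in (π, 2π). Replicons with < 3 motifs on
either strand are not analysed; with < 15 the verdict is
`underpowered`, since Monte-Carlo power of the Rayleigh test under weak
unimodal clustering falls below 0.5 there (measured: 0.43 at N=10,
0.61 at N=15 for a von Mises alternative with κ=1). The von Mises
alternative and κ default of 1.0 are modelling choices — the power
statement is about weak, single-mode clustering — and κ is an exposed
parameter.

## Word exceptionality

For the degenerate family GGGNAGGG (h=8) the maximal Markov model
(order h−2 = 6) estimates each instantiation's expected count from the
observed counts of its two flanking 7-mers and central 6-mer,
E[w] = N₁N₂/N₃, with asymptotic variance E[w](1−N₁/N₃)(1−N₂/N₃).
Family expectation and variance are summed over instantiations;
covariances between instantiations are neglected, which is the standard
asymptotic estimator — validation is by calibration (scores on
sequences generated from a chain the maximal model subsumes are ~N(0,1)
with ≤1% beyond |3|) rather than bit-compatibility with any external
tool. Counting is single-strand and circular; the reverse pattern is a
separate query, matching the per-strand treatment of KOPS. Verdict
thresholds are the conventional ±3.

The calibration null uses sequences generated from an order-3 chain:
any lower-order chain is a special case of the order-6 null, so the
maximal-model scores must be standard normal on them.

## Markov-recoded null ensemble

"Matching the 4-mer distribution" is implemented as an order-3 Markov
chain whose transitions are the conditional frequencies of the circular
4-mer counts — the canonical generative model whose stationary 4-mer law
matches the counts. The initial 3-mer is drawn from the 3-mer marginal.
Generation is deterministic given (background, length, seed); replicate
i of the null ensemble uses seed + i, giving reproducible independent
streams. Generated sequences are linear strings scanned circularly,
exactly like the real plasmids they stand in for. A context absent from
the model (possible only for pathological inputs, since circular
counting gives every observed 3-mer an outgoing edge) restarts from the
initial distribution.

Measured fidelity: median 4-mer total-variation distance between a
250 kb source and its generated nulls is ~0.012, and decreases with
generated length (0.06 at 10 kb).

## matS PSSM and Poisson enrichment

The PSSM is 13 columns of log2-odds,
matrix[b][j] = log2((count(b,j)+pc)/(n+4pc)/background(b)), with
pseudocount 0.5 and uniform background by default (both exposed; the
training data give no reason for a non-uniform background). The
detection threshold is the minimum training-site score, which makes
"detect all training sites" true by construction; selectivity at that
threshold is *measured* (≈2×10⁻⁶ chance hits per bp on random sequence
with the shipped fixture), never optimized. Scanning covers both
strands at every circular position; windows containing N are skipped; a
window passing on both strands (quasi-palindromic site) is one merged
hit keeping the higher-scoring strand; otherwise overlapping
above-threshold windows are all reported, since genuine matS sites do
not overlap and no suppression rule is warranted.

Enrichment: k = observed merged hit count; λ = mean hit count over
n_null = 1000 recoded sequences of the replicon's length; the reported
point probability is P(X=k) = λᵏe^(−λ)/k! (k=0, λ=0 → 1), with the
upper tail P(X≥k) as a secondary column — the point form is the primary
statistic, the tail answers "how unlikely is a count at least this
large". Null counts are Poisson to good approximation (pooled
variance/mean ≈ 1.008 over 30×1000 nulls); the tiny overdispersion
comes from occasional overlapping windows at one strong locus and is
visible only as a slightly elevated goodness-of-fit rejection rate.

## xrs and accessory-sequence detection

Half-site PWMs (11 columns each, same builder and pseudocount as the
matS PSSM) are trained on a seed alignment whose headers annotate the
XerC/central/XerD boundaries; central regions are excluded as
unconserved. The three empirical screening rules become parameters:

* **XerD stricter than XerC** — t_xerD is the minimum seed XerD score;
  t_xerC is the minimum seed XerC score relaxed by 20% of the XerC
  PWM's achievable score range.
* **Inner palindromy** — the last 5 bp of the XerC half must match the
  reverse complement of the first 5 bp of the XerD half in ≥ m
  positions, default m=3 (a soft constraint; the characterized sites in
  the seed set score 3–5).
* **Central length** ∈ {6, 7, 8}, sequence-free.

Candidates are evaluated at every position, strand and central length;
overlapping candidates are pruned greedily by combined (XerC + XerD)
score. Measured operating characteristics of the shipped defaults:
100% recovery (±1 bp) of 200 planted seed sites in random 10 kb
backgrounds, and < 0.1 false candidates per 50 kb of random sequence
(0 observed in 5 Mb).

Accessory regions are searched only on the XerC side (where functional
ASs sit), in a 200 bp window, both strands, requiring an ArgR or ArcA
PWM hit above its own min-seed threshold with offset in a 10–200 bp
band from the xrs end. The window and band are package decisions — the
precise positional bands of characterized ASs are not public data — and
are configurable. Classification is then: AS present → `AS_associated`;
else 28 bp → `AS_free_28bp` (the only length shown to recombine
FtsK-dependently); else `AS_free_other_len`.

**Fixtures.** The seed alignment contains the two functionally
characterized sites whose sequences are public (the E. coli dif site
and the corrected R27 plasmid site) plus six synthetic
pseudo-palindromic variants emulating the diversity of characterized
plasmid sites; the matS training set and the ArgR/ArcA operator sets
are likewise synthetic constructions around published consensus motifs
(palindromic GTGACRNYGTCAC for matS). All fixture filenames carry a
`_synthetic` marker and all loaders accept replacement files, so users
with curated site collections can drop them in.

## Synthetic cohorts and what validation shows

`make_plasmid` builds an i.i.d. background at the requested GC, then
*scrubs* it: every chance instance of a planted motif class (KOPS,
matS above threshold, xrs candidate) has one constrained base mutated,
for up to four passes; anything that survives — including instances
created later at plant junctions — is recorded in the truth row, not
erased. (Whole-sequence rejection sampling cannot terminate for large
replicons, where dozens of chance KOPS are expected.) Features are then
planted without overlap: the xrs drawn from the seed set (28 bp only
for the FtsK type), an ArgR consensus box 100 bp on the XerC side for
the AS type, forward/reverse KOPS placed in the xrs-centered frame with
probability `bias` of falling in their convergent half (0.5 = no
signal; cohort default 0.9), and matS sites sampled from the training
fixture so the scan is exercised across score diversity.

Default cohorts mirror a bimodal enterobacterial size survey: 25%
small (2–25 kb, AS-type xrs), 60% mid (30–150 kb, recombinase flag
only), 15% large (250–500 kb, FtsK-type xrs + KOPS bias 0.9 + ≥2 matS),
so every replicon above 250 kb carries an FtsK-type site by
construction. Recombinase presence is an input flag throughout — the
pipeline deliberately does not run protein searches.

What passing tests show: every stage recovers what was planted at
realistic sizes and signal strengths, the statistics are calibrated on
their own nulls, and the end-to-end category recovery is ≥95% on a
60-replicon cohort. What they do not show: performance on real
replicons, whose xrs diverge beyond the seed set, whose backgrounds are
not order-3, and whose accessory sequences are defined by more than one
operator box. The fixture PWMs are stand-ins; on real data they should
be replaced by curated training sets.

## Problem sizes and numerics

Validation workloads are sized for a single CPU: Rayleigh calibration
at 10,000 simulations (N=30); power at 2,000–5,000 simulations per
point; word calibration on 200 sequences of 100 kb; null fidelity at
9×250 kb; Poisson goodness-of-fit on 50 plasmids of 100 kb × 1000
recoded nulls each (χ² with tail bins pooled to expectation ≥5, one
estimated parameter, α=0.01); cohort validation at n=60. Generation and
window scoring run as numba kernels with early termination against a
suffix-max bound; p-values are clipped to (0, 1]; degenerate inputs
(all-N, too-short sequences, empty angle sets, uncalibrated matrices)
raise informative errors rather than returning defaults.
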