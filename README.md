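# xerscan

**Dimer-resolution architecture of circular bacterial replicons.**

Circular plasmids, megaplasmids and secondary chromosomes accumulate
dimers through homologous recombination between sister copies; a dimer
blocks faithful segregation unless it is resolved back to monomers by
site-specific recombination. Bacteria use two control modes for the
XerCD recombinase: small high-copy plasmids carry a Xer recombination
site (*xrs*) flanked by a ~200 bp accessory sequence (AS) bound by
ArgR/ArcA + PepA, while chromosomes — and, it turns out, the largest
secondary replicons — carry a 28 bp *xrs* activated at cell division by
the FtsK translocase, guided by KOPS motif polarity and a MatP/*matS*
organized terminus region. Mid-size plasmids instead tend to encode
their own resolution recombinase.

`xerscan` is a tested, reusable pipeline that detects these sequence
signatures on arbitrary circular replicons and classifies each replicon
into one of the three strategies. It is aimed at comparative genomicists
studying plasmid maintenance and chromid evolution.

## What it computes

* **xrs detection** — rule-based scan for the 28–30 bp pseudo-palindrome
  (11 bp XerC site + 6–8 bp central region + 11 bp XerD site) using two
  half-site PWMs, with the empirical rules as filter parameters: the
  XerD half is held to a stricter threshold, and the inner 5 bp of the
  half-sites must be at least partially palindromic.
* **Accessory sequences** — ArgR/ArcA operator PWM hits at a constrained
  offset on the XerC side; an *xrs* with an AS is classed FtsK-independent,
  a 28 bp *xrs* without one is the chromosome-like (FtsK-dependent) class.
* **KOPS orientation bias** — all instances of GGGNAGGG and its reverse
  complement CCCTNCCC are mapped, after rotating the replicon so the
  *xrs* sits at mid-sequence, to angles θᵢ = 2π·lᵢ/L. Clustering is
  summarized by the squared resultant length
  R² = ( Σcosθᵢ/N )² + ( Σsinθᵢ/N )² and tested with the Rayleigh test
  (Z = N·R², series approximation of the p-value). Forward KOPS
  clustering in the half-circle before the site and reverse KOPS in the
  half after it is called *convergent at the xrs*; replicons with < 3
  motifs are not analysed and < 15 motifs is flagged underpowered
  (Monte-Carlo power < 0.5 under weak von Mises clustering).
* **Word exceptionality** — over/under-representation of GGGNAGGG under
  the maximal Markov model (order h−2 = 6), with the standard estimator
  E[w] = N(w₁..ₕ₋₁)·N(w₂..ₕ)/N(w₂..ₕ₋₁) summed over the family and the
  normalized score thresholded at ±3.
* ***matS* detection and enrichment** — a 13-column log-odds PSSM built
  from training sites, threshold calibrated as the minimum training-site
  score (all training sites detected by construction). Observed counts k
  are compared to the mean count λ over 1000 sequences recoded from the
  replicon's own circular 4-mer composition (order-3 Markov chain); the
  null counts are Poisson to good approximation, so enrichment is
  reported as P(X=k) = λᵏe^(−λ)/k! plus the upper tail P(X≥k).
* **Synthetic cohorts** — replicons with planted, fully known
  architecture (bimodal size distribution, planted xrs/AS/KOPS-bias/matS)
  for end-to-end validation with ground truth.

The shipped training fixtures (matS sites, xrs seed alignment beyond
the characterized dif and R27 sites, ArgR/ArcA operators) are synthetic
stand-ins built around published consensus sequences; their filenames
say so, and every fixture path is replaceable.

## Worked example

```python
from xerscan import PlasmidSpec, make_plasmid, run_replicon, PipelineConfig

spec = PlasmidSpec(
    length=300_000, xrs="FtsK_type",
    n_forward_kops=40, n_reverse_kops=40, kops_orientation_bias=0.9,
    n_mats=3, seed=11, id="demo_megaplasmid",
)
replicon, truth = make_plasmid(spec)
report = run_replicon(replicon, config=PipelineConfig(n_null=1000, seed=0))
```

prints (via the snippet in the docstrings):

```
replicon        demo_megaplasmid  (300,000 bp)
xrs             115,508 (+)  28 bp  class=AS_free_28bp
KOPS            42 forward / 40 reverse
  forward mean  1.126 rad  R2=0.245  p=1.88e-05
  reverse mean  4.314 rad  R2=0.462  p=4.05e-09
  verdict       convergent_at_xrs
word GGGNAGGG   score=+3.40 (over)
matS            k=3  lambda=0.778  P(X=k)=3.61e-02
category        FtsK_chromosome_like
```

Read it as: a 28 bp AS-free xrs was found; in the frame centered on it
the forward-KOPS mean direction (1.13 rad) lies in the preceding
half-circle and the reverse mean (4.31 rad) in the following one, both
significantly clustered, so KOPS polarity converges on the site; the
KOPS word itself is over-represented (+3.4σ); three matS sites were
found where the recoded-sequence null expects 0.78 — the full
chromosome-like signature, hence `FtsK_chromosome_like`.

A command-line interface mirrors the library:

```
xerscan --out-dir out --seed 3 simulate --n 20
xerscan --out-dir out run out/cohort.fasta --flags out/flags.tsv
xerscan --out-dir out scan-kops genome.fasta     # also: scan-mats, scan-xrs, enrich
```

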