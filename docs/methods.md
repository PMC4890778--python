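# Methods

This note documents the models and procedures implemented in `mircold`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions the
implementation commits to.

## Study design being modeled

The pipeline targets a common plant sRNA-seq design: four single-replicate
libraries from two reproductive tissues (anther, ovary) under control and
cold-stress conditions, identified throughout by the library ids HCA,
HSA, HCO and HSO. Because each condition has exactly one library, no
dispersion is estimable and differential expression must rely on an exact
count test rather than a replicate-based model. A known-mature miRNA
catalog stands in for an miRBase snapshot, and a set of transcript
contigs stands in for an RNA-seq assembly of an unsequenced genome.

## Preprocessing

Reads are trimmed at the left-most occurrence of the 3′ adapter, located
by an exact prefix match: at a candidate position the read must equal
`adapter[:k]` where `k` runs to the end of the read or of the adapter,
with `k ≥ min_overlap` (default 6). Mismatch-tolerant trimming is
deliberately not the default: on synthetic data errors are explicit, and
exact trimming keeps every downstream count auditable. Reads with no
adapter, an empty insert, an N in the insert, mean Phred < 20, or an
insert outside 18–24 nt are discarded. Survivors are collapsed into
unique tags; a tag observed in any library carries an explicit count
(possibly 0) in every library, which the zero-replacement rule below
requires. The per-library survivor total ("clean reads") is the
normalization denominator.

## Contaminant removal and catalog matching

A tag is a contaminant iff it occurs as an exact substring (default; a
mismatch tolerance is configurable) of any contaminant ncRNA sequence on
either strand. Remaining tags are matched against the catalog by Hamming
distance over the best ungapped end-to-end overlap covering the full
shorter sequence, with candidate entries restricted to a length
difference ≤ 2. The best entry minimizes (mismatches, |Δlength|, name) —
the lexicographic name is the declared tie-break, making results
independent of catalog order. Tags with best distance > 2 are passed to
novel discovery. Family names collapse `<species>-miR<number><letters>[-arm]`
to `miR<number>`; unparseable names survive verbatim with a warning.

Specificity sets evaluate the tissue axis and the condition axis
independently on a family × library presence matrix (presence = assigned
count ≥ 1, configurable): a family can be simultaneously anther-only and
control-only; `shared` collects families specific on neither axis.

## Novel miRNA discovery

Unassigned tags are mapped exactly to both contig strands (tags with
more than 20 loci are discarded as repeats), ±150 nt windows are excised
(strand-oriented, clipped at contig ends), and folded to the
minimum-free-energy structure. Folding is a pluggable contract —
balanced dot-bracket of the input length, MFE ≤ 0, deterministic — with
the ViennaRNA thermodynamic engine as the default backend.

The 300+ nt excision window is then trimmed to the hairpin that actually
contains the mature: starting from the span of the mature and its
pairing partners, enclosing base pairs are added outward only while the
region remains a simple stem-loop (exactly one terminal loop, no
multiloop branching) and the interior gap to the next enclosing pair is
≤ 15 nt. Without the gap/branching guards, incidental long-range pairs
in the random flanking sequence get absorbed into the precursor and
dilute its energy density; with them, trimmed precursor lengths land in
the tens-to-150 nt range typical of plant pre-miRNAs. The trimmed
sequence is refolded and all reported statistics refer to it.

Acceptance criteria (all required):

| criterion | default | rationale |
|---|---|---|
| mature on one arm | — | no mature base inside the terminal loop |
| unpaired mature bases | ≤ 4 | duplex quality, per plant annotation conventions |
| longest bulge in mature span | ≤ 2 nt | same |
| trimmed precursor length | 45–400 nt | plausible pre-miRNA range |
| MFEI | negative, \|MFEI\| ≥ 0.85 | the strongest single discriminator of miRNA hairpins |

with AMFE = MFE/length × 100 (kcal/mol per 100 nt) and MFEI = AMFE/GC%
(GC as a percentage, e.g. 50, not 0.5). The arm is 5p when the mature
midpoint precedes its partners' midpoint, else 3p. When the same mature
passes at several loci, the locus with the largest |MFEI| is reported.

## Differential expression

Expression is TPM = count / total clean reads × 10⁶; a zero count
becomes TPM 0.01 so fold changes stay finite. Significance uses the
Audic–Claverie exact test: conditional on observing x in library 1, the
count in library 2 follows

P(y | x) = (N₂/N₁)^y (x+y)! / ( x! y! (1+N₂/N₁)^(x+y+1) ),

a negative binomial with x+1 successes and success probability
N₁/(N₁+N₂). The two-sided p doubles the smaller tail, capped at 1. The
raw conditional definition is *not* symmetric in its two libraries (the
conditioning side contributes x+1 rather than x to the posterior), so
the implementation canonicalizes: it always conditions on the library
whose (count, depth) pair sorts first, making `ac_test(x,N1,y,N2) ==
ac_test(y,N2,x,N1)` exact by construction. Tails are computed in log
space (log-gamma terms, log-sum-exp accumulation); when the upper tail
is below 10⁻⁶ its complement is re-summed directly to avoid
cancellation. Calls: up iff log₂FC > 0.5 and p < 0.05, down iff
log₂FC < −0.5 and p < 0.05, else ns — strict inequalities, boundaries
fall to ns. No multiple-testing correction is applied by default (an
optional Benjamini–Hochberg column is available); the denominator is the
library's total clean reads, not the miRNA-mapped total.

## Target prediction

The miRNA (5′→3′) is scored ungapped against each transcript window
read 3′→5′: Watson–Crick 0, G:U wobble 0.5, otherwise 1.0, penalties
doubled at miRNA positions 2–13 (1-based). Windows with expectation ≤ 3.0
(default) are reported sorted by (expectation, position). The predicted
cleavage coordinate is the transcript base paired to miRNA position 10:
`window_start + L − 10` (0-based). Gapless scanning keeps an exhaustive
brute-force oracle feasible; a bulged-site extension is out of scope by
default. Position 1 is never doubled; accessibility/UPE energetics and
conservation filters are not modeled.

## qPCR analysis

Technical replicates (≤ 3) are averaged on the Ct scale. ΔCt = Ct(gene) −
Ct(reference) within a sample; ΔΔCt subtracts the calibrator's ΔCt; RQ =
2^−ΔΔCt with amplification efficiency fixed at 2. The standard error of
ΔΔCt propagates the four cells' standard errors of the mean in
quadrature and reaches the RQ scale via the delta method (ln2 · RQ ·
SE). Direction calls use |log₂RQ| > 0.5 (strict), mirroring the
sequencing-side threshold; the reference gene is 18S rRNA for miRNAs and
actin (PduAct1) for targets. A miRNA/target pair is negatively
correlated in a sample when one is called up and the other down.

## Synthetic data generator

The generator's defaults define the standard study conditions: four
libraries of 10⁵ reads, 20 conserved + 10 novel planted miRNAs, 20 %
contaminant reads, 0.5 % per-base substitution error, 51 nt reads, 30
contigs of 2 kb, TruSeq small-RNA 3′ adapter. All randomness flows from
one seed through named substreams, so outputs are byte-identical per
seed.

* **Matures** are random 18–22 nt sequences (21 nt most common, GC
  35–65 %), mutually ≥ 3 mismatches apart and free of the adapter's 6 nt
  prefix (an internal occurrence would derail trimming — a real artifact
  of adapter-ligation protocols that the generator simply avoids).
* **Novel precursors** are arm + 6–12 nt AU-rich loop + near-reverse-
  complement arm (≤ 2 engineered mismatches), planted on a fixed
  non-overlapping grid in the contigs. Each construct is validated twice
  with the package's own hairpin module — in isolation and as the ±150 nt
  excision window in its contig context — and re-engineered until it
  passes, so planted-truth recovery is a property of the pipeline, not
  luck.
* **Contaminants** are checked exhaustively to share no ≤ 2-mismatch
  window with any planted mature on either strand.
* **Counts** are Poisson around expected means: relative abundances are
  lognormal (σ = 0.8), and stress libraries multiply responders by
  2^log₂FC. The default effect plan assigns six conserved and two novel
  responders (|log₂FC| ∈ {2, 2.5, 3}), each in exactly one tissue with
  both signs present per tissue, and the down-regulated responders'
  weights are rescaled so expected stress and control depths match —
  otherwise the depth shift leaks into every null miRNA's TPM ratio.
* **Reads** are mature (or a random 18–24 nt contaminant window) +
  adapter, truncated to 51 nt, with i.i.d. substitution errors; Phred 39
  throughout. The manifest records realized pre-error source counts.
* **Ct tables**: Ct = baseline(gene) − log₂(expression) + N(0, σ) per
  technical replicate, reference genes condition-independent; planted
  relative quantities follow the sequencing fold changes in the tolerant
  genotype (opposite in the sensitive one), targets move exactly
  opposite their miRNA, and one responder carries a landmark 8.6-fold
  ovary induction. With σ = 0 the qPCR module recovers every planted RQ
  exactly.

What the generator does **not** emulate: instrument-specific quality
profiles, indels, degradation products, ligation bias, multi-locus
conserved miRNA genes, or isomiR heterogeneity. Passing recovery tests
therefore demonstrates the pipeline's correctness on its own model of
the data, not performance on real libraries, where trimming and matching
tolerances matter more.

A side effect of planting near-complement star arms: sequencing-error
tags occasionally coincide with the star sequence and are discovered as
additional novel loci. These are genuine hairpins (the miRNA* of a
planted precursor), so the recovered novel set is a superset of the
planted one.

## Problem sizes used by the test suite

The end-to-end fixtures run at 4 × 4 000 reads (8 conserved, 5 novel);
the study-scale checks run once at the full default conditions
(4 × 10⁵ reads); differential-expression recovery uses 20 seeded
count-level replicates drawn directly from the generator's Poisson
layer, which is exactly the stochastic stage the exact test sees. Exact-
test arithmetic is verified against exact rational (integer) summation
for all counts ≤ 30 at two depth scales, and the target scan and catalog
matcher against brute-force enumeration.

## Known limitations

* Adapter trimming is exact-match; a single error in the adapter region
  discards the read. With 0.5 % error this removes ~10 % of reads and
  ~19 % of contaminant reads' recognizability — accounted for in tests,
  but real data would use mismatch-tolerant trimming.
* The hairpin trimming rule (single terminal loop, ≤ 15 nt interior gap)
  is a declared convention; other reasonable conventions shift MFEI for
  borderline candidates.
* The exact test's canonical conditioning side is a package convention;
  implementations that always condition on the first argument will
  differ in the (small) asymmetric regime.
* qPCR standard errors mix technical replication only; biological
  replicate variance is summarized downstream, not propagated into SE.
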