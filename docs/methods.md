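# Methods

This note documents the models, rules and numerical choices behind
`viraltc`, what the synthetic-data generator does and does not emulate, and
the limits of what its passing tests demonstrate.

## Coordinates and data model

All internal coordinates are 0-based half-open; GFF3/bedGraph I/O follows
each format's convention (1-based inclusive and 0-based half-open
respectively). A `CoverageExperiment` stores per-base depth as a
`(timepoints × replicates × strands × genome length)` array plus per-sample
library sizes (total mapped reads, host and virus combined; a virus-only
denominator can be supplied instead — percent-of-max profiles are invariant
to the choice). Genome topology defaults to linear; a circularly permuted
genome analysed linearly is the intended use, and no computation wraps
around the origin.

## RPKM and percent-of-max profiles

Per-base depth summed over a gene is converted to a read-count equivalent
by dividing by `read_length_proxy` (default 75 nt, a nominal read length);
RPKM = count_equiv × 10⁹ / (length × library size). The proxy cancels in
percent-of-max, so every classification result is independent of it. RPKM
is averaged across replicates *before* the percent-of-max transform.
Features whose maximal replicate-averaged RPKM is below `expression_floor`
(default 1) are reported unclassified rather than given a shape fitted to
noise; an all-zero gene gets a NaN percent profile.

## Temporal classification

The half-maximum rule (threshold 50%, early deadline 20 min, middle
deadline 60 min; all configurable) is applied to the percent-of-max
profile. Choices where the rule needed sharpening:

* A value exactly at the threshold counts as *reached* (≥, not >).
* The "-down" variant exists only for the middle group. An early gene that
  later falls below threshold stays early but is flagged
  (`drops_after_early`) in the output table.
* The middle-down drop may occur at any timepoint strictly after t½,
  including beyond the middle deadline.
* All feature kinds are classified, tRNAs included.

## TSS detection

The detector formalises manual annotation of "sudden coverage spikes" as a
windowed step-ratio test. At candidate position *p*, mean depth over the
*w* = 20 nt windows downstream and upstream (in transcription direction) is
compared at the timepoint of maximal local expression — pooling across
timepoints would dilute late transcripts with early zero-coverage samples.
A position qualifies when ratio ≥ 5, downstream mean ≥ 10, and the same
base passes in ≥ `replicate_quorum` replicates (default: all). Runs of
qualifying positions are collapsed to the argmax of the pooled ratio, ties
broken by maximal downstream mean, then leftmost (forward) / rightmost
(reverse). For a clean step this sequence of tie-breaks provably lands on
the exact first transcribed base; a plain "leftmost qualifying base" rule
would sit up to `w·(1−min_cov/step)` bases upstream, because positions with
an all-silent upstream window also have an infinite ratio. Ratios over
silence are reported as infinity and capped at 1000 in BED scores.
Thresholds are design defaults, not fitted values.

Orientation precedence is internal_sense > sense > antisense
(configurable). A TSS inside an opposite-strand gene that also sits within
250 nt of a same-strand gene start is therefore labelled sense; positions
only are used in recovery scoring, so this ambiguity affects labels, not
detection.

## Transcriptional-unit assembly

Greedy left-to-right chaining in transcription order per strand; two
consecutive classified features join iff gap ≤ 30 nt (overlaps allowed),
same temporal class, and continuous coverage, with promoter-driven splits
taking precedence: a sense TSS in the intergenic interval or an internal
promoter inside the *downstream* member starts a new unit at that TSS, and
that member joins the downstream unit flagged `truncated_first_member`
(its mRNA from that TSS lacks the 5′ end of the gene). Continuity is
evaluated pairwise over the transcribed part of the two members' span —
when the upstream member is itself 5′-truncated by an internal promoter,
the untranscribed prefix does not count against coverage — at the
timepoint maximising replicate-mean depth over that span, requiring ≥ 90%
of bases at depth ≥ 5. Because all criteria are pairwise-local, the greedy
result equals the unique coarsest partition whose blocks satisfy the
criteria; the test suite verifies this against exhaustive enumeration.
Units whose first member has no assignable TSS are kept and flagged
`no_tss`. Unexpressed (unclassified) features are excluded from the
partition. Middle and middle-down count as *different* classes — this
distinction is exactly what separates adjacent differently-regulated units
sharing one gene run.

## Host differential expression and category representation

DESeq2-style model fitting is deliberately out of scope; the caller is a
transparent stand-in whose contract (a per-gene p-value, log2 fold change
and direction) any external DE table can replace via TSV. Counts are
normalised by median-of-ratios size factors (column totals are biased when
differential expression is asymmetric), summed over replicates, and tested
with the negative-binomial conditional exact test: for replicate sums
s₁ + s₂ = n and common dispersion φ,
P(k | n) ∝ Γ(k + r₁)/k! · Γ(n − k + r₂)/(n − k)! with rᵢ = Rᵢ/φ, which is
free of the unknown mean; φ → 0 recovers the binomial conditional test.
Two-sided p-values sum all outcomes no more likely than the observed one.
φ is estimated by the ratio estimator Σ(v − m)/Σm² over genes with mean
≥ 5 (for NB counts E[v − m] = φμ², making the ratio nearly unbiased even
with 3 replicates, where a median of per-gene moment estimates is badly
biased low and would inflate the false-positive rate). Raw p < 0.05 with
no multiple-testing correction is the default convention;
Benjamini–Hochberg is available behind `adjust="bh"`. With thousands of
genes, raw α = 0.05 necessarily yields ~α·G false calls when little is
truly differential — the reason early-infection timepoints are typically
omitted from enrichment displays, which the report does automatically when
a DEG set is empty.

Category representation compares the observed share of a category among
DEGs with its genome share; underrepresentation is displayed as −1/fold so
the signed value is never inside (−1, 1) and flips sign exactly at
fold = 1. Genes missing from the category map fall into the unknown
category "S". A hypergeometric tail p-value is available but off by
default — the headline statistic is the fold, not a test.

## Synthetic-data generator

The generator plants every structure the pipeline estimates:

* **Layout.** Transcriptional units of 1–7 genes (mix chosen to give ~2.6
  genes/unit and ~42% monocistronic units), ORF lengths 150–450 nt, one
  78-nt tRNA, intra-unit gaps drawn from {−4 nt overlap, 0–20 nt},
  inter-unit gaps 80–400 nt (shrunk proportionally, floor 50 nt, if a draw
  would overflow the genome), 70% forward strand, on a 36 kb genome with
  80 ORFs. Each unit gets a functional label; antisense transcripts are
  planted only over structural/replication-labelled genes.
* **Profiles.** Piecewise class archetypes in percent-of-max space that
  satisfy the half-maximum rule by construction (early peaks at 5 min;
  middle/middle-down reach half-max at 60 min, the latter decaying to
  < 50%; late reaches half-max at 180 min). Antisense transcripts follow a
  late-type shape peaking at 180 min. Unit amplitudes are
  `mean_depth × U(0.6, 1.6)` (antisense `U(0.4, 1.4)`) with
  `mean_depth` = 50×.
* **Class mix** defaults to 7/25/14/54% early/middle/middle-down/late and
  is applied per unit (members of a unit must share a class for the
  planted partition to be self-consistent), so realised per-gene fractions
  fluctuate with unit sizes.
* **TSSs** are realised as coverage steps at transcript 5′ ends, 20–60 nt
  upstream of the first gene (20–40 nt for reverse units). One unit per
  genome is split by an internal promoter placed ¼–½ into the gene body of
  the downstream unit's first gene. Antisense TSSs (23 by default) sit
  near the 3′ end of their host gene with the asRNA confined to that gene;
  a 26-nt far-edge margin guarantees neighbouring planted steps never
  contaminate each other's detection windows.
* **Noise.** Per-base Poisson by default (negative-binomial optional,
  dispersion 0.05); host counts are negative-binomial (dispersion 0.05)
  around lognormal baseline means, with planted DEG sets per timepoint
  (nested cores across late timepoints) at 4-fold by default, including a
  37-gene category holding exactly 5 of the 118 down-regulated genes at
  120 min — the configuration of the category-representation worked
  example. Library sizes vary ±15% per sample; planted coverage amplitudes
  scale with each sample's library size so the planted percent-of-max
  profile is exact in RPKM space.
* **Ground truth** for antisense dominance is computed from the noise-free
  expected signal with the same comparison the caller uses, keeping truth
  self-consistent by construction.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: there is no background transcription (coverage is
exactly zero outside planted transcripts, so false-positive TSS rates are
measured under idealised silence), no 5′→3′ coverage decay or ragged
transcript ends, no sequence content or mappability structure, no
overlapping convergent transcription beyond the planted asRNAs, and real
TSS annotation involves judgement the step detector only approximates.
Recovery rates of 100% under Poisson noise at 50× depth reflect these
favourable conditions; on real libraries the thresholds are starting
points, not guarantees.

## Problem sizes and determinism

Default validation runs use the full-size synthetic experiment (36 kb, 81
features, 6 × 3 samples); the noisy-recovery figure aggregates 20
independent simulations, the classifier oracle uses 10,000 random profiles,
and the assembler oracle enumerates all contiguous partitions on 200
instances of ≤ 10 genes. Every stochastic component takes a single integer
seed; identical seeds reproduce outputs byte-for-byte (bedGraph floats are
serialised with `%.17g` and parsed with round-trip precision).

## Known limitations

* The step detector requires exact per-base replicate agreement
  (`±0 nt` quorum); real replicates with staggered 5′ ends would need a
  small positional tolerance.
* The internal-promoter split assumes the internal TSS is detected; a
  missed internal TSS merges the two units whenever their classes agree.
* The DE stand-in shares one dispersion across genes; strongly
  gene-specific dispersion would mis-calibrate tail p-values.
* Enrichment folds for small categories are unstable at small DEG totals
  (k = 0 yields −∞ signed representation, reported as such rather than
  clipped).
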