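# Methods

`somaclone` reconstructs, end to end and on fully synthetic data, the
workflow used to compare vegetatively propagated grapevine clones by
partial-genome pyrosequencing: simulate clone genomes and 454-style reads,
mask repeats, align in three tiers, gate calls by coverage and allele
frequency, and summarise mobile-element dynamics with S-SAP fingerprints
and LTR-form clustering.  This note records the models, the defaults and
why they are what they are, and what the synthetic results do and do not
demonstrate.

## The somatic divergence model

Clones are haploid genomes derived from one ancestral reference by three
somatic event types, drawn as independent Poisson processes per chromosome:

| event | default rate (per Mb per clone) | detail |
|---|---|---|
| SNP | 1.6 | random alternative base |
| indel | 5.1 | insertion or deletion, 1–10 bp |
| TE insertion | 35.2 | near-identical copy of a library element, random orientation, 5-bp target-site duplication |

The defaults are the somatic rates reported for Pinot noir clones.  Events
of one clone are at least 10 bp apart so each is independently resolvable.
A new somatic TE insertion copies the family's currently active form
(dominant subfamily variant with probability 0.8) at ~1% divergence — a
fresh copy has had no time to drift.  The ledger of applied events is the
ground truth for every recall/precision measurement; re-applying a ledger
to the ancestor reproduces the clone byte for byte.

Haploidy is a deliberate simplification: the comparison semantics are
allele *sets* per clone, and a haploid truth makes recall/precision
unambiguous.  A diploid overlay would add heterozygous sites whose allele
frequencies straddle the 0.3 gate; nothing in the caller assumes ploidy.

## The reference landscape

The ancestral genome is random sequence at 33% GC with, per chromosome:

* **gene models** totalling ~6.9% exonic bases (2–6 exons of 150–400 bp),
  placed outside repeats;
* **TE copies** up to the requested repeat fraction, drawn by family
  *abundance* (a LINE-dominated landscape, as in real grape), plus one
  dense centromere-like block per chromosome;
* **segmental duplications** over ~8% of bases (4–12 kb blocks at 2%
  divergence) — the ancient-polyploidy paralogs that make a material share
  of reads unplaceable in the real genome.

Chromosome lengths taper linearly to 60% of the longest so that aligned
bases can be regressed on chromosome length.

Each TE family carries a base LTR, major subfamily variants with Table-4
style copy weights, and a diffuse "minor" pool.  The divergence geometry is
chosen once for separability and never revisited:

* major variants sit 15% from the base LTR (pairwise ~26%), so the 75%
  harvest floor still detects them while the 90% clustering bar keeps them
  apart;
* copies of a non-recent variant carry 1.5% private divergence each —
  close enough (~3% pairwise) that a hash aligner cannot resolve their
  reads to a single copy, far enough that they never masquerade as a
  recently amplified cohort (pairwise identity stays below the 0.99
  activity bar);
* minor-pool copies carry 17–22% private divergence: recognisably
  repetitive to a RepeatMasker-grade screen, unclusterable at 90%;
* young cohorts (LINE and DNA-transposon families) are near-identical
  copies at 0.8% divergence — the high-copy mass that an aligner must
  reject as repetitive;
* a copy's two LTR ends accumulate their post-insertion substitutions
  independently, as in real elements — otherwise every copy contributes a
  pair of trivially identical LTRs and dormant families acquire spurious
  "recent activity" cliques.

## The 454 read model

Read lengths are Normal(355, 60) truncated to [60, 700]; per-base quality
decays linearly from Q36 to Q24 (run mean ≈ Q30); substitution errors occur
at the per-base Phred rate; homopolymer runs ≥ 3 bp gain or lose one base
with probability 0.02 per run; 0.58% of reads are exact emulsion-PCR
duplicates; 3.8% organelle and 0.013% foreign-organism reads are spiked.
The quality-decay endpoints and homopolymer rate are model constants chosen
to land the run-level summary statistics (mean quality ≈ 30) of a real
GS-FLX run; everything is a `ReadProfile` field.  `ReadProfile.error_free()`
turns all error processes off — the configuration used for ground-truth
recovery experiments, where the question is whether the *pipeline* loses or
invents events, not whether base errors do.

Assembly-derived samples are modelled by `shear_assembly`: 1000-bp
non-overlapping tiles at maximum quality, the standard treatment for
feeding a finished assembly through a read pipeline.

## Repeat masking

Reads are screened against the library (base LTRs, variant LTRs, internal
regions) by 11-mer seeding and gapless maximal-scoring-segment extension
along each candidate diagonal, with the mismatch penalty set so a stretch
at exactly the identity floor scores zero.  The maximal-score core is then
widened while the whole stretch keeps the floor, but only through blocks
that are themselves diverged homology (≥ 12 bp at ≥ 65% identity) — random
flanking sequence (25% expected identity) cannot extend a hit.  Defaults:
≥ 50 bp at ≥ 75% identity, i.e. RepeatMasker-grade sensitivity, which is
what recognises the 17–22%-diverged old copies; the floor is a parameter.

Composition classes over the masked/unmasked balance (evaluated in order):
`TE_EVIDENCE` (≥ 150 unmasked and ≥ 100 masked bases), `REPEAT_READ`
(≥ 90% masked), `MOSTLY_UNIQUE` (< 50 masked), else `OTHER`.

## Tiered alignment

A dense 13-mer index over the reference is queried with read-side seeds
every 24 bp on both strands; diagonal clusters are verified with banded
edit-distance alignment (edlib).  Candidate clusters closer than half a
read length on one strand are one locus.  The per-mode rules:

* **STRICT (step 1)** — accept the best locus at ≥ 95% identity if the
  runner-up trails by more than 7% of the read length in score;
* **MASKED (step 2)** — repeat-mask the read; if the longest unmasked run
  is ≥ 150 bp, align it under STRICT rules and record the reference
  coordinate where the masked segment abuts the flank (the junction used
  for TE-insertion calling, tagged with the masked segment's best family);
* **RELAXED (step 3)** — unit-cost (minimum-gap-penalty) alignment
  accepted at ≥ 90% identity at a unique locus.

Three numerical details matter downstream.  First, a read is repetitive —
rejected as multi-locus without further alignment — when at least half its
seeds exceed the per-seed hit cap (it lives inside a high-copy cohort) or
when more than 24 distinct loci collect multiple seed votes.  This is not
just a speed device: inside a near-identical cohort the shared k-mers are
capped away and only the source copy's private-mutation seeds survive, so
without the gate such reads "uniquely" mis-place at full mapping quality
and deposit coordinated false mismatches.  Second, a best candidate must
itself be a plausible placement (estimated identity within 2 points of the
mode floor) before the ambiguity test runs — otherwise two equally bad
chance hits masquerade as a paralog.  Third, edlib's unit-cost optimum
scatters a multi-base indel across co-optimal fragments; records with two
or more gap operations are realigned with affine gap costs so an event is
one contiguous, left-normalisable operation.

The 7%-of-read-length uniqueness margin reflects what a hash-based aligner
resolves: copies ~3% apart pairwise are ambiguous, copies ≥ 5% apart are
not.  Mapping quality is phred-like on a 0–90 scale,
`min(90, round(90·(best−second)/read_length))`, 90 when nothing competes.

Unaligned reads are classified in priority order LOW_QUALITY (< 100 bp or
mean < Q20) → REPEAT (≥ 90% masked) → PARALOG (multi-locus) → CYTOPLASMIC →
CONTAMINANT (≥ 90% identity to the respective references, both strands) →
UNKNOWN.  The classes partition the read set exactly.

## Coverage gating and calling

Depth counts *independent* reads: exact duplicates (same sequence, same
placement) collapse to one.  The calling pileup is built from reads with
mapping quality above 60, so the ≥ 6× depth gate and the > 60 quality gate
describe the same territory — without this, the interior of near-identical
repeat copies looks callable but can never yield a passing call.  The
callable territory of a pair is the intersection of both clones' ≥ 6×
regions.

* **SNPs** — a clone's allele set is the alleles at within-clone frequency
  ≥ 0.3 (reference allele included); a site is a SNP when the sets differ,
  both depths are ≥ 6 and supporting evidence exceeds quality 60.
* **Indels** — same gates, but evidence counts only from step-1/2 reads
  with the event ≥ 20 bp from both alignment ends; events are
  left-normalised; calls in a reference homopolymer ≥ 6 bp are flagged
  low-confidence (the pyrosequencing artefact class) but kept.
* **TE insertions** — step-2 junction evidence clusters within ±15 bp; a
  cluster is an insertion when it accounts for ≥ 30% of the carrier's
  site-spanning reads, the other clone covers the site *continuously* at
  ≥ 6× — reads whose alignments pass through the site interior, not reads
  that merely end there — with no junction evidence of its own, and
  quality exceeds 60.  Junctions present in both clones, and sites where
  both clones' alignments break, are ancestral element boundaries, not
  polymorphisms.  An insertion landing inside or hard against an existing
  repeat copy localises at the copy's edge at best — a shared limitation
  with any flank-anchored method.

Substitution and indel evidence additionally requires the supporting read
to be otherwise clean: substitution identity ≥ 0.99 outside the event
itself.  This one rule is the automated stand-in for the original study's
read-by-read visual curation; without it, junction-straddling reads and
repeat reads mis-placed onto a lone related copy deposit *coordinated*
false mismatches that pass every frequency gate (measured: 162 false SNPs
on a 1-Mb clean-read pair before the rule, 0 after).

Because coverage dips by construction at an insertion junction, the TE
depth/shared gates are evaluated within the ±15 bp cluster radius rather
than at a single base; indel gates use the two bases flanking the
left-normalised coordinate.

Rates are calls per Mb of shared territory.  With both clones mutated at
rate r, the pairwise density is 2r; the per-lineage estimate is half the
pairwise rate (equal branch lengths — exact here by construction).

## S-SAP and trees

In-silico S-SAP takes a primer from the 3' end of a family's base LTR
(its most conserved stretch), finds every genomic occurrence on either
strand, and extends to the nearest downstream enzyme motif; fragment
lengths within 50–1000 bp are bands, binned at 4 bp (±2 bp gel
resolution).  The default motif is TTAA (MseI-like): S-SAP/AFLP chemistry
cuts with a frequent four-cutter precisely because a six-cutter leaves
most loci without a site inside the resolvable range (with GAATTC, ~78% of
junctions yield no band and fingerprints stop distinguishing clones).  The
motif, primer and size range are arguments.

Band presence/absence matrices give Nei–Li distances
(D = 1 − 2·n_xy/(n_x+n_y)); topology comes from neighbor joining
(scikit-bio's implementation, negative branch lengths clamped at zero);
support values are nonparametric bootstrap over band columns, counting
canonical bipartitions.  The same machinery builds conserved-LTR-region
trees from p-distances with column bootstrap.

## LTR-form dynamics

Reads matching a family's base LTR at ≥ 75% identity over ≥ 100 aligned
columns are projected into LTR coordinates (a star alignment with the base
LTR as the frame).  Greedy clustering seeds with the longest unassigned
segment; members join at ≥ 90% identity to the running consensus over
≥ 100 shared columns, with a one-sided small-sample guard of 0.8 binomial
standard errors so a short overlap cannot clear the bar on sampling noise
(unassigned segments are re-tested after every consensus update, which
otherwise gives diverged copies many chances to leak in); the consensus is
per-column majority (ties broken alphabetically).  Clusters of ≥ 10
members are major forms, the remainder pool as minor.  The population simulations run at ~0.75× coverage so each
locus contributes roughly one read and the "10 reads" threshold counts
loci, as it did at the original sequencing depth; counting is read-level
throughout and stated as such.

The recent-activity signature is a clique of ≥ 5 segments mutually ≥ 99%
identical over the conserved region (default: final 200 bp of the LTR) —
copies that have had no time to diverge.  The clique bound is greedy
(exact cliques are unnecessary: active cohorts are near-complete
subgraphs, dormant families have ~6% edge density).

## Standard study conditions

The reproduction script and the acceptance tests run fixed conditions
(chosen once as a desk-scale version of the original design, with problem
sizes that keep the full run within minutes on one core):

* **clone pair study** — 10 Mb over four tapering chromosomes, 30% repeat,
  8% duplications, two clones at the default rates, clean reads at 12×
  (≥ 6× in both clones over > 50% of the genome), correlations over 50-kb
  windows (≈ 200 windows; the window is configurable and defaults to
  100 kb in the library);
* **LTR populations** — 500 copies per family at the family's form
  weights, deterministic per-variant allocation;
* **fingerprint panel** — eight clones of a 0.4-Mb ancestor, banded with
  the four focal families;
* **rate calibration** — 20 replicate clone pairs of a 0.39-Mb ancestor
  at 10×.

## What passing tests show — and what they do not

The simulations exercise placement ambiguity, repeat masking, junction
evidence, coverage gating and frequency gating under a known truth.  They
do not model diploid heterozygosity, chimeric (periclinal) tissue
mixtures, PCR/base-call error correlation, reference mis-assembly, or
nested/truncated TE structures; recall and precision measured here are
therefore upper bounds for real data, and the headline claim they support
is that the *pipeline logic* neither loses nor invents events under its
own gates.  Real 454 error processes are available in the read model
(`ReadProfile()` defaults) but ground-truth scoring runs clean reads so
that failures are attributable to the method, not to base errors.

## Known limitations

* The masker's seed-and-extend is substitution-oriented; a copy diverged
  mainly by indels would fragment its hits (real TE decay is mostly
  substitutions and truncations, which it handles).
* TE insertions into existing repeat copies are largely invisible (no
  unique flank within a read length) — also true of the original method.
* The NJ bootstrap resamples band columns, the standard reading of
  permutation support for dominant markers; it is not a Bayesian or
  likelihood support.
* `to_ancestor` coordinate projection is nearest-left-anchor inside
  inserted material; truth matching uses tolerance windows (±12 bp indel,
  ±25 bp TE) to absorb representation ambiguity, not caller error.
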