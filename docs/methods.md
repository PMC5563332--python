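# Methods

This note documents the models, conventions, and design choices behind
`ptcrescue`, in the spirit of a methods appendix: what is computed, under
what assumptions, and what the synthetic-data tests do and do not show.

## Gene models and translation

A gene is represented as a single transcript: an ordered set of disjoint
genomic exon intervals on one reference sequence, a strand, and a CDS span in
transcript coordinates.  All internal coordinates are 0-based half-open;
1-based conventions (HGVS, SAM, BED display) are converted only at I/O
boundaries, so off-by-one arithmetic lives in exactly one place.  Multi-
transcript models, UTR-intron structures, and recoding (selenocysteine,
read-through) are out of scope.

Model validation at construction requires an ATG start, a terminal stop, no
internal in-frame stop, and no N bases in the CDS (translation must be
unambiguous).  Stop codons are the standard nuclear set {TAA, TAG, TGA}.

A *mature transcript* is built by applying splice events first (exon
removal, cryptic-site boundary shifts, retained-intron insertion) and then
the variant's sequence edit, provided the variant's position survived the
events (otherwise the transcript is flagged `variant_removed` — the
mutation was spliced out).  Intronic variants never edit the mature
sequence; their effect is carried by the splice events they cause.

**Premature stop definition.** Translation proceeds in-frame from the CDS
start; a stop is premature iff it begins strictly upstream of where the
canonical terminal codon sits in the edited sequence.  A stop at the
canonical position is canonical; a missing stop is flagged `nonstop`.  No
50-nt-rule NMD prediction is applied anywhere: the pipeline *measures* decay
from read counts rather than predicting it.

## HGVS parsing and the mutation taxonomy

The parser covers the coding-HGVS subset that PTC analyses need:
substitutions (with intronic offsets, accepting both ASCII and typographic
minus signs), deletions, duplications, and insertions.  Inputs are assumed
3'-normalized per HGVS convention; the parser does not re-normalize
(re-normalization would require the real transcript sequence).

Grammar classification follows field convention: intronic offsets ±1/±2 are
canonical splice donor/acceptor; |offset| ≥ 3 is splice region; exonic
indels are frameshift or in-frame by span modulo 3; exonic SNVs are
undetermined until either a protein label (`*` → nonsense, `fs` →
frameshift) or a reference sequence resolves them.  Protein labels are taken
as authoritative for *category* only — protein-level positions of
frameshifts depend on downstream sequence and are recomputed only when a
sequence is available.  Frameshift, nonsense, and canonical-splice
categories are PTC-class; splice-region and in-frame indels are not.

The deleterious-missense filter keeps records with MAF < 0.01% (fraction
1e-4), depth ≥ 20, a less-than-threefold reference/alternate count
difference, and Phred-scaled CADD strictly above 20.  All comparisons are
strict except depth; a putative heterozygote with a zero allele count is
excluded and flagged rather than silently dropped.

## Read classification

Input is a set of spliced alignments (SAM with N-gap CIGARs; secondary and
supplementary/chimeric records are dropped and counted).  Each alignment is
decomposed into blocks and splice gaps; deletions shorter than
`gap_threshold` (default 30 nt) stay inside a block, longer ones are treated
as junctions.  Fixture introns are ≥ 60 nt, so the two regimes cannot
collide.

**Splice-event detection.** A junction matching a canonical junction within
±`tolerance` (default 3 nt, absorbing aligner wobble at splice sites) is
canonical.  A junction joining exon *k−1*'s donor to exon *k+1*'s acceptor
is an exon skip; one canonical end with the other ≥ tolerance away is a
cryptic donor/acceptor with its signed length change; a block running ≥
tolerance past an exon–intron boundary without a junction explaining the
crossing is intron retention.  Junctions matching nothing mark the read
unresolvable (classed OTHER).  Two consequences of the tolerance are worth
stating: cryptic shifts smaller than the tolerance are indistinguishable
from wobble and are canonicalized (analyses targeting a known −2 cryptic
donor should pass `tolerance=1`; with the exact truth alignments the
simulator emits, wobble is zero and this is safe), and a partial intron
retention that later splices at a deeper position is structurally identical
to a cryptic donor extension and is reported as such — the implied
transcript, and therefore the classification, is the same.

**Allele calling.**  For SNVs, the vote is the base aligned to the variant
position (reference base → WT, alternate → MUT, anything else → abstain),
gated by requiring ≥ `min_agree` (default 0.7) of the ±`window` (default
12 nt) flanking bases to match the reference, which discards misaligned or
garbage windows.  For indel variants the read's window sequence is compared
against the wild-type and mutant local haplotypes by edit distance, taking
the nearer and abstaining on ties.  The edit-distance vote was chosen over a
net inserted-minus-deleted length vote because the latter collapses for
1-nt indels under a 5%/3%/5% substitution/insertion/deletion error profile
(error indels swamp a ±1 signal), while the most frequent real PTC
mutations in this setting are exactly 1-nt indels.  A read whose events
removed the variant's region is REMOVED.  For canonical-splice variants
no exonic base can witness the allele; assignment is by the junction
outcome at the mutated splice site alone (aberrant → mutant,
canonical → wild-type), flagged `junction_inferred` in the output.

**Transcript class.**  The read's implied mature transcript (allele +
events) is built and translated: WT = wild-type allele, no premature stop,
no deleterious event; PTC = premature stop attributable to the variant
(mutant allele, or a canonical-splice variant with an aberrant junction at
the mutated site); RESCUE = mutant or mutation-excised allele with an open
frame to the canonical stop; OTHER = everything else (unassigned alleles,
deleterious events on the wild-type allele, unresolvable junctions,
nonstop transcripts), with a reason code.  Reads carrying the mutant allele
*and* an unrelated deleterious splice event are PTC — the premature stop
attributable to the variant takes precedence.

**Quantification.**  `ptc_expression_fraction = n_PTC / (n_PTC + n_WT)`;
RESCUE and OTHER reads are excluded from this denominator.  The rescue
fraction is reported as `n_RESCUE / (n_PTC + n_WT + n_RESCUE)`; since the
field has no single convention for this denominator, raw counts are always
emitted so any convention can be recomputed.  Abstaining (UNASSIGNED) reads
never enter any denominator — dropping them is error-rate-symmetric,
whereas force-calling them would import an error-rate-dependent bias.
Event frequencies are computed allele-agnostically over all reads spanning
the event's genomic extent.

## The generative simulator

The simulator emulates amplicon cDNA sequencing of a heterozygous carrier.
Per molecule: allele ~ Bernoulli(1 − `wt_allele_share`) for mutant
(default share 0.5, balanced allelic expression); mutant molecules use
rescue isoform *k* with probability r_k, otherwise the PTC isoform, which
survives NMD with probability 1 − e; wild-type molecules always survive;
survivors are sampled uniformly to `n_reads`.  The expected PTC fraction is

    f = (1 − R)(1 − e)·m / ((1 − R)(1 − e)·m + w),   R = Σ r_k, m = 1 − w,

recorded in the output metadata; `nmd_efficiency_for_fraction` inverts it
(at w = 0.5, R = 0: e = 1 − f/(1−f), e.g. f = 0.41 → e ≈ 0.305).  NMD is a
single per-transcript survival Bernoulli, not a mechanistic 50-nt-rule
model: the simulator's job is to produce known fractions, not to predict
biology.  Rescue isoforms are verified at template-build time (by
translation) to carry no premature stop, and the PTC isoform to carry one,
so truth labels cannot drift from the sequence model.  Rescue-type splicing
on the wild-type allele (observed in real data unrelated to any PTC) is
generable via `wt_rescue_proportion`, default 0.

Reads are full-length amplicon copies with per-base substitution /
insertion / deletion errors (defaults 0.05 / 0.03 / 0.05 — an
order-of-magnitude match to early nanopore base-calling error; all
configurable).  Because error positions are known, the emitted SAM carries
the *exact* alignment of each errorful read (planted errors appear as
M/I/D operations, splice gaps as N), so the test suite never needs an
external spliced aligner.  Identical configurations are bit-reproducible.
Default toy-locus exon sizes (30/168/45/255/33 nt) echo the commonly
skipped coding-exon sizes of the gene this package models; a default
variant of the generator with 44/256-nt exons provides out-of-frame
skipping fixtures.  Synthetic introns start GT and end AG and carry a
planted early stop in the frame a retained intron would be read in —
real retained introns almost always truncate the frame within a few
codons, and without the plant a ~90-nt random intron has a ~20% chance of
containing no stop at all, which would make "retention is deleterious"
fixtures depend on the seed.

What the simulator does *not* emulate: homopolymer-structured nanopore
error, PCR chimeras (the amplicon design this models avoids them), barcode
demultiplexing, 5'/3' read truncation, or multi-amplicon abundance
normalization.  Passing tests therefore demonstrate correctness of the
classification logic under realistic *random* error, not robustness to
systematic basecaller artifacts.

**Known estimator floor.**  With a single-nucleotide variant, a
substitution error at the variant site converts a wild-type read into a
perfect mutant vote with probability p_sub/3 (≈1.7% at default error).
At the complete-degradation pole (e = 1) the estimated PTC fraction is
therefore ≈1.5–2% rather than exactly 0; the effect is symmetric and
negligible away from the poles.  This is the information-theoretic floor of
single-base assignment at that error rate, not a removable bias.

## Cohort statistics

Carrier-level (dominant) 2×2 tables per population stratum are the unit of
association, matching how carriers are reported in this literature.  The
CMH summary odds ratio, its Robins–Breslow–Greenland 95% CI, and the CMH
chi-square (hypergeometric moments, no continuity correction — the
convention of the standard genetics toolchains) are computed via
`statsmodels`' `StratifiedTable`; the test suite checks the estimate
against a hand-computed Σ(a_i d_i/n_i)/Σ(b_i c_i/n_i) oracle.  Strata with
an empty margin carry no information and are dropped with a count rather
than raising (small national strata with zero controls occur in practice).
Single-table odds ratios use ad/bc with a Woolf log-scale CI and
Haldane–Anscombe +0.5 correction (flagged) when any cell is zero.
Variance-component rare-variant tests (SKAT-O and relatives) are
deliberately not reimplemented; the rare-variant test offered is the
carrier-burden CMH.

Hardy–Weinberg QC uses the exact conditional test by full enumeration of
heterozygote counts given the allele counts (log-factorial arithmetic; the
QC gate in this literature is p > 0.001).  Pairwise LD accepts phased
haplotype counts or an unphased 3×3 joint genotype table; in the unphased
case haplotype frequencies come from the standard EM split of double
heterozygotes (convergence when the largest frequency change is < 1e-10,
≤ 1000 iterations), and D, r², and D′ = |D|/D_max follow the usual
definitions.  The multiple-testing threshold uses the Li–Ji
spectral-decomposition effective number of tests,
M_eff = Σ[I(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)] over eigenvalues of the
absolute-value correlation matrix, threshold = α/M_eff (the Li–Ji variant
was chosen over Nyholt's as the modern default).  Display rounding is
half-up to two decimals; all internal computation is full precision.

## Numerical and testing choices

Problem sizes in the test suite — 2000-read simulations for parameter
recovery across the observed fraction range (5–41%), 5000 reads for the
fraction poles, 20000 reads for the law-of-large-numbers check (error-free,
isolating generative sampling noise), 100 replicates for CMH CI coverage —
were chosen so each check's binomial noise is several times smaller than
the tolerance it asserts.  All randomness flows through
`numpy.random.default_rng` seeds; hypothesis-based property tests are
derandomized.  Independent oracles (Biopython translation for stop
scanning and SNV consequences, exact rational-arithmetic enumeration for
HWE) deliberately avoid the implementation's code paths.

## Limitations

* Single-transcript models only; exon numbering is fixture-local, and no
  real gene model ships with the package (the real transcript's
  exon-to-genome mapping is not packaged).
* Observed minor-allele frequencies in the packaged variant table are
  consumed as printed, never recomputed: their denominators (per-variant
  genotyped subsets) are not public.
* The read simulator is plus-strand; minus-strand support is exercised at
  the gene-model layer (coordinates, mature sequences) but not in read
  generation.
* Real-cohort quantities that require patient-level or unpublished
  per-stratum data (the published stratified odds ratio, per-mutation
  expression fractions, LD on real genotypes) are covered by method-level
  properties on synthetic data, not reproduced numerically.
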