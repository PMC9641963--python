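# Methods

This note documents the models and procedures implemented in `hapchar`, the
parameter defaults and why they were chosen, the numerical decisions, and the
limits of what the synthetic-data tests demonstrate.

## Synthetic data and planted truth

All analyses are exercised on generated data with machine-readable ground
truth (`hapchar.synthetic.TruthSet`). Design choices:

- **Base composition is uniform** over A/C/G/T. None of the implemented
  statistics depend on composition, so modelling it would add noise without
  adding coverage.
- **Duplication identity is realized by substitutions only.** The identity
  fraction of a planted pair then has exactly the matched-base semantics of a
  self-alignment table, with no ambiguity from indel placement. Planted
  events are kept mutually disjoint so the recorded truth (copy locations,
  genes-per-duplication) stays exact; real duplication histories nest and
  overlap, which the recovery tests therefore do not probe.
- **Depth tracks** are negative binomial per 100 bp bin with
  variance = dispersion × mean (Poisson when dispersion = 1). Inside a
  collapsed interval the mean scales by true/assembled copies. Defaults
  (mean 60, dispersion 3) match deep long-read coverage with moderate
  overdispersion. No GC bias, mappability structure, or edge effects are
  simulated.
- **Trio tables** contain one row per genome position (base-pair-resolution
  calling), annotation values that pass every filter by default (QD 20, FS 1,
  MQ 60, rank sums 0, SOR 1, GQ 99, DP ~ Poisson around the per-individual
  mean), and explicitly injected violations. Read-name overlap between call
  sets is abstracted to a shared integer evidence token carried by both
  mapping tables; this preserves the intersection logic exactly while
  avoiding read-level simulation. Per-individual depth means default to
  56/78/84 (offspring/father/mother), the depths of the sequenced trio this
  pipeline is modelled on.
- **Second haplotypes** are derived by planting SNVs, small indels (1–10 bp)
  and SVs (insertion, deletion, inversion, translocation, tandem CNV) at
  reserved, non-overlapping positions. Truth coordinates refer to the
  reference haplotype.

Determinism: every generator is a pure function of its parameters and a
single integer seed (numpy `default_rng`).

## Segmental duplications

The post-processing chain is: repeat-mask filter → interval graph → high-copy
filter → summaries.

- A pair is removed when **either copy is more than 90% repeat-masked**
  (strictly greater; masked fraction is computed against the union of repeat
  intervals, not per family).
- The graph joins the two intervals of each alignment and **any two
  intervals overlapping by ≥ 1 bp** on one scaffold. "Unique intervals" are
  distinct by exact coordinates; overlapping-but-unequal intervals count
  separately and are linked only by overlap edges. This is the most literal
  reading of the construction; merging near-identical intervals before
  counting would lower copy numbers and is deliberately not done.
- Components with more than 20 unique intervals are removed (high-copy,
  mobile-element-like families).
- The age conversion `divergence_to_age` uses a configurable calibration,
  default 0.5% divergence per 100 ky. The default is a published rule of
  thumb rather than a derived constant; callers working in another clade
  should set `SDConfig.divergence_per_100ky` themselves.

The bundled `naive_self_align` is desk-scale plumbing (exact 20-mer
anchoring on merged diagonals, refinement by full edit-distance alignment,
identity = matched bases / aligned columns). It refuses genomes above 10 Mb,
where an external self-aligner's pair table should be supplied instead. It
reports forward-strand duplications only.

## Duplicated genes

Eligibility follows the multi-exon rule: at least one intron and a gene body
of at least 1 kb. One isoform represents each gene; the longest spliced
sequence is used (ties by transcript id) — the choice of representative is
not prescribed anywhere authoritative, and the longest isoform maximizes
mappable sequence. Placements need identity ≥ 0.90 over aligned columns of
the spliced sequence and query coverage ≥ 0.90. When passing placements of
two genes overlap by ≥ 1 bp, the first gene in input order keeps the
placement ("first mapped wins"); input order is used because mapping order is
what a streaming pipeline would see.

Mode classification: tandem iff all copies are on one scaffold and no
consecutive gap exceeds 500 kb (configurable). The default separates
adjacent arrays from copies megabases apart; there is no published cutoff,
and borderline cases move between the classes as the knob moves.

A gene is flagged collapsed when ≥ 50% of its body overlaps depth segments
decoded above copy number 2; implied missing copies = decoded − assembled.

The desk-scale transcript mapper projects every exact 20-mer hit of the
spliced sequence back to an implied gene-body start using the exon layout,
clusters implied starts (tolerance 100 bp), and aligns each exon within the
candidate locus by infix edit distance. This assumes gene copies preserve
exon layout up to small indels — true of the generator and approximately
true of recent duplications, but not of retrogenes (intronless copies),
which the mapper will report at low coverage rather than as copies.

## Collapsed-duplication HMM

States are copy numbers 0…12. Emissions at state *c* are negative binomial
with mean (c/2)·μ₂ and variance max((c/2)·σ₂², 1.01·mean); the variance
floor keeps the distribution overdispersed and the size parameter finite,
and when σ₂² ≤ μ₂ the model falls back to Poisson emissions throughout.
State 0 uses mean 0.02·μ₂ instead of zero so log-likelihoods stay finite.

Transitions are sticky: stay-probability 1 − ε with ε = 10⁻⁴ split uniformly
over the other states. With 100 bp bins, ε = 10⁻⁴ means a state switch needs
roughly 9–10 nats of cumulative emission evidence, i.e. a few bins of
clearly shifted depth — appropriate for multi-kilobase duplications and
robust to single-bin noise.

Baseline estimation: the diploid peak is located as the mode of the trimmed
(1%–99%), lightly smoothed unit-bin histogram (ties to the lower depth); μ₂
is then the mean of bins within [0.5, 1.5] × mode. The raw histogram mode of
an overdispersed count distribution sits measurably below the mean (the
distribution is right-skewed), so the windowed mean removes that bias while
the mode-centred window still excludes other copy-number states; σ₂² is the
variance of bins within μ₂ ± 3√μ₂. On simulated tracks (mean 60,
dispersion 3, 10k bins) the estimator lands within ±2 of the true mean with
or without 10% copy-4 contamination.

Decoding is by Viterbi (not posterior marginals) so that each reported
segment belongs to one globally consistent path; segments shorter than 5
bins are absorbed into whichever neighbouring state explains their bins
better. Missing bases sum, over segments decoded above the assembled copy
number, segment length × (decoded − assembled)/assembled, with assembled
copies 2 for a combined-diploid track and 1 for a haploid one.

The BUSCO depth screen takes the mean depth as given and does not round the
threshold; a copy exactly at threshold passes (≥). Genes whose copies
overlap no depth bins are excluded from the summary denominator and logged.

## Trio mutation rate

Site filters (fail if any holds): QD < 2, FS > 20, MQ < 40,
MQRankSum outside [−2, 4], ReadPosRankSum outside [−3, 3], SOR > 3.
Missing annotations pass their sub-filter (logged); penalizing missingness
would silently deflate callability. Individual filters: DP within
[0.5, 2] × the individual's mean depth, GQ ≥ 60; for candidacy, parents must
show zero alternate-allele reads (AD = 0) and the offspring's allelic
balance must lie in [0.3, 0.7]. The AB filter applies to the offspring only;
parents are screened through AD.

Candidates must satisfy the dual-mapping configuration (0/0 parents with a
0/1 child on the mapping lacking the allele; 1/1 parents with a 0/1 child on
the mapping carrying it), pass the site filters **on both mappings**, and
share an evidence token. Filtering on both mappings is the stricter of the
two defensible readings and is what the implementation applies.

Callability counts sites where all three individuals pass DP and GQ and the
parents pass AD; site-level and AB filters are excluded there because their
cost to true variants is what the FNR measures. The FNR combines the two
losses multiplicatively, FNR = 1 − s_AB · s_site, where s_AB is the fraction
of obligate-heterozygous sites (0/0 × 1/1 parents, 0/1 child) surviving the
AB filter and s_site the fraction surviving the site filters; the
multiplicative form assumes the two filters act independently on a true
variant, which holds in the generator and is the natural first-order model.

Rate = (n_maternal + n_paternal) / [(C_mat + C_pat)(1 − FNR)]. With the
published counts (1 + 3), callabilities (1,371,536,436 and 1,365,805,112 bp)
and FNR 5%, the diploid callable size is ~2.6 Gb and the rate is
0.15 × 10⁻⁸ per site per generation.

## Heterozygosity spectrum

One classifier replaces the aligner/Assemblytics/SyRi tool stack at desk
scale; alignment blocks may also be supplied externally. In the bundled
block builder, unique 32-mer anchors (forward and reverse-complement) are
chained per scaffold pair; a chain breaks on a *balanced* simultaneous jump
of both haplotypes (the signature of an inverted or relocated segment) but
tolerates one-sided jumps (indels, CNV ambiguity). Base-level operations are
computed piecewise between anchors; a one-sided inter-anchor length jump
above 50 bp is emitted as a single explicit gap run, because an
edit-distance alignment of flanking random sequence would otherwise smear a
long indel into spurious mismatches and split gaps. Nearby same-type gap
runs are re-merged (gap ≤ 10 columns), undoing the opposite artifact of
parsimony alignment splitting one indel around accidental matches.

Classification: SNVs from mismatch columns and indels from gap runs in
forward same-scaffold blocks (≤ 50 bp small, > 50 bp large — the boundary
counts 50 as small); reverse same-scaffold blocks are inversions; blocks
joining different scaffolds (or same-scaffold positions > 100 kb apart) of
at least 1 kb are translocations, inverted when reversed — the size floor
suppresses spurious calls from repeats. A large indel whose gained or lost
sequence matches its flank at ≤ 20% divergence is reclassified as a tandem
CNV. Indels that merely re-describe a translocated segment at its source or
destination are suppressed. SVs whose feature is more than half N are
dropped (exactly half is retained); SNVs are never gap-composed and are
never dropped.

Heterozygosity rates: the SNV rate is mismatch columns / aligned bases; the
full-spectrum rate counts *affected bases* (each indel or SV contributes its
size). A variant-count numerator cannot reach percent-scale values on real
genomes, so the affected-bases convention is the one implemented; it is a
documented choice, and both numbers are reported side by side.

Size-spectrum peaks are local maxima of the pooled non-SNV histogram
(100 bp bins) exceeding 3 × the median bin count and an absolute floor of 5;
the floor keeps sparse background bins from becoming peaks when the median
is zero.

## Evidence scores

Composite score: weighted sum over sources reporting the gene
(databases 3, KinderMiner 2, GWAS 2, SKiM 1; range 1–8 with ≥ 1 source).
SKiM prediction score: −log(p_FET) + n_AB/n_B, log base 10 by default (the
base is configurable; only the ranking, which is base-invariant, matters
downstream). Ranking is by descending score with lexicographic tie-break
for reproducibility.

## Problem sizes and test scope

The bundled aligners and simulators run at desk scale by design: synthetic
genomes of 50 kb–1 Mb, trios at base-pair resolution over 50 kb, depth
tracks of 3,000–10,000 bins, and brute-force oracles (path enumeration,
transitive closure, full DP alignment) on instances small enough to
enumerate. Passing tests demonstrate correctness of the *procedures* on
data matching the generator's assumptions — clean substitution-only
duplications, independent filter violations, disjoint SVs — not performance
or robustness on repeat-rich mammalian assemblies, where the external
aligners these modules consume do the heavy lifting.
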