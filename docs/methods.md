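# Methods

## Scope and data model

The package analyses conservation at four-fold degenerate (4d) third codon
positions of protein-coding transcripts, as seen in a reference-anchored
multi-species alignment with a per-base conservation score track. All internal
coordinates are 0-based half-open on the reference forward strand; 1-based
conventions (GTF/GFF3, WIG, VCF) are converted at the I/O boundary and nowhere
else. Per-species bases stored on site records are in coding-strand
orientation so that every summary is invariant under reverse-complementing the
whole reference (verified by a mirrored-genome test).

## Site catalog

Reference CDS codons are enumerated in translation order (minus-strand codons
are reverse-complemented genomic bases; codons spanning exon junctions keep
the genomic coordinate of each base). A species' codon is treated as
unaligned when any of its three bases is missing, gapped or ambiguous. A third
position enters the catalog when:

1. the reference codon is four-fold degenerate under the standard nuclear
   code (degeneracy = number of amino-acid-preserving bases at the position,
   incumbent included: 1→"0d", 2→"2d", 3→"3d", 4→"4d"; stop codons get a
   distinct "stop" label);
2. aligned species / total species ≥ 0.85; and
3. four-fold codons / aligned codons ≥ 0.95.

Both comparisons are *inclusive*. The source analyses print strict
inequalities but also state that the rule admits sites present in "at least
194" of the 204 aligned species at the 240-species scale, and
⌈0.95 × 204⌉ = 194 is only consistent with inclusive thresholds; we adopt the
inclusive reading and pin it with boundary tests. Base counts per site are
taken over all aligned species; "fixed" sites additionally require every
species present and a single observed base; the "complete" subset requires
every species present.

CpG context is evaluated on the spliced CDS (mRNA) sequence, so a codon split
across exons uses its transcript neighbours rather than intronic genomic
neighbours; the underlying convention in the source material is ambiguous and
this is a design choice.

## Conservation summaries

Sites are classified conserved when score ≥ τ (inclusive; default τ = 2.27,
the 5%-FDR calibration of the score track; the synthetic generator calibrates
its own τ the same way). Score histogram bins are unit-width, left-closed and
integer-aligned — bin edges are not stated in the source material, so this
convention is fixed here and reused by the population-variation summaries.
Exon-position classes (in transcription order): the first three bases of a
non-first exon are 5′+1/+2/+3, the last and penultimate base of a non-last
exon are 3′−1/−2, everything else (and all of a single-exon transcript) is
internal; where a very short exon could host both labels the 5′ label wins.
Local GC context is the overlap-length-weighted mean of fixed-window GC
(1 Mb at genome scale; the analysis scripts use 20 kb on the synthetic
genome, which is ~100 kb long) over the transcript span.

## Enrichment

The enrichment score of a unit with k conserved events out of n is
(k/n)/(K/N) with K, N the global totals — 1 means "as expected", and the
unit totals always sum to the global totals, also under the optional
exclusions (CpG-context sites; sites within 3 bp of an exon edge), which
recompute both numerator and denominator. Percentile cut-offs use linear
interpolation between order statistics with strict (>) membership. The TF
variant counts (site, binding-interval) overlap pairs per TF and pools all
TFs for the expectation — the exact normalisation in the source material is
unstated, and the pooled observed/expected form is chosen for consistency
with the transcript score. PcG overlap is counted on the gene's genomic span,
not exons only.

## Population variation

"Variable" means MAF strictly greater than the threshold (0 or 0.001).
Variant types are the 12 ordered major→minor pairs in reference-forward
orientation. The χ² expectation for a subset scales the type proportions of
*all variable* sites (a monomorphic site has no type; whether the original
expectation included monomorphic sites is unstated, and this choice is the
defensible one). Categories with zero global count are dropped with reduced
degrees of freedom. The MAF comparison between conserved and non-conserved
sites uses Welch's unequal-variance t, consistent with the fractional degrees
of freedom reported in the source analyses.

## Phylogenetics

Pseudosequences concatenate each species' bases over the complete-site subset
in a fixed genomic order. Dissimilarity is the raw p-distance (no
multiple-hit correction — the plainest reading of "dissimilarity"; at the
tree depths simulated, distances near saturation compress but the
neighbour-joining topology is driven by relative values). NJ is the classical
agglomerative algorithm: Q-criterion selection with the first strict minimum
in (i, j) order as deterministic tie-break, Studier–Keppler distance updates,
and negative limb estimates clamped to zero with the deficit transferred to
the sister branch. On additive matrices the implementation recovers the
generating topology and branch lengths exactly (enumerated for every binary
tree on up to 6 taxa). Canonical newick output orders children by their
smallest descendant leaf label and prints lengths with 10 significant digits,
making write→read→write byte-stable.

## Model statistics

The conservation model is Gaussian OLS of per-site scores on 14 predictors,
restricted to sites with score ≥ 0 so that it explains conservation rather
than acceleration. Predictors are left on their raw scales. Relative
importance is the LMG (Shapley) decomposition of r²: each predictor's share
is its average increment to r² over predictor orderings, computed exactly by
subset enumeration (feasible to p = 16 via centered cross-product matrices;
one small solve per subset) or by seeded sampling of orderings for larger p;
shares are normalised to sum to one. For mutually orthogonal, centered
predictors the shares reduce to marginal-r² proportions, which the tests use
as a closed-form oracle. The ESE feature flags sites inside a hexamer match
on the spliced CDS *and* within 70 bp of an exon end.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions used by the acceptance checks.

- **Tree.** Pure-birth (Yule) with the root splitting at time zero, rescaled
  so every root-to-tip path equals the configured depth (default 4.0 expected
  neutral events per site). 12 species by default; the first leaf is the
  reference and is never masked.
- **Genes.** 60 genes of 200–500 codons, single-exon fraction 0.10 allocated
  exactly, multi-exon counts 2 + Poisson, exon pieces ≥ 60 nt cut without
  regard to codon phase (so junction-spanning codons occur), introns and
  intergenic spacers of GC 0.40, strands assigned at random. Root codons
  draw an amino acid uniformly, then a codon family, then the third base
  from the site's stationary distribution.
- **Rate classes.** Each four-fold third position is conserved with
  per-gene probability π_g (overall π = 0.20; a designated 6-gene enriched
  set has a 3× multiplier, renormalised so the overall fraction stays π) and
  evolves at ρ = 0.1 of the neutral rate; all other positions evolve at a
  small amino-acid-constrained rate (0.02) with proposals rejected unless
  synonymous and non-stop. Stationary base frequencies at 4d sites are
  GC-split: conserved 0.80, neutral 0.50, plus a +0.10 first-exon elevation.
  A per-gene lognormal rate multiplier (σ = 0.1) provides mutation-rate
  heterogeneity and doubles as the per-gene synonymous rate feature.
- **Substitution events.** Evolution runs as a Poisson event process per site
  per branch; a proposal from the stationary distribution counts as an event
  whether or not it changes the base, so a neutral site's event count has
  mean exactly the tree length and the score's normal-deviate scaling is
  exact. Recorded event counts are the ground truth for scores.
- **Scores.** s = (T − x)/√T + Normal(0, 0.5), with T the tree length and x
  the site's event count — strictly decreasing in x before noise, i.e. a
  monotone surrogate for a conservation score (the real scoring model is out
  of scope; the pipeline consumes scores as opaque). τ is calibrated so the
  neutral fraction among sites scoring ≥ τ (positive scores only) meets the
  5% FDR target, mirroring the published threshold's semantics.
- **Variants.** A site is variable with probability 0.3, damped by λ_v = 0.4
  at conserved sites; MAF ~ 0.5·Beta(0.3, 8); minor alleles at conserved G/C
  sites fall in {A, T} with probability 0.7 (the GC→AT excess); 2% of
  variable sites have the reference differing from the major allele
  (recorded in the truth for the overlay check).
- **Tracks and metadata.** One TF's binding intervals and the PcG tracks
  prefer the enriched-gene set (preference 0.8); methylation class c5 is
  assigned preferentially to PcG-covered genes; per-species log Ne couples
  negatively (−0.5 per SD) to that species' GC at conserved sites, and
  young-TE fraction couples negatively to log Ne. Every coupling is a config
  field whose null value (multiplier 1, preference 0, coupling 0) produces a
  null fixture.

Determinism: one RNG stream seeded from the config, fixed call order —
identical (config, seed) bundles are byte-identical on disk.

### What the generator does and does not emulate

It reproduces the *statistical couplings* the analysis is designed to detect
(rate-class mixture, GC-biased equilibria, conservation-damped variability,
enrichment concentration, Ne–GC coupling), at ~7,000 sites instead of
~2.6 million, 12 species instead of 240, and with a score that is a
calibrated monotone function of the substitution deficit rather than a
likelihood-ratio statistic. Passing tests therefore demonstrate that the
pipeline's computations are correct and that planted effects of realistic
sign and magnitude are recovered; they do not validate biological claims
about real genomes, nor the robustness of the score itself to alignment
error, selection on codon usage, or non-stationary base composition — none
of which the generator simulates. Random (uniform) unalignment masking also
means the complete-site subset is an unbiased sample of the catalog, whereas
in real alignments completeness correlates with conservation.

## Numerical and degenerate-input conventions

Missing scores are NaN and excluded with logged counts, never treated as 0.
Ties in the mammalian major base break in fixed A<C<G<T order with a tie
flag. Empty summary classes yield n = 0 rows with missing proportions.
Enrichment of a unit with no events is missing, not 0. χ² categories with
zero global counts are dropped with reduced df. Rank-deficient model designs
raise with the collinear columns named; constant features are dropped with a
warning. Problem sizes throughout (fixture scale, window sizes, permutation
counts) are the package's own desk-scale choices, stated where used.

## Known limitations

- The alignment reader supports the per-site TSV dialect and a minimal MAF
  subset (forward-strand reference rows only); bigWig/bigBed and tabix are
  out of scope.
- No multiple-hit correction on p-distances; deep trees compress distances
  toward saturation.
- The LMG exact mode is exponential in the predictor count (capped at 16).
- The generator does not simulate indels, recombination, explicit gBGC
  mechanics, or genome-scale sequence.
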