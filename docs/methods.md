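# Methods

## Scope and model

`dremap` operationalizes a histone-mark definition of regulatory elements
and their hormone-response dynamics. It deliberately starts *after* read
alignment and peak calling: its inputs are called peak lists (narrowPeak /
BED6), per-base coverage (bedGraph / WIG), gene models (GFF3), an RPKM
table and a genome FASTA. Everything upstream (mapping, MACS-style peak
calling, RNA quantification) and everything orthogonal (differential
testing with count models, de novo motif discovery, GO enrichment) is out
of scope; the twofold rule below replaces significance testing by design,
so the output is a fold-class, never a p-value.

All in-memory coordinates are 0-based half-open; GFF3 and WIG are converted
at the I/O boundary and back on write. Interval overlap means ≥ 1 shared
base; abutting half-open intervals do not overlap.

### Element definitions

* Promoter element: H3K4me3 peak whose **summit** lies within 1.5 kb of
  some TSS (boundary inclusive).
* DRE (distal regulatory element, the enhancer candidate): H3K4me1 peak
  whose summit lies > 1.5 kb from **every** TSS. H3K4me1 peaks inside the
  proximal window are dropped, not reclassified — promoters derive from
  H3K4me3 only, so no peak can be both kinds.
* Active: the element's source peak overlaps ≥ 1 H3K27ac peak. Activity is
  monotone in the H3K27ac set (adding peaks can only activate).
* Nearest gene: the gene minimizing |summit − TSS|, same scaffold only,
  ties broken by lexicographically smallest gene id. Summit-based
  assignment (with midpoint fallback when a summit is absent) is used
  consistently pipeline-wide, including for distance thresholds — a
  deliberate, documented difference from end-to-end interval distance
  tools, chosen so region assignment and distance assignment agree.

### Five-way genome partition

promoter-TSS = strand-oriented [TSS−1000, TSS+200); TTS = the mirrored
[3'end−200, 3'end+1000) window hung off the gene's 3' boundary; exon and
intron from the gene structure; remainder intergenic. Conflicts resolve by
fixed priority promoter-TSS > exon > intron > TTS > intergenic, implemented
by painting labels from lowest to highest priority, which makes the
partition a total function (every base, exactly one label — property-tested
against a per-base brute-force oracle).

### Dynamics

Region signal = mean per-base coverage × 10⁶ / library_size (a
counts-per-million density). fold = (treated + ψ)/(control + ψ) with
pseudocount ψ = 0.5 density units, which stabilizes folds on empty regions
while staying small against real signal (tens of density units at
default depth). Generic classification is strict (fold > 2 / fold < 0.5);
per-DRE H3K27ac dynamics use the at-least-twofold boundary (≥ 2 / ≤ 0.5),
the convention for enhancer-activation counting; the two rules are named in
the output metadata. Union regions are connected components of the combined
two-condition peak set under ≥ 1 bp overlap. The classifier is
antisymmetric under swapping conditions and invariant under rescaling both
tracks and their library sizes together.

### Expression linkage

Categories: RPKM < 1 → "none"; remaining genes ranked by (RPKM, gene id)
and cut into tertiles low/medium/high, remainder genes to the lower
tertiles (sizes differ by ≤ 1). The no-expression threshold and rank-based
tertiles are scale-free conventions; nothing downstream depends on their
exact placement. Metaprofiles average strand-oriented [TSS−2 kb, TSS+2 kb)
windows in 50-bp bins; for "−" genes the window is [TSS−flank+1, TSS+flank+1)
before reversal so the TSS base lands in the first downstream bin. Windows
truncated by scaffold ends contribute only fully covered bins; categories
with no genes are absent, not zero. Class-wise expression is the mean of
log2(RPKM+1) over nearest genes, deduplicated per class by default (a
per-element mode exists) so multi-enhancer genes cannot dominate; genes
missing from the table are dropped and tallied.

### Motif scanning

PFMs are normalized to column probabilities with a 0.01 pseudocount per
cell. Scores are log2(p/background) sums; background defaults to uniform
0.25, with a genome-derived mononucleotide mode available. Both strands are
scanned (reverse strand via matrix reversal + complement, so coordinates
stay in the forward frame); windows containing N are skipped; a window is a
hit at ≥ threshold_fraction of the min–max achievable score (default 0.80;
no universal cutoff exists, so it is exposed as a flag). "Contains the
motif" means ≥ 1 hit anywhere in the peak; overlapping hits are all
reported. A 10⁻⁹ score slack absorbs summation-order rounding at exact
thresholds.

## The synthetic study

The generator emulates the statistical structure of a two-condition
hormone-response ChIP-seq experiment on a small multi-scaffold genome, with
every planted fact recorded in a truth table. Defaults (= the conditions
the test suite runs at): 6 scaffolds × 2 Mb on a 12-kb block grid; 300
genes, 300 established active enhancers, 300 poised enhancers;
activation_fraction 0.3 of poised enhancers gain H3K27ac only after
treatment at fold_gain 4; mean depth 30 with a 5% flat Poisson background;
summit jitter σ 50 bp; 5% dropouts and 5% decoy peaks per list; 150
receptor peaks, 40% carrying a planted response-element instance mutated at
0.05 per base; expression coupling ×4 for genes nearest to active (both
conditions) and newly activated (treated only) enhancers.

Design choices worth knowing:

* **Acetylation geometry.** Established active enhancers carry two
  flanking H3K27ac peaks around the nucleosome-depleted core — the mature
  double-peak pattern — while newly activated enhancers carry a single
  nascent treated-only peak. This keeps treated-only H3K27ac presence
  counts equal to the number of activations (Binomial(n_poised,
  activation_fraction)) while modeling established enhancers realistically.
* **Coverage.** Expected density is a flat background plus Gaussian bumps:
  unimodal H3K4me3/H3K27ac at promoters with amplitude scaled by the
  gene's expression category (factors 0.1/0.6/1.2/2.4 × depth for
  none/low/medium/high), bimodal H3K4me1 at promoters (bumps at ±500 bp,
  producing the characteristic TSS dip) and at enhancer cores, and a
  single bump at activated enhancers whose amplitude is depth/fold_gain
  before and depth after treatment. Counts are Poisson at 10-bp bins;
  library size is the simulated tag count (coverage sum / 100-bp read
  length) and is carried on the bedGraph track line so disk round trips
  preserve scaling.
* **Sequence.** The genome is uniform random; response-element instances
  are inserted inside receptor peaks on a random strand. Chance
  near-consensus matches (≥ 11/13 agreement, either strand) inside
  receptor peaks are deterministically disrupted outside planted spans, so
  in the noise-free limit "peak contains motif" is exactly the planting
  flag. The bundled 13-bp near-palindromic nuclear-receptor-style matrix
  (homogeneous 97/1/1/1 columns) is synthetic, for simulation and testing
  only; real analyses must supply their own matrix. Its homogeneous
  columns make detection equivalent to a mismatch budget (≤ 2 mismatches
  at threshold 0.80, ≤ 1 at 0.85), which the tests exploit as a binomial
  oracle.
* **Corruption.** Dropouts are independent per peak per list; decoy counts
  are Binomial(n, rate) with uniform placement; jitter moves summits only
  (clipped to the peak). The noise-free configuration zeroes jitter,
  dropouts, decoys and motif mutation; Poisson counting noise remains, but
  at default depth the planted fold separations are many standard errors
  wide, so recovery there is exact, not merely likely.
* **Determinism.** Every stage draws from its own child RNG
  (`default_rng([seed, stage])`), so datasets are bit-reproducible and a
  caller can skip the expensive track/sequence stages without disturbing
  the others. Placements use integer arithmetic; track summation order is
  fixed (marks × conditions × sorted scaffolds).

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: irregular gene density and gene nesting,
replicate structure and between-replicate dispersion (no DESeq-style
shrinkage is needed or provided), fragment-length effects and GC bias,
enhancer–promoter looping, H3K27ac *losses* on treatment (the decrease
branch of the classifier is exercised by the track-swap antisymmetry
property instead), and motif occurrences outside receptor peaks.

## Recovery scoring

A predicted element matches a planted one iff their summits lie within
500 bp on the same scaffold and the labels agree, where the predicted label
is promoter / active_DRE (DRE + active) / poised_DRE (DRE + inactive).
Truth kinds describe the **baseline (control) condition**; recovery is
therefore scored against control-condition calls, while the
treated-condition check compares predicted active DREs against planted
actives plus planted activations. Matching is set-based (nearest
same-label element within the tolerance), precision and recall are
reported per label together with unmatched lists. Dynamics calls are
matched to planted enhancers by region-summit proximity; the fraction of
matched "gain" rows classified increased is the sensitivity, of "stable"
rows the false-positive rate. Motif detection is scored by peak name over
observed peaks; decoys count as unplanted.

## Problem sizes and runtime

The default study (12 Mb genome, ~900 planted elements, six coverage
tracks) simulates in ~2 s and the full test suite runs in well under a
minute; the replicate expression-coupling check runs 20 seeds with the
track and sequence stages skipped. These sizes were chosen so the planted
effects are estimated with comfortable margins (binomial standard errors
~1%) while the whole analysis stays interactive.

## Known limitations

* Fractions whose published denominators are internally inconsistent are
  always re-derived from the two counts (half-up, one decimal) and printed
  alongside them; the package never reproduces a percentage it cannot
  recompute.
* Nearest-gene assignment is a heuristic for target assignment; no contact
  data is consulted.
* The five-way partition depends on annotation completeness; unannotated
  transcripts inflate "intergenic".
* WIG support covers fixedStep/variableStep with span; bigWig and BAM are
  intentionally unsupported (text formats only).
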