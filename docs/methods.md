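# Methods

This note records the models, rules and numerical choices behind katalogkit,
and what its synthetic data do and do not demonstrate about real catalogues.

## Contig post-processing

**Fragmentation.** Large contigs are split at starts 0, s, 2s, … with step
s = fragment_length − overlap (defaults 2,000 and 300 nt, so s = 1,700 nt).
Every fragment has the full fragment length except possibly the last.  The
handling of the terminal short piece is not fixed by the procedure being
emulated; we truncate it at the contig end rather than discard it, so the
union of fragments covers the contig exactly and overlap-aware concatenation
is an exact inverse (this round trip is property-tested).

**Redundancy collapse.** Greedy longest-first (ties by id, which makes the
output deterministic): a candidate is removed iff some already-retained contig
aligns at identity ≥ 0.99 over ≥ 0.90 of the shorter sequence.  The default
identity function is a global alignment with free terminal gaps
(match +1, mismatch −1, gap −2); identity is matches / alignment columns of
the aligned core, internal gaps counting as columns, and coverage is measured
by those core columns against the shorter sequence.  Reference clustering
tools do not publish their internal identity definition, so ours is stated
explicitly and is injectable (`identity_fn`) for callers who prefer another.
The greedy result is checked against brute-force all-pairs filtering on
instances of ≤ 200 contigs.

The 300 nt minimum-length floor can be applied before or after the collapse
(`collapse_and_filter`, ``order``); the default is filter-last, which lets a
short contig still absorb an even shorter redundant copy before being dropped
itself.

**Artefact peaks.** Contig lengths are binned at 200 nt.  A peak is a bin that
exceeds both neighbours and a moving-median baseline (window 5 bins,
zero-padded at the histogram ends) by a factor of 1.5 (configurable).  The
"assembly artefact" flag is raised when two peaks are spaced by
fragment_length − overlap within one bin width.  The zero padding matters:
edge replication would suppress genuine peaks in the first or last bins.

## Reference-protein QC

Coordinates are 1-based inclusive throughout (the tabular-alignment
convention); interval arithmetic uses merged interval unions.  E-values are
clamped to ≥ 10⁻³⁰⁰ on ingest so orders-of-magnitude ratios stay finite.

* **Coverage / representation:** per protein, the union of subject intervals
  over all hits; "single-contig sufficient" asks whether one contig's own
  union reaches the 90 % threshold.
* **Terminal classes:** n_terminal iff the union touches residue 1 but not the
  last residue; c_terminal symmetric; complete iff both; complete_with_utr
  additionally requires ≥ 30 unaligned nt flanking the aligned region on
  *both* sides of the contig.  The 30 nt margin is our own default (a UTR
  shorter than a primer is not evidence of one) and the both-sides reading is
  an interpretation choice; both are configurable.
* **Chimeras:** a contig is chimeric iff two hits target different proteins,
  their query intervals overlap by ≤ 0 nt (strict non-overlap, with a
  tolerance knob), and each hit has e ≤ 10⁻²⁰, subject coverage ≥ 75 % and
  identity ≥ 50 %.  "Coverage of both protein hits" is read as coverage of
  each subject protein by its own hit, not query coverage.
* **Contamination:** flagged iff the best (lowest e-value) hit is non-fish and
  either no fish hit exists (vacuous gap, reported distinctly via
  `fish_hit_present=False`) or the best fish e-value is ≥ 10¹⁰ times larger.

Both screens are verified against literal brute-force evaluation of the
predicates on every hit pair / contig.

## Annotation

Each database carries its own thresholds (protein defaults: e ≤ 10⁻¹⁰,
overlap ≥ 33 columns, identity ≥ 30 %; nucleotide: e ≤ 10⁻²⁰, identity
≥ 70 %) and a priority rank.  These defaults are this package's declarations —
sensible translated-search settings — not values taken from any particular
pipeline.  Best hit within a database: lowest e-value, ties by higher bit
score then lexicographic subject id.  Across databases, strict priority wins
even over a dramatically better e-value in a lower-priority database; the
alternative (global best) is a deliberate non-default because mixing
databases with different score scales makes e-values incomparable.
Descriptions containing "bac", "fosmid" or "shotgun" are blacklisted as
non-informative.

CDS completeness uses a strict > 0.90 cut (a gene at exactly 90 % is not
complete).  The decile histogram bins fractions into (0,0.1], …, (0.9,1.0].
GO counts are deduplicated per contig before counting, so one (contig, term)
pair counts once regardless of how many databases asserted it; per-namespace
counts must sum to the total by construction and are tested to.  Slim mapping
returns the most-specific slim ancestors: a slim term is reported iff some
upward is_a path from the query reaches it without passing another slim term
(a slim term maps to itself); this matches the semantics of the classic
map2slim tool and is verified against a path-enumeration oracle.

## Paralogy

**Shared families.** Two catalogue genes are paralogous iff their best
cross-species hits are recorded teleost-specific paralogs after the ortholog
replacement rule maps both hits into one species.  We resolve the rule's
species asymmetry by attempting the replacement in both directions and taking
the symmetric closure, so processing order cannot change the families.
Families are connected components; lookup failures skip the pair.

**Species-specific clusters.** Contig translation uses the annotation frame
when hinted, else the longest stop-free ORF over six frames; proteins
< 100 aa are dropped, as are pairwise alignments < 100 aa.  Divergences of
secondary contigs to the longest contig are clustered in 1-D by splitting the
sorted values at gaps ≥ 0.10.  The longest contig contributes an implicit
divergence of 0 — without it a gene with a single distant secondary could
never reach "two or more clusters".  Cluster count is order-invariant and
equals the number of connected components of the "closer than gap" relation
(property-tested).

**Summary arithmetic.** Collapsed gene count = total − shared members +
shared families; mean family size = members/families at one decimal; the pair
fraction pools shared families of size 2 with genes having exactly two
clusters.  With no families the ratios are reported as undefined rather
than zero.

## Expression

RPKM = count / (length_kb × totals_millions); the identity
Σ_g rpkm_g · length_kb,g = Σ_g count_g / totals_millions is tested exactly.
Correlation and PCA run on log₁₀(RPKM + 1); the offset is recorded in output.
Constant genes are dropped with a warning (they carry no ordering
information for Spearman and would zero-divide standardization).

The DEG-overlap test is an upper-tail exact binomial: k genes of list A found
in list B with matching direction, null probability
(|B|/universe) × direction_factor with direction_factor = 0.5 by default (a
random gene matches direction half the time).  Universe size, factor and
sidedness are parameters because published analyses rarely state them.

Time normalization of an old/young fold change assumes transcript levels
change linearly in time: fc′ = 1 + (fc − 1)·(span_target/span_source).  A
log-linear mode (log fc′ = log fc · ratio) is offered because fold changes
are usually inspected on a log scale; the mode used is recorded in output.
The strain comparison applies a paired Wilcoxon signed-rank test to log fold
changes — exact null distribution for n ≤ 25 pairs, normal approximation with
continuity correction above — over all genes and the up-/down-regulated
subsets separately.  Whether to test log or linear fold changes is genuinely
open; log was chosen because the paired differences are closer to symmetric
there, and the Monte-Carlo calibration below is run under that choice.

DEG calling itself is ingested from upstream tools.  A pooled-count exact
binomial test exists purely as a smoke test for synthetic data; it models no
overdispersion and is explicitly not equivalent to a negative-binomial DEG
caller.

## Synthetic data: what it emulates, and what it does not

The generators plant every feature the downstream rules look for, with truth
labels: paralog families (seed protein copied, a controlled fraction of
residues mutated), fragments (internal protein windows), redundant copies
(~99.5 % nucleotide identity over ~95 % of the source contig), chimeras
(two genes' coding sequences concatenated), contaminants (a disjoint
"non-fish" protein set; an optional weak fish hit is emitted ≥ 10 orders of
magnitude above the best non-fish e-value).  Reverse translation uses the
standard codon table with uniformly random synonymous codons.  The emitted
e-value heuristic 10^(−round(2·aligned_aa·identity/100)), clamped at 10⁻³⁰⁰,
is declared synthetic: it is not an aligner's extreme-value statistic, but
every downstream rule depends only on relative e-value magnitudes, which it
preserves monotonically.

Counts follow a gamma-Poisson (negative-binomial) model: mean =
baseline × 2^(effect·old) × library factor, variance = m + α·m², with
baselines log-uniform on [50, 500], lengths uniform on [500, 3000] nt and
library factors uniform on [0.8, 1.2] — unremarkable bulk-RNA-seq magnitudes.
At dispersion 0 the counts are deterministic rounded means.  The default
ageing design is the 8-sample layout of two strains (GRZ young/old at 5/14
weeks; MZM-0403 at 5/31 weeks) × two tissues (skin, brain).

For the strain-comparison calibration, genes change linearly in level at the
same per-week rate in both strains: fc = 1 + rate·span·ε with rate magnitudes
uniform on [0.005, 0.015] per week (down-regulated genes get negative rates;
the rate ceiling keeps fc positive over a 26-week span), and multiplicative
noise ε = exp(N(0, 0.25)) truncated at 2.5 sd independently per strain.
Truncation keeps the noise symmetric, so after rescaling to the common span
the two strains' fold changes are exchangeable and the paired differences are
symmetric about zero — exactly the null the signed-rank test assumes.  The
43-gene lists use the 11-up / 32-down split of the skin DEG set.

What passing these tests does *not* show: the generators contain no sequencing
error, no splice isoforms, no read-level simulation, no compositional bias,
and their hit tables encode provenance rather than alignment search behaviour.
Recovery rates near 1.0 certify the *rules*, not the difficulty of real
cross-species searches, where diverged or short proteins will miss thresholds
that synthetic hits satisfy by construction.

## Problem sizes and runtime choices

The planted-truth experiments use a 500-gene reference expanded to ~2,100
contigs (four pooled catalogues) for the chimera/contamination screens, 200
genes for duplication-status recovery, and 200 simulations of 43-gene DEG
lists for the rejection-rate calibration; oracle-equivalence checks run on
100–120 random small instances per rule.  These sizes give stable estimates
(binomial standard error ≤ ~1.5 points on the rejection rates) while keeping
the full test suite and the acceptance script each under a minute.

## Known limitations

* The greedy redundancy collapse is O(n²) alignments and is intended for
  post-assembly polishing scales, not for clustering millions of reads.
* `shared_paralog_families` examines gene pairs quadratically; catalogue-scale
  use should pre-partition genes by hit family.
* Chimera detection cannot see chimeras whose halves hit the same protein
  (tandem duplications) — a limitation of the defining rule itself.
* The contamination rule trusts the supplied species → taxon map; species
  absent from it default to "other", i.e. non-fish.
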