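# Methods

## Data model

The unit of observation is a per-cytosine call: at chromosome position
*p* on strand *s*, a cytosine of context *c* ∈ {CG, CHG, CHH} was covered
by *t* reads of which *m* reported methylation.  Methylation levels are
read-weighted — the level of any set of sites is Σm/Σt — which is the
standard WGBS convention and weights deeply covered sites more.  A
site-count-weighted alternative (mean of per-site m/t) is available via
`region_level(..., weight="sites")` for sensitivity analyses.

Coordinates are 0-based half-open everywhere inside the package; the call
TSV dialect and GFF3 use their native 1-based conventions and are
converted at the I/O boundary.

### Context classification

Context is read 5'→3' on the strand carrying the cytosine: the CG call
needs only the next base, CHG/CHH need two.  On the minus strand the
classifier inspects the reference positions p−1 and p−2 and complements.
Sites whose context window runs off the chromosome or touches an N are
excluded from every analysis: an ambiguous context has no defensible
count contribution.

## Methylated-site calling

Whether a covered site is "methylated" is a statistical call, because
bisulfite non-conversion makes a fraction of unmethylated cytosines read
as methylated.  A site is called methylated when a one-sided binomial test
of m successes in t trials at success probability equal to the
non-conversion rate, BH-adjusted across all sites, gives q < 0.05.  The
non-conversion rate itself is estimated from a biologically unmethylated
control (in real experiments, an organellar genome) as 1 − Σm/Σt.  Both
the threshold and the rate are parameters; the 0.05 default is a
conventional FDR level, and the calling criterion only affects the
descriptive mC composition summaries, not DMR calling.

## The DMR caller

Per context, each chromosome is tiled with 200-bp windows stepping by
50 bp (no partial trailing window).  Only cytosines covered ≥ 4× in
*both* libraries enter any two-sample computation; the pooled 2×2 table
(methylated/unmethylated reads × sample) of each window is tested with a
two-sided Fisher exact test.  P-values are BH-adjusted per context across
all tested windows genome-wide: the three contexts differ by orders of
magnitude in window counts and mixing them would let CHH dominate the
correction.  Windows with q < 0.01 and a fold change above 2.5 (ratio of
the higher to the lower read-weighted level; a zero level against a
positive one counts as infinite and passes) are significant.  Overlapping
or bookended significant windows *of the same direction* are unioned into
candidate regions — without the union, one differential locus would be
reported up to four times by overlapping windows; opposite directions
never union.

Inside each candidate region every common cytosine is retested
individually; sites with two-sided exact p < 0.01 are DMCs.  A candidate
region containing at least 7 DMCs is a DMR and keeps the candidate-region
extent — the procedure defines DMRs as the selected regions that pass the
DMC filter, so the reported interval is the union of the windows that
carried the evidence.  Same-context, same-direction DMRs separated by
≤ 100 bp are merged, and the merged span's levels, DMC count and fold
change are recomputed so reported attributes always describe the reported
interval.  Direction is *hyper* when sample B (case) exceeds sample A
(control); swapping the samples flips every direction and nothing else.

Defaults (window 200, step 50, coverage 4, q 0.01, fold 2.5, DMC p 0.01,
≥ 7 DMCs, merge gap 100) are the standard sliding-window WGBS parameter
set and are all exposed as flags.  There is no replicate handling: the
caller compares exactly two pooled libraries; dispersion-aware designs
are out of scope.

### Exact-test implementation

A genome-scale run tests 10⁴–10⁶ windows, so the two-sided Fisher test is
evaluated for whole arrays of tables at once (`stats.fisher_exact_vec`):
each table's hypergeometric support is enumerated in one flattened pass,
log-pmfs come from log-gamma, and the two-sided p is the sum of point
masses not exceeding the observed one within a relative tolerance of
1e-7 (the convention shared by mainstream implementations, guarding
against ties lost to floating-point error).  The tests verify agreement
with `scipy.stats.fisher_exact` and with a definitional enumeration
oracle over all tables with row margins ≤ 30.

## Gene assignment and enrichment

Functional regions per gene are promoter (2 kb upstream of the TSS,
strand-aware, clipped at the chromosome edge), UTR, exon and intron, with
UTR taking precedence over the exon sequence containing it so the labels
partition promoter ∪ body.  The 2-kb promoter default matches the flank
width used in the metaprofiles; it is a convention, not a biological
constant, and is configurable.  A DMR overlapping any functional region
by ≥ 1 bp (configurable) marks the gene as a DMG; every overlapped gene
and every overlapped region label is recorded, deduplicated per (gene,
context, direction).  A gene with DMRs of both directions appears in both
direction tallies but once in a non-repeat total.  For DMR genomic
composition the compartments are made mutually exclusive by the
precedence genic > promoter > intergenic.  DMGs expressed below
TPM 10 can be filtered out when an expression table is supplied.

Enrichment is the flat hypergeometric over-representation test: for a
term with K background genes, the upper tail P(X ≥ k) of drawing k
annotated genes in a list of n from a universe of N, BH-corrected across
terms, significant at FDR < 0.01.  GO-graph propagation and pathway
topology are deliberately not modelled.

## The simulator

The generator emulates the features of a two-sample plant WGBS experiment
that the pipeline's statistics actually consume:

- **Genome**: uniform-random nucleotides, 2 × 500 kb by default.
- **Annotation**: genes (50/Mb, 1–4 kb, 1–5 exons with terminal UTRs) and
  TEs (80/Mb, 0.3–3 kb), placed without overlap; 70% of TEs go to the
  central 30% of each chromosome to mimic TE-dense pericentromeres (with
  genome-wide fallback when the central zone is congested).
- **True methylation levels** per (compartment, context):
  intergenic 0.55/0.35/0.08, gene body 0.35/0.08/0.03, TE 0.90/0.70/0.12
  for CG/CHG/CHH — reproducing CG > CHG > CHH ordering, TE
  hypermethylation, gene-body CG methylation and genic CHG/CHH depletion.
- **Counts**: coverage ~ Poisson(mean depth; defaults 12.64 and 13.42 for
  the two samples), methylated reads ~ Binomial(coverage, p_obs) with
  p_obs = p(1 − over-conversion) + (1 − p)·non-conversion; non-conversion
  defaults to 0.008 (a 99.2% conversion rate), over-conversion to 0.
- **Spiked truth**: differential regions of configurable context, length,
  count and signed level change are placed in intergenic space where at
  least 10 context-matching cytosines exist (so the ≥ 7-DMC rule is
  attainable in principle), never overlapping; sample B differs from A
  only there.  Spikes from the intergenic CG base of 0.55 use the
  hypomethylation direction for effect sizes near 0.4 — 0.55 → 0.15 is a
  3.7-fold change, whereas 0.55 → 0.95 (1.7-fold) would be removed by the
  caller's own 2.5-fold gate by design.

Everything is deterministic given the seed (independent RNG streams per
stage), and each run records a hash of its resolved configuration.

### What the simulation does not capture

Sequence composition is unrealistic (no CpG islands, repeats or
compositional bias), true levels are piecewise-constant per compartment
rather than bimodal per site, coverage is equidispersed Poisson (an
overdispersion option exists in the count model's design space but the
default is plain Poisson), and there is no read-level error, mapping bias
or M-bias.  Passing the validation suite therefore demonstrates that the
*statistical machinery* is correct and calibrated under its stated
assumptions — it does not certify performance on real libraries, where
dispersion between biological replicates is the dominant unmodelled
effect.

## Validation and problem sizes

The simulation-based checks run at desk scale, sized to finish in minutes
on one CPU while keeping enough sites for the asymptotics to hold:

- **Null calibration**: 20 independent null sample pairs (2 × 500 kb,
  12×); the caller averages ≤ 1 false DMR per replicate across all three
  contexts (measured: 0).
- **Recovery**: 20 spiked CG regions (|Δ| = 0.4, 600 bp, 15×) per genome,
  5 seeds; nucleotide-level precision and recall ≥ 0.9 (measured ≈
  0.94/0.98).
- **Conversion estimator**: 100 simulated 50-kb controls at 0.8%
  non-conversion; ≥ 99% of estimates fall in [0.990, 0.994].
- **Metaprofiles**: under a uniform true level all 60 bins sit within
  3 SE of the expected observed level, and profiles are exactly invariant
  under reverse-complementing the genome and reflecting all features —
  bin remainders are allocated 5'-first in the feature's own orientation
  precisely so this symmetry is exact.
- **Enrichment null**: 200 random gene lists from a 1000-gene universe
  with 50 terms produce a significant term in ≤ 5% of replicates.

`scripts/acceptance.py` recomputes these quantities from scratch.

## Numerical and degenerate-input conventions

Empty margins in a 2×2 table give p = 1 (no information).  Regions or
windows with no commonly covered site are skipped, not reported as zero.
Windows shorter than the window size are never emitted.  Metaprofile bins
with no data are NaN; features shorter than the bin count are skipped
with a warning.  Composition fractions over zero called methylated sites
are reported as zeros with an explicit flag.  Equal levels cannot occur
for a DMR (the fold filter removes them) and direction classification
raises rather than guessing.
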