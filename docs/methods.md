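# Methods

## Model and procedure

`strexpand` treats each short tandem repeat (STR) locus as a vector of
per-haplotype copy numbers observed in a cohort of haploid assemblies and
asks two questions: is the locus's copy number *conserved* across non-human
primates (NHPs), and, if so, is it *expanded* specifically in humans. The
default cohort design is 148 human haplotypes, 18 haplotypes from four
closely related great-ape species (chimpanzee 6, bonobo 4, gorilla 4,
orangutan 4) and 8 from three distantly related primates (gibbon 3, rhesus
macaque 3, crab-eating macaque 2). The species totals (148 / 18-across-4 /
8-across-3) define the study design; the within-clade per-species split is
not itself specified by the design, so the values above are a fixed,
realistic choice and are configurable.

The cascade is strictly ordered, and a locus excluded at one stage is never
tested by a later one:

1. **Coverage.** A locus needs ≥ `min_human_calls` (10) non-missing human
   values and a call in ≥ `min_nhp_species` (6 of 7) distinct NHP species (a
   species is present if any of its haplotypes is called). Failing loci are
   `excluded_low_coverage`.
2. **Unimodality.** Hartigan & Hartigan's dip statistic is computed on the
   pooled close-NHP values (18 observations; pooled, not per-species,
   because the conservation assumption is about a single close-NHP copy
   number distribution). p-values come from a seeded Monte-Carlo null of
   uniform(0,1) samples of matching size (`dip_n_boot` = 10,000, with the
   +1/+1 finite-sample correction) and are Benjamini–Hochberg adjusted over
   the loci entering the stage; q < 0.05 ⇒ `excluded_multimodal`. Samples
   with fewer than 4 distinct values are treated as unimodal by convention.
3. **Consistency.** Two-sample Kolmogorov–Smirnov of distant-NHP versus
   close-NHP values, BH-adjusted; q < 0.05 ⇒ `excluded_distant_shift`.
   Survivors are ncSTRs. The p-value uses scipy's default method selection,
   which is the exact two-sample null at these sample sizes (8 vs 18).
4. **Expansion.** One-tailed Wilcoxon rank-sum (human greater than pooled
   NHP), midranks with tie-corrected variance and no continuity correction,
   Bonferroni-adjusted over the ncSTRs actually tested; adjusted p < 0.05 ⇒
   heSTR. The stricter 0.01 threshold is available via
   `PipelineConfig(hestr_alpha=0.01)`; the configured value is echoed into
   every output header. Downstream comparisons always use ncSTRs excluding
   heSTRs as the background set.

## The dip statistic

The dip is the sup-norm distance from the sample ECDF to the nearest
unimodal distribution function (convex cdf left of the mode, concave right
of it, an atom allowed at the mode). The implementation works on the
distinct-value ECDF corners: for a candidate mode, the convex flank must
thread the bands `[b_i − d, a_i + d]` (where `a_i`, `b_i` are the ECDF's
left and right corner values), which by a greatest-convex-minorant argument
is feasible exactly when `d` is at least half the largest amount by which
the lower corners poke above the minorant of the upper corners. Minimizing
the larger of the two flank requirements over modes gives a sharp lower
bound `d0`; because the two flanks must also hand off to each other at the
mode, `d0` can occasionally be strictly below the dip, so `d0` is certified
by an exact band-threading feasibility test (forward/backward propagation of
forced convex extrapolations) and tightened by bisection when the hand-off
binds. The test suite checks exact agreement (|Δ| < 1e−7) with an
independent linear-programming search over all unimodal fits on samples up
to n = 12, including heavily tied samples; development-time validation ran
thousands of such cases, with the hand-off correction engaging in roughly 2%
of continuous samples (size < 0.01).

A single point mass has dip 0; two equal point masses attain the maximum,
0.25; distinct samples lie in [1/(2n), 0.25].

### Power of the dip filter at the study's sample size

With only 18 pooled close-NHP observations the dip has limited resolution.
Simulation at the default generator settings (component sd 1, equal mixture
weights, values rounded to 0.1):

| mixture separation | median dip | P(p < 0.05) | cascade exclusion (BH) |
|---|---|---|---|
| 4 sd | 0.098 | 0.26 | — |
| 5 sd | 0.114 | 0.57 | ≈ 15% |
| 6 sd | 0.133 | 0.86 | ≈ 45% |
| 8 sd | 0.158 | 0.99 | ≈ 82% |
| 10 sd | — | — | ≈ 92% |

(The uniform-null 95th percentile of the dip at n = 18 is ≈ 0.110.) A
5-sd-separated mixture is therefore only weakly detectable at this sample
size, and the acceptance check asserting ≥ 90% exclusion at 5 sd fails
honestly; ≥ 90% exclusion is reached near 10 sd separation. The unit test of
dip power asserts the 8-sd regime, which the statistic reliably detects.
By contrast a 4-copy human expansion (148 vs 26 haplotypes, rank-sum under
Bonferroni) and a 4-sd distant shift (K-S, 8 vs 18) are both recovered at
≈ 100%, and 20,000 all-conserved loci across 10 seeds produce zero false
heSTR calls.

## Genotyping

The reference panel keeps `Simple_repeat` records with ACGT motifs of 1–6
bp. Motifs are canonicalized as the lexicographic minimum over cyclic
rotations of the motif and of its reverse complement; tract motifs are
reduced to primitive form (never reported as a repetition of a shorter
unit). Localization anchors the 500-bp flanks with exact 21-mer seeds, slid
inward in k-sized steps when the outermost seed carries a mismatch; among
candidate anchor pairs the longest region wins, mirroring the
longest-mapped-region rule; externally produced alignment intervals can be
substituted, with only the longest-region rule applied. A full aligner is
deliberately not reimplemented — the bespoke logic of interest is the
region/tract selection. Tract detection finds maximal perfect runs
(`s[i] == s[i+m]`, m = 1..6) and reports copies = length / motif length;
when several tracts match the expected canonical motif, the one minimizing
`|left_gap − 500| + |right_gap − 500|` (L1 over both boundaries, ties to the
smaller start) is called. Tracts are perfect by construction
(purity 1.0); mismatch-tolerant detection is out of scope. Coordinates are
0-based half-open throughout.

## Synthetic data

The cohort generator draws copy numbers as normals truncated below at 1 and
rounded to 0.1 copies — the simplest generating model whose unimodality the
dip filter should accept; `base_sd` defaults to 1.0 copies and is
deliberately configurable because real per-locus variances are not
characterized here. Scenarios: `conserved` (one mean for all clades),
`human_expanded` (mean + effect in humans only), `close_multimodal`
(symmetric two-component mixture, means ± effect/2, in close NHPs only),
`distant_shifted` (mean + effect in distant NHPs only). Missingness is
i.i.d. per cell — real missingness (mapping failure) is locus-correlated,
but i.i.d. suffices to exercise the coverage filter. Genome fixtures plant
pure tandem tracts inside i.i.d. uniform flanks whose 21-mers are rejection
sampled against collisions, with flank-adjacent bases chosen so the tract
cannot extend into a flank; SNVs mutate flank bases only (substitution may
resample the same base, so the realized rate is 3/4 of nominal). What
passing tests show about real data is therefore limited: perfect tracts and
unique flanks make genotyping exactly recoverable by construction, and real
assemblies (impure repeats, repetitive flanks, assembly errors) will be
harder; the value of the fixtures is end-to-end verification of the
selection logic and statistics, not a claim about real-genome accuracy.

## Interval and enrichment layer

Overlap and closest-distance queries are computed per chromosome with
sorted-array scans and are property-tested against O(n·m) brute force;
strand is carried but ignored. Fisher enrichments use the exact
hypergeometric two-sided p (scipy) with the sample odds ratio ad/bc,
Haldane-Anscombe +0.5 applied (and flagged) only when a cell is zero — a
conditional-MLE odds ratio, as some R defaults report, may differ slightly.
Enhancer-style proximity uses symmetric slop (10 kb default sweepable to
40 kb). The promoter is TSS ± 3 kb; category precedence is promoter > exon >
intron, with intergenic meaning no promoter or gene-body overlap. The
permutation test resamples size-matched locus sets from the ncSTR pool
(statistic supplied by the caller) with the +1 empirical correction.
Random-effects pooling is DerSimonian–Laird, cross-checked in the tests
against R's `metafor::rma(method = "DL")`.

## Expression and motif layers

Fold changes are computed on a counts-per-million scale with a pseudocount
(default 1), averaging replicate conditions; gene-set shift tests use the
same rank-sum as the cascade, BH across conditions at q < 0.1, with
"human > NHP" as the fixed tested direction. Pseudotime bins are equal-count
(quantile) bins, 100 by default, so no bin can be empty. The GSEA-style
ranked enrichment uses weight exponent 1 by default; at exponent 0 it
reduces to the K-S distance between member and non-member rank
distributions, which the tests exploit as an analytic oracle. PWM score
thresholds discretize log-odds scores to 0.01-bit steps by default and
convolve per-position distributions exactly; per-TF bias uses flank
occupancy (≥ 1 hit per locus's concatenated flank unit) rather than raw site
counts, because Fisher's test needs exchangeable units — raw counts remain
available from the scan output. Cross-species OR comparison is a one-sided
Wilcoxon signed-rank on per-TF OR differences, zeros dropped.

## Numerical and reproducibility choices

Every stochastic component takes an explicit seed (generators refuse to run
without one); the dip null table is cached per (n, n_boot, seed) and derived
via `SeedSequence([seed, n, n_boot])`, so classification is bit-reproducible
and outputs are written with fixed float formatting to make whole-pipeline
runs byte-identical. Problem sizes in the acceptance script (2,000-locus
null runs over 10 seeds, 500-locus recovery runs, 200-locus genotyping
fixtures) were chosen to estimate rates to within a few percent while
keeping a full run in the low minutes on one CPU.

## Known limitations

- The dip filter is under-powered at 18 observations (table above); this is
  a property of the study design, not of the implementation.
- The rank-sum normal approximation deviates from exact enumeration by up
  to ~0.08 at the smallest oracle sizes (n = 5–8 with ties); at the
  cascade's 148-vs-26 comparison the approximation error is negligible.
- Exact two-sample K-S p-values assume a continuous null; with heavily tied
  data they differ from the label-permutation p by design.
- Genotyping assumes locally unique flanks and perfect tracts; nested,
  compound or impure repeats and motifs > 6 bp are out of scope.
- Hi-C processing, TAD calling, liftover, per-gene differential-expression
  modelling and external-database enrichment are consumed as inputs, never
  computed.
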