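# Methods

## The problem

In a heterozygous individual, the two alleles of a gene can contribute
unequally to its transcript pool — allelic expression imbalance (AEI).
Because both alleles sit in the same nucleus, trans-acting factors affect
them equally; a reproducible imbalance therefore points to a *cis*-acting
regulatory difference (promoter SNPs, methylation, imprinting).  A practical
survey design measures, at an exonic marker SNP (cSNP), the percentage of
each allele incorporated during pyrosequencing of cDNA from heterozygous
animals, and compares it against the same assay run on their genomic DNA,
which is necessarily 1:1.

pyroaei implements the complete computational side of such a survey:
genotyping heterozygotes in silico by (forced-)PCR-RFLP, turning allele
percentages into standardized allelic ratios with a 60:40 decision rule,
summarising and testing imbalance per gene and tissue, and screening
promoter sequences for candidate *cis* mechanisms (CpG islands, SNPs inside
transcription-factor binding motifs, allele-dependent CpG dinucleotides).
A synthetic-data generator reproduces the statistical structure of the
study design so every stage is testable without downloads.

## The AEI statistic

For one measurement with allele percentages `(pct_a, pct_b)`,
`pct_a + pct_b = 100`, the allelic ratio is `r = pct_a / pct_b`.  For each
gene, the heterozygous-gDNA reference is the arithmetic mean of the gDNA
ratios, `m = mean(r_gDNA)`; every cDNA ratio is standardized as `r* = r/m`,
which removes the assay-specific technical skew (gDNA should be 1:1, so `m`
measures exactly that skew).  The standardized majority-allele percentage
is `p* = 100·r*/(1+r*)`; a sample is called **imbalanced** iff
`p* ≥ 60` or `p* ≤ 40`, boundary inclusive (exactly 60.0 is imbalanced —
documented and configurable via `RunConfig.imbalance_threshold_pct`).
The **folded ratio** `max(r*, 1/r*) ≥ 1` neglects direction; per gene and
tissue we report per-direction group means ± sample SD (n−1) of folded
ratios over imbalanced samples, and the overall mean folded ratio over all
samples.  Monoallelic rows (one allele at 0 %) are capped at 99.5:0.5
(ratio 199) and flagged, keeping means finite while preserving the
"nearly monoallelic" reading.

Significance is a two-tailed Welch (unequal-variance) two-sample t-test of
cDNA folded ratios against gDNA folded ratios; a one-sample variant
(cDNA folded vs 1.0) is available behind a flag.  In the pipeline driver
the gDNA folded ratios enter the test on the same standardized scale as the
cDNA (each gDNA ratio divided by `m`): otherwise the test would compare
bias-free cDNA against bias-carrying gDNA and reject for balanced genes
simply because standardization worked.  Degenerate zero-variance inputs
return p = 1 when the means agree.  No multiple-testing correction is
applied across genes/tissues by default (the survey design applies none);
`statsmodels`-style BH correction can be layered on by the user.

A note on exactness of allele relabelling: swapping the A/B labels inverts
every ratio.  Because the reference is an *arithmetic* mean,
`mean(1/r) ≠ 1/mean(r)`, so re-deriving the reference from relabelled gDNA
rows is not exactly equivariant.  `GdnaReference.relabelled()` therefore
defines relabelling as `m → 1/m`, under which calls, folded ratios and
summaries are exactly preserved with directions flipped; re-averaging
differs at O(variance of the gDNA ratios), i.e. third decimal place at
typical deviations.

## Heterozygote selection

Only heterozygotes are informative, so a gene enters the expression
analysis only if its heterozygote count reaches
`ceil(min_het_fraction × n_animals)`; the defaults (12.5 %, 40 animals)
give a minimum qualifying count of 5.

## In-silico PCR-RFLP and forced-RFLP

Primers bind by exact match, except at declared *forced* positions (at most
one per primer, within the last 8 nt of the 3' end) where any template base
is accepted; amplification substitutes both primer sequences into the
product, so forced bases are physically present in the amplicon.  Digestion
finds every IUPAC recognition-site occurrence on either strand, cuts at the
enzyme's top-strand offset (bottom-strand sites cut the top strand at
`site_start + len − cut_offset_bottom`), requires both strand cuts to fall
strictly inside the molecule (a double-strand break needs both), resolves
overlapping sites left-to-right under complete digestion (a site destroyed
by an earlier cut is not cut), and reports top-strand fragment lengths —
the agarose-gel readout.  Genotype calling compares the observed ladder,
deduplicated by length as a gel would, against the two expected allele
patterns; a heterozygote shows their union; two identical expected patterns
are an uninformative assay.  The forced-RFLP generator places the forward
primer immediately 5' of the SNP with one substitution (preferring the
penultimate 3' position, as a terminal mismatch would abort extension at
the bench), so that the site completes for exactly one allele in the
amplicon and for neither allele in the unamplified template.

Out of scope by design: thermodynamic primer design, partial digestion,
methylation-sensitive enzyme behaviour.

## Promoter analysis

CpG islands use the classic Gardiner-Garden/Frommer criteria — length
≥ 200 bp, G+C ≥ 0.5, CpG observed/expected ≥ 0.6 with
`obs/exp = n_CpG·L/(n_C·n_G)` — via a 1-bp-step sliding window, merging of
qualifying windows, and trimming of each merged interval to its maximal
(longest, then leftmost) sub-interval satisfying all three criteria, which
exists because at least one window did.  N bases break windows.  This is
the documented classic algorithm, not any specific genome-browser variant;
boundaries of detected islands are therefore fuzzy at the window-length
scale (a strong island dilutes through up to ~2 window lengths of flanking
sequence while the criteria still hold), which is why island tests assert
overlap with the planted truth rather than exact coordinates.

The motif scanner scores log-odds in bits against a uniform background
with additive pseudocount 0.25 per matrix cell; hits are thresholded on the
min–max normalised score (0 accepts everything, 1 only the optimal word;
default 0.8), and minus-strand hits are reported in plus-strand
coordinates.  SNP annotation uses TSS-relative 1-based coordinates with no
position 0 (−1 is the base 5' of the start).  The CpG effect of a SNP is
classified from CG occurrences in the two allele sequences over a ±1 bp
window: `creates`, `destroys`, `none`, or `shifts` when both alleles carry
the same number of CGs at different offsets — the situation of a C[C/G]G
context, where the C allele forms CG at (−105, −104) and the G allele at
(−106, −105) when the SNP sits at −105.

## The synthetic-data generator

The generator encodes the study conditions; it is the fixture factory for
every test.

**Genotypes.**  Hardy-Weinberg draws for 40 animals by default, with a
marker panel whose allele frequencies span per-SNP heterozygosity from
roughly 15 % to 67 %.

**gDNA technical bias.**  The deviation `d` of a heterozygous gDNA
measurement from 50 % is signed half-normal truncated at the hard maximum
(default 8), with the scale solved numerically so the post-truncation mean
of |d| equals the target (default 3).  This family needs `mean < max/2`
(the truncated-uniform limit), which is validated.  Draws use the inverse
CDF, so they are deterministic and vectorisable.

**cDNA imbalance archetypes.**  Each gene/tissue preset draws true folded
ratios per direction group from a lognormal moment-matched to the group's
natural-scale mean ± SD (support > 0 and right-skew fit groups ranging from
1.6 to near-monoallelic ~31; the within-group distribution is not published,
so lognormal is this package's choice).  Group counts are fixed by
largest-remainder rounding of the group weights, mirroring the fixed
per-tissue counts of the emulated survey (e.g. 7 of 9 toward T in the
IGF2-pituitary preset, groups 31.37 ± 7.37 and 15.67 ± 10.1).  Samples not
in a direction group draw a mild "balanced" fold ratio, lognormal
mean 1.2, SD 0.12 — the value consistent with back-calculating the
balanced-group contribution from the presets where the printed overall and
group means are mutually consistent.  (Some printed overall means are not
arithmetically consistent with their group statistics, so exact
reproduction of the summary table is not a target.)  Draws above 199
(99.5:0.5) are capped and logged.

**Measurement noise.**  Applied on the log-ratio scale as mean-one
lognormal with `σ = noise_sd_pct / 25` (the Jacobian of percent vs
log-ratio at 50:50), default `noise_sd_pct = 1.5` — a typical
pyrosequencing replicate SD.  The mean-one correction makes the noise
unbiased on the ratio scale, so simulated group means center on their
targets after the pipeline's standardization.

**Bias coupling.**  `simulate_experiment` draws one assay bias per
gene/experiment and applies it to both the gDNA rows (plus replicate
jitter, truncated at the hard maximum) and the cDNA rows — the shared
technical skew that gDNA standardization exists to neutralize.  The
standalone `simulate_gdna_measurement` remains i.i.d. per draw.

**Promoters and RFLP templates.**  Backgrounds are first-order Markov
sequences at 40 % GC with a CpG depletion factor 0.25 (obs/exp ≈ 0.25), so
islands planted at, e.g., GC 0.65 / obs-exp 0.75 are unambiguous; planted
islands are re-verified against the detection criteria and resampled if a
draw misses its targets.  RFLP generators build templates whose flanks are
verified free of confounding sites, and return truth (cut allele, site
span, SNP position) alongside the assay.

**What the generator does not emulate** — and hence what green tests do not
demonstrate about real data: read-level pyrosequencing chemistry
(dispensation orders, homopolymer artifacts), pedigree/relatedness,
parent-of-origin effects, RNA degradation or reverse-transcription bias,
and real promoter composition (isochores, repeats).  Recovery results on
synthetic data bound what the pipeline can do when its measurement model is
correct, not the field error of the assay.

## Numerical choices and problem sizes

Percent pairs must sum to 100 within 0.1; generated rows sum exactly.
Threshold comparisons are plain floating-point `>=`; the 60.0 boundary is
representable exactly for the canonical (60, 40) case.  Calibration checks
run at: 10,000–20,000 gDNA draws (mean deviation within 3 Monte-Carlo SEs
of 3.0, maximum ≤ 8); 1,000 simulated IGF2-pituitary experiments through
the full pipeline (T-group mean folded ratio within 3 MC SEs of 31.37);
5,000 null replicates for the t-test type-I error (required within
[3.5 %, 6.5 %] at α = 0.05; observed ≈ 5.1 %); 1,000 random amplicons for
digestion conservation; 100 sequences for scanner/oracle equivalence; and
50 + 50 promoter fixtures for island recall (100 %) and background false
calls (0).  These sizes keep the whole suite around ten seconds on one
core while leaving Monte-Carlo error well below the tolerances tested.

## Known limitations

* The island detector implements the classic criteria, not any specific
  browser-track variant; published island coordinates from such tools may
  differ at the boundary scale.
* The trimming step's longest-then-leftmost tie-break makes coordinates
  reproducible but not reflection-symmetric in the rare case of ties.
* Arithmetic-mean standardization (kept for fidelity to the emulated
  procedure) makes end-to-end allele relabelling only approximately
  equivariant; a geometric mean would be exact but is not what the
  procedure specifies.
* The Welch test on folded ratios treats n≈9 skewed samples; its level is
  adequate (see calibration) but p-values for near-monoallelic groups are
  driven by a few large values and should be read qualitatively.
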