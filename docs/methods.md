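# Methods

This note documents the statistical procedures poolcoev implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions. It states no
empirical result that the test suite does not itself compute.

## Coordinate and data conventions

All intervals are 0-based half-open internally; VCF output converts to
1-based, BED stays 0-based half-open. The strain panel is a pre-computed
multiple alignment (whole-genome alignment is out of scope); contigs carry
a role label, `chromosomal` or `plasmid`, because chromosomal depth is the
normalizer for every copy-number and HGT-frequency ratio. All output files
carry provenance headers (tool version, config hash, seed) and no
timestamps, so a rerun with the same configuration is bit-identical.

## Strain composition

Diagnostic sites are alignment columns with a biallelic 1-vs-rest
substitution pattern: exactly one strain carries the minority allele and
every other strain the shared background allele. Columns containing gaps,
N, any other ambiguity code, or more than two alleles are excluded —
conservative, and it keeps the "single substituted strain" definition
literal. Two-strain panels yield no diagnostic sites (the 1-vs-rest
pattern is then ambiguous).

At each usable site (depth ≥ `min_depth`, default 10 — sites thinner than
this make frequency ratios too noisy to be worth one vote each) the
diagnostic-allele frequency is an independent estimate of the strain's
abundance. The per-strain point estimate is the **half-sample mode**:
recursively keep the minimum-width window containing ⌈n/2⌉ of the sorted
values (leftmost window on ties) until ≤ 3 points remain, then average the
two closest. HSM was chosen over kernel-density modes because it is
deterministic, O(n log n), bandwidth-free, and robust for the skewed
unimodal frequency distributions that pooled read sampling produces; a KDE
mode (Scott bandwidth, 512-point grid) is available behind
`method="kde"`. Estimates are clipped to [0, 1] and **not** renormalized
to sum to one; the residual 1 − Σ is reported as a diagnostic of
unattributed mixture mass. Strains with fewer than `min_sites` (default
20) usable sites are estimated anyway but flagged low-support.

## Variant filters

Order: (i) coverage quantile, (ii) strand bias, (iii) indel collision,
(iv) MAF. Only step (i) is order-sensitive (its quantiles are computed on
the pre-filter depth distribution); (ii)–(iv) commute, which the suite
property-tests. Choices the source description left open, fixed here:
quantiles are per-sample (not pooled across samples) with linear
interpolation; samples with < 50 records skip the quantile step with a
warning rather than estimating meaningless tails; "above 5%" is read
strictly (5/100 fails, 6/100 passes); the strand-bias test is the
two-sided Fisher exact p on [[alt_fwd, alt_rev], [ref_fwd, ref_rev]] at
α = 0.05. Upstream caller-specific pre-thresholds are subsumed by the
explicit Fisher filter. Note the perfectly unbalanced 20/0 vs 0/20 table
has two-sided p = 2/C(40,20) ≈ 1.45e-11 — twice the one-sided tail,
because the table is symmetric.

## CNV detection

The detector targets pooled samples, where a duplication carried by a
fraction f of one population's individuals shifts that population's
coverage by only 1 + f(CN−1): per-sample depth is converted to fractional
(tie-averaged) ranks, normalized by the number of positions so samples of
different sequencing depth and breadth are comparable; the sample variance
(n−1 denominator) of each position's normalized rank across samples is the
detection statistic; its right tail is screened for outliers. Ranks are
computed genome-wide across contigs (a per-contig switch exists).

Outlier extraction re-specifies the "method I, normal fit" procedure of
the R `extremevalues::getOutliers` function: sort the variances, fit
y = μ + σ·Φ⁻¹((i+0.5)/N) by least squares over the central 10–90%
quantile band, and flag values whose expected count under the fitted
normal, N·(1−Φ((y−μ)/σ)), is below ρ (default 1). Only the right tail is
screened — CNVs raise rank variance; anomalously *low* variance is not a
CNV signature. Flagged positions closer than 100 bp (strict) merge into
one region. Per-sample copy number is the region's median depth divided by
the median depth over chromosomal positions; contig-level copy number uses
mean-depth ratios, with a variance from 10,000 positions drawn with
replacement.

Two calibration facts the acceptance suite measures and that users should
know:

* **The statistic needs shared coverage structure.** If coverage were
  exchangeable across positions (iid Poisson per position and sample), a
  null position's ranks across samples would be iid uniform — rank
  variance ≈ 1/12 with a wide spread — while a CNV carried by half the
  samples raises the expectation only to ≈ 0.10. No calibrated threshold
  separates those. Real libraries share a systematic positional coverage
  profile (GC content, mappability, library chemistry), which pins each
  null position's rank to a consistent value across samples and gives the
  statistic its power; the synthetic generator reproduces this with
  `simulate_coverage_bias` (lognormal per-position multiplier, unit mean,
  CV 0.15 — a typical magnitude for bacterial Illumina coverage bias —
  shared across samples, default off). Under that structure, planted
  CN-2 duplications in half the samples are recovered with truth Jaccard
  ≈ 0.99 and copy-number error < 0.05.
* **The normal fit under-covers its own tail.** The null distribution of
  a rank variance over 10 samples is right-skewed, so the QQ-normal fit on
  the central band underestimates the extreme right tail: at ρ = 1 on
  100-kb null Poisson matrices the suite measures ≈ 2.6 false flags per
  run instead of the nominal 1 (a per-position false-flag rate of
  2.6e-5). This is a property of the re-specified method, left as is;
  raising ρ or transforming the variances would change the procedure.

## HGT detection

Reads are competitively assigned by SAM `NM` edit distance: a read belongs
to a strain iff that strain's distance is strictly lower than every
other's; any tie excludes the read, and a strain the read did not map to
counts as infinitely distant. Donor-assigned coverage is piled on donor
coordinates; maximal runs with depth ≥ 1 are extended across internal
gaps of ≤ 100 bp (read sampling at low fragment frequency would otherwise
shatter true fragments; the tolerance mirrors the CNV merge distance) and
kept iff they span ≥ 1 kb. Fragment frequency is the median
donor-assigned depth in the fragment over the median depth of the focal
strain's chromosomal contigs; it may exceed 1 for multicopy elements and
is not clipped. Continuity is evaluated per sample and results reported
per sample. The treatment screen flags fragments whose per-treatment mean
frequencies have sample variance strictly greater than 0.04.

## Windowed population genetics

Read depth proxies the number of sampled chromosomes, so the estimators
let sample size vary per site: θ̂_W sums 1/a₁(nᵢ) over segregating sites;
π̂ sums the per-site unbiased heterozygosity [nᵢ/(nᵢ−1)]·2pᵢ(1−pᵢ). Sites
need coverage ≥ 2 and minor-allele frequency strictly above the MAF
threshold (default 0.05; the minor-allele reading drops near-fixed sites
on both sides, and at maf = 0 exactly the segregating sites remain).
Tajima's D uses the classical variance constants at n = round(mean
coverage of the window's retained sites) — median and harmonic-mean
summaries are exposed — and is missing when S = 0 or the variance term
degenerates. Windows are coordinate-anchored, 10 kb wide with 5-kb steps,
half-open, with trailing partials normalized by their true length.
Pool-size binomial double-sampling corrections are deliberately not
implemented (documented simplification; the per-site forms above are the
coverage-as-sample-size model, and the classical-limit reduction is the
anchor the suite verifies to 1e-9).

## Association statistics

WLS is the closed-form weighted normal-equations solution with a
two-sided t-test on the slope (n−2 df); estimates and p-values are
invariant to weight rescaling. The nested ANOVA is a fixed-effects model —
transfer + treatment + replicate-within-treatment (a fixed blocking
factor, no REML, since simple effect tests are reported) +
transfer×treatment — with Type-II sums of squares, chosen to tolerate the
mild unbalance that extinct replicates produce. Replicate labels are
re-coded within treatment so globally unique labels cannot produce
structural-zero cells. Terms with zero sum of squares report F = 0, p = 1;
with zero residual variance, positive-SS terms report F = ∞, p = 0.
Spearman's ρ is the Pearson correlation of tie-averaged ranks with exact
full-enumeration permutation p for n < 10 and the t approximation
otherwise. BH-FDR is the standard step-up with the running-minimum
formulation, order-stable. The candidate screen requires variation in ≥ 4
replicate populations, treatment q < 0.05 with transfer and interaction
q ≥ 0.05, the > 0.04 treatment-variance rule for HGT features, and a
functional-consequence annotation; excluded samples (e.g. a replicate
dominated by a different strain) are handled by a config blacklist, not
hard-coded.

## Synthetic data: what it emulates, and what a green test establishes

The generator works at the summary level the pipeline consumes —
per-position depth tracks, diagnostic-site base counts, assignment
records — not FASTQ; mapper error profiles and indels are not simulated.
Strain genomes are an ancestral random sequence with independent per-site
substitutions at the divergence rate (default 1%, five strains, matching
the diverged-but-alignable regime of a within-species panel); coverage is
Poisson at `mean_coverage` (default 100×; scaling to 1,000× is a config
choice) with a negative-binomial overdispersion hook (off by default) and
the optional shared bias profile described above; sequencing error is a
symmetric per-base substitution (default 0.001 in the demo pipeline)
applied to allele counts; planted CNVs multiply coverage by
1 + f(CN−1); planted HGT fragments add donor-assigned Poisson coverage at
`mean_coverage × frequency`. Haplotype windows place infinite-sites
mutations per site (segregating with probability θ·a₁(n), derived count
from the neutral 1/i spectrum), which reproduces E[θ̂_W] = E[π̂] = θ but
carries no linkage, so window-statistic variances are smaller than a
coalescent's. One global seed drives a SeedSequence-spawned hierarchy, so
each sample is independently reproducible.

Green parameter-recovery tests therefore establish that the estimators
invert the generator's model; they do not establish robustness to mapping
bias, indel misalignment, GC-dependent error, or linked selection, none of
which the generator produces.

## Known limitations

* Variant calling itself (and structural-variant calling) is out of
  scope; the filter module consumes VCF/TSV from an external caller.
* The CNV outlier rule's nominal false-positive budget under-covers by a
  factor ≈ 2.6 (see above).
* HGT donor attribution is limited to the panel strains; transfer
  mechanism is not inferred.
* Association models are fixed-effects only; no mixed-model variants.
* Strain-composition confidence intervals are not provided.
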