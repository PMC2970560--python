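# Methods

## Directional association testing

Marker allele frequencies are compared between cases and controls on the 2N
allele scale: each fully called genotype contributes two alleles, genotypes
with any missing allele are dropped per SNP (pairwise deletion, no
imputation), and alleles within an individual are treated as independent.
The test is the one-sided Fisher exact test with the rejection direction
fixed *a priori* per SNP by the reference disease's risk allele:

p = P(X ≥ x_obs) for X hypergeometric with all margins fixed,

including the observed table in the tail (the standard exact convention; a
mid-p variant is available behind a flag, default off). A table with a zero
margin carries no directional information and returns p = 1 with a warning
rather than raising. An effect opposite to the reference direction yields a
large p by construction — there is no folding or two-sided fallback, which is
what makes a panel of such tests interpretable as shared-direction overlap.

Family-wise correction is Bonferroni, min(1, p·n), with the family defaulting
to the non-established markers only (established loci — e.g. an MHC or IL23R
proxy — are reported with nominal p and excluded from the family; with 39
markers of which 2 are established, n = 37). QC follows genotyping practice:
samples, then markers, with call rate below a threshold (default 0.97) are
excluded with a report, and controls are checked per marker with the exact
conditional Hardy–Weinberg test (enumeration over heterozygote counts given
the allele totals, summing configurations no more probable than the observed
one). HWE departure in controls flags assay artefacts, not association.

## Combined evidence and the truncation scan

For the m markers below family-wise significance the combined statistic is
S = Σ ln(1/pᵢ), computed in nats. Under independent uniform nulls each term
is Exp(1), so S ~ Gamma(m, 1) and 2S ~ χ² with 2m df — Fisher's combination
test. Significance is assessed empirically: S is compared against n_sims
(default 10,000) simulated null sums of ln(1/rᵢ) with rᵢ ~ Uniform(0,1), and

empirical p = #{null ≥ S} / n_sims.

Ties count toward exceedance (a null that *reaches* S argues against
significance) and the plain ratio is used rather than (count+1)/(n_sims+1):
the plain estimator is what maps an exceedance count of 7 in 10,000 onto
exactly 0.0007; the add-one variant, which can never return zero, sits behind
a flag. When the count is zero the function warns that the true p is only
bounded above by 1/n_sims, and the display series plots that bound. The
Gamma(m, 1) upper tail is carried alongside every empirical p as a
closed-form cross-check; the Monte Carlo p itself is invariant to the log
base since observed and null statistics scale together.

The sequential truncation scan sorts the panel by ascending p (stable order
for ties), and at step k removes the k smallest p-values and recombines the
remaining m − k against a fresh uniform null of matching size, down to two
remaining values. Each step's null uses a generator seeded deterministically
from (master seed, step), so scans are reproducible and steps are
independent; step statistics follow by exact subtraction of ln(1/p_dropped),
so the identity S_k = S_{k−1} − ln(1/p_dropped) holds to the last bit. Note
the scan is conservative by construction: the retained values are the m − k
*largest* of m order statistics, which are stochastically larger than m − k
fresh uniforms, so significance decays quickly once the true signal is
removed — the step at which it dies is a lower bound on the number of
signal-bearing tests, not an unbiased count.

The display series mirror the standard four-series panel figure: per rank i,
log10(1/p) of the nominal p, of the Bonferroni-adjusted p, of the expected
null order statistic i/(m+1), and of the scan step starting at that rank,
with a horizontal reference at log10(1/α).

## qPCR quantification and the eQTL arm

Amplification efficiency per gene comes from a dilution series of Cq against
log10 concentration: the least-squares slope gives the per-cycle
amplification factor 10^(−1/slope). A perfect doubling assay has slope
−1/log10(2) ≈ −3.3219 and factor 2. Percent efficiency is reported as
(factor − 1)·100, reconciling the common shorthand that prints a factor of
2.05 as "E = 105%"; both numbers are kept on the fitted curve object. A
non-negative fitted slope (an inverted dilution series) is an error.

Relative quantities are efficiency-corrected, quantity ∝ factor^(−Cq), and
the target is normalized by the geometric mean of three reference-gene
quantities. Two identities pin the arithmetic: when all genes share one
amplification factor, a common Cq shift cancels exactly, and multiplying
every reference quantity by c divides the normalized ratio by c. Samples
with any missing Cq are excluded with a warning.

Group differences use the tie-corrected Kruskal–Wallis H with Dunn's
pairwise z tests on mean ranks (tie-corrected pooled variance), two-sided
normal p-values, Bonferroni-adjusted over all pairs (unadjusted values are
also emitted); a totally tied sample is vacuous (H = 0, p = 1) rather than
an error. Genotype–expression association is the tie-corrected Spearman
correlation between the risk-allele count (0/1/2 — heavily tied by design)
and normalized expression, reported for the whole cohort and per tissue;
a subgroup with constant genotype has an undefined rank correlation and is
reported as missing with a reason.

## Synthetic data: what it emulates and what it does not

The generators exist because studies of this design rarely deposit
genotypes; they reproduce the *assumptions* of the analysis, so green tests
certify the statistics, not any particular cohort.

* **Genotype panels.** Controls are Binomial(2, f) risk-allele dosages (HWE
  at the control frequency f ∈ (0, 0.5]); cases are HWE at
  p_case = OR·f/(1 − f + OR·f), the allele-scale solution of a
  multiplicative allelic odds ratio — matching the allele-frequency
  comparison the test performs. Defaults mirror the study scale: 182 cases
  against a 1000-control panel. No linkage disequilibrium between SNPs and
  no population structure are modeled; the generator cannot probe robustness
  to stratification.
* **P-value panels.** Nulls are exact Uniform(0,1); alternatives follow the
  power-function law with CDF p^a, a ∈ (0,1] (sampled as U^(1/a)), chosen
  for closed-form control of low-p enrichment; a = 1 degenerates to uniform.
  The default scan-recovery condition plants 5 alternatives with a = 0.15
  among 36 tests. Real panels have discretely supported, super-uniform exact
  p-values and correlated tests; the generator has neither.
* **Expression cohorts.** Default group sizes 21/39/10/14
  (control/CD/UC/AS) copy the colonic arm of the motivating study design;
  tissue is assigned 60/40 colon/ileum. Log expression is a group baseline
  (zero by default) plus an additive per-allele eQTL effect β·g plus
  N(0, 0.25²) biological noise; Cq values are back-computed at one cycle per
  doubling with N(0, 0.15²) technical noise, reference genes are constant.
  The noise scales are typical of replicate qPCR on biopsies; they are fixed
  study conditions, not fitting knobs. Amplification efficiency differences
  between genes, reference-gene instability, and RNA-quality effects are not
  simulated.
* **Standard curves.** Points on a line at log10 dilutions 0, −1, … with
  optional Cq noise.

Every generator consumes an explicit seed and a single
`numpy.random.Generator`; identical seeds are bit-reproducible.

## Numerical and design choices

* Natural log for S; only the closed-form Gamma tail depends on the base.
  Display series use log10 (configurable, display only).
* Exceedance estimator: plain count/n_sims (see above); ties count as
  exceedance.
* The HWE test works in log-space with a 1e−12 relative slack when summing
  probability ties.
* Direction is reported as +1 when the case risk-allele frequency is ≥ the
  control frequency, −1 otherwise.
* Drop-order ties in the scan follow stable input order.
* Positions are 1-based; alleles are panel-defined symbols with no strand
  handling; "." marks a missing allele.
* Problem sizes in the test-suite simulations (e.g. 2000 replicate null
  SNPs, 1000 null panels at 2000 null draws each, 200 scan-recovery seeds,
  500 null expression cohorts) were chosen so that 3-standard-error bounds
  are meaningfully tight while a full run of suite plus acceptance script
  stays interactive on a single CPU.

## Known limitations

* Independence between SNP tests is assumed throughout the combined
  statistic; no analytic treatment of LD-induced dependence is offered.
* Only Fisher-type log combination is implemented (no Stouffer, no
  minimum-p, no weighting).
* No logistic regression, covariate adjustment, or stratification
  correction in the association arm; no imputation.
* The qPCR arm starts from Cq values; raw fluorescence and melting-curve
  processing are out of scope.
* The truncation scan's stopping step is a conservative lower bound on the
  number of true alternatives (see above), and with Monte Carlo nulls its
  p-values have granularity 1/n_sims.
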