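# Methods and design notes

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer would want
spelled out.

## Directional regulon divergence

The question is whether the members of a predefined gene group (regulon,
GO term) shift coherently in one direction between two populations, given
per-gene differential-expression results. Two statistics are offered over
the regulon members significant at adjusted *P* < α (default 0.05):

- `sign_sum` (default): the sum of signs of the members' log2 fold
  changes; bounded by the member count, insensitive to effect magnitude.
- `ratio_sum`: the sum of the log2 fold changes themselves.

Both appear in the literature for this procedure, sometimes
interchangeably within one description; results therefore carry the mode
used. The null is resampling-based: groups of the same effective size are
drawn uniformly **without replacement** from all genes significant at the
same cutoff ("random gene groups" implies distinct genes), independently
across the default 10,000 draws. The two-sided empirical *P* uses the
add-one estimator `(1 + #{|null| ≥ |observed|}) / (n_perm + 1)`, which is
never zero and recovers the plain proportion as draws grow; ties at the
boundary count as extreme, with a 1e-12 tolerance so floating-point
summation order cannot break an exact tie. Two-sidedness is by absolute
value of the statistic, not by doubling a tail. Genes not significant at
the cutoff are excluded from the regulon's effective size *k* (they do
not contribute zeros); a regulon with *k* = 0 is untestable and gets no
*P* rather than *P* = 1. BH adjustment spans the testable sets only.

An important property of this design is that it is *conditional on the
significant set*: it asks whether the regulon is more directionally
coherent than random significant genes. If nearly all significant genes
belong to one coherent set, the test correctly reports nothing unusual —
null-power simulations must therefore plant background DE alongside the
focal set.

## Negative-binomial differential expression

Counts for gene *g*, sample *j* are modeled NB with mean μ = q·s_j and
variance μ + αμ². Normalization is staged: upper-quartile factors (75th
percentile of nonzero counts, rescaled to geometric mean 1) equalize
library sizes between lanes; an optional locally-weighted regression of
log(count + 0.5) on GC content (span 0.3) removes per-sample GC trends
with column totals restored; the test itself uses median-of-ratios size
factors on its input. Constant GC or a single gene makes the GC step an
identity with a warning.

Dispersion: per-gene pooled within-group method of moments on normalized
counts (`α̂ = (var − mean·E[1/s]) / mean²`, clipped at 0), a parametric
trend α(μ) = a0 + a1/μ fitted across genes by least squares with
nonnegative coefficients, and a 50/50 blend of trend and gene-wise value
(the blend weight is a parameter). Dispersions are floored at 1e-8, below
which the likelihood is effectively Poisson. Significance is a
likelihood-ratio test of a common normalized mean against per-group
means, referred to χ²(1); the mean MLE is found by vectorized Newton
iterations on log q (the score has the closed form Σ r(y−μ)/(r+μ)).
The per-gene log2 fold change is the ratio of normalized group means;
when one group is all zeros, 0.5 is added to both normalized means *for
reporting only* and the gene is flagged, and genes with zero counts
everywhere get *P* = 1. At three-versus-three replicates this test holds
its empirical type-I error near 0.06 at nominal 0.05 (measured over 200
null simulations) — slightly liberal, as is typical for
dispersion-estimated NB tests at this sample size — and BH discoveries
under the null remain rare.

Group-swap symmetry holds exactly: the LRT is invariant and the fold
change negates.

## Ka/Ks from private fixed SNPs

A SNP is *private and fixed* for population P when every non-missing
strain of P carries the alternate allele and every non-missing strain of
every other population carries the reference. A population with at least
one non-missing call is judged on its non-missing calls; a SNP missing in
all populations is uninformative. Multi-allelic records are rejected;
the analysis targets homozygous strain panels, so heterozygous VCF calls
are read as missing. Coordinates are 1-based in files and messages,
0-based internally.

Site counting is the counting-method definition: for each codon position,
the fraction of the three possible substitutions that are synonymous
(stop-creating changes count as nonsynonymous), summed over codons, so
N + S = 3 × codon count exactly; the standard nuclear genetic code is
hard-coded. Substitution proportions per site are corrected with
Jukes–Cantor, d(p) = −(3/4)ln(1 − 4p/3) (a raw-proportion mode ships for
sensitivity analysis, since the multiple-hit treatment behind published
intra-population Ka/Ks values is often unstated; at within-species
divergences the correction is nearly the identity). Ka/Ks is undefined
when Ks = 0; such genes are excluded from regulon and genome means (no
pseudocounts) and their number is reported. The regulon statistic is the
arithmetic mean of per-gene ratios — not the ratio of summed counts — so
with few SNPs per gene it is Jensen-inflated relative to the count-level
ratio; this affects regulon and null draws alike. The enrichment test is
one-sided (upper tail) over 10,000 same-size draws from all genes with a
defined ratio.

## Allele-specific expression

Reads are modeled as error-free single-end stubs on gene coordinates. A
read informs ASE only if it covers ≥ 1 diagnostic SNP and matches one
parent exactly over its full span; covering no diagnostic site is
*ambiguous*, matching neither parent exactly (including conflicting
parental matches at different covered SNPs) is *discordant*. This
reproduces unique exact-match mapping against concatenated parental
references, verified by brute force on all possible reads of a fixture
gene. Counts feed the NB test with alleles as groups and hybrids (≥ 2)
as replicates; the directional screen then runs unchanged on allelic
log2 ratios.

## Growth curves

Model: logistic OD(t) = K/(1 + ((K−N0)/N0)e^(−r(t−lag))) (flat during
lag), written in the overflow-stable form. `rate_per_hr` is the maximal
specific growth rate (natural log); doubling time = 60·ln2/r minutes.

Fitting is the sliding-window method on log2(OD − background), default
window 5 points (2 h at 30-min sampling): the maximal window slope gives
the rate, its reciprocal the doubling time, the intercept construction
the lag, and the OD gain the efficiency. Numerical choices that matter:

- **Background** defaults to 0, correct for pre-blanked readings and for
  the generator's curves; `"auto"` estimates it as the minimum of the
  first three readings, which is appropriate only when the inoculum is
  optically negligible next to the medium blank — subtracting a blank
  equal to the culture's own starting OD makes every early log-slope
  steeper than the true rate.
- Log values are floored at 1e-3 before the logarithm (no additive
  offset, which would damp slopes at low OD).
- Windows must stay above a **minimum signal** of 0.03 OD; below that,
  reader noise dominates the log-slope. Curves that never reach it fall
  back to all windows (they are usually flagged non-growing anyway:
  total gain < 0.1).
- The curve is smoothed with a 5-point centered moving average before
  the slope search. A moving average leaves a locally linear log-curve
  unbiased while damping noise, which otherwise inflates the maximum
  taken over many windows.

Achieved accuracy under the generator's conditions: noiseless
exponentials are exact to < 0.2%; with additive reader noise of 0.005 OD
the per-curve median relative error of the doubling time is ≈ 6%
(noise-floor-limited near the minimum usable OD); planted between-group
rate ratios are recovered within a few percent after averaging over
replicate groups. Comparisons use the two-sided Wilcoxon rank-sum test
(exact where sample sizes and ties permit; group sizes in this design
differ, so a paired test is not applicable), fold change of mean doubling
times, and t-based 95% CIs per group mean; at least three growing
replicates per side are required.

## qPCR

Technical replicates are collapsed by arithmetic mean Ct first (the
convention of the 2^−ΔΔCt method). ΔCt = Ct_gene − Ct_reference within a
genotype × biological replicate; ΔΔCt subtracts the calibrator genotype's
mean ΔCt per gene; relative expression is 2^−ΔΔCt, so adding any constant
to all Ct values of a replicate cancels. Replicates lacking the reference
gene are dropped with a warning. Median centering subtracts the median of
log2 values within a gene × strain-background set (output median exactly
0). Regulon comparisons pair genes across genotypes and use the two-sided
Wilcoxon signed-rank test, exact for n ≤ 25 when free of zeros; identical
vectors give *P* = 1 and a single gene is untestable.

## The synthetic-data generator

Defaults encode the study design the pipeline targets: two populations
("Malaysian", "WineEuropean") of 3 and 2 homozygous strains; 200 genes of
100 codons; 100 private fixed SNPs per population at a 50:50
nonsynonymous:synonymous split (overridable per gene set, which is how
elevated protein evolution is planted in a focal regulon); NB counts
with dispersion 0.05 around lognormal baselines (median ≈ 200 counts);
three 20-gene iron-metabolism-style regulons with planted log2 shifts of
−1 (iron starvation, iron transport) and +1 (iron toxicity response) in
the first population; triplicate logistic growth curves sampled every
30 min for 24 h (90-min doubling, K = 1.2, lag 120 min), with the first
population's doubling time 1.7× longer in the stress condition
(K = 0.96); additive Gaussian reader noise of 0.005 OD truncated at zero
(a proportional model is available); and Ct tables with 2 biological ×
3 technical replicates at noise 0.1 Ct, reference gene fixed and
unshifted. One global seed drives CRC-hashed per-stage substreams, so a
stage rerun in isolation reproduces the numbers it saw in a full run,
and identical configurations are byte-identical end to end.

Planted SNPs are placed only where the required codon effect exists
without creating a stop, each at a distinct site, and every planted site
is recorded with its population and codon-effect truth label; the
variants module recovers 100% of these labels, which is a test of the
pipeline, not of the generator's realism. What the generator does *not*
emulate: sequencing reads with base-call errors, mapping and reference
bias, lane batch effects beyond library size and GC trend, linkage
between SNPs, diauxic shifts in growth, or amplification-efficiency
variation in qPCR. Passing tests therefore demonstrate the statistical
machinery on clean, assumption-true data; they do not certify robustness
to those real-data artifacts.

## Problem sizes used in checks

The packaged checks run at desk scale, chosen to finish in seconds to a
few minutes while keeping Monte-Carlo error well inside the asserted
bands: permutation-versus-enumeration on universes of 6–12 genes with
50,000–100,000 draws; null calibration over 200 simulation seeds
(150–250 genes, 3 vs 3); planted-shift recovery pooled over 10 seeds of
500 genes; growth recovery over 20 seeds of 9 vs 9 replicate curves; the
full default pipeline (10,000 resamples) runs in well under a minute.

## Known limitations

- The NB likelihood-ratio test is mildly liberal at 2–3 replicates per
  group (empirical type-I ≈ 0.06 at nominal 0.05); interpretation should
  lean on the BH-adjusted values, whose null discovery rate is controlled.
- The directional test's *P* values are discrete (resolution 1/(n_perm+1))
  and, in sign-sum mode with small regulons, lumpy; ratio-sum mode gives
  finer granularity.
- Mean-of-ratios Ka/Ks is upward-biased at low SNP counts per gene
  (Jensen); comparisons against the same-universe null remain valid.
- The sliding-window growth rate inherits a small downward bias from
  logistic curvature within the measured window; it largely cancels in
  between-genotype fold changes, which is what the comparisons report.
- `apply_snps` handles substitutions only; indels and chromosome-to-CDS
  liftover are out of scope, as is SNP calling itself.
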