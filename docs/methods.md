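# Methods

This note documents the statistical machinery in `admixchron`: the models,
their assumptions, the defaults that matter, and what the synthetic test
suite does and does not demonstrate.

## f4-statistics and the block jackknife

For populations A, B, C, D the statistic is the average over usable SNPs of
(p_A − p_B)(p_C − p_D), computed from allele frequencies with
pseudo-haploid-aware allele accounting: a pseudo-haploid call contributes
one allele slot (its dosage halved), a diploid call two, and a male X call
one. Under a population tree in which (A,B) and (C,D) are symmetric clades
the expectation is zero; gene flow makes it systematically nonzero. Each
statistic uses every SNP at which its own four frequencies are defined
("allsnps" behaviour); a strict mask can force a common SNP set when exact
cross-statistic arithmetic is needed (the additivity identity
f4(A,B;C,D) = f4(A,B;C,E) + f4(A,B;E,D) holds exactly only then).

Standard errors come from a weighted delete-one-block jackknife over
contiguous genomic blocks (default 0.05 Morgans; one-block-per-chromosome
is used for dating). Per-block SNP counts are the weights; the variance is
Busing's weighted form, which reduces to the textbook delete-one jackknife
at equal weights. Blocks of this size are long enough that LD between
blocks is negligible, which is the assumption that makes the jackknife
valid.

No small-sample frequency unbiasing ("inbreed"-style corrections) is
applied: with pseudo-haploid single-allele sampling there is no
within-individual heterozygosity term to correct, and the block jackknife
absorbs the remaining sampling noise into the reported SE. This is a
deliberate simplification of the first release.

## Source-affinity regression

The f4 regression takes paired statistics (x_i ± s_xi, y_i ± s_yi) and fits
y = a + b·x by weighted least squares with weights 1/s_yi². Per-point
residual SEs are obtained by deleting one jackknife block, re-deriving
every point from its block-level replicates, re-fitting the line, and
taking the weighted-jackknife spread of that point's residual; residual Z
scores are residuals over these SEs. When no block replicates are
available the y-errors serve as a fallback residual scale. Block weights
for the refit are averaged across the contributing statistics — the exact
residual-resampling scheme used with real data is not uniquely determined
by its published description, so this documented variant is used
consistently.

## qpAdm-style mixture model

With sources S_1..S_k and rights R_0..R_m (R_0 the base right), the model
states that the target's statistic vector y_j = f4(T, R_0; R_j, R_0)
equals Σ_i w_i · f4(S_i, R_0; R_j, R_0) for mixture weights summing to 1.
Weights minimise (y − Xᵀw)ᵀ Σ⁻¹ (y − Xᵀw) subject to Σw = 1 (Lagrange
solution of the constrained GLS). The residual covariance Σ is estimated
by the weighted block jackknife; since Σ depends on w, the fit starts from
the jackknife covariance of y and iterates twice between covariance and
weights, which converges for all tested systems. When Σ is
ill-conditioned, a ridge of 1e-6·trace/m is added with a warning.

Weight SEs and their covariance come from delete-one-block refits of the
whole system. The model-fit tail probability is the χ² survival function
of the minimised quadratic form with (m−1) − (k−1) degrees of freedom —
the χ² approximation rather than a Hotelling correction, adequate for the
several-hundred-block panels used here and verified empirically: with one
source (a pure symmetry test) the fit P is uniform on [0,1] over null
replicates.

Identifiability requires rights that are differentially related to the
sources; a star-shaped outgroup panel makes X rank-deficient. The
synthetic default therefore includes one sister group per source lineage
plus two deep outgroups.

The sex-bias statistic is Z = (α_auto − α_X) / sqrt(se_auto² + se_X²)
between two independent fits of the same model on autosomes and on the X;
positive Z means the ancestry in question (Papuan by convention) is higher
on the autosomes, the signature of male-biased admixture from that source.

## Projection PCA

Axes are the singular vectors of the reference samples' genotype matrix
after mean centring and 1/sqrt(p(1−p)) normalisation per SNP; missing
entries contribute zero after centring. Non-reference samples are placed
by least squares on their non-missing sites only. No shrinkage correction
is applied, so projections of very sparse samples are biased toward the
origin — the PCA is an overview figure, not a headline number, and with a
two-population reference only PC1 carries structure.

## Admixture-LD decay dating

A single admixture pulse n generations ago leaves ancestry tracts of mean
length 1/n Morgans, so the covariance of local ancestry at genetic
distance d decays as α(1−α)·e^{−n·d}. Local ancestry is unobserved;
instead each SNP gets the weight w_s = p̂_1,s − p̂_2,s (source frequency
difference) and each individual the residual x_is = g_is/2 − μ_s, where
μ_s = (1−α)p̂_1,s + αp̂_2,s is the mixture mean. α is re-estimated
internally by least squares of the target mean frequency on the source
frequency difference (an override accepts an external value, e.g. a qpAdm
weight). Same-chromosome SNP pairs are binned by distance (default bin
0.001 M, maximum distance 1.0 M — distances are Morgans *throughout*, and
the generous maximum keeps the long-range LD of recent pulses); each bin
averages w_s·w_t·⟨x_s·x_t⟩ over individuals, normalised by Σ|w_s·w_t|.
Missing calls drop an individual from a pair.

The curve is fitted with A·e^{−n·d} + c over [mindis, maxdis] — a
geometric grid on n with the linear parameters solved exactly at each
step, then bounded local refinement. The default mindis of 0.005 M
discards near-zero bins contaminated by background LD. The affine term c
is fitted by default: it absorbs both genuine background LD and the
constant positive offset created by sampling noise in the source
frequencies (which correlates w_s with x_s identically at all distances);
it can be pinned to zero. The SE of n is a weighted delete-one-chromosome
jackknife of the complete fit (chromosomes, not sub-chromosome blocks,
because pairs span within-chromosome distances). The per-chromosome
numerator/denominator sums are retained, so the leave-one-out curves are
exact recombinations, and the curve of a merged target group is by
construction the pair-weighted combination of its parts.

The normalisation of the curve is this package's own; against other
implementations in this family it is expected to agree in the decay rate n
(the quantity of interest), not in the amplitude.

## Radiocarbon calibration

Calibration curves are (calBP, ¹⁴C age, 1σ) tables interpolated onto a
uniform 5-year grid; calBP counts years before 1950 CE. A reservoir
offset ΔR ± σ_ΔR shifts the marine curve's mean and adds σ_ΔR in
quadrature. Mixed marine/terrestrial calibration works in the ¹⁴C-age
domain: μ_mix = (1−p)μ_T + pμ_M and
σ_mix² = (1−p)²σ_T² + p²σ_M² + σ_p²(μ_M−μ_T)², with p the marine fraction
of dietary protein and σ_p its uncertainty — a first-order match to
OxCal's curve mixing, treated as an approximation.

A measurement m ± σ_m is calibrated under a flat calendar prior:
posterior(cal) ∝ N(m; μ(cal), sqrt(σ_m² + σ(cal)²)), normalised over the
grid. Reported summaries are the posterior mean and SD and the 95.4%
highest-density region, which may be a list of disjoint intervals; the
single printed interval convention is the envelope (oldest, youngest).
Directionally: more negative ΔR values give older calibrated dates, and a
larger marine diet fraction gives younger ones, because more of the
measured age is attributed to reservoir carbon.

## Calendar propagation

The admixture date is date = T + n·g (anchor date plus generations times
generation interval, all independent). The delta-method mode gives
sd = sqrt((ḡ·se_n)² + (n̄·se_g)² + se_T²) and a 1.96σ interval (the exact
multiplier, not 2.0). The Monte-Carlo mode draws the three inputs
(Gaussian for n and g; the full calibrated posterior for T when supplied)
and reports 2.5/97.5 percentiles; it differs from the analytic mode only
through the mild non-Gaussianity of the n·g product (the σ_n·σ_g
cross-term), and the two agree within 1% of the half-width for Gaussian
inputs. Monte-Carlo percentiles are preferred for headline intervals;
both are always computed. Integer generation CIs are rounded to the
nearest whole generation; calendar bounds are reported to the year with a
nearest-10 display option.

The threshold verdict asks whether the *entire* 95% CI predates a
reference horizon (e.g. a settlement date): strict inequality of the young
bound, so a bound exactly at the threshold does not pass. The sensitivity
table repeats calibration and propagation over a (ΔR, marine-fraction)
grid.

## Synthetic cohorts: what they emulate and what they do not

The generator draws ancestral frequencies q ~ Uniform(0.05, 0.95) and
population frequencies from the Balding–Nichols Beta(q(1−F)/F,
(1−q)(1−F)/F) with per-population drift F; nested populations (the sister
outgroups) re-apply the same draw to their parent's frequencies. Admixed
diploids carry two independent haploid tract sets per chromosome, with
Poisson(n per Morgan) breakpoints and i.i.d. ancestry redraw (Papuan with
probability α) — the standard one-pulse approximation whose ancestry
covariance is exactly α(1−α)e^{−n·d}, i.e. the model the dating module
fits. Genotypes are drawn per site from the local ancestry's source
frequency, pseudo-haploid collapsed (one allele kept uniformly at random),
and masked i.i.d. Sex bias is modelled directly as α_X ≠ α_autosome, with
haploid male X. Defaults are the conditions the statistics are designed
for: α_autosome = 0.40, α_X = 0.30, n = 30 generations, source drifts
0.10/0.12, sister-outgroup drift 0.08, deep outgroups 0.25/0.30, 5%
missingness, 22 autosomes of 1 Morgan. Toy calibration curves are linear
(slope 1 ¹⁴C yr per cal yr) with an optional sinusoidal wiggle and a
constant marine offset of 500 ¹⁴C years.

Deliberately not emulated: coalescent genealogical noise within
populations (frequencies are the truth; only binomial sampling noise is
added), recombination-rate variation and hotspots, multi-pulse or
continuous admixture, post-admixture drift, ancient-DNA damage and
reference bias, and real calibration-curve wiggles/plateaus. Passing
tests therefore demonstrate the correctness of the estimators under their
own model assumptions and their calibration against sampling noise — not
robustness to demographic misspecification, which on real data is handled
by the usual sensitivity analyses (alternative sources, varying ΔR and
diet fractions) that the pipeline automates.

## Numerical choices and problem sizes

Tolerances: f4 estimates are exact sums (oracle-checked to 1e-12); the
exponential fit refines n to 1e-6 absolute within its bracket; posteriors
normalise to 1e-9. Degenerate inputs raise informative errors: fewer than
two jackknife blocks, a singular residual covariance (add rights/blocks),
all-equal regression x, a non-positive decay amplitude ("no decay
signal"), a measurement off the curve. Ties: HPD membership is decided by
density ranking with mass accumulated to at least 95.4%.

The test suite and the acceptance script run on desk-scale problem sizes
chosen to make each check's statistical power explicit: 500-SNP oracle
datasets; 22 × 2000 SNPs with 20 admixed samples for dating recovery
(jackknife CI covers the truth); 22 × 9100 ≈ 200k SNPs for mixture-weight
recovery (SE ≈ 0.4%); 200 replicates of a 22 × 400 null cohort for the
fit-P calibration; 100 round-trips for HPD coverage; 10⁶ Monte-Carlo
draws for calendar CIs (stable to ±3 years across seeds).
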