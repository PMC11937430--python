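# Methods

## Model

A case family contributes the ordered quadruple of parental alleles
(maternal non-transmitted, maternal transmitted, paternal
non-transmitted, paternal transmitted). Each slot carries the effect
allele or not, giving 16 transmission configurations. Three assumptions
make the likelihood tractable:

1. **Hardy-Weinberg parental genotypes and random mating** — the four
   slots are independent Bernoulli(`p`) draws, so the configuration
   prior factorises through a single allele frequency;
2. **Mendelian transmission** — which of a parent's two alleles is
   transmitted is uniform, which is what makes the ordered-slot prior
   exchangeable;
3. **Multiplicative penetrance** —
   `Pr(case) = B · RRcm^{m_t} · RRcf^{f_t} · RR*^{m_t f_t} · RRm^{m_nt+m_t}`,
   where `m_t`, `f_t` indicate an effect allele in the transmitted slots
   and the maternal-genotype term `RRm` is optional.

Conditioning on case ascertainment tilts the prior by the penetrance and
normalises over the 16 cells; the baseline risk `B` and the prevalence
cancel and are never estimated (they are unidentifiable from case-only
families). The observed data (mother, father, child dosages) determine
the configuration only up to ambiguity — the double-heterozygote triad
is compatible with two configurations, and a dyad leaves the missing
parent's two slots free — so each family's likelihood is the normalised
sum of its compatible cell weights. This summation is simultaneously the
dyad marginalisation and the latent-origin marginalisation; no separate
EM is needed for the SNP model, although posterior configuration
weights are exposed as a diagnostic.

The parent-of-origin null is `RRcm = RRcf`, tested by a two-sided Wald
test of `log(RRcm/RRcf)` with variance
`Var(log RRcm) + Var(log RRcf) − 2 Cov`, mirroring the exp-scale
asymmetric confidence intervals that family-based association tables
report. Likelihood-ratio alternatives were considered; Wald was chosen
because it matches those symmetric log-scale intervals and gives every
scan row a ratio CI at no extra cost.

## Estimation and numerics

The observed-data log-likelihood is maximised over
`(logit p, log RRcm, log RRcf[, log RR*][, log RRm])` by BFGS with an
analytic gradient; families are first aggregated into distinct
(mother, father, child) dosage patterns, making each evaluation a
handful of 16-vector operations regardless of sample size. Convergence
requires the gradient's maximum component to fall below `1e-8` per
family (`gtol = 1e-8 · n`). Standard errors come from the inverse
numerical Hessian (central differences of the analytic gradient,
relative step `1e-5`) at the optimum; the inverse falls back to a
pseudo-inverse if the Hessian is numerically singular, and intervals are
exp/expit-transformed to the natural scale. `|log RR| > log 50` marks
boundary divergence (e.g. quasi-separation in tiny datasets) and flags
the fit as non-converged; the ratio test refuses non-converged fits.
Starting values are the naive allele frequency of all observed
genotypes (clipped to [0.05, 0.95]) with all risks at 1 — deterministic,
so refitting the same data is bitwise reproducible.

`RR*` is fixed at 1 by default (multiplicative dose-response); freeing
it adds the `m_t·f_t` interaction column. The maternal extension adds
`RRm` with exponent equal to the mother's dosage and is fitted jointly,
so reported PoO risks are adjusted for the maternal-genotype effect and
vice versa.

## Haplotype windows

For a window of `k` neighbouring SNPs (default 3, refused above 5) the
latent state is an ordered quadruple of haplotypes with cell weight
`f(h_mnt) f(h_mt) f(h_fnt) f(h_ft) · RRcm(h_mt) · RRcf(h_ft)`, risks
being contrasts against a reference haplotype fixed at 1. Compatibility
now also absorbs phase ambiguity: a family's likelihood sums every
quadruple whose per-SNP genotype sums match the observations. The sum
factorises — over maternal-side haplotypes given `h_mt`, paternal-side
given `h_ft`, coupled only through the child mask — so evaluation is
O(4^k) per pattern rather than O(16^k).

Frequencies are initialised by a risk-free EM on the parents' unphased
multilocus genotypes (each parent once; monotone in the observed-data
likelihood), then the full likelihood is maximised directly over
softmax-parameterised frequencies and log risks. Haplotypes with EM
frequency below `1e-6` are removed from the support entirely;
haplotypes below the `rare_floor` (default 0.01) keep their risks
pinned at 1 and are reported as rare rather than estimated, since a
handful of copies cannot support a risk contrast. The reference
haplotype defaults to the most frequent one and can be forced by an
explicit allele string, so a published contrast can be reproduced. A
`k = 1` window is algebraically the SNP model and reproduces its fit;
this reduction is tested.

## Scan driver

The genome scan is deliberately thin: one independent fit per SNP
passing the founder-MAF filter (strictly `> 0.05`), Benjamini-Hochberg
adjustment of the converged ratio-test p-values, and two selection
routes — ratio FDR ≤ 0.05, or a one-parent-only rule
`min(p_RRcm, p_RRcf) < 1e-5` that catches SNPs where one transmitted
risk is strong while the ratio is diluted by a null partner. LD clumping
is greedy: the smallest-p row (ties broken by smaller position) becomes
an index SNP and removes neighbours within 500 kb whose founder-dosage
r² exceeds 0.1; both thresholds and the p-value criterion
(ratio vs. one-parent) are configurable since conventions differ between
studies. Founder statistics (MAF, exact Hardy-Weinberg test in the
standard exact-SNP-HWE construction) use parents only, each parent
counted once; children of case-ascertained families are not a random
sample, so they are excluded from founder QC.

## Synthetic data

The generator draws the four parental allele slots i.i.d. Bernoulli(`p`)
(or haplotype quadruples from a supplied frequency vector / first-order
correlation chain for LD regions), computes the child's penetrance
under the same multiplicative model, and rejection-samples case
families. Rejection sampling — rather than importance weighting — makes
the accepted families exactly the conditional multinomial the model
fits; the baseline risk (default 0.05, a realistic childhood-asthma
scale) affects only the acceptance rate, which is tested. Dyads are
created by deleting a parent completely at random according to a
(triad, mother-dyad, father-dyad) composition; the packaged
`COMPOSITION_STUDY` constant reproduces the motivating study's
915/603/113 split of 1,631 families. Missingness is therefore MCAR by
construction; informative missingness, realistic genome-wide LD maps,
population structure and imputation uncertainty are deliberately not
emulated, so passing tests say nothing about robustness to those
features of real data.

## What the tests establish (and at what sizes)

Likelihood code is checked against brute-force enumeration (16
configurations; all haplotype quadruples) on 1,000 random inputs at
tolerance 1e-9–1e-10, and the optimizer against a dense 41³ grid on a
fixed toy dataset. Statistical behaviour is checked by simulation at
sizes chosen to keep the default suite in the low minutes: parameter
recovery at 5,000 triads (200 replicates for the log-ratio bias, bound
±0.02), ratio-test size and 95% CI coverage over 1,000 replicates of
500 triads, dyad-thinning bias/precision at the study composition, and
KS uniformity of null scan p-values aggregated over 50 replicates of a
200-SNP panel at the study's 1,631-family composition. One genuine
discreteness effect is worth knowing: with triads only, the ML log-ratio
has a point mass at exactly 0 (probability ~ n^-1/2, about 2% at 500
triads), because integer transmission counts can tie; the resulting
p = 1 atom is a property of discrete family data, not a bug. Under the
study's triad/dyad mixture the tie lattice is broken and the null
p-value distribution is uniform to KS resolution at 10,000 draws.

## Known limitations

- No covariates, gene-environment interaction, or X-chromosome model.
- Hard-call dosages only; imputation uncertainty is ignored.
- Wald inference can be anti-conservative in very small samples or at
  rare alleles; the boundary flag catches divergence but not moderate
  small-sample bias.
- Sibling families are treated as independent; a de-duplication helper
  (first-listed child per family) supports sensitivity analyses instead.
- The haplotype model reports windows independently with no
  cross-window multiplicity handling.
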