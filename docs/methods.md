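# Methods

## Scope and model

`pleioscan` studies a two-stage discovery design for an underpowered GWAS
trait: loci are ascertained on a well-powered partner trait (genome-wide
significance, p < 5e-8, anywhere in a 200kb window) and on a suggestive
signal for the underpowered trait (p < 0.01 anywhere in the window), then
classified by per-locus tests into "shared causal variant" versus "distinct
causal variants in LD" versus "no effect". The package implements the data
generators, the tests, the selection rules, the replication projection, and
the applied screening workflow. Coordinates are 1-based (VCF convention);
windows of "200kb around the focal SNP" mean ±100,000 bp inclusive; the MAF
floor is 0.05 and is applied before any LD computation.

## Haplotype panels

Local LD comes from synthetic haplotype panels generated with the standard
neutral coalescent with recombination (msprime), 200kb per locus, constant
population size 1e4, recombination 3.5e-9 /bp/gen, mutation 4e-8 /bp/gen
(binary model), 1,000 haplotypes, m SNPs subsampled uniformly among sites
with MAF ≥ 0.05. The recombination and mutation rates were calibrated once
against a single target: the |r| distribution of random SNP pairs within a
locus, 72/19/5/4 percent over the bins [0,0.3)/[0.3,0.6)/[0.6,0.8)/
[0.8,0.95), the composition observed between random pairs of common SNPs in
European-ancestry reference data. Measured composition: ≈71/22/5/2.4 with
≈2% of pairs at |r| ≥ 0.95 (mean per-bin deviation ≈1.3 points over 22
seeds). Pairs at |r| ≥ 0.95 are tracked but never used as "distinct" causal
pairs. These panels reproduce the *composition* of pairwise LD but not every
feature of real haplotypes — no recombination hotspot structure, no
population substructure, no imputation error — so quantities that depend on
the fine shape of the high-LD tail (e.g. lead-SNP tagging rates) carry a few
percentage points of LD-proxy uncertainty.

LD is computed as the Pearson correlation of haplotype columns for panels,
and of standardized diploid dosages for cohort-level operations; both are
plain sample correlations and agree up to sampling noise.

## Effect sizes and ascertainment

Causal effects (beta1, beta2) are bivariate normal with per-SNP variance
sigma^2 = h^2/(causal fraction × markers) = 0.5/(0.01×1e6) = 5e-5 on the
standardized scale, correlation rho (0.7 in the main scenario) under H1,
independent under H2, and beta2 = 0 under H0. The well-powered trait
(N1 = 150,000) is sampled at the summary level, z ~ MVN(sqrt(N1) D beta, D)
(Cholesky with escalating diagonal jitter from 1e-8 for rank-deficient D);
the underpowered trait (N2 = 10,000) at the individual level: 2N2
haplotypes resampled from the panel, dosages standardized, phenotype
y ~ N(x_causal beta2, 1), per-SNP simple-regression t statistics treated as
z. The causal SNP sits at the SNP nearest the base-pair midpoint (ties to
the lower index). H2 partners are drawn uniformly within the requested |r|
bin relative to the midpoint SNP. Simulated loci are rejected until both
ascertainment filters pass; because selection acts on beta1 (and via rho on
beta2), retained effects carry winner's-curse inflation, which is the
central driver of the replication results.

## Colocalization tests

With z ~ MVN(sqrt(N) D beta, D), the marginal likelihood of the z-vector
with a single causal SNP j and effect prior b ~ N(0, w) has covariance
D + N w d_j d_j'; the rank-one identity D^{-1} d_j = e_j collapses the
likelihood ratio against beta = 0 to a function of z_j alone:

    log BF_j = ½ κ z_j² − ½ log(1 + N w),   κ = N w / (1 + N w).

This closed form is verified in the test suite against brute-force
multivariate-normal density evaluation. The likelihood-ratio statistic is
Λ = max_{j∈S} log BF_j − max_{j∉S} log BF_j with S = {j : r²(j, lead1) ≥ θ}
anchored at the well-powered lead and θ = 0.5 (relaxed from the
conventional 0.8 because underpowered data localize causal variants
poorly). Loci where S is empty or covers every SNP are rejected as
degenerate. Since w only rescales Λ monotonically, the permutation p-value
is invariant to the prior variance; w (default 0.15² on the standardized
scale) matters only for CLPP, mildly. This statistic is a reimplementation
in spirit of joint likelihood mapping and is not bit-compatible with any
released tool.

P-values come from permutation: either within-cohort phenotype shuffling
(covariates stay attached to individuals; per-cohort rescans are combined
by IVW meta-analysis), or the summary-level equivalent z ~ MVN(0, D), which
is the exact law of a scan of panel genotypes against random normal
phenotypes. The adaptive rule draws batches of 100, stops once 10
exceedances have accumulated (never before 100 draws), caps at 100,000, and
uses the add-one estimator p = (1+#{Λ0 ≥ Λ})/(1+n). In the large simulation
study the summary-level null is used with 1,000 draws per locus, and null
draws are cached per (panel, lead SNP) pair — the null law depends only on
(D, S) — which cuts the study's cost by roughly an order of magnitude.

CLPP is the product of the two traits' normalized single-causal posteriors
(uniform prior over SNPs), reported at the well-powered lead by default; the
sum-over-SNPs variant is symmetric in trait order and also exposed. CLPP
thresholds are calibrated as empirical quantiles of unfiltered-null scores.

The FDR table implements fdr(p) = p·N/#{l : p_l ≤ p} with step-up
monotonization (the ≤ in the count is immaterial for continuous p-values)
and yields p_q, the largest p with FDR ≤ q; it matches the textbook
Benjamini–Hochberg adjusted values.

## Selection rules and replication

The conditional-threshold rule ("cFDR" in this context) selects a locus
when the underpowered association p at the focal SNP (the well-powered
lead) is strictly below the cutoff (0.01 in the simulation study; p_0.2 in
the applied workflow). The consensus is the exact intersection with the
colocalization hits. Replication in a validation cohort of size N_v uses
the plug-in expected z, E[z_v] = sqrt(N_v) beta2 r, with r taken from the
validation panel between the focal SNP and the true underpowered causal
variant (0 for H0, so plug-in mode never replicates H0 hits; a stochastic
mode draws z_v ~ N(E[z_v],1) and gives them the nominal rate), and the
Bonferroni decision 2Φ(−|E[z_v]|) < 0.05/M with M the number of carried
candidates. Confidence bands on benchmark curves are percentile intervals
over scenario replicates.

Scenario class counts are deterministic: round(T·prop_H0) H0 loci, floor of
the H1 share, remainder to H2; the H2 pool is titrated to the 72/19/5/4
composition, the limiting bin setting the subsample size. In the benchmark
and the study driver, scenario-level rates are computed as
composition-weighted expectations over large per-class pools — the same
estimand as repeated scenario subsampling (the original design averaged
1,000 subsample iterations) with the subsampling noise integrated out.

## Study driver scales

`scripts/acceptance.py` uses 64 panels × 500 SNPs, 40,000 unfiltered H0
draws for the consensus false-positive rate, 4,000/2,500 ascertained H0/H1
loci, 1,000 H2 loci per LD bin (2,400 in the 0.8–0.95 bin), 1,000
permutation-null draws per locus, and 4,000 loci for the well-powered
lead-tagging calibration; it completes in a few minutes on one CPU. The
underpowered lead-tagging fraction is read off the H1 pool, where beta2 is
coupled (rho = 0.7) to the ascertained beta1 — the winner's-curse-inflated
regime the headline tagging numbers describe; an uncoupled variant is
available via `lead_ld_calibration`. The consensus false-positive rate is
measured on the unfiltered null (no preconditioning on the underpowered
minimum p), the construction under which a focal-SNP p threshold equal to
that rate has, by definition, the same false-positive rate.

## Numerical and degenerate-input choices

Lead SNPs break ties to the smallest p then leftmost position. Monomorphic
SNP columns are rejected by name. Constant covariate columns (including
fully missing ones after mean imputation) are dropped with a warning;
collinear covariates raise with the offending pair named. The per-SNP
covariate-adjusted regression uses Frisch–Waugh residualization and matches
full normal-equation OLS to 1e-8. IVW meta-analysis drops variants absent
from any cohort. The rank-based inverse-normal transform uses the Blom
offset 3/8 with average ranks for ties. The extended MHC exclusion is
chr6:25–35Mb (GRCh37), configurable.

## What the synthetic data do and do not show

Passing tests demonstrate internal correctness (oracle agreement, null
calibration, reproducibility) and that the strategy's qualitative claims
hold under the stated generative model: selection-rule hits are
H1-enriched, replicated loci far more so, the consensus advantage grows
with the H2 share, and trans-ancestry LD attenuation lowers projected
replication. They do not show performance on real cohorts, where LD panel
mismatch, imputation noise, covariate confounding and non-normal traits all
enter.

## Known limitations

* The likelihood-ratio statistic is not the released colocalization tool;
  its permutation p-values are exactly calibrated under the null by
  construction, but its behavior *jointly* with the focal-SNP rule under H2
  differs from the originally reported consensus behavior. Under this
  package's generative model, a noise peak of the underpowered trait that
  lands inside the θ-shared set fires the focal-SNP rule and the
  colocalization test together, putting the consensus H2 contamination in
  the tens of percent; sum-integrated and posterior-product variants were
  measured and behave the same way. The reported low single-digit consensus
  contamination would require the two rules to be negatively dependent
  under H2 on shared data, which no variant tested here produces.
* Tagging-rate and misclassification quantities inherit the LD-proxy
  uncertainty of the synthetic panels (a few percentage points).
* Case-control traits, gene–environment interaction, relatedness and
  population structure are out of scope; multi-allelic sites and structural
  variants are excluded at input.
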