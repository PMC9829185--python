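# pleioscan

Pleiotropy-leveraged locus discovery for underpowered GWAS.

Many clinically important traits — overnight oximetry and other sleep-apnea
indices are the motivating case — can only be phenotyped in cohorts of a few
thousand individuals, far below the sample sizes at which GWAS reliably
discovers loci. `pleioscan` implements a two-stage strategy that borrows
power from large GWAS of correlated ("clinical") traits: take genome-wide
significant clinical loci, keep those with at least a suggestive signal for
the underpowered trait, and then ask — with an LD-aware colocalization test —
whether the two association signals are driven by the *same* causal variant.
The toolkit covers the full simulation study behind that strategy and the
applied screening workflow, on synthetic data.

## The model

At a locus of m SNPs with local LD matrix D (Pearson r between haplotypes),
well-powered GWAS summary statistics are simulated directly:

    z ~ MVN( sqrt(N1) * D * beta,  D ),        p_j = 2 Phi(-|z_j|)

with beta nonzero only at the causal SNP and causal effects drawn from a
bivariate normal prior with per-SNP variance sigma^2 = h^2/(pi_c * M) =
0.5/(0.01 * 1e6) = 5e-5 and cross-trait correlation rho. The underpowered
trait (N2 = 10,000) is simulated at the individual level: genotypes drawn
from the haplotype panel and phenotype y_i ~ N(x_i * beta2, 1). Three locus
classes are generated: H0 (no underpowered effect), H1 (shared causal
variant), H2 (two distinct causal variants in LD, titrated to the empirical
random-pair |r| composition 72/19/5/4 over [0,0.3)/[0.3,0.6)/[0.6,0.8)/[0.8,0.95)).

Per locus pair, the colocalization statistic contrasts the resolution-limited
hypotheses H1θ (underpowered causal variant within r² ≥ θ of the
well-powered lead, θ = 0.5) and H2θ (outside):

    Λ = max_{j∈S} log L2(j) − max_{j∉S} log L2(j),
    log BF_j = ½ κ z_j² − ½ log(1+N2 w),   κ = N2 w/(1+N2 w)

where L2(j) is the single-causal marginal likelihood of the underpowered
z-vector under an effect prior N(0, w); significance comes from an adaptive
permutation null (up to 100,000 permutations). The posterior-product test
(CLPP) multiplies the two traits' normalized single-causal posteriors at the
well-powered lead. The conditional-threshold rule ("cFDR") selects loci with
focal-SNP association p below a cutoff given upstream clinical significance,
and the consensus is the exact intersection. Replication in a validation
cohort of size N_v is projected through E[z_v] = sqrt(N_v)·beta2·r_jj' and a
Bonferroni decision 2Φ(−|E[z_v]|) < 0.05/M.

## A worked example

```bash
python examples/02_locus_coloc.py
```

```
H1 (shared variant):
  well-powered lead SNP 146 (p=4.09e-09); underpowered lead 146 (p=4.38e-06)
  likelihood-ratio statistic +4.22, permutation p = 0.0005 (2000 permutations)
  CLPP at the well-powered lead = 0.081
H2 (distinct, |r| in [0.3,0.6)):
  well-powered lead SNP 155 (p=1.54e-08); underpowered lead 273 (p=6.08e-08)
  likelihood-ratio statistic -7.38, permutation p = 1.0000 (100 permutations)
  CLPP at the well-powered lead = 0.000
```

With a shared causal variant both traits peak at the same SNP, the
likelihood ratio favors the shared set (Λ > 0) and the permutation p-value
is small; with distinct variants in moderate LD the underpowered likelihood
concentrates outside the θ-neighborhood, Λ is negative, and the adaptive
permutation loop stops after 100 draws with p ≈ 1.

Other example scripts: `01_synthesize_panel.py` (calibrated LD panels and
pruning), `03_replication_power.py` (expected-z replication curves),
`04_benchmark.py` (the reduced-scale simulation study end to end),
`05_discovery_workflow.py` (rank-normalization, covariate-adjusted scans,
IVW meta-analysis, candidate windows, eQTL causal chains). A thin CLI mirrors
the main entry points: `pleioscan panel synth`, `pleioscan coloc jlim`,
`pleioscan coloc clpp`, `pleioscan bench run`.

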