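"""Colocalization and pleiotropy-selection tests for one locus pair.

Two per-locus tests decide whether the association signals of a well-powered
and an underpowered trait are driven by the same causal variant:

* a likelihood-ratio statistic Lambda contrasting the resolution-limited
  hypotheses "shared" (causal variant of the underpowered trait inside the
  set S of SNPs with r^2 >= theta to the well-powered lead) versus
  "distinct" (outside S), with significance from a permutation /
  null-sampling distribution;
* a colocalization posterior probability (CLPP): the product of the two
  traits' single-causal posterior probabilities at the well-powered lead SNP
  (optionally summed over all SNPs).

Both are built on the single-causal-variant marginal likelihood of a z-score
vector under a normal effect prior b ~ N(0, w). With z ~ MVN(sqrt(N) D beta,
D) this marginal likelihood has a closed form that depends on the candidate
SNP only through its own z-score:

    log BF_j = 0.5 * kappa * z_j^2 - 0.5 * log(1 + N w),   kappa = Nw/(1+Nw)

(the rank-one identity D^{-1} D e_j = e_j collapses the quadratic forms).
One consequence, documented here on purpose: the permutation p-value of
Lambda is invariant to the prior variance w, because w only rescales Lambda
monotonically.

The module also carries the locus-selection rules built on these tests: the
conditional-threshold rule (focal-SNP association p below a cutoff, given
genome-wide significance of the well-powered trait upstream), the consensus
intersection, the per-trait-pair FDR table, and empirical threshold
calibration from null scores.

This likelihood-ratio test is a reimplementation in spirit of joint
likelihood mapping; it is not bit-compatible with any released tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .simulate import CohortData, LocusSummary, assoc_scan, chol_with_jitter
from .panel import LDMatrix

__all__ = [
    "ColocConfig",
    "ColocResult",
    "FdrTable",
    "single_causal_log_bf",
    "shared_snp_set",
    "jlim_statistic",
    "SummaryNull",
    "CohortPermutationNull",
    "jlim_pvalue",
    "clpp",
    "calibrate_threshold",
    "cfdr_select",
    "consensus",
    "fdr_table",
]


@dataclass(frozen=True)
class ColocConfig:
    """Tuning knobs shared by the likelihood-ratio test and CLPP.

    theta
        Genetic-resolution r^2 threshold separating "shared" from
        "distinct" (0.5 here, relaxed from the conventional 0.8 because
        underpowered GWAS localize poorly).
    prior_var
        Variance of the normal effect prior in the single-causal Bayes
        factor (standardized scale). Affects CLPP mildly; the permutation
        p-value of Lambda not at all.
    """

    theta: float = 0.5
    max_perm: int = 100_000
    min_exceedances: int = 10
    min_perm: int = 100
    batch: int = 100
    prior_var: float = 0.15**2

    def __post_init__(self):
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        if self.max_perm < 100:
            raise ValueError("max_perm must be >= 100")


@dataclass(frozen=True)
class ColocResult:
    statistic: float
    p_value: float | None
    n_perm_used: int
    lead1: int
    lead2: int
    hit: bool | None = None

    def __post_init__(self):
        if self.p_value is not None and not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


def single_causal_log_bf(z: np.ndarray, n: int, prior_var: float) -> np.ndarray:
    """log Bayes factor (vs no effect) for each candidate causal SNP."""
    z = np.asarray(z, float)
    nw = n * prior_var
    kappa = nw / (1.0 + nw)
    return 0.5 * kappa * z**2 - 0.5 * np.log1p(nw)


def shared_snp_set(ld: LDMatrix, lead1: int, theta: float) -> np.ndarray:
    """Boolean mask of SNPs with r^2 >= theta to the well-powered lead."""
    return ld.r2[:, lead1] >= theta


def _lambda_from_z(z2: np.ndarray, shared: np.ndarray, n2: int, prior_var: float) -> float:
    lbf = single_causal_log_bf(z2, n2, prior_var)
    return float(lbf[shared].max() - lbf[~shared].max())


def jlim_statistic(
    ws: LocusSummary,
    us: LocusSummary,
    ld: LDMatrix,
    cfg: ColocConfig | None = None,
) -> float:
    """Likelihood-ratio statistic Lambda for shared vs distinct causal variant.

    Lambda = max_{j in S} log L2(j) - max_{j not in S} log L2(j), where S is
    the theta-shared set around the well-powered lead and L2(j) the
    single-causal marginal likelihood of the underpowered z-vector with the
    causal variant at j. Positive values favor a shared effect.
    """
    cfg = cfg or ColocConfig()
    if ws.z.shape != us.z.shape or ws.z.shape[0] != ld.m:
        raise ValueError("both summaries must cover the panel SNP set")
    shared = shared_snp_set(ld, ws.lead_index, cfg.theta)
    if shared.all() or not shared.any():
        raise ValueError("degenerate locus: theta-shared set is empty or covers all SNPs")
    return _lambda_from_z(us.z, shared, us.n, cfg.prior_var)


class SummaryNull:
    """Null Lambda source sampling z ~ MVN(0, D) at the reference LD.

    Emulates phenotype randomization without individual-level data: random
    normal phenotypes regressed on panel genotypes give, in distribution,
    exactly MVN(0, D) association z-scores.
    """

    def __init__(self, ld: LDMatrix, lead1: int, n2: int, cfg: ColocConfig, chol: np.ndarray | None = None):
        self.shared = shared_snp_set(ld, lead1, cfg.theta)
        if self.shared.all() or not self.shared.any():
            raise ValueError("degenerate locus: theta-shared set is empty or covers all SNPs")
        self.chol = chol if chol is not None else chol_with_jitter(ld)
        self.n2 = n2
        self.prior_var = cfg.prior_var

    def draw(self, batch: int, rng: np.random.Generator) -> np.ndarray:
        z0 = self.chol @ rng.standard_normal((self.chol.shape[0], batch))
        nw = self.n2 * self.prior_var
        kappa = nw / (1.0 + nw)
        sq = z0**2
        return 0.5 * kappa * (sq[self.shared].max(axis=0) - sq[~self.shared].max(axis=0))


class CohortPermutationNull:
    """Null Lambda source by shuffling phenotypes within each cohort.

    Each draw permutes every cohort's phenotype (covariates, if any, stay
    attached to individuals), rescans, meta-analyzes across cohorts by
    inverse-variance weighting, and recomputes Lambda.
    """

    def __init__(
        self,
        cohorts: Sequence[CohortData],
        ld: LDMatrix,
        lead1: int,
        cfg: ColocConfig,
        scan: Callable[[CohortData], LocusSummary] = assoc_scan,
    ):
        self.cohorts = list(cohorts)
        self.shared = shared_snp_set(ld, lead1, cfg.theta)
        if self.shared.all() or not self.shared.any():
            raise ValueError("degenerate locus: theta-shared set is empty or covers all SNPs")
        self.cfg = cfg
        self.scan = scan
        self.n_total = sum(c.n for c in self.cohorts)

    def _one(self, rng: np.random.Generator) -> float:
        from .workflow import ivw_meta_summaries

        perm = [
            CohortData(c.dosages, rng.permutation(c.phenotype), c.covariates)
            for c in self.cohorts
        ]
        meta = ivw_meta_summaries([self.scan(c) for c in perm])
        return _lambda_from_z(meta.z, self.shared, meta.n, self.cfg.prior_var)

    def draw(self, batch: int, rng: np.random.Generator) -> np.ndarray:
        return np.array([self._one(rng) for _ in range(batch)])


def jlim_pvalue(
    lambda_obs: float,
    null_source,
    cfg: ColocConfig,
    rng: np.random.Generator,
    lead1: int = -1,
    lead2: int = -1,
    adaptive: bool = True,
    p_cut: float | None = None,
) -> ColocResult:
    """Adaptive permutation p-value for the likelihood-ratio statistic.

    p = (1 + #{Lambda_null >= Lambda_obs}) / (1 + n_perm), drawing nulls in
    batches and stopping early once ``cfg.min_exceedances`` null values at or
    above the observed statistic have accumulated (never before
    ``cfg.min_perm`` draws, never beyond ``cfg.max_perm``).
    """
    exceed = 0
    n_done = 0
    while n_done < cfg.max_perm:
        batch = min(cfg.batch, cfg.max_perm - n_done)
        lam0 = null_source.draw(batch, rng)
        exceed += int((lam0 >= lambda_obs).sum())
        n_done += batch
        if adaptive and n_done >= cfg.min_perm and exceed >= cfg.min_exceedances:
            break
    if n_done < cfg.min_perm:
        raise RuntimeError(f"only {n_done} permutations completed (< {cfg.min_perm})")
    p = (1 + exceed) / (1 + n_done)
    return ColocResult(
        statistic=lambda_obs,
        p_value=p,
        n_perm_used=n_done,
        lead1=lead1,
        lead2=lead2,
        hit=None if p_cut is None else p < p_cut,
    )


def clpp(
    ws: LocusSummary,
    us: LocusSummary,
    ld: LDMatrix,
    cfg: ColocConfig | None = None,
    mode: str = "lead",
) -> ColocResult:
    """Colocalization posterior probability under one causal variant per trait.

    Per trait, the posterior over the causal SNP is the normalized
    single-causal Bayes factor with a uniform prior; CLPP(j) is the product
    of the two posteriors at SNP j. ``mode="lead"`` (default) reports CLPP at
    the well-powered lead; ``mode="sum"`` reports sum_j CLPP(j), which is
    symmetric in trait order (the lead-SNP variant is not).
    """
    cfg = cfg or ColocConfig()
    if ws.z.shape != us.z.shape or ws.z.shape[0] != ld.m:
        raise ValueError("both summaries must cover the panel SNP set")
    out = []
    for s in (ws, us):
        lbf = single_causal_log_bf(s.z, s.n, cfg.prior_var)
        if not np.isfinite(lbf).all():
            raise FloatingPointError("non-finite Bayes factor")
        out.append(np.exp(lbf - logsumexp(lbf)))
    post1, post2 = out
    if mode == "lead":
        stat = float(post1[ws.lead_index] * post2[ws.lead_index])
    elif mode == "sum":
        stat = float(np.sum(post1 * post2))
    else:
        raise ValueError("mode must be 'lead' or 'sum'")
    return ColocResult(stat, None, 0, ws.lead_index, us.lead_index)


def calibrate_threshold(
    h0_scores: Sequence[float],
    target_rate: float,
    tail: str = "upper",
) -> float:
    """Empirical cutoff with exceedance rate ``target_rate`` under the null.

    ``tail="upper"`` (statistic-like scores, larger = more significant)
    returns the (1 - target_rate) quantile; ``tail="lower"`` (p-value-like
    scores) the target_rate quantile.
    """
    scores = np.asarray(h0_scores, float)
    if scores.size < 1.0 / target_rate:
        raise ValueError(
            f"need >= {int(np.ceil(1 / target_rate))} null scores to calibrate at {target_rate}"
        )
    q = 1.0 - target_rate if tail == "upper" else target_rate
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    return float(np.quantile(scores, q))


def cfdr_select(focal_p_underpowered: float, p_threshold: float) -> bool:
    """Conditional-threshold rule at the focal SNP (strict inequality).

    The focal SNP is the well-powered lead; its genome-wide significance for
    the well-powered trait is ascertained upstream.
    """
    return bool(focal_p_underpowered < p_threshold)


def consensus(jlim_hits: Iterable, cfdr_hits: Iterable) -> set:
    """Exact intersection of the two methods' hit sets."""
    return set(jlim_hits) & set(cfdr_hits)


@dataclass(frozen=True)
class FdrTable:
    """Benjamini-Hochberg FDR over one trait pair's colocalization p-values.

    fdr(p) = p * N / #{l : p_l <= p}, monotonized by the step-up rule.
    """

    trait_pair: tuple[str, str]
    p_values: np.ndarray
    fdr: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        p = np.asarray(self.p_values, float)
        if p.size < 1:
            raise ValueError("need at least one p-value")
        order = np.argsort(p, kind="stable")
        n = p.size
        raw = p[order] * n / np.arange(1, n + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        fdr = np.empty(n)
        fdr[order] = np.minimum(stepped, 1.0)
        object.__setattr__(self, "p_values", p)
        object.__setattr__(self, "fdr", fdr)

    @property
    def n_tests(self) -> int:
        return self.p_values.size

    def p_cut_at_fdr(self, q: float) -> float:
        """Largest observed p-value whose FDR is at most q (0.0 if none)."""
        ok = self.fdr <= q
        return float(self.p_values[ok].max()) if ok.any() else 0.0

    def hits(self, q: float) -> np.ndarray:
        return np.flatnonzero(self.fdr <= q)


def fdr_table(p_values: Sequence[float], trait_pair: tuple[str, str] = ("u", "v")) -> FdrTable:
    """Build the per-trait-pair FDR table."""
    return FdrTable(trait_pair, np.asarray(p_values, float))
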