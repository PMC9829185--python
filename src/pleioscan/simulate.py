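"""Ground-truth locus-pair simulation for pleiotropy studies.

Simulates pairs of GWAS association signals at one locus under three
hypotheses about the underpowered trait:

* H0 — no causal variant for the underpowered trait;
* H1 — the same causal variant drives both traits;
* H2 — two distinct causal variants in LD drive the two traits.

The well-powered trait (sample size N1, default 150,000) is simulated
directly at the summary level: z ~ MVN(sqrt(N1) * D * beta, D) where D is the
local LD matrix and beta is nonzero only at the causal SNP. The underpowered
trait (N2, default 10,000) is by default simulated at the individual level:
genotypes drawn from the haplotype panel, phenotype y_i ~ N(x_i * beta2, 1)
with x_i the standardized causal dosage, then per-SNP linear regression. A
fast summary-level mode using the same MVN shortcut is available.

Causal effect pairs (beta1, beta2) are drawn from a bivariate normal with
per-SNP variance sigma^2 (default 5e-5, i.e. heritability 0.5 spread over
1% of 1e6 markers) and correlation rho (H1 only; H2 draws are independent;
H0 sets beta2 = 0).

Loci are ascertained the way a real two-stage analysis would be: the
well-powered trait must reach genome-wide significance (min p < 5e-8) and
the underpowered trait must show at least a suggestive signal (min p < 0.01)
somewhere in the locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import ndtr

from .panel import (
    LD_BIN_EDGES,
    TARGET_COMPOSITION,
    HaplotypePanel,
    LDComposition,
    LDMatrix,
)

__all__ = [
    "EffectPair",
    "LocusTruth",
    "LocusSummary",
    "CohortData",
    "ScenarioSet",
    "per_snp_variance",
    "sample_effects",
    "chol_with_jitter",
    "sample_summary_stats",
    "build_cohort_genotypes",
    "simulate_cohort",
    "assoc_scan",
    "make_h2_pair",
    "midpoint_snp",
    "ascertain",
    "titrate_h2",
    "assemble_scenario",
    "scenario_counts",
    "simulate_multitrait_focal",
    "lead_causal_ld_summary",
    "GW_SIG",
    "SUGGESTIVE",
]

GW_SIG = 5e-8
SUGGESTIVE = 0.01

Hypothesis = Literal["H0", "H1", "H2"]


def per_snp_variance(h2: float = 0.5, causal_fraction: float = 0.01, n_markers: float = 1e6) -> float:
    """Per-SNP heritability under an evenly spread polygenic architecture.

    h2 / (causal_fraction * n_markers); the defaults give 5e-5.
    """
    if h2 <= 0 or causal_fraction <= 0 or n_markers <= 0:
        raise ValueError("all arguments must be positive")
    return h2 / (causal_fraction * n_markers)


@dataclass(frozen=True)
class EffectPair:
    """Standardized causal effect sizes for the two traits."""

    beta1: float
    beta2: float
    rho: float
    sigma1_sq: float = 5e-5
    sigma2_sq: float = 5e-5

    def __post_init__(self):
        if self.sigma1_sq <= 0 or self.sigma2_sq <= 0:
            raise ValueError("per-SNP variances must be > 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")


@dataclass(frozen=True)
class LocusTruth:
    """Simulation ground truth for one locus pair."""

    hypothesis: Hypothesis
    causal_index_1: int
    causal_index_2: int | None
    effects: EffectPair
    ld_bin: int | None = None  # index into LD_BIN_EDGES bins, H2 only
    causal_index_1b: int | None = None  # optional second shared causal (H1)
    effects_b: EffectPair | None = None

    def __post_init__(self):
        if self.hypothesis == "H0" and self.causal_index_2 is not None:
            raise ValueError("H0 loci have no underpowered causal variant")
        if self.hypothesis == "H1" and self.causal_index_2 != self.causal_index_1:
            raise ValueError("H1 loci share the causal variant")
        if self.hypothesis == "H2":
            if self.causal_index_2 is None or self.causal_index_2 == self.causal_index_1:
                raise ValueError("H2 loci need a distinct second causal variant")

    @property
    def n_causal_1(self) -> int:
        return 2 if self.causal_index_1b is not None else 1


@dataclass(frozen=True)
class LocusSummary:
    """Per-SNP association summary for one trait at one locus."""

    z: np.ndarray
    p: np.ndarray
    n: int

    def __post_init__(self):
        z = np.asarray(self.z, float)
        p = np.asarray(self.p, float)
        if z.shape != p.shape or z.ndim != 1:
            raise ValueError("z and p must be 1-D and congruent")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "p", p)

    @property
    def lead_index(self) -> int:
        """Index of the smallest p-value; ties broken leftmost."""
        return int(np.argmin(self.p))

    @property
    def min_p(self) -> float:
        return float(self.p.min())

    @classmethod
    def from_z(cls, z: np.ndarray, n: int) -> "LocusSummary":
        z = np.asarray(z, float)
        return cls(z, 2.0 * ndtr(-np.abs(z)), n)


@dataclass(frozen=True)
class CohortData:
    """Individual-level cohort: standardized dosages, phenotype, covariates."""

    dosages: np.ndarray  # n x m, each column mean 0 / variance 1
    phenotype: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self):
        x = np.asarray(self.dosages, float)
        y = np.asarray(self.phenotype, float)
        if x.ndim != 2 or y.shape != (x.shape[0],):
            raise ValueError("dosages must be n x m and phenotype length n")
        object.__setattr__(self, "dosages", x)
        object.__setattr__(self, "phenotype", y)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]


@dataclass
class ScenarioSet:
    """An assembled discovery scenario of T ascertained loci."""

    truths: list[LocusTruth]
    well_powered: list[LocusSummary]
    underpowered: list[LocusSummary]
    panel_index: list[int] = field(default_factory=list)
    prop_h0: float = 0.30
    h1_h2_ratio: tuple[int, int] = (1, 19)

    @property
    def T(self) -> int:
        return len(self.truths)

    def labels(self) -> np.ndarray:
        return np.array([t.hypothesis for t in self.truths])


def sample_effects(
    rho: float,
    sigma1_sq: float,
    sigma2_sq: float,
    hypothesis: Hypothesis,
    rng: np.random.Generator,
) -> EffectPair:
    """Draw (beta1, beta2) from the bivariate normal effect prior.

    H1 uses the requested rho; H2 draws the two effects independently
    (rho = 0, distinct variants); H0 draws beta1 and forces beta2 = 0.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    s1, s2 = np.sqrt(sigma1_sq), np.sqrt(sigma2_sq)
    if hypothesis == "H0":
        return EffectPair(float(rng.normal(0, s1)), 0.0, rho, sigma1_sq, sigma2_sq)
    use_rho = rho if hypothesis == "H1" else 0.0
    e1, e2 = rng.standard_normal(2)
    b1 = s1 * e1
    b2 = s2 * (use_rho * e1 + np.sqrt(1 - use_rho**2) * e2)
    return EffectPair(float(b1), float(b2), use_rho, sigma1_sq, sigma2_sq)


def chol_with_jitter(ld: LDMatrix | np.ndarray, jitter: float = 1e-8, max_tries: int = 6) -> np.ndarray:
    """Cholesky factor of an LD matrix, adding diagonal jitter when rank-deficient."""
    d = ld.r if isinstance(ld, LDMatrix) else np.asarray(ld, float)
    eps = 0.0
    for _ in range(max_tries):
        try:
            return np.linalg.cholesky(d + eps * np.eye(d.shape[0]))
        except np.linalg.LinAlgError:
            eps = jitter if eps == 0.0 else eps * 10.0
    raise np.linalg.LinAlgError("LD matrix not positive definite even after jitter")


def sample_summary_stats(
    ld: LDMatrix,
    beta: np.ndarray,
    n: int,
    rng: np.random.Generator,
    chol: np.ndarray | None = None,
) -> LocusSummary:
    """One draw of GWAS summary statistics: z ~ MVN(sqrt(n) D beta, D)."""
    beta = np.asarray(beta, float)
    if beta.shape != (ld.m,):
        raise ValueError("beta must have one entry per SNP")
    L = chol if chol is not None else chol_with_jitter(ld)
    mean = np.sqrt(n) * (ld.r @ beta)
    z = mean + L @ rng.standard_normal(ld.m)
    return LocusSummary.from_z(z, n)


def build_cohort_genotypes(
    panel: HaplotypePanel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n diploid genotypes from random haplotype pairs, standardized per SNP.

    Columns are scaled to mean 0 / variance 1 (population-style, ddof=0). A
    monomorphic draw (possible at small n) raises.
    """
    idx = rng.integers(0, panel.n_hap, size=2 * n)
    g = panel.haplotypes[idx[:n]].astype(np.float64) + panel.haplotypes[idx[n:]]
    sd = g.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic genotype column in sampled cohort")
    return (g - g.mean(axis=0)) / sd


def simulate_cohort(
    genotypes: HaplotypePanel | np.ndarray,
    causal_index: int | None,
    beta2: float,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    second_causal: tuple[int, float] | None = None,
) -> CohortData:
    """Individual-level cohort with y ~ N(x_causal * beta2, 1).

    ``genotypes`` may be a panel (a fresh standardized dosage matrix is
    sampled) or a pre-standardized dosage matrix to reuse across loci.
    ``causal_index=None`` simulates no causal effect (H0).
    """
    rng = rng or np.random.default_rng()
    if isinstance(genotypes, HaplotypePanel):
        if n is None or n < 2:
            raise ValueError("n >= 2 required when sampling from a panel")
        x = build_cohort_genotypes(genotypes, n, rng)
    else:
        x = np.asarray(genotypes, float)
    mean = np.zeros(x.shape[0])
    if causal_index is not None:
        mean = x[:, causal_index] * beta2
    if second_causal is not None:
        j2, b2b = second_causal
        mean = mean + x[:, j2] * b2b
    y = mean + rng.standard_normal(x.shape[0])
    return CohortData(x, y)


def assoc_scan(cohort: CohortData) -> LocusSummary:
    """Per-SNP simple linear regression of phenotype on standardized dosage.

    Returns the t statistic as z (n is large in all study settings) with
    p = 2 Phi(-|z|). Covariate-adjusted association lives in the discovery
    workflow module.
    """
    x, y = cohort.dosages, cohort.phenotype
    n = cohort.n
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("zero-variance dosage column")
    yc = y - y.mean()
    bhat = (x.T @ yc) / n  # columns have sum-of-squares n
    rss = yc @ yc - n * bhat**2
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / n)
    with np.errstate(divide="ignore"):
        z = np.where(se > 0, bhat / se, np.inf * np.sign(bhat))
    return LocusSummary.from_z(z, n)


def midpoint_snp(panel: HaplotypePanel) -> int:
    """SNP nearest the base-pair midpoint of the locus (ties -> lower index)."""
    mid = (panel.positions[0] + panel.positions[-1]) / 2.0
    return int(np.argmin(np.abs(panel.positions - mid)))


def make_h2_pair(
    ld: LDMatrix,
    causal_index_1: int,
    ld_bin: int,
    rng: np.random.Generator,
) -> int:
    """Pick the second (distinct) causal variant uniformly within an |r| bin.

    ``ld_bin`` indexes the bins [0,0.3), [0.3,0.6), [0.6,0.8), [0.8,0.95)
    of |r| relative to ``causal_index_1``.
    """
    lo, hi = LD_BIN_EDGES[ld_bin], LD_BIN_EDGES[ld_bin + 1]
    absr = np.abs(ld.r[:, causal_index_1])
    eligible = np.flatnonzero((absr >= lo) & (absr < hi))
    eligible = eligible[eligible != causal_index_1]
    if eligible.size == 0:
        raise ValueError(f"no SNP in |r| bin [{lo}, {hi}) relative to SNP {causal_index_1}")
    return int(rng.choice(eligible))


def ascertain(ws: LocusSummary, us: LocusSummary) -> bool:
    """Two-stage locus ascertainment.

    Keep iff the well-powered trait is genome-wide significant somewhere in
    the locus (min p < 5e-8) and the underpowered trait shows a suggestive
    signal (min p < 0.01).
    """
    if ws.z.shape != us.z.shape:
        raise ValueError("summaries must cover the same SNP set")
    return bool(ws.min_p < GW_SIG and us.min_p < SUGGESTIVE)


def titrate_h2(
    bin_labels: Sequence[int],
    target: LDComposition | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Largest subsample of H2 loci matching the target bin composition.

    The limiting bin (smallest available/target ratio) sets the subsample
    size; counts in the other bins are rounded down to keep proportions
    within one locus of exact. Returns indices into ``bin_labels``.
    """
    rng = rng or np.random.default_rng()
    props = np.asarray(target.proportions if target else TARGET_COMPOSITION, float)
    labels = np.asarray(bin_labels, int)
    avail = np.array([(labels == b).sum() for b in range(len(props))])
    if np.any(avail == 0):
        raise ValueError(f"empty LD bin(s): {np.flatnonzero(avail == 0).tolist()}")
    total = int(np.floor((avail / props).min()))
    picked: list[np.ndarray] = []
    for b, pb in enumerate(props):
        k = int(np.floor(total * pb)) if avail[b] >= total * pb else avail[b]
        k = min(max(k, 1), avail[b])
        pool = np.flatnonzero(labels == b)
        picked.append(rng.choice(pool, size=k, replace=False))
    return np.sort(np.concatenate(picked))


def scenario_counts(T: int, prop_h0: float, h1_h2_ratio: tuple[int, int]) -> tuple[int, int, int]:
    """Deterministic class counts: round H0, floor H1, remainder to H2."""
    n_h0 = int(round(T * prop_h0))
    rest = T - n_h0
    a, b = h1_h2_ratio
    if a <= 0:
        raise ValueError("H1 share of the ratio must be positive")
    n_h1 = rest if b == 0 else int(np.floor(rest * a / (a + b)))
    return n_h0, n_h1, rest - n_h1


def assemble_scenario(
    T: int,
    prop_h0: float,
    h1_h2_ratio: tuple[int, int],
    pools: dict[str, list[tuple[LocusTruth, LocusSummary, LocusSummary, int]]],
    rng: np.random.Generator,
) -> ScenarioSet:
    """Sample an ascertained scenario without replacement from class pools.

    ``pools`` maps "H0"/"H1"/"H2" to lists of
    (truth, well-powered summary, underpowered summary, panel index); the H2
    pool is expected to be pre-titrated to the LD composition.
    """
    counts = dict(zip(("H0", "H1", "H2"), scenario_counts(T, prop_h0, h1_h2_ratio)))
    truths, ws, us, panels = [], [], [], []
    for hyp, k in counts.items():
        pool = pools.get(hyp, [])
        if len(pool) < k:
            raise ValueError(f"{hyp} pool exhausted: need {k}, have {len(pool)}")
        for i in rng.choice(len(pool), size=k, replace=False):
            t, w, u, pidx = pool[int(i)]
            truths.append(t)
            ws.append(w)
            us.append(u)
            panels.append(pidx)
    return ScenarioSet(truths, ws, us, panels, prop_h0, h1_h2_ratio)


def simulate_multitrait_focal(
    hypothesis: Hypothesis,
    rng: np.random.Generator,
    K: int = 10,
    rho: float = 0.7,
    ld_composition: LDComposition | None = None,
    n1: int = 150_000,
    n2: int = 10_000,
    sigma_sq: float = 5e-5,
    p_share: float = 1.0 / 20.0,
) -> dict[str, np.ndarray]:
    """Focal-SNP z-scores for K well-powered traits plus one underpowered trait.

    The main well-powered trait is causal at the focal SNP. Each of the K-1
    additional well-powered traits shares that causal variant with
    probability ``p_share`` (count ~ Binomial(K-1, p_share)); sharing traits'
    effects are drawn jointly with pairwise correlation ``rho``, and
    distinct-causal traits' focal z is attenuated by an |r| drawn from the
    LD composition (random sign). The underpowered trait follows
    ``hypothesis`` (H0 none / H1 shared / H2 distinct).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    props = np.asarray(
        ld_composition.proportions if ld_composition else TARGET_COMPOSITION, float
    )
    props = props / props.sum()
    s = np.sqrt(sigma_sq)
    n_extra_shared = rng.binomial(K - 1, p_share) if K > 1 else 0
    shared_mask = np.zeros(K, dtype=bool)
    shared_mask[0] = True
    if n_extra_shared:
        shared_mask[1 + np.asarray(rng.choice(K - 1, size=n_extra_shared, replace=False))] = True
    up_shares = hypothesis == "H1"
    n_shared = int(shared_mask.sum()) + int(up_shares)

    # effects of all traits sharing the causal variant: equicorrelated MVN
    cov = np.full((n_shared, n_shared), rho * sigma_sq)
    np.fill_diagonal(cov, sigma_sq)
    shared_betas = rng.multivariate_normal(np.zeros(n_shared), cov)

    def _r_draw() -> float:
        b = rng.choice(len(props), p=props)
        lo, hi = LD_BIN_EDGES[b], LD_BIN_EDGES[b + 1]
        return float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))

    z_wp = np.empty(K)
    k_shared = 0
    for t in range(K):
        if shared_mask[t]:
            mean = np.sqrt(n1) * shared_betas[k_shared]
            k_shared += 1
        else:
            mean = np.sqrt(n1) * float(rng.normal(0, s)) * _r_draw()
        z_wp[t] = mean + rng.standard_normal()

    if hypothesis == "H0":
        z_up = float(rng.standard_normal())
    elif hypothesis == "H1":
        z_up = np.sqrt(n2) * shared_betas[k_shared] + rng.standard_normal()
    else:
        z_up = np.sqrt(n2) * float(rng.normal(0, s)) * _r_draw() + rng.standard_normal()
    return {
        "z_well_powered": z_wp,
        "z_underpowered": np.float64(z_up),
        "shared_mask": shared_mask,
    }


def lead_causal_ld_summary(
    summaries: Sequence[LocusSummary],
    truths: Sequence[LocusTruth],
    lds: Sequence[LDMatrix],
    which_causal: Literal["trait1", "trait2"] = "trait1",
    thresholds: tuple[float, float] = (0.5, 0.8),
) -> dict[str, tuple[float, tuple[float, float]]]:
    """Fraction of loci whose lead SNP tags the causal SNP at r^2 > threshold.

    Returns per threshold the fraction and a 95% normal-approximation
    binomial CI.
    """
    hits = {t: 0 for t in thresholds}
    total = 0
    for s, truth, ld in zip(summaries, truths, lds):
        causal = truth.causal_index_1 if which_causal == "trait1" else truth.causal_index_2
        if causal is None:
            continue
        total += 1
        r2 = ld.r[s.lead_index, causal] ** 2
        for t in thresholds:
            hits[t] += int(r2 > t)
    if total == 0:
        raise ValueError("no loci with the requested causal variant")
    out = {}
    for t in thresholds:
        frac = hits[t] / total
        half = 1.959963984540054 * np.sqrt(max(frac * (1 - frac), 1e-12) / total)
        out[f"r2>{t}"] = (frac, (max(frac - half, 0.0), min(frac + half, 1.0)))
    return out
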