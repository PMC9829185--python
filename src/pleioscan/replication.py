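"""Replication of candidate loci in independent validation cohorts.

Candidates discovered in the underpowered study are carried to a validation
cohort of size N_v. The expected association z at the focal SNP j (the
well-powered lead) is

    E[z_v] = sqrt(N_v) * beta2 * r_jj'

where beta2 is the true underpowered effect at its causal SNP j' and r_jj'
the LD between focal and causal SNP **in the validation panel** (this is how
ancestry mismatch enters: a different-ancestry panel attenuates r). A locus
counts as replicated under the Bonferroni rule when 2 Phi(-|E[z_v]|) <
alpha / M with M the number of candidates carried forward; a stochastic mode
instead draws z_v ~ N(E[z_v], 1) and averages the indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import hypergeom

from .panel import LDMatrix
from .simulate import LocusSummary, LocusTruth

__all__ = [
    "ReplicationPlan",
    "ReplicationOutcome",
    "expected_replication_z",
    "replication_decision",
    "evaluate_strategy",
    "enrichment_test",
]


@dataclass(frozen=True)
class ReplicationPlan:
    n_v: int
    alpha: float = 0.05
    mode: str = "plugin"  # or "stochastic"
    n_draws: int = 200  # stochastic mode only

    def __post_init__(self):
        if self.n_v <= 0:
            raise ValueError("n_v must be positive")
        if self.mode not in ("plugin", "stochastic"):
            raise ValueError("mode must be 'plugin' or 'stochastic'")


@dataclass(frozen=True)
class ReplicationOutcome:
    expected_z: np.ndarray
    replicated: np.ndarray  # per-locus probability (0/1 in plugin mode)
    hypotheses: tuple[str, ...]
    M: int

    @property
    def expected_count(self) -> float:
        return float(self.replicated.sum())

    @property
    def h1_fraction(self) -> float:
        """Fraction of (expected) replications driven by a shared variant."""
        total = self.replicated.sum()
        if total == 0:
            return float("nan")
        is_h1 = np.array([h == "H1" for h in self.hypotheses])
        return float(self.replicated[is_h1].sum() / total)


def expected_replication_z(n_v: int, beta2: float, r_focal_causal: float) -> float:
    """sqrt(N_v) * beta2 * r between focal and causal SNP."""
    if abs(r_focal_causal) > 1:
        raise ValueError("|r| must be <= 1")
    return float(np.sqrt(n_v) * beta2 * r_focal_causal)


def replication_decision(
    z_expected: float,
    M: int,
    alpha: float = 0.05,
    mode: str = "plugin",
    rng: np.random.Generator | None = None,
    n_draws: int = 200,
) -> float:
    """Bonferroni replication decision at the alpha/M level.

    Plug-in mode returns the 0/1 indicator 2 Phi(-|E[z_v]|) < alpha/M;
    stochastic mode returns the Monte-Carlo probability that a noisy
    validation z-score z_v ~ N(E[z_v], 1) passes the same cutoff.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    cut = alpha / M
    if mode == "plugin":
        return float(2.0 * ndtr(-abs(z_expected)) < cut)
    rng = rng or np.random.default_rng()
    zv = z_expected + rng.standard_normal(n_draws)
    return float((2.0 * ndtr(-np.abs(zv)) < cut).mean())


def evaluate_strategy(
    truths: Sequence[LocusTruth],
    well_powered: Sequence[LocusSummary],
    hit_indices: Sequence[int],
    validation_ld: Sequence[LDMatrix] | LDMatrix,
    plan: ReplicationPlan,
    rng: np.random.Generator | None = None,
) -> ReplicationOutcome:
    """Replication outcome for one method's hit set on a simulated scenario.

    For each hit locus, the focal SNP is the well-powered lead and r is read
    from the validation-ancestry LD (per-locus matrix, or one shared matrix).
    H0 hits have no causal variant for the underpowered trait: their expected
    z is 0 by construction, so plug-in mode never replicates them while
    stochastic mode gives them the nominal alpha/M rate.
    """
    hits = list(hit_indices)
    M = len(hits)
    if M == 0:
        return ReplicationOutcome(np.empty(0), np.empty(0), (), 0)
    ez = np.empty(M)
    hyps = []
    for k, i in enumerate(hits):
        truth, ws = truths[i], well_powered[i]
        ld = validation_ld[i] if isinstance(validation_ld, (list, tuple)) else validation_ld
        if truth.hypothesis == "H0":
            ez[k] = 0.0
        else:
            r = float(ld.r[ws.lead_index, truth.causal_index_2])
            ez[k] = expected_replication_z(plan.n_v, truth.effects.beta2, r)
        hyps.append(truth.hypothesis)
    rep = np.array(
        [
            replication_decision(z, M, plan.alpha, plan.mode, rng, plan.n_draws)
            for z in ez
        ]
    )
    return ReplicationOutcome(ez, rep, tuple(hyps), M)


def enrichment_test(
    k_hits: int, n_hits: int, k_base: int, n_base: int
) -> tuple[float, float]:
    """Fold enrichment of a hit rate over a baseline rate, with one-sided p.

    fold = (k_hits/n_hits) / (k_base/n_base); the p-value is the upper
    hypergeometric tail P(X >= k_hits) drawing n_hits from the pooled 2x2
    margin — the one-sided Fisher exact test.
    """
    if min(k_hits, k_base) < 0 or k_hits > n_hits or k_base > n_base:
        raise ValueError("counts must satisfy 0 <= k <= n")
    if n_hits == 0 or n_base == 0 or k_base == 0:
        if n_hits == 0 or n_base == 0:
            raise ValueError("zero denominator")
    rate_base = k_base / n_base
    fold = float("inf") if rate_base == 0 and k_hits > 0 else (
        (k_hits / n_hits) / rate_base if rate_base > 0 else float("nan")
    )
    total = n_hits + n_base
    good = k_hits + k_base
    p = float(hypergeom.sf(k_hits - 1, total, good, n_hits))
    return fold, min(max(p, 0.0), 1.0)
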