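"""Applied locus-screening pipeline on cohort and summary data.

Covers the steps a real two-trait screen runs around the per-locus tests:
candidate-window selection from genome-wide summary statistics, rank-based
inverse-normal phenotype transformation, covariate-adjusted per-SNP
association with mean imputation of missing covariates, fixed-effect
inverse-variance-weighted (IVW) meta-analysis across cohorts, the
within-cohort phenotype-permutation null engine, and the eQTL causal-chain
scan that links gene expression, a clinical trait and the underpowered trait
at one variant.

Summary statistics travel as pandas DataFrames with columns
``id, chrom, pos, ref, alt, beta, se, z, p, n`` (whitespace/tab-delimited on
disk); gene annotation is BED-like (``gene_id, chrom, tss, strand, biotype``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .simulate import GW_SIG, SUGGESTIVE, CohortData, LocusSummary

__all__ = [
    "SUMSTAT_COLUMNS",
    "LocusWindow",
    "ChainResult",
    "read_sumstats",
    "write_sumstats",
    "select_candidate_loci",
    "rank_inverse_normal",
    "covariate_assoc",
    "ivw_meta",
    "ivw_meta_summaries",
    "permutation_null_engine",
    "eqtl_chain_scan",
    "gwas_locus_eqtl_mode",
]

SUMSTAT_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "beta", "se", "z", "p", "n")

HALF_WIDTH_BP = 100_000
MHC_REGION = ("6", 25_000_000, 35_000_000)  # extended MHC, GRCh37
SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY", "23", "24"})


@dataclass(frozen=True)
class LocusWindow:
    """A 200kb analysis window anchored at a focal SNP (clinical-trait lead)."""

    focal_id: str
    chrom: str
    pos: int
    half_width: int = HALF_WIDTH_BP

    @property
    def start(self) -> int:
        return max(self.pos - self.half_width, 1)

    @property
    def end(self) -> int:
        return self.pos + self.half_width

    def contains(self, chrom, pos) -> np.ndarray:
        return (np.asarray(chrom).astype(str) == self.chrom) & (
            (np.asarray(pos) >= self.start) & (np.asarray(pos) <= self.end)
        )


@dataclass(frozen=True)
class ChainResult:
    """One candidate causal chain: eQTL <-> clinical trait <-> underpowered trait."""

    focal_id: str
    clinical_trait: str
    osa_trait: str
    gene: str
    tissue: str
    eqtl_coloc_p: float
    eqtl_fdr: float
    clin_osa_coloc_p: float
    clin_osa_fdr: float


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    missing = set(SUMSTAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistic table missing columns: {sorted(missing)}")
    return df.assign(chrom=df["chrom"].astype(str))


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.loc[:, list(SUMSTAT_COLUMNS)].to_csv(path, sep="\t", index=False)


def select_candidate_loci(
    clinical: pd.DataFrame,
    osa: pd.DataFrame,
    half_width: int = HALF_WIDTH_BP,
    gw_sig: float = GW_SIG,
    suggestive: float = SUGGESTIVE,
    mhc: tuple[str, int, int] | None = MHC_REGION,
    exclude_chroms: frozenset = SEX_CHROMS,
) -> list[LocusWindow]:
    """Candidate windows: clinical genome-wide significance plus a suggestive
    underpowered signal in the same window.

    Clinical leads are picked greedily by p-value; once a lead claims a
    window, other genome-wide-significant SNPs inside it are absorbed rather
    than spawning their own windows. Windows on the sex chromosomes or
    overlapping the extended MHC region are excluded.
    """
    cand = clinical[clinical["p"] < gw_sig].sort_values("p", kind="stable")
    windows: list[LocusWindow] = []
    for row in cand.itertuples():
        chrom = str(row.chrom)
        if chrom in exclude_chroms:
            continue
        if mhc and chrom == mhc[0] and mhc[1] <= row.pos <= mhc[2]:
            continue
        if any(w.chrom == chrom and abs(w.pos - row.pos) <= 2 * half_width for w in windows):
            continue
        w = LocusWindow(str(row.id), chrom, int(row.pos), half_width)
        in_w = w.contains(osa["chrom"], osa["pos"])
        if in_w.any() and osa.loc[in_w, "p"].min() < suggestive:
            windows.append(w)
    return sorted(windows, key=lambda w: (w.chrom, w.pos))


def rank_inverse_normal(values: Sequence[float], offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps ranks through Phi^{-1}((rank - c) / (n - 2c + 1)), ties receiving
    their average rank. Raises on a constant vector.
    """
    x = np.asarray(values, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector with n >= 2")
    if np.all(x == x[0]):
        raise ValueError("constant vector cannot be rank-normalized")
    ranks = rankdata(x, method="average")
    return ndtri((ranks - offset) / (x.size - 2 * offset + 1))


def _prepare_covariates(cov: np.ndarray | None, n: int) -> np.ndarray | None:
    """Mean-impute missing values; drop constant columns with a warning."""
    if cov is None:
        return None
    c = np.array(cov, float, copy=True)
    if c.ndim != 2 or c.shape[0] != n:
        raise ValueError("covariates must be n x k")
    for j in range(c.shape[1]):
        nan = np.isnan(c[:, j])
        if nan.all():
            c[:, j] = 0.0
        elif nan.any():
            c[nan, j] = c[~nan, j].mean()
    keep = c.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping constant covariate column(s): {np.flatnonzero(~keep).tolist()}",
            stacklevel=3,
        )
        c = c[:, keep]
    return c if c.shape[1] else None


def covariate_assoc(cohort: CohortData, ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-SNP linear regression adjusted for covariates.

    Missing covariate values are mean-imputed per column; collinear
    covariates raise with the offending columns named. Implemented by
    residualizing phenotype and dosages on the covariates
    (Frisch-Waugh-Lovell), which reproduces the multiple-regression slope,
    standard error and t statistic for the genotype term.
    """
    x, y = cohort.dosages, cohort.phenotype
    n, m = x.shape
    c = _prepare_covariates(cohort.covariates, n)
    if c is None:
        design = np.ones((n, 1))
    else:
        design = np.column_stack([np.ones(n), c])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            corr = np.corrcoef(c, rowvar=False)
            pairs = [
                (int(i), int(j))
                for i in range(corr.shape[0])
                for j in range(i + 1, corr.shape[0])
                if abs(corr[i, j]) > 1 - 1e-10
            ]
            raise ValueError(f"collinear covariate columns: {pairs or 'rank-deficient design'}")
    k = design.shape[1]
    proj, *_ = np.linalg.lstsq(design, np.column_stack([y, x]), rcond=None)
    resid = np.column_stack([y, x]) - design @ proj
    ry, rx = resid[:, 0], resid[:, 1:]
    sxx = (rx**2).sum(axis=0)
    if np.any(sxx <= 0):
        raise ValueError("dosage column collinear with covariates")
    beta = (rx.T @ ry) / sxx
    df = n - k - 1
    rss = (ry**2).sum() - beta**2 * sxx
    se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
    with np.errstate(divide="ignore"):
        z = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    return pd.DataFrame(
        {
            "id": list(ids) if ids is not None else [f"snp{j}" for j in range(m)],
            "chrom": "0",
            "pos": np.arange(m),
            "ref": "A",
            "alt": "B",
            "beta": beta,
            "se": se,
            "z": z,
            "p": 2.0 * ndtr(-np.abs(z)),
            "n": n,
        }
    )


def ivw_meta(per_cohort: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance-weighted meta-analysis across cohorts.

    Only variants present in every cohort are kept. Weights are 1/se^2;
    the pooled effect is sum(w b)/sum(w) with se 1/sqrt(sum w), and z and p
    are recomputed from the pooled values.
    """
    if not per_cohort:
        raise ValueError("need at least one cohort")
    common = set(per_cohort[0]["id"])
    for df in per_cohort[1:]:
        common &= set(df["id"])
    if not common:
        raise ValueError("no variant present in all cohorts")
    aligned = [
        df[df["id"].isin(common)].set_index("id").sort_index() for df in per_cohort
    ]
    base = aligned[0]
    if (base["se"] <= 0).any():
        raise ValueError("standard errors must be positive")
    w = np.array([1.0 / df["se"] ** 2 for df in aligned])
    b = np.array([df["beta"] for df in aligned])
    wsum = w.sum(axis=0)
    beta = (w * b).sum(axis=0) / wsum
    se = 1.0 / np.sqrt(wsum)
    z = beta / se
    return pd.DataFrame(
        {
            "id": base.index,
            "chrom": base["chrom"].values,
            "pos": base["pos"].values,
            "ref": base["ref"].values,
            "alt": base["alt"].values,
            "beta": beta,
            "se": se,
            "z": z,
            "p": 2.0 * ndtr(-np.abs(z)),
            "n": np.sum([df["n"] for df in aligned], axis=0),
        }
    ).reset_index(drop=True)


def ivw_meta_summaries(summaries: Sequence[LocusSummary]) -> LocusSummary:
    """IVW meta-analysis of per-cohort z-scores on the standardized scale.

    With standardized dosages each cohort's se is ~1/sqrt(n_c), so the
    fixed-effect pooled z is sum(sqrt(n_c) z_c) / sqrt(sum n_c).
    """
    if not summaries:
        raise ValueError("need at least one summary")
    ns = np.array([s.n for s in summaries], float)
    zs = np.array([s.z for s in summaries])
    z = (np.sqrt(ns)[:, None] * zs).sum(axis=0) / np.sqrt(ns.sum())
    return LocusSummary.from_z(z, int(ns.sum()))


def permutation_null_engine(
    cohorts: Sequence[CohortData],
    statistic: Callable[[LocusSummary], float],
    rng: np.random.Generator,
    n_max: int = 100_000,
    scan: Callable[[CohortData], LocusSummary] | None = None,
) -> Iterator[float]:
    """Stream of null statistics from within-cohort phenotype permutation.

    Each iteration shuffles every cohort's phenotype (covariates stay
    attached to their individuals), re-runs the per-cohort association scan,
    meta-analyzes across cohorts, and yields ``statistic`` of the pooled
    summary.
    """
    from .simulate import assoc_scan

    def _default_scan(c: CohortData) -> LocusSummary:
        if c.covariates is not None:
            df = covariate_assoc(c)
            return LocusSummary(df["z"].to_numpy(), df["p"].to_numpy(), c.n)
        return assoc_scan(c)

    scan = scan or _default_scan
    for _ in range(n_max):
        perm = [
            CohortData(c.dosages, rng.permutation(c.phenotype), c.covariates)
            for c in cohorts
        ]
        yield statistic(ivw_meta_summaries([scan(c) for c in perm]))


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p, kind="stable")
    n = p.size
    raw = p[order] * n / np.arange(1, n + 1)
    stepped = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    out = np.empty(n)
    out[order] = stepped
    return out


def eqtl_chain_scan(
    hit_loci: Sequence[LocusWindow],
    eqtl_tables: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    clin_osa: pd.DataFrame,
    coloc_p: Callable[[LocusWindow, pd.DataFrame], float],
    tss_max_dist: int = 1_000_000,
    locus_eqtl_p: float = 0.05,
    fdr_eqtl: float = 0.05,
    fdr_clin_osa: float = 0.20,
) -> list[ChainResult]:
    """Scan candidate pleiotropic loci for eQTL <-> clinical <-> underpowered chains.

    ``eqtl_tables`` is a long summary table with additional ``gene`` and
    ``tissue`` columns; ``gene_annotation`` is BED-like with ``gene_id``,
    ``chrom``, ``tss`` and ``biotype``; ``clin_osa`` has one row per focal id
    with ``clinical_trait``, ``osa_trait``, ``coloc_p`` and ``fdr`` for the
    clinical <-> underpowered link. ``coloc_p`` runs the clinical <-> eQTL
    colocalization for one (window, eQTL subtable) and returns its p-value.

    Genes must be protein-coding, have their TSS within ``tss_max_dist`` of
    the focal SNP, and show at least one locus SNP with eQTL p <= 0.05. The
    FDR over colocalization p-values is computed per tissue, and chains are
    assembled at eQTL-link FDR < 0.05 and clinical-link FDR < 0.2.
    """
    genes = gene_annotation.set_index("gene_id")
    rows: list[dict] = []
    for w in hit_loci:
        meta = clin_osa[clin_osa["focal_id"] == w.focal_id]
        if meta.empty or float(meta["fdr"].iloc[0]) >= fdr_clin_osa:
            continue
        for (gene, tissue), sub in eqtl_tables.groupby(["gene", "tissue"], sort=True):
            if gene not in genes.index:
                continue
            g = genes.loc[gene]
            if g["biotype"] != "protein_coding" or str(g["chrom"]) != w.chrom:
                continue
            if abs(int(g["tss"]) - w.pos) > tss_max_dist:
                continue
            in_w = sub[w.contains(sub["chrom"], sub["pos"])]
            if in_w.empty or in_w["p"].min() > locus_eqtl_p:
                continue
            rows.append(
                {
                    "focal_id": w.focal_id,
                    "clinical_trait": str(meta["clinical_trait"].iloc[0]),
                    "osa_trait": str(meta["osa_trait"].iloc[0]),
                    "gene": gene,
                    "tissue": tissue,
                    "eqtl_coloc_p": float(coloc_p(w, in_w)),
                    "clin_osa_coloc_p": float(meta["coloc_p"].iloc[0]),
                    "clin_osa_fdr": float(meta["fdr"].iloc[0]),
                }
            )
    if not rows:
        return []
    df = pd.DataFrame(rows)
    df["eqtl_fdr"] = np.nan
    for _, idx in df.groupby("tissue").groups.items():
        df.loc[idx, "eqtl_fdr"] = _bh_fdr(df.loc[idx, "eqtl_coloc_p"].to_numpy())
    kept = df[df["eqtl_fdr"] < fdr_eqtl]
    return [
        ChainResult(
            r.focal_id, r.clinical_trait, r.osa_trait, r.gene, r.tissue,
            r.eqtl_coloc_p, r.eqtl_fdr, r.clin_osa_coloc_p, r.clin_osa_fdr,
        )
        for r in kept.itertuples()
    ]


def gwas_locus_eqtl_mode(
    osa_locus: LocusWindow,
    eqtl_tables: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    coloc_p: Callable[[LocusWindow, pd.DataFrame], float],
    eqtl_gw_sig: float = GW_SIG,
    tss_max_dist: int = 1_000_000,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Use eQTLs as the well-powered traits at a known underpowered-GWAS locus.

    Qualifying eQTLs have genome-wide significance (p < 5e-8) at some SNP in
    the 200kb window around the known associated SNP and a TSS within 1Mb.
    Returns a table of per-eQTL colocalization p-values with BH FDR.
    """
    genes = gene_annotation.set_index("gene_id")
    rows = []
    for (gene, tissue), sub in eqtl_tables.groupby(["gene", "tissue"], sort=True):
        if gene not in genes.index:
            continue
        g = genes.loc[gene]
        if str(g["chrom"]) != osa_locus.chrom or abs(int(g["tss"]) - osa_locus.pos) > tss_max_dist:
            continue
        in_w = sub[osa_locus.contains(sub["chrom"], sub["pos"])]
        if in_w.empty or in_w["p"].min() >= eqtl_gw_sig:
            continue
        rows.append(
            {
                "focal_id": osa_locus.focal_id,
                "gene": gene,
                "tissue": tissue,
                "coloc_p": float(coloc_p(osa_locus, in_w)),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["focal_id", "gene", "tissue", "coloc_p", "fdr", "hit"])
    df = pd.DataFrame(rows)
    df["fdr"] = _bh_fdr(df["coloc_p"].to_numpy())
    df["hit"] = df["fdr"] < fdr_cut
    return df
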