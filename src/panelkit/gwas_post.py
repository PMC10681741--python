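"""GWAS variant filters, association fits, genomic control and loci.

Single-SNP association is ordinary least squares of a quantitative
phenotype on genotype dose plus covariates; genome scans use an
algebraically identical residualized (Frisch–Waugh) fast path.  SNP
filters follow the printed operators (MAF > 0.01, exact HWE p > 1e-6,
missing rate < 0.01, all strict); significance is the genome-wide
threshold p < 5e-8.  Significant SNPs are grouped into loci with a
left-anchored fixed-width 1-Mb window and loci from two analyses are
declared shared when their centers lie within 500 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .panel_qc import _het_log_pmf, _het_support
from .vcf_io import MISSING, AssocRecord

GENOME_WIDE_ALPHA = 5e-8
LOCUS_WINDOW = 1_000_000     # bp, fixed-width grouping window
LOCUS_MATCH_DIST = 500_000   # bp, shared-locus center distance
MAF_MIN = 0.01
HWE_P_MIN = 1e-6
MISSING_RATE_MAX = 0.01

#: Median of the 1-df chi-square distribution, the null λ_gc denominator.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...


# ---------------------------------------------------------------------------
# per-SNP statistics
# ---------------------------------------------------------------------------

def maf(column: np.ndarray) -> float:
    """Minor allele frequency min(p, 1-p) over non-missing genotype codes."""
    col = np.asarray(column)
    ok = col != MISSING
    if not np.any(ok):
        raise ValueError("all genotypes missing: MAF undefined")
    p = float(col[ok].mean() / 2.0)
    return min(p, 1.0 - p)


def missing_rate(column: np.ndarray) -> float:
    """Fraction of missing genotype calls in the column."""
    col = np.asarray(column)
    if col.size == 0:
        raise ValueError("empty genotype column")
    return float(np.mean(col == MISSING))


def hwe_exact_p(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Conditional on the allele totals, sums the probabilities of every
    heterozygote count (same parity) whose exact conditional probability
    does not exceed that of the observed count.  Monomorphic sites return
    1, and the value is invariant to swapping the homozygote counts.
    """
    for name, v in (("n_homref", n_homref), ("n_het", n_het),
                    ("n_homalt", n_homalt)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_alt = n_het + 2 * min(n_homref, n_homalt)  # minor-allele total
    support = _het_support(n, n_alt)
    probs = np.exp(_het_log_pmf(support, n, n_alt))
    p_obs = probs[support == n_het]
    if p_obs.size == 0:  # parity mismatch cannot occur for valid counts
        raise ValueError("observed het count outside conditional support")
    # small relative slack so float noise cannot drop the observed term
    p = float(probs[probs <= p_obs[0] * (1 + 1e-12)].sum())
    return min(1.0, p)


def filter_gwas_snps(
    mafs: Sequence[float],
    hwe_ps: Sequence[float],
    missing_rates: Sequence[float],
    maf_min: float = MAF_MIN,
    hwe_p_min: float = HWE_P_MIN,
    missing_max: float = MISSING_RATE_MAX,
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Keep SNPs with MAF > 0.01, HWE p > 1e-6 and missing rate < 0.01.

    All three comparisons are strict.  Returns (kept indices, removal log
    with the first violated rule per dropped SNP).
    """
    mafs = np.asarray(mafs, dtype=float)
    hwe_ps = np.asarray(hwe_ps, dtype=float)
    missing_rates = np.asarray(missing_rates, dtype=float)
    kept, log = [], []
    for j in range(mafs.size):
        if not mafs[j] > maf_min:
            log.append((j, "maf"))
        elif not hwe_ps[j] > hwe_p_min:
            log.append((j, "hwe"))
        elif not missing_rates[j] < missing_max:
            log.append((j, "missing"))
        else:
            kept.append(j)
    return np.asarray(kept, dtype=np.intp), log


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def linear_assoc(
    phenotype: np.ndarray,
    genotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> tuple[float, float, float]:
    """OLS of phenotype on genotype dose (+ intercept + covariates).

    Rows with a missing genotype code are dropped.  Returns (beta, se, p)
    with the p-value from the two-sided t distribution of beta/se; a
    rank-deficient or variance-free design returns NaNs.
    """
    import statsmodels.api as sm

    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(genotype)
    ok = g != MISSING
    y, gk = y[ok], g[ok].astype(float)
    if np.ptp(gk) == 0:
        return (math.nan, math.nan, math.nan)
    design = [gk, np.ones_like(gk)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        design.append(cov[ok])
    X = np.column_stack(design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return (math.nan, math.nan, math.nan)
    fit = sm.OLS(y, X).fit()
    return (float(fit.params[0]), float(fit.bse[0]), float(fit.pvalues[0]))


def gwas_scan(
    phenotype: np.ndarray,
    genotypes: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP OLS over a samples × sites code matrix.

    Residualizes the phenotype and every genotype column on the
    intercept-plus-covariate block (Frisch–Waugh), then fits each residual
    simple regression in closed form — numerically identical to
    :func:`linear_assoc` on complete columns.  Columns containing missing
    codes fall back to the per-SNP path.  Returns (beta, se, p) arrays.
    """
    y = np.asarray(phenotype, dtype=float)
    G = np.asarray(genotypes)
    n, m = G.shape
    C = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        C = np.column_stack([C, cov])
    k = C.shape[1]
    df = n - k - 1
    if df < 1:
        raise ValueError(f"too few samples ({n}) for {k} covariate columns")

    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    yty = float(y_r @ y_r)

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    has_missing = np.any(G == MISSING, axis=0)
    complete = ~has_missing
    if np.any(complete):
        Gc = G[:, complete].astype(float)
        G_r = Gc - Q @ (Q.T @ Gc)
        gg = np.einsum("ij,ij->j", G_r, G_r)
        gy = G_r.T @ y_r
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(gg > 0, gy / np.maximum(gg, 1e-300), np.nan)
            rss = yty - b * b * gg
            s2 = rss / df
            s = np.sqrt(np.maximum(s2, 0) / np.maximum(gg, 1e-300))
        b[gg == 0] = np.nan
        s[gg == 0] = np.nan
        beta[complete] = b
        se[complete] = s
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # columns with missing calls drop rows, so they get their own exact fit
    for j in np.flatnonzero(has_missing):
        beta[j], se[j], p[j] = linear_assoc(y, G[:, j], covariates)
    return beta, se, p


def lambda_gc(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


# ---------------------------------------------------------------------------
# loci
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A run of genome-wide-significant SNPs grouped by a fixed window."""

    chrom: str
    start: int
    end: int
    center: float
    lead: AssocRecord
    n_sig: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start > end")
        if self.n_sig < 1:
            raise ValueError("locus must contain at least one SNP")


@dataclass(frozen=True)
class LocusMatch:
    shared: tuple[tuple[Locus, Locus], ...]
    unique_a: tuple[Locus, ...]
    unique_b: tuple[Locus, ...]


def significant(
    results: Sequence[AssocRecord], alpha: float = GENOME_WIDE_ALPHA
) -> list[AssocRecord]:
    """SNPs with p strictly below alpha, sorted by (chrom, pos)."""
    hits = [r for r in results if r.p < alpha]
    return sorted(hits, key=lambda r: (r.chrom, r.pos))


def group_loci(
    snps: Sequence[AssocRecord], window: int = LOCUS_WINDOW
) -> list[Locus]:
    """Left-anchored fixed-width grouping of significant SNPs into loci.

    Per chromosome: open a window at the first unassigned SNP position p0;
    every SNP with position < p0 + window joins that locus; repeat from the
    next unassigned SNP.  Each SNP lands in exactly one locus and every
    locus spans strictly less than the window.
    """
    keys = [(r.chrom, r.pos) for r in snps]
    if keys != sorted(keys):
        raise ValueError("SNPs must be sorted by (chrom, pos)")
    loci: list[Locus] = []
    i, n = 0, len(snps)
    while i < n:
        chrom = snps[i].chrom
        p0 = snps[i].pos
        j = i
        while j < n and snps[j].chrom == chrom and snps[j].pos < p0 + window:
            j += 1
        members = snps[i:j]
        lead = min(members, key=lambda r: (r.p, r.pos))
        loci.append(Locus(
            chrom=chrom, start=members[0].pos, end=members[-1].pos,
            center=(members[0].pos + members[-1].pos) / 2.0,
            lead=lead, n_sig=len(members),
        ))
        i = j
    return loci


def match_loci(
    loci_a: Sequence[Locus],
    loci_b: Sequence[Locus],
    max_dist: int = LOCUS_MATCH_DIST,
) -> LocusMatch:
    """One-to-one greedy matching of loci by ascending center distance.

    Same-chromosome pairs whose centers differ by at most ``max_dist`` are
    candidates; the closest pair is matched first, each locus at most
    once.  The tie-break is symmetric, so swapping the inputs preserves
    the shared count.
    """
    candidates = []
    for i, a in enumerate(loci_a):
        for j, b in enumerate(loci_b):
            if a.chrom != b.chrom:
                continue
            d = abs(a.center - b.center)
            if d <= max_dist:
                tie = (min(a.center, b.center), max(a.center, b.center))
                candidates.append((d, tie, i, j))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = []
    for d, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared.append((loci_a[i], loci_b[j]))
    unique_a = tuple(l for i, l in enumerate(loci_a) if i not in used_a)
    unique_b = tuple(l for j, l in enumerate(loci_b) if j not in used_b)
    return LocusMatch(shared=tuple(shared), unique_a=unique_a,
                      unique_b=unique_b)
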