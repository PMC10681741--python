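"""Reference-panel construction QC.

The cascade mirrors how high-coverage WGS panels are built: per-sample gates
on contamination / duplication / depth / GC, masking of low-confidence
genotypes (GQ < 20), splitting multiallelic SNPs into biallelic rows,
removal of degenerate sites (AC < 1, missing ALT, heterozygote excess,
failed FILTER), and greedy pruning of close relatives from a KING kinship
table.  Thresholds follow the printed operators exactly: contamination and
duplication gates are strict ``<``; depth is inclusive ``>=``; the GC window
is a closed interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .vcf_io import MISSING, GenotypeMatrix, KinshipPair, VariantSite

# sample-level gates
FREEMIX_MAX = 0.03     # contamination, strict <
DUP_RATE_MAX = 0.05    # read duplication, strict <
DEPTH_MIN = 10.0       # mean fold-coverage, inclusive >=
GC_RANGE = (40.0, 44.0)  # percent, closed interval

GQ_THRESHOLD = 20      # genotypes below this are set missing
EXCESS_HET_MAX = 54.69  # phred-scaled; sites strictly above are dropped

#: KING kinship inference boundaries: a pair above ``2^-(d+1.5)`` is related
#: at degree <= d (duplicates sit above 2^-1.5).
KING_DEGREE_CUTS = {0: 2 ** -1.5, 1: 2 ** -2.5, 2: 2 ** -3.5, 3: 2 ** -4.5}


@dataclass(frozen=True)
class SampleMetrics:
    """Per-sample sequencing QC metrics consumed by the sample gates."""

    freemix: float      # contamination fraction estimate, [0, 1]
    dup_rate: float     # read duplication fraction, [0, 1]
    mean_depth: float   # mean fold-coverage
    gc: float           # GC content, percent

    def __post_init__(self) -> None:
        for name in ("freemix", "dup_rate", "mean_depth", "gc"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"metric '{name}' missing or non-finite: {v!r}")


@dataclass(frozen=True)
class QCDecision:
    sample: str
    passed: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("pass flag inconsistent with reasons list")


def evaluate_sample_qc(metrics: SampleMetrics, sample: str = "") -> QCDecision:
    """Apply the four sample gates; every violated gate is listed.

    Pass requires freemix < 0.03, dup_rate < 0.05, mean_depth >= 10 and
    GC in [40, 44].
    """
    reasons = []
    if not metrics.freemix < FREEMIX_MAX:
        reasons.append("contamination")
    if not metrics.dup_rate < DUP_RATE_MAX:
        reasons.append("duplication")
    if not metrics.mean_depth >= DEPTH_MIN:
        reasons.append("depth")
    if not GC_RANGE[0] <= metrics.gc <= GC_RANGE[1]:
        reasons.append("gc")
    return QCDecision(sample=sample, passed=not reasons, reasons=tuple(reasons))


def mask_low_gq(
    genotypes: GenotypeMatrix, threshold: int = GQ_THRESHOLD
) -> GenotypeMatrix:
    """Set genotype codes with GQ strictly below ``threshold`` to missing.

    The GQ layer itself is preserved; GQ exactly at the threshold is kept.
    """
    if genotypes.gq is None:
        raise ValueError("genotype matrix has no GQ layer to mask on")
    out = genotypes.copy()
    low = out.gq < threshold
    out.codes[low] = MISSING
    if out.allele_pairs is not None:
        out.allele_pairs[low] = MISSING
    return out


# ---------------------------------------------------------------------------
# multiallelic splitting
# ---------------------------------------------------------------------------

def split_multiallelic(
    site: VariantSite,
    gt_pairs: np.ndarray,
    other_alt_to: str = "ref",
) -> list[tuple[VariantSite, np.ndarray]]:
    """Split a k-alt record into k biallelic rows, one per ALT allele.

    ``gt_pairs`` is the (n_samples, 2) raw allele-index column for the site
    (missing = -1).  In row *j* the code counts copies of alt *j* only;
    alleles matching a *different* alt count as reference by default
    (``other_alt_to="ref"``) or may be masked (``other_alt_to="missing"``).
    AC/AN/AF are recomputed per output row.  Biallelic input returns the
    site unchanged (counts refreshed).
    """
    if other_alt_to not in ("ref", "missing"):
        raise ValueError(f"other_alt_to must be 'ref' or 'missing', "
                         f"got {other_alt_to!r}")
    gt_pairs = np.asarray(gt_pairs)
    if gt_pairs.ndim != 2 or gt_pairs.shape[1] != 2:
        raise ValueError("gt_pairs must be (n_samples, 2)")
    missing = np.any(gt_pairs < 0, axis=1)

    out: list[tuple[VariantSite, np.ndarray]] = []
    for j, alt in enumerate(site.alts, start=1):
        codes = np.sum(gt_pairs == j, axis=1).astype(np.int8)
        if other_alt_to == "missing" and len(site.alts) > 1:
            other = np.any((gt_pairs > 0) & (gt_pairs != j), axis=1)
            codes[other] = MISSING
        codes[missing] = MISSING
        ok = codes != MISSING
        ac, an = int(codes[ok].sum()), int(2 * ok.sum())
        row = VariantSite(
            chrom=site.chrom, pos=site.pos, id=site.id, ref=site.ref,
            alts=(alt,), excess_het=site.excess_het, filter=site.filter,
            info_score=site.info_score,
        ).with_counts((ac,), an)
        out.append((row, codes))
    return out


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def compute_af(ac: int, an: int) -> float:
    """Alternate allele frequency AF = AC/AN."""
    if an == 0:
        raise ValueError("AN = 0: allele frequency undefined")
    if not 0 <= ac <= an:
        raise ValueError(f"AC {ac} outside [0, AN={an}]")
    return ac / an


def filter_sites(
    sites: Sequence[VariantSite],
    genotypes: GenotypeMatrix,
    excess_het_max: float = EXCESS_HET_MAX,
) -> tuple[list[int], list[tuple[int, str]]]:
    """Drop degenerate / low-quality sites after GQ masking.

    Removal rules, applied in order with the first match logged:

    1. ``AC<1`` — no alternate allele survives among non-missing genotypes;
    2. ``missing_alt`` — the ALT column is absent (``.``);
    3. ``excess_het`` — annotated ExcessHet strictly above ``excess_het_max``;
    4. ``filter_fail`` — FILTER is anything but PASS.

    Returns (kept site indices, removal log of (index, reason)).
    """
    kept: list[int] = []
    removed: list[tuple[int, str]] = []
    for j, site in enumerate(sites):
        col = genotypes.codes[:, j]
        ok = col != MISSING
        ac = int(col[ok].sum())
        if ac < 1:
            removed.append((j, "AC<1"))
        elif site.alts == (".",) or site.alts == ("",):
            removed.append((j, "missing_alt"))
        elif site.excess_het is not None and site.excess_het > excess_het_max:
            removed.append((j, "excess_het"))
        elif (site.filter or "PASS") != "PASS":
            removed.append((j, "filter_fail"))
        else:
            kept.append(j)
    return kept, removed


# ---------------------------------------------------------------------------
# heterozygote-excess exact score
# ---------------------------------------------------------------------------

def _het_log_pmf(n_het_values: np.ndarray, n: int, n_alt: int) -> np.ndarray:
    """Log pmf of the heterozygote count conditional on allele totals.

    Under random union of gametes, given ``n`` diploid genotypes carrying
    ``n_alt`` alternate alleles in ``2n`` total, the chance of ``h``
    heterozygotes is  n! / (n_rr! n_het! n_aa!) * 2^h / C(2n, n_alt)
    with n_aa = (n_alt - h)/2 and n_rr = n - h - n_aa.
    """
    h = np.asarray(n_het_values, dtype=np.int64)
    n_aa = (n_alt - h) // 2
    n_rr = n - h - n_aa
    log_denom = (gammaln(2 * n + 1) - gammaln(n_alt + 1)
                 - gammaln(2 * n - n_alt + 1))
    return (gammaln(n + 1) - gammaln(n_rr + 1) - gammaln(h + 1)
            - gammaln(n_aa + 1) + h * math.log(2) - log_denom)


def _het_support(n: int, n_alt: int) -> np.ndarray:
    """All admissible heterozygote counts for the given allele totals."""
    n_ref = 2 * n - n_alt
    h_max = min(n_alt, n_ref)
    h_min = n_alt % 2
    return np.arange(h_min, h_max + 1, 2)


def compute_excess_het(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Phred-scaled one-sided exact heterozygote-excess score.

    The score is ``-10*log10 P(H >= n_het)`` where *H* follows the exact
    conditional distribution of heterozygote counts given the observed
    allele totals under Hardy–Weinberg equilibrium.  Monomorphic
    configurations score 0 (the tail probability is 1).
    """
    for name, v in (("n_homref", n_homref), ("n_het", n_het),
                    ("n_homalt", n_homalt)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_alt = n_het + 2 * n_homalt
    support = _het_support(n, n_alt)
    logp = _het_log_pmf(support, n, n_alt)
    tail = support >= n_het
    log_tail = logsumexp(logp[tail])
    p = min(1.0, float(np.exp(log_tail)))
    return max(0.0, -10.0 * math.log10(p))


# ---------------------------------------------------------------------------
# relative pruning
# ---------------------------------------------------------------------------

def prune_relatives(
    pairs: Iterable[KinshipPair],
    max_degree: int = 2,
    cut: Optional[float] = None,
) -> set[str]:
    """Greedy vertex cover over the relatedness graph.

    An edge joins two samples whose kinship exceeds the KING boundary for
    ``max_degree`` (default 2nd degree: kinship > 0.0884).  The sample with
    the most remaining related partners is removed first (ties broken by
    sample id), until no related pair survives.
    """
    if cut is None:
        if max_degree not in KING_DEGREE_CUTS:
            raise ValueError(
                f"unknown degree {max_degree}; known: "
                f"{sorted(KING_DEGREE_CUTS)}"
            )
        cut = KING_DEGREE_CUTS[max_degree]

    adj: dict[str, set[str]] = {}
    for p in pairs:
        if p.kinship > cut:
            adj.setdefault(p.sample_a, set()).add(p.sample_b)
            adj.setdefault(p.sample_b, set()).add(p.sample_a)

    removed: set[str] = set()
    while any(adj.values()):
        best_deg = max(len(nbrs) for nbrs in adj.values())
        victim = min(s for s in adj if len(adj[s]) == best_deg)
        removed.add(victim)
        for other in adj.pop(victim):
            adj[other].discard(victim)
    return removed
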