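"""Imputation-accuracy evaluation.

Truth (WGS) and imputed genotype sets are matched on exact
``(chrom, pos, ref, alt)``; each matched, non-missing genotype pair is
classified into a 3x3 confusion table collapsed to TP/FP/FN/TN, from which
the ratio metrics, precision (TP/(TP+FP)), sensitivity (TP/(TP+FN)) and
non-reference concordance (NRC, genotype-aware recall) are derived.
Per-sample dosage R^2 is the squared Pearson correlation of truth hard
calls with imputed dosages.  Sites are additionally tiered by their
imputation information score (high > 0.8, medium in [0.4, 0.8], low < 0.4)
within allele-frequency bins, reproducing the shape of a standard
well-imputed-variant summary table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .vcf_io import MISSING, GenotypeMatrix, VariantSite

POLICIES = ("allele-dose", "mismatch-to-FP", "mismatch-to-FN")

AF_BIN_LABELS = ("AF<=1%", "1%<AF<=5%", "AF>5%")
TIER_HIGH_MIN = 0.8   # strict >
TIER_MEDIUM_MIN = 0.4  # inclusive both ends of [0.4, 0.8]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def round_pct(x: float, digits: int = 2) -> float:
    """Round half-up (printed-table convention), on the percent scale."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# site matching
# ---------------------------------------------------------------------------

class SiteMatch(NamedTuple):
    pairs: list[tuple[int, int]]       # (truth index, imputed index)
    unmatched_truth: list[int]
    unmatched_imputed: list[int]


def _check_sorted(sites: Sequence[VariantSite], label: str) -> None:
    keys = [(s.chrom, s.pos) for s in sites]
    if keys != sorted(keys):
        raise ValueError(f"{label} sites are not sorted by (chrom, pos)")


def match_sites(
    truth: Sequence[VariantSite], imputed: Sequence[VariantSite]
) -> SiteMatch:
    """Pair sites on exact (chrom, pos, ref, alt) identity.

    Both lists must already be sorted by (chrom, pos).  Swapped ref/alt or
    any allele difference leaves a site unmatched — no harmonization.
    """
    _check_sorted(truth, "truth")
    _check_sorted(imputed, "imputed")
    by_key = {s.key: j for j, s in enumerate(imputed)}
    pairs: list[tuple[int, int]] = []
    matched_imp: set[int] = set()
    unmatched_truth: list[int] = []
    for i, s in enumerate(truth):
        j = by_key.get(s.key)
        if j is None:
            unmatched_truth.append(i)
        else:
            pairs.append((i, j))
            matched_imp.add(j)
    unmatched_imp = [j for j in range(len(imputed)) if j not in matched_imp]
    return SiteMatch(pairs, unmatched_truth, unmatched_imp)


# ---------------------------------------------------------------------------
# confusion classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def classify_pair(
    truth_code: int, imputed_code: int, policy: str = "allele-dose"
) -> str:
    """Map one (truth, imputed) genotype pair to TP/FP/FN/TN.

    Under the default allele-dose policy an imputed call asserting *more*
    alternate alleles than the truth is a false positive and one asserting
    fewer is a false negative; exact agreement on a variant genotype is a
    true positive and concordant hom-ref is a true negative.  The two
    alternative policies send both het/hom-alt discordances to FP or to FN
    respectively.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    t, c = int(truth_code), int(imputed_code)
    if t == MISSING or c == MISSING:
        raise ValueError("missing genotype reached classify_pair; "
                         "pre-filter missing pairs")
    if t not in (0, 1, 2) or c not in (0, 1, 2):
        raise ValueError(f"genotype codes must be 0/1/2, got ({t}, {c})")
    if t == c:
        return "TN" if t == 0 else "TP"
    if t == 0:
        return "FP"
    if c == 0:
        return "FN"
    # het/hom-alt discordance
    if policy == "mismatch-to-FP":
        return "FP"
    if policy == "mismatch-to-FN":
        return "FN"
    return "FP" if c > t else "FN"


def confusion(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    pairs: Sequence[tuple[int, int]],
    policy: str = "allele-dose",
    drop_concordant_homref: bool = True,
) -> ConfusionCounts:
    """Tally classify_pair over all matched, non-missing genotype pairs.

    With ``drop_concordant_homref`` (the default), concordant hom-ref pairs
    are excluded before tallying, so TN = 0 — the convention under which
    the ratio metrics describe variant genotypes only.
    """
    if truth.n_samples != imputed.n_samples:
        raise ValueError(
            f"sample count mismatch: {truth.n_samples} vs {imputed.n_samples}"
        )
    ti = np.asarray([p[0] for p in pairs], dtype=np.intp)
    ii = np.asarray([p[1] for p in pairs], dtype=np.intp)
    t = truth.codes[:, ti].ravel()
    c = imputed.codes[:, ii].ravel()
    ok = (t != MISSING) & (c != MISSING)
    t, c = t[ok], c[ok]

    tn_mask = (t == 0) & (c == 0)
    tp = int(np.sum((t == c) & (t > 0)))
    fp_base = int(np.sum((t == 0) & (c > 0)))
    fn_base = int(np.sum((t > 0) & (c == 0)))
    up = int(np.sum((t == 1) & (c == 2)))    # extra alt allele asserted
    down = int(np.sum((t == 2) & (c == 1)))  # alt allele missed
    if policy == "allele-dose":
        fp, fn = fp_base + up, fn_base + down
    elif policy == "mismatch-to-FP":
        fp, fn = fp_base + up + down, fn_base
    elif policy == "mismatch-to-FN":
        fp, fn = fp_base, fn_base + up + down
    else:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    tn = 0 if drop_concordant_homref else int(np.sum(tn_mask))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def ratios(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(tp, fp, fn, tn) each divided by the grand total; sums to 1."""
    if counts.total == 0:
        raise ValueError("empty confusion table: ratios undefined")
    n = counts.total
    return (counts.tp / n, counts.fp / n, counts.fn / n, counts.tn / n)


def precision(counts: ConfusionCounts) -> float:
    """TP/(TP+FP); NaN (with a warning) when no positive calls exist."""
    denom = counts.tp + counts.fp
    if denom == 0:
        warnings.warn("precision undefined: TP+FP = 0", stacklevel=2)
        return math.nan
    return counts.tp / denom


def sensitivity(counts: ConfusionCounts) -> float:
    """TP/(TP+FN); NaN (with a warning) when no truth positives exist."""
    denom = counts.tp + counts.fn
    if denom == 0:
        warnings.warn("sensitivity undefined: TP+FN = 0", stacklevel=2)
        return math.nan
    return counts.tp / denom


def nrc(
    truth: GenotypeMatrix,
    called: GenotypeMatrix,
    pairs: Sequence[tuple[int, int]],
) -> float:
    """Non-reference concordance: genotype-aware recall.

    Over pairs whose truth genotype is non-reference (het or hom-alt), the
    fraction called with the exact same genotype.  Any disagreement —
    including het vs hom-alt — counts against.
    """
    ti = np.asarray([p[0] for p in pairs], dtype=np.intp)
    ii = np.asarray([p[1] for p in pairs], dtype=np.intp)
    t = truth.codes[:, ti].ravel()
    c = called.codes[:, ii].ravel()
    ok = (t != MISSING) & (c != MISSING) & (t > 0)
    if not np.any(ok):
        warnings.warn("NRC undefined: no non-reference truth genotypes",
                      stacklevel=2)
        return math.nan
    return float(np.mean(t[ok] == c[ok]))


# ---------------------------------------------------------------------------
# dosage R^2
# ---------------------------------------------------------------------------

def sample_dosage_r2(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    pairs: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, float]:
    """Per-sample squared Pearson correlation of truth codes vs dosages.

    For each sample the correlation runs across matched sites with both a
    non-missing truth call and a finite imputed dosage.  A sample whose
    truth or dosage vector has zero variance (or fewer than two usable
    sites) is flagged NaN and excluded from the reported mean.
    """
    if imputed.dosage is None:
        raise ValueError("imputed matrix has no dosage layer")
    ti = np.asarray([p[0] for p in pairs], dtype=np.intp)
    ii = np.asarray([p[1] for p in pairs], dtype=np.intp)
    t = truth.codes[:, ti].astype(np.float64)
    d = imputed.dosage[:, ii].astype(np.float64)
    usable = (truth.codes[:, ti] != MISSING) & np.isfinite(d)

    out = np.full(truth.n_samples, np.nan)
    for i in range(truth.n_samples):
        m = usable[i]
        if m.sum() < 2:
            continue
        x, y = t[i, m], d[i, m]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[i] = r * r
    defined = out[np.isfinite(out)]
    if defined.size < out.size:
        warnings.warn(
            f"{out.size - defined.size} sample(s) with undefined R^2 "
            "excluded from the mean", stacklevel=2,
        )
    mean = float(defined.mean()) if defined.size else math.nan
    return out, mean


# ---------------------------------------------------------------------------
# info-score tiers
# ---------------------------------------------------------------------------

def tier_classify(info_score: float) -> str:
    """high (> 0.8), medium ([0.4, 0.8], both ends inclusive) or low (< 0.4)."""
    if not 0.0 <= info_score <= 1.0:
        raise ValueError(f"info score {info_score} outside [0, 1]")
    if info_score > TIER_HIGH_MIN:
        return "high"
    if info_score >= TIER_MEDIUM_MIN:
        return "medium"
    return "low"


@dataclass(frozen=True)
class TierSummary:
    """Variant counts per info-score tier x AF bin (plus derived rates).

    ``medium`` and ``high`` hold one count per AF bin (AF <= 1%,
    1% < AF <= 5%, AF > 5%); the ALL column is their exact integer sum.
    """

    medium: tuple[int, int, int]
    high: tuple[int, int, int]
    low: tuple[int, int, int] = (0, 0, 0)

    @property
    def medium_all(self) -> int:
        return sum(self.medium)

    @property
    def high_all(self) -> int:
        return sum(self.high)

    @property
    def total_well_imputed(self) -> int:
        """Medium-or-better variants over all AF bins."""
        return self.medium_all + self.high_all

    def high_rate(self) -> tuple[float, float, float, float]:
        """high/(high+medium) per AF bin and for the ALL column (NaN if empty)."""
        rates = []
        for m, h in zip(self.medium + (self.medium_all,),
                        self.high + (self.high_all,)):
            rates.append(h / (h + m) if h + m else math.nan)
        return tuple(rates)

    def to_frame(self) -> pd.DataFrame:
        cols = list(AF_BIN_LABELS) + ["ALL"]
        return pd.DataFrame(
            {
                "medium": list(self.medium) + [self.medium_all],
                "high": list(self.high) + [self.high_all],
                "high_rate": list(self.high_rate()),
            },
            index=cols,
        ).T


def tier_summary(
    sites: Sequence[VariantSite] = (),
    afs: Optional[np.ndarray] = None,
    info_scores: Optional[np.ndarray] = None,
    af_bins: tuple[float, float] = (0.01, 0.05),
) -> TierSummary:
    """Count imputed variants per info-score tier within AF bins.

    Accepts either :class:`VariantSite` objects (with ``af`` and
    ``info_score`` annotated) or raw parallel arrays.  AF bins are
    (0, b1], (b1, b2], (b2, 1] with the standard cuts at 1% and 5%.
    """
    if afs is None or info_scores is None:
        afs = np.asarray([s.af1 for s in sites], dtype=float)
        info_scores = np.asarray(
            [math.nan if s.info_score is None else s.info_score for s in sites],
            dtype=float,
        )
    else:
        afs = np.asarray(afs, dtype=float)
        info_scores = np.asarray(info_scores, dtype=float)
    if afs.shape != info_scores.shape:
        raise ValueError("afs and info_scores must be parallel")
    ok = np.isfinite(afs) & np.isfinite(info_scores)
    afs, info_scores = afs[ok], info_scores[ok]
    if np.any((info_scores < 0) | (info_scores > 1)):
        raise ValueError("info scores outside [0, 1]")

    b1, b2 = af_bins
    bin_idx = np.digitize(afs, [b1, b2], right=True)  # 0,1,2
    counts = {tier: [0, 0, 0] for tier in ("low", "medium", "high")}
    tiers = np.where(
        info_scores > TIER_HIGH_MIN, 2,
        np.where(info_scores >= TIER_MEDIUM_MIN, 1, 0),
    )
    for t_idx, name in enumerate(("low", "medium", "high")):
        for b in range(3):
            counts[name][b] = int(np.sum((tiers == t_idx) & (bin_idx == b)))
    return TierSummary(
        medium=tuple(counts["medium"]),
        high=tuple(counts["high"]),
        low=tuple(counts["low"]),
    )


# ---------------------------------------------------------------------------
# cohort-level quality indicators
# ---------------------------------------------------------------------------

def titv(sites: Sequence[VariantSite]) -> float:
    """Transition:transversion ratio over biallelic SNVs.

    Transitions are A<->G and C<->T; every other single-base change is a
    transversion.  Indels are ignored.  NaN (flagged) with zero
    transversions.
    """
    ti = tv = 0
    for s in sites:
        if not s.is_snv() or len(s.alts) != 1:
            continue
        pair = (s.ref.upper(), s.alt.upper())
        if pair in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        warnings.warn("Ti:Tv undefined: no transversions", stacklevel=2)
        return math.nan
    return ti / tv


def het_hom_ratio(genotypes: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Per-sample het:hom-alt genotype-count ratio and the cohort median.

    Samples with zero hom-alt genotypes are flagged NaN and excluded from
    the median.
    """
    het = np.sum(genotypes.codes == 1, axis=1)
    hom = np.sum(genotypes.codes == 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_sample = np.where(hom > 0, het / np.maximum(hom, 1), np.nan)
    defined = per_sample[np.isfinite(per_sample)]
    if defined.size < per_sample.size:
        warnings.warn(
            f"{per_sample.size - defined.size} sample(s) with no hom-alt "
            "genotypes excluded from het:hom median", stacklevel=2,
        )
    median = float(np.median(defined)) if defined.size else math.nan
    return per_sample, median


# ---------------------------------------------------------------------------
# bundled accuracy report
# ---------------------------------------------------------------------------

@dataclass
class AccuracySummary:
    counts: ConfusionCounts
    tp_ratio: float
    fp_ratio: float
    fn_ratio: float
    tn_ratio: float
    precision: float
    sensitivity: float
    nrc: float
    sample_r2: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_r2: float = math.nan


def evaluate(
    truth_sites: Sequence[VariantSite],
    truth: GenotypeMatrix,
    imputed_sites: Sequence[VariantSite],
    imputed: GenotypeMatrix,
    policy: str = "allele-dose",
    drop_concordant_homref: bool = True,
) -> AccuracySummary:
    """One-call evaluation: match, classify, and summarise accuracy."""
    match = match_sites(truth_sites, imputed_sites)
    counts = confusion(truth, imputed, match.pairs, policy=policy,
                       drop_concordant_homref=drop_concordant_homref)
    tp_r, fp_r, fn_r, tn_r = ratios(counts)
    if imputed.dosage is not None:
        r2, mean_r2 = sample_dosage_r2(truth, imputed, match.pairs)
    else:
        r2, mean_r2 = np.array([]), math.nan
    return AccuracySummary(
        counts=counts, tp_ratio=tp_r, fp_ratio=fp_r, fn_ratio=fn_r,
        tn_ratio=tn_r, precision=precision(counts),
        sensitivity=sensitivity(counts),
        nrc=nrc(truth, imputed, match.pairs),
        sample_r2=r2, mean_r2=mean_r2,
    )
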