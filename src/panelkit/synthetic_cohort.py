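"""Synthetic cohort generator with known ground truth.

Everything the pipeline consumes can be simulated here: diploid truth
genotypes at biallelic SNVs drawn under Hardy–Weinberg equilibrium from a
configurable allele-frequency spectrum (optionally with block-copy LD from
a small founder pool), microarray-style site ascertainment, imputed calls
with per-genotype-class miscall rates plus dosage noise and per-site info
scores, null and linear-model phenotypes, per-sample sequencing QC metrics
with planted single-gate failures, and KING-style kinship tables with
planted relative pairs.  All generators are pure functions of their seed.

The defaults emulate a biobank-scale WGS panel at desk scale: a
rare-skewed AF spectrum (beta(0.3, 2) truncated to [0.001, 0.5], matching
a panel in which most variants are rare and tier tables bin at 1% and 5%)
and five causal SNPs with effect sizes (0.02, 0.01, 0.02, 0.03, 0.01) for
the alternative-phenotype model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .vcf_io import MISSING, GenotypeMatrix, KinshipPair, VariantSite

#: Effect sizes of the five default causal SNPs in the alternative
#: phenotype model, in site order.
DEFAULT_CAUSAL_BETAS = (0.02, 0.01, 0.02, 0.03, 0.01)

#: Kinship midpoints of the KING inference intervals used for planted pairs.
KINSHIP_MIDPOINTS = {"duplicate": 0.40, 1: 0.25, 2: 0.1326, 3: 0.0663}

#: Unrelated-pair ceiling (the KING 3rd-degree lower boundary).
UNRELATED_MAX = 2 ** -4.5  # 0.0442

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"),
                  "C": ("A", "G"), "T": ("A", "G")}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AFModel:
    """Allele-frequency spectrum: 'beta' (truncated), 'uniform' or 'fixed'."""

    name: str = "beta"
    params: tuple[float, ...] = (0.3, 2.0, 0.001, 0.5)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.name == "beta":
            a, b, low, high = self.params
            out = np.empty(n)
            filled = 0
            while filled < n:  # rejection sampling onto the truncation window
                draw = rng.beta(a, b, size=2 * (n - filled) + 16)
                keep = draw[(draw >= low) & (draw <= high)]
                take = min(len(keep), n - filled)
                out[filled:filled + take] = keep[:take]
                filled += take
            return out
        if self.name == "uniform":
            low, high = self.params
            return rng.uniform(low, high, size=n)
        if self.name == "fixed":
            (value,) = self.params
            if not 0.0 < value < 1.0:
                raise ValueError(f"fixed AF must lie in (0,1), got {value}")
            return np.full(n, value)
        raise ValueError(f"unknown AF model {self.name!r}")


@dataclass(frozen=True)
class CohortSpec:
    n_samples: int
    n_sites: int
    af_model: AFModel = AFModel()
    ld_block: Optional[int] = None   # sites per founder-copy block
    seed: int = 0
    chrom: str = "1"
    spacing: int = 1_000             # bp between adjacent sites
    n_founders: int = 20

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_sites < 1:
            raise ValueError("n_samples and n_sites must be >= 1")
        if self.ld_block is not None and self.ld_block < 1:
            raise ValueError("ld_block must be >= 1 when set")


@dataclass(frozen=True)
class ErrorModel:
    """Per-genotype-class miscall probabilities plus dosage noise.

    ``e_rr``/``e_ra``/``e_aa`` are the probabilities that a truth
    hom-ref/het/hom-alt genotype is imputed to a *different* class; the
    destination class follows an adjacent-dose kernel (an erroneous hom
    becomes het with probability 0.9, an erroneous het splits evenly).
    ``dosage_sd`` is the s.d. of Gaussian noise added to the imputed hard
    call before truncation to [0, 2].
    """

    e_rr: float = 0.0
    e_ra: float = 0.0
    e_aa: float = 0.0
    dosage_sd: float = 0.0
    hom_to_het: float = 0.9   # adjacent-dose kernel weight

    def __post_init__(self) -> None:
        for name in ("e_rr", "e_ra", "e_aa"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0,1), got {v}")
        if self.dosage_sd < 0:
            raise ValueError("dosage_sd must be >= 0")


@dataclass(frozen=True)
class PhenotypeSpec:
    mode: str = "null"                                  # 'null' | 'alternative'
    causal: tuple[tuple[int, float], ...] = ()          # (site index, beta)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("null", "alternative"):
            raise ValueError(f"mode must be 'null' or 'alternative', "
                             f"got {self.mode!r}")
        if self.mode == "null" and self.causal:
            raise ValueError("null mode admits no causal SNPs")
        for _, beta in self.causal:
            if not math.isfinite(beta):
                raise ValueError(f"non-finite effect size {beta}")


# ---------------------------------------------------------------------------
# truth genotypes
# ---------------------------------------------------------------------------

def _draw_alleles(n_sites: int, rng: np.random.Generator):
    """REF drawn uniformly; ALT is a transition with probability 2/3."""
    refs = rng.choice(_BASES, size=n_sites)
    alts = []
    for r in refs:
        if rng.random() < 2.0 / 3.0:
            alts.append(_TRANSITION[r])
        else:
            alts.append(_TRANSVERSIONS[r][rng.integers(2)])
    return refs, np.array(alts)


def simulate_truth_cohort(
    spec: CohortSpec,
) -> tuple[list[VariantSite], GenotypeMatrix]:
    """Simulate truth genotypes under HWE (or founder-block LD).

    Per site an AF ``p`` is drawn from the spectrum; without ``ld_block``
    genotypes are i.i.d. binomial(2, p).  With ``ld_block`` set, each
    sample haplotype is assembled by copying blocks of ``ld_block``
    consecutive sites from one of ``n_founders`` founder haplotypes, which
    induces LD inside blocks.  AC/AN/AF annotations are recomputed from the
    realized genotypes.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.af_model.draw(spec.n_sites, rng)
    refs, alts = _draw_alleles(spec.n_sites, rng)

    if spec.ld_block is None:
        codes = rng.binomial(2, p, size=(spec.n_samples, spec.n_sites))
    else:
        founders = (rng.random((spec.n_founders, spec.n_sites)) < p
                    ).astype(np.int8)
        n_blocks = -(-spec.n_sites // spec.ld_block)
        picks = rng.integers(0, spec.n_founders,
                             size=(spec.n_samples, 2, n_blocks))
        block_of = np.arange(spec.n_sites) // spec.ld_block
        h1 = founders[picks[:, 0, :][:, block_of], np.arange(spec.n_sites)]
        h2 = founders[picks[:, 1, :][:, block_of], np.arange(spec.n_sites)]
        codes = h1 + h2
    codes = codes.astype(np.int8)

    sites = []
    for j in range(spec.n_sites):
        col = codes[:, j]
        ac, an = int(col.sum()), 2 * spec.n_samples
        sites.append(VariantSite(
            chrom=spec.chrom, pos=(j + 1) * spec.spacing, id=f"snp{j}",
            ref=str(refs[j]), alts=(str(alts[j]),),
        ).with_counts((ac,), an))
    matrix = GenotypeMatrix(
        codes=codes,
        samples=[f"S{i:05d}" for i in range(spec.n_samples)],
    )
    return sites, matrix


def select_array_sites(
    sites: Sequence[VariantSite],
    n_array: int,
    maf_min: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Uniform random subset of sites with MAF >= ``maf_min``, position-sorted.

    Emulates microarray ascertainment, which targets common variation.
    """
    mafs = np.array([min(s.af1, 1 - s.af1) for s in sites])
    eligible = np.flatnonzero(mafs >= maf_min)
    if n_array > eligible.size:
        raise ValueError(
            f"requested {n_array} array sites but only {eligible.size} of "
            f"{len(sites)} sites have MAF >= {maf_min}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_array, replace=False)
    return np.sort(chosen)


# ---------------------------------------------------------------------------
# imputation-error injection
# ---------------------------------------------------------------------------

def compute_info_score(
    dosages: np.ndarray, estimated_af: Optional[float] = None
) -> float:
    """Variance-ratio information score from a vector of dosages.

    ``var(dosage) / (2 p (1-p))`` with ``p = mean(dosage)/2`` (or the
    supplied estimate), clipped to [0, 1].  Monomorphic input (p in {0,1})
    scores 0 by definition.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("empty dosage vector")
    if d.size < 2:
        raise ValueError("need at least 2 dosage values")
    p = float(np.mean(d) / 2.0) if estimated_af is None else float(estimated_af)
    if p <= 0.0 or p >= 1.0:
        return 0.0
    score = float(np.var(d) / (2.0 * p * (1.0 - p)))
    return min(1.0, max(0.0, score))


def _empirical_r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(min(1.0, max(0.0, r * r)))


def simulate_imputed(
    truth: GenotypeMatrix,
    sites: Sequence[VariantSite],
    model: ErrorModel,
    seed: int = 0,
) -> tuple[list[VariantSite], GenotypeMatrix]:
    """Inject class-conditional miscalls and dosage noise into truth calls.

    Each non-missing genotype is independently miscalled with its class
    probability, the destination drawn from the adjacent-dose kernel.  The
    dosage layer is the imputed hard call plus truncated Gaussian noise.
    Each site is annotated with an info score — the squared Pearson
    correlation between the emitted dosages and the imputed hard calls —
    which is exactly 1 for a polymorphic site at zero noise and degrades as
    ``dosage_sd`` grows; AC/AN/AF are recomputed from the imputed calls.
    """
    rng = np.random.default_rng(seed)
    codes = truth.codes.copy()
    n, s = codes.shape

    err_p = np.zeros_like(codes, dtype=float)
    err_p[codes == 0] = model.e_rr
    err_p[codes == 1] = model.e_ra
    err_p[codes == 2] = model.e_aa
    err_p[codes == MISSING] = 0.0
    flip = rng.random((n, s)) < err_p
    kernel_draw = rng.random((n, s))

    out = codes.copy()
    w = model.hom_to_het
    m0 = flip & (codes == 0)
    out[m0] = np.where(kernel_draw[m0] < w, 1, 2)
    m1 = flip & (codes == 1)
    out[m1] = np.where(kernel_draw[m1] < 0.5, 0, 2)
    m2 = flip & (codes == 2)
    out[m2] = np.where(kernel_draw[m2] < w, 1, 0)

    dosage = out.astype(np.float32)
    dosage[out == MISSING] = np.nan
    noise = rng.normal(0.0, model.dosage_sd, size=(n, s)).astype(np.float32)
    if model.dosage_sd > 0:
        dosage = np.clip(dosage + noise, 0.0, 2.0)

    imputed_sites = []
    for j, site in enumerate(sites):
        col = out[:, j]
        ok = col != MISSING
        ac, an = int(col[ok].sum()), int(2 * ok.sum())
        info = _empirical_r2(dosage[ok, j], col[ok].astype(float))
        new = VariantSite(
            chrom=site.chrom, pos=site.pos, id=site.id, ref=site.ref,
            alts=site.alts, excess_het=site.excess_het, filter=site.filter,
            info_score=info,
        )
        imputed_sites.append(new.with_counts((ac,), an) if an else new)

    matrix = GenotypeMatrix(
        codes=out, samples=list(truth.samples), dosage=dosage,
    )
    return imputed_sites, matrix


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotype(
    genotypes: GenotypeMatrix, spec: PhenotypeSpec
) -> np.ndarray:
    """Null phenotypes ~ N(0,1); alternative y = sum(beta_j g_j) + noise.

    Missing genotype codes contribute zero to the genetic value.  With all
    betas zero and ``noise_sd`` 1 the alternative construction reduces
    bit-for-bit to the null draw at the same seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = genotypes.n_samples
    if spec.mode == "null":
        return rng.standard_normal(n)
    y = np.zeros(n)
    for idx, beta in spec.causal:
        if not 0 <= idx < genotypes.n_sites:
            raise IndexError(
                f"causal site index {idx} out of range "
                f"[0, {genotypes.n_sites})"
            )
        g = genotypes.codes[:, idx].astype(float)
        g[genotypes.codes[:, idx] == MISSING] = 0.0
        y += beta * g
    return y + rng.normal(0.0, spec.noise_sd, size=n)


def default_phenotype_spec(
    sites: Sequence[VariantSite],
    noise_sd: float = 1.0,
    seed: int = 0,
    maf_min: float = 0.2,
    scale: float = 1.0,
) -> PhenotypeSpec:
    """Alternative-model spec with the five default causal effects.

    The five causal sites are spread evenly across the common
    (MAF >= ``maf_min``) sites so that each lands in its own genomic
    neighbourhood; ``scale`` multiplies every default effect size.
    """
    mafs = np.array([min(s.af1, 1 - s.af1) for s in sites])
    eligible = np.flatnonzero(mafs >= maf_min)
    k = len(DEFAULT_CAUSAL_BETAS)
    if eligible.size < k:
        raise ValueError(
            f"need {k} sites with MAF >= {maf_min}, found {eligible.size}"
        )
    picks = eligible[np.linspace(0, eligible.size - 1, k).round().astype(int)]
    causal = tuple(
        (int(i), scale * b) for i, b in zip(picks, DEFAULT_CAUSAL_BETAS)
    )
    return PhenotypeSpec(mode="alternative", causal=causal,
                         noise_sd=noise_sd, seed=seed)


def power_calibrated_scale(
    mafs: Sequence[float],
    betas: Sequence[float] = DEFAULT_CAUSAL_BETAS,
    n_samples: int = 2000,
    noise_sd: float = 1.0,
    ncp_target: float = 73.0,
) -> float:
    """Effect-size multiplier giving each causal SNP a target non-centrality.

    For a single-SNP test of causal SNP *j* in a phenotype built from all
    the causal SNPs, the non-centrality is
    ``(c b_j)^2 v_j n / (sigma^2 + c^2 sum_{k != j} b_k^2 v_k)`` with
    ``v_j = 2 p_j (1 - p_j)`` — the *other* causal SNPs inflate the
    residual.  Solves for the common multiplier ``c`` by fixed point so
    the weakest SNP reaches ``ncp_target`` (73 corresponds to power
    ~0.999 at the genome-wide 5e-8 threshold).
    """
    v = np.array([2 * m * (1 - m) for m in mafs])
    b = np.asarray(betas, dtype=float)
    if v.shape != b.shape:
        raise ValueError("one MAF per causal effect required")
    bv = b * b * v
    total = bv.sum()
    c2 = ncp_target * noise_sd ** 2 / (bv.min() * n_samples)
    for _ in range(100):
        need = ncp_target * (noise_sd ** 2 + c2 * (total - bv)) / (
            bv * n_samples)
        new = float(need.max())
        if abs(new - c2) < 1e-12 * max(1.0, c2):
            c2 = new
            break
        c2 = new
    return math.sqrt(c2)


# ---------------------------------------------------------------------------
# sample metrics and kinship
# ---------------------------------------------------------------------------

_GATES = ("contamination", "duplication", "depth", "gc")


def simulate_sample_metrics(
    n: int,
    fail_fraction_per_gate: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample QC metric table with planted single-gate failures.

    Passing samples are drawn uniformly inside the acceptance region
    (freemix < 0.03, dup < 0.05, depth in [10, 40], GC in [40, 44]); a
    planted failure violates exactly its named gate and no other.  The
    ``planted_failure`` column carries the truth label ('' for clean
    samples).
    """
    fracs = np.asarray(fail_fraction_per_gate, dtype=float)
    if fracs.shape != (4,) or np.any(fracs < 0) or fracs.sum() > 1:
        raise ValueError("need four per-gate fractions with sum <= 1")
    rng = np.random.default_rng(seed)
    category = rng.choice(5, size=n, p=[1 - fracs.sum(), *fracs])

    freemix = rng.uniform(0.0, 0.029, size=n)
    dup = rng.uniform(0.0, 0.049, size=n)
    depth = rng.uniform(10.0, 40.0, size=n)
    gc = rng.uniform(40.0, 44.0, size=n)

    freemix[category == 1] = rng.uniform(0.03, 0.10, size=(category == 1).sum())
    dup[category == 2] = rng.uniform(0.05, 0.20, size=(category == 2).sum())
    depth[category == 3] = rng.uniform(2.0, 9.99, size=(category == 3).sum())
    gc_fail = category == 4
    low_side = rng.random(gc_fail.sum()) < 0.5
    gc[gc_fail] = np.where(low_side,
                           rng.uniform(36.0, 39.99, size=gc_fail.sum()),
                           rng.uniform(44.01, 48.0, size=gc_fail.sum()))

    return pd.DataFrame({
        "sample": [f"S{i:05d}" for i in range(n)],
        "freemix": freemix,
        "dup_rate": dup,
        "mean_depth": depth,
        "gc": gc,
        "planted_failure": ["" if c == 0 else _GATES[c - 1] for c in category],
    })


def simulate_kinship_pairs(
    sample_ids: Sequence[str],
    planted: Sequence[tuple[tuple[str, str], object]] = (),
    background_sd: float = 0.01,
    seed: int = 0,
) -> list[KinshipPair]:
    """All unordered sample pairs with planted relatives on a noise floor.

    Planted pairs receive the midpoint kinship of their KING degree
    interval (duplicate 0.40, 1st 0.25, 2nd 0.1326, 3rd 0.0663); every
    other pair gets ``|N(0, background_sd)|`` capped strictly below the
    unrelated boundary 0.0442.
    """
    rng = np.random.default_rng(seed)
    planted_map: dict[tuple[str, str], float] = {}
    for (a, b), degree in planted:
        if degree not in KINSHIP_MIDPOINTS:
            raise ValueError(
                f"unknown degree {degree!r}; known: "
                f"{sorted(map(str, KINSHIP_MIDPOINTS))}"
            )
        planted_map[tuple(sorted((a, b)))] = KINSHIP_MIDPOINTS[degree]

    pairs: list[KinshipPair] = []
    ids = list(sample_ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            key = tuple(sorted((ids[i], ids[j])))
            if key in planted_map:
                k = planted_map[key]
            else:
                k = min(abs(rng.normal(0.0, background_sd)),
                        UNRELATED_MAX - 1e-4)
            pairs.append(KinshipPair(ids[i], ids[j], float(k)))
    return pairs
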